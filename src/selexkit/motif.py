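"""Top-k-mer selection, representative bound sequences, anchored motifs.

The motif stage mirrors how SELEX-seq studies summarize specificity: take
the top fraction (default 0.1%) of k-mers by relative affinity, find for
each the most recurrent full-length library sequence containing it, and
summarize those sequences. The package exports them as MEME-ready FASTA
and additionally builds a simple anchored position frequency matrix: each
representative is aligned by pinning its first occurrence of the k-mer,
extended by ``flank`` bases on both sides (positions running off a read
contribute a flat 1/4 per base), and accumulated with the k-mer's
relative affinity as weight.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import seq
from .affinity import AffinityTable
from .reads import RoundReads

MOTIF_FORMATS = ("meme", "jaspar")
ROW_BASES = "ACGT"


@dataclass
class TopKmerSet:
    """The highest-affinity words of one condition, affinity-sorted."""

    words: list[str]
    affinities: list[float]
    selection_fraction: float
    universe: str
    universe_size: int
    tie_policy: str = "lexicographic"


@dataclass
class MotifMatrix:
    """Anchored position frequency matrix (rows A, C, G, T)."""

    width: int
    counts: np.ndarray  # (4, width)
    n_contributing: int
    anchor_offset: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (4, self.width):
            raise ValueError("counts must have shape (4, width)")
        col = self.counts.sum(axis=0)
        if col.size and np.abs(col - col[0]).max() > 1e-9 * max(col[0], 1.0):
            raise ValueError("column totals must be equal")

    @property
    def probabilities(self) -> np.ndarray:
        total = self.counts.sum(axis=0)
        return self.counts / total

    def consensus(self) -> str:
        """Column-majority base at each position."""
        return "".join(ROW_BASES[i] for i in self.counts.argmax(axis=0))

    def information_content(self) -> np.ndarray:
        p = self.probabilities
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(p > 0, -p * np.log2(p), 0.0).sum(axis=0)
        return 2.0 - h


def top_kmers(table: AffinityTable, fraction: float = 0.001,
              universe: str = "observed") -> TopKmerSet:
    """Select the ceil(fraction * universe) highest-affinity words.

    universe="observed": words passing the table's min-count filter (the
    default — observed top-set sizes then vary with sequencing depth);
    universe="possible": all 4^k words. Boundary ties break
    lexicographically (the smaller word is kept).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if universe == "observed":
        idx = table.observed_indices()
    elif universe == "possible":
        idx = np.arange(4 ** table.k, dtype=np.int64)
        if table.strand_mode == "collapsed":
            idx = np.unique(seq.canonical_index(idx, table.k))
    else:
        raise ValueError("universe must be 'observed' or 'possible'")
    if idx.size == 0:
        raise ValueError("empty affinity table")
    n_sel = math.ceil(fraction * idx.size)
    aff = table.rel_affinity[idx]
    order = np.lexsort((idx, -aff))[:n_sel]
    chosen = idx[order]
    return TopKmerSet(words=seq.indices_to_words(chosen, table.k),
                      affinities=[float(a) for a in table.rel_affinity[chosen]],
                      selection_fraction=fraction, universe=universe,
                      universe_size=int(idx.size))


class _WindowLookup:
    """Sorted window-index table for fast 'which reads contain word w'."""

    def __init__(self, reads: RoundReads, k: int):
        idx = seq.window_indices(reads.codes(), k)
        n, wins = idx.shape
        flat = idx.ravel()
        self.order = np.argsort(flat, kind="stable")
        self.sorted = flat[self.order]
        self.rows = (self.order // wins).astype(np.int64)

    def rows_containing(self, word_idx: int) -> np.ndarray:
        lo = np.searchsorted(self.sorted, word_idx, side="left")
        hi = np.searchsorted(self.sorted, word_idx, side="right")
        return np.unique(self.rows[lo:hi])


def representative_sequences(words: list[str], reads: RoundReads,
                             strand_mode: str = "collapsed") -> dict[str, str | None]:
    """Most recurrent read containing each word.

    In collapsed mode a read matching only the reverse complement of the
    word contributes its own reverse complement (the forward-oriented
    copy with respect to the word). Multiplicity is the exact multiplicity
    of the read as sequenced; ties break to the lexicographically smaller
    oriented sequence. Words contained in no read map to None.
    """
    if not words:
        return {}
    k = len(words[0])
    from collections import Counter

    multiplicity = Counter(reads.sequences)
    lookup = _WindowLookup(reads, k)
    out: dict[str, str | None] = {}
    for word in words:
        widx = seq.word_to_index(word)
        candidates: list[tuple[int, str]] = []
        seen_rows: set[int] = set()
        for query, orient_rc in ((widx, False),) + (
                ((seq.revcomp_index(widx, k), True),) if strand_mode == "collapsed"
                and seq.revcomp_index(widx, k) != widx else ()):
            for row in lookup.rows_containing(query):
                if row in seen_rows:
                    continue
                seen_rows.add(int(row))
                read = reads.sequences[row]
                oriented = read if word in read else seq.revcomp(read)
                candidates.append((multiplicity[read], oriented))
        if not candidates:
            out[word] = None
            continue
        best = max(candidates, key=lambda t: (t[0], [-ord(c) for c in t[1]]))
        out[word] = best[1]
    return out


def representative_sequence(word: str, reads: RoundReads,
                            strand_mode: str = "collapsed") -> str | None:
    return representative_sequences([word], reads, strand_mode)[word]


def build_anchored_pfm(top: TopKmerSet, table: AffinityTable, flank: int,
                       reps: dict[str, str | None],
                       weighted: bool = True) -> MotifMatrix:
    """Accumulate representatives into a PFM anchored on the k-mer.

    Each representative is aligned so its first occurrence of the word
    starts at column ``flank``; positions outside the read contribute a
    flat 0.25 to every base. Contribution weight is the word's relative
    affinity (or 1 when unweighted). Column totals equal the summed
    weights by construction.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    k = table.k
    width = k + 2 * flank
    counts = np.zeros((4, width), dtype=float)
    n_contributing = 0
    for word, aff in zip(top.words, top.affinities):
        rep = reps.get(word)
        if rep is None:
            continue
        pos = rep.find(word)
        if pos < 0:
            continue
        weight = aff if weighted else 1.0
        start = pos - flank
        for col in range(width):
            i = start + col
            if 0 <= i < len(rep):
                counts[seq.word_to_index(rep[i]), col] += weight
            else:
                counts[:, col] += weight / 4.0
        n_contributing += 1
    if n_contributing == 0:
        raise ValueError("no representative available for any selected word")
    return MotifMatrix(width=width, counts=counts,
                       n_contributing=n_contributing, anchor_offset=flank)


def write_representatives_fasta(top: TopKmerSet,
                                reps: dict[str, str | None],
                                path: str | Path) -> int:
    """MEME-ready FASTA of representatives (header: word + affinity).

    Returns the number of sequences written; words with no representative
    are skipped.
    """
    n = 0
    with open(path, "w") as fh:
        for word, aff in zip(top.words, top.affinities):
            rep = reps.get(word)
            if rep is None:
                continue
            fh.write(f">{word} rel_affinity={aff:.10g}\n{rep}\n")
            n += 1
    return n


# ----------------------------------------------------------------- formats

def export_motif(matrix: MotifMatrix, path: str | Path, fmt: str = "meme",
                 name: str = "selexkit_motif") -> None:
    if fmt == "meme":
        _write_meme(matrix, path, name)
    elif fmt == "jaspar":
        _write_jaspar(matrix, path, name)
    else:
        raise ValueError(f"unknown motif format {fmt!r}; choose from {MOTIF_FORMATS}")


def _write_meme(matrix: MotifMatrix, path: str | Path, name: str) -> None:
    p = matrix.probabilities
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A 0.25 C 0.25 G 0.25 T 0.25\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write(f"letter-probability matrix: alength= 4 w= {matrix.width} "
                 f"nsites= {matrix.n_contributing} E= 0\n")
        for col in range(matrix.width):
            fh.write(" " + " ".join(f"{p[row, col]:.6f}" for row in range(4)) + "\n")


def _write_jaspar(matrix: MotifMatrix, path: str | Path, name: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for row, base in enumerate(ROW_BASES):
            vals = " ".join(f"{matrix.counts[row, col]:.6f}"
                            for col in range(matrix.width))
            fh.write(f"{base} [ {vals} ]\n")


def read_motif(path: str | Path, fmt: str = "meme") -> MotifMatrix:
    """Read back a motif written by export_motif (lossless round trip at
    the printed precision)."""
    text = Path(path).read_text()
    if fmt == "meme":
        m = re.search(r"letter-probability matrix: alength= 4 w= (\d+) "
                      r"nsites= (\d+) E= \S+\n", text)
        if not m:
            raise ValueError("not a MEME-minimal motif file")
        width, nsites = int(m.group(1)), int(m.group(2))
        rows = []
        for line in text[m.end():].strip().splitlines()[:width]:
            rows.append([float(v) for v in line.split()])
        probs = np.array(rows).T
        return MotifMatrix(width=width, counts=probs * nsites,
                           n_contributing=nsites, anchor_offset=0)
    if fmt == "jaspar":
        counts = []
        for base in ROW_BASES:
            m = re.search(rf"^{base} \[ (.*) \]$", text, flags=re.M)
            if not m:
                raise ValueError("not a JASPAR PFM file")
            counts.append([float(v) for v in m.group(1).split()])
        arr = np.array(counts)
        return MotifMatrix(width=arr.shape[1], counts=arr,
                           n_contributing=0, anchor_offset=0)
    raise ValueError(f"unknown motif format {fmt!r}")
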