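"""k-mer counting over selection rounds, and CArG-box prevalence.

Counting is per-window: a read of length L contributes L-k+1 windows.
Two strand conventions are supported. ``single`` counts every window as
read. ``collapsed`` (the default throughout the pipeline) maps each
window to the lexicographically smaller of the word and its reverse
complement before counting — appropriate for a double-stranded library
bound by a protein dimer that cannot distinguish the two strands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import seq
from .reads import RoundReads

CARG_PATTERN = "CCWWWWWWGG"

STRAND_MODES = ("single", "collapsed")


@dataclass
class KmerTable:
    """Dense per-word window counts for one round.

    ``counts`` is indexed by the 2-bit packed word index; in collapsed
    mode all mass sits on canonical (lexicographically minimal) indices.
    Sum of counts always equals ``total_windows``.
    """

    k: int
    strand_mode: str
    counts: np.ndarray
    total_windows: int
    n_reads: int
    round_index: int | None = None
    condition_label: str = ""

    def __post_init__(self) -> None:
        if self.strand_mode not in STRAND_MODES:
            raise ValueError(f"strand_mode must be one of {STRAND_MODES}")
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (4 ** self.k,):
            raise ValueError("counts must be a dense array over all 4^k words")

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.total_windows

    def count(self, word: str) -> int:
        idx = seq.word_to_index(word)
        if self.strand_mode == "collapsed":
            idx = seq.canonical_index(idx, self.k)
        return int(self.counts[idx])

    def frequency(self, word: str) -> float:
        return self.count(word) / self.total_windows

    # ------------------------------------------------------------------ io
    def to_tsv(self, path: str | Path) -> None:
        """Sparse TSV (word, count, frequency) with a metadata header block."""
        nz = np.flatnonzero(self.counts)
        words = seq.indices_to_words(nz, self.k)
        with open(path, "w") as fh:
            fh.write(f"# k={self.k}\n# strand_mode={self.strand_mode}\n")
            fh.write(f"# total_windows={self.total_windows}\n# n_reads={self.n_reads}\n")
            fh.write(f"# round_index={self.round_index}\n")
            fh.write(f"# condition_label={self.condition_label}\n")
            fh.write("word\tcount\tfrequency\n")
            for w, i in zip(words, nz):
                c = int(self.counts[i])
                fh.write(f"{w}\t{c}\t{c / self.total_windows:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KmerTable":
        meta: dict[str, str] = {}
        rows: list[tuple[str, int]] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    meta[key] = val
                elif line and not line.startswith("word\t"):
                    w, c, _ = line.split("\t")
                    rows.append((w, int(c)))
        k = int(meta["k"])
        counts = np.zeros(4 ** k, dtype=np.int64)
        for w, c in rows:
            counts[seq.word_to_index(w)] = c
        round_index = None if meta.get("round_index") in (None, "None") else int(meta["round_index"])
        return cls(k=k, strand_mode=meta["strand_mode"], counts=counts,
                   total_windows=int(meta["total_windows"]), n_reads=int(meta["n_reads"]),
                   round_index=round_index, condition_label=meta.get("condition_label", ""))


def count_kmers(reads: RoundReads, k: int, strand_mode: str = "collapsed") -> KmerTable:
    """Count all length-k windows of a round's variable regions."""
    if strand_mode not in STRAND_MODES:
        raise ValueError(f"strand_mode must be one of {STRAND_MODES}")
    codes = reads.codes()
    if codes.shape[1] < k:
        raise ValueError(f"k={k} exceeds read length {codes.shape[1]}")
    idx = seq.window_indices(codes, k).ravel()
    if strand_mode == "collapsed":
        idx = seq.canonical_index(idx, k)
    counts = np.bincount(idx, minlength=4 ** k).astype(np.int64)
    return KmerTable(k=k, strand_mode=strand_mode, counts=counts,
                     total_windows=int(idx.size), n_reads=len(reads),
                     round_index=reads.round_index,
                     condition_label=reads.condition_label)


_carg_mask_cache: np.ndarray | None = None


def _carg_mask() -> np.ndarray:
    global _carg_mask_cache
    if _carg_mask_cache is None:
        # the CArG box is its own degenerate reverse complement, so scanning
        # the forward strand alone finds every double-stranded occurrence
        assert seq.iupac_revcomp(CARG_PATTERN) == CARG_PATTERN
        _carg_mask_cache = seq.pattern_mask(CARG_PATTERN)
    return _carg_mask_cache


def carg_prevalence(reads: RoundReads) -> tuple[float, dict[str, int]]:
    """Fraction of reads containing >=1 perfect CArG box (CC[A/T]6GG).

    Returns the prevalence and the per-variant window-occurrence counts of
    the 64 concrete CArG words (overlapping occurrences all counted).
    """
    k = len(CARG_PATTERN)
    codes = reads.codes()
    if codes.shape[1] < k:
        raise ValueError(f"reads shorter than the {k} bp CArG box")
    mask = _carg_mask()
    idx = seq.window_indices(codes, k)
    hit = mask[idx]
    prevalence = float(hit.any(axis=1).mean())
    variant_idx = idx[hit]
    variant_counts = {}
    if variant_idx.size:
        uniq, cnt = np.unique(variant_idx, return_counts=True)
        variant_counts = dict(zip(seq.indices_to_words(uniq, k), cnt.astype(int).tolist()))
    return prevalence, variant_counts


def expected_carg_prevalence(length: int) -> float:
    """Closed-form CArG prevalence of uniform random reads, treating the
    length-10 windows as independent (a very good approximation)."""
    q = 64 / 4 ** 10
    return 1.0 - (1.0 - q) ** (length - 10 + 1)
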