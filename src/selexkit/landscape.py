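"""Ground-truth binding-affinity landscapes for the SELEX simulator.

A landscape assigns every DNA word of length ``k`` a relative affinity in
(0, 1], with the best word(s) at exactly 1. The default family is a
mismatch-energy model around a degenerate consensus: each position where a
word violates the consensus multiplies its affinity by a fixed penalty
factor. With the CArG-box consensus ``CCWWWWWWGG`` (the MADS-domain
binding site CC[A/T]6GG) this gives a smooth, strand-symmetric truth that
downstream estimators are asked to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import seq

CARG_CONSENSUS = "CCWWWWWWGG"


@dataclass
class AffinityLandscape:
    """Per-word relative affinities, stored densely over all 4^k words.

    Attributes
    ----------
    k : word length.
    values : float array of shape (4**k,), all strictly positive, max == 1.
    strand_symmetric : True if affinity(w) == affinity(revcomp(w)) for all w.
    description : provenance note (consensus/factor for mismatch landscapes).
    """

    k: int
    values: np.ndarray
    strand_symmetric: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (4 ** self.k,):
            raise ValueError(f"values must have shape (4**{self.k},)")
        if not np.all(self.values > 0):
            raise ValueError("all affinities must be strictly positive")
        if not np.isclose(self.values.max(), 1.0, rtol=0, atol=1e-12):
            raise ValueError("maximum affinity must equal 1")

    def strand_max_values(self) -> np.ndarray:
        """Per-word max of the affinity of the word and its reverse
        complement — the score a window contributes regardless of which
        strand carries it. Cached (4^k array)."""
        cached = getattr(self, "_strand_max", None)
        if cached is None:
            rc = seq.revcomp_index(np.arange(4 ** self.k, dtype=np.int64), self.k)
            cached = np.maximum(self.values, self.values[rc])
            self._strand_max = cached
        return cached

    def affinity(self, word: str) -> float:
        if len(word) != self.k:
            raise ValueError(f"word length {len(word)} != k={self.k}")
        return float(self.values[seq.word_to_index(word)])

    @classmethod
    def from_table(cls, table: dict[str, float], k: int | None = None,
                   **kwargs) -> "AffinityLandscape":
        """Extensional landscape; words absent from the table get the minimum
        tabulated affinity (keeps every value strictly positive)."""
        if not table:
            raise ValueError("empty affinity table")
        if k is None:
            k = len(next(iter(table)))
        vals = np.full(4 ** k, min(table.values()), dtype=float)
        for w, a in table.items():
            if len(w) != k:
                raise ValueError(f"word {w!r} does not have length {k}")
            if not 0 < a <= 1:
                raise ValueError(f"affinity of {w!r} outside (0, 1]")
            vals[seq.word_to_index(w)] = a
        return cls(k=k, values=vals, **kwargs)


def make_landscape(consensus: str = CARG_CONSENSUS, mismatch_factor: float = 0.3,
                   k: int | None = None) -> AffinityLandscape:
    """Mismatch-penalty landscape around a degenerate IUPAC consensus.

    affinity(w) = mismatch_factor ** (number of positions of w that fall
    outside the consensus letter's allowed bases). Words matching the
    consensus everywhere score exactly 1.
    """
    consensus = consensus.upper()
    if k is None:
        k = len(consensus)
    if len(consensus) != k:
        raise ValueError(f"consensus length {len(consensus)} != k={k}")
    if not 0 < mismatch_factor < 1:
        raise ValueError("mismatch_factor must lie in (0, 1)")
    n = 4 ** k
    mismatches = np.zeros(n, dtype=np.int16)
    idx = np.arange(n, dtype=np.int64)
    for j, letter in enumerate(consensus):
        try:
            allowed = seq.IUPAC_CODES[letter]
        except KeyError as exc:
            raise ValueError(f"non-IUPAC character {letter!r} in consensus") from exc
        digit = (idx >> (2 * (k - 1 - j))) & 3
        mismatches += ~np.isin(digit, list(allowed))
    values = np.power(mismatch_factor, mismatches, dtype=float)
    symmetric = seq.iupac_revcomp(consensus) == consensus
    return AffinityLandscape(
        k=k, values=values, strand_symmetric=symmetric,
        description=f"mismatch(consensus={consensus}, factor={mismatch_factor})",
    )


def constant_landscape(k: int = 10) -> AffinityLandscape:
    """Null landscape: every word binds equally (no enrichment)."""
    return AffinityLandscape(k=k, values=np.ones(4 ** k), strand_symmetric=True,
                             description="constant")


def score_matrix(codes: np.ndarray, landscape: AffinityLandscape) -> np.ndarray:
    """Best-window score for each row of an (n, L) code matrix.

    The score of a read is the maximum landscape affinity over every
    length-k window on either strand; because the reverse complement of a
    read exposes exactly the reverse complements of its forward windows,
    both strands are covered by also scoring each window's revcomp.
    """
    idx = seq.window_indices(codes, landscape.k)
    return landscape.strand_max_values()[idx].max(axis=-1)


def score_sequence(sequence: str, landscape: AffinityLandscape) -> float:
    """Score one read: max affinity over all windows of both strands."""
    if len(sequence) < landscape.k:
        raise ValueError(
            f"sequence length {len(sequence)} shorter than k={landscape.k}")
    return float(score_matrix(seq.encode(sequence), landscape))
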