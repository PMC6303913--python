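"""Order-m Markov background model of the unselected (Round 0) library.

A randomized 40-nt library holds ~4^10 times more distinct 10-mers than a
Round-0 sequencing run has windows, so 10-mer background frequencies
cannot be counted directly. Following standard SELEX practice they are
instead *predicted* from a sixth-order Markov chain fitted to Round 0:
every length-m window estimates the initial m-mer law, every length-(m+1)
window estimates the conditional next-base law, and any k-mer probability
follows exactly by the chain rule — no sampling is involved.

Strand handling: with ``strand_mode="collapsed"`` the training windows
include both strands of every read, and a word is evaluated as the mean
of the chain-rule probabilities of the word and its reverse complement.
This makes P(w) == P(revcomp(w)) hold exactly (the raw chain rule only
achieves it up to read-edge effects) while remaining a proper probability
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import seq
from .kmers import KmerTable
from .reads import RoundReads


@dataclass
class MarkovModel:
    """Fitted order-m background model.

    Attributes
    ----------
    order : context length m (default 6 in the pipeline).
    initial : (4**m,) probability of each starting m-mer; sums to 1.
    transitions : (4**m, 4) row-stochastic next-base probabilities.
    alpha : additive pseudocount used per count cell during fitting.
    strand_mode : "single" or "collapsed" (see module docstring).
    """

    order: int
    initial: np.ndarray
    transitions: np.ndarray
    alpha: float = 0.0
    strand_mode: str = "single"

    def __post_init__(self) -> None:
        m = self.order
        if m < 1:
            raise ValueError("order must be >= 1")
        self.initial = np.asarray(self.initial, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        if self.initial.shape != (4 ** m,):
            raise ValueError("initial must have shape (4**m,)")
        if self.transitions.shape != (4 ** m, 4):
            raise ValueError("transitions must have shape (4**m, 4)")
        if abs(self.initial.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution must sum to 1")
        rows = self.transitions.sum(axis=1)
        if np.abs(rows - 1.0).max() > 1e-9:
            raise ValueError("every transition row must sum to 1")
        if (self.initial < 0).any() or (self.transitions < 0).any():
            raise ValueError("probabilities must be nonnegative")

    # ------------------------------------------------------------ evaluation
    def _chain_prob(self, idx: np.ndarray, k: int) -> np.ndarray:
        """Raw chain-rule probability of the words with packed indices idx."""
        m = self.order
        ctx_mask = 4 ** m - 1
        p = self.initial[idx >> (2 * (k - m))]
        for i in range(m, k):
            ctx = (idx >> (2 * (k - i))) & ctx_mask
            base = (idx >> (2 * (k - 1 - i))) & 3
            p = p * self.transitions[ctx, base]
        return p

    def kmer_prob_array(self, idx: np.ndarray, k: int) -> np.ndarray:
        """Vectorized model probability of length-k words given as indices."""
        if k < self.order:
            raise ValueError(f"word length {k} shorter than model order {self.order}")
        idx = np.asarray(idx, dtype=np.int64)
        p = self._chain_prob(idx, k)
        if self.strand_mode == "collapsed":
            p = 0.5 * (p + self._chain_prob(seq.revcomp_index(idx, k), k))
        return p

    def kmer_prob(self, word: str) -> float:
        return float(self.kmer_prob_array(np.array([seq.word_to_index(word)]),
                                          len(word))[0])

    def all_kmer_probs(self, k: int) -> np.ndarray:
        """Probabilities of all 4^k words, in lexicographic order."""
        return self.kmer_prob_array(np.arange(4 ** k, dtype=np.int64), k)

    # ------------------------------------------------------------------- io
    def to_tsv(self, path: str | Path) -> None:
        m = self.order
        contexts = seq.indices_to_words(np.arange(4 ** m), m)
        with open(path, "w") as fh:
            fh.write(f"# order={m}\n# alpha={self.alpha!r}\n")
            fh.write(f"# strand_mode={self.strand_mode}\n")
            fh.write("context\tinitial\tA\tC\tG\tT\n")
            for i, c in enumerate(contexts):
                row = "\t".join(f"{v:.17g}" for v in self.transitions[i])
                fh.write(f"{c}\t{self.initial[i]:.17g}\t{row}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MarkovModel":
        meta: dict[str, str] = {}
        initial, rows = [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    meta[key] = val
                elif line and not line.startswith("context\t"):
                    parts = line.split("\t")
                    initial.append(float(parts[1]))
                    rows.append([float(v) for v in parts[2:6]])
        return cls(order=int(meta["order"]), initial=np.array(initial),
                   transitions=np.array(rows), alpha=float(meta["alpha"]),
                   strand_mode=meta["strand_mode"])


def fit_markov(round0: RoundReads, order: int = 6, alpha: float = 1.0,
               strand_mode: str = "collapsed") -> MarkovModel:
    """Fit the background model on Round-0 reads.

    The initial distribution is trained on every length-m window (the same
    per-window frame the k-mer tables use); transitions on every
    length-(m+1) window. In collapsed mode the reverse complement of every
    read is added to the training pool. Contexts never observed fall back
    to a uniform next-base row when alpha == 0.
    """
    m = order
    if m < 1:
        raise ValueError("order must be >= 1")
    if alpha < 0:
        raise ValueError("pseudocount alpha must be nonnegative")
    if len(round0) == 0:
        raise ValueError("cannot fit a background model on zero reads")
    codes = round0.codes()
    if codes.shape[1] < m + 1:
        raise ValueError(f"reads must be at least order+1 = {m + 1} nt long")
    if strand_mode == "collapsed":
        codes = np.vstack([codes, 3 - codes[:, ::-1]])
    elif strand_mode != "single":
        raise ValueError("strand_mode must be 'single' or 'collapsed'")

    cnt_m = np.bincount(seq.window_indices(codes, m).ravel(),
                        minlength=4 ** m).astype(float)
    cnt_m1 = np.bincount(seq.window_indices(codes, m + 1).ravel(),
                         minlength=4 ** (m + 1)).astype(float)

    initial = (cnt_m + alpha) / (cnt_m.sum() + alpha * 4 ** m)
    succ = cnt_m1.reshape(4 ** m, 4)  # row c: counts of c followed by A,C,G,T
    denom = succ.sum(axis=1) + 4 * alpha
    with np.errstate(invalid="ignore", divide="ignore"):
        transitions = (succ + alpha) / denom[:, None]
    transitions[denom == 0] = 0.25
    return MarkovModel(order=m, initial=initial, transitions=transitions,
                       alpha=alpha, strand_mode=strand_mode)


def expected_kmer_table(model: MarkovModel, k: int,
                        total_windows: int = 1) -> KmerTable:
    """Model-implied k-mer table (frequencies x total_windows as counts).

    The returned table mirrors the model's strand mode: in collapsed mode
    the probability mass of each word/revcomp pair is folded onto the
    canonical index, matching how observed collapsed tables are counted.
    Frequencies sum to 1 either way.
    """
    if k < model.order:
        raise ValueError(f"k={k} smaller than model order {model.order}")
    probs = model.all_kmer_probs(k)
    if model.strand_mode == "collapsed":
        idx = np.arange(4 ** k, dtype=np.int64)
        canon = seq.canonical_index(idx, k)
        folded = np.zeros_like(probs)
        np.add.at(folded, canon, probs)
        probs = folded
    return KmerTable(k=k, strand_mode=model.strand_mode,
                     counts=probs * total_windows, total_windows=total_windows,
                     n_reads=0, round_index=0, condition_label="background")
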