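"""Per-k-mer relative affinity and cross-condition comparison.

The estimator follows the standard SELEX-seq construction: for every
10-mer with adequate counts in the final enriched round, the raw
enrichment ratio is its observed per-window frequency divided by the
frequency the Round-0 Markov background model predicts, and relative
affinities rescale those ratios so the best word scores exactly 1.

Because different conditions may be sequenced at different rounds (e.g.
round 8 vs round 5), a ``per_round_root`` mode is offered that replaces
the ratio by ratio^(1/R) before normalizing — a per-round geometric mean
enrichment that is comparable across conditions. Both modes induce the
same within-condition ranking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import seq
from .background import MarkovModel
from .kmers import KmerTable

EXPONENT_MODES = ("ratio", "per_round_root")


@dataclass
class AffinityTable:
    """Dense per-word relative affinities for one condition.

    ``raw_ratio`` and ``rel_affinity`` are indexed by packed word index;
    in collapsed strand mode only canonical indices carry values and
    lookups of a non-canonical word are redirected to its canonical
    partner, so rel_affinity(w) == rel_affinity(revcomp(w)) exactly.
    Words observed fewer than ``min_count`` times are flagged with ratio
    and affinity 0.
    """

    k: int
    condition_label: str
    final_round_index: int
    strand_mode: str
    counts: np.ndarray
    raw_ratio: np.ndarray
    rel_affinity: np.ndarray
    min_count: int
    exponent_mode: str
    normalization_word: str
    n_below_min_count: int = 0

    @property
    def observed_mask(self) -> np.ndarray:
        return (self.counts >= max(self.min_count, 1))

    def observed_indices(self) -> np.ndarray:
        return np.flatnonzero(self.observed_mask)

    def _lookup(self, word: str) -> int:
        if len(word) != self.k:
            raise ValueError(f"word length {len(word)} != k={self.k}")
        idx = seq.word_to_index(word)
        if self.strand_mode == "collapsed":
            idx = seq.canonical_index(idx, self.k)
        return idx

    def affinity(self, word: str) -> float:
        return float(self.rel_affinity[self._lookup(word)])

    def ratio(self, word: str) -> float:
        return float(self.raw_ratio[self._lookup(word)])

    def metadata(self) -> dict:
        return {
            "k": self.k,
            "condition_label": self.condition_label,
            "final_round_index": self.final_round_index,
            "strand_mode": self.strand_mode,
            "min_count": self.min_count,
            "exponent_mode": self.exponent_mode,
            "normalization_word": self.normalization_word,
            "n_observed": int(self.observed_mask.sum()),
            "n_below_min_count": self.n_below_min_count,
        }

    def to_tsv(self, path: str | Path) -> None:
        idx = self.observed_indices()
        order = np.lexsort((idx, -self.rel_affinity[idx]))
        idx = idx[order]
        words = seq.indices_to_words(idx, self.k)
        with open(path, "w") as fh:
            for key, val in self.metadata().items():
                fh.write(f"# {key}={val}\n")
            fh.write("word\tcount\traw_ratio\trel_affinity\n")
            for w, i in zip(words, idx):
                fh.write(f"{w}\t{int(self.counts[i])}\t"
                         f"{self.raw_ratio[i]:.10g}\t{self.rel_affinity[i]:.10g}\n")

    def write_metadata(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metadata(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def relative_affinity(final_table: KmerTable, background: MarkovModel,
                      min_count: int = 2,
                      exponent_mode: str = "ratio") -> AffinityTable:
    """Relative affinity of every adequately observed k-mer.

    raw_ratio(w) = f_R(w) / P_background(w) for words with count >=
    min_count (others 0, flagged); in per_round_root mode the ratio is
    replaced by its R-th root before max-normalization to 1.
    """
    from .background import expected_kmer_table

    if exponent_mode not in EXPONENT_MODES:
        raise ValueError(f"exponent_mode must be one of {EXPONENT_MODES}")
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    if final_table.round_index is None or final_table.round_index < 1:
        raise ValueError("final k-mer table must carry its round index (>= 1)")
    if final_table.k < background.order:
        raise ValueError("k must be >= the background model order")
    if final_table.strand_mode != background.strand_mode:
        raise ValueError("k-mer table and background strand modes differ")

    bg = expected_kmer_table(background, final_table.k).frequencies
    counts = np.asarray(final_table.counts)
    mask = (counts >= max(min_count, 1))
    if not mask.any():
        raise ValueError("no word passes the min_count threshold")
    if (bg[mask] <= 0).any():
        raise ValueError("background assigns zero probability to an observed "
                         "word; fit the model with pseudocount alpha > 0")
    freq = counts / final_table.total_windows
    raw = np.zeros(len(bg), dtype=float)
    raw[mask] = freq[mask] / bg[mask]
    if exponent_mode == "per_round_root":
        raw[mask] = raw[mask] ** (1.0 / final_table.round_index)
    top = int(raw.argmax())  # argmax returns the lexicographically least tie
    rel = raw / raw[top]
    return AffinityTable(
        k=final_table.k, condition_label=final_table.condition_label,
        final_round_index=final_table.round_index,
        strand_mode=final_table.strand_mode, counts=counts,
        raw_ratio=raw, rel_affinity=rel, min_count=min_count,
        exponent_mode=exponent_mode,
        normalization_word=seq.index_to_word(top, final_table.k),
        n_below_min_count=int(((counts > 0) & ~mask).sum()),
    )


@dataclass
class AffinityComparison:
    """Join of two conditions' affinity tables over shared observed words."""

    words: list[str]
    rel_a: np.ndarray
    rel_b: np.ndarray
    label_a: str
    label_b: str
    pearson_r: float
    spearman_rho: float
    n_a_only: int
    n_b_only: int

    @property
    def log_discordance(self) -> np.ndarray:
        return np.abs(np.log(self.rel_a) - np.log(self.rel_b))

    def top_discordant(self, n: int = 20) -> list[tuple[str, float, float, float]]:
        d = self.log_discordance
        order = np.lexsort((np.asarray(self.words), -d))[:n]
        return [(self.words[i], float(self.rel_a[i]), float(self.rel_b[i]),
                 float(d[i])) for i in order]

    def to_tsv(self, path: str | Path) -> None:
        d = self.log_discordance
        order = np.lexsort((np.asarray(self.words), -d))
        with open(path, "w") as fh:
            fh.write(f"# condition_a={self.label_a}\n# condition_b={self.label_b}\n")
            fh.write(f"# pearson_r={self.pearson_r:.10g}\n")
            fh.write(f"# spearman_rho={self.spearman_rho:.10g}\n")
            fh.write(f"# n_shared={len(self.words)}\n")
            fh.write(f"# n_a_only={self.n_a_only}\n# n_b_only={self.n_b_only}\n")
            fh.write("word\trel_a\trel_b\tabs_log_ratio\n")
            for i in order:
                fh.write(f"{self.words[i]}\t{self.rel_a[i]:.10g}\t"
                         f"{self.rel_b[i]:.10g}\t{d[i]:.10g}\n")

    def plot_dotplot(self, path: str | Path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        plt.rcParams["svg.hashsalt"] = "selexkit"
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(self.rel_a, self.rel_b, s=4, alpha=0.4,
                   color="#20639b", edgecolors="none")
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel(f"relative affinity ({self.label_a})")
        ax.set_ylabel(f"relative affinity ({self.label_b})")
        ax.set_title(f"Spearman rho = {self.spearman_rho:.3f}")
        fig.tight_layout()
        fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
        plt.close(fig)


def compare_affinities(table_a: AffinityTable,
                       table_b: AffinityTable) -> AffinityComparison:
    """Inner-join two conditions over words passing both min-count filters
    and summarize concordance (Pearson/Spearman + top discordant words)."""
    from scipy import stats

    if table_a.k != table_b.k:
        raise ValueError("affinity tables have different k")
    if table_a.strand_mode != table_b.strand_mode:
        raise ValueError("affinity tables have different strand modes")
    mask_a, mask_b = table_a.observed_mask, table_b.observed_mask
    shared = np.flatnonzero(mask_a & mask_b)
    if shared.size == 0:
        raise ValueError("no word is observed in both conditions")
    rel_a = table_a.rel_affinity[shared]
    rel_b = table_b.rel_affinity[shared]
    if shared.size > 1:
        pearson = float(stats.pearsonr(rel_a, rel_b).statistic)
        spearman = float(stats.spearmanr(rel_a, rel_b).statistic)
    else:
        pearson = spearman = float("nan")
    return AffinityComparison(
        words=seq.indices_to_words(shared, table_a.k),
        rel_a=rel_a, rel_b=rel_b,
        label_a=table_a.condition_label, label_b=table_b.condition_label,
        pearson_r=pearson, spearman_rho=spearman,
        n_a_only=int((mask_a & ~mask_b).sum()),
        n_b_only=int((mask_b & ~mask_a).sum()),
    )
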