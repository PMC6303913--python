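"""Synthetic SELEX-seq experiment generator.

Emulates the library design and selection scheme of a MADS-domain
SELEX-seq experiment: a 40-nt randomized region flanked by fixed barcode
sequence, iterated over rounds of affinity-proportional capture. A
molecule's retention probability per round is proportional to
(best-window binding score)^s, where s is a washing-stringency exponent.

Two selection modes are offered:

``iid`` (default)
    The infinite-library limit. A real randomized library holds ~10^12
    distinct molecules while a round is sequenced at 10^4-10^7 reads, so
    the reads of round r are effectively i.i.d. draws from the evolving
    population law p_r(x) proportional to score(x)^(r*s). The simulator
    samples that law directly by rejection from the uniform proposal,
    sharing one proposal stream across rounds (a molecule accepted into
    round r is also accepted into every earlier round — acceptance sets
    are nested, mirroring real survival). No founder effects, no PCR
    overdispersion (both vanish at infinite complexity; pcr_noise is
    ignored in this mode).

``pool``
    A finite pool of n_reads_per_round molecules resampled with
    replacement round over round via :func:`simulate_round` — bottleneck
    and founder effects included. PCR is modelled as Dirichlet-
    multinomial overdispersion: with pcr_noise > 0 the selection
    probabilities are jittered by a Dirichlet draw with concentration
    p_i / pcr_noise before the multinomial resampling (pcr_noise -> 0
    recovers exact multinomial sampling).

Everything is deterministic given the config seed, down to the bytes of
the FASTQ files written.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import seq
from .landscape import AffinityLandscape, score_matrix
from .reads import RoundReads

DEFAULT_LEFT_FLANK = "ACGTAGCA"
DEFAULT_RIGHT_FLANK = "TGCATCGT"


@dataclass
class SimConfig:
    """Study conditions for one simulated SELEX run.

    variable_length
        Length L of the randomized region (40 nt library design).
    left_flank, right_flank
        Fixed barcode/adapter context written around the variable region
        in the FASTQ output.
    n_reads_per_round
        Sequencing depth per round.
    n_rounds
        Number of selection rounds R; rounds 0..R are emitted.
    stringency
        Exponent s applied to binding scores before sampling; larger s =
        more stringent washing.
    pcr_noise
        Dirichlet-multinomial overdispersion control; 0 = pure
        multinomial (pool mode only).
    selection_mode
        "iid" (infinite-library limit, default) or "pool" (finite pool
        resampling); see module docstring.
    base_weights
        Optional (L, 4) per-position base probabilities for a biased
        synthesis of Round 0; default uniform 0.25 everywhere.
    """

    variable_length: int = 40
    left_flank: str = DEFAULT_LEFT_FLANK
    right_flank: str = DEFAULT_RIGHT_FLANK
    n_reads_per_round: int = 50_000
    n_rounds: int = 5
    stringency: float = 2.0
    pcr_noise: float = 0.0
    seed: int = 0
    selection_mode: str = "iid"
    base_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.variable_length < 1:
            raise ValueError("variable_length must be positive")
        if self.n_reads_per_round < 1:
            raise ValueError("n_reads_per_round must be positive")
        if self.n_rounds < 0:
            raise ValueError("n_rounds must be >= 0")
        if self.stringency <= 0:
            raise ValueError("stringency must be > 0")
        if self.pcr_noise < 0:
            raise ValueError("pcr_noise must be >= 0")
        if self.selection_mode not in ("iid", "pool"):
            raise ValueError("selection_mode must be 'iid' or 'pool'")
        for flank in (self.left_flank, self.right_flank):
            if flank:
                seq.encode(flank)  # validates alphabet
        if self.base_weights is not None:
            w = np.asarray(self.base_weights, dtype=float)
            if w.shape != (self.variable_length, 4):
                raise ValueError("base_weights must have shape (L, 4)")
            if (w < 0).any() or np.abs(w.sum(axis=1) - 1).max() > 1e-9:
                raise ValueError("base_weights rows must be distributions")
            self.base_weights = w

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["base_weights"] is not None:
            d["base_weights"] = np.asarray(d["base_weights"]).tolist()
        return d


def _draw_codes(config: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """n i.i.d. synthesis draws of the variable region (uniform or biased)."""
    L = config.variable_length
    if config.base_weights is None:
        return rng.integers(0, 4, size=(n, L), dtype=np.uint8)
    cum = np.cumsum(config.base_weights, axis=1)
    u = rng.random((n, L))
    return (u[..., None] > cum[None, :, :]).sum(axis=2).astype(np.uint8)


def initial_library(config: SimConfig, rng: np.random.Generator,
                    condition_label: str = "") -> RoundReads:
    """Round 0: i.i.d. random variable regions (uniform unless biased)."""
    codes = _draw_codes(config, rng, config.n_reads_per_round)
    return RoundReads.from_codes(codes, round_index=0,
                                 condition_label=condition_label)


def simulate_round(pool: RoundReads, landscape: AffinityLandscape,
                   config: SimConfig, rng: np.random.Generator) -> RoundReads:
    """One capture + amplification cycle.

    Draws n_reads_per_round sequences with replacement from the pool with
    probability proportional to score^s, optionally overdispersed by the
    Dirichlet PCR-noise model.
    """
    if len(pool) == 0:
        raise ValueError("cannot select from an empty pool")
    codes = pool.codes()
    scores = score_matrix(codes, landscape)
    weights = scores ** config.stringency
    p = weights / weights.sum()
    if config.pcr_noise > 0:
        # Dirichlet-multinomial: gamma-jitter with concentration p/pcr_noise
        g = rng.standard_gamma(p / config.pcr_noise)
        total = g.sum()
        if total == 0:  # pathological concentration; fall back to p
            g, total = p, 1.0
        p = g / total
    counts = rng.multinomial(config.n_reads_per_round, p)
    out = np.repeat(codes, counts, axis=0)
    return RoundReads.from_codes(out, round_index=pool.round_index + 1,
                                 condition_label=pool.condition_label)


def _sample_rounds_iid(config: SimConfig, landscape: AffinityLandscape,
                       rng: np.random.Generator, condition_label: str,
                       batch_size: int = 200_000) -> list[RoundReads]:
    """Rounds 0..R as i.i.d. samples of p_r(x) ~ score(x)^(r*s).

    One uniform proposal stream is shared by all rounds: proposal i with
    acceptance variate u_i enters round r iff u_i < score_i^(r*s), so the
    accepted sets are nested across rounds (survival is monotone). Each
    round's marginal is exactly p_r.
    """
    n, R, s = config.n_reads_per_round, config.n_rounds, config.stringency
    rounds = [initial_library(config, rng, condition_label)]
    if R == 0:
        return rounds
    if config.variable_length < landscape.k:
        raise ValueError("variable_length must be >= the landscape word size")
    table = landscape.strand_max_values()
    k = landscape.k
    need = {r: n for r in range(1, R + 1)}
    chunks: dict[int, list[np.ndarray]] = {r: [] for r in range(1, R + 1)}
    while any(v > 0 for v in need.values()):
        codes = _draw_codes(config, rng, batch_size)
        a = table[seq.window_indices(codes, k)].max(axis=1)
        u = rng.random(batch_size)
        for r in range(1, R + 1):
            if need[r] <= 0:
                continue
            accepted = codes[u < a ** (r * s)]
            take = accepted[:need[r]]
            chunks[r].append(take)
            need[r] -= take.shape[0]
    for r in range(1, R + 1):
        rounds.append(RoundReads.from_codes(
            np.vstack(chunks[r]), round_index=r, condition_label=condition_label))
    return rounds


def run_selex(config: SimConfig, landscape: AffinityLandscape,
              outdir: str | Path | None = None, condition_label: str = "sim",
              gz: bool = False) -> list[RoundReads]:
    """Simulate rounds 0..R; optionally write per-round FASTQ + ground truth.

    FASTQ records wrap each variable region in the configured flanks and
    carry a CASAVA-1.8-style header whose filter field is "N" (passing).
    The generating landscape and config are serialized alongside so that
    parameter-recovery analyses can compare estimates to the truth.
    """
    rng = np.random.default_rng(config.seed)
    if config.selection_mode == "iid":
        rounds = _sample_rounds_iid(config, landscape, rng, condition_label)
    else:
        rounds = [initial_library(config, rng, condition_label)]
        for _ in range(config.n_rounds):
            rounds.append(simulate_round(rounds[-1], landscape, config, rng))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for rr in rounds:
            suffix = ".fastq.gz" if gz else ".fastq"
            write_fastq(rr, outdir / f"{condition_label}_round{rr.round_index}{suffix}",
                        config)
        write_truth_table(landscape, outdir / f"{condition_label}_truth.tsv")
        with open(outdir / f"{condition_label}_config.json", "w") as fh:
            json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return rounds


def write_fastq(reads: RoundReads, path: str | Path, config: SimConfig) -> None:
    """4-line FASTQ with flanks and constant high quality (Q40)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    left, right = config.left_flank, config.right_flank
    qual = "I" * (len(left) + config.variable_length + len(right))
    with opener(path, "wt") as fh:
        for i, s in enumerate(reads.sequences):
            header = (f"@SIMSEQ:1:FLOWCELL:1:{reads.round_index + 1}:{i}:0"
                      f" 1:N:0:{reads.condition_label or 'NA'}")
            fh.write(f"{header}\n{left}{s}{right}\n+\n{qual}\n")


def write_truth_table(landscape: AffinityLandscape, path: str | Path,
                      min_affinity: float = 1e-6) -> None:
    """Ground-truth (word, affinity) TSV; words below min_affinity omitted
    to keep files small (the full landscape is reconstructible from the
    description line for mismatch landscapes)."""
    keep = np.flatnonzero(landscape.values >= min_affinity)
    order = np.lexsort((keep, -landscape.values[keep]))
    keep = keep[order]
    words = seq.indices_to_words(keep, landscape.k)
    with open(path, "w") as fh:
        fh.write(f"# k={landscape.k}\n# description={landscape.description}\n")
        fh.write(f"# strand_symmetric={landscape.strand_symmetric}\n")
        fh.write(f"# min_affinity={min_affinity!r}\n")
        fh.write("word\taffinity\n")
        for w, i in zip(words, keep):
            fh.write(f"{w}\t{landscape.values[i]:.10g}\n")
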