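"""Manifest-driven orchestration of the full analysis.

A run manifest names, per protein condition, the Round-0 FASTQ, the final
enriched-round FASTQ and its round number, plus the shared parameters
(k, Markov order, strand mode, min count, top fraction, ...). The
pipeline then executes prep -> count -> background -> affinity -> motif
per condition, compares conditions pairwise, and writes every artifact
plus a machine-readable JSON report. All artifacts are deterministic
functions of the manifest contents, so a rerun reproduces them
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .affinity import EXPONENT_MODES, compare_affinities, relative_affinity
from .background import fit_markov
from .kmers import STRAND_MODES, carg_prevalence, count_kmers
from .motif import (build_anchored_pfm, export_motif, representative_sequences,
                    top_kmers, write_representatives_fasta)
from .prep import PrepConfig, filter_reads

logger = logging.getLogger("selexkit")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, condition: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed for condition "
                         f"'{condition}': {cause}")
        self.stage = stage
        self.condition = condition


@dataclass
class ConditionSpec:
    label: str
    round0: str
    final_round: str
    final_round_index: int


@dataclass
class PipelineParams:
    k: int = 10
    order: int = 6
    strand_mode: str = "collapsed"
    min_count: int = 2
    fraction: float = 0.001
    exponent_mode: str = "ratio"
    alpha: float = 1.0
    flank: int = 5
    universe: str = "observed"
    weighted_pfm: bool = True


@dataclass
class RunManifest:
    conditions: list[ConditionSpec]
    params: PipelineParams = field(default_factory=PipelineParams)
    prep: PrepConfig = field(default_factory=PrepConfig)
    contaminants: str | None = None
    output_dir: str = "selexkit_out"
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "conditions": [asdict(c) for c in self.conditions],
            "params": asdict(self.params),
            "prep": asdict(self.prep),
            "contaminants": self.contaminants,
            "output_dir": self.output_dir,
            "seed": self.seed,
        }

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def derive_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed: stable hash of the master seed and stage name,
    folded below 2^31."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def validate_manifest(path: str | Path) -> tuple[RunManifest | None, list[str]]:
    """Parse + validate a YAML/JSON manifest; errors are aggregated, not
    first-fail. Returns (manifest, []) or (None, errors)."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except Exception as exc:  # noqa: BLE001 - reported, not raised
        return None, [f"manifest unreadable: {exc}"]
    if not isinstance(raw, dict):
        return None, ["manifest must be a mapping"]

    errors: list[str] = []
    conditions: list[ConditionSpec] = []
    raw_conditions = raw.get("conditions")
    if not isinstance(raw_conditions, list) or not raw_conditions:
        errors.append("conditions: at least one condition is required")
        raw_conditions = []
    labels: set[str] = set()
    for i, entry in enumerate(raw_conditions):
        where = f"conditions[{i}]"
        if not isinstance(entry, dict):
            errors.append(f"{where}: must be a mapping")
            continue
        label = entry.get("label")
        if not label:
            errors.append(f"{where}.label: missing")
            label = f"condition{i}"
        if label in labels:
            errors.append(f"{where}.label: duplicate label {label!r}")
        labels.add(label)
        for key in ("round0", "final_round"):
            val = entry.get(key)
            if not val:
                errors.append(f"{where}.{key}: missing for condition {label!r}")
            elif not Path(val).exists():
                errors.append(f"{where}.{key}: file not found: {val}")
        r = entry.get("final_round_index")
        if not isinstance(r, int) or r < 1:
            errors.append(f"{where}.final_round_index: must be an integer >= 1")
            r = 1
        conditions.append(ConditionSpec(label=str(label),
                                        round0=str(entry.get("round0", "")),
                                        final_round=str(entry.get("final_round", "")),
                                        final_round_index=r))

    params = PipelineParams()
    for key, val in (raw.get("params") or {}).items():
        if not hasattr(params, key):
            errors.append(f"params.{key}: unknown parameter")
        else:
            setattr(params, key, val)
    if params.strand_mode not in STRAND_MODES:
        errors.append(f"params.strand_mode: must be one of {STRAND_MODES}")
    if params.exponent_mode not in EXPONENT_MODES:
        errors.append(f"params.exponent_mode: must be one of {EXPONENT_MODES}")
    if not 0 < params.fraction <= 1:
        errors.append("params.fraction: must lie in (0, 1]")
    if params.min_count < 0:
        errors.append("params.min_count: must be >= 0")
    if params.k < params.order:
        errors.append("params.k: must be >= params.order")
    if params.alpha <= 0:
        errors.append("params.alpha: must be > 0 (positive background)")
    if params.flank < 0:
        errors.append("params.flank: must be >= 0")

    try:
        prep = PrepConfig(**(raw.get("prep") or {}))
        if prep.variable_length < params.k:
            errors.append("prep.variable_length: must be >= params.k")
    except (TypeError, ValueError) as exc:
        errors.append(f"prep: {exc}")
        prep = PrepConfig()

    contaminants = raw.get("contaminants")
    if contaminants is not None and not Path(contaminants).exists():
        errors.append(f"contaminants: file not found: {contaminants}")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append("seed: must be an integer")
        seed = 0

    if errors:
        return None, errors
    return RunManifest(conditions=conditions, params=params, prep=prep,
                       contaminants=contaminants,
                       output_dir=str(raw.get("output_dir", "selexkit_out")),
                       seed=seed), []


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(manifest: RunManifest) -> dict:
    """Execute all stages; returns the run report (also written as JSON).

    A stage failure raises PipelineError naming the stage and condition;
    artifacts produced so far stay on disk next to a FAILED marker.
    """
    outdir = Path(manifest.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    mhash = manifest.content_hash()
    report: dict = {
        "manifest_hash": mhash,
        "params": asdict(manifest.params),
        "seed": manifest.seed,
        "conditions": {},
        "comparisons": {},
        "status": "RUNNING",
    }
    params = manifest.params
    tables = {}
    try:
        for cond in manifest.conditions:
            logger.info("condition %s: prep", cond.label)
            cdir = outdir / cond.label
            cdir.mkdir(exist_ok=True)
            centry: dict = {"final_round_index": cond.final_round_index}
            report["conditions"][cond.label] = centry

            stage = "prep"
            try:
                round0, rep0 = filter_reads(
                    cond.round0, manifest.prep, manifest.contaminants,
                    round_index=0, condition_label=cond.label)
                final, repf = filter_reads(
                    cond.final_round, manifest.prep, manifest.contaminants,
                    round_index=cond.final_round_index,
                    condition_label=cond.label)
                rep0.to_tsv(cdir / "prep_round0.tsv", label=f"{cond.label}_r0")
                repf.to_tsv(cdir / "prep_final.tsv",
                            label=f"{cond.label}_r{cond.final_round_index}")
                centry["prep"] = {
                    "round0": {"input": rep0.n_input, "kept": rep0.n_kept,
                               "dropped": rep0.dropped},
                    "final": {"input": repf.n_input, "kept": repf.n_kept,
                              "dropped": repf.dropped},
                }
                if not round0.sequences or not final.sequences:
                    raise ValueError("no reads left after filtering")

                stage = "carg"
                prev0, _ = carg_prevalence(round0)
                prevf, _ = carg_prevalence(final)
                centry["carg_percent"] = {
                    "round0": round(100 * prev0, 4),
                    f"round{cond.final_round_index}": round(100 * prevf, 4),
                }
                logger.info("condition %s: perfect CArG-box %% round0=%.3f "
                            "final=%.3f", cond.label, 100 * prev0, 100 * prevf)

                stage = "count"
                ktab = count_kmers(final, params.k, params.strand_mode)
                ktab.to_tsv(cdir / "kmer_counts_final.tsv")
                centry["n_distinct_kmers"] = int((ktab.counts > 0).sum())
                centry["total_windows"] = ktab.total_windows

                stage = "background"
                model = fit_markov(round0, params.order, params.alpha,
                                   params.strand_mode)
                model.to_tsv(cdir / "background_model.tsv")

                stage = "affinity"
                atab = relative_affinity(ktab, model, params.min_count,
                                         params.exponent_mode)
                atab.to_tsv(cdir / "affinity.tsv")
                atab.write_metadata(cdir / "affinity_meta.json")
                centry["n_observed_words"] = int(atab.observed_mask.sum())
                centry["normalization_word"] = atab.normalization_word
                tables[cond.label] = atab

                stage = "motif"
                top = top_kmers(atab, params.fraction, params.universe)
                reps = representative_sequences(top.words, final,
                                                params.strand_mode)
                n_fa = write_representatives_fasta(
                    top, reps, cdir / "top_kmer_representatives.fasta")
                pfm = build_anchored_pfm(top, atab, params.flank, reps,
                                         weighted=params.weighted_pfm)
                export_motif(pfm, cdir / "motif_meme.txt", "meme",
                             name=f"{cond.label}_anchored")
                export_motif(pfm, cdir / "motif_jaspar.pfm", "jaspar",
                             name=f"{cond.label}_anchored")
                centry["n_top_kmers"] = len(top.words)
                centry["n_representatives"] = n_fa
                centry["motif_consensus"] = pfm.consensus()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(stage, cond.label, exc) from exc

            centry["artifacts"] = {
                p.name: _sha256(p) for p in sorted(cdir.iterdir()) if p.is_file()
            }

        labels = [c.label for c in manifest.conditions]
        if len(labels) < 2:
            report["comparisons"]["note"] = (
                "single condition: cross-condition comparison skipped")
            logger.info("single condition; comparison stage skipped")
        else:
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    a, b = labels[i], labels[j]
                    try:
                        comp = compare_affinities(tables[a], tables[b])
                    except Exception as exc:
                        raise PipelineError("compare", f"{a} vs {b}", exc) from exc
                    stem = outdir / f"compare_{a}_vs_{b}"
                    comp.to_tsv(stem.with_suffix(".tsv"))
                    comp.plot_dotplot(stem.with_suffix(".png"))
                    report["comparisons"][f"{a}_vs_{b}"] = {
                        "pearson_r": round(comp.pearson_r, 6),
                        "spearman_rho": round(comp.spearman_rho, 6),
                        "n_shared": len(comp.words),
                        "n_a_only": comp.n_a_only,
                        "n_b_only": comp.n_b_only,
                        "artifact": _sha256(stem.with_suffix(".tsv")),
                    }
    except PipelineError as exc:
        report["status"] = "FAILED"
        report["failure"] = {"stage": exc.stage, "condition": exc.condition,
                             "error": str(exc)}
        (outdir / "FAILED").write_text(str(exc) + "\n")
        _write_report(report, outdir)
        raise

    report["status"] = "OK"
    _write_report(report, outdir)
    return report


def _write_report(report: dict, outdir: Path) -> None:
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    lines = [f"selexkit run report (manifest {report['manifest_hash'][:12]})",
             f"status: {report['status']}"]
    for label, entry in report["conditions"].items():
        lines.append(f"condition {label}:")
        for key, val in entry.items():
            if key != "artifacts":
                lines.append(f"  {key}: {val}")
    for pair, stats in report["comparisons"].items():
        lines.append(f"comparison {pair}: {stats}")
    (outdir / "run_report.txt").write_text("\n".join(lines) + "\n")
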