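"""The full mapping pipeline on one simulated (or user-supplied) cohort."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np
import pandas as pd

from enumap._rng import stage_rng
from enumap.assoc.permute import permutation_maxT
from enumap.assoc.qc import qc_filter
from enumap.assoc.regions import RegionCall, call_significant_region
from enumap.exome.cascade import CascadeThresholds, Variant, filter_cascade
from enumap.exome.coverage import CoverageConfig, coverage_summary
from enumap.pedsim.breed import TruthSet
from enumap.pedsim.cohort import Cohort, emit_cohort, simulate_cohort
from enumap.pedsim.variants import exome_records
from enumap.pipeline.config import RunConfig
from enumap.splice.pwm import WeightMatrix, compare_alleles
from enumap.splice.transcript import amplicon_length, consequence_of_skip, skip_exon


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunReport:
    """Machine-readable record of one run."""

    seed: int
    config: Dict[str, Any]
    qc: Dict[str, Any] = field(default_factory=dict)
    coverage: Dict[str, Any] = field(default_factory=dict)
    regions: List[Dict[str, Any]] = field(default_factory=list)
    cascade: List[Dict[str, Any]] = field(default_factory=list)
    candidates: List[Dict[str, Any]] = field(default_factory=list)
    splice: List[Dict[str, Any]] = field(default_factory=list)
    truth_eval: Dict[str, Any] = field(default_factory=dict)
    provenance: Dict[str, str] = field(default_factory=dict)

    def to_json(self, path: Optional[Path] = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True, default=_jsonable)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _simulate_depths(cohort: Cohort, seed: int) -> Dict:
    """Per-base exome depth tracks: Poisson around a per-target mean drawn
    from a Gamma, mimicking uneven capture efficiency."""
    rng = stage_rng(seed, "coverage")
    depths = {}
    for chrom, start, end in cohort.exon_targets():
        mean = rng.gamma(20.0, cohort.params.depth_mean / 20.0)
        depths[(chrom, start, end)] = rng.poisson(mean, size=end - start + 1)
    return depths


def _pick_region(regions: List[RegionCall], results: pd.DataFrame) -> Optional[RegionCall]:
    """The region holding the genome-wide peak statistic."""
    if not regions:
        return None
    peak_scores = {}
    for r in regions:
        row = results[results["marker"] == r.peak_marker]
        peak_scores[id(r)] = float(row["chi2"].iloc[0]) if len(row) else -np.inf
    return max(regions, key=lambda r: peak_scores[id(r)])


def run_all(cfg: RunConfig) -> RunReport:
    """Execute simulate -> QC/TDT -> coverage -> cascade -> splice.

    Any stage failure raises :class:`StageError` naming the stage; partial
    file outputs (when an output directory is configured) are left behind
    for inspection.
    """
    report = RunReport(seed=cfg.seed, config=cfg.to_dict())
    outdir = Path(cfg.outdir) if cfg.outdir else None

    try:
        cohort = simulate_cohort(cfg.sim, cfg.seed)
        paths: Dict[str, Path] = {}
        if outdir is not None:
            paths = emit_cohort(cohort, outdir, cfg.seed)
            cfg.to_yaml(outdir / "config.yaml")
            paths["config"] = outdir / "config.yaml"
    except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
        raise StageError("simulate", exc) from exc

    try:
        filtered, qc_report = qc_filter(
            cohort.matrix, cohort.truth.pedigree, cfg.qc, population=cfg.qc_population
        )
        results = permutation_maxT(
            filtered, cohort.truth.pedigree, cfg.n_perm, stage_rng(cfg.seed, "permutation")
        )
        regions = call_significant_region(
            results, alpha=cfg.alpha, merge_gap_bp=cfg.merge_gap_bp
        )
        report.qc = {
            "steps": qc_report.to_dict(orient="records"),
            "markers_tested": int(filtered.n_markers),
        }
        report.regions = [asdict(r) for r in regions]
        if outdir is not None:
            results.to_csv(outdir / "tdt_results.tsv", sep="\t", index=False)
            paths["tdt_results"] = outdir / "tdt_results.tsv"
    except Exception as exc:
        raise StageError("association", exc) from exc

    try:
        depths = _simulate_depths(cohort, cfg.seed)
        frac, _ = coverage_summary(depths, CoverageConfig(min_depth=cfg.min_coverage_depth))
        report.coverage = {
            "fraction_at_min_depth": frac,
            "min_depth": cfg.min_coverage_depth,
            "target_bases": int(sum(e - s + 1 for _, s, e in cohort.exon_targets())),
        }
    except Exception as exc:
        raise StageError("coverage", exc) from exc

    try:
        regions_objs = [RegionCall(**r) for r in report.regions]
        region = _pick_region(regions_objs, results)
        candidates = pd.DataFrame(
            columns=["gene", "chrom", "pos", "ref", "alt", "hgvs_c", "hgvs_p", "effect"]
        )
        if region is not None:
            records = exome_records(
                cohort.truth,
                cohort.sequenced,
                depth_mean=cohort.params.depth_mean,
                rng=stage_rng(cfg.seed, "exome_depths"),
            )
            variants = [
                Variant(
                    chromosome=r.chrom,
                    position=r.pos,
                    ref=r.ref,
                    alt=r.alt,
                    qual=r.qual,
                    genotypes=dict(r.genotypes),
                    depths=dict(r.depths),
                    id=r.id,
                )
                for r in records
            ]
            candidates, cascade_report = filter_cascade(
                variants,
                region,
                cohort.genes,
                cohort.fragments,
                [cohort.control_panel],
                cohort.phenotypes,
                sequenced_affected=cohort.sequenced,
                thresholds=cfg.cascade,
                full_genotypes=lambda v: cohort.full_genotypes(v.chromosome, v.position),
            )
            report.cascade = cascade_report.to_frame().to_dict(orient="records")
        report.candidates = candidates.to_dict(orient="records")
        if outdir is not None:
            candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
            paths["candidates"] = outdir / "candidates.tsv"
    except Exception as exc:
        raise StageError("filter", exc) from exc

    try:
        report.splice = _splice_stage(cohort, cfg)
    except Exception as exc:
        raise StageError("splice", exc) from exc

    if cohort.truth.causal is not None:
        report.truth_eval = evaluate_against_truth(report, cohort.truth)
    if outdir is not None:
        for name, path in sorted(paths.items()):
            report.provenance[name] = _sha256(path)
        report.to_json(outdir / "run_report.json")
    return report


def _splice_stage(cohort: Cohort, cfg: RunConfig) -> List[Dict[str, Any]]:
    """ESE contrast and skip-consequence prediction for candidates falling
    in the multi-exon planted gene (background genes are single-exon, so
    exon skipping is undefined for them)."""
    if cohort.fixture is None:
        return []
    fx = cohort.fixture
    wm = (
        WeightMatrix.from_tsv(cfg.matrix_path)
        if cfg.matrix_path
        else fx.weight_matrix
    )
    out = []
    cds = fx.transcript.cds_seq
    plant = fx.plant
    ref_max, alt_max, delta = compare_alleles(
        cds, plant.cds_position, plant.ref_allele, plant.alt_allele, wm
    )
    cons = consequence_of_skip(fx.transcript, fx.skipped_exon_id)
    full_len = amplicon_length(fx.transcript, fx.primers)
    skipped_len = amplicon_length(skip_exon(fx.transcript, fx.skipped_exon_id), fx.primers)
    out.append(
        {
            "gene": fx.gene.gene_id,
            "matrix": wm.name,
            "ese_ref_max": ref_max,
            "ese_alt_max": alt_max,
            "ese_delta": delta,
            "skipped_exon": cons.skipped_exon,
            "skipped_length": cons.skipped_length,
            "frameshift": cons.frameshift,
            "premature_stop": cons.premature_stop,
            "protein_length": cons.protein_length,
            "amplicon_full": full_len,
            "amplicon_skipped": skipped_len,
        }
    )
    return out


def evaluate_against_truth(report: RunReport, truth: TruthSet) -> Dict[str, Any]:
    """Region-hit flag plus candidate precision/recall against the plant."""
    if truth.causal is None:
        raise ValueError("truth set has no planted causal variant")
    causal = truth.causal
    region_hit = any(
        r["chromosome"] == causal.chromosome and r["start"] <= causal.position <= r["end"]
        for r in report.regions
    )
    n_candidates = len(report.candidates)
    causal_found = any(
        c["chrom"] == causal.chromosome and c["pos"] == causal.position
        for c in report.candidates
    )
    return {
        "region_hit": bool(region_hit),
        "n_candidates": n_candidates,
        "recall": 1.0 if causal_found else 0.0,
        "precision": (1.0 / n_candidates if causal_found else 0.0)
        if n_candidates
        else 0.0,
    }
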