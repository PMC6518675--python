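"""End-to-end orchestration: simulate → discover → classify → de → pairs →
enrich → energy, with a machine-readable run report.

Stages run in dependency order; each stage logs a timer to stderr and a
failure aborts with a stage-named error. All randomness flows from the
single top-level seed in the run config.
"""

from __future__ import annotations

import json
import logging
import time

import pandas as pd
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .coexpression_pairs import correlated_pairs, join_cis
from .enrichment_orthologs import categorize_families, contingency_enrichment
from .expression_stats import (
    ExpressionMatrix,
    de_overlap_counts,
    de_results_frame,
    differential_expression,
    filter_expressed,
    percent_de,
    pvca,
)
from .feeding_energy import (
    energy_difference,
    published_control,
    published_schedule,
    total_intake,
)
from .genome import AnnotationSet, attach_sequences, read_gtf, write_gtf
from .positional_classification import classify_all, cis_candidates
from .synthetic_data import SimulationConfig, simulate_to_dir
from .transcript_filtering import FilterParams, filter_candidates

logger = logging.getLogger("lncflux")

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Thresholds and paths for one pipeline run; defaults are the
    published analysis thresholds."""

    outdir: str = "lncflux_run"
    seed: int = 0
    min_length: int = 200
    max_coding_score: float = 1.0
    min_exons: int = 2
    fpkm_threshold: float = 0.1
    cis_window: int = 10_000
    r_min: float = 0.80
    p_max: float = 0.05
    alpha: float = 0.05
    top_n_pairs: int = 10
    stages: tuple[str, ...] = (
        "simulate",
        "discover",
        "classify",
        "de",
        "pairs",
        "enrich",
        "energy",
    )
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.min_length < 0 or self.min_exons < 1:
            raise ValueError("invalid filter thresholds")
        if self.cis_window < 0 or self.fpkm_threshold < 0:
            raise ValueError("invalid window/threshold")
        if not (0 < self.alpha < 1 and 0 < self.p_max < 1 and 0 <= self.r_min <= 1):
            raise ValueError("invalid statistical thresholds")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageError(
            stage, f"missing input {path}; run the producing stage first"
        )
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages on the synthetic fixture bundle and
    return (and write) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "tool_version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
        "stages": {},
    }
    timings: dict[str, float] = {}

    def stage_enabled(name: str) -> bool:
        return name in config.stages

    sim_cfg = SimulationConfig(seed=config.seed, **config.simulation)

    # --- simulate ---------------------------------------------------------
    if stage_enabled("simulate"):
        t0 = time.perf_counter()
        paths = simulate_to_dir(sim_cfg, outdir / "fixtures")
        timings["simulate"] = time.perf_counter() - t0
        report["stages"]["simulate"] = {
            "n_reference_transcripts": len(read_gtf(paths["reference_gtf"])),
            "n_candidates": len(read_gtf(paths["candidates_gtf"])),
        }
    fixtures = outdir / "fixtures"

    # --- discover ---------------------------------------------------------
    lnc_set = None
    if stage_enabled("discover"):
        t0 = time.perf_counter()
        reference = read_gtf(_require(fixtures / "reference.gtf", "discover"))
        candidates = read_gtf(_require(fixtures / "candidates.gtf", "discover"))
        candidates = attach_sequences(
            candidates, _require(fixtures / "candidates.fa", "discover")
        )
        params = FilterParams(
            min_length=config.min_length,
            max_coding_score=config.max_coding_score,
            min_exons=config.min_exons,
        )
        lnc_set, filt_report = filter_candidates(
            list(candidates), reference, params=params
        )
        write_gtf(lnc_set, outdir / "lncrna.gtf")
        timings["discover"] = time.perf_counter() - t0
        report["stages"]["discover"] = {
            "input_count": filt_report.input_count,
            "removed_by": filt_report.removed_by,
            "n_lncrna": len(filt_report.surviving_ids),
        }

    # --- classify ---------------------------------------------------------
    cis_pairs = None
    if stage_enabled("classify"):
        t0 = time.perf_counter()
        reference = read_gtf(_require(fixtures / "reference.gtf", "classify"))
        if lnc_set is None:
            lnc_set = read_gtf(_require(outdir / "lncrna.gtf", "classify"))
        records = classify_all(lnc_set, reference, window=config.cis_window)
        cis_pairs = cis_candidates(lnc_set, reference, window=config.cis_window)
        cls_frame = [
            {
                "transcript_id": r.transcript_id,
                "category": r.category,
                "nearest_gene": r.nearest_gene_id,
                "signed_distance_bp": r.signed_distance,
                "cis_candidate": r.cis_candidate,
            }
            for r in records
        ]
        pd.DataFrame(cls_frame).to_csv(
            outdir / "classification.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            cis_pairs, columns=["lncrna_id", "gene_id", "signed_distance_bp"]
        ).to_csv(outdir / "cis_pairs.tsv", sep="\t", index=False)
        counts: dict[str, int] = {}
        for r in records:
            counts[r.category] = counts.get(r.category, 0) + 1
        timings["classify"] = time.perf_counter() - t0
        report["stages"]["classify"] = {
            "category_counts": counts,
            "n_cis_pairs": len(cis_pairs),
        }

    # --- de ---------------------------------------------------------------
    de_sets: dict[str, set] = {}
    expressed_ids: set = set()
    expr = None
    if stage_enabled("de"):
        t0 = time.perf_counter()
        expr = ExpressionMatrix.read(
            _require(fixtures / "expression.tsv", "de"),
            _require(fixtures / "samples.tsv", "de"),
        )
        expressed, n_expressed = filter_expressed(expr, config.fpkm_threshold)
        expressed_ids = set(expressed.feature_ids)
        de_stage: dict = {"n_expressed": n_expressed, "tissues": {}}
        for tissue in expressed.tissues:
            results = differential_expression(expressed, tissue, alpha=config.alpha)
            frame = de_results_frame(results)
            frame.to_csv(outdir / f"de_{tissue}.tsv", sep="\t")
            de_ids = {r.feature_id for r in results if r.is_de}
            de_sets[tissue] = de_ids
            de_stage["tissues"][tissue] = {
                "n_de": len(de_ids),
                "percent_de": percent_de(len(de_ids), n_expressed),
            }
        de_stage["venn"] = de_overlap_counts(de_sets)
        pv = pvca(expressed)
        de_stage["pvca"] = pv.weighted_proportions
        with open(outdir / "venn.json", "w") as fh:
            json.dump(de_stage["venn"], fh, indent=1, sort_keys=True)
        timings["de"] = time.perf_counter() - t0
        report["stages"]["de"] = de_stage

    # --- pairs ------------------------------------------------------------
    if stage_enabled("pairs"):
        t0 = time.perf_counter()
        if expr is None:
            expr = ExpressionMatrix.read(
                _require(fixtures / "expression.tsv", "pairs"),
                _require(fixtures / "samples.tsv", "pairs"),
            )
        if lnc_set is None:
            lnc_set = read_gtf(_require(outdir / "lncrna.gtf", "pairs"))
        lnc_ids = [
            t.transcript_id for t in lnc_set if t.transcript_id in set(expr.feature_ids)
        ]
        gene_ids = [
            f for f in expr.feature_ids if f not in set(lnc_ids)
        ]
        pairs = correlated_pairs(
            expr.subset_features(lnc_ids),
            expr.subset_features(gene_ids),
            r_min=config.r_min,
            p_max=config.p_max,
        )
        if cis_pairs is None:
            reference = read_gtf(_require(fixtures / "reference.gtf", "pairs"))
            cis_pairs = cis_candidates(lnc_set, reference, window=config.cis_window)
        top = join_cis(pairs, cis_pairs, top_n=config.top_n_pairs)
        pd.DataFrame([p.__dict__ for p in pairs]).to_csv(
            outdir / "correlated_pairs.tsv", sep="\t", index=False
        )
        timings["pairs"] = time.perf_counter() - t0
        report["stages"]["pairs"] = {
            "n_correlated_pairs": len(pairs),
            "n_top_cis": len(top),
            "top_cis": [
                {
                    "lncrna_id": p.lncrna_id,
                    "gene_id": p.gene_id,
                    "r": p.r,
                    "signed_distance_bp": p.signed_distance,
                }
                for p in top
            ],
        }

    # --- enrich -----------------------------------------------------------
    if stage_enabled("enrich"):
        t0 = time.perf_counter()
        if not de_sets:
            raise StageError("enrich", "DE stage must run before enrichment")
        gene_set_path = _require(fixtures / "gene_set.txt", "enrich")
        gene_set = {
            line.strip() for line in gene_set_path.read_text().splitlines() if line.strip()
        }
        tissue = next(iter(de_sets))
        universe = {f for f in expressed_ids if f.startswith("gene")} or expressed_ids
        enr = contingency_enrichment(gene_set, de_sets[tissue] & universe, universe)
        families = pd.read_csv(_require(fixtures / "families.tsv", "enrich"), sep="\t")
        sim = sim_cfg
        records, proportions = categorize_families(
            families, sim.focal_species, sim.reference_species
        )
        timings["enrich"] = time.perf_counter() - t0
        report["stages"]["enrich"] = {
            "tissue": tissue,
            "chi_square": enr.chi_square,
            "p_value": enr.p_value,
            "odds_ratio": enr.odds_ratio,
            "family_category_proportions": proportions,
        }

    # --- energy -----------------------------------------------------------
    if stage_enabled("energy"):
        t0 = time.perf_counter()
        schedule = published_schedule()
        control = published_control()
        timings["energy"] = time.perf_counter() - t0
        report["stages"]["energy"] = {
            "treated_total_g": total_intake(schedule),
            "control_total_g": control.total_g,
            "energy_difference_mj": energy_difference(schedule, control),
        }

    report["timings_s"] = {k: round(v, 4) for k, v in timings.items()}
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    summary = []
    for stage, payload in report["stages"].items():
        summary.append(f"{stage}: {json.dumps(payload, sort_keys=True)[:200]}")
    (outdir / "report.txt").write_text("\n".join(summary) + "\n")
    for stage, dt in report["timings_s"].items():
        logger.info("stage %-9s %.3fs", stage, dt)
    return report
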