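"""End-to-end orchestration: preprocess -> discovery -> pathway impact ->
panels -> networks -> abnormality partition, with a seeded, reproducible
report bundle.

One global seed fans out to per-stage seeds by fixed offsets so any stage
can be rerun in isolation. All intermediates are written at full
precision; rounding happens only in the display tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .abnormality import partition_abnormalities, summarize_profiles
from .discovery import fit_plsda, diagnosis_correlations, pca_scree, screen_metabolites
from .network import compare_networks, count_significant, export_network, pairwise_edges
from .panels import PanelConfig, grow_panels
from .pathways import build_impact_table, render_impact_table
from .preprocess import (CohortMatrix, PathwayAnnotation, log_transform,
                         read_cohort, write_cohort, zscore_against_controls)
from .simulate import CohortConfig, generate_cohort, write_truth

__all__ = ["RunConfig", "run_full_pipeline"]

log = logging.getLogger(__name__)

# fixed per-stage seed offsets from the global seed
SEED_OFFSETS = {"simulate": 0, "discover": 101, "panel": 211, "network": 307}


@dataclass
class RunConfig:
    """Thresholds and resampling sizes for a full pipeline run."""

    matrix_path: str | None = None
    annotation_path: str | None = None
    simulate: bool = False
    n_cases: int = 20
    n_controls: int = 20
    case_coupling_multiplier: float = 1.0
    vip_threshold: float = 1.5
    p_threshold: float = 0.05
    fdr_threshold: float = 0.05
    z_cut: float = 2.0
    top_k: int = 30
    r_min: float = 0.85
    n_components: int = 2
    n_boot: int = 100
    n_perm: int = 1000
    max_panel_size: int = 6
    candidate_pool: int = 12
    seed: int = 0
    out_dir: str = "metsig_run"

    def __post_init__(self) -> None:
        for name in ("vip_threshold", "p_threshold", "fdr_threshold", "z_cut",
                     "top_k", "r_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.simulate and self.matrix_path is None:
            raise ValueError("either an input matrix or simulate=True is required")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # tag the failing stage
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result
        return inner
    return wrap


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle to ``out_dir``.

    Returns a manifest dict (also written as run_manifest.json) listing
    the seed, every threshold applied, and the artifact paths. Identical
    config + seed yields a byte-identical bundle.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save_df(df: pd.DataFrame, name: str, **kwargs) -> None:
        path = out / name
        df.to_csv(path, float_format="%.10g", **kwargs)
        artifacts[name] = str(path)

    # --- input -----------------------------------------------------------
    if config.simulate:
        cohort, annotation, truth = _simulate_stage(config, out, artifacts)
    else:
        cohort, annotation = _load_stage(config)
        truth = None

    # --- preprocess ------------------------------------------------------
    z = _preprocess_stage(cohort)

    # --- discovery -------------------------------------------------------
    model = _discover_fit(z, config)
    screen = screen_metabolites(z, model, vip_threshold=config.vip_threshold,
                                p_threshold=config.p_threshold)
    save_df(screen.table, "metabolite_screen.csv")
    save_df(diagnosis_correlations(z), "diagnosis_correlations.csv")
    save_df(pca_scree(z), "pca_scree.csv")

    # --- pathway impact --------------------------------------------------
    impact = build_impact_table(screen, annotation, k=config.top_k)
    save_df(impact, "pathway_impact.csv", index=False)
    save_df(render_impact_table(impact), "pathway_impact_display.csv", index=False)

    # --- panels ----------------------------------------------------------
    panel_cfg = PanelConfig(n_boot_ci=config.n_boot, rdcv_splits=config.n_boot,
                            n_perm=config.n_perm,
                            seed=config.seed + SEED_OFFSETS["panel"])
    panel_rows = _panel_stage(screen, z, config, panel_cfg)
    save_df(pd.DataFrame(panel_rows), "panel_report.csv", index=False)

    # --- networks --------------------------------------------------------
    network_summary = _network_stage(z, annotation, config, out, artifacts, save_df)

    # --- abnormality partition ------------------------------------------
    profiles = partition_abnormalities(z, screen, z_cut=config.z_cut,
                                       vip_threshold=config.vip_threshold)
    save_df(pd.DataFrame([
        {"sample_id": p.sample_id, "group": p.group,
         "diagnostic": p.diagnostic_count,
         "individualized": p.individualized_count,
         "total": p.total_abnormal} for p in profiles
    ]), "abnormality_partition.csv", index=False)
    save_df(summarize_profiles(profiles), "abnormality_summary.csv")

    manifest = {
        "package": "metsig",
        "version": __version__,
        "seed": config.seed,
        "stage_seed_offsets": SEED_OFFSETS,
        "thresholds": {
            "vip": config.vip_threshold, "p": config.p_threshold,
            "fdr": config.fdr_threshold, "z_cut": config.z_cut,
            "top_k": config.top_k, "r_min": config.r_min,
        },
        "resampling": {"n_boot": config.n_boot, "n_perm": config.n_perm},
        "network_summary": network_summary,
        "n_significant_metabolites": screen.n_significant,
        "artifacts": artifacts,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


@_stage("simulate")
def _simulate_stage(config: RunConfig, out: Path, artifacts: dict):
    sim_cfg = CohortConfig(n_cases=config.n_cases, n_controls=config.n_controls,
                           case_coupling_multiplier=config.case_coupling_multiplier,
                           seed=config.seed + SEED_OFFSETS["simulate"])
    cohort, truth = generate_cohort(sim_cfg)
    write_cohort(cohort, sim_cfg.catalog, out / "cohort.csv", out / "annotation.csv")
    write_truth(truth, out / "truth.json")
    artifacts.update({n: str(out / n) for n in ("cohort.csv", "annotation.csv",
                                                "truth.json")})
    return cohort, sim_cfg.catalog, truth


@_stage("load")
def _load_stage(config: RunConfig):
    return read_cohort(config.matrix_path, config.annotation_path)


@_stage("preprocess")
def _preprocess_stage(cohort: CohortMatrix):
    return zscore_against_controls(log_transform(cohort))


@_stage("discover")
def _discover_fit(z, config: RunConfig):
    return fit_plsda(z, n_components=config.n_components)


@_stage("panel")
def _panel_stage(screen, z, config: RunConfig, panel_cfg: PanelConfig):
    evals = grow_panels(screen, z, max_size=config.max_panel_size,
                        candidate_pool=config.candidate_pool, config=panel_cfg)
    return [{
        "n_members": len(e.members),
        "members": "; ".join(e.members),
        "auroc": e.auroc,
        "auroc_ci_lo": e.auroc_ci[0], "auroc_ci_hi": e.auroc_ci[1],
        "sensitivity": e.contingency.sensitivity,
        "specificity": e.contingency.specificity,
        "accuracy": e.contingency.accuracy,
        "rdcv": e.rdcv_score,
        "permutation_p": e.permutation_p,
        "seed": e.seed,
    } for e in evals]


@_stage("network")
def _network_stage(z, annotation: PathwayAnnotation, config: RunConfig,
                   out: Path, artifacts: dict, save_df):
    case_edges = pairwise_edges(z, "case")
    control_edges = pairwise_edges(z, "control")
    save_df(case_edges.edges, "edges_case.csv", index=False)
    save_df(control_edges.edges, "edges_control.csv", index=False)
    comparison = compare_networks(case_edges, control_edges, config.fdr_threshold)
    save_df(pd.DataFrame([asdict(comparison)]), "network_comparison.csv", index=False)
    for edges, name in ((case_edges, "case"), (control_edges, "control")):
        export_network(edges, out / f"network_{name}.json",
                       out / f"network_{name}.graphml",
                       r_min=config.r_min, annotation=annotation)
        artifacts[f"network_{name}.json"] = str(out / f"network_{name}.json")
        artifacts[f"network_{name}.graphml"] = str(out / f"network_{name}.graphml")
    return asdict(comparison)
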