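"""Synthetic case-control cohorts with planted, recoverable structure.

Emulates the statistical shape of a targeted serum metabolomics study:
358 metabolites across 46 biochemical pathways, 20 cases vs 20 controls,
log-normal intensities with within-pathway correlation blocks, planted
case shifts expressed directly on the control-SD (Z) scale, and an
optional tightening of inter-metabolite coupling in cases.

Control log-intensities are drawn from a one-factor-per-block Gaussian:

    z_ij = sqrt(rho_b) g_i + sqrt(rho_w - rho_b) b_ik + sqrt(1 - rho_w) e_ij

(g global factor, b block factor, e idiosyncratic), which realises an
exchangeable correlation rho_w within pathways and rho_b between them and
is positive semi-definite by construction whenever 0 <= rho_b <= rho_w <= 1.
Case shifts add ``mean_z_shift`` control-log-SD units to affected
metabolites, so a downstream control-referenced Z-score recovers the
planted shift directly. The coupling multiplier c >= 1 tightens case
blocks by shrinking idiosyncratic noise: rho_w_case = 1 - (1 - rho_w)/c^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import CohortMatrix, PathwayAnnotation

__all__ = [
    "EffectSpec",
    "CohortConfig",
    "build_default_catalog",
    "default_effects",
    "generate_cohort",
]

# named pathways with the study's sizes; the remaining 189 metabolites are
# split across 38 null pathways so the catalog totals 358 in 46 pathways
NAMED_PATHWAYS: dict[str, tuple[str, int]] = {
    "ceramide": ("cer", 31),
    "phospholipid": ("pl", 56),
    "sphingomyelin": ("sm", 36),
    "purine": ("pur", 18),
    "pyrimidine": ("pyr", 9),
    "endocannabinoid": ("ecb", 4),
    "eicosanoid": ("eic", 7),
    "branched_chain_amino_acid": ("bcaa", 8),
}
N_TOTAL = 358
N_PATHWAYS = 46


@dataclass(frozen=True)
class EffectSpec:
    """A planted case shift: ``mean_z_shift`` control-SD units applied to
    ``affected_fraction`` of a pathway's metabolites."""

    pathway: str
    mean_z_shift: float
    affected_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.affected_fraction <= 1.0):
            raise ValueError("affected_fraction must lie in [0, 1]")


def default_effects() -> list[EffectSpec]:
    """Planted shifts mirroring the study's per-pathway directions and
    magnitudes (increased lipids, decreased purines/endocannabinoids...)."""
    return [
        EffectSpec("ceramide", +0.80, 11 / 31),
        EffectSpec("phospholipid", +0.78, 4 / 56),
        EffectSpec("phospholipid", -0.66, 1 / 56),
        EffectSpec("sphingomyelin", +0.75, 4 / 36),
        EffectSpec("purine", -0.70, 4 / 18),
        EffectSpec("pyrimidine", +0.89, 1 / 9),
        EffectSpec("pyrimidine", -0.88, 1 / 9),
        EffectSpec("endocannabinoid", -0.84, 1 / 4),
        EffectSpec("endocannabinoid", -0.60, 1 / 4),
        EffectSpec("eicosanoid", -0.84, 1 / 7),
        EffectSpec("branched_chain_amino_acid", +0.64, 1 / 8),
    ]


def build_default_catalog() -> PathwayAnnotation:
    """The default 358-metabolite, 46-pathway annotation."""
    mapping: dict[str, str] = {}
    for pathway, (prefix, size) in NAMED_PATHWAYS.items():
        for i in range(size):
            mapping[f"{prefix}_{i + 1:02d}"] = pathway
    n_named = len(mapping)
    n_null = N_TOTAL - n_named
    n_null_pathways = N_PATHWAYS - len(NAMED_PATHWAYS)
    base, extra = divmod(n_null, n_null_pathways)
    k = 0
    for j in range(n_null_pathways):
        size = base + (1 if j < extra else 0)
        name = f"pathway_{len(NAMED_PATHWAYS) + j + 1:02d}"
        for _ in range(size):
            mapping[f"met_{k + 1:03d}"] = name
            k += 1
    assert len(mapping) == N_TOTAL
    return PathwayAnnotation(mapping)


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort."""

    n_cases: int = 20
    n_controls: int = 20
    catalog: PathwayAnnotation | None = None
    effects: list[EffectSpec] | None = None
    rho_within: float = 0.5
    rho_between: float = 0.05
    case_coupling_multiplier: float = 1.0
    log_mean_range: tuple[float, float] = (2.0, 8.0)
    log_sd_range: tuple[float, float] = (0.2, 0.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("need >= 2 samples per group")
        if not (0.0 <= self.rho_between <= self.rho_within < 1.0):
            raise ValueError(
                "require 0 <= rho_between <= rho_within < 1 for a PSD covariance")
        if self.case_coupling_multiplier < 1.0:
            raise ValueError("case_coupling_multiplier must be >= 1")
        if self.catalog is None:
            self.catalog = build_default_catalog()
        if self.effects is None:
            self.effects = default_effects()


def _block_normal(rng: np.random.Generator, n: int, blocks: list[np.ndarray],
                  m: int, rho_b: float, rho_w: float) -> np.ndarray:
    """n x m standard-normal draws with exchangeable block correlation."""
    g = rng.standard_normal((n, 1))
    e = rng.standard_normal((n, m))
    z = np.sqrt(rho_b) * g + np.sqrt(1.0 - rho_w) * e
    w_block = np.sqrt(rho_w - rho_b)
    for idx in blocks:
        b = rng.standard_normal((n, 1))
        z[:, idx] += w_block * b
    return z


def _planted_shifts(config: CohortConfig) -> pd.Series:
    """Per-metabolite planted Z-shift; effect specs in one pathway claim
    disjoint members in order."""
    catalog = config.catalog
    shifts = pd.Series(0.0, index=list(catalog.mapping))
    cursor: dict[str, int] = {}
    for eff in config.effects:
        members = catalog.members(eff.pathway)
        if not members:
            raise ValueError(f"effect names unknown pathway {eff.pathway!r}")
        n_aff = int(round(eff.affected_fraction * len(members)))
        start = cursor.get(eff.pathway, 0)
        chosen = members[start:start + n_aff]
        cursor[eff.pathway] = start + len(chosen)
        shifts[chosen] = eff.mean_z_shift
    return shifts


def generate_cohort(config: CohortConfig) -> tuple[CohortMatrix, dict]:
    """Draw a cohort; returns the intensity matrix and a truth record.

    The truth record lists the seed, the generative assumptions (log-normal
    baseline — an assumption, not a measured property) and every planted
    per-metabolite Z-shift, so recovery can be scored downstream.
    """
    rng = np.random.default_rng(config.seed)
    catalog = config.catalog
    mets = list(catalog.mapping)
    m = len(mets)
    col_of = {met: j for j, met in enumerate(mets)}
    blocks = [np.array([col_of[x] for x in catalog.members(pw)])
              for pw in catalog.pathways]

    mu = rng.uniform(*config.log_mean_range, size=m)
    sigma = rng.uniform(*config.log_sd_range, size=m)
    shifts = _planted_shifts(config)

    z_ctrl = _block_normal(rng, config.n_controls, blocks, m,
                           config.rho_between, config.rho_within)
    c = config.case_coupling_multiplier
    rho_w_case = 1.0 - (1.0 - config.rho_within) / (c * c)
    z_case = _block_normal(rng, config.n_cases, blocks, m,
                           config.rho_between, rho_w_case)
    z_case = z_case + shifts.to_numpy()[None, :]

    log_x = np.vstack([np.vstack([z_case, z_ctrl]) * sigma + mu])
    intensities = np.exp(log_x)
    sample_ids = ([f"case_{i + 1:02d}" for i in range(config.n_cases)]
                  + [f"control_{i + 1:02d}" for i in range(config.n_controls)])
    labels = pd.Series(["case"] * config.n_cases + ["control"] * config.n_controls,
                       index=sample_ids)
    data = pd.DataFrame(intensities, index=sample_ids, columns=mets)
    truth = {
        "seed": config.seed,
        "baseline_distribution": "log-normal (assumed; instrument-scale "
                                 "distributions are not modelled)",
        "n_cases": config.n_cases,
        "n_controls": config.n_controls,
        "rho_within": config.rho_within,
        "rho_between": config.rho_between,
        "case_coupling_multiplier": config.case_coupling_multiplier,
        "planted_z_shifts": {k: v for k, v in shifts.items() if v != 0.0},
    }
    return CohortMatrix(data=data, labels=labels), truth


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2))
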