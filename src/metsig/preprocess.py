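"""Cohort matrix I/O, log transformation and control-referenced Z-scoring.

The pipeline's universal input is a samples x metabolites intensity table
with a binary case/control label per sample, plus a metabolite -> pathway
annotation. All downstream statistics operate on Z-scores referenced to
the control group: z = (x - mean_control) / sd_control, computed per
metabolite after a natural-log transform.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortMatrix",
    "PathwayAnnotation",
    "ZScoreMatrix",
    "read_cohort",
    "write_cohort",
    "log_transform",
    "zscore_against_controls",
]

log = logging.getLogger(__name__)

CASE, CONTROL = "case", "control"
UNASSIGNED = "unassigned"

#: drop metabolites missing in more than this fraction of samples
MAX_MISSING_FRACTION = 0.20


@dataclass
class PathwayAnnotation:
    """Mapping from metabolite ID to pathway name."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.mapping)) != len(self.mapping):
            raise ValueError("duplicate metabolite IDs in annotation")

    @property
    def pathways(self) -> list[str]:
        seen: dict[str, None] = {}
        for pw in self.mapping.values():
            seen.setdefault(pw, None)
        return list(seen)

    def sizes(self) -> pd.Series:
        return pd.Series(self.mapping, name="pathway").value_counts()

    def pathway_of(self, metabolite_id: str) -> str:
        return self.mapping.get(metabolite_id, UNASSIGNED)

    def members(self, pathway: str) -> list[str]:
        return [m for m, p in self.mapping.items() if p == pathway]

    @property
    def n_metabolites(self) -> int:
        return len(self.mapping)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"metabolite_id": list(self.mapping), "pathway": list(self.mapping.values())}
        )


@dataclass
class CohortMatrix:
    """Samples x metabolites intensities with a case/control label per sample.

    ``data`` is indexed by sample ID with metabolite IDs as columns;
    ``labels`` is aligned to the same index with values 'case'/'control'.
    """

    data: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample IDs")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate metabolite IDs")
        if not self.data.index.equals(self.labels.index):
            raise ValueError("labels not aligned to sample IDs")
        bad = set(self.labels.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"labels must be 'case'/'control'; found {sorted(bad)}")
        self.data.index.name = "sample_id"
        self.labels.index.name = "sample_id"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def case_mask(self) -> np.ndarray:
        return (self.labels == CASE).to_numpy()

    @property
    def n_cases(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.case_mask).sum())

    def require_both_classes(self) -> None:
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValueError("both case and control samples are required")


@dataclass
class ZScoreMatrix:
    """Control-referenced Z-scores; same axes as the source CohortMatrix."""

    z: pd.DataFrame
    labels: pd.Series
    control_means: pd.Series
    control_sds: pd.Series

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.z.columns)

    @property
    def case_mask(self) -> np.ndarray:
        return (self.labels == CASE).to_numpy()

    def case_z(self) -> pd.DataFrame:
        return self.z.loc[self.case_mask]

    def control_z(self) -> pd.DataFrame:
        return self.z.loc[~self.case_mask]

    def mean_case_z(self) -> pd.Series:
        """Per-metabolite mean Z among cases — the study's effect scale."""
        return self.case_z().mean(axis=0)

    def group_values(self, metabolite: str) -> tuple[np.ndarray, np.ndarray]:
        col = self.z[metabolite].to_numpy()
        mask = self.case_mask
        return col[mask], col[~mask]


class FormatError(ValueError):
    """Raised when an input CSV violates the cohort/annotation contract."""


def read_cohort(matrix_path: str | Path,
                annotation_path: str | Path | None = None,
                label_column: str = "group") -> tuple[CohortMatrix, PathwayAnnotation]:
    """Read a cohort CSV (sample_id, group, metabolite columns) and annotation.

    Metabolites absent from the annotation are assigned the pathway
    'unassigned' with a warning. Non-numeric intensities are reported with
    their row/column coordinates.
    """
    df = pd.read_csv(matrix_path, dtype={0: str})
    if df.columns[0] != "sample_id" or label_column not in df.columns[:2]:
        raise FormatError("expected columns: sample_id, group, <metabolites...>")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample IDs: {dups}")
    df = df.set_index("sample_id")
    labels = df.pop(label_column).astype(str)
    bad_labels = set(labels.unique()) - {CASE, CONTROL}
    if bad_labels:
        raise FormatError(f"label column has levels outside case/control: {sorted(bad_labels)}")
    values = df.apply(pd.to_numeric, errors="coerce").astype(float)
    introduced = values.isna() & df.notna()
    if introduced.to_numpy().any():
        r, c = np.argwhere(introduced.to_numpy())[0]
        raise FormatError(
            f"non-numeric intensity at sample {df.index[r]!r}, metabolite {df.columns[c]!r}"
        )
    if (values.to_numpy() < 0).any():
        raise FormatError("negative intensities are not allowed")

    mapping: dict[str, str] = {}
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path)
        if not {"metabolite_id", "pathway"} <= set(ann.columns):
            raise FormatError("annotation needs columns metabolite_id,pathway")
        if ann["metabolite_id"].duplicated().any():
            raise FormatError("duplicate metabolite IDs in annotation")
        mapping = dict(zip(ann["metabolite_id"].astype(str), ann["pathway"].astype(str)))
    missing = [m for m in values.columns if m not in mapping]
    if mapping and missing:
        log.warning("%d metabolites missing from annotation; assigned %r",
                    len(missing), UNASSIGNED)
    for m in missing:
        mapping[m] = UNASSIGNED
    annotation = PathwayAnnotation({m: mapping[m] for m in values.columns})
    return CohortMatrix(data=values, labels=labels), annotation


def write_cohort(cohort: CohortMatrix, annotation: PathwayAnnotation,
                 matrix_path: str | Path, annotation_path: str | Path,
                 label_column: str = "group") -> None:
    out = cohort.data.copy()
    out.insert(0, label_column, cohort.labels)
    out.index.name = "sample_id"
    # repr-precision floats so a write -> read roundtrip is lossless
    out.to_csv(matrix_path, float_format="%.17g")
    annotation.to_frame().to_csv(annotation_path, index=False)


def log_transform(m: CohortMatrix, pseudocount: float | None = None) -> CohortMatrix:
    """Natural log of (intensity + pseudocount); missing values stay missing.

    With ``pseudocount=None`` a pseudocount of 1 is applied only when
    zeros are present, otherwise 0.
    """
    x = m.data.to_numpy(dtype=float)
    if np.nanmin(x) < 0:
        raise ValueError("negative intensities cannot be log-transformed")
    if pseudocount is None:
        pseudocount = 1.0 if np.nanmin(x) == 0 else 0.0
    elif pseudocount <= 0 and np.nanmin(x) == 0:
        raise ValueError("a positive pseudocount is required when zeros are present")
    with np.errstate(divide="ignore"):
        logged = np.log(x + pseudocount)
    return CohortMatrix(data=pd.DataFrame(logged, index=m.data.index,
                                          columns=m.data.columns),
                        labels=m.labels)


def zscore_against_controls(m: CohortMatrix,
                            max_missing_fraction: float = MAX_MISSING_FRACTION
                            ) -> ZScoreMatrix:
    """Scale every sample by the control group's per-metabolite mean and SD.

    Control SD uses the n-1 denominator. Metabolites with zero control SD
    are dropped with a warning, as are metabolites missing in more than
    ``max_missing_fraction`` of samples (the study kept only metabolites
    measurable in every sample). Missing values are excluded pairwise.
    """
    m.require_both_classes()
    if m.n_controls < 2:
        raise ValueError("need >= 2 controls to estimate the reference SD")
    data = m.data
    frac_missing = data.isna().mean(axis=0)
    too_missing = frac_missing[frac_missing > max_missing_fraction].index
    if len(too_missing):
        log.warning("dropping %d metabolites missing in > %.0f%% of samples",
                    len(too_missing), 100 * max_missing_fraction)
        data = data.drop(columns=too_missing)
    controls = data.loc[~m.case_mask]
    mu = controls.mean(axis=0, skipna=True)
    sd = controls.std(axis=0, ddof=1, skipna=True)
    degenerate = sd[(sd == 0) | sd.isna()].index
    if len(degenerate):
        log.warning("dropping %d metabolites with zero/undefined control SD",
                    len(degenerate))
        data = data.drop(columns=degenerate)
        mu = mu.drop(degenerate)
        sd = sd.drop(degenerate)
    z = (data - mu) / sd
    return ZScoreMatrix(z=z, labels=m.labels, control_means=mu, control_sds=sd)
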