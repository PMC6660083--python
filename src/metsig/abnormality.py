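"""Per-subject partition of extreme metabolites into shared "diagnostic"
vs subject-specific "individualized" abnormalities.

A metabolite is abnormal for a subject when |Z| >= 2 (about 4.6% of
metabolites by chance under a Gaussian reference). An abnormal metabolite
is *diagnostic* when the cohort-level screen also selected it (VIP >= 1.5)
and the subject's excursion points the same way as the cohort-level
direction; otherwise it is *individualized* — extreme in that subject but
not part of the shared signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discovery import MetaboliteScreen
from .preprocess import ZScoreMatrix

__all__ = ["AbnormalityProfile", "partition_abnormalities", "summarize_profiles"]

Z_CUT = 2.0
VIP_DIAGNOSTIC = 1.5


@dataclass
class AbnormalityProfile:
    sample_id: str
    group: str
    diagnostic_count: int
    individualized_count: int
    diagnostic_metabolites: list[str]
    individualized_metabolites: list[str]

    @property
    def total_abnormal(self) -> int:
        return self.diagnostic_count + self.individualized_count


def partition_abnormalities(z: ZScoreMatrix, screen: MetaboliteScreen,
                            z_cut: float = Z_CUT,
                            vip_threshold: float = VIP_DIAGNOSTIC,
                            include_controls: bool = True
                            ) -> list[AbnormalityProfile]:
    """Partition each subject's |Z| >= z_cut metabolites.

    Diagnostic: VIP >= vip_threshold and the subject's Z sign matches the
    cohort direction from the screen. Everything else extreme is
    individualized. The partition is exhaustive and exclusive. Control
    subjects' profiles are computed too (useful for calibration) unless
    ``include_controls`` is false.
    """
    table = screen.table.reindex(z.metabolite_ids)
    vip = table["vip"].to_numpy(dtype=float)
    direction_up = (table["direction"] == "up").to_numpy()
    eligible = vip >= vip_threshold

    profiles = []
    for sample_id in z.z.index:
        group = str(z.labels.loc[sample_id])
        if group == "control" and not include_controls:
            continue
        row = z.z.loc[sample_id].to_numpy(dtype=float)
        extreme = np.abs(row) >= z_cut
        concordant = np.where(direction_up, row > 0, row < 0)
        diag_mask = extreme & eligible & concordant
        indiv_mask = extreme & ~diag_mask
        mets = np.asarray(z.metabolite_ids)
        profiles.append(AbnormalityProfile(
            sample_id=str(sample_id),
            group=group,
            diagnostic_count=int(diag_mask.sum()),
            individualized_count=int(indiv_mask.sum()),
            diagnostic_metabolites=list(mets[diag_mask]),
            individualized_metabolites=list(mets[indiv_mask]),
        ))
    return profiles


def summarize_profiles(profiles: list[AbnormalityProfile]) -> pd.DataFrame:
    """Per-group mean +/- SE of diagnostic / individualized / total counts."""
    df = pd.DataFrame([
        {"sample_id": p.sample_id, "group": p.group,
         "diagnostic": p.diagnostic_count,
         "individualized": p.individualized_count,
         "total": p.total_abnormal}
        for p in profiles
    ])
    def agg(g: pd.DataFrame) -> pd.Series:
        out = {}
        for col in ("diagnostic", "individualized", "total"):
            out[f"{col}_mean"] = g[col].mean()
            out[f"{col}_se"] = g[col].std(ddof=1) / np.sqrt(len(g))
        out["n_subjects"] = len(g)
        return pd.Series(out)
    return df.groupby("group").apply(agg, include_groups=False)
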