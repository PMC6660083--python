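"""Pathway-level aggregation of the metabolite screen.

The top-k metabolites by VIP are mapped to pathways; each hit pathway gets
expected hits (pathway share of the metabolome times k), fold enrichment
(observed/expected), a "metabolic impact" (the sum of member VIPs among
the selected metabolites), its fraction of the total impact, and counts of
increased/decreased members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discovery import MetaboliteScreen
from .preprocess import PathwayAnnotation

__all__ = ["expected_hits", "fold_enrichment", "build_impact_table", "round_half_up"]

log = logging.getLogger(__name__)

DEFAULT_TOP_K = 30


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal display rounding (0.25 -> 0.3 at 1 digit), as printed tables use."""
    factor = 10 ** ndigits
    return float(np.floor(x * factor + 0.5) / factor)


def expected_hits(n_pathway: int, n_total: int, k: int) -> float:
    """Expected pathway hits in a top-k list: (n_pathway / n_total) * k."""
    if n_total <= 0 or k <= 0:
        raise ValueError("totals must be positive")
    if not (0 < n_pathway <= n_total):
        raise ValueError("require 0 < n_pathway <= n_total")
    return n_pathway / n_total * k


def fold_enrichment(observed: int, expected: float) -> float:
    """Observed / expected hits, on the unrounded expected value."""
    if expected <= 0:
        raise ValueError("expected must be positive")
    if observed < 0:
        raise ValueError("observed must be non-negative")
    return observed / expected


def build_impact_table(screen: MetaboliteScreen, annotation: PathwayAnnotation,
                       k: int = DEFAULT_TOP_K,
                       include_empty: bool = False) -> pd.DataFrame:
    """Build the pathway impact table from the top-k screened metabolites.

    Selection takes the k highest-VIP metabolites among those passing the
    joint significance rule (falling back to all of them, with a warning,
    when fewer than k are significant). Impact is the summed VIP of a
    pathway's selected members; impact_fraction normalises over pathways
    with at least one hit. Rows sorted by impact descending. Pathways with
    zero hits are omitted unless ``include_empty``.
    """
    sig = screen.table[screen.table["significant"]]
    if len(sig) < k:
        log.warning("only %d significant metabolites for top-%d selection; using all",
                    len(sig), k)
    top = sig.head(k)
    n_total = annotation.n_metabolites
    sizes = annotation.sizes()
    pathway_of = top.index.to_series().map(annotation.pathway_of)

    rows = []
    for pathway in annotation.pathways:
        members = top[pathway_of == pathway]
        observed = len(members)
        if observed == 0 and not include_empty:
            continue
        n_pw = int(sizes.get(pathway, 0))
        if n_pw == 0:
            continue
        exp = expected_hits(n_pw, n_total, len(top)) if len(top) else 0.0
        rows.append({
            "pathway": pathway,
            "n_measured": n_pw,
            "proportion": n_pw / n_total,
            "expected_hits": exp,
            "observed_hits": observed,
            "fold_enrichment": fold_enrichment(observed, exp) if observed else 0.0,
            "impact": float(members["vip"].sum()),
            "n_increased": int((members["direction"] == "up").sum()),
            "n_decreased": int((members["direction"] == "down").sum()),
        })
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    total_impact = table.loc[table["observed_hits"] > 0, "impact"].sum()
    table["impact_fraction"] = np.where(
        total_impact > 0, table["impact"] / total_impact, 0.0)
    return (table.sort_values(["impact", "pathway"], ascending=[False, True],
                              kind="mergesort")
                 .reset_index(drop=True))


def render_impact_table(table: pd.DataFrame) -> pd.DataFrame:
    """Display-rounded copy: 1-decimal expected hits / enrichment / impact,
    whole-percent impact fractions."""
    out = table.copy()
    out["proportion"] = out["proportion"].map(lambda v: round_half_up(v, 2))
    for col in ("expected_hits", "fold_enrichment", "impact"):
        out[col] = out[col].map(lambda v: round_half_up(v, 1))
    out["impact_fraction"] = out["impact_fraction"].map(
        lambda v: f"{round_half_up(100 * v, 0):.0f}%")
    return out
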