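"""Per-group metabolite correlation networks and differential coupling.

All m(m-1)/2 unordered metabolite pairs get Pearson r and Spearman rho on
the group's Z-scores. Edge significance uses the Spearman p (t
approximation) with BH FDR and Storey q computed within the group over
all pairs. The coupling comparison counts FDR-significant pairs per group
and contrasts them with a two-sided Fisher exact test; the display export
(d3 JSON + GraphML) applies the Pearson r >= 0.85 threshold used for
figure rendering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import PathwayAnnotation, ZScoreMatrix
from .stats_core import bh_fdr, fisher_exact_2x2, storey_q

__all__ = [
    "EdgeTable",
    "NetworkComparison",
    "pairwise_edges",
    "count_significant",
    "compare_networks",
    "export_network",
    "neighbor_subnetwork",
]

FDR_THRESHOLD = 0.05
DISPLAY_R_MIN = 0.85


@dataclass
class EdgeTable:
    """One row per unordered metabolite pair within one group."""

    edges: pd.DataFrame  # metabolite_a, metabolite_b, pearson_r, spearman_rho, p, fdr, q
    group: str
    metabolite_ids: list[str]

    @property
    def n_pairs(self) -> int:
        return len(self.edges)


@dataclass
class NetworkComparison:
    n_pairs_total: int
    significant_case: int
    significant_control: int
    positive_case: int
    negative_case: int
    positive_control: int
    negative_control: int
    ratio: float
    fisher_p: float


def _pair_index(m: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(m, k=1)


def _corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t approximation t = r sqrt((n-2)/(1-r^2))."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(t), 1.0, p)      # constant columns -> r flagged 0
    p = np.where(np.isinf(t), 0.0, p)      # |r| == 1
    return np.clip(p, 0.0, 1.0)


def pairwise_edges(z: ZScoreMatrix, group: str) -> EdgeTable:
    """All unordered pairwise correlations within one group's samples.

    Constant metabolites get correlation 0 (flagged via p = 1) for all
    their pairs.
    """
    if group not in ("case", "control"):
        raise ValueError("group must be 'case' or 'control'")
    sub = z.case_z() if group == "case" else z.control_z()
    n = len(sub)
    if n < 4:
        raise ValueError("need >= 4 samples per group for pairwise correlations")
    X = sub.to_numpy(dtype=float)
    sd = X.std(axis=0)
    constant = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        pear = np.corrcoef(X, rowvar=False)
        ranks = np.apply_along_axis(stats.rankdata, 0, X)
        spear = np.corrcoef(ranks, rowvar=False)
    for mat in (pear, spear):
        mat[constant, :] = 0.0
        mat[:, constant] = 0.0
        np.fill_diagonal(mat, 1.0)
    iu, ju = _pair_index(X.shape[1])
    rho = spear[iu, ju]
    p = _corr_pvalues(rho, n)
    pair_constant = constant[iu] | constant[ju]
    p[pair_constant] = 1.0
    fdr = bh_fdr(p).adjusted
    q = storey_q(p).adjusted if p.size >= 10 else fdr
    mets = np.asarray(z.metabolite_ids)
    edges = pd.DataFrame({
        "metabolite_a": mets[iu],
        "metabolite_b": mets[ju],
        "pearson_r": pear[iu, ju],
        "spearman_rho": rho,
        "p": p,
        "fdr": fdr,
        "q": q,
    })
    return EdgeTable(edges=edges, group=group, metabolite_ids=list(mets))


def count_significant(edges: EdgeTable,
                      fdr_threshold: float = FDR_THRESHOLD) -> dict:
    """Counts of FDR-significant pairs, split by the sign of rho."""
    sig = edges.edges[edges.edges["fdr"] < fdr_threshold]
    positive = int((sig["spearman_rho"] > 0).sum())
    negative = int((sig["spearman_rho"] < 0).sum())
    return {"total": len(sig), "positive": positive, "negative": negative}


def compare_networks(case_edges: EdgeTable, control_edges: EdgeTable,
                     fdr_threshold: float = FDR_THRESHOLD) -> NetworkComparison:
    """Differential coupling: ratio of significant pair counts and a
    two-sided Fisher exact test on {significant, not} x {case, control}."""
    if case_edges.metabolite_ids != control_edges.metabolite_ids:
        raise ValueError("edge tables cover different metabolite sets")
    n_pairs = case_edges.n_pairs
    cs = count_significant(case_edges, fdr_threshold)
    ct = count_significant(control_edges, fdr_threshold)
    return _comparison_from_counts(cs, ct, n_pairs)


def comparison_from_counts(significant_case: int, significant_control: int,
                           n_pairs_total: int,
                           positive_case: int = 0, negative_case: int = 0,
                           positive_control: int = 0, negative_control: int = 0
                           ) -> NetworkComparison:
    """Build the comparison directly from pair counts (e.g. published
    tables), without edge tables."""
    cs = {"total": significant_case, "positive": positive_case,
          "negative": negative_case}
    ct = {"total": significant_control, "positive": positive_control,
          "negative": negative_control}
    return _comparison_from_counts(cs, ct, n_pairs_total)


def _comparison_from_counts(cs: dict, ct: dict, n_pairs: int) -> NetworkComparison:
    fisher = fisher_exact_2x2(cs["total"], n_pairs - cs["total"],
                              ct["total"], n_pairs - ct["total"])
    ratio = cs["total"] / ct["total"] if ct["total"] > 0 else float("inf")
    return NetworkComparison(
        n_pairs_total=n_pairs,
        significant_case=cs["total"], significant_control=ct["total"],
        positive_case=cs["positive"], negative_case=cs["negative"],
        positive_control=ct["positive"], negative_control=ct["negative"],
        ratio=ratio, fisher_p=fisher.p_value,
    )


def _display_edges(edges: EdgeTable, r_min: float, absolute: bool) -> pd.DataFrame:
    r = edges.edges["pearson_r"]
    mask = (r.abs() >= r_min) if absolute else (r >= r_min)
    return edges.edges[mask]


def export_network(edges: EdgeTable, json_path: str | Path,
                   graphml_path: str | Path | None = None,
                   r_min: float = DISPLAY_R_MIN, absolute: bool = False,
                   annotation: PathwayAnnotation | None = None) -> dict:
    """Write the display network (Pearson r >= r_min; ``absolute`` switches
    to |r| >= r_min) as d3 force-layout JSON and optionally GraphML.
    Isolated nodes are dropped. Returns the d3 document."""
    kept = _display_edges(edges, r_min, absolute)
    nodes = sorted(set(kept["metabolite_a"]) | set(kept["metabolite_b"]))
    doc = {
        "nodes": [
            {"id": node,
             "group": annotation.pathway_of(node) if annotation else "unassigned"}
            for node in nodes
        ],
        "links": [
            {"source": row.metabolite_a, "target": row.metabolite_b,
             "weight": float(row.pearson_r),
             "sign": 1 if row.pearson_r >= 0 else -1}
            for row in kept.itertuples()
        ],
    }
    Path(json_path).write_text(json.dumps(doc, indent=2))
    if graphml_path is not None:
        g = nx.Graph()
        for node in doc["nodes"]:
            g.add_node(node["id"], group=node["group"])
        for link in doc["links"]:
            g.add_edge(link["source"], link["target"],
                       weight=link["weight"], sign=link["sign"])
        nx.write_graphml(g, graphml_path)
    return doc


def neighbor_subnetwork(edges: EdgeTable, metabolite_id: str, top_k: int = 25,
                        annotation: PathwayAnnotation | None = None
                        ) -> pd.DataFrame:
    """Top partners of one metabolite by |rho|, with sign, FDR and pathway
    (first-neighbour subnetwork of a classifier metabolite)."""
    if metabolite_id not in edges.metabolite_ids:
        raise ValueError(f"unknown metabolite {metabolite_id!r}")
    e = edges.edges
    mask = (e["metabolite_a"] == metabolite_id) | (e["metabolite_b"] == metabolite_id)
    sub = e[mask].copy()
    sub["neighbor"] = np.where(sub["metabolite_a"] == metabolite_id,
                               sub["metabolite_b"], sub["metabolite_a"])
    sub["sign"] = np.where(sub["spearman_rho"] >= 0, "positive", "negative")
    sub = (sub.assign(abs_rho=sub["spearman_rho"].abs())
              .sort_values(["abs_rho", "neighbor"], ascending=[False, True],
                           kind="mergesort")
              .head(top_k))
    if annotation is not None:
        sub["pathway"] = sub["neighbor"].map(annotation.pathway_of)
    cols = ["neighbor", "spearman_rho", "pearson_r", "sign", "p", "fdr", "q"]
    if annotation is not None:
        cols.append("pathway")
    return sub[cols].reset_index(drop=True)
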