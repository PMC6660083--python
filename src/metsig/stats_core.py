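"""Statistical primitives shared by every analysis stage.

Thin, validated wrappers around scipy/statsmodels for the rank tests,
multiple-testing procedures, exact 2x2 tests, AUROC and contingency
metrics used throughout the pipeline, plus an in-house Storey q-value
estimator (no installed package exposes the smoothed-pi0 q-value).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "TestResult",
    "AdjustedPvalues",
    "ContingencyMetrics",
    "mann_whitney_u",
    "bh_fdr",
    "storey_q",
    "fisher_exact_2x2",
    "auroc_from_scores",
    "panel_contingency_metrics",
]

# combined sample size at or below which the exact U distribution is used
EXACT_U_LIMIT = 20


class Method(str, Enum):
    exact = "exact"
    normal_approx = "normal_approx"


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its two-sided p-value."""

    statistic: float
    p_value: float
    method: Method

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0,1]: {self.p_value}")


@dataclass(frozen=True)
class AdjustedPvalues:
    raw: np.ndarray
    adjusted: np.ndarray
    method: str
    pi0: float = 1.0

    def __post_init__(self) -> None:
        if len(self.raw) != len(self.adjusted):
            raise ValueError("raw/adjusted length mismatch")


@dataclass(frozen=True)
class ContingencyMetrics:
    tp: int
    fn: int
    fp: int
    tn: int
    sensitivity: float
    specificity: float
    accuracy: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]


def _as_finite_array(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def mann_whitney_u(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test; U is reported for ``group_a``.

    The exact null distribution is used whenever the combined sample size
    is at most 20 and there are no ties across groups; otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    a = _as_finite_array(group_a, "group_a")
    b = _as_finite_array(group_b, "group_b")
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= EXACT_U_LIMIT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return TestResult(
        statistic=float(res.statistic),
        p_value=min(1.0, float(res.pvalue)),
        method=Method.exact if method == "exact" else Method.normal_approx,
    )


def _validated_pvals(pvals: Sequence[float]) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_fdr(pvals: Sequence[float]) -> AdjustedPvalues:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = _validated_pvals(pvals)
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return AdjustedPvalues(raw=p, adjusted=adj, method="BH", pi0=1.0)


DEFAULT_LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)


def estimate_pi0(pvals: np.ndarray, lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID) -> float:
    """Storey's smoothed estimate of the null proportion pi0.

    pi0_hat(lambda) = #{p > lambda} / (m (1 - lambda)) is smoothed with a
    precision-weighted cubic fit over the lambda grid (an interpolating
    spline would just reproduce the noisy right-most point; the weights
    1/sqrt(1-lambda) reflect the shrinking tail count) and read off at the
    largest lambda; estimates above 1 fall back to 1.
    """
    lam = np.asarray(lambda_grid, dtype=float)
    if lam.size < 4 or np.unique(lam).size < 4 or np.any(lam <= 0) or np.any(lam >= 1):
        raise ValueError("lambda grid must hold >= 4 distinct values in (0, 1)")
    lam = np.sort(lam)
    m = pvals.size
    pi0_lam = np.array([(pvals > l).sum() / (m * (1.0 - l)) for l in lam])
    coef = np.polynomial.polynomial.polyfit(lam, pi0_lam, 3, w=np.sqrt(1.0 - lam))
    pi0 = float(np.polynomial.polynomial.polyval(lam[-1], coef))
    if pi0 > 1.0 or not np.isfinite(pi0):
        pi0 = 1.0
    return max(pi0, 1.0 / m)


def storey_q(pvals: Sequence[float],
             lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
             pi0: float | None = None) -> AdjustedPvalues:
    """Storey q-values: pi0 times the BH step-up quantity.

    ``pi0`` may be forced (pi0=1 reduces exactly to BH); otherwise it is
    estimated by :func:`estimate_pi0`, which needs >= 10 p-values.
    """
    p = _validated_pvals(pvals)
    if pi0 is None:
        if p.size < 10:
            raise ValueError("need >= 10 p-values to estimate pi0")
        pi0 = estimate_pi0(p, np.asarray(lambda_grid, dtype=float))
    if not (0.0 < pi0 <= 1.0):
        raise ValueError("pi0 must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * ranked * m / np.arange(1, m + 1)
    # step-up: enforce monotonicity from the largest p downwards
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return AdjustedPvalues(raw=p, adjusted=out, method="Storey", pi0=pi0)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher exact test on the table [[a, b], [c, d]].

    Two-sidedness by the probability-mass convention: the p-value sums
    hypergeometric probabilities no larger than the observed table's.
    """
    counts = np.array([[a, b], [c, d]])
    if np.any(counts < 0) or counts.dtype.kind not in "iu" and np.any(counts != np.floor(counts)):
        raise ValueError("counts must be non-negative integers")
    if counts.sum() == 0:
        raise ValueError("at least one positive margin required")
    odds, p = stats.fisher_exact(counts, alternative="two-sided")
    return TestResult(statistic=float(odds), p_value=min(1.0, float(p)),
                      method=Method.exact)


def auroc_from_scores(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability a random positive outscores a random negative; ties count 1/2.

    Computed via the rank-sum identity AUROC = (R1 - n1(n1+1)/2) / (n1 n0),
    which handles ties exactly.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    pos = y == 1 if y.dtype.kind in "biu" else y.astype(bool)
    n1 = int(pos.sum())
    n0 = int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    r1 = ranks[pos].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def panel_contingency_metrics(tp: int, fn: int, fp: int, tn: int,
                              alpha: float = 0.05) -> ContingencyMetrics:
    """Sensitivity/specificity/accuracy with Wilson score 95% CIs."""
    for name, v in (("tp", tp), ("fn", fn), ("fp", fp), ("tn", tn)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a non-negative integer")
    if tp + fn == 0 or fp + tn == 0:
        raise ValueError("both a positive and a negative margin are required")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / (tp + fn + fp + tn)
    sens_ci = proportion_confint(tp, tp + fn, alpha=alpha, method="wilson")
    spec_ci = proportion_confint(tn, tn + fp, alpha=alpha, method="wilson")
    return ContingencyMetrics(
        tp=int(tp), fn=int(fn), fp=int(fp), tn=int(tn),
        sensitivity=sens, specificity=spec, accuracy=acc,
        sensitivity_ci=(float(sens_ci[0]), float(sens_ci[1])),
        specificity_ci=(float(spec_ci[0]), float(spec_ci[1])),
    )
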