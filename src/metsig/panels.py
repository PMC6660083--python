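"""Sparse diagnostic panels (1-6 metabolites) and their validation.

A panel is scored by a seeded random forest on its Z-score columns.
Apparent performance uses out-of-bag class probabilities (resubstitution
probabilities of a forest are essentially the labels themselves and carry
no information about generalisation); validation uses repeated double
cross-validation (rdCV: 100 stratified 2/3-in / 1/3-out resamples, model
refit per split, mean held-out AUROC) and an empirical permutation p-value
with the (b+1)/(B+1) convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedShuffleSplit

from .discovery import MetaboliteScreen
from .preprocess import ZScoreMatrix
from .stats_core import ContingencyMetrics, auroc_from_scores, panel_contingency_metrics

__all__ = [
    "PanelConfig",
    "PanelEvaluation",
    "PowerConfig",
    "evaluate_panel",
    "rdcv_score",
    "permutation_pvalue",
    "grow_panels",
    "required_sample_size",
]


@dataclass
class PanelConfig:
    n_trees: int = 200          # forest size for the apparent (OOB) model
    n_boot_ci: int = 100        # bootstrap resamples for the AUROC CI
    rdcv_splits: int = 100      # stratified 2/3-in 1/3-out resamples
    train_fraction: float = 2 / 3
    n_perm: int = 1000          # label permutations for the empirical p
    perm_statistic: str = "auroc"  # 'auroc' | 'rdcv' | 'mean_score'
    resample_n_trees: int = 50  # lighter forest inside rdCV/permutation loops
    selection_splits: int = 30  # rdCV splits while scoring greedy candidates
    seed: int = 0


@dataclass
class PanelEvaluation:
    members: list[str]
    auroc: float
    auroc_ci: tuple[float, float]
    contingency: ContingencyMetrics
    rdcv_score: float
    permutation_p: float
    seed: int


@dataclass(frozen=True)
class PowerConfig:
    """Planning parameters for a future two-group study."""

    alpha: float = 0.05
    power: float = 0.8
    effect_size: float = 0.51
    n_predictors: int = 6

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")


def _panel_matrix(z: ZScoreMatrix, members: list[str]) -> tuple[np.ndarray, np.ndarray]:
    unknown = [m for m in members if m not in z.z.columns]
    if unknown:
        raise ValueError(f"unknown panel members: {unknown}")
    X = z.z[members].to_numpy(dtype=float)
    y = (z.labels == "case").to_numpy(dtype=int)
    if y.sum() in (0, y.size):
        raise ValueError("both classes must be present")
    return X, y


def _oob_case_probability(X: np.ndarray, y: np.ndarray, n_trees: int,
                          seed: int) -> np.ndarray:
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", oob_score=True,
        bootstrap=True, random_state=seed, n_jobs=1,
    ).fit(X, y)
    prob = forest.oob_decision_function_[:, list(forest.classes_).index(1)]
    # a sample in every bootstrap of every tree has no OOB vote; call it 0.5
    return np.where(np.isfinite(prob), prob, 0.5)


def _bootstrap_auroc_ci(scores: np.ndarray, y: np.ndarray, n_boot: int,
                        rng: np.random.Generator) -> tuple[float, float]:
    n = y.size
    vals = []
    while len(vals) < n_boot:
        idx = rng.integers(0, n, size=n)
        if y[idx].sum() in (0, n):
            continue
        vals.append(auroc_from_scores(scores[idx], y[idx]))
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


def _youden_contingency(scores: np.ndarray, y: np.ndarray) -> ContingencyMetrics:
    fpr, tpr, thresholds = roc_curve(y, scores)
    best = np.argmax(tpr - fpr)
    predicted = scores >= thresholds[best]
    tp = int(np.sum(predicted & (y == 1)))
    fn = int(np.sum(~predicted & (y == 1)))
    fp = int(np.sum(predicted & (y == 0)))
    tn = int(np.sum(~predicted & (y == 0)))
    return panel_contingency_metrics(tp, fn, fp, tn)


def rdcv_score(z: ZScoreMatrix, members: list[str], n_boot: int = 100,
               train_fraction: float = 2 / 3, seed: int = 0,
               n_trees: int = 100) -> float:
    """Mean held-out AUROC over stratified random 2/3-in / 1/3-out splits,
    refitting a seeded forest per split. Deterministic given the seed."""
    X, y = _panel_matrix(z, members)
    splitter = StratifiedShuffleSplit(n_splits=n_boot, train_size=train_fraction,
                                      random_state=seed)
    scores = []
    for i, (tr, te) in enumerate(splitter.split(X, y)):
        forest = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt",
            random_state=seed + i + 1, n_jobs=1,
        ).fit(X[tr], y[tr])
        prob = forest.predict_proba(X[te])[:, list(forest.classes_).index(1)]
        scores.append(auroc_from_scores(prob, y[te]))
    return float(np.mean(scores))


def _statistic(name: str, X: np.ndarray, y: np.ndarray, seed: int,
               config: PanelConfig) -> float:
    if name == "auroc":
        prob = _oob_case_probability(X, y, config.resample_n_trees, seed)
        return auroc_from_scores(prob, y)
    if name == "mean_score":
        # model-free: AUROC of the panel's mean Z — cheap enough for
        # large calibration studies of the permutation machinery
        return auroc_from_scores(X.mean(axis=1), y)
    if name == "rdcv":
        splitter = StratifiedShuffleSplit(n_splits=min(config.rdcv_splits, 30),
                                          train_size=config.train_fraction,
                                          random_state=seed)
        vals = []
        for i, (tr, te) in enumerate(splitter.split(X, y)):
            forest = RandomForestClassifier(
                n_estimators=config.resample_n_trees, max_features="sqrt",
                random_state=seed + i + 1, n_jobs=1,
            ).fit(X[tr], y[tr])
            prob = forest.predict_proba(X[te])[:, list(forest.classes_).index(1)]
            vals.append(auroc_from_scores(prob, y[te]))
        return float(np.mean(vals))
    raise ValueError(f"unknown statistic {name!r}")


def permutation_pvalue(z: ZScoreMatrix, members: list[str], B: int = 1000,
                       seed: int = 0, statistic: str = "auroc",
                       config: PanelConfig | None = None) -> float:
    """Empirical p-value: labels permuted B times, p = (1 + #{perm >= obs})
    / (B + 1); never zero."""
    if B < 1:
        raise ValueError("B must be >= 1")
    config = config or PanelConfig()
    X, y = _panel_matrix(z, members)
    rng = np.random.default_rng(seed)
    observed = _statistic(statistic, X, y, seed, config)
    exceed = 0
    for b in range(B):
        y_perm = rng.permutation(y)
        if _statistic(statistic, X, y_perm, seed + b + 1, config) >= observed:
            exceed += 1
    return (1 + exceed) / (B + 1)


def evaluate_panel(z: ZScoreMatrix, members: list[str],
                   config: PanelConfig | None = None) -> PanelEvaluation:
    """Full panel report: OOB-forest AUROC with a 100-resample bootstrap
    percentile CI, a 2x2 table at the Youden-J operating point, the rdCV
    score, and the permutation p-value."""
    config = config or PanelConfig()
    X, y = _panel_matrix(z, members)
    prob = _oob_case_probability(X, y, config.n_trees, config.seed)
    auroc = auroc_from_scores(prob, y)
    rng = np.random.default_rng(config.seed)
    ci = _bootstrap_auroc_ci(prob, y, config.n_boot_ci, rng)
    contingency = _youden_contingency(prob, y)
    rdcv = rdcv_score(z, members, n_boot=config.rdcv_splits,
                      train_fraction=config.train_fraction,
                      seed=config.seed, n_trees=config.resample_n_trees)
    if config.n_perm > 0:
        perm_p = permutation_pvalue(z, members, B=config.n_perm,
                                    seed=config.seed,
                                    statistic=config.perm_statistic,
                                    config=config)
    else:
        perm_p = float("nan")
    return PanelEvaluation(members=list(members), auroc=auroc, auroc_ci=ci,
                           contingency=contingency, rdcv_score=rdcv,
                           permutation_p=perm_p, seed=config.seed)


def grow_panels(screen: MetaboliteScreen, z: ZScoreMatrix, max_size: int = 6,
                candidate_pool: int = 12,
                config: PanelConfig | None = None) -> list[PanelEvaluation]:
    """Greedy forward panel selection: starting from the best single
    candidate (by rdCV), at each step add the candidate maximising the
    rdCV score; emits a full evaluation for every panel size 1..max_size.

    Candidates are the ``candidate_pool`` top metabolites of the screen
    (by its VIP ordering). Greedy search is not exhaustive — other sets
    may perform equally well.
    """
    config = config or PanelConfig()
    candidates = list(screen.table.head(candidate_pool).index)
    if len(candidates) < max_size:
        raise ValueError("candidate pool smaller than max panel size")
    chosen: list[str] = []
    evaluations = []
    for step in range(max_size):
        best_member, best_score = None, -np.inf
        for cand in candidates:
            if cand in chosen:
                continue
            score = rdcv_score(z, chosen + [cand], n_boot=config.selection_splits,
                               train_fraction=config.train_fraction,
                               seed=config.seed, n_trees=config.resample_n_trees)
            if score > best_score:
                best_member, best_score = cand, score
        chosen.append(best_member)
        evaluations.append(evaluate_panel(z, list(chosen), config))
    return evaluations


def required_sample_size(p: PowerConfig | None = None,
                         inflate_for_predictors: bool = True) -> dict:
    """Per-group sample size for a two-group comparison at effect size d.

    Normal-approximation formula n = 2 (z_{1-alpha/2} + z_{power})^2 / d^2
    per group, optionally inflated by adding one subject per group per
    predictor in the downstream multivariable model. The convention is
    reported in the output because conventions differ between tools.
    """
    p = p or PowerConfig()
    z_a = stats.norm.ppf(1 - p.alpha / 2)
    z_b = stats.norm.ppf(p.power)
    base = 2 * (z_a + z_b) ** 2 / p.effect_size ** 2
    n = math.ceil(base)
    if inflate_for_predictors:
        n += p.n_predictors
    return {
        "n_per_group": n,
        "base_n_per_group": base,
        "alpha": p.alpha,
        "power": p.power,
        "effect_size": p.effect_size,
        "n_predictors": p.n_predictors,
        "convention": (
            "normal-approximation two-group n = 2(z_{1-a/2}+z_{power})^2/d^2 "
            "per group"
            + (", plus one subject per group per model predictor"
               if inflate_for_predictors else ", no predictor inflation")
        ),
    }
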