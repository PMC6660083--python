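"""Supervised discovery: PLS-DA with VIP scores, the joint VIP/U-test
significance rule, univariate diagnosis correlations, random-forest
ranking, a pathway-set group shift test, and a PCA scree.

The PLS-DA is a NIPALS PLS1 against the centered case indicator. Variable
importance in projection follows the standard Wold formula

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a )

where SSY_a is the response variance explained by component a, so the
mean squared VIP is exactly 1 for every fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .preprocess import ZScoreMatrix
from .stats_core import mann_whitney_u

__all__ = [
    "PLSDAModel",
    "MetaboliteScreen",
    "fit_plsda",
    "vip_scores",
    "screen_metabolites",
    "diagnosis_correlations",
    "rf_rank",
    "group_shift_test",
    "pca_scree",
]

VIP_THRESHOLD = 1.5
P_THRESHOLD = 0.05


@dataclass
class PLSDAModel:
    """Fitted NIPALS PLS1 state: per-component weights w_a (unit norm),
    scores t_a, X-loadings p_a and explained response variance SSY_a."""

    metabolite_ids: list[str]
    weights: np.ndarray        # (m, A), each column unit norm
    scores: np.ndarray         # (n, A), mutually orthogonal
    x_loadings: np.ndarray     # (m, A)
    y_loadings: np.ndarray     # (A,)
    ssy: np.ndarray            # (A,) response variance explained per component
    total_ssy: float           # centered response sum of squares

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def y_variance_explained(self) -> float:
        return float(self.ssy.sum() / self.total_ssy)


def _case_indicator(labels: pd.Series) -> np.ndarray:
    y = (labels == "case").to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both classes must be present")
    return y


def fit_plsda(z: ZScoreMatrix, n_components: int = 2) -> PLSDAModel:
    """Fit a PLS1 discriminant model of the case indicator on the Z-scores.

    X columns and the 0/1 response are mean-centered; components are
    extracted sequentially with deflation of both X and y.
    """
    X = z.z.to_numpy(dtype=float).copy()
    y = _case_indicator(z.labels)
    n, m = X.shape
    if not (1 <= n_components <= min(n - 1, m)):
        raise ValueError("n_components must lie in [1, min(samples-1, metabolites)]")
    X -= X.mean(axis=0)
    y = y - y.mean()
    total_ssy = float(y @ y)

    W = np.zeros((m, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((m, n_components))
    q = np.zeros(n_components)
    ssy = np.zeros(n_components)
    for a in range(n_components):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            # response fully deflated; truncate to the components found
            W, T, P, q, ssy = (arr[..., :a] for arr in (W, T, P, q, ssy))
            break
        w /= norm
        t = X @ w
        tt = float(t @ t)
        p_load = X.T @ t / tt
        q_a = float(y @ t) / tt
        X -= np.outer(t, p_load)
        y = y - q_a * t
        W[:, a], T[:, a], P[:, a] = w, t, p_load
        q[a] = q_a
        ssy[a] = q_a * q_a * tt
    return PLSDAModel(
        metabolite_ids=z.metabolite_ids,
        weights=W, scores=T, x_loadings=P, y_loadings=q,
        ssy=ssy, total_ssy=total_ssy,
    )


def vip_scores(model: PLSDAModel) -> pd.Series:
    """Wold VIP per metabolite; sum of squared VIPs equals the number of
    metabolites."""
    if model.n_components == 0 or model.ssy.sum() <= 0:
        raise ValueError("model explains no response variance; VIP undefined")
    m = len(model.metabolite_ids)
    w2 = model.weights ** 2          # columns already unit norm
    vip = np.sqrt(m * (w2 @ model.ssy) / model.ssy.sum())
    return pd.Series(vip, index=model.metabolite_ids, name="vip")


@dataclass
class MetaboliteScreen:
    """Per-metabolite VIP, U-test p, direction and the joint significance
    flag (VIP > 1.5 and p <= 0.05), ranked by VIP descending."""

    table: pd.DataFrame  # index metabolite_id; vip, u_p, direction, significant

    def top(self, k: int) -> pd.DataFrame:
        return self.table.head(k)

    def top_significant(self, k: int) -> pd.DataFrame:
        sig = self.table[self.table["significant"]]
        return sig.head(k)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def vip(self) -> pd.Series:
        return self.table["vip"]


def screen_metabolites(z: ZScoreMatrix, model: PLSDAModel,
                       vip_threshold: float = VIP_THRESHOLD,
                       p_threshold: float = P_THRESHOLD) -> MetaboliteScreen:
    """Apply the joint selection rule: VIP above threshold AND a two-sided
    Mann-Whitney U p at or below threshold; direction is the sign of the
    mean case Z. Rows ranked by VIP desc, ties by p asc then ID."""
    if model.metabolite_ids != z.metabolite_ids:
        raise ValueError("model and matrix metabolite axes differ")
    vip = vip_scores(model)
    mask = z.case_mask
    values = z.z.to_numpy(dtype=float)
    pvals = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        pvals[j] = mann_whitney_u(values[mask, j], values[~mask, j]).p_value
    mean_case = z.mean_case_z()
    table = pd.DataFrame({
        "vip": vip,
        "u_p": pvals,
        "mean_case_z": mean_case,
        "direction": np.where(mean_case >= 0, "up", "down"),
    })
    table["significant"] = (table["vip"] > vip_threshold) & (table["u_p"] <= p_threshold)
    table = (table.reset_index(names="metabolite_id")
                  .sort_values(["vip", "u_p", "metabolite_id"],
                               ascending=[False, True, True], kind="mergesort")
                  .set_index("metabolite_id"))
    return MetaboliteScreen(table)


def diagnosis_correlations(z: ZScoreMatrix) -> pd.DataFrame:
    """Point-biserial Pearson r and Spearman rho of each metabolite's
    Z-scores with the case indicator; constant metabolites get r = 0 and a
    flag. Sorted by |r| descending."""
    y = _case_indicator(z.labels)
    rows = []
    for met in z.metabolite_ids:
        x = z.z[met].to_numpy(dtype=float)
        constant = np.ptp(x) == 0
        if constant:
            r = rho = 0.0
        else:
            r = float(stats.pearsonr(x, y).statistic)
            rho = float(stats.spearmanr(x, y).statistic)
        rows.append((met, r, rho, constant))
    df = pd.DataFrame(rows, columns=["metabolite_id", "pearson_r",
                                     "spearman_rho", "constant"])
    return (df.assign(abs_r=lambda d: d["pearson_r"].abs())
              .sort_values(["abs_r", "metabolite_id"], ascending=[False, True],
                           kind="mergesort")
              .drop(columns="abs_r")
              .set_index("metabolite_id"))


@dataclass
class RFConfig:
    n_trees: int = 500
    seed: int = 0
    n_repeats: int = 5  # label-permutation repeats per feature


def rf_rank(z: ZScoreMatrix, config: RFConfig | None = None) -> pd.DataFrame:
    """Permutation importance from a seeded random forest (sqrt-features
    splits), ranked descending; deterministic for a fixed seed."""
    config = config or RFConfig()
    y = _case_indicator(z.labels)
    X = z.z.to_numpy(dtype=float)
    forest = RandomForestClassifier(
        n_estimators=config.n_trees, max_features="sqrt",
        random_state=config.seed, n_jobs=1,
    ).fit(X, y)
    imp = permutation_importance(
        forest, X, y, scoring="roc_auc", n_repeats=config.n_repeats,
        random_state=config.seed, n_jobs=1,
    )
    df = pd.DataFrame({
        "importance": imp.importances_mean,
        "importance_sd": imp.importances_std,
    }, index=z.metabolite_ids)
    df.index.name = "metabolite_id"
    df = df.sort_values(["importance"], ascending=False, kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    df.attrs["seed"] = config.seed
    return df


def group_shift_test(z: ZScoreMatrix, vip: pd.Series,
                     metabolite_subset: list[str],
                     min_vip: float = 0.5) -> dict:
    """Coordinate shift of a metabolite family (e.g. all acyl-carnitines):
    the subset is filtered to members with VIP above ``min_vip``, each
    member's mean case Z is computed, and the set of means is tested
    against zero with a one-sample Wilcoxon signed-rank (exact for small
    sets). Reports mean +/- SE of the member means."""
    members = [m for m in metabolite_subset if vip.get(m, 0.0) > min_vip]
    if not members:
        raise ValueError("no subset members pass the VIP filter")
    means = z.mean_case_z()[members].to_numpy(dtype=float)
    if np.all(means == 0):
        p = 1.0
    else:
        method = "exact" if len(means) <= 25 else "approx"
        res = stats.wilcoxon(means, alternative="two-sided", method=method)
        p = float(res.pvalue)
    se = float(means.std(ddof=1) / np.sqrt(len(means))) if len(means) > 1 else float("nan")
    return {
        "members": members,
        "n": len(members),
        "mean_z": float(means.mean()),
        "se": se,
        "p_value": p,
    }


def pca_scree(z: ZScoreMatrix) -> pd.DataFrame:
    """Variance fractions of the principal components of the Z-score
    matrix (eigenvalues of the sample covariance); fractions sum to 1."""
    X = z.z.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    X = X - X.mean(axis=0)
    s = np.linalg.svd(X, compute_uv=False)
    var = s ** 2
    frac = var / var.sum()
    return pd.DataFrame({
        "component": np.arange(1, len(frac) + 1),
        "variance_fraction": frac,
        "cumulative_fraction": np.cumsum(frac),
    }).set_index("component")
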