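"""PLS-DA/VIP, the joint screen, correlations, forest ranking, shift test."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

import metsig as ms
from conftest import zscores_from_z


@pytest.fixture
def separable_z():
    """Two point clouds split cleanly along the first two metabolites."""
    rng = np.random.default_rng(0)
    z = rng.standard_normal((20, 5)) * 0.1
    z[:10, :2] += 3.0
    return zscores_from_z(z, ["case"] * 10 + ["control"] * 10)


class TestPLSDA:
    def test_separable_toy_first_component_separates(self, separable_z):
        model = ms.fit_plsda(separable_z, n_components=2)
        t1 = model.scores[:, 0]
        case = separable_z.case_mask
        assert min(t1[case]) > max(t1[~case]) or max(t1[case]) < min(t1[~case])
        assert model.y_variance_explained > 0.95

    def test_score_orthogonality_and_unit_weights(self, default_zscores):
        z, _, _ = default_zscores
        model = ms.fit_plsda(z, n_components=3)
        T = model.scores
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.all(np.abs(off) < 1e-8)
        assert np.allclose(np.linalg.norm(model.weights, axis=0), 1.0)

    def test_first_weight_is_dominant_eigenvector_of_xt_yyt_x(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((5, 6))
        labels = ["case", "case", "control", "control", "control"]
        z = zscores_from_z(X, labels)
        model = ms.fit_plsda(z, n_components=1)
        Xc = X - X.mean(axis=0)
        y = np.array([1, 1, 0, 0, 0], dtype=float)
        y = y - y.mean()
        M = np.outer(Xc.T @ y, y @ Xc)  # X'y y'X, rank one
        vals, vecs = np.linalg.eigh(M)
        dominant = vecs[:, np.argmax(vals)]
        cos = abs(dominant @ model.weights[:, 0])
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_sklearn_pls_scores_agree_on_first_component(self, default_zscores):
        """Independent cross-check: sklearn's PLS x-scores are collinear
        with ours on component 1."""
        z, _, _ = default_zscores
        model = ms.fit_plsda(z, n_components=2)
        y = (z.labels == "case").to_numpy(dtype=float)
        ref = PLSRegression(n_components=2, scale=False).fit(z.z.to_numpy(), y)
        r = np.corrcoef(model.scores[:, 0], ref.x_scores_[:, 0])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-8)

    def test_single_class_rejected(self):
        z = zscores_from_z(np.eye(4), ["case"] * 4)
        with pytest.raises(ValueError):
            ms.fit_plsda(z, n_components=1)


class TestVIP:
    def test_single_metabolite_vip_is_one(self):
        rng = np.random.default_rng(1)
        z = zscores_from_z(rng.standard_normal((10, 1)) +
                           np.array([1.0] * 5 + [0.0] * 5)[:, None],
                           ["case"] * 5 + ["control"] * 5)
        vip = ms.vip_scores(ms.fit_plsda(z, n_components=1))
        assert vip.iloc[0] == pytest.approx(1.0)

    def test_exchangeable_metabolites_equal_vip(self):
        rng = np.random.default_rng(2)
        shared = rng.standard_normal(12) + np.array([1.5] * 6 + [0.0] * 6)
        z = zscores_from_z(np.column_stack([shared, shared]),
                           ["case"] * 6 + ["control"] * 6)
        vip = ms.vip_scores(ms.fit_plsda(z, n_components=1))
        assert vip.iloc[0] == pytest.approx(vip.iloc[1], abs=1e-10)
        assert vip.iloc[0] == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_mean_squared_vip_is_one(self, seed):
        rng = np.random.default_rng(seed)
        z = zscores_from_z(rng.standard_normal((10, 8)),
                           ["case"] * 5 + ["control"] * 5)
        vip = ms.vip_scores(ms.fit_plsda(z, n_components=2))
        assert (vip ** 2).mean() == pytest.approx(1.0, abs=1e-8)


class TestScreen:
    def test_rule_is_joint(self, default_screen):
        screen, _, _, _ = default_screen
        t = screen.table
        expected = (t["vip"] > 1.5) & (t["u_p"] <= 0.05)
        assert (t["significant"] == expected).all()
        # high VIP with weak p must not pass
        weak = t[(t["vip"] > 1.5) & (t["u_p"] > 0.05)]
        assert not weak["significant"].any()

    def test_ranked_by_vip_descending(self, default_screen):
        screen, _, _, _ = default_screen
        assert (screen.table["vip"].diff().dropna() <= 1e-12).all()

    def test_planted_pathway_enriched_in_top30(self, default_screen):
        screen, _, config, truth = default_screen
        top30 = set(screen.table.head(30).index)
        cer = [m for m in truth["planted_z_shifts"] if m.startswith("cer_")]
        observed = len(top30 & set(cer))
        expected = 31 / 358 * 30
        assert observed / expected > 1.0

    def test_directions_match_planted_signs(self, default_screen):
        screen, _, _, truth = default_screen
        planted = truth["planted_z_shifts"]
        sig = screen.table[screen.table["significant"]]
        hits = [m for m in sig.index if m in planted]
        assert hits, "no planted metabolite recovered"
        for m in hits:
            assert (sig.loc[m, "direction"] == "up") == (planted[m] > 0)


class TestDiagnosisCorrelations:
    def test_indicator_metabolite_perfect_r(self):
        y = np.array([1.0] * 5 + [0.0] * 5)
        rng = np.random.default_rng(0)
        z = zscores_from_z(np.column_stack([y, rng.standard_normal(10)]),
                           ["case"] * 5 + ["control"] * 5)
        corr = ms.diagnosis_correlations(z)
        assert corr.loc["m0", "pearson_r"] == pytest.approx(1.0)

    def test_point_biserial_closed_form(self):
        # r = 4.5 / sqrt(17.5 * 1.5) for values 1..6 against 0,0,0,1,1,1
        z = zscores_from_z(np.arange(1.0, 7.0)[:, None],
                           ["control"] * 3 + ["case"] * 3)
        corr = ms.diagnosis_correlations(z)
        expected = 4.5 / np.sqrt(17.5 * 1.5)
        assert corr.loc["m0", "pearson_r"] == pytest.approx(expected, abs=1e-12)
        assert corr.loc["m0", "spearman_rho"] == pytest.approx(expected, abs=1e-9)

    def test_constant_metabolite_flagged_zero(self):
        z = zscores_from_z(np.column_stack([np.ones(6), np.arange(6.0)]),
                           ["case"] * 3 + ["control"] * 3)
        corr = ms.diagnosis_correlations(z)
        assert corr.loc["m0", "pearson_r"] == 0.0
        assert corr.loc["m0", "constant"]


class TestRandomForestRank:
    def test_deterministic_given_seed(self, small_informative_zscores):
        cfg = ms.discovery.RFConfig(n_trees=50, seed=3)
        r1 = ms.rf_rank(small_informative_zscores, cfg)
        r2 = ms.rf_rank(small_informative_zscores, cfg)
        pd.testing.assert_frame_equal(r1, r2)

    def test_planted_strong_metabolite_ranks_first(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            z = rng.standard_normal((30, 12))
            z[:15, 0] += 2.5
            zs = zscores_from_z(z, ["case"] * 15 + ["control"] * 15)
            top = ms.rf_rank(zs, ms.discovery.RFConfig(n_trees=100, seed=seed)).index[0]
            wins += top == "m0"
        assert wins >= 9

    def test_all_noise_importance_near_permuted_baseline(self):
        rng = np.random.default_rng(12)
        z = zscores_from_z(rng.standard_normal((30, 10)),
                           ["case"] * 15 + ["control"] * 15)
        ranking = ms.rf_rank(z, ms.discovery.RFConfig(n_trees=100, seed=1))
        # top importance should stay within a couple of SDs of zero
        top = ranking.iloc[0]
        assert top["importance"] < 4 * max(top["importance_sd"], 1e-3)


class TestGroupShift:
    def test_all_zero_means_p_one(self):
        z = zscores_from_z(np.zeros((8, 6)), ["case"] * 4 + ["control"] * 4)
        vip = pd.Series(1.0, index=z.metabolite_ids)
        res = ms.group_shift_test(z, vip, z.metabolite_ids, min_vip=0.5)
        assert res["p_value"] == 1.0

    def test_six_positive_members_exact_p(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal((10, 6)) * 0.1
        z[:5] += np.linspace(0.5, 1.0, 6)  # all member means positive
        zs = zscores_from_z(z, ["case"] * 5 + ["control"] * 5)
        vip = pd.Series(1.0, index=zs.metabolite_ids)
        res = ms.group_shift_test(zs, vip, zs.metabolite_ids, min_vip=0.5)
        assert res["p_value"] == pytest.approx(2 / 64)

    def test_planted_family_shift_detected(self):
        """18-member family shifted +0.9: p < 0.001 in most seeds."""
        detections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            z = rng.standard_normal((40, 18))
            z[:20] += 0.9
            zs = zscores_from_z(z, ["case"] * 20 + ["control"] * 20)
            vip = pd.Series(1.0, index=zs.metabolite_ids)
            res = ms.group_shift_test(zs, vip, zs.metabolite_ids, min_vip=0.5)
            detections += res["p_value"] < 0.001
        assert detections >= 18

    def test_empty_filtered_subset_rejected(self):
        z = zscores_from_z(np.zeros((4, 2)), ["case"] * 2 + ["control"] * 2)
        vip = pd.Series(0.1, index=z.metabolite_ids)
        with pytest.raises(ValueError):
            ms.group_shift_test(z, vip, z.metabolite_ids, min_vip=0.5)


class TestPCAScree:
    def test_fractions_sum_to_one(self, default_zscores):
        z, _, _ = default_zscores
        scree = ms.pca_scree(z)
        assert scree["variance_fraction"].sum() == pytest.approx(1.0)
        assert scree["cumulative_fraction"].iloc[-1] == pytest.approx(1.0)

    def test_rank_one_data(self):
        u = np.arange(1.0, 7.0)[:, None]
        z = zscores_from_z(u @ np.array([[1.0, 2.0, -1.0]]),
                           ["case"] * 3 + ["control"] * 3)
        scree = ms.pca_scree(z)
        assert scree["variance_fraction"].iloc[0] == pytest.approx(1.0)

    def test_matches_covariance_eigenvalues(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((8, 3))
        z = zscores_from_z(X, ["case"] * 4 + ["control"] * 4)
        scree = ms.pca_scree(z)
        eig = np.linalg.eigvalsh(np.cov(X, rowvar=False))[::-1]
        assert np.allclose(scree["variance_fraction"].to_numpy()[:3],
                           eig / eig.sum(), atol=1e-10)
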