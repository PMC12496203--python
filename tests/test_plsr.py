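"""NIPALS PLS1, VIP scores, component selection, prediction."""

import numpy as np
import pandas as pd
import pytest

from synphen.plsr import (
    extract_signature, fit_pls1, loo_rrmsep_select, predict_phenotype,
    select_variable_genes, vip_scores, VIPVector,
)


def _vip_oracle(model):
    """Direct evaluation of the VIP definition, independent of the library
    code path: VIP_j = sqrt(p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a).
    """
    W, ssy = model.W, model.ssy
    p = W.shape[0]
    Wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    return np.sqrt(p * ((Wn ** 2) * ssy).sum(axis=1) / ssy.sum())


class TestVariableGenes:
    def test_high_variance_gene_ranked_first(self, rng):
        n = 40
        base = rng.normal(10, 1, size=(n, 30))
        base[:, 0] = 10 + rng.normal(0, 5, size=n)  # same mean, high var
        expr = pd.DataFrame(base, columns=[f"g{i}" for i in range(30)])
        top = select_variable_genes(expr, n=5)
        assert "g0" in top

    def test_requesting_more_than_available_returns_all(self, rng):
        expr = pd.DataFrame(rng.normal(5, 1, size=(10, 8)))
        assert len(select_variable_genes(expr, n=100)) == 8

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            select_variable_genes(pd.DataFrame(np.ones((5, 4))), n=2)

    def test_planted_overdispersed_genes_recovered(self, rng):
        n_samples, n_genes = 24, 2500
        means = rng.uniform(5, 10, n_genes)
        sds = np.full(n_genes, 0.3)
        hot = rng.choice(n_genes, size=50, replace=False)
        sds[hot] = 2.0
        expr = pd.DataFrame(
            means + sds * rng.standard_normal((n_samples, n_genes)),
            columns=[f"g{i:04d}" for i in range(n_genes)])
        top100 = set(select_variable_genes(expr, n=100))
        recovered = sum(f"g{i:04d}" in top100 for i in hot)
        assert recovered >= 45


class TestFit:
    def test_single_informative_gene_identified(self, rng):
        # other columns orthogonalized against g3 so y lies along one weight
        raw = rng.normal(size=(20, 6))
        g3 = raw[:, 3] - raw[:, 3].mean()
        for j in range(6):
            if j != 3:
                raw[:, j] -= g3 * (raw[:, j] @ g3) / (g3 @ g3)
        X = pd.DataFrame(raw, columns=[f"g{i}" for i in range(6)])
        y = X["g3"].to_numpy() * 2.0 + 1.0
        model = fit_pls1(X, y, n_components=1)
        np.testing.assert_allclose(model.predict(raw), y, atol=1e-8)
        assert np.argmax(np.abs(model.coef)) == 3

    def test_full_rank_matches_ols(self, rng):
        n, p = 12, 5
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        model = fit_pls1(X, y, n_components=p)
        Z = np.column_stack([np.ones(n), X])
        beta = np.linalg.lstsq(Z, y, rcond=None)[0]
        np.testing.assert_allclose(model.predict(X), Z @ beta, atol=1e-6)

    def test_matches_reference_pls_implementation(self, rng):
        from sklearn.cross_decomposition import PLSRegression
        n, p, A = 15, 8, 3
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        model = fit_pls1(X, y, n_components=A)
        ref = PLSRegression(n_components=A, scale=True).fit(X, y)
        np.testing.assert_allclose(model.predict(X),
                                   ref.predict(X).ravel(), atol=1e-8)

    def test_sample_permutation_equivariance(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        perm = rng.permutation(10)
        m1 = fit_pls1(X, y, 2)
        m2 = fit_pls1(X[perm], y[perm], 2)
        np.testing.assert_allclose(m1.coef, m2.coef, atol=1e-10)

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        model = fit_pls1(X, y, n_components=4)
        G = model.T.T @ model.T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_zero_variance_response_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pls1(rng.normal(size=(5, 3)), np.ones(5), 1)

    def test_excess_components_truncated_with_warning(self, rng):
        X = np.tile(rng.normal(size=(6, 1)), (1, 3))  # rank 1
        y = X[:, 0] * 2
        model = fit_pls1(X, y, n_components=3)
        assert model.n_components < 3 and model.warnings


class TestVIP:
    def test_equal_weights_give_unit_vip(self):
        class M:
            pass
        X = np.array([[1.0, 1], [2, 2], [3, 3], [0, 0]])
        y = X[:, 0].copy()
        model = fit_pls1(X, y, 1)
        v = vip_scores(model)
        np.testing.assert_allclose(v.vip, 1.0, atol=1e-10)

    def test_mean_square_is_one(self, rng):
        X = rng.normal(size=(18, 25))
        y = rng.normal(size=18)
        model = fit_pls1(X, y, 3)
        v = vip_scores(model, X)
        assert np.mean(v.vip ** 2) == pytest.approx(1.0, abs=1e-8)

    def test_matches_formula_oracle(self, rng):
        X = rng.normal(size=(10, 6))
        y = X @ rng.normal(size=6) + 0.3 * rng.normal(size=10)
        model = fit_pls1(X, y, 2)
        v = vip_scores(model, X)
        np.testing.assert_allclose(v.vip.to_numpy(), _vip_oracle(model),
                                   atol=1e-10)

    def test_sign_matches_first_component_correlation(self, rng):
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        model = fit_pls1(X, y, 2)
        v = vip_scores(model, X)
        Xs = (X - model.x_mean) / model.x_scale
        for j in range(5):
            r = np.corrcoef(Xs[:, j], model.T[:, 0])[0, 1]
            assert np.sign(r) == v.sign.iloc[j]


class TestComponentSelection:
    def test_noiseless_rank_one_chooses_one_component(self, rng):
        t = rng.normal(size=(20, 1))
        X = t @ rng.normal(size=(1, 30))
        y = (t[:, 0] * 2 + 1)
        curve = loo_rrmsep_select(X, y, a_max=5)
        assert curve.chosen == 1
        assert curve.rrmsep[0] <= 0.05

    def test_pure_noise_response_rrmsep_near_one(self, rng):
        X = rng.normal(size=(24, 100))
        y = rng.normal(size=24)
        curve = loo_rrmsep_select(X, y, a_max=6)
        assert 0.8 <= curve.rrmsep.min() <= 1.3

    def test_needs_three_samples(self, rng):
        with pytest.raises(ValueError):
            loo_rrmsep_select(rng.normal(size=(2, 4)), np.array([1.0, 2.0]))


class TestSignatures:
    def test_short_side_takes_all(self):
        vip = pd.Series([3.0, 2.0, 1.5, 1.0, 0.5],
                        index=[f"g{i}" for i in range(5)])
        sign = pd.Series([1, 1, -1, -1, -1], index=vip.index)
        sig = extract_signature(VIPVector(vip, sign), n_each=100)
        assert sig.positive == ["g0", "g1"]
        assert sig.shortfall["positive"] == 98

    def test_zero_sign_excluded_from_both_sides(self):
        vip = pd.Series([3.0, 2.0], index=["g0", "g1"])
        sign = pd.Series([0, 1], index=vip.index)
        sig = extract_signature(VIPVector(vip, sign), n_each=10)
        assert "g0" not in sig.positive and "g0" not in sig.negative

    def test_tie_breaks_on_gene_id(self):
        vip = pd.Series([1.0, 1.0, 1.0], index=["gC", "gA", "gB"])
        sign = pd.Series([1, 1, 1], index=vip.index)
        sig = extract_signature(VIPVector(vip, sign), n_each=2)
        assert sig.positive == ["gA", "gB"]


class TestPredict:
    def test_training_round_trip(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 6)),
                         columns=[f"g{i}" for i in range(6)])
        y = rng.normal(size=12)
        model = fit_pls1(X, y, 2)
        pred = predict_phenotype(model, X.T)
        np.testing.assert_allclose(pred.to_numpy(),
                                   model.predict(X.to_numpy()), atol=1e-8)

    def test_prediction_varies_only_along_present_gene(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 4)),
                         columns=list("abcd"))
        y = rng.normal(size=12)
        model = fit_pls1(X, y, 1)
        ext = pd.DataFrame({"s1": [0.0], "s2": [1.0], "s3": [2.0]},
                           index=["b"])
        with pytest.warns(UserWarning):
            pred = predict_phenotype(model, ext)
        diffs = np.diff(pred.to_numpy())
        assert diffs[0] == pytest.approx(diffs[1], rel=1e-9)

    def test_column_order_invariance(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 5)),
                         columns=[f"g{i}" for i in range(5)])
        y = rng.normal(size=10)
        model = fit_pls1(X, y, 2)
        ext = pd.DataFrame(rng.normal(size=(5, 7)), index=X.columns)
        shuffled = ext.sample(frac=1, random_state=1)
        np.testing.assert_allclose(predict_phenotype(model, ext),
                                   predict_phenotype(model, shuffled),
                                   atol=1e-10)

    def test_no_overlap_is_an_error(self, rng):
        X = pd.DataFrame(rng.normal(size=(8, 3)), columns=list("abc"))
        model = fit_pls1(X, rng.normal(size=8), 1)
        with pytest.raises(ValueError):
            predict_phenotype(model, pd.DataFrame({"s": [1.0]}, index=["z"]))
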