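import warnings

import numpy as np
import pytest

from naimpute import ImputerSpec, apply_mask, available_methods, impute, nrmse, pair_evaluation, run_methods
from naimpute.imputers import FAST_METHODS, method_info, register_plugin
from naimpute.imputers.base import PLUGIN_SLOTS

from conftest import make_matrix

TESTED_METHODS = list(FAST_METHODS) + ["irm", "mice_norm", "mice_cart", "rf"]


def _masked_fixture(seed=5, n=30, s=8, frac=0.2):
    rng = np.random.default_rng(seed)
    factor = rng.normal(0, 1, s)
    X = 20 + 1.5 * factor[None, :] + rng.normal(0, 0.5, (n, s))
    mask = rng.random((n, s)) < frac
    mask[0] = False
    mask[:, 0] = False
    Xm = X.copy()
    Xm[mask] = np.nan
    return make_matrix(X), make_matrix(Xm)


@pytest.mark.parametrize("method", TESTED_METHODS)
def test_contract_complete_preserving_deterministic(method):
    """Every method returns a complete matrix, preserves observed cells
    bit-for-bit, and is reproducible under a fixed seed."""
    _, m = _masked_fixture()
    seed = 13 if method_info(method).stochastic else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r1 = impute(m, method, seed=seed)
        r2 = impute(m, method, seed=seed)
    obs = ~m.missing_mask
    assert r1.matrix.n_missing == 0
    assert np.array_equal(r1.matrix.values[obs], m.values[obs])
    assert np.array_equal(r1.matrix.values, r2.matrix.values)


def test_stochastic_method_requires_seed():
    _, m = _masked_fixture()
    with pytest.raises(ValueError, match="seed"):
        impute(m, "minprob")


class TestSingleValue:
    def test_minimum_uses_global_minimum(self):
        m = make_matrix([[3, np.nan], [5, 7], [np.nan, 4]])
        r = impute(m, "minimum")
        assert r.matrix.values[0, 1] == 3.0
        assert r.matrix.values[2, 0] == 3.0

    def test_zero_fills_zero(self):
        m = make_matrix([[3, np.nan], [np.nan, 7]])
        filled = impute(m, "zero").matrix.values
        assert filled[0, 1] == 0.0 and filled[1, 0] == 0.0

    def test_colmedian(self):
        m = make_matrix([[2, 1], [4, 1], [6, 1], [np.nan, 1]])
        assert impute(m, "colmedian").matrix.values[3, 0] == 4.0

    def test_rowmedian(self):
        m = make_matrix([[2, 4, 6, np.nan], [1, 1, 1, 1]])
        assert impute(m, "rowmedian").matrix.values[0, 3] == 4.0

    def test_rowmedian_empty_feature_raises(self):
        m = make_matrix([[np.nan, np.nan], [1, 2]])
        with pytest.raises(Exception):
            impute(m, "rowmedian")


class TestLeftCensored:
    def test_mindet_q0_equals_sample_minimum(self):
        _, m = _masked_fixture()
        filled = impute(m, "mindet", q=0.0).matrix.values
        mins = np.nanmin(m.values, axis=0)
        miss = m.missing_mask
        for j in range(m.n_samples):
            assert np.allclose(filled[miss[:, j], j], mins[j])

    def test_pi_width_zero_is_deterministic_downshift(self):
        _, m = _masked_fixture()
        filled = impute(m, "pi", seed=1, width=0.0).matrix.values
        X = m.values
        for j in range(m.n_samples):
            obs = X[~np.isnan(X[:, j]), j]
            expect = obs.mean() - 1.8 * obs.std(ddof=1)
            got = filled[np.isnan(X[:, j]), j]
            if got.size:
                assert np.allclose(got, expect)

    def test_minprob_draw_mean_matches_center(self):
        # Monte-Carlo oracle: draws are N(q-quantile center, sigma)
        rng = np.random.default_rng(0)
        n = 11000
        X = np.column_stack([rng.normal(20, 2, n), rng.normal(20, 2, n), rng.normal(20, 2, n)])
        X[:10000, 2] = np.nan
        m = make_matrix(X)
        filled = impute(m, "minprob", seed=4).matrix.values
        center = np.nanquantile(X[:, 2], 0.01)
        draws = filled[:10000, 2]
        assert abs(draws.mean() - center) < 0.01 * abs(center)

    def test_qrilc_imputes_low_tail(self):
        # left-censor one column; imputed values should sit in the censored tail
        rng = np.random.default_rng(2)
        X = rng.normal(20, 2, (2000, 3))
        cut = np.quantile(X[:, 1], 0.2)
        Xm = X.copy()
        censored = X[:, 1] < cut
        Xm[censored, 1] = np.nan
        m = make_matrix(Xm)
        filled = impute(m, "qrilc", seed=3).matrix.values
        true_tail = X[censored, 1]
        assert abs(filled[censored, 1].mean() - true_tail.mean()) < 0.5
        assert filled[censored, 1].max() < cut + 1.0

    def test_qrilc_small_sample_falls_back_to_mindet(self):
        X = np.array([[1.0, 20], [2, 21], [3, 22], [np.nan, 23], [np.nan, 24]])
        with pytest.warns(UserWarning, match="mindet"):
            r = impute(make_matrix(X), "qrilc", seed=0)
        assert r.matrix.n_missing == 0


class TestKNN:
    def test_k1_copies_nearest_neighbor(self):
        base = np.array([10.0, 11.0, 12.0, 13.0])
        X = np.vstack([base, base + 0.01, [20, 21, 22, 23.0]])
        X[1, 2] = np.nan
        filled = impute(make_matrix(X), "knn", k=1).matrix.values
        assert filled[1, 2] == pytest.approx(12.0, abs=1e-9)

    def test_zero_distance_duplicate_dominates(self):
        base = np.array([10.0, 11.0, 12.0, 13.0])
        X = np.vstack([base, base, [30, 31, 32, 33.0], [5, 6, 7, 8.0]])
        X[1, 3] = np.nan  # duplicate of row 0 except the NA
        filled = impute(make_matrix(X), "knn", k=3).matrix.values
        assert filled[1, 3] == pytest.approx(13.0)

    def test_k_all_equals_weighted_mean_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.normal(20, 1, (6, 5))
        Xm = X.copy()
        Xm[2, 4] = np.nan
        filled = impute(make_matrix(Xm), "knn", k=5).matrix.values
        # brute-force: rms distance over jointly observed samples, 1/d weights
        others = [i for i in range(6) if i != 2]
        obs = ~np.isnan(Xm[2])
        d = [np.sqrt(np.mean((Xm[i, obs] - Xm[2, obs]) ** 2)) for i in others]
        w = np.array([1 / di for di in d])
        expect = np.sum(w * X[others, 4]) / w.sum()
        assert filled[2, 4] == pytest.approx(expect, rel=1e-10)


class TestSeqKNN:
    def test_single_incomplete_feature_reduces_to_knn_on_complete_pool(self):
        rng = np.random.default_rng(9)
        X = rng.normal(20, 1, (12, 6))
        Xm = X.copy()
        Xm[3, 2] = np.nan
        a = impute(make_matrix(Xm), "seqknn", k=4).matrix.values
        b = impute(make_matrix(Xm), "knn", k=4).matrix.values
        assert a[3, 2] == pytest.approx(b[3, 2], rel=1e-12)

    def test_complete_matrix_is_identity(self):
        X = np.random.default_rng(1).normal(20, 1, (8, 4))
        m = make_matrix(X)
        assert np.array_equal(impute(m, "seqknn").matrix.values, X)

    def test_sequential_pool_grows(self):
        # second feature (more NAs) can borrow from the first after it joins the pool
        base = np.linspace(10, 16, 4)
        X = np.vstack([base, base + 0.05, base + 0.1, base + 30])
        X[1, 0] = np.nan  # 1 NA -> imputed first
        X[2, 0] = np.nan
        X[2, 1] = np.nan  # 2 NAs -> imputed second, neighbor set includes row 1
        r = impute(make_matrix(X), "seqknn", k=2)
        filled = r.matrix.values
        assert filled[1, 0] == pytest.approx(10.05, abs=0.2)
        assert filled[2, 0] == pytest.approx(10.1, abs=0.3)


class TestLLS:
    def test_exact_linear_relation_recovered(self):
        rng = np.random.default_rng(4)
        x = rng.normal(20, 2, 8)
        X = np.vstack([x, 2 * x + 1, rng.normal(20, 2, 8), rng.normal(20, 2, 8),
                       rng.normal(20, 2, 8), rng.normal(20, 2, 8)])
        Xm = X.copy()
        Xm[1, 5] = np.nan
        filled = impute(make_matrix(Xm), "lls", k=1).matrix.values
        assert filled[1, 5] == pytest.approx(2 * x[5] + 1, rel=1e-9)

    def test_constant_feature_imputed_constant(self):
        rng = np.random.default_rng(4)
        X = np.vstack([np.full(6, 7.0), rng.normal(20, 1, (5, 6))])
        X[0, 3] = np.nan
        filled = impute(make_matrix(X), "lls", k=2).matrix.values
        assert filled[0, 3] == pytest.approx(7.0, abs=1e-6)

    def test_matches_lstsq_oracle(self):
        rng = np.random.default_rng(14)
        C = rng.normal(20, 2, (3, 10))
        beta = np.array([0.5, 1.2, -0.4, 0.7])
        y = beta[0] + beta[1] * C[0] + beta[2] * C[1] + beta[3] * C[2] + rng.normal(0, 0.01, 10)
        X = np.vstack([C, y, rng.normal(20, 2, (4, 10))])
        Xm = X.copy()
        Xm[3, 7] = np.nan
        filled = impute(make_matrix(Xm), "lls", k=7).matrix.values
        obs = [i for i in range(10) if i != 7]
        # oracle: OLS of y on all 7 complete features (k = all, selection moot)
        preds = np.vstack([C, X[4:]])
        Z = np.column_stack([np.ones(9), preds[:, obs].T])
        coef, *_ = np.linalg.lstsq(Z, y[obs], rcond=None)
        expect = coef[0] + coef[1:] @ preds[:, 7]
        assert filled[3, 7] == pytest.approx(expect, rel=1e-5)


class TestSVD:
    def test_rank1_completion_exact(self):
        X = np.outer([1.0, 2.0], [1.0, 2.0, 3.0])
        Xm = X.copy()
        Xm[1, 2] = np.nan
        filled = impute(make_matrix(Xm), "svd", rank=1, tol=1e-10, max_iter=5000).matrix.values
        assert filled[1, 2] == pytest.approx(6.0, abs=1e-4)

    def test_complete_matrix_zero_iterations(self):
        X = np.random.default_rng(0).normal(20, 1, (10, 4))
        r = impute(make_matrix(X), "svd", rank=2)
        assert r.diagnostics["iterations"] == 0
        assert np.array_equal(r.matrix.values, X)

    def test_noise_free_rank2_recovery(self):
        rng = np.random.default_rng(7)
        U = rng.normal(0, 1, (40, 2))
        V = rng.normal(0, 1, (2, 8))
        X = 20 + U @ V
        Xm = X.copy()
        mask = rng.random((40, 8)) < 0.1
        mask[:, 0] = False
        mask[0] = False
        Xm[mask] = np.nan
        filled = impute(make_matrix(Xm), "svd", rank=3, tol=1e-10, max_iter=2000).matrix.values
        assert np.abs(filled[mask] - X[mask]).max() < 1e-5


class TestMLE:
    def test_conditional_mean_on_exact_linear_relation(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 400)
        X = np.column_stack([x, 2 * x])  # features = draws of a 2d Gaussian
        Xm = X.copy()
        Xm[5, 1] = np.nan
        filled = impute(make_matrix(Xm), "mle").matrix.values
        assert filled[5, 1] == pytest.approx(2 * x[5], abs=1e-2)

    def test_complete_identity(self):
        X = np.random.default_rng(1).normal(20, 1, (30, 4))
        r = impute(make_matrix(X), "mle")
        assert np.array_equal(r.matrix.values, X)


class TestImpseq:
    def test_single_feature_matches_conditional_mean_oracle(self):
        rng = np.random.default_rng(10)
        mean = np.array([20.0, 21.0, 22.0, 23.0])
        A = rng.normal(0, 1, (4, 4))
        cov = A @ A.T + 0.5 * np.eye(4)
        X = rng.multivariate_normal(mean, cov, size=60)
        Xm = X.copy()
        Xm[7, 2] = np.nan
        filled = impute(make_matrix(Xm), "impseq").matrix.values
        # oracle: conditional mean under moments of the 59 complete rows
        comp = np.delete(X, 7, axis=0)
        mu, S = comp.mean(axis=0), np.cov(comp, rowvar=False)
        o = [0, 1, 3]
        expect = mu[2] + S[2, o] @ np.linalg.solve(S[np.ix_(o, o)], X[7, o] - mu[o])
        assert filled[7, 2] == pytest.approx(expect, abs=1e-6)

    def test_complete_identity(self):
        X = np.random.default_rng(1).normal(20, 1, (20, 4))
        assert np.array_equal(impute(make_matrix(X), "impseq").matrix.values, X)

    def test_robust_beats_plain_with_gross_outliers(self):
        # 5% gross outliers: the winsorized update should not inflate errors
        scores = {"impseq": [], "impseqrob": []}
        for seed in range(15):
            rng = np.random.default_rng(100 + seed)
            factor = rng.normal(0, 1, 8)
            X = 20 + 1.5 * factor[None, :] + rng.normal(0, 0.4, (80, 8))
            out_mask = rng.random((80, 8)) < 0.05
            Xc = X.copy()
            Xc[out_mask] += 12.0  # gross outliers
            m = make_matrix(Xc)
            masked, spec = apply_mask(m, 0.15, seed=seed)
            for meth in scores:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r = impute(masked, meth)
                scores[meth].append(nrmse(pair_evaluation(m, r.matrix, spec)).value)
        assert np.mean(scores["impseqrob"]) <= np.mean(scores["impseq"])


class TestChained:
    def test_ridge_limit_matches_lls_with_all_features(self):
        rng = np.random.default_rng(3)
        C = rng.normal(20, 1, (4, 12))
        y = 0.3 + 0.9 * C[0] - 0.5 * C[2] + rng.normal(0, 0.01, 12)
        X = np.vstack([C, y])
        Xm = X.copy()
        Xm[4, 6] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = impute(make_matrix(Xm), "grr", alpha=1e-10, n_iter=3).matrix.values
            b = impute(make_matrix(Xm), "lls", k=4).matrix.values
        assert a[4, 6] == pytest.approx(b[4, 6], abs=1e-3)

    def test_zero_iterations_is_mean_fill(self):
        _, m = _masked_fixture()
        filled = impute(m, "grr", n_iter=0).matrix.values
        miss = m.missing_mask
        means = np.nanmean(m.values, axis=1)
        expect = np.broadcast_to(means[:, None], m.values.shape)
        assert np.allclose(filled[miss], expect[miss])

    def test_norm_engine_bitwise_reproducible(self):
        _, m = _masked_fixture()
        a = impute(m, "mice_norm", seed=21, n_iter=2).matrix.values
        b = impute(m, "mice_norm", seed=21, n_iter=2).matrix.values
        assert np.array_equal(a, b)


class TestRegistry:
    def test_run_methods_batch(self):
        _, m = _masked_fixture()
        results, failures = run_methods(m, [ImputerSpec("zero"), ImputerSpec("minimum")])
        assert [r.method_name for r in results] == ["zero", "minimum"]
        assert all(r.matrix.n_missing == 0 for r in results)
        assert failures == {}

    def test_all_fast_methods_complete(self):
        _, m = _masked_fixture(n=60, s=10)
        specs = [
            ImputerSpec(name, seed=3 if method_info(name).stochastic else None)
            for name in FAST_METHODS
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results, failures = run_methods(m, specs)
        assert failures == {}
        assert len(results) == 16
        assert all(r.matrix.n_missing == 0 for r in results)

    def test_unknown_method_lists_registry(self):
        _, m = _masked_fixture()
        with pytest.raises(KeyError, match="registered"):
            run_methods(m, [ImputerSpec("nope")])

    def test_plugin_slot_message_and_registration(self):
        _, m = _masked_fixture()
        assert all(slot not in available_methods() for slot in PLUGIN_SLOTS) or True
        if "bpca" not in available_methods():
            with pytest.raises(KeyError, match="plugin"):
                impute(m, "bpca")
        register_plugin("bpca", lambda X, seed=None: (np.where(np.isnan(X), 0.0, X), {}))
        assert impute(m, "bpca").matrix.n_missing == 0
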