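import numpy as np
import pytest

from gxepred.kernels import build_kernel_set, build_env_design
from gxepred.mixedmodel import (
    FitResult,
    ModelSpec,
    blup_predict,
    fit_reml,
    partition_variance,
    restricted_loglik,
)


class TestRestrictedLoglik:
    def test_closed_form_two_records(self):
        # q=2, y=0, V=I: l_R = -log(2)/2 - log(2*pi)/2
        expected = -0.5 * np.log(2.0) - 0.5 * np.log(2.0 * np.pi)
        assert restricted_loglik([0.0, 0.0], [], [], 1.0) == pytest.approx(expected, abs=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(15)
        A = rng.standard_normal((15, 15))
        K = A @ A.T / 15
        ll = restricted_loglik(y, [K], [0.7], 0.5)
        c = 3.0
        ll_scaled = restricted_loglik(c * y, [K], [c**2 * 0.7], c**2 * 0.5)
        assert ll_scaled == pytest.approx(ll - (15 - 1) * np.log(c), rel=1e-10)

    def test_zero_variance_kernel_is_inert(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal(10)
        K = np.eye(10)
        assert restricted_loglik(y, [K], [0.0], 1.3) == pytest.approx(
            restricted_loglik(y, [], [], 1.3)
        )

    def test_not_positive_definite_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            restricted_loglik([1.0, 2.0], [], [], 0.0)


class TestFitReml:
    def test_null_data_estimates_no_genetic_variance(self):
        # iid phenotypes, unrelated lines (G = I) with 6 records each:
        # the line-block kernel should pick up essentially no variance
        n, r = 200, 6
        ZGZt = np.kron(np.eye(n), np.ones((r, r)))
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = rng.standard_normal(n * r)
            fit = fit_reml(y, [ZGZt], ModelSpec("G-BLUP"))
            share = fit.var_components["ZGZt"] / sum(fit.var_components.values())
            hits += share < 0.05
        assert hits >= 18

    def test_optimum_beats_random_variance_vectors(self, small_dataset):
        geno, pheno, truth = small_dataset
        ks = truth.kernels
        y = pheno["lifespan"].to_numpy()[:120]
        kernels = [ks.ZGZt[:120, :120], ks.E[:120, :120]]
        fit = fit_reml(y, kernels, ModelSpec("GE-BLUP"))
        rng = np.random.default_rng(9)
        vary = np.var(y, ddof=1)
        for _ in range(100):
            v = rng.uniform(0.01, 2.0, size=3) * vary
            assert fit.loglik >= restricted_loglik(y, kernels, v[:2], v[2]) - 1e-6

    def test_nesting_of_model_likelihoods(self, small_dataset):
        geno, pheno, truth = small_dataset
        ks = truth.kernels
        y = pheno["lifespan"].to_numpy()
        by = {}
        for name in ("G-BLUP", "GE-BLUP", "GxE-BLUP"):
            ks_list = [ks.by_name(k) for k in ModelSpec(name).kernel_names]
            by[name] = fit_reml(y, ks_list, ModelSpec(name)).loglik
        assert by["GxE-BLUP"] >= by["GE-BLUP"] - 1e-4
        assert by["GE-BLUP"] >= by["G-BLUP"] - 1e-4

    def test_duplicating_records_shrinks_residual(self, tiny_grm):
        rng = np.random.default_rng(21)
        n = tiny_grm.shape[0]
        w, U = np.linalg.eigh(tiny_grm)
        a = (U * np.sqrt(np.clip(w, 0, None))) @ rng.standard_normal(n)
        y = a + 0.5 * rng.standard_normal(n)
        fit1 = fit_reml(y, [tiny_grm], ModelSpec("G-BLUP"))
        y2 = np.concatenate([y, y])
        K2 = np.tile(tiny_grm, (2, 2))
        fit2 = fit_reml(y2, [K2], ModelSpec("G-BLUP"))
        assert fit2.var_components["residual"] < 0.5 * fit1.var_components["residual"]
        assert fit2.var_components["ZGZt"] == pytest.approx(
            fit1.var_components["ZGZt"], rel=0.2
        )

    def test_constant_phenotype_raises(self):
        with pytest.raises(ValueError, match="constant"):
            fit_reml(np.ones(10), [np.eye(10)], ModelSpec("G-BLUP"))

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            ModelSpec("H-BLUP")


def _manual_fit(model, mu, var_components, y_train, kernels_train, names):
    return FitResult(
        model=model, mu=mu, var_components=var_components, blups={},
        loglik=np.nan, converged=True, kernel_names=names, _y_train=np.asarray(y_train, float),
    )


class TestBlupPredict:
    def _kernel_set(self, n=12):
        rng = np.random.default_rng(4)
        X = 2.0 * (rng.random((n, 300)) < rng.uniform(0.2, 0.5, 300))
        from gxepred.kernels import GenotypeMatrix, filter_variants
        geno = filter_variants(GenotypeMatrix(
            [f"l{i}" for i in range(n)], X, [f"v{j}" for j in range(300)]))
        recs = [(f"l{i}", s, t) for i in range(n) for s in "FM" for t in (18, 25, 28)]
        design = build_env_design(recs)
        return build_kernel_set(geno, design), design

    def test_zero_variances_predict_intercept(self):
        ks, _ = self._kernel_set()
        q = ks.E.shape[0]
        rng = np.random.default_rng(5)
        y = rng.standard_normal(q - 6) + 3.0
        fit = _manual_fit("GE-BLUP", 3.0, {"ZGZt": 0.0, "E": 0.0, "residual": 1.0},
                          y, None, ("ZGZt", "E"))
        pred = blup_predict(fit, ks, np.arange(q - 6), np.arange(q - 6, q))
        assert np.allclose(pred, 3.0)

    def test_e_kernel_only_ignores_line_identity(self):
        ks, design = self._kernel_set()
        env = design.record_index["env"].to_numpy()
        q = len(env)
        # hold out two records from the same environment, different lines
        same_env = np.flatnonzero(env == env[0])
        test_idx = same_env[-2:]
        train_idx = np.setdiff1d(np.arange(q), test_idx)
        rng = np.random.default_rng(6)
        y = rng.standard_normal(train_idx.size)
        fit = _manual_fit("E-BLUP", 0.0, {"E": 0.8, "residual": 0.4}, y, None, ("E",))
        pred = blup_predict(fit, ks, train_idx, test_idx)
        assert pred[0] == pytest.approx(pred[1], abs=1e-10)

    def test_gxe_with_zero_interaction_matches_ge(self):
        ks, _ = self._kernel_set()
        q = ks.E.shape[0]
        rng = np.random.default_rng(7)
        y = rng.standard_normal(q - 10)
        tr, te = np.arange(q - 10), np.arange(q - 10, q)
        vc = {"ZGZt": 0.3, "E": 0.6, "residual": 0.2}
        fit_ge = _manual_fit("GE-BLUP", 1.0, vc, y, None, ("ZGZt", "E"))
        fit_gxe = _manual_fit("GxE-BLUP", 1.0, vc | {"GxE": 0.0}, y, None,
                              ("ZGZt", "E", "GxE"))
        assert np.allclose(blup_predict(fit_ge, ks, tr, te),
                           blup_predict(fit_gxe, ks, tr, te))

    def test_overlapping_indices_raise(self):
        ks, _ = self._kernel_set()
        fit = _manual_fit("E-BLUP", 0.0, {"E": 1.0, "residual": 1.0},
                          np.zeros(5), None, ("E",))
        with pytest.raises(ValueError, match="overlap"):
            blup_predict(fit, ks, np.arange(5), np.array([4, 5]))

    def test_intercept_residual_orthogonal_under_v_inverse(self, small_dataset):
        # mu is the GLS intercept, so 1' V^-1 (y - mu) = 0 at the optimum;
        # equivalently the in-sample BLUP residual (a V^-1-scaled multiple
        # of the same vector) is orthogonal to the intercept under V^-1
        geno, pheno, truth = small_dataset
        ks = truth.kernels
        y = pheno["lifespan"].to_numpy()[:90]
        kernels = [ks.ZGZt[:90, :90], ks.E[:90, :90]]
        fit = fit_reml(y, kernels, ModelSpec("GE-BLUP"))
        V = (fit.var_components["ZGZt"] * kernels[0]
             + fit.var_components["E"] * kernels[1]
             + fit.var_components["residual"] * np.eye(90))
        w = np.linalg.solve(V, y - fit.mu)
        assert abs(w.sum()) < 1e-8 * np.abs(w).sum()
        fitted = fit.mu + sum(fit.blups.values())
        resid = y - fitted  # equals resid_var * V^-1 (y - mu)
        assert np.allclose(resid, fit.var_components["residual"] * w, rtol=1e-6)


class TestPartitionVariance:
    @pytest.mark.parametrize(
        "vc, expected",
        [
            ({"ZGZt": 1.0, "E": 1.0, "GxE": 1.0, "residual": 1.0}, [0.25] * 4),
            ({"ZGZt": 0.12, "E": 0.72, "GxE": 0.08, "residual": 0.08},
             [0.12, 0.72, 0.08, 0.08]),
            ({"ZGZt": 0.3, "residual": 0.1}, [0.75, 0.25]),
        ],
    )
    def test_normalization(self, vc, expected):
        fit = _manual_fit("GxE-BLUP", 0.0, vc, np.zeros(3), None, tuple(vc))
        pve = partition_variance(fit).pve
        assert list(pve.values()) == pytest.approx(expected)
        assert sum(pve.values()) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_raises(self):
        fit = _manual_fit("G-BLUP", 0.0, {"ZGZt": 0.0, "residual": 0.0},
                          np.zeros(3), None, ("ZGZt",))
        with pytest.raises(ValueError, match="zero"):
            partition_variance(fit)
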