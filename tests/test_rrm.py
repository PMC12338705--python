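import numpy as np
import pandas as pd
import pytest

from gxepred.kernels import build_env_design
from gxepred.rrm import (
    EnvValueMap,
    RRMFit,
    env_values,
    extrapolate_env_values,
    fit_rrm,
    legendre_basis,
    predict_rrm,
)


def closed_form_legendre(x, t):
    return [1.0, x, (3 * x**2 - 1) / 2, (5 * x**3 - 3 * x) / 2][t]


class TestLegendre:
    def test_endpoints_and_hand_values(self):
        assert np.allclose(legendre_basis(-1.0, 1), [1.0, -1.0])
        assert np.allclose(legendre_basis(0.0, 2), [1.0, 0.0, -0.5])

    def test_matches_closed_forms_on_grid(self):
        for x in np.linspace(-1, 1, 101):
            vals = legendre_basis(x, 3)
            for t in range(4):
                assert vals[t] == pytest.approx(closed_form_legendre(x, t), abs=1e-12)

    def test_orthogonality_by_quadrature(self):
        nodes, weights = np.polynomial.legendre.leggauss(64)
        vals = np.array([legendre_basis(x, 1) for x in nodes])
        assert abs(np.sum(weights * vals[:, 0] * vals[:, 1])) < 1e-12

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError, match="outside"):
            legendre_basis(1.1, 1)


def _pheno(env_means, lines=("a", "b")):
    rows = []
    for (sex, temp), m in env_means.items():
        for l in lines:
            rows.append({"line": l, "sex": sex, "temperature": temp, "lifespan": m})
    return pd.DataFrame(rows)


class TestEnvValues:
    MEANS = {("F", 18): 10.0, ("F", 25): 20.0, ("F", 28): 30.0}

    def test_min_max_mapping(self):
        em = env_values(_pheno(self.MEANS))
        assert em.x["F_18"] == pytest.approx(-1.0)
        assert em.x["F_25"] == pytest.approx(0.0)
        assert em.x["F_28"] == pytest.approx(1.0)

    def test_location_invariance(self):
        df = _pheno(self.MEANS)
        shifted = df.assign(lifespan=df["lifespan"] + 17.3)
        assert env_values(df).x == pytest.approx(env_values(shifted).x)

    def test_degenerate_gradient_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            env_values(_pheno({("F", 18): 5.0, ("F", 25): 5.0}))

    def test_extrapolation_is_clipped_and_leakage_free(self):
        recs = [(l, s, t) for l in "ab" for s in "FM" for t in (18, 25, 28)]
        design = build_env_design(recs)
        # training misses the M_28 cell; means rise with temperature
        means = {(s, t): 10.0 + t + (2.0 if s == "M" else 0.0)
                 for s in "FM" for t in (18, 25, 28)}
        del means[("M", 28)]
        em = env_values(_pheno(means))
        assert "M_28" not in em.x
        extrapolate_env_values(em, design)
        assert em.x["M_28"] == 1.0  # beyond the training max, clipped
        assert em.raw_means["M_28"] == pytest.approx(40.0, abs=0.5)


@pytest.fixture(scope="module")
def rrm_fit(small_dataset):
    geno, pheno, truth = small_dataset
    fit = fit_rrm(pheno, truth.kernels.G, geno.line_ids)
    return geno, pheno, truth, fit


class TestFitRrm:
    def test_converges_and_shapes(self, rrm_fit):
        geno, pheno, truth, fit = rrm_fit
        assert fit.converged
        assert fit.beta.shape == (2,)
        assert fit.Sigma_a.shape == (2, 2)
        assert len(fit.resid_vars) == 6
        assert fit.coef_blups.shape == (geno.n_lines, 2)
        w = np.linalg.eigvalsh(fit.Sigma_a)
        assert w.min() >= -1e-10

    def test_optimum_beats_random_parameter_sweep(self):
        # tiny instance: REML optimum dominates a random search
        rng = np.random.default_rng(14)
        n, r = 6, 3
        from gxepred.reml import reml_loglik_parts

        G = np.eye(n) + 0.1
        df = pd.DataFrame({
            "line": [f"l{i}" for i in range(n)] * r,
            "sex": ["F"] * (n * r),
            "temperature": np.repeat([18, 25, 28], n),
            "lifespan": rng.standard_normal(n * r) + np.repeat([0.0, 1.0, 3.0], n),
        })
        fit = fit_rrm(df, G, [f"l{i}" for i in range(n)])
        em = fit.env_map
        x = df["sex"].astype(str) + "_" + df["temperature"].map(lambda v: f"{v:g}")
        Phi = np.vstack([legendre_basis(em.x[e], 1) for e in x])
        rows = df["line"].map({f"l{i}": i for i in range(n)}).to_numpy()
        ZGZt = G[np.ix_(rows, rows)]
        env_masks = [(x == e).to_numpy(float) for e in dict.fromkeys(x)]
        y = df["lifespan"].to_numpy()
        best_rand = -np.inf
        for _ in range(2000):
            L = np.tril(rng.uniform(-1, 1, (2, 2)))
            L[np.diag_indices(2)] = rng.uniform(0.01, 1.5, 2)
            Sa = L @ L.T
            s2 = rng.uniform(0.05, 2.0, len(env_masks))
            V = (Phi @ Sa @ Phi.T) * ZGZt + np.diag(sum(s * m for s, m in zip(s2, env_masks)))
            try:
                ll, *_ = reml_loglik_parts(y, Phi, V)
            except np.linalg.LinAlgError:
                continue
            best_rand = max(best_rand, ll)
        assert fit.loglik >= best_rand - 1e-6

    def test_intercept_only_truth_recovers_small_slope_variance(self, tiny_grm):
        hits = 0
        n = tiny_grm.shape[0]
        ids = [f"l{i}" for i in range(n)]
        for seed in range(10):
            rng = np.random.default_rng(30 + seed)
            w, U = np.linalg.eigh(tiny_grm)
            a0 = (U * np.sqrt(np.clip(w, 0, None))) @ rng.standard_normal(n)
            rows = []
            for j, (s, t, m) in enumerate([("F", 18, 0.0), ("F", 25, 1.0), ("F", 28, 2.0),
                                           ("M", 18, 0.2), ("M", 25, 1.2), ("M", 28, 2.2)]):
                for i in range(n):
                    rows.append({"line": ids[i], "sex": s, "temperature": t,
                                 "lifespan": m + a0[i] + 0.3 * rng.standard_normal()})
            fit = fit_rrm(pd.DataFrame(rows), tiny_grm, ids)
            hits += fit.Sigma_a[1, 1] < 0.1 * fit.Sigma_a[0, 0]
        assert hits >= 8


class TestPredictRrm:
    def _manual_fit(self, beta, Sigma_a, coefs, xmap, ids):
        em = EnvValueMap(raw_means={k: 0.0 for k in xmap}, m_min=0.0, m_max=1.0, x=dict(xmap))
        return RRMFit(beta=np.asarray(beta, float), Sigma_a=np.asarray(Sigma_a, float),
                      resid_vars={}, coef_blups=np.asarray(coefs, float), env_map=em,
                      line_ids=np.asarray(ids, object), loglik=0.0, converged=True, T=1)

    def test_zero_coefficients_give_fixed_curve(self):
        fit = self._manual_fit([2.0, 1.0], np.eye(2), np.zeros((2, 2)),
                               {"e1": -1.0, "e2": 0.5}, ["a", "b"])
        pred = predict_rrm(fit, [("a", "e1"), ("b", "e2")])
        assert pred[0] == pytest.approx(2.0 - 1.0)
        assert pred[1] == pytest.approx(2.0 + 0.5)

    def test_equal_env_values_give_identical_predictions(self):
        fit = self._manual_fit([2.0, 1.0], np.eye(2), [[0.3, -0.2], [0.1, 0.4]],
                               {"e1": 0.25, "e2": 0.25}, ["a", "b"])
        pred = predict_rrm(fit, [("a", "e1"), ("a", "e2"), ("b", "e1"), ("b", "e2")])
        assert pred[0] == pytest.approx(pred[1])
        assert pred[2] == pytest.approx(pred[3])

    def test_predictions_affine_in_x_at_linear_order(self):
        fit = self._manual_fit([1.0, 2.0], np.eye(2), [[0.5, 0.25]],
                               {"a": -1.0, "b": 0.0, "c": 1.0}, ["l"])
        p = predict_rrm(fit, [("l", "a"), ("l", "b"), ("l", "c")])
        assert p[1] - p[0] == pytest.approx(p[2] - p[1])

    def test_unmapped_environment_raises(self):
        fit = self._manual_fit([0.0, 0.0], np.eye(2), np.zeros((1, 2)), {"e1": 0.0}, ["a"])
        with pytest.raises(KeyError, match="environmental value"):
            predict_rrm(fit, [("a", "mystery")])
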