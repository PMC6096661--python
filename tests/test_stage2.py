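"""WLS structural fitting: oracles, weight invariance, delta method."""

import numpy as np
import pytest

from masem.dataset import unvech, vech
from masem.model import implied_matrix, model_df, parse_model
from masem.simulate import _PATH_MODEL, path_population_matrix
from masem.stage1_fixed import FixedStage1Result
from masem.stage2 import derived_parameter, fit_wls, saturated_model

TABLE5_VECH = np.array([-0.24, 0.32, 0.14, -0.31, -0.18, 0.28])


def stage1_stub(P, acov, n=1000):
    """Hand-built pooled input for weight-sensitivity experiments."""
    return FixedStage1Result(
        P=P, acov=acov, chi2=0.0, df=0, total_n=n, converged=True
    )


def random_acov(q, scale, seed):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((q, 2 * q))
    return (A @ A.T + 2 * q * np.eye(q)) / scale


class TestFitWls:
    def test_saturated_model_reproduces_input_with_zero_chi2(self):
        P = unvech(TABLE5_VECH)
        res = fit_wls(stage1_stub(P, random_acov(6, 1e4, 0)), saturated_model(
            ["v1", "v2", "v3", "v4"]
        ))
        assert res.chi2 == pytest.approx(0.0, abs=1e-10)
        assert res.df == 0
        implied = implied_matrix(
            saturated_model(["v1", "v2", "v3", "v4"]), res.theta, check_admissible=False
        )
        assert np.allclose(vech(implied), TABLE5_VECH, atol=1e-8)

    @pytest.mark.parametrize("wseed", [0, 1, 2])
    def test_saturated_submodel_is_weight_invariant_partial_regression(self, wseed):
        """Regressing engagement on the two relation measures alone is
        saturated in those 3 variables, so the estimate is the usual
        partial regression coefficient whatever the weight matrix."""
        P3 = unvech(TABLE5_VECH)[:3, :3]
        m = parse_model("v3 ~ b31:v1 + b32:v2\nv1 ~~ psi12:v2", ["v1", "v2", "v3"])
        res = fit_wls(stage1_stub(P3, random_acov(3, 1e4, wseed)), m)
        r12, r13, r23 = -0.24, 0.32, -0.31
        expected = (r13 - r12 * r23) / (1 - r12**2)
        assert res.theta["b31"] == pytest.approx(expected, abs=1e-7)
        assert res.theta["b31"] == pytest.approx(0.2606, abs=5e-5)

    def test_one_parameter_model_matches_grid_search(self):
        m = parse_model("F =~ l:v1 + l:v2 + l:v3", ["v1", "v2", "v3"])
        P = unvech(np.array([0.35, 0.30, 0.42]))
        acov = random_acov(3, 5e3, 3)
        res = fit_wls(stage1_stub(P, acov), m)
        W = np.linalg.inv(acov)
        r = vech(P)
        grid = np.linspace(0.4, 0.8, 400_001)
        vals = [
            (r - vech(implied_matrix(m, {"l": t}, check_admissible=False)))
            @ W
            @ (r - vech(implied_matrix(m, {"l": t}, check_admissible=False)))
            for t in grid[:: 100]
        ]
        coarse = grid[::100][int(np.argmin(vals))]
        fine = np.linspace(coarse - 2e-4, coarse + 2e-4, 4001)
        valsf = [
            (r - vech(implied_matrix(m, {"l": t}, check_admissible=False)))
            @ W
            @ (r - vech(implied_matrix(m, {"l": t}, check_admissible=False)))
            for t in fine
        ]
        oracle = fine[int(np.argmin(valsf))]
        assert res.theta["l"] == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("wseed", [0, 5])
    def test_population_correlations_recover_generating_parameters(self, wseed):
        truth = {"b31": 0.265, "b32": -0.307, "b43": 0.288, "psi12": -0.329}
        P = path_population_matrix(0.265, -0.307, 0.288, -0.329)
        res = fit_wls(stage1_stub(P, random_acov(6, 1e4, wseed)), _PATH_MODEL)
        for name, val in truth.items():
            assert res.theta[name] == pytest.approx(val, abs=1e-6)
        assert res.chi2 == pytest.approx(0.0, abs=1e-10)

    def test_underidentified_model_rejected(self):
        # 2 observed variables, 3 free parameters
        m = parse_model("F =~ v1 + v2\nv1 ~~ v2", ["v1", "v2"])
        assert model_df(m) < 0
        P = unvech(np.array([0.4]))
        with pytest.raises(ValueError, match="identified"):
            fit_wls(stage1_stub(P, np.array([[0.001]])), m)

    def test_releasing_a_constraint_never_increases_chi2(self):
        P = path_population_matrix(0.3, -0.2, 0.35, -0.25)
        # perturb away from the model so chi2 > 0
        r = vech(P) + np.array([0.02, -0.01, 0.03, 0.01, -0.02, 0.02])
        s1 = stage1_stub(unvech(r), random_acov(6, 1e4, 9))
        constrained = parse_model(
            "v3 ~ b:v1 + b:v2\nv4 ~ b43:v3\nv1 ~~ psi12:v2", ["v1", "v2", "v3", "v4"]
        )
        free = parse_model(
            "v3 ~ b31:v1 + b32:v2\nv4 ~ b43:v3\nv1 ~~ psi12:v2", ["v1", "v2", "v3", "v4"]
        )
        c = fit_wls(s1, constrained)
        f = fit_wls(s1, free)
        assert f.chi2 <= c.chi2 + 1e-6
        assert f.df == c.df - 1


class TestSignConvention:
    def test_factor_with_negative_first_loading_is_flipped(self):
        """A one-factor model fitted to positive correlations has two
        equivalent optima (all loadings negated); the reported one has a
        positive first declared loading."""
        from masem.stage2 import _apply_sign_convention

        m = parse_model("F =~ a:v1 + b:v2 + c:v3", ["v1", "v2", "v3"])
        P = unvech(np.array([0.35, 0.30, 0.42]))
        acov = random_acov(3, 5e3, 3)
        res = fit_wls(stage1_stub(P, acov), m)
        assert res.theta["a"] > 0
        # flipping by hand and re-applying the convention restores the fit
        name_index = {n: i for i, n in enumerate(res.param_names)}
        x_neg = -np.array([res.theta[n] for n in res.param_names])
        groups = [(None, None, m, {lab: lab for lab in m.param_names})]
        x_back = _apply_sign_convention(groups, name_index, x_neg)
        assert np.allclose(x_back, [res.theta[n] for n in res.param_names])
        # both sign patterns imply the same correlation matrix
        assert np.allclose(
            implied_matrix(m, dict(zip(res.param_names, x_neg))),
            implied_matrix(m, res.theta),
        )


class TestDerivedParameter:
    def _fit(self):
        P = path_population_matrix(0.265, -0.307, 0.288, -0.329)
        return fit_wls(stage1_stub(P, random_acov(6, 1e4, 11)), _PATH_MODEL)

    def test_single_name_product_is_identity(self):
        res = self._fit()
        est, se, ci = derived_parameter(res, ["b43"])
        assert est == pytest.approx(res.theta["b43"])
        assert se == pytest.approx(res.se["b43"])

    def test_delta_method_arithmetic_for_independent_parameters(self):
        res = self._fit()
        res.vcov = np.diag([0.01, 0.01, 0.01, 0.01])
        res.theta = dict(zip(res.param_names, [0.5, 0.4, 0.1, 0.1]))
        est, se, _ = derived_parameter(res, res.param_names[:2])
        assert est == pytest.approx(0.2)
        assert se == pytest.approx(np.sqrt(0.4**2 * 0.01 + 0.5**2 * 0.01), abs=1e-10)

    def test_matches_parametric_bootstrap_sd(self):
        res = self._fit()
        est, se, _ = derived_parameter(res, ["b31", "b43"])
        rng = np.random.default_rng(0)
        mean = [res.theta[n] for n in res.param_names]
        draws = rng.multivariate_normal(mean, res.vcov, 10_000)
        i, j = res.param_names.index("b31"), res.param_names.index("b43")
        boot_sd = (draws[:, i] * draws[:, j]).std(ddof=1)
        assert abs(se - boot_sd) / boot_sd < 0.05

    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError):
            derived_parameter(self._fit(), ["nope"])
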