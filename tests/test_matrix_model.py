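"""Projection matrices, growth rates, and the counterfactual search."""

import numpy as np
import pytest

from sulapop.matrix_model import (
    BURN_IN,
    MC_MATRICES,
    N_CLASSES,
    STOCHASTIC_HORIZON,
    AnnualMatrix,
    build_annual_matrix,
    deterministic_lambda,
    lag1_autocorrelation,
    mc_lambda_ci,
    required_fertility_increase,
    stochastic_lambda,
)
from sulapop.vital_rates import VitalRateTable


def leslie_3x3():
    """F = (0, 1, 1), P = (0.5, 0.4): characteristic polynomial
    lambda^3 - 0.5 lambda - 0.2 = 0."""
    A = np.zeros((3, 3))
    A[0] = [0.0, 1.0, 1.0]
    A[1, 0] = 0.5
    A[2, 1] = 0.4
    return A


def bisect_char_root(lo=0.1, hi=2.0, tol=1e-13):
    f = lambda lam: lam**3 - 0.5 * lam - 0.2
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def uniform_matrix(fert=0.12, surv=0.92):
    F = np.zeros(N_CLASSES)
    F[3:21] = fert
    P = np.ones(N_CLASSES)
    P[3:] = surv
    comp = {
        "abs_mean": np.where(F > 0, 2 * fert / 0.4, 0.0),
        "abs_var": np.where(F > 0, 1e-4, 0.0),
        "fjuv_mean": np.where(F > 0, 0.4, 0.0),
        "fjuv_var": np.where(F > 0, 1e-4, 0.0),
        "surv_mean": P.copy(),
        "surv_var": np.where(P < 1, 1e-5, 0.0),
    }
    return AnnualMatrix(year=0, F=F, P=P, components=comp)


class TestDeterministicLambda:
    def test_leslie_matches_characteristic_polynomial_root(self):
        lam = deterministic_lambda(leslie_3x3())
        assert lam == pytest.approx(bisect_char_root(), abs=1e-10)

    def test_identity_matrix(self):
        assert deterministic_lambda(np.eye(22)) == pytest.approx(1.0, abs=1e-12)

    def test_eigen_homogeneity_under_scaling(self):
        A = leslie_3x3()
        lam = deterministic_lambda(A)
        assert deterministic_lambda(3.0 * A) == pytest.approx(3.0 * lam, rel=1e-12)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero matrix"):
            deterministic_lambda(np.zeros((4, 4)))

    def test_permutation_similarity_invariance(self, rng):
        A = uniform_matrix().A
        perm = rng.permutation(N_CLASSES)
        Pm = np.eye(N_CLASSES)[perm]
        assert deterministic_lambda(Pm @ A @ Pm.T) == pytest.approx(
            deterministic_lambda(A), rel=1e-10
        )


class TestAnnualMatrixStructure:
    def test_dimensions_and_structural_zeros(self):
        m = uniform_matrix()
        assert m.A.shape == (22, 22)
        assert m.F[0] == m.F[1] == m.F[21] == 0.0
        assert np.all(m.P[:3] == 1.0)

    def test_invalid_fertility_rejected(self):
        F = np.zeros(N_CLASSES)
        F[21] = 0.1  # terminal class must have zero fertility
        with pytest.raises(ValueError, match="classes 1, 2 and 22"):
            AnnualMatrix(year=0, F=F, P=np.ones(N_CLASSES))

    def test_survival_outside_unit_interval_rejected(self):
        P = np.ones(N_CLASSES)
        P[5] = 1.2
        with pytest.raises(ValueError, match="survival"):
            AnnualMatrix(year=0, F=np.zeros(N_CLASSES), P=P)


def _tables(abs_val=0.6, juv_val=0.5, surv_val=0.9, var=0.0):
    ages = np.arange(3, 23)
    years = np.array([0])
    mk = lambda v: np.full((len(ages), 1), v)
    prov = np.full((len(ages), 1), "estimated", dtype=object)
    abs_t = VitalRateTable("ABS", ages, years, mk(abs_val), mk(var), prov.copy())
    juv_t = VitalRateTable("juv_survival", ages, years, mk(juv_val), mk(var), prov.copy())
    surv_t = VitalRateTable("adult_survival", ages, years, mk(surv_val), mk(var), prov.copy())
    return abs_t, juv_t, surv_t


class TestBuildAnnualMatrix:
    def test_fertility_formula_arithmetic(self):
        abs_t, juv_t, surv_t = _tables(abs_val=0.6, juv_val=0.5)
        m = build_annual_matrix(abs_t, juv_t, surv_t, 0, juv_is_female=True)
        # F_8 = ABS/2 * female juvenile survival = 0.6/2 * 0.5 = 0.15
        assert m.F[7] == pytest.approx(0.15, abs=1e-12)
        assert m.F[0] == m.F[1] == m.F[21] == 0.0
        assert np.all(m.P[:3] == 1.0)
        assert m.P[7] == pytest.approx(0.9)
        assert m.P[21] == pytest.approx(0.9)  # terminal self-loop

    def test_sex_adjustment_applied_to_combined_rate(self):
        abs_t, juv_t, surv_t = _tables(abs_val=0.6, juv_val=0.233)
        m = build_annual_matrix(abs_t, juv_t, surv_t, 0, male_advantage=1.33)
        assert m.F[7] == pytest.approx(0.3 * 0.2, abs=1e-12)

    def test_missing_cell_error_names_rate_age_year(self):
        abs_t, juv_t, surv_t = _tables()
        with pytest.raises(KeyError, match="ABS, age=3, year=7"):
            build_annual_matrix(abs_t, juv_t, surv_t, 7)

    def test_product_variance_delta_vs_monte_carlo(self, rng):
        # Var(XY) ~= Y^2 VarX + X^2 VarY at CV <= 0.2
        x0, y0 = 0.3, 0.4
        vx, vy = (0.2 * x0) ** 2, (0.15 * y0) ** 2
        delta = y0**2 * vx + x0**2 * vy
        draws = rng.normal(x0, np.sqrt(vx), 200_000) * rng.normal(y0, np.sqrt(vy), 200_000)
        assert delta == pytest.approx(np.var(draws), rel=0.05)


class TestMcLambdaCi:
    def test_zero_variance_collapses_to_point(self):
        m = uniform_matrix()
        for k in m.components:
            if k.endswith("_var"):
                m.components[k] = np.zeros(N_CLASSES)
        est = mc_lambda_ci(m, n=100, seed=0)
        assert est.ci_low == pytest.approx(est.value, abs=1e-12)
        assert est.ci_high == pytest.approx(est.value, abs=1e-12)

    def test_default_resample_count_is_1000(self):
        import inspect

        assert inspect.signature(mc_lambda_ci).parameters["n"].default == 1000
        assert MC_MATRICES == 1000

    def test_bias_corrected_percentiles_consistent_with_draws(self):
        m = uniform_matrix()
        est = mc_lambda_ci(m, n=400, seed=3)
        draws = est.extra["draws"]
        lam0 = deterministic_lambda(m.A)
        assert np.mean(draws) == pytest.approx(lam0, abs=1e-12)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        assert est.ci_low == pytest.approx(lo, abs=1e-12)
        assert est.ci_high == pytest.approx(hi, abs=1e-12)

    def test_excess_variance_clipped_with_warning(self):
        m = uniform_matrix()
        m.components["abs_var"] = np.where(
            m.components["abs_mean"] > 0, 0.9, 0.0
        )
        with pytest.warns(UserWarning, match="clipped"):
            mc_lambda_ci(m, n=50, seed=1)


class TestStochasticLambda:
    def test_single_matrix_reduces_to_deterministic(self):
        m = uniform_matrix()
        est = stochastic_lambda([m], horizon=3000, seed=0)
        assert est.value == pytest.approx(deterministic_lambda(m.A), abs=1e-6)

    def test_proportional_pool_closed_form(self):
        # pool {A, cA} equiprobable: log lambda_s = log lambda_A + 0.5 log c
        m = uniform_matrix()
        c = 0.8
        lamA = deterministic_lambda(m.A)
        est = stochastic_lambda([m.A, c * m.A], horizon=10_000, seed=5)
        expected = np.exp(np.log(lamA) + 0.5 * np.log(c))
        se_log = est.extra["se_log"]
        assert abs(np.log(est.value) - np.log(expected)) < 3 * se_log

    def test_default_horizon_and_burn_in(self):
        import inspect

        sig = inspect.signature(stochastic_lambda)
        assert sig.parameters["horizon"].default == 10_000
        assert STOCHASTIC_HORIZON == 10_000
        assert BURN_IN == 1000

    def test_zero_eigenvalue_matrix_rejected(self):
        nilpotent = np.array([[0.0, 0.0], [0.5, 0.0]])  # spectral radius 0
        with pytest.raises(ValueError, match="zero dominant"):
            stochastic_lambda([nilpotent], horizon=100)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            stochastic_lambda([])


class TestLag1Autocorrelation:
    def test_alternating_series_fully_negative(self):
        out = lag1_autocorrelation([1, 2, 1, 2, 1, 2])
        assert out["r"] == pytest.approx(-1.0, abs=1e-12)
        assert out["df"] == 3  # n_pairs - 2 convention

    def test_null_distribution_of_iid_series(self, rng):
        # |r| < 0.45 in ~95% of length-20 white-noise series
        hits = 0
        for _ in range(200):
            out = lag1_autocorrelation(rng.normal(size=20))
            hits += abs(out["r"]) < 0.45
        assert hits / 200 > 0.88

    def test_constant_series_reported_undefined(self):
        out = lag1_autocorrelation([1.0, 1.0, 1.0, 1.0])
        assert np.isnan(out["r"])
        assert "undefined" in out["note"]

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            lag1_autocorrelation([1.0, 2.0, 3.0])


class TestRequiredFertilityIncrease:
    def _declining_pool(self):
        return [uniform_matrix(fert=0.075, surv=0.92)]

    def test_counterfactual_reaches_target_on_resimulation(self):
        pool = self._declining_pool()
        base = stochastic_lambda(pool, horizon=10_000, seed=7)
        assert base.value < 1.0
        out = required_fertility_increase(pool, target=1.0, seed=7)
        assert not out["cap_limited"]
        assert out["increase"] > 0
        # independent re-simulation at the recovered multiplier
        from sulapop.matrix_model import _scaled_pool

        lam = stochastic_lambda(
            _scaled_pool(pool, 1.0 + out["increase"]), horizon=10_000, seed=1234
        ).value
        assert lam == pytest.approx(1.0, abs=1e-3)

    def test_pool_already_at_target_needs_no_increase(self):
        pool = [uniform_matrix(fert=0.25, surv=0.95)]
        out = required_fertility_increase(pool, target=1.0, seed=2)
        assert out["increase"] == 0.0

    def test_lambda_monotone_in_multiplier_before_caps(self):
        pool = self._declining_pool()
        from sulapop.matrix_model import _scaled_pool

        lams = [
            stochastic_lambda(_scaled_pool(pool, c), horizon=2000, seed=11).value
            for c in (1.0, 1.2, 1.4, 1.6)
        ]
        assert np.all(np.diff(lams) > 0)

    def test_unreachable_target_reported_cap_limited(self):
        # survival so low that even certain breeding cannot reach lambda 1
        pool = [uniform_matrix(fert=0.05, surv=0.35)]
        out = required_fertility_increase(pool, target=1.0, seed=3)
        assert out["cap_limited"]
        assert out["lambda_achieved"] < 1.0
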