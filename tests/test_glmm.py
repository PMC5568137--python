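"""Binomial mixed model: quadrature accuracy, fitting, bootstrap, YBD prep."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from sulapop.glmm import (
    BinomialMixedModel,
    SEPARATION_THRESHOLD,
    _bernoulli_loglik,
    bootstrap_ci,
    ybd_prepare,
)

from conftest import make_glmm_data


def dense_grid_loglik(y, X, codes, beta, sigma, width=10.0, npts=2001):
    """Brute-force marginal log-likelihood by trapezoid integration over
    the scaled intercept z in [-width, width] (u = sigma*z)."""
    total = 0.0
    z = np.linspace(-width, width, npts)
    for g in np.unique(codes):
        sel = codes == g
        etag = X[sel] @ beta
        lin = etag[:, None] + sigma * z[None, :]
        ll = (y[sel, None] * lin - np.logaddexp(0, lin)).sum(axis=0)
        dens = np.exp(ll) * np.exp(-0.5 * z**2) / np.sqrt(2 * np.pi)
        total += np.log(np.trapezoid(dens, z))
    return total


@pytest.fixture(scope="module")
def tiny_model():
    rng = np.random.default_rng(7)
    y, X, codes = make_glmm_data(rng, n_groups=3, n_obs=4, sigma=1.0)
    # ensure both outcome classes are present in this tiny draw
    y[0], y[1] = 0.0, 1.0
    return y, X, codes, BinomialMixedModel(y, X, {"g": codes})


class TestQuadrature:
    def test_agq_matches_dense_grid(self, tiny_model):
        y, X, codes, m = tiny_model
        beta = np.array([-0.3, 0.8])
        oracle = dense_grid_loglik(y, X, codes, beta, 1.0)
        assert m.loglik_agq(beta, np.log(1.0), n_nodes=15) == pytest.approx(
            oracle, abs=1e-6
        )

    def test_single_node_equals_laplace(self, tiny_model):
        y, X, codes, m = tiny_model
        beta = np.array([-0.3, 0.8])
        agq1 = m.loglik_agq(beta, np.log(0.8), n_nodes=1)
        lap = m._loglik_laplace(beta, {"g": 0.8})
        assert agq1 == pytest.approx(lap, abs=1e-10)

    def test_sigma_zero_reduces_to_glm(self, tiny_model):
        y, X, codes, m = tiny_model
        beta = np.array([-0.3, 0.8])
        glm = float(_bernoulli_loglik(y, X @ beta).sum())
        assert m.loglik_agq(beta, np.log(1e-8)) == pytest.approx(glm, abs=1e-8)

    def test_node_convergence_monotone(self, tiny_model):
        y, X, codes, m = tiny_model
        beta = np.array([-0.3, 0.8])
        ref = m.loglik_agq(beta, 0.0, n_nodes=51)
        errs = [abs(m.loglik_agq(beta, 0.0, n_nodes=k) - ref) for k in (3, 7, 15)]
        assert errs[0] > errs[1] > errs[2]

    def test_zero_nodes_rejected(self, tiny_model):
        *_, m = tiny_model
        with pytest.raises(ValueError):
            m.loglik_agq(np.zeros(2), 0.0, n_nodes=0)

    def test_nonfinite_predictor_rejected(self, tiny_model):
        *_, m = tiny_model
        with pytest.raises(FloatingPointError):
            m.loglik_agq(np.array([np.inf, 0.0]), 0.0)


class TestFit:
    def test_closed_form_glm_intercept(self):
        # outcome frequency 0.25, sigma fixed 0 -> intercept = logit(0.25)
        y = np.array([1.0, 0, 0, 0] * 25)
        X = np.ones((100, 1))
        m = BinomialMixedModel(y, X, {"g": np.arange(100) % 10})
        fit = m.fit(fix_sigma={"g": 0.0})
        assert fit.beta[0] == pytest.approx(np.log(0.25 / 0.75), abs=1e-9)

    def test_recovery_within_three_se(self, rng):
        y, X, codes = make_glmm_data(rng, n_groups=500, n_obs=6)
        fit = BinomialMixedModel(y, X, {"g": codes}).fit()
        assert fit.converged
        se = fit.bse().to_numpy()
        assert abs(fit.beta[0] - (-1.0)) < 3 * se[0]
        assert abs(fit.beta[1] - 0.5) < 3 * se[1]
        assert abs(fit.sigma["g"] - 0.7) < 0.15

    def test_invariant_to_row_order_and_relabeling(self, rng):
        y, X, codes = make_glmm_data(rng, n_groups=40, n_obs=5)
        fit1 = BinomialMixedModel(y, X, {"g": codes}).fit()
        perm = rng.permutation(len(y))
        relabel = rng.permutation(40)
        fit2 = BinomialMixedModel(
            y[perm], X[perm], {"g": relabel[codes[perm]]}
        ).fit()
        np.testing.assert_allclose(fit1.beta, fit2.beta, atol=1e-5)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-6)

    def test_rank_deficiency_names_aliased_columns(self):
        X = np.column_stack([np.ones(40), np.arange(40.0), 2 * np.arange(40.0)])
        y = (np.arange(40) % 2).astype(float)
        with pytest.raises(ValueError, match="aliased"):
            BinomialMixedModel(y, X, {"g": np.arange(40) % 4},
                               exog_names=["Intercept", "x", "x2"])

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError, match="both 0s and 1s"):
            BinomialMixedModel(np.ones(10), np.ones((10, 1)), {"g": np.arange(10) % 2})

    def test_separation_flagged_not_silent(self):
        # perfectly separated covariate
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        X = np.column_stack([np.ones(40), x])
        fit = BinomialMixedModel(y + 0.0, X, {"g": np.arange(40) % 5}).fit(
            fix_sigma={"g": 0.0}
        )
        assert (not fit.converged) or "separated_terms" in fit.metadata or \
            np.max(np.abs(fit.beta)) > SEPARATION_THRESHOLD

    def test_agq_requires_single_group(self, rng):
        y, X, codes = make_glmm_data(rng, n_groups=20, n_obs=4)
        with pytest.raises(ValueError, match="one random group"):
            BinomialMixedModel(y, X, {"a": codes, "b": codes[::-1]}, method="agq")

    def test_crossed_laplace_consistent_with_agq_when_one_sigma_zero(self, rng):
        y, X, codes = make_glmm_data(rng, n_groups=30, n_obs=5)
        yr = np.arange(len(y)) % 6
        m2 = BinomialMixedModel(y, X, {"g": codes, "yr": yr})
        m1 = BinomialMixedModel(y, X, {"g": codes})
        beta = np.array([-0.8, 0.4])
        assert m2._loglik_laplace(beta, {"g": 0.5, "yr": 0.0}) == pytest.approx(
            m1.loglik_agq(beta, np.log(0.5), n_nodes=1), abs=1e-9
        )


class TestFromDataFrame:
    def test_paper_shaped_model_and_interaction_null(self):
        # age quadratic (centered) + binary phase; truth has no interaction,
        # so its fitted coefficient should sit within ~3 SE of zero
        rng = np.random.default_rng(1)
        n = 4000
        age = rng.integers(4, 18, n)
        phase = rng.integers(0, 2, n)
        ids = rng.integers(0, 400, n)
        u = rng.normal(0, 0.4, 400)
        eta = 0.5 - 0.03 * (age - 10.0) ** 2 - 1.0 * phase + u[ids]
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        df = pd.DataFrame({"y": y, "age": age, "phase": phase, "bird": ids})
        m = BinomialMixedModel.from_dataframe(
            df, "y", ["age", "age^2", "C(phase)", "age:C(phase)"], ["bird"],
            n_nodes=7,
        )
        fit = m.fit()
        assert fit.converged
        name = [n_ for n_ in fit.params.index if ":" in n_][0]
        ci = fit.conf_int()
        z = abs(fit.params[name]) / fit.bse()[name]
        assert z < 3.0
        assert ci.loc[name, "lcl"] < 0 < ci.loc[name, "ucl"]

    def test_marginality_enforced(self, small_dataset):
        with pytest.raises(ValueError, match="marginality|requires"):
            BinomialMixedModel.from_dataframe(
                small_dataset.breeding, "success", ["age^2"], ["bird_id"]
            )

    def test_summary_mentions_all_terms(self, rng):
        y, X, codes = make_glmm_data(rng, n_groups=30, n_obs=4)
        fit = BinomialMixedModel(y, X, {"g": codes}).fit()
        s = fit.summary()
        assert "sigma(g)" in s and "AICc" in s


class TestBootstrap:
    def test_default_sample_count_is_1000(self):
        import inspect

        assert inspect.signature(bootstrap_ci).parameters["n_boot"].default == 1000

    def test_deterministic_under_seed(self, rng):
        y, X, codes = make_glmm_data(rng, n_groups=60, n_obs=4, sigma=0.3)
        fit = BinomialMixedModel(y, X, {"g": codes}).fit()
        ci1 = bootstrap_ci(fit, n_boot=30, seed=5)
        ci2 = bootstrap_ci(fit, n_boot=30, seed=5)
        pd.testing.assert_frame_equal(ci1, ci2)

    def test_matches_wald_for_sigma_zero_large_n(self, rng):
        y, X, codes = make_glmm_data(rng, n_groups=4000, n_obs=4, sigma=0.0)
        fit = BinomialMixedModel(y, X, {"g": codes}).fit(fix_sigma={"g": 0.0})
        boot = bootstrap_ci(fit, n_boot=200, seed=11)
        wald = fit.conf_int()
        for name in ("x0", "x1"):
            hw_b = (boot.loc[name, "ucl"] - boot.loc[name, "lcl"]) / 2
            hw_w = (wald.loc[name, "ucl"] - wald.loc[name, "lcl"]) / 2
            assert hw_b == pytest.approx(hw_w, rel=0.10)


class TestAgainstLme4:
    def test_loglik_and_coefficients_match_lme4(self, rng, tmp_path):
        """Independent cross-check of the AGQ fit against lme4::glmer."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        y, X, codes = make_glmm_data(rng, n_groups=150, n_obs=5,
                                     beta=(-0.6, 0.9), sigma=0.6)
        df = pd.DataFrame({"y": y.astype(int), "x": X[:, 1], "g": codes})
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(y ~ x + (1|g), data=d, family=binomial, nAGQ=15)
            cat(logLik(m), fixef(m), sqrt(unlist(VarCorr(m))), sep="\\n")
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        ll_r, b0_r, b1_r, sig_r = map(float, out.stdout.split())
        fit = BinomialMixedModel(y, X, {"g": codes}, n_nodes=15).fit()
        assert fit.loglik == pytest.approx(ll_r, abs=0.05)
        assert fit.beta[0] == pytest.approx(b0_r, abs=0.02)
        assert fit.beta[1] == pytest.approx(b1_r, abs=0.02)
        assert fit.sigma["g"] == pytest.approx(sig_r, abs=0.05)


class TestYbdPrepare:
    def _records(self, bird, seasons, entry_age):
        return pd.DataFrame(
            {
                "bird_id": bird,
                "season": list(seasons),
                "age": [entry_age + i for i in range(len(seasons))],
            }
        )

    def test_final_window_of_qualifying_bird(self):
        # bird with 12 seasons of records dying at known age >= 13:
        # exactly the last 5 records retained, YBD 5..1
        df = self._records("b1", range(0, 12), entry_age=4)  # dies age 16
        out = ybd_prepare(df, data_end=20)
        assert len(out) == 5
        assert out["ybd"].tolist() == [5, 4, 3, 2, 1]
        assert out["season"].tolist() == [7, 8, 9, 10, 11]

    def test_young_death_excluded(self):
        df = self._records("b2", range(0, 8), entry_age=4)  # dies age 12
        out = ybd_prepare(df, data_end=20)
        assert out.empty
        assert out.attrs["n_young_excluded"] == 1

    def test_alive_at_data_end_excluded_and_counted(self):
        df = self._records("b3", range(0, 12), entry_age=4)
        out = ybd_prepare(df, data_end=12)  # only one absence observable
        assert out.empty
        assert out.attrs["n_alive_excluded"] == 1

    def test_empty_input_is_vacuous(self):
        out = ybd_prepare(pd.DataFrame(columns=["bird_id", "season", "age"]))
        assert out.empty
        assert "ybd" in out.columns
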