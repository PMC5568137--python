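"""CJS likelihood correctness, fitting, model comparison, and c-hat."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sulapop.cjs import CJSModel, CjsSpec, bootstrap_chat, compare_models

from conftest import simulate_cjs_histories


def logit(p):
    return np.log(p / (1 - p))


CONST = CjsSpec(phi_time="const", p_time="const")


def const_params(phi, p):
    return np.array([logit(phi), logit(p)])


def enumeration_probability(history, f, T, phi, p):
    """Exhaustive latent-state oracle: sum over the occasion k through
    which the animal stayed alive (k = T-1 covers survival to the end)."""
    total = 0.0
    for k in range(f, T):
        pr = phi ** (k - f) * ((1 - phi) if k < T - 1 else 1.0)
        pd_ = 1.0
        ok = True
        for t in range(f + 1, T):
            if t <= k:
                pd_ *= p if history[t] else (1 - p)
            elif history[t]:
                ok = False
                break
        if ok:
            total += pr * pd_
    return total


@pytest.fixture(scope="module")
def host_model():
    det = np.array([[1, 0, 1, 0], [1, 1, 1, 1], [0, 1, 0, 1]], dtype=np.int8)
    return CJSModel(det, [0, 0, 1], [4, 4, 4], CONST)


class TestLikelihood:
    def test_matches_latent_state_enumeration(self, host_model):
        params = const_params(0.8, 0.9)
        total = 0.0
        for rest in itertools.product([0, 1], repeat=3):
            h = (1,) + rest
            oracle = enumeration_probability(h, 0, 4, 0.8, 0.9)
            model_p = host_model.history_probability(params, h)
            assert model_p == pytest.approx(oracle, abs=1e-10)
            total += model_p
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_two_occasion_closed_form(self):
        m = CJSModel(np.array([[1, 1]], dtype=np.int8), [0], [4], CONST)
        assert m.history_probability(const_params(0.8, 0.9), [1, 1]) == \
            pytest.approx(0.8 * 0.9, abs=1e-12)

    def test_perfect_detection_reduces_to_bernoulli_survival(self):
        # p -> 1: each history's probability is phi^(survived) * (1-phi)
        # for animals that disappear, phi^(T-1-f) for those seen to the end
        phi = 0.85
        params = np.array([logit(phi), 37.0])  # p = 1 - ~1e-16
        T = 6
        m = CJSModel(np.array([[1] * T], dtype=np.int8), [0], [4], CONST)
        full = np.ones(T, dtype=np.int8)
        assert m.history_probability(params, full) == pytest.approx(
            phi ** (T - 1), abs=1e-10
        )
        # seen for 3 occasions then never again => died in the next interval
        h = np.array([1, 1, 1, 0, 0, 0], dtype=np.int8)
        assert m.history_probability(params, h) == pytest.approx(
            phi**2 * (1 - phi), abs=1e-10
        )

    def test_wrong_parameter_length_rejected(self, host_model):
        with pytest.raises(ValueError, match="parameters"):
            host_model.loglik(np.zeros(5))

    def test_order_invariance_via_aggregation(self, rng):
        det, grp, age = simulate_cjs_histories(rng, n=200, T=8)
        m1 = CJSModel(det, grp, age, CONST)
        perm = rng.permutation(len(det))
        m2 = CJSModel(det[perm], grp[perm], age[perm], CONST)
        params = const_params(0.9, 0.9)
        assert m1.loglik(params) == pytest.approx(m2.loglik(params), abs=1e-10)

    def test_pre_adult_detections_deleted(self):
        # a nestling first seen at age 2 has those occasions stripped and
        # the history re-anchored at the first adult detection
        det = np.array([[1, 1, 0, 1, 0, 0]], dtype=np.int8)
        m = CJSModel(det, [0], [2], CONST)
        assert m.first[0] == 3
        assert m.entry_age[0] == 5  # age at the first adult-age detection
        assert m.det[0].tolist() == [0, 0, 0, 1, 0, 0]


class TestFit:
    def test_recovery_and_wald_coverage(self, rng):
        det, grp, age = simulate_cjs_histories(rng, n=2000, T=20, phi=0.9, p=0.9)
        res = CJSModel(det, grp, age, CONST).fit()
        assert res.converged
        tab = res.coef_table()
        for name, truth in (("phi:Intercept", logit(0.9)), ("p:Intercept", logit(0.9))):
            assert abs(tab.loc[name, "coef"] - truth) < 3 * tab.loc[name, "se"]

    def test_period_effect_recovers_survival_shift(self, small_dataset):
        # generating truth: +0.55 logit survival after the regime change
        cfg = small_dataset.config
        spec = CjsSpec(
            phi_time="period", p_time="const",
            period_breaks=(cfg.regime_change_season, cfg.regime_change_season + 1),
        )
        res = CJSModel.from_dataframe(small_dataset.encounters, spec).fit()
        tab = res.coef_table()
        row = tab.loc["phi:P2"]
        assert row["lcl"] < 0.55 < row["ucl"]

    def test_saturated_detection_gives_p_near_one(self):
        rng = np.random.default_rng(3)
        det, grp, age = simulate_cjs_histories(rng, n=300, T=8, phi=0.85, p=0.999)
        res = CJSModel(det, grp, age, CONST).fit()
        ptab = res.p_table()
        assert (ptab["estimate"] > 0.98).all()

    def test_final_interval_flagged_confounded_for_time_models(self, rng):
        det, grp, age = simulate_cjs_histories(rng, n=400, T=6)
        spec = CjsSpec(phi_time="year", p_time="year")
        res = CJSModel(det, grp, age, spec).fit()
        phi = res.phi_table()
        assert not phi.loc[phi["time"] == phi["time"].max(), "usable"].any()
        assert phi.loc[phi["time"] < phi["time"].max(), "usable"].all()

    def test_probability_outputs_in_unit_interval(self, rng):
        det, grp, age = simulate_cjs_histories(rng, n=150, T=6)
        res = CJSModel(det, grp, age, CONST).fit()
        for tab in (res.phi_table(), res.p_table()):
            assert ((tab["estimate"] > 0) & (tab["estimate"] < 1)).all()
            assert (tab["se"] >= 0).all()

    def test_age_group_design_gives_distinct_profiles(self, rng):
        det, grp, age = simulate_cjs_histories(rng, n=400, T=8)
        grp[200:] = 1
        spec = CjsSpec(phi_time="const", phi_age=True, phi_group=True,
                       p_time="const")
        m = CJSModel(det, grp, age, spec)
        # age effects are nested within group: one age-contrast set per group
        age_cols = [n for n in m.param_names if ":age" in n]
        assert any(":g0:" in n for n in age_cols)
        assert any(":g1:" in n for n in age_cols)


class TestCompareModels:
    def _fits(self, rng, shift=0.0):
        cfgdet = simulate_cjs_histories(rng, n=600, T=10, phi=0.88)
        det, grp, age = cfgdet
        fits = {}
        for name, spec in (
            ("const", CONST),
            ("period", CjsSpec(phi_time="period", p_time="const",
                               period_breaks=(4, 5))),
        ):
            fits[name] = CJSModel(det, grp, age, spec).fit()
        return fits

    def test_lrt_df_two_for_three_level_period(self, rng, small_dataset):
        cfg = small_dataset.config
        change = cfg.regime_change_season
        det = small_dataset.encounters
        fits = {
            "period": CJSModel.from_dataframe(
                det, CjsSpec(phi_time="period", p_time="const",
                             period_breaks=(change, change + 1))).fit(),
            "const": CJSModel.from_dataframe(
                det, CjsSpec(phi_time="const", p_time="const")).fit(),
        }
        table, lrt = compare_models(fits, tests=[("period", "const")])
        assert lrt["df"].iloc[0] == 2
        assert lrt["chi2"].iloc[0] > 0  # the statistic itself is data-dependent

    def test_identical_models_tie(self, rng):
        det, grp, age = simulate_cjs_histories(rng, n=200, T=6)
        f1 = CJSModel(det, grp, age, CONST).fit()
        f2 = CJSModel(det, grp, age, CONST).fit()
        table, lrt = compare_models({"a": f1, "b": f2}, tests=[("a", "b")])
        assert table["delta_aicc"].abs().max() < 1e-6
        assert abs(lrt["chi2"].iloc[0]) < 1e-6

    def test_non_nested_pair_rejected(self, rng):
        det, grp, age = simulate_cjs_histories(rng, n=200, T=8)
        f_p = CJSModel(det, grp, age,
                       CjsSpec(phi_time="period", p_time="const",
                               period_breaks=(3, 4))).fit()
        f_age = CJSModel(det, grp, age,
                         CjsSpec(phi_time="const", phi_age=True,
                                 p_time="const")).fit()
        with pytest.raises(ValueError, match="not nested"):
            compare_models({"p": f_p, "a": f_age}, tests=[("p", "a")])


class TestBootstrapChat:
    def test_null_calibration_near_one(self, rng):
        det, grp, age = simulate_cjs_histories(rng, n=400, T=8)
        res = CJSModel(det, grp, age, CONST).fit()
        chat, devs = bootstrap_chat(res, n_boot=60, seed=9)
        assert 1.0 <= chat < 1.15

    def test_overdispersion_increases_chat(self, rng):
        # extra-binomial structure: whole broods share one survival draw,
        # equivalent to duplicated histories -> deviance doubles relative
        # to independent birds of the same nominal sample size
        det, grp, age = simulate_cjs_histories(rng, n=250, T=8)
        det2 = np.repeat(det, 2, axis=0)
        grp2 = np.repeat(grp, 2)
        age2 = np.repeat(age, 2)
        res = CJSModel(det2, grp2, age2, CONST).fit()
        # bootstrap simulates independent birds; observed deviance carries
        # the duplication, so c-hat should exceed 1 clearly
        chat, _ = bootstrap_chat(res, n_boot=60, seed=9)
        assert chat > 1.3

    def test_small_bootstrap_warns(self, rng):
        det, grp, age = simulate_cjs_histories(rng, n=100, T=5)
        res = CJSModel(det, grp, age, CONST).fit()
        with pytest.warns(UserWarning, match="unstable"):
            bootstrap_chat(res, n_boot=5, seed=1)


class TestInpRoundtrip:
    def test_fixed_width_format_roundtrips(self, tmp_path, small_dataset):
        from sulapop.cjs import read_encounters_inp
        from sulapop.simulate import write_encounters_inp

        path = tmp_path / "enc.inp"
        write_encounters_inp(small_dataset.encounters, path)
        back = read_encounters_inp(path)
        assert len(back) == len(small_dataset.encounters)
        assert back["detections"].tolist() == \
            small_dataset.encounters["detections"].tolist()
        grp = small_dataset.encounters["group"].tolist()
        assert back["group"].tolist() == grp
        # the recovered frame feeds the model directly
        m = CJSModel.from_dataframe(back, CONST)
        assert m.n_released == len(back)

    def test_malformed_line_rejected(self, tmp_path):
        from sulapop.cjs import read_encounters_inp

        bad = tmp_path / "bad.inp"
        bad.write_text("10x01 1 0;\n")
        with pytest.raises(ValueError, match="line 1"):
            read_encounters_inp(bad)
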