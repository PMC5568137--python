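"""Age x year vital-rate tables built from fitted models.

Three rates feed the projection matrices: Annual Breeding Success (ABS,
the probability a living female produces an independent offspring),
juvenile survival from independence to recruitment, and annual adult
survival.  Model predictions are evaluated at random-effect zero (the
population-median scale) and carried with delta-method variances.  Two
imputation regressions fill years without direct estimates: ABS for a
partially monitored year is predicted from annual adult survival
(logit-logit OLS, both standardized at age 10), and juvenile survival for
recent cohorts - whose members have not all had time to recruit - is
predicted from ABS the same way, after a-priori and leverage-based year
exclusions.  Juvenile survival is estimated on mixed-sex cohorts, so the
female rate is recovered assuming a 50/50 sex ratio at independence and a
configurable male survival advantage (default 1.33x).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "VitalRateTable",
    "abs_table",
    "impute_abs_from_survival",
    "impute_juv_survival",
    "female_juv_survival",
    "logit_logit_regression",
    "MALE_JUV_ADVANTAGE",
]

#: default male:female juvenile survival ratio (males survive ~33% better)
MALE_JUV_ADVANTAGE = 1.33


def _logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


@dataclass
class VitalRateTable:
    """A rate on an age x year grid with variances and provenance flags."""

    rate: str
    ages: np.ndarray
    years: np.ndarray
    values: np.ndarray      # (n_ages, n_years), probabilities
    variances: np.ndarray   # matching grid, >= 0
    provenance: np.ndarray  # matching grid of {"estimated", "imputed"}

    def __post_init__(self):
        self.ages = np.asarray(self.ages)
        self.years = np.asarray(self.years)
        shape = (len(self.ages), len(self.years))
        for name in ("values", "variances", "provenance"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
            setattr(self, name, arr)
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("values must lie in [0, 1]")
        if np.any(self.variances < 0):
            raise ValueError("variances must be >= 0")

    def cell(self, age, year) -> tuple[float, float]:
        i = np.flatnonzero(self.ages == age)
        j = np.flatnonzero(self.years == year)
        if len(i) == 0 or len(j) == 0:
            raise KeyError(f"({self.rate}, age={age}, year={year}) not in table")
        return float(self.values[i[0], j[0]]), float(self.variances[i[0], j[0]])

    def has(self, age, year) -> bool:
        return age in self.ages and year in self.years

    def set_imputed(self, year, values, variances) -> None:
        """Write a whole imputed year column; refuses to overwrite
        estimated cells."""
        j = np.flatnonzero(self.years == year)
        if len(j) == 0:
            raise KeyError(f"year {year} not in table")
        if np.any(self.provenance[:, j[0]] == "estimated"):
            raise ValueError(f"year {year} already holds estimated cells")
        self.values[:, j[0]] = values
        self.variances[:, j[0]] = variances
        self.provenance[:, j[0]] = "imputed"

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.ages):
            for j, y in enumerate(self.years):
                rows.append(
                    (self.rate, a, y, self.values[i, j], self.variances[i, j],
                     self.provenance[i, j])
                )
        return pd.DataFrame(
            rows, columns=["rate", "age", "year", "value", "variance", "provenance"]
        )


def abs_table(fit, ages, years, age_col: str = "age", year_col: str = "season") -> VitalRateTable:
    """Annual Breeding Success per (age, year) cell from a mixed-model fit
    with age and year factors.

    Predictions are inverse-logit values at random-effect mode zero;
    variances follow from Var(p) ~= [p(1-p)]^2 Var(eta) (delta method).
    Requesting a level outside the fitted factors raises.
    """
    ages = np.asarray(ages)
    years = np.asarray(years)
    grid = pd.DataFrame(
        {age_col: np.repeat(ages, len(years)), year_col: np.tile(years, len(ages))}
    )
    m, v = fit.predict(grid)  # raises on unseen factor levels
    values = m.reshape(len(ages), len(years))
    variances = v.reshape(len(ages), len(years))
    prov = np.full(values.shape, "estimated", dtype=object)
    return VitalRateTable("ABS", ages, years, values, variances, prov)


def logit_logit_regression(
    y_prob: pd.Series, x_prob: pd.Series
) -> sm.regression.linear_model.RegressionResultsWrapper:
    """OLS of logit(y) on logit(x) over the common index (shared utility
    for the imputation and trend diagnostics)."""
    common = y_prob.index.intersection(x_prob.index)
    if len(common) < 3:
        raise ValueError("need at least 3 complete years")
    ylog = _logit(y_prob.loc[common].to_numpy())
    xlog = _logit(x_prob.loc[common].to_numpy())
    X = sm.add_constant(xlog)
    if np.linalg.matrix_rank(X) < 2:
        raise ValueError("singular design: predictor has no variation")
    res = sm.OLS(ylog, X).fit()
    res.years_used = list(common)
    return res


def impute_abs_from_survival(
    abs_by_year: pd.Series, surv_by_year: pd.Series, target_year
) -> dict:
    """Impute ABS for a year from annual adult survival.

    Both series are probabilities indexed by year (age standardized at 10
    upstream).  Fits logit(ABS) ~ logit(survival) by OLS over the years
    where both are known, predicts at the target year's survival, and
    back-transforms.  Returns value, its delta-method SE/variance, and the
    regression summary (slope, slope SE, adjusted R^2, p-value).
    """
    if target_year not in surv_by_year.index or pd.isna(surv_by_year.get(target_year)):
        raise ValueError(f"survival for target year {target_year!r} is missing")
    known = abs_by_year.drop(index=[target_year], errors="ignore").dropna()
    res = logit_logit_regression(known, surv_by_year)
    xnew = np.array([[1.0, _logit(surv_by_year.loc[target_year])]])
    pred = res.get_prediction(xnew)
    eta = float(pred.predicted_mean[0])
    var_eta = float(pred.var_pred_mean[0])
    p = float(_expit(eta))
    var_p = (p * (1 - p)) ** 2 * var_eta
    return {
        "year": target_year,
        "value": p,
        "se": float(np.sqrt(var_p)),
        "variance": var_p,
        "logit_value": eta,
        "slope": float(res.params[1]),
        "slope_se": float(res.bse[1]),
        "adj_r2": float(res.rsquared_adj),
        "p_value": float(res.pvalues[1]),
        "n_years": int(res.nobs),
    }


def impute_juv_survival(
    juv_by_year: pd.Series,
    abs_by_year: pd.Series,
    target_years,
    exclusions=(),
    leverage_factor: float = 3.0,
) -> dict:
    """Impute juvenile survival for recent cohorts from ABS.

    ``exclusions`` lists years removed before fitting (a-priori unusual
    seasons).  The fit is logit(juvenile survival) ~ logit(ABS) by OLS;
    leverage (hat values) is reported for every point and years whose
    leverage exceeds ``leverage_factor`` x mean are flagged, mirroring
    post-hoc model checking.  Returns per-target predictions with
    delta-method variances and the regression summary.
    """
    juv = juv_by_year.drop(index=list(exclusions), errors="ignore").dropna()
    if juv.empty:
        raise ValueError("all years excluded; nothing to fit")
    res = logit_logit_regression(juv, abs_by_year)
    hat = res.get_influence().hat_matrix_diag
    years_used = res.years_used
    lev = pd.DataFrame(
        {"year": years_used, "leverage": hat,
         "flagged": hat > leverage_factor * hat.mean()}
    )
    preds = {}
    for ty in np.atleast_1d(target_years):
        if ty not in abs_by_year.index or pd.isna(abs_by_year.get(ty)):
            raise ValueError(f"ABS for target year {ty!r} is missing")
        xnew = np.array([[1.0, _logit(abs_by_year.loc[ty])]])
        pr = res.get_prediction(xnew)
        eta = float(pr.predicted_mean[0])
        var_eta = float(pr.var_pred_mean[0])
        p = float(_expit(eta))
        preds[ty] = {
            "value": p,
            "variance": (p * (1 - p)) ** 2 * var_eta,
            "se": float(np.sqrt((p * (1 - p)) ** 2 * var_eta)),
        }
    return {
        "predictions": preds,
        "slope": float(res.params[1]),
        "slope_se": float(res.bse[1]),
        "adj_r2": float(res.rsquared_adj),
        "p_value": float(res.pvalues[1]),
        "n_years": int(res.nobs),
        "leverage": lev,
    }


def female_juv_survival(
    combined: float,
    male_advantage: float = MALE_JUV_ADVANTAGE,
    convention: str = "male_ratio",
    variance: float | None = None,
):
    """Female juvenile survival from the mixed-sex estimate.

    With a 50/50 sex ratio at independence and male survival equal to
    ``male_advantage`` x female survival, the combined rate is
    ``(s_f + s_m)/2``, so ``s_f = 2 c / (1 + r)`` (convention
    ``"male_ratio"``, the default).  The alternative reading of a "33%
    higher" male survival, ``s_f = c / r`` with ``s_m = c`` scaled
    (convention ``"female_scaled"``), is available for sensitivity work.
    Raises if the implied male survival reaches 1.  When ``variance`` is
    given, the matching delta-method variance of the female rate is
    returned as well.
    """
    combined = float(combined)
    if not 0 < combined < 1:
        raise ValueError("combined survival must lie in (0, 1)")
    if convention == "male_ratio":
        female = 2.0 * combined / (1.0 + male_advantage)
        scale = 2.0 / (1.0 + male_advantage)
    elif convention == "female_scaled":
        female = combined / male_advantage
        scale = 1.0 / male_advantage
    else:
        raise ValueError(f"unknown convention {convention!r}")
    male = male_advantage * female
    if male >= 1.0:
        raise ValueError(
            f"implied male survival {male:.3f} >= 1 (combined={combined}, "
            f"advantage={male_advantage})"
        )
    if variance is None:
        return female
    return female, scale**2 * float(variance)
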