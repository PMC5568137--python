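"""Annual 22-class projection matrices and population growth rates.

Matrices follow a single-sex, pre-breeding-census, birth-pulse Leslie
structure with 22 age classes (the terminal class pools ages 22+ with a
survival self-loop).  Fertility for age class i is

    F_i = (ABS_i / 2) * s_juv_female,i        for i = 3..21,

the mean number of daughters per female of class i surviving to the next
census: annual breeding success halved for the 50/50 offspring sex ratio,
times female first-year (independence-to-recruitment) survival.  F for
classes 1, 2 and 22 is zero.  Mortality between independence and
recruitment is folded into fertility, so survival coefficients P_1..P_3
are one and P_i for i >= 4 comes from the mark-recapture estimates.

Deterministic lambda is the dominant eigenvalue of a matrix; its CI comes
from 1000 beta-resampled matrices (component rates sampled independently
by moments matching, the lambda distribution shifted so its mean equals
the exact asymptotic lambda).  Stochastic lambda is the long-run average
growth rate over i.i.d. draws from a pool of annual matrices across
10,000 year-long intervals, with an increment-variance 95% CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AnnualMatrix",
    "LambdaEstimate",
    "build_annual_matrix",
    "deterministic_lambda",
    "mc_lambda_ci",
    "stochastic_lambda",
    "lag1_autocorrelation",
    "required_fertility_increase",
    "N_CLASSES",
    "MC_MATRICES",
    "STOCHASTIC_HORIZON",
    "BURN_IN",
]

#: number of age classes; class 22 pools all ages >= 22
N_CLASSES = 22
#: matrices resampled for the deterministic-lambda CI
MC_MATRICES = 1000
#: year-long intervals simulated for stochastic lambda
STOCHASTIC_HORIZON = 10_000
#: steps discarded before averaging log increments
BURN_IN = 1000
#: fertile age classes (F elsewhere is structurally zero)
FERTILE_CLASSES = tuple(range(3, 22))


@dataclass
class LambdaEstimate:
    """A population growth rate with its 95% CI and provenance."""

    value: float
    ci_low: float
    ci_high: float
    method: str  # "deterministic" | "stochastic"
    n_sim: int = 0
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.ci_low <= self.value <= self.ci_high):
            raise ValueError(
                f"CI [{self.ci_low}, {self.ci_high}] does not bracket {self.value}"
            )
        if self.value <= 0:
            raise ValueError("lambda must be positive")


@dataclass
class AnnualMatrix:
    """One year's projection matrix plus per-entry moments for resampling.

    ``F``/``P`` are length-22 vectors: F is the top row; P[i-1] is the
    survival of class i into class i+1 for i = 1..21 and P[21] is the
    terminal self-loop.  ``components`` stores the mean and variance of
    each underlying rate (ABS, female juvenile survival, adult survival)
    per class so uncertainty can be resampled at the component level.
    """

    year: object
    F: np.ndarray
    P: np.ndarray
    components: dict = field(default_factory=dict)

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if self.F.shape != (N_CLASSES,) or self.P.shape != (N_CLASSES,):
            raise ValueError(f"F and P must have length {N_CLASSES}")
        if self.F[0] != 0 or self.F[1] != 0 or self.F[N_CLASSES - 1] != 0:
            raise ValueError("F for classes 1, 2 and 22 must be zero")
        if np.any(self.F < 0):
            raise ValueError("fertility must be nonnegative")
        if np.any((self.P < 0) | (self.P > 1)):
            raise ValueError("survival coefficients must lie in [0, 1]")

    @property
    def A(self) -> np.ndarray:
        A = np.zeros((N_CLASSES, N_CLASSES))
        A[0, :] = self.F
        for i in range(1, N_CLASSES):
            A[i, i - 1] = self.P[i - 1]
        A[N_CLASSES - 1, N_CLASSES - 1] = self.P[N_CLASSES - 1]
        return A


def build_annual_matrix(
    abs_table,
    juv_table,
    surv_table,
    year,
    fertility_ages=FERTILE_CLASSES,
    juv_is_female: bool = False,
    male_advantage: float | None = None,
    sex_convention: str = "male_ratio",
) -> AnnualMatrix:
    """Assemble one annual matrix from the three vital-rate tables.

    ``fertility_ages`` lists the classes given nonzero fertility; classes
    1, 2 and 22 are always zero and listed ages must have cells in both
    the ABS and juvenile-survival tables for ``year`` (a missing cell
    raises, naming rate, age and year).  ``juv_table`` holds the
    mixed-sex rate unless ``juv_is_female``; the female rate and its
    variance then come from the 50/50 sex-ratio adjustment.  Variances of
    the fertility products follow the delta method,
    Var(XY) ~= Y^2 Var(X) + X^2 Var(Y).
    """
    from .vital_rates import MALE_JUV_ADVANTAGE, female_juv_survival

    if male_advantage is None:
        male_advantage = MALE_JUV_ADVANTAGE
    F = np.zeros(N_CLASSES)
    abs_m = np.zeros(N_CLASSES)
    abs_v = np.zeros(N_CLASSES)
    fjuv_m = np.zeros(N_CLASSES)
    fjuv_v = np.zeros(N_CLASSES)
    F_var = np.zeros(N_CLASSES)
    for age in fertility_ages:
        if age in (1, 2, N_CLASSES):
            continue
        try:
            a, va = abs_table.cell(age, year)
        except KeyError:
            raise KeyError(f"missing cell (ABS, age={age}, year={year})") from None
        try:
            jm, jv = juv_table.cell(age, year)
        except KeyError:
            raise KeyError(
                f"missing cell (juv_survival, age={age}, year={year})"
            ) from None
        if juv_is_female:
            f, vf = jm, jv
        elif jm <= 0.0:
            # a collapsed cohort (no recruits at all) contributes no fertility
            f, vf = 0.0, jv
        else:
            f, vf = female_juv_survival(
                jm, male_advantage, convention=sex_convention, variance=jv
            )
        i = age - 1
        abs_m[i], abs_v[i] = a, va
        fjuv_m[i], fjuv_v[i] = f, vf
        half_a = a / 2.0
        F[i] = half_a * f
        F_var[i] = f**2 * (va / 4.0) + half_a**2 * vf

    P = np.ones(N_CLASSES)
    P_var = np.zeros(N_CLASSES)
    surv_m = np.ones(N_CLASSES)
    surv_v = np.zeros(N_CLASSES)
    for age in range(4, N_CLASSES + 1):
        try:
            s, vs = surv_table.cell(age, year)
        except KeyError:
            raise KeyError(
                f"missing cell (adult_survival, age={age}, year={year})"
            ) from None
        P[age - 1] = s
        P_var[age - 1] = vs
        surv_m[age - 1], surv_v[age - 1] = s, vs

    return AnnualMatrix(
        year=year,
        F=F,
        P=P,
        components={
            "abs_mean": abs_m, "abs_var": abs_v,
            "fjuv_mean": fjuv_m, "fjuv_var": fjuv_v,
            "surv_mean": surv_m, "surv_var": surv_v,
            "F_var": F_var, "P_var": P_var,
        },
    )


def deterministic_lambda(A: np.ndarray, tol: float = 1e-10) -> float:
    """Dominant eigenvalue (asymptotic annual growth factor) of a
    nonnegative projection matrix."""
    A = np.asarray(A, dtype=float)
    if np.all(A == 0):
        raise ValueError("zero matrix has no dominant eigenvalue")
    if np.any(A < 0):
        raise ValueError("projection matrix must be nonnegative")
    eig = np.linalg.eigvals(A)
    lam = float(np.max(np.abs(eig)))
    # Perron root of a nonnegative matrix equals the spectral radius and is
    # attained by a real eigenvalue; |.| removes the tiny imaginary noise
    return lam


def _beta_draws(rng, m, v, size):
    """Moment-matched beta draws; degenerate at m when v = 0, variance
    clipped just below the feasible bound when necessary."""
    m = float(m)
    v = float(v)
    if v <= 0:
        return np.full(size, m)
    bound = m * (1 - m)
    if v >= bound:
        warnings.warn(
            f"variance {v:.3g} >= m(1-m) = {bound:.3g}; clipped to 0.99*bound"
        )
        v = 0.99 * bound
    t = bound / v - 1.0
    return rng.beta(m * t, (1 - m) * t, size=size)


def mc_lambda_ci(
    matrix: AnnualMatrix, n: int = MC_MATRICES, seed: int | None = None
) -> LambdaEstimate:
    """Monte-Carlo 95% CI for one matrix's deterministic lambda.

    Each underlying rate (ABS, female juvenile survival, adult survival)
    is sampled from a beta distribution with the estimated mean and
    variance; fertilities are recombined per the F formula; the n lambda
    values are shifted additively so their mean equals the exact
    asymptotic lambda (bias correction) and the CI is the shifted
    2.5/97.5 percentile pair.
    """
    rng = np.random.default_rng(seed)
    comp = matrix.components
    if not comp:
        raise ValueError("matrix carries no component moments for resampling")
    lam0 = deterministic_lambda(matrix.A)
    lams = np.empty(n)
    fertile = np.flatnonzero(matrix.F > 0)
    adult = np.arange(3, N_CLASSES)
    abs_draws = {i: _beta_draws(rng, comp["abs_mean"][i], comp["abs_var"][i], n) for i in fertile}
    fjuv_draws = {i: _beta_draws(rng, comp["fjuv_mean"][i], comp["fjuv_var"][i], n) for i in fertile}
    surv_draws = {i: _beta_draws(rng, comp["surv_mean"][i], comp["surv_var"][i], n) for i in adult}
    for r in range(n):
        F = np.zeros(N_CLASSES)
        for i in fertile:
            F[i] = abs_draws[i][r] / 2.0 * fjuv_draws[i][r]
        P = matrix.P.copy()
        for i in adult:
            P[i] = surv_draws[i][r]
        am = AnnualMatrix(year=matrix.year, F=F, P=P)
        lams[r] = deterministic_lambda(am.A)
    shifted = lams + (lam0 - lams.mean())
    lo, hi = np.percentile(shifted, [2.5, 97.5])
    return LambdaEstimate(
        value=lam0,
        ci_low=float(min(lo, lam0)),
        ci_high=float(max(hi, lam0)),
        method="deterministic",
        n_sim=n,
        seed=seed,
        extra={"draws": shifted},
    )


def stochastic_lambda(
    matrices,
    horizon: int = STOCHASTIC_HORIZON,
    seed: int | None = None,
    burn_in: int = BURN_IN,
) -> LambdaEstimate:
    """Stochastic growth rate of an i.i.d. environment.

    Annual matrices are drawn uniformly with replacement; the population
    vector is renormalized (sum norm) each step and
    ``log lambda_s = mean(log ||n_{t+1}|| / ||n_t||)`` over ``horizon``
    post-burn-in steps.  The 95% CI is
    ``exp(log lambda_s +/- 1.96 sd(log increments)/sqrt(horizon))``.
    """
    mats = [m.A if isinstance(m, AnnualMatrix) else np.asarray(m, dtype=float) for m in matrices]
    if not mats:
        raise ValueError("empty matrix pool")
    for A in mats:
        if deterministic_lambda(A) <= 1e-12:
            raise ValueError("matrix with zero dominant eigenvalue in pool")
    rng = np.random.default_rng(seed)
    k = mats[0].shape[0]
    nvec = np.full(k, 1.0 / k)
    idx = rng.integers(0, len(mats), size=burn_in + horizon)
    incs = np.empty(horizon)
    for t, j in enumerate(idx):
        nvec = mats[j] @ nvec
        g = nvec.sum()
        if g <= 0:
            raise ValueError("population vector collapsed to zero")
        if t >= burn_in:
            incs[t - burn_in] = np.log(g)
        nvec /= g
    mean_log = float(incs.mean())
    se = float(incs.std(ddof=1) / np.sqrt(horizon))
    return LambdaEstimate(
        value=float(np.exp(mean_log)),
        ci_low=float(np.exp(mean_log - 1.96 * se)),
        ci_high=float(np.exp(mean_log + 1.96 * se)),
        method="stochastic",
        n_sim=horizon,
        seed=seed,
        extra={"se_log": se},
    )


def lag1_autocorrelation(lambdas) -> dict:
    """Lag-1 Pearson autocorrelation of a growth-rate series.

    Returns r, df = n_pairs - 2 and the two-sided t-based P value; a
    constant series has undefined r and is reported as such.
    """
    x = np.asarray(lambdas, dtype=float)
    if len(x) < 4:
        raise ValueError("series length must be >= 4")
    a, b = x[:-1], x[1:]
    if np.std(a) == 0 or np.std(b) == 0:
        return {"r": np.nan, "df": len(a) - 2, "p_value": np.nan,
                "note": "undefined for constant series"}
    r = float(np.corrcoef(a, b)[0, 1])
    df = len(a) - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        tstat = r * np.sqrt(df / (1.0 - r**2))
        p = float(2 * stats.t.sf(abs(tstat), df))
    return {"r": r, "df": df, "p_value": p}


def _scaled_pool(matrices: list[AnnualMatrix], c: float) -> list[np.ndarray]:
    """Scale the ABS component of every fertility by c, capping the
    implied breeding-success probability at 1."""
    out = []
    for m in matrices:
        comp = m.components
        F = np.zeros(N_CLASSES)
        for i in np.flatnonzero(m.F > 0):
            a = min(c * comp["abs_mean"][i], 1.0)
            F[i] = a / 2.0 * comp["fjuv_mean"][i]
        am = AnnualMatrix(year=m.year, F=F, P=m.P.copy())
        out.append(am.A)
    return out


def required_fertility_increase(
    matrices,
    target: float = 1.0,
    seed: int | None = None,
    horizon: int = STOCHASTIC_HORIZON,
    tol: float = 1e-4,
) -> dict:
    """Proportional increase in the breeding-success component of all
    fertilities needed for the pool's stochastic lambda to reach ``target``.

    Bisection on the multiplier c (probabilities capped at 1), with
    common random numbers across evaluations so lambda(c) is monotone in
    c until the caps bind.  Returns ``increase`` (c - 1), the achieved
    lambda, and a ``cap_limited`` flag when the target is unreachable.
    """
    mats = list(matrices)
    if not all(isinstance(m, AnnualMatrix) for m in mats):
        raise TypeError("required_fertility_increase needs AnnualMatrix inputs")

    def lam(c):
        return stochastic_lambda(
            _scaled_pool(mats, c), horizon=horizon, seed=seed
        ).value

    lam1 = lam(1.0)
    if lam1 >= target:
        return {"increase": 0.0, "lambda_achieved": lam1, "cap_limited": False}
    # expand the bracket; caps make lambda(c) eventually flat
    hi = 2.0
    lam_hi = lam(hi)
    while lam_hi < target and hi < 64:
        prev = lam_hi
        hi *= 2.0
        lam_hi = lam(hi)
        if lam_hi <= prev + 1e-12:  # caps fully bound
            return {
                "increase": hi - 1.0,
                "lambda_achieved": lam_hi,
                "cap_limited": True,
            }
    if lam_hi < target:
        return {"increase": hi - 1.0, "lambda_achieved": lam_hi, "cap_limited": True}
    lo = 1.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        lm = lam(mid)
        if abs(lm - target) <= tol and (hi - lo) < 1e-4:
            lo = hi = mid
            break
        if lm < target:
            lo = mid
        else:
            hi = mid
    c = 0.5 * (lo + hi)
    return {"increase": c - 1.0, "lambda_achieved": lam(c), "cap_limited": False}
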