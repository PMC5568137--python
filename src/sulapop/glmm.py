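"""Binomial logit-link mixed models with one or two crossed Gaussian
random intercepts, fitted by maximum likelihood.

With a single grouping factor the marginal likelihood

    L = prod_g  ∫ prod_i Bern(y_gi | logit^-1(x_gi' beta + u_g))  phi(u_g; 0, sigma^2) du_g

is approximated by adaptive Gauss-Hermite quadrature (AGQ) centered at
each group's conditional mode; with ``n_nodes = 1`` AGQ coincides with
the Laplace approximation.  Crossed random intercepts (e.g. individual
identity and year) are handled by a joint Laplace approximation over the
stacked intercept vector, since AGQ does not extend to crossed designs.

The optimizer works on ``(beta, log sigma)`` with a quasi-Newton method;
coefficient covariance comes from the inverse observed information
(finite-difference Hessian of the marginal log-likelihood).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.special import logsumexp, roots_hermitenorm

from .design import DesignInfo, apply_design, build_design
from .model_selection import aicc as _aicc

__all__ = [
    "BinomialMixedModel",
    "MixedFitResults",
    "bootstrap_ci",
    "ybd_prepare",
    "SEPARATION_THRESHOLD",
    "DEFAULT_NODES",
]

#: |beta| beyond this (logit scale) is treated as quasi-separation
SEPARATION_THRESHOLD = 15.0
#: default quadrature node count for AGQ
DEFAULT_NODES = 15
#: floor on log(sigma) during optimisation (sigma ~ 3e-4 is numerically zero)
_LOG_SIGMA_MIN = -8.0
_LOG_SIGMA_MAX = 3.0


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Elementwise Bernoulli log-likelihood on the logit scale, stable."""
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError("non-finite linear predictor")
    return y * eta - np.logaddexp(0.0, eta)


def _expit(eta):
    out = np.empty_like(eta, dtype=float)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _irls_glm(y: np.ndarray, X: np.ndarray, maxiter: int = 50) -> np.ndarray:
    """Plain logistic GLM by iteratively reweighted least squares.

    Used for starting values and for the sigma = 0 degenerate fit.
    """
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = X @ beta
        p = _expit(eta)
        w = np.clip(p * (1 - p), 1e-10, None)
        z = eta + (y - p) / w
        wX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ wX, wX.T @ z)
        if np.max(np.abs(beta_new - beta)) < 1e-12:
            beta = beta_new
            break
        beta = beta_new
        if np.max(np.abs(beta)) > 2 * SEPARATION_THRESHOLD:
            break
    return beta


class BinomialMixedModel:
    """Bernoulli GLMM with logit link and Gaussian random intercepts.

    Parameters
    ----------
    endog
        0/1 response vector.
    exog
        Fixed-effects design matrix (including an intercept column).
    groups
        Mapping of grouping-factor name to integer codes (0..q-1), one
        entry for a single random intercept, two for crossed intercepts.
    method
        ``"agq"`` (single grouping factor only) or ``"laplace"``.  The
        default picks AGQ for one factor and Laplace for two.
    n_nodes
        Quadrature node count for AGQ; ``n_nodes = 1`` is Laplace.
    """

    def __init__(
        self,
        endog,
        exog,
        groups: dict[str, np.ndarray],
        method: str | None = None,
        n_nodes: int = DEFAULT_NODES,
        design_info: DesignInfo | None = None,
        exog_names: list[str] | None = None,
    ):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.endog.ndim != 1 or self.exog.ndim != 2:
            raise ValueError("endog must be 1-D, exog 2-D")
        uniq = np.unique(self.endog)
        if not np.all(np.isin(uniq, [0.0, 1.0])) or len(uniq) < 2:
            raise ValueError("response must contain both 0s and 1s")
        if not groups or len(groups) > 2:
            raise ValueError("one or two grouping factors required")
        self.group_names = list(groups)
        self.group_codes = {}
        self.group_sizes = {}
        for name, codes in groups.items():
            codes = np.asarray(codes)
            _, inv = np.unique(codes, return_inverse=True)
            self.group_codes[name] = inv
            self.group_sizes[name] = int(inv.max()) + 1
        if method is None:
            method = "agq" if len(groups) == 1 else "laplace"
        if method == "agq" and len(groups) != 1:
            raise ValueError("AGQ is only available with exactly one random group")
        if n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        self.method = method
        self.n_nodes = int(n_nodes)
        self.design_info = design_info
        self.exog_names = exog_names or [f"x{j}" for j in range(self.exog.shape[1])]
        self._check_rank()

    # ------------------------------------------------------------------ #
    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        fixed_terms: list[str],
        random_groups: list[str],
        method: str | None = None,
        n_nodes: int = DEFAULT_NODES,
    ) -> "BinomialMixedModel":
        """Construct the model from a tidy DataFrame and term strings.

        Continuous covariates are centered; factors use treatment coding
        with the first (sorted) level as reference.  Marginality is
        enforced: an interaction or quadratic requires its parents in
        ``fixed_terms``.
        """
        tset = set(fixed_terms)
        for t in fixed_terms:
            required = set()
            if ":" in t:
                required |= set(t.split(":"))
            elif t.endswith("^2"):
                required.add(t[:-2])
            missing = required - tset
            if missing:
                raise ValueError(
                    f"term {t!r} requires {sorted(missing)} (marginality)"
                )
        X, info = build_design(data, fixed_terms)
        groups = {g: data[g].to_numpy() for g in random_groups}
        return cls(
            data[response].to_numpy(dtype=float),
            X,
            groups,
            method=method,
            n_nodes=n_nodes,
            design_info=info,
            exog_names=info.column_names,
        )

    # ------------------------------------------------------------------ #
    def _check_rank(self) -> None:
        q, r, piv = linalg.qr(self.exog, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(self.exog.shape) * np.finfo(float).eps
        rank = int((diag > tol).sum())
        if rank < self.exog.shape[1]:
            aliased = [self.exog_names[j] for j in piv[rank:]]
            raise ValueError(f"design matrix rank deficient; aliased columns: {aliased}")

    @property
    def n_params(self) -> int:
        return self.exog.shape[1] + len(self.group_names)

    # --------------------------- AGQ ---------------------------------- #
    def _group_modes(self, eta: np.ndarray, sigma: float, codes: np.ndarray, q: int):
        """Conditional modes (and curvatures) of the scaled intercepts z_g."""
        y = self.endog
        z = np.zeros(q)
        for _ in range(100):
            p = _expit(eta + sigma * z[codes])
            grad = sigma * np.bincount(codes, weights=y - p, minlength=q) - z
            w = np.bincount(codes, weights=p * (1 - p), minlength=q)
            curv = sigma**2 * w + 1.0
            step = grad / curv
            np.clip(step, -4.0, 4.0, out=step)
            z += step
            if np.max(np.abs(step)) < 1e-10:
                break
        p = _expit(eta + sigma * z[codes])
        curv = sigma**2 * np.bincount(codes, weights=p * (1 - p), minlength=q) + 1.0
        return z, curv

    def loglik_agq(self, beta: np.ndarray, log_sigma: float, n_nodes: int | None = None) -> float:
        """Marginal log-likelihood by adaptive Gauss-Hermite quadrature.

        The integral over each group's intercept is re-centered at the
        conditional mode and re-scaled by the conditional curvature, so
        few nodes suffice even for large groups.
        """
        if len(self.group_names) != 1:
            raise ValueError("AGQ requires exactly one random group")
        K = self.n_nodes if n_nodes is None else int(n_nodes)
        if K < 1:
            raise ValueError("n_nodes must be >= 1")
        sigma = float(np.exp(log_sigma))
        codes = self.group_codes[self.group_names[0]]
        q = self.group_sizes[self.group_names[0]]
        eta = self.exog @ beta
        if not np.all(np.isfinite(eta)):
            raise FloatingPointError("non-finite linear predictor")
        zhat, curv = self._group_modes(eta, sigma, codes, q)
        shat = 1.0 / np.sqrt(curv)
        t, w = roots_hermitenorm(K)
        znodes = zhat[:, None] + shat[:, None] * t[None, :]  # (q, K)
        per_node = np.empty((q, K))
        y = self.endog
        for k in range(K):
            etak = eta + sigma * znodes[codes, k]
            ll = _bernoulli_loglik(y, etak)
            per_node[:, k] = np.bincount(codes, weights=ll, minlength=q)
        body = per_node - 0.5 * znodes**2 + (np.log(w) + 0.5 * t**2)[None, :]
        logL = np.log(shat) - 0.5 * np.log(2 * np.pi) + logsumexp(body, axis=1)
        return float(logL.sum())

    # ------------------------ crossed Laplace -------------------------- #
    def _loglik_laplace(self, beta: np.ndarray, sigmas: dict[str, float]) -> float:
        """Joint Laplace approximation over the stacked intercept vector."""
        active = [g for g in self.group_names if sigmas[g] > 0]
        y = self.endog
        eta0 = self.exog @ beta
        if not np.all(np.isfinite(eta0)):
            raise FloatingPointError("non-finite linear predictor")
        if not active:
            return float(_bernoulli_loglik(y, eta0).sum())
        codes = [self.group_codes[g] for g in active]
        qs = [self.group_sizes[g] for g in active]
        sig = np.concatenate([np.full(q, sigmas[g]) for g, q in zip(active, qs)])
        offs = np.concatenate([[0], np.cumsum(qs)])[:-1]
        qtot = int(sum(qs))
        u = np.zeros(qtot)

        def add_u(e, u):
            for (c, o, q) in zip(codes, offs, qs):
                e = e + u[o : o + q][c]
            return e

        prec = 1.0 / sig**2
        for _ in range(100):
            eta = add_u(eta0, u)
            p = _expit(eta)
            r = y - p
            grad = np.concatenate(
                [np.bincount(c, weights=r, minlength=q) for c, q in zip(codes, qs)]
            ) - u * prec
            W = p * (1 - p)
            H = np.zeros((qtot, qtot))
            for a, (ca, oa, qa) in enumerate(zip(codes, offs, qs)):
                H[oa : oa + qa, oa : oa + qa] += np.diag(
                    np.bincount(ca, weights=W, minlength=qa)
                )
                for cb, ob, qb in list(zip(codes, offs, qs))[a + 1 :]:
                    block = np.zeros((qa, qb))
                    np.add.at(block, (ca, cb), W)
                    H[oa : oa + qa, ob : ob + qb] += block
                    H[ob : ob + qb, oa : oa + qa] += block.T
            H[np.diag_indices_from(H)] += prec
            cf = linalg.cho_factor(H, lower=True)
            step = linalg.cho_solve(cf, grad)
            np.clip(step, -4.0, 4.0, out=step)
            u += step
            if np.max(np.abs(step)) < 1e-9:
                break
        eta = add_u(eta0, u)
        pen = 0.5 * np.sum(u**2 * prec)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        ll = (
            _bernoulli_loglik(y, eta).sum()
            - pen
            - np.sum(np.log(sig))
            - 0.5 * logdet
        )
        return float(ll)

    # ------------------------------------------------------------------ #
    def loglik(self, params: np.ndarray) -> float:
        """Marginal log-likelihood at ``params = (beta, log sigma(s))``."""
        p = self.exog.shape[1]
        beta = params[:p]
        log_sigmas = params[p:]
        if self.method == "agq" and len(self.group_names) == 1:
            return self.loglik_agq(beta, float(log_sigmas[0]))
        sigmas = {
            g: float(np.exp(ls)) for g, ls in zip(self.group_names, log_sigmas)
        }
        return self._loglik_laplace(beta, sigmas)

    def fit(
        self,
        start: np.ndarray | None = None,
        fix_sigma: dict[str, float] | None = None,
        maxiter: int = 300,
    ) -> "MixedFitResults":
        """Maximize the marginal likelihood over ``(beta, log sigma)``.

        ``fix_sigma`` pins named random-intercept SDs (a value of 0 drops
        the integral for that factor; with every sigma fixed at 0 the fit
        is an exact logistic GLM).
        """
        p = self.exog.shape[1]
        fix_sigma = fix_sigma or {}
        free_groups = [g for g in self.group_names if g not in fix_sigma]

        if not free_groups and all(v == 0.0 for v in fix_sigma.values()):
            beta = _irls_glm(self.endog, self.exog)
            ll = float(_bernoulli_loglik(self.endog, self.exog @ beta).sum())
            out = self._make_results(beta, {g: 0.0 for g in self.group_names}, ll,
                                     vcov=self._glm_vcov(beta), converged=True,
                                     k=p)
            out.metadata["fix_sigma"] = dict(fix_sigma)
            return out

        beta0 = _irls_glm(self.endog, self.exog) if start is None else start[:p]
        x0 = np.concatenate([beta0, np.full(len(free_groups), np.log(0.5))])
        if start is not None and len(start) == p + len(free_groups):
            x0 = np.asarray(start, dtype=float)

        def unpack(x):
            beta = x[:p]
            log_s = {g: x[p + j] for j, g in enumerate(free_groups)}
            sig = {}
            for g in self.group_names:
                sig[g] = fix_sigma.get(g, None)
                if sig[g] is None:
                    sig[g] = float(np.exp(log_s[g]))
            return beta, sig

        def negll(x):
            beta, sig = unpack(x)
            if self.method == "agq" and len(self.group_names) == 1 and not fix_sigma:
                return -self.loglik_agq(beta, np.log(max(sig[self.group_names[0]], 1e-8)))
            return -self._loglik_laplace(beta, sig)

        bounds = [(None, None)] * p + [(_LOG_SIGMA_MIN, _LOG_SIGMA_MAX)] * len(free_groups)
        res = optimize.minimize(
            negll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
        )
        beta, sig = unpack(res.x)
        ll = -float(res.fun)
        vcov = _fd_hessian_inverse(negll, res.x)
        separated = [
            self.exog_names[j] for j in np.flatnonzero(
                np.abs(beta) > SEPARATION_THRESHOLD
            )
        ]
        converged = bool(res.success) and not separated
        k = p + len(free_groups)
        out = self._make_results(beta, sig, ll, vcov=vcov, converged=converged,
                                 k=k, opt_x=res.x)
        out.metadata["fix_sigma"] = dict(fix_sigma)
        if separated:
            out.metadata["separated_terms"] = separated
        return out

    def _glm_vcov(self, beta):
        eta = self.exog @ beta
        p_ = _expit(eta)
        w = p_ * (1 - p_)
        info = self.exog.T @ (self.exog * w[:, None])
        return np.linalg.pinv(info)

    def _make_results(self, beta, sigmas, loglik, vcov, converged, k, opt_x=None):
        return MixedFitResults(
            model=self,
            beta=np.asarray(beta, dtype=float),
            sigma=dict(sigmas),
            vcov=np.asarray(vcov, dtype=float),
            loglik=float(loglik),
            k=int(k),
            n=len(self.endog),
            converged=bool(converged),
            opt_x=opt_x,
        )


def _fd_hessian_inverse(f, x, rel_step: float = 1e-4):
    """Inverse of a central finite-difference Hessian; pinv fallback."""
    n = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        cov = linalg.inv(H)
        if not np.all(np.isfinite(cov)):
            raise linalg.LinAlgError
    except linalg.LinAlgError:
        cov = linalg.pinvh(H)
    # symmetrize; clip tiny negative diagonal from FD noise
    cov = 0.5 * (cov + cov.T)
    return cov


@dataclass
class MixedFitResults:
    """Maximum-likelihood fit of a :class:`BinomialMixedModel`.

    ``vcov`` covers the full parameter vector ``(beta, log sigma_free)``;
    :meth:`bse` and :meth:`conf_int` address the fixed effects.
    """

    model: BinomialMixedModel
    beta: np.ndarray
    sigma: dict[str, float]
    vcov: np.ndarray
    loglik: float
    k: int
    n: int
    converged: bool
    opt_x: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def aicc(self) -> float:
        return _aicc(self.loglik, self.k, self.n)

    @property
    def terms(self):
        di = self.model.design_info
        return tuple(di.terms) if di is not None else tuple(self.model.exog_names[1:])

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.beta, index=self.model.exog_names, name="coef")

    def bse(self) -> pd.Series:
        p = len(self.beta)
        se = np.sqrt(np.clip(np.diag(self.vcov)[:p], 0, None))
        return pd.Series(se, index=self.model.exog_names, name="se")

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        se = self.bse()
        return pd.DataFrame(
            {"lcl": self.beta - z * se, "ucl": self.beta + z * se},
            index=self.model.exog_names,
        )

    def predict(self, data: pd.DataFrame, linear: bool = False):
        """Predict at random-effect mode zero (population-median scale).

        Returns ``(mean, var)`` on the probability scale unless
        ``linear=True`` (then on the logit scale).  Variances come from
        the coefficient covariance via the delta method.
        """
        if self.model.design_info is None:
            raise ValueError("model was not built from a DataFrame; no design info")
        X = apply_design(data, self.model.design_info)
        eta = X @ self.beta
        p = len(self.beta)
        var_eta = np.einsum("ij,jk,ik->i", X, self.vcov[:p, :p], X)
        var_eta = np.clip(var_eta, 0, None)
        if linear:
            return eta, var_eta
        m = _expit(eta)
        return m, (m * (1 - m)) ** 2 * var_eta

    def summary(self) -> str:
        se = self.bse()
        ci = self.conf_int()
        lines = [
            "Binomial mixed model (logit link)",
            f"  method: {self.model.method}  groups: {self.model.group_names}",
            f"  n = {self.n}   k = {self.k}   logLik = {self.loglik:.3f}   AICc = {self.aicc:.3f}",
            f"  converged: {self.converged}",
            "",
            f"  {'term':<28}{'coef':>10}{'se':>10}{'lcl':>10}{'ucl':>10}",
        ]
        for name in self.model.exog_names:
            lines.append(
                f"  {name:<28}{self.params[name]:>10.4f}{se[name]:>10.4f}"
                f"{ci.loc[name, 'lcl']:>10.4f}{ci.loc[name, 'ucl']:>10.4f}"
            )
        for g, s in self.sigma.items():
            lines.append(f"  sigma({g}) = {s:.4f}")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "beta": dict(zip(self.model.exog_names, self.beta.tolist())),
                "sigma": self.sigma,
                "vcov": self.vcov.tolist(),
                "loglik": self.loglik,
                "k": self.k,
                "n": self.n,
                "aicc": self.aicc,
                "converged": self.converged,
                "method": self.model.method,
                "terms": list(self.terms),
            },
            indent=1,
        )


def bootstrap_ci(
    results: MixedFitResults,
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Parametric-bootstrap percentile intervals for the fixed effects.

    Each replicate draws fresh random intercepts from the fitted
    N(0, sigma^2) distributions and fresh Bernoulli responses from the
    fitted linear predictor, refits the model, and collects the
    coefficients.  Default 1,000 samples.
    """
    if not results.converged:
        raise ValueError("bootstrap requires a converged fit")
    model = results.model
    rng = np.random.default_rng(seed)
    p = model.exog.shape[1]
    eta_fix = model.exog @ results.beta
    draws = []
    n_fail = 0
    for _ in range(n_boot):
        eta = eta_fix.copy()
        for g in model.group_names:
            u = rng.normal(0.0, results.sigma[g], size=model.group_sizes[g])
            eta = eta + u[model.group_codes[g]]
        y = rng.binomial(1, _expit(eta)).astype(float)
        if y.min() == y.max():
            n_fail += 1
            continue
        bm = BinomialMixedModel(
            y, model.exog, {g: model.group_codes[g] for g in model.group_names},
            method=model.method, n_nodes=model.n_nodes,
            exog_names=model.exog_names,
        )
        try:
            r = bm.fit(start=results.opt_x,
                       fix_sigma=results.metadata.get("fix_sigma") or None)
        except Exception:
            n_fail += 1
            continue
        if not r.converged:
            n_fail += 1
            continue
        draws.append(r.beta)
    if n_fail > 0.05 * n_boot:
        warnings.warn(
            f"{n_fail}/{n_boot} bootstrap refits failed or did not converge; "
            f"effective n_boot = {len(draws)}"
        )
    arr = np.asarray(draws)
    lo = np.percentile(arr, 100 * alpha / 2, axis=0)
    hi = np.percentile(arr, 100 * (1 - alpha / 2), axis=0)
    out = pd.DataFrame({"lcl": lo, "ucl": hi}, index=model.exog_names[:p])
    out.attrs["n_boot_effective"] = len(draws)
    return out


def ybd_prepare(
    breeding: pd.DataFrame,
    min_age_at_death: int = 13,
    window: int = 5,
    data_end: int | None = None,
) -> pd.DataFrame:
    """Restrict breeding records to the final years before death (YBD proxy).

    Chronological age is unknown for birds banded as adults, so late-life
    performance is modelled against years before death.  A bird is
    declared dead in the first of two or more consecutive seasons with no
    record before the end of the study; only birds whose age at death was
    at least ``min_age_at_death`` qualify, and only their last ``window``
    seasons before death are retained, with a ``ybd`` column (1 = last
    season alive) and a centered copy ``ybd_c``.

    Birds still alive at the end of the data (death unknown) are excluded
    and counted in ``result.attrs['n_alive_excluded']``.
    """
    cols = list(breeding.columns) + ["ybd", "ybd_c"]
    if breeding.empty:
        out = pd.DataFrame(columns=cols)
        out.attrs.update(n_alive_excluded=0, n_young_excluded=0, n_birds_kept=0)
        return out
    if data_end is None:
        data_end = int(breeding["season"].max())
    kept = []
    n_alive = n_young = 0
    for _, grp in breeding.groupby("bird_id"):
        last = int(grp["season"].max())
        if last > data_end - 2:  # cannot yet observe two consecutive absences
            n_alive += 1
            continue
        death_season = last + 1
        age_at_death = int(grp.loc[grp["season"] == last, "age"].iloc[0]) + 1
        if age_at_death < min_age_at_death:
            n_young += 1
            continue
        sel = grp[grp["season"] >= death_season - window].copy()
        sel["ybd"] = death_season - sel["season"]
        kept.append(sel)
    if kept:
        out = pd.concat(kept, ignore_index=True)
        out["ybd_c"] = out["ybd"] - out["ybd"].mean()
    else:
        out = pd.DataFrame(columns=cols)
    out.attrs.update(
        n_alive_excluded=n_alive,
        n_young_excluded=n_young,
        n_birds_kept=out["bird_id"].nunique() if len(out) else 0,
    )
    return out
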