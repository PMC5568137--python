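"""End-to-end orchestration: data -> vital-rate fits -> matrices -> lambda.

The pipeline runs as file-backed stages sharing one run directory, so
each stage can also be run standalone on the previous stage's outputs
(the CLI exposes them as subcommands) and a monolithic run equals stage
composition.  One root seed is split deterministically per stage, so
re-running a stage never perturbs the others.

Stage order mirrors the demographic analysis: (1) simulate or ingest
individual records; (2) fit the Annual Breeding Success and juvenile
survival mixed models and the CJS survival model, with optional
imputation of unmonitored years; (3) assemble annual 22-class projection
matrices; (4) deterministic lambda per year with Monte-Carlo CIs,
phase-specific stochastic lambda, the between-year autocorrelation check
and the required-fertility-increase counterfactual; (5) environmental
covariate summaries.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cjs import CJSModel, CjsSpec, compare_models
from .glmm import BinomialMixedModel
from .matrix_model import (
    AnnualMatrix,
    MC_MATRICES,
    N_CLASSES,
    STOCHASTIC_HORIZON,
    build_annual_matrix,
    deterministic_lambda,
    lag1_autocorrelation,
    mc_lambda_ci,
    required_fertility_increase,
    stochastic_lambda,
)
from .environment import ThresholdConfig, seasonal_ssta_table, threshold_exceedance
from .simulate import ENTRY_AGE, MAX_AGE, SimConfig, pyify, simulate_population
from .vital_rates import VitalRateTable, abs_table, impute_juv_survival

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("data", "fit", "matrices", "lambda", "environment")

#: stage name -> child index of the root SeedSequence
_STAGE_SEED = {name: i for i, name in enumerate(STAGES)}


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run.

    Exactly one of ``simulate`` (a :class:`SimConfig`) or ``inputs``
    (paths to breeding/juveniles/encounters/sst/ssta CSVs) must be set;
    ``seed`` is mandatory and drives every stochastic stage.
    """

    seed: int
    simulate: SimConfig | None = None
    inputs: dict | None = None
    # model structure
    n_nodes: int = 7
    abs_age_terms: tuple[str, ...] = ("age", "age^2")
    juv_age_terms: tuple[str, ...] = ("mother_age", "mother_age^2")
    cjs_phi_time: str = "year"
    cjs_phi_age: bool = False
    cjs_p_time: str = "const"
    run_model_selection: bool = False
    # imputation
    impute_abs_year: int | None = None
    juv_unobserved_tail: int = 0
    juv_impute_exclusions: tuple[int, ...] = ()
    # matrices / lambda
    fertility_ages: tuple[int, ...] = tuple(range(ENTRY_AGE, N_CLASSES))
    n_mc: int = MC_MATRICES
    horizon: int = STOCHASTIC_HORIZON
    sardine_last_k: int = 5
    exclude_change_year: bool = True
    regime_change_season: int | None = None
    counterfactual_target: float = 1.0

    def __post_init__(self):
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of 'simulate' or 'inputs' must be set")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def change_season(self) -> int:
        if self.regime_change_season is not None:
            return self.regime_change_season
        if self.simulate is not None:
            return self.simulate.regime_change_season
        raise ValueError("regime_change_season must be set when loading external data")

    def stage_seed(self, stage: str) -> np.random.SeedSequence:
        return np.random.SeedSequence(self.seed).spawn(len(STAGES))[_STAGE_SEED[stage]]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(pyify(asdict(self)), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulate") is not None and isinstance(d["simulate"], dict):
            d["simulate"] = SimConfig.from_dict(d["simulate"])
        for key in ("abs_age_terms", "juv_age_terms", "fertility_ages",
                    "juv_impute_exclusions"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def demo_config(seed: int = 1, scale: float = 1.0) -> PipelineConfig:
    """The bundled demonstration configuration.

    A 22-season simulated study under the default generating parameters
    (regime change at season 5), analysed with quadratic age profiles, a
    year-additive CJS survival model and constant recapture.  ``scale``
    shrinks the cohort size for quick smoke runs.
    """
    sim = SimConfig(seed=seed, n_recruits_per_season=max(10, int(100 * scale)))
    return PipelineConfig(
        seed=seed,
        simulate=sim,
        run_model_selection=True,
        juv_impute_exclusions=tuple(sim.failure_years),
    )


# --------------------------------------------------------------------- #
# stage implementations

def _derive_seed(ss: np.random.SeedSequence, k: int = 0) -> int:
    return int(ss.spawn(k + 1)[k].generate_state(1)[0] % (2**31))


def stage_data(config: PipelineConfig, outdir: Path) -> None:
    """Simulate (or copy in) the individual-level data tables."""
    outdir.mkdir(parents=True, exist_ok=True)
    if config.simulate is not None:
        ds = simulate_population(config.simulate)
        ds.write(outdir)
    else:
        for name, path in config.inputs.items():
            df = pd.read_csv(path)
            df.to_csv(outdir / f"{name}.csv", index=False)


def _load(outdir: Path, name: str) -> pd.DataFrame:
    p = outdir / f"{name}.csv"
    if not p.exists():
        raise FileNotFoundError(f"stage input missing: {p}; run earlier stages first")
    # detection strings must keep leading zeros
    return pd.read_csv(p, dtype={"detections": str})


def _surv_table_from_cjs(res, ages, seasons) -> VitalRateTable:
    """Per-age, per-season adult survival from the fitted CJS model
    (known-age group), delta-method variances, confounded cells flagged."""
    phi = res.phi_table()
    design = res.model.dphi
    values = np.zeros((len(ages), len(seasons)))
    variances = np.zeros_like(values)
    prov = np.full(values.shape, "estimated", dtype=object)
    phi = phi[phi["group"] == 0]
    by_cell = {}
    for _, row in phi.iterrows():
        by_cell[(int(row["time"]), row["age"])] = (
            row["estimate"], row["se"] ** 2, row["usable"]
        )
    for j, s in enumerate(seasons):
        beyond = int(s) >= len(design.tcodes)  # final season has no interval
        interval = min(int(s), len(design.tcodes) - 1)
        tcode = int(design.tcodes[interval])
        for i, a in enumerate(ages):
            key_age = min(int(a), MAX_AGE) if design.use_age else None
            est, var, usable = by_cell[(tcode, key_age)]
            values[i, j] = est
            variances[i, j] = var
            if beyond:
                prov[i, j] = "extrapolated"
            elif not usable:
                prov[i, j] = "confounded"
    return VitalRateTable("adult_survival", ages, seasons, values, variances, prov)


def _predict_table(fit, rate, ages, seasons, age_col, season_col) -> VitalRateTable:
    grid = pd.DataFrame(
        {
            age_col: np.repeat(ages, len(seasons)),
            season_col: np.tile(seasons, len(ages)),
        }
    )
    m, v = fit.predict(grid)
    prov = np.full((len(ages), len(seasons)), "estimated", dtype=object)
    return VitalRateTable(
        rate, ages, seasons,
        m.reshape(len(ages), len(seasons)),
        v.reshape(len(ages), len(seasons)),
        prov,
    )


def stage_fit(config: PipelineConfig, outdir: Path) -> dict:
    """Fit the three vital-rate models and write the rate tables."""
    breeding = _load(outdir, "breeding")
    juveniles = _load(outdir, "juveniles")
    encounters = _load(outdir, "encounters")
    n_seasons = len(encounters["detections"].iloc[0])
    seasons = np.arange(n_seasons)
    ages = np.arange(ENTRY_AGE, MAX_AGE + 1)
    info: dict = {}

    # --- Annual Breeding Success ---------------------------------------
    abs_fit_data = breeding
    impute_year = config.impute_abs_year
    if impute_year is not None:
        abs_fit_data = breeding[breeding["season"] != impute_year]
    abs_terms = list(config.abs_age_terms) + ["C(season)"]
    abs_model = BinomialMixedModel.from_dataframe(
        abs_fit_data, "success", abs_terms, ["bird_id"], n_nodes=config.n_nodes
    )
    abs_fit = abs_model.fit()
    info["abs_fit"] = {"loglik": abs_fit.loglik, "aicc": abs_fit.aicc,
                       "sigma": abs_fit.sigma, "converged": abs_fit.converged}
    fit_seasons = np.array(sorted(abs_fit_data["season"].unique()))
    abs_tab = _predict_table(abs_fit, "ABS", ages, fit_seasons, "age", "season")
    if impute_year is not None:
        abs_tab = _impute_abs_year(config, outdir, abs_fit, abs_tab, ages,
                                   seasons, impute_year, info)

    # --- juvenile survival ---------------------------------------------
    juv_data = juveniles
    tail = config.juv_unobserved_tail
    observed_max = n_seasons - 1 - tail
    if tail > 0:
        juv_data = juveniles[juveniles["season"] <= observed_max]
    juv_terms = list(config.juv_age_terms) + ["C(season)"]
    juv_model = BinomialMixedModel.from_dataframe(
        juv_data, "recruited", juv_terms, ["mother_id"], n_nodes=config.n_nodes
    )
    juv_fit = juv_model.fit()
    info["juv_fit"] = {"loglik": juv_fit.loglik, "aicc": juv_fit.aicc,
                       "sigma": juv_fit.sigma, "converged": juv_fit.converged}
    juv_seasons = np.array(sorted(juv_data["season"].unique()))
    juv_tab = _predict_table(juv_fit, "juv_survival", ages, juv_seasons,
                             "mother_age", "season")
    if tail > 0:
        juv_tab = _impute_juv_tail(config, abs_tab, juv_tab, ages, seasons,
                                   observed_max, info)

    # --- adult survival (CJS) -------------------------------------------
    change = config.change_season
    spec = CjsSpec(
        phi_time=config.cjs_phi_time,
        phi_age=config.cjs_phi_age,
        phi_group=config.cjs_phi_age,
        p_time=config.cjs_p_time,
        period_breaks=(change, change + 1),
        period2_breaks=(max(change - 3, 1), change, change + 1),
    )
    cjs_model = CJSModel.from_dataframe(encounters, spec)
    cjs_fit = cjs_model.fit()
    info["cjs_fit"] = {"loglik": cjs_fit.loglik, "aicc": cjs_fit.aicc,
                       "k": cjs_fit.k, "converged": cjs_fit.converged}
    surv_tab = _surv_table_from_cjs(cjs_fit, ages, seasons)

    if config.run_model_selection:
        _cjs_model_selection(config, encounters, spec, cjs_fit, outdir, info)

    for tab, name in ((abs_tab, "abs"), (juv_tab, "juv_survival"),
                      (surv_tab, "adult_survival")):
        tidy = tab.to_tidy()
        tidy["value"] = tidy["value"].round(6)
        tidy.to_csv(outdir / f"vital_{name}.csv", index=False)
    (outdir / "fit_info.json").write_text(json.dumps(info, indent=1, default=str))
    (outdir / "abs_fit.json").write_text(abs_fit.to_json())
    (outdir / "juv_fit.json").write_text(juv_fit.to_json())
    return info


def _impute_abs_year(config, outdir, abs_fit, abs_tab, ages, seasons,
                     impute_year, info) -> VitalRateTable:
    """Impute a held-out season's ABS from annual survival (logit-logit
    OLS at age 10) and extend the table with the model's age profile."""
    from .vital_rates import impute_abs_from_survival

    encounters = _load(outdir, "encounters")
    change = config.change_season
    spec = CjsSpec(phi_time="year", p_time=config.cjs_p_time,
                   period_breaks=(change, change + 1))
    res = CJSModel.from_dataframe(encounters, spec).fit()
    phi = res.phi_table()
    phi = phi[(phi["group"] == 0) & phi["usable"]]
    surv_by_year = pd.Series(
        phi.set_index("time")["estimate"]
    )
    i10 = np.flatnonzero(abs_tab.ages == 10)[0]
    abs_by_year = pd.Series(abs_tab.values[i10, :], index=abs_tab.years)
    common = [y for y in abs_by_year.index if y in surv_by_year.index]
    imp = impute_abs_from_survival(
        abs_by_year.loc[common], surv_by_year, impute_year
    )
    info["abs_imputation"] = {k: v for k, v in imp.items() if k != "year"}
    # apply the fitted age profile around the imputed age-10 logit value
    eta10 = imp["logit_value"]
    grid = pd.DataFrame({"age": abs_tab.ages,
                         "season": np.full(len(abs_tab.ages), abs_tab.years[0])})
    eta_prof, _ = abs_fit.predict(grid, linear=True)
    prof = eta_prof - eta_prof[np.flatnonzero(abs_tab.ages == 10)[0]]
    vals = 1.0 / (1.0 + np.exp(-(eta10 + prof)))
    # prediction variance on the logit scale, re-transformed per age
    var_eta10 = imp["variance"] / (imp["value"] * (1 - imp["value"])) ** 2
    variances = (vals * (1 - vals)) ** 2 * var_eta10
    years = np.append(abs_tab.years, impute_year)
    order = np.argsort(years)
    values = np.column_stack([abs_tab.values, vals])[:, order]
    var_all = np.column_stack([abs_tab.variances, variances])[:, order]
    prov = np.column_stack(
        [abs_tab.provenance, np.full(len(abs_tab.ages), "imputed", dtype=object)]
    )[:, order]
    return VitalRateTable("ABS", abs_tab.ages, np.sort(years), values, var_all, prov)


def _impute_juv_tail(config, abs_tab, juv_tab, ages, seasons, observed_max,
                     info) -> VitalRateTable:
    """Impute juvenile survival for recent cohorts from ABS (age 10)."""
    i10 = np.flatnonzero(juv_tab.ages == 10)[0]
    juv_by_year = pd.Series(juv_tab.values[i10, :], index=juv_tab.years)
    a10 = np.flatnonzero(abs_tab.ages == 10)[0]
    abs_by_year = pd.Series(abs_tab.values[a10, :], index=abs_tab.years)
    targets = [s for s in seasons if s > observed_max and s in abs_by_year.index]
    imp = impute_juv_survival(
        juv_by_year, abs_by_year, targets,
        exclusions=config.juv_impute_exclusions,
    )
    info["juv_imputation"] = {
        "slope": imp["slope"], "slope_se": imp["slope_se"],
        "adj_r2": imp["adj_r2"], "p_value": imp["p_value"],
        "n_years": imp["n_years"],
        "high_leverage_years": imp["leverage"].loc[
            imp["leverage"]["flagged"], "year"].tolist(),
    }
    # age profile of the observed years, rescaled through the imputed level
    prof = juv_tab.values / np.clip(juv_tab.values[i10, :], 1e-12, None)
    mean_prof = prof.mean(axis=1)
    new_years = np.array(targets)
    vals = np.clip(np.outer(mean_prof, [imp["predictions"][t]["value"] for t in targets]), 0, 1)
    variances = np.outer(mean_prof**2,
                         [imp["predictions"][t]["variance"] for t in targets])
    years = np.concatenate([juv_tab.years, new_years])
    order = np.argsort(years)
    values = np.column_stack([juv_tab.values, vals])[:, order]
    var_all = np.column_stack([juv_tab.variances, variances])[:, order]
    prov = np.column_stack(
        [juv_tab.provenance,
         np.full((len(juv_tab.ages), len(new_years)), "imputed", dtype=object)]
    )[:, order]
    return VitalRateTable("juv_survival", juv_tab.ages, np.sort(years),
                          values, var_all, prov)


def _cjs_model_selection(config, encounters, general_spec, general_fit,
                         outdir, info) -> None:
    """Small time-structure model set for survival, with the Period-vs-
    constant likelihood-ratio test (df = 2 for the 3-level factor)."""
    change = config.change_season
    fits = {"phi(year)": general_fit} if config.cjs_phi_time == "year" else {}
    for name, phi_time in (("phi(period)", "period"),
                           ("phi(period2)", "period2"),
                           ("phi(const)", "const")):
        spec = CjsSpec(
            phi_time=phi_time, p_time=config.cjs_p_time,
            period_breaks=(change, change + 1),
            period2_breaks=(max(change - 3, 1), change, change + 1),
        )
        fits[name] = CJSModel.from_dataframe(encounters, spec).fit()
    table, lrt = compare_models(
        fits, tests=[("phi(period)", "phi(const)")]
    )
    table.to_csv(outdir / "cjs_model_selection.csv", index=False)
    lrt.to_csv(outdir / "cjs_lrt.csv", index=False)
    info["cjs_lrt"] = lrt.to_dict("records")


def stage_matrices(config: PipelineConfig, outdir: Path) -> list[AnnualMatrix]:
    """Assemble annual matrices for every season with full vital data."""
    tabs = {}
    for name, rate in (("abs", "ABS"), ("juv_survival", "juv_survival"),
                       ("adult_survival", "adult_survival")):
        tidy = pd.read_csv(outdir / f"vital_{name}.csv")
        ages = np.array(sorted(tidy["age"].unique()))
        years = np.array(sorted(tidy["year"].unique()))
        piv = tidy.pivot(index="age", columns="year", values="value")
        pvv = tidy.pivot(index="age", columns="year", values="variance")
        pvp = tidy.pivot(index="age", columns="year", values="provenance")
        tabs[name] = VitalRateTable(
            rate, ages, years,
            piv.loc[ages, years].to_numpy(),
            pvv.loc[ages, years].to_numpy(),
            pvp.loc[ages, years].to_numpy(dtype=object),
        )
    surv = tabs["adult_survival"]
    usable_seasons = [
        int(y) for j, y in enumerate(surv.years)
        if not np.any(np.isin(surv.provenance[:, j], ("confounded", "extrapolated")))
    ]
    years = sorted(
        set(map(int, tabs["abs"].years))
        & set(map(int, tabs["juv_survival"].years))
        & set(usable_seasons)
    )
    matrices = []
    for y in years:
        matrices.append(
            build_annual_matrix(
                tabs["abs"], tabs["juv_survival"], surv, y,
                fertility_ages=config.fertility_ages,
            )
        )
    bundle = []
    for m in matrices:
        pd.DataFrame(m.A).to_csv(outdir / f"matrix_{m.year}.csv", index=False)
        bundle.append(
            {
                "year": int(m.year),
                "F": m.F.tolist(),
                "P": m.P.tolist(),
                "components": {k: v.tolist() for k, v in m.components.items()},
            }
        )
    (outdir / "matrices.json").write_text(json.dumps(bundle, indent=1))
    return matrices


def _load_matrices(outdir: Path) -> list[AnnualMatrix]:
    bundle = json.loads((outdir / "matrices.json").read_text())
    return [
        AnnualMatrix(
            year=b["year"], F=np.array(b["F"]), P=np.array(b["P"]),
            components={k: np.array(v) for k, v in b["components"].items()},
        )
        for b in bundle
    ]


def stage_lambda(config: PipelineConfig, outdir: Path) -> dict:
    """Growth rates: per-year deterministic lambda with MC CIs,
    phase-specific stochastic lambda, autocorrelation, counterfactual."""
    matrices = _load_matrices(outdir)
    ss = config.stage_seed("lambda")
    rows = []
    det_lams = []
    for i, m in enumerate(matrices):
        est = mc_lambda_ci(m, n=config.n_mc, seed=_derive_seed(ss, i))
        det_lams.append(est.value)
        rows.append((m.year, round(est.value, 4), round(est.ci_low, 4),
                     round(est.ci_high, 4), "deterministic"))
    lam_table = pd.DataFrame(
        rows, columns=["year", "lambda", "lcl", "ucl", "method"]
    )
    autocorr = lag1_autocorrelation(det_lams) if len(det_lams) >= 4 else None

    change = config.change_season
    pre = [m for m in matrices if m.year < change]
    post = [m for m in matrices if m.year > change]
    if not config.exclude_change_year:
        pre = [m for m in matrices if m.year <= change]
    if config.sardine_last_k and len(pre) > config.sardine_last_k:
        pre = pre[-config.sardine_last_k:]
    out = {"per_year": lam_table, "autocorrelation": autocorr}
    stoch_rows = []
    for name, pool, k in (("sardine", pre, 1001), ("flyingfish", post, 1002)):
        if not pool:
            continue
        est = stochastic_lambda(pool, horizon=config.horizon,
                                seed=_derive_seed(ss, k))
        out[f"stochastic_{name}"] = est
        stoch_rows.append((name, len(pool), round(est.value, 4),
                           round(est.ci_low, 4), round(est.ci_high, 4)))
    stoch = pd.DataFrame(
        stoch_rows, columns=["phase", "n_matrices", "lambda", "lcl", "ucl"]
    )
    if post:
        cf = required_fertility_increase(
            post, target=config.counterfactual_target,
            seed=_derive_seed(ss, 1003), horizon=config.horizon,
        )
        out["counterfactual"] = cf
    lam_table.to_csv(outdir / "lambda_table.csv", index=False)
    stoch.to_csv(outdir / "stochastic_lambda.csv", index=False)
    summary = {
        "autocorrelation": autocorr,
        "counterfactual": out.get("counterfactual"),
        "stochastic": stoch.to_dict("records"),
    }
    (outdir / "lambda_summary.json").write_text(
        json.dumps(summary, indent=1, default=float)
    )
    return out


def stage_environment(config: PipelineConfig, outdir: Path) -> dict:
    """Seasonal SSTA covariates and the warming threshold summary."""
    ssta = _load(outdir, "ssta")
    sst = _load(outdir, "sst")
    n_seasons = ssta["year"].nunique() - 1
    first = int(ssta["year"].min())
    seasons = range(first, first + n_seasons)
    cov = seasonal_ssta_table(ssta, seasons)
    cov.to_csv(outdir / "ssta_covariates.csv", index=False)
    exc = threshold_exceedance(sst, ThresholdConfig())
    for name, df in exc.items():
        df.to_csv(outdir / f"threshold_{name}.csv", index=False)
    return {"covariates": cov, "exceedance": exc}


# --------------------------------------------------------------------- #

def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run all stages into ``outdir``; returns the in-memory results.

    Writes a machine-readable manifest (seed, config hash, versions,
    per-stage wall time).  Any stage failure leaves partial outputs and a
    ``FAILED`` marker naming the stage, then re-raises.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    timings = {}
    stage_fns = {
        "data": stage_data,
        "fit": stage_fit,
        "matrices": stage_matrices,
        "lambda": stage_lambda,
        "environment": stage_environment,
    }
    for stage in STAGES:
        t0 = time.perf_counter()
        try:
            results[stage] = stage_fns[stage](config, outdir)
        except Exception as exc:
            (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
            raise
        timings[stage] = round(time.perf_counter() - t0, 3)
    from . import __version__ as pkg_version

    cfg_yaml = yaml.safe_dump(pyify(asdict(config)), sort_keys=True)
    manifest = {
        "package": "sulapop",
        "version": pkg_version,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "stage_seconds": timings,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return results
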