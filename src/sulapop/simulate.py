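"""Individual-based synthetic data with known ground truth.

The generator emulates a two-decade longitudinal study of a long-lived
colonial seabird spanning a decadal diet-regime change: individually
marked females recruit into the breeding pool at age 4, breed annually
with an age-quadratic success probability that drops sharply after the
regime change, survive with high age-structured annual probability
(slightly higher after the change), and are resighted imperfectly each
season.  Offspring survive from independence to recruitment with a
maternal-age-dependent probability, males about a third more often than
females.  Occasional near-total failure seasons (El Niño-like) enter as
year-intercept overrides.  Individual and year random intercepts on the
logit scale induce the heterogeneity the downstream mixed models assume.

All Bernoulli outcomes are drawn from logit-linear predictors, so every
generating rate is recoverable by the estimation modules, and the
per-age, per-season ground-truth grids are returned alongside the data
for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SstParams",
    "SimConfig",
    "SyntheticDataset",
    "simulate_population",
    "simulate_sst",
    "simulate_ssta",
    "default_survival_schedule",
    "write_encounters_inp",
]

#: age at entry into the breeding pool (median recruitment age)
ENTRY_AGE = 4
#: terminal pooled age class
MAX_AGE = 22


def default_survival_schedule() -> tuple[float, ...]:
    """Logit-scale annual adult survival by age 4..22+.

    0.92 through mid-life, with a mild senescent decline after age 14;
    still >= 0.80 in the terminal class, matching a population where
    annual survival is typically >= 0.90.
    """
    ages = np.arange(ENTRY_AGE, MAX_AGE + 1)
    base = np.log(0.92 / 0.08)
    return tuple(float(v) for v in base - 0.12 * np.clip(ages - 14, 0, None))


@dataclass
class SstParams:
    """Monthly sea-surface temperature process: seasonal cycle plus AR(1)
    anomalies.  ``ar_coef`` must be < 1 (stationarity)."""

    mean: float = 24.0
    amplitude: float = 2.0
    peak_month: int = 3
    ar_coef: float = 0.6
    innovation_sd: float = 0.4


@dataclass
class SimConfig:
    """Ground-truth parameters of the synthetic study.

    Defaults emulate the study conditions: 22 breeding seasons with the
    diet-regime change at season index 5 (a 1992-2013-like span changing
    at 1997), annual breeding success with a quadratic age profile
    peaking near age 8 and roughly halved after the change, adult
    survival typically >= 0.90 and ~0.55 logits higher after the change,
    resighting probability 0.90, male juvenile survival 1.33x female,
    and near-total breeding failure in two El Niño-like seasons.
    Logit-scale random-intercept SDs are free parameters of the design
    (the within-phase year-to-year spread of the real vital rates is not
    published); see the methods note for the rationale.
    """

    n_seasons: int = 22
    regime_change_season: int = 5
    n_recruits_per_season: int = 100
    adult_banded_fraction: float = 0.25
    # logit ABS = a0 + a1*(age-8) + a2*(age-8)^2 + phase + u_id + u_year
    age_effect: tuple[float, float, float] = (0.6, 0.0, -0.02)
    age_center: float = 8.0
    phase_effect_abs: float = -1.34
    phase_effect_surv: float = 0.55
    survival_schedule: tuple[float, ...] = field(default_factory=default_survival_schedule)
    survival_year_shift: dict[int, float] = field(default_factory=dict)
    # logit female juvenile survival = j0 + j1*(mage-8) + j2*(mage-8)^2
    juv_surv_baseline: tuple[float, float, float] = (-0.35, 0.02, -0.005)
    male_juv_advantage: float = 1.33
    sigma_id: float = 0.5
    sigma_year: float = 0.3
    sigma_id_juv: float = 0.1
    sigma_year_juv: float = 0.12
    juv_year_share: float = 0.6
    p_detect: float = 0.90
    failure_years: dict[int, float] = field(default_factory=lambda: {5: -4.0, 7: -4.0})
    stage_failure_split: tuple[float, float, float] = (0.15, 0.50, 0.35)
    first_year_label: int = 1992
    sst_params: SstParams = field(default_factory=SstParams)
    seed: int = 1

    def __post_init__(self):
        if self.n_seasons < 4:
            raise ValueError("n_seasons must be >= 4")
        if self.male_juv_advantage <= 0:
            raise ValueError("male_juv_advantage must be > 0")
        if not 0 < self.p_detect <= 1:
            raise ValueError("p_detect must be in (0, 1]")
        if not 0 <= self.regime_change_season < self.n_seasons:
            raise ValueError("regime_change_season outside the season range")
        if len(self.survival_schedule) != MAX_AGE - ENTRY_AGE + 1:
            raise ValueError(
                f"survival_schedule needs {MAX_AGE - ENTRY_AGE + 1} entries (ages "
                f"{ENTRY_AGE}..{MAX_AGE}+)"
            )
        if abs(sum(self.stage_failure_split) - 1.0) > 1e-9:
            raise ValueError("stage_failure_split must sum to 1")
        if self.sst_params.ar_coef >= 1.0:
            raise ValueError("AR(1) coefficient must be < 1 (stationarity)")
        self._validate_probability_range()

    def _validate_probability_range(self):
        """Reject configs whose linear predictors leave a representable
        probability range at +/- 6 SD of the random effects, or whose
        implied male juvenile survival can reach 1."""
        d = np.arange(ENTRY_AGE, 31) - self.age_center
        a0, a1, a2 = self.age_effect
        eta_abs = a0 + a1 * d + a2 * d**2
        spread = 6.0 * (self.sigma_id + self.sigma_year)
        extremes = [
            np.max(np.abs(eta_abs)) + abs(self.phase_effect_abs) + spread,
            np.max(np.abs(np.asarray(self.survival_schedule)))
            + abs(self.phase_effect_surv),
        ]
        if max(extremes) > 30.0:
            raise ValueError(
                "config rejected: linear predictor can exceed +/-30 logits at "
                f"+/-6 SD (max |eta| = {max(extremes):.1f}); probabilities would "
                "degenerate to 0/1 in floating point"
            )
        j0, j1, j2 = self.juv_surv_baseline
        eta_juv = j0 + j1 * d + j2 * d**2
        eta_max = np.max(eta_juv) + 6.0 * (self.sigma_id_juv + self.sigma_year_juv)
        f_max = _expit(eta_max)
        if self.male_juv_advantage * f_max >= 1.0:
            raise ValueError(
                "config rejected: implied male juvenile survival reaches "
                f"{self.male_juv_advantage * f_max:.3f} >= 1 at +6 SD of the "
                "random effects; lower juv_surv_baseline or the SDs"
            )

    # ------------------------------------------------------------------ #
    def season_labels(self) -> list[int]:
        return [self.first_year_label + s for s in range(self.n_seasons)]

    def abs_logit(self, age, season) -> np.ndarray:
        """Ground-truth logit of annual breeding success at random-effect 0
        (year override years use their override as the year effect)."""
        d = np.asarray(age, dtype=float) - self.age_center
        a0, a1, a2 = self.age_effect
        eta = a0 + a1 * d + a2 * d**2
        eta = eta + self.phase_effect_abs * (np.asarray(season) >= self.regime_change_season)
        return eta

    def surv_logit(self, age, season) -> np.ndarray:
        age = np.clip(np.asarray(age, dtype=int), ENTRY_AGE, MAX_AGE)
        sched = np.asarray(self.survival_schedule)
        eta = sched[age - ENTRY_AGE].astype(float)
        season = np.asarray(season)
        eta = eta + self.phase_effect_surv * (season > self.regime_change_season)
        shift = np.zeros_like(eta, dtype=float)
        for s, v in self.survival_year_shift.items():
            shift = shift + np.where(season == s, v, 0.0)
        return eta + shift

    def juv_logit_female(self, mother_age, season=None) -> np.ndarray:
        d = np.asarray(mother_age, dtype=float) - self.age_center
        j0, j1, j2 = self.juv_surv_baseline
        return j0 + j1 * d + j2 * d**2

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(pyify(asdict(self)), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "sst_params" in d and isinstance(d["sst_params"], dict):
            d["sst_params"] = SstParams(**d["sst_params"])
        for key in ("age_effect", "juv_surv_baseline", "stage_failure_split",
                    "survival_schedule"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "failure_years" in d and d["failure_years"] is not None:
            d["failure_years"] = {int(k): float(v) for k, v in d["failure_years"].items()}
        if "survival_year_shift" in d and d["survival_year_shift"] is not None:
            d["survival_year_shift"] = {
                int(k): float(v) for k, v in d["survival_year_shift"].items()
            }
        return cls(**d)


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def pyify(obj):
    """Recursively convert numpy scalars/arrays to plain Python types
    (YAML/JSON-serializable)."""
    if isinstance(obj, dict):
        return {pyify(k): pyify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [pyify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


@dataclass
class SyntheticDataset:
    """Simulated records plus the generating truth.

    ``breeding``: one row per bird-season (bird_id, season, year, age,
    stage outcomes, success).  ``juveniles``: one row per independent
    offspring (mother_id, mother_age, cohort season, sex, recruited).
    ``encounters``: one row per bird with a 0/1 detection string.
    ``truth`` carries the realized year effects and the per-age,
    per-season ground-truth rate grids used by recovery tests.
    """

    config: SimConfig
    breeding: pd.DataFrame
    juveniles: pd.DataFrame
    encounters: pd.DataFrame
    sst: pd.DataFrame
    ssta: pd.DataFrame
    truth: dict

    def write(self, outdir) -> dict[str, Path]:
        """Write all tables as UTF-8 CSV (plus the INP-like encounter
        format) and the config as YAML; returns the path map."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("breeding", "juveniles", "encounters", "sst", "ssta"):
            p = out / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            paths[name] = p
        paths["encounters_inp"] = out / "encounters.inp"
        write_encounters_inp(self.encounters, paths["encounters_inp"])
        paths["config"] = out / "sim_config.yaml"
        self.config.to_yaml(paths["config"])
        paths["truth"] = out / "truth.json"
        truth = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.truth.items()
        }
        Path(paths["truth"]).write_text(json.dumps(truth, indent=1))
        return paths


def write_encounters_inp(encounters: pd.DataFrame, path) -> None:
    """Classic fixed-width mark-recapture layout: one 0/1 history per
    line, two group-frequency columns (nestling-banded, adult-banded)."""
    lines = []
    for _, row in encounters.iterrows():
        g = 0 if row["group"] == "nestling" else 1
        freq = "1 0" if g == 0 else "0 1"
        lines.append(f"{row['detections']} {freq};")
    Path(path).write_text("\n".join(lines) + "\n")


def simulate_population(config: SimConfig) -> SyntheticDataset:
    """Generate breeding records, juvenile fates and encounter histories.

    Cohorts of ``n_recruits_per_season`` females enter the breeding pool
    at age 4 each season (the recruit stream is exogenous, so marked
    juveniles do not feed back into the adult pool; this keeps the
    marked-population size controlled without affecting any estimand).
    Stage outcomes (clutch initiated -> egg hatched -> offspring
    independent) are generated by first drawing overall season success
    from its logit-linear predictor and then attributing failures to a
    stage, so the unconditional annual success matches the generating
    quadratic exactly while conditional stage rates remain available.
    """
    rng = np.random.default_rng(config.seed)
    n_s = config.n_seasons
    labels = config.season_labels()

    u_year = rng.normal(0.0, config.sigma_year, n_s)
    for s, v in config.failure_years.items():
        if 0 <= int(s) < n_s:  # overrides beyond a short run are moot
            u_year[int(s)] = v
    eps = rng.normal(0.0, 1.0, n_s)
    share = config.juv_year_share
    u_year_juv = config.sigma_year_juv * (
        share * (u_year / max(config.sigma_year, 1e-12)) + np.sqrt(max(1 - share**2, 0.0)) * eps
    ) if config.sigma_year > 0 else config.sigma_year_juv * eps
    # failure years hammer juvenile survival too (El Niño cohorts)
    for s in config.failure_years:
        if 0 <= int(s) < n_s:
            u_year_juv[int(s)] = min(u_year_juv[int(s)], -1.5)

    breeding_rows = []
    juvenile_rows = []
    enc_rows = []
    bird_counter = 0
    split = np.asarray(config.stage_failure_split)

    for entry in range(n_s):
        n_new = config.n_recruits_per_season
        groups = rng.random(n_new) < config.adult_banded_fraction
        u_ids = rng.normal(0.0, config.sigma_id, n_new)
        u_ids_juv = rng.normal(0.0, config.sigma_id_juv, n_new)
        for j in range(n_new):
            bird_id = f"b{bird_counter:05d}"
            bird_counter += 1
            u_i = u_ids[j]
            u_ij = u_ids_juv[j]
            alive = np.zeros(n_s, dtype=bool)
            s = entry
            age = ENTRY_AGE
            death_season = None
            while s < n_s:
                alive[s] = True
                eta = config.abs_logit(age, s) + u_i + u_year[s]
                success = rng.random() < _expit(eta)
                if success:
                    initiated, hatched, fledged = 1, 1, 1
                else:
                    k = rng.choice(3, p=split)
                    initiated = int(k > 0)
                    hatched = int(k > 1)
                    fledged = 0
                breeding_rows.append(
                    (bird_id, s, labels[s], age, initiated, hatched, fledged, int(success))
                )
                if fledged:
                    sex = "m" if rng.random() < 0.5 else "f"
                    f_surv = _expit(config.juv_logit_female(age) + u_ij + u_year_juv[s])
                    p_rec = f_surv if sex == "f" else min(
                        config.male_juv_advantage * f_surv, 1.0
                    )
                    recruited = int(rng.random() < p_rec)
                    juvenile_rows.append((bird_id, age, s, labels[s], sex, recruited))
                p_surv = _expit(config.surv_logit(age, s))
                if rng.random() >= p_surv:
                    death_season = s + 1
                    break
                s += 1
                age += 1
            det = (rng.random(n_s) < config.p_detect) & alive
            det[entry] = True
            enc_rows.append(
                (
                    bird_id,
                    "adult" if groups[j] else "nestling",
                    entry,
                    ENTRY_AGE,
                    "".join("1" if d else "0" for d in det),
                    death_season if death_season is not None else -1,
                )
            )

    breeding = pd.DataFrame(
        breeding_rows,
        columns=["bird_id", "season", "year", "age", "clutch_initiated",
                 "egg_hatched", "offspring_independent", "success"],
    )
    juveniles = pd.DataFrame(
        juvenile_rows,
        columns=["mother_id", "mother_age", "season", "year", "sex", "recruited"],
    )
    encounters = pd.DataFrame(
        enc_rows,
        columns=["bird_id", "group", "entry_season", "entry_age", "detections",
                 "death_season"],
    )

    sst = simulate_sst(config, n_blocks=12)
    ssta = simulate_ssta(config, n_years=n_s + 1)

    ages = np.arange(ENTRY_AGE, MAX_AGE + 1)
    seasons = np.arange(n_s)
    A, S = np.meshgrid(ages, seasons, indexing="ij")
    true_abs = _expit(config.abs_logit(A, S) + u_year[S])
    fjuv = _expit(config.juv_logit_female(A)[:, None] + u_year_juv[S])
    true_fjuv = fjuv
    true_mjuv = np.minimum(config.male_juv_advantage * fjuv, 1.0)
    true_juv_combined = 0.5 * (true_fjuv + true_mjuv)
    true_surv = _expit(config.surv_logit(A, S))

    realized_abs = (
        breeding.groupby("season")["success"].mean().reindex(seasons).to_numpy()
    )
    realized_juv = (
        juveniles.groupby("season")["recruited"].mean().reindex(seasons).to_numpy()
    )

    truth = {
        "ages": ages,
        "seasons": seasons,
        "u_year": u_year,
        "u_year_juv": u_year_juv,
        "true_abs": true_abs,
        "true_female_juv_survival": true_fjuv,
        "true_juv_survival_combined": true_juv_combined,
        "true_adult_survival": true_surv,
        "realized_abs_by_season": realized_abs,
        "realized_juv_by_season": realized_juv,
    }
    return SyntheticDataset(
        config=config,
        breeding=breeding,
        juveniles=juveniles,
        encounters=encounters,
        sst=sst,
        ssta=ssta,
        truth=truth,
    )


def true_annual_matrix(config: SimConfig, season: int,
                       u_year: float = 0.0, u_year_juv: float = 0.0):
    """Ground-truth projection matrix implied by the generating rates.

    Evaluates the generating logit-linear predictors at individual
    random-effect zero (optionally at given realized year effects),
    applies the 50/50 sex split and the daughters-only halving, and
    assembles the 22-class matrix.  Fertility starts at age 4 because the
    synthetic population recruits at 4 (no age-3 breeding exists to
    contribute).  This is the reference against which estimated matrices
    and growth rates are judged in recovery tests.
    """
    from .matrix_model import AnnualMatrix, N_CLASSES

    F = np.zeros(N_CLASSES)
    P = np.ones(N_CLASSES)
    for a in range(ENTRY_AGE, N_CLASSES):
        absv = _expit(config.abs_logit(a, season) + u_year)
        fjuv = _expit(config.juv_logit_female(a) + u_year_juv)
        F[a - 1] = absv / 2.0 * fjuv
    for a in range(ENTRY_AGE, N_CLASSES + 1):
        P[a - 1] = _expit(config.surv_logit(a, season))
    return AnnualMatrix(year=season, F=F, P=P)


def simulate_sst(config: SimConfig, n_blocks: int, n_years: int | None = None) -> pd.DataFrame:
    """Monthly SST per 2°x2°-like block: mean + seasonal cycle + AR(1)
    anomaly.  Long-format columns (block, year, month, sst).  Reproducible
    under the config seed (independent of the population stream)."""
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    p = config.sst_params
    if p.ar_coef >= 1.0:
        raise ValueError("AR(1) coefficient must be < 1 (nonstationary)")
    ny = config.n_seasons if n_years is None else int(n_years)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7001]))
    months = np.arange(ny * 12)
    cycle = p.mean + p.amplitude * np.cos(2 * np.pi * (months % 12 + 1 - p.peak_month) / 12)
    rows = []
    for b in range(n_blocks):
        anom = np.zeros(len(months))
        innov = rng.normal(0.0, p.innovation_sd, len(months))
        for t in range(1, len(months)):
            anom[t] = p.ar_coef * anom[t - 1] + innov[t]
        vals = cycle + anom
        for t in range(len(months)):
            rows.append(
                (b, config.first_year_label + t // 12, t % 12 + 1, vals[t])
            )
    return pd.DataFrame(rows, columns=["block", "year", "month", "sst"])


def simulate_ssta(config: SimConfig, n_years: int | None = None,
                  region: str = "nino3-like") -> pd.DataFrame:
    """Monthly SST anomaly series for a named index region (AR(1))."""
    p = config.sst_params
    if p.ar_coef >= 1.0:
        raise ValueError("AR(1) coefficient must be < 1 (nonstationary)")
    ny = config.n_seasons + 1 if n_years is None else int(n_years)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7002]))
    n = ny * 12
    anom = np.zeros(n)
    innov = rng.normal(0.0, p.innovation_sd, n)
    for t in range(1, n):
        anom[t] = p.ar_coef * anom[t - 1] + innov[t]
    return pd.DataFrame(
        {
            "region": region,
            "year": config.first_year_label + np.arange(n) // 12,
            "month": np.arange(n) % 12 + 1,
            "anomaly": anom,
        }
    )
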