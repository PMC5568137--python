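"""Environmental covariates and the thermal-threshold projection.

Seasonal sea-surface-temperature-anomaly means serve as model covariates:
SSTA_DJF (December of the season's label year through February of the
next calendar year, the peak of El Niño-like events) and SSTA_AMJ (April
to June of the following calendar year, late in the breeding season).
Breeding seasons span two calendar years and are labelled by the first.

The threshold projection adds a fixed warming offset (default +4.5 °C,
the regional expectation over the next century) to observed monthly SST
and counts exceedances of two sardine thermal limits: the upper limit of
the spawning range (25.0 °C) and the upper incipient lethal temperature
for warm-acclimated temperate-origin sardines (25.6 °C).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdConfig",
    "seasonal_ssta",
    "seasonal_ssta_table",
    "threshold_exceedance",
    "WARMING_OFFSET",
    "SPAWN_LIMIT",
    "LETHAL_LIMIT",
]

#: fixed warming scenario, °C over the next ~100 years
WARMING_OFFSET = 4.5
#: upper limit of the sardine spawning SST range, °C
SPAWN_LIMIT = 25.0
#: upper incipient lethal limit for warm-acclimated sardines, °C
LETHAL_LIMIT = 25.6

#: window -> list of (month, year offset from the season label)
_WINDOWS = {
    "DJF": [(12, 0), (1, 1), (2, 1)],
    "AMJ": [(4, 1), (5, 1), (6, 1)],
}


@dataclass(frozen=True)
class ThresholdConfig:
    """Warming scenario and sardine thermal limits (°C)."""

    warming: float = WARMING_OFFSET
    spawn_limit: float = SPAWN_LIMIT
    lethal_limit: float = LETHAL_LIMIT

    def __post_init__(self):
        if self.spawn_limit <= 0 or self.lethal_limit <= 0:
            raise ValueError("thermal limits must be positive")
        if self.warming < 0:
            raise ValueError("warming offset must be >= 0")


def seasonal_ssta(ssta: pd.DataFrame, window: str, season_year: int) -> float:
    """Mean anomaly over a three-month seasonal window.

    ``window`` is ``"DJF"`` or ``"AMJ"``; DJF spans the year boundary
    (December of ``season_year``, January-February of the next year).
    Raises if any of the three months is missing, naming it.
    """
    if window not in _WINDOWS:
        raise ValueError(f"unknown window {window!r}; use 'DJF' or 'AMJ'")
    vals = []
    for month, offset in _WINDOWS[window]:
        year = season_year + offset
        sel = ssta[(ssta["year"] == year) & (ssta["month"] == month)]
        if sel.empty:
            raise ValueError(f"missing month {year}-{month:02d} for window {window}")
        vals.append(float(sel["anomaly"].mean()))
    return float(np.mean(vals))


def seasonal_ssta_table(ssta: pd.DataFrame, season_years) -> pd.DataFrame:
    """DJF and AMJ means per breeding season, tagged by window so joins
    onto breeding seasons are unambiguous."""
    rows = []
    for y in season_years:
        for w in _WINDOWS:
            rows.append((int(y), w, seasonal_ssta(ssta, w, int(y))))
    return pd.DataFrame(rows, columns=["season_year", "window", "ssta_mean"])


def threshold_exceedance(
    sst: pd.DataFrame, cfg: ThresholdConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Warmed-SST exceedance of the sardine thermal limits.

    Adds the warming offset to every monthly value and summarizes per
    block and calendar month (mean warmed SST, months above each limit)
    plus a cross-block monthly climatology (mean ± 2 SD over all
    block-year values within the calendar month).
    """
    if cfg is None:
        cfg = ThresholdConfig()
    if sst.empty:
        raise ValueError("empty SST series")
    df = sst.copy()
    df["warmed"] = df["sst"] + cfg.warming
    df["above_spawn"] = df["warmed"] > cfg.spawn_limit
    df["above_lethal"] = df["warmed"] > cfg.lethal_limit

    per_block = (
        df.groupby(["block", "month"])
        .agg(
            mean_warmed=("warmed", "mean"),
            n_months=("warmed", "size"),
            n_above_spawn=("above_spawn", "sum"),
            n_above_lethal=("above_lethal", "sum"),
        )
        .reset_index()
    )
    # SD over all block-year values within each calendar month
    monthly = (
        df.groupby("month")["warmed"]
        .agg(["mean", "std", "size"])
        .rename(columns={"mean": "mean_warmed", "std": "sd", "size": "n"})
        .reset_index()
    )
    monthly["lo_2sd"] = monthly["mean_warmed"] - 2 * monthly["sd"]
    monthly["hi_2sd"] = monthly["mean_warmed"] + 2 * monthly["sd"]
    totals = pd.DataFrame(
        {
            "n_months": [len(df)],
            "n_above_spawn": [int(df["above_spawn"].sum())],
            "n_above_lethal": [int(df["above_lethal"].sum())],
            "warming": [cfg.warming],
            "spawn_limit": [cfg.spawn_limit],
            "lethal_limit": [cfg.lethal_limit],
        }
    )
    return {"per_block": per_block, "monthly": monthly, "totals": totals}
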