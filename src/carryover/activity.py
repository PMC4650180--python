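"""Daily daytime activity budgets from saltwater-immersion series.

A leg-mounted logger reports, per fixed block, the fraction of time its
sensor was wet.  Dry blocks indicate flight, fully wet blocks indicate
resting on the water, and intermediate wet fractions indicate foraging
(repeated surface contact).  This module classifies blocks and aggregates
them into per-day proportions of daytime spent flying, resting and foraging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import ImmersionSeries

#: (dry_max, wet_min): wet fractions <= dry_max are flight, >= wet_min rest.
DEFAULT_THRESHOLDS = (0.05, 0.95)

FLY, REST, FORAGE = "FLY", "REST", "FORAGE"


@dataclass
class DailyActivityProfile:
    bird_id: str
    date: object
    p_fly: float
    p_rest: float
    p_forage: float
    n_daytime_blocks: int


def _check_thresholds(thresholds) -> tuple[float, float]:
    dry_max, wet_min = thresholds
    if not 0 <= dry_max < wet_min <= 1:
        raise ValueError(
            f"thresholds must satisfy 0 <= dry_max < wet_min <= 1, got {thresholds}"
        )
    return float(dry_max), float(wet_min)


def classify_block(wet_fraction: float, thresholds=DEFAULT_THRESHOLDS) -> str:
    """Classify a single block as FLY, REST or FORAGE.

    Total and deterministic in (wet_fraction, thresholds): at or below
    ``dry_max`` the bird was airborne, at or above ``wet_min`` it sat on the
    water, anything between is the foraging signature.
    """
    dry_max, wet_min = _check_thresholds(thresholds)
    if wet_fraction <= dry_max:
        return FLY
    if wet_fraction >= wet_min:
        return REST
    return FORAGE


def classify_blocks(
    wet_fraction: np.ndarray, thresholds=DEFAULT_THRESHOLDS
) -> np.ndarray:
    """Vectorised :func:`classify_block`; returns an array of activity labels."""
    dry_max, wet_min = _check_thresholds(thresholds)
    w = np.asarray(wet_fraction, dtype=float)
    return np.where(w <= dry_max, FLY, np.where(w >= wet_min, REST, FORAGE))


def daily_profiles(
    series: ImmersionSeries | pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
    include_night: bool = False,
    bird_id: str | None = None,
) -> pd.DataFrame:
    """Aggregate an immersion series into per-day activity proportions.

    One row per calendar date (local midnight boundaries, no timezone
    conversion) with at least one daytime block; proportions are block counts
    per class divided by the daytime block count, so they sum to one exactly.
    ``include_night=True`` budgets over all blocks instead (exploratory; the
    headline analyses are daytime-only).
    """
    if isinstance(series, ImmersionSeries):
        df = series.blocks
        bird_id = series.bird_id
    else:
        df = series
        if bird_id is None:
            bird_id = str(df["bird_id"].iloc[0]) if "bird_id" in df else "NA"
    if len(df) == 0:
        raise ValueError("empty immersion series")
    use = df if include_night else df[df["is_daytime"]]
    if len(use) == 0:
        return pd.DataFrame(
            columns=["bird_id", "date", "p_fly", "p_rest", "p_forage", "n_daytime_blocks"]
        )
    labels = classify_blocks(use["wet_fraction"].to_numpy(), thresholds)
    tmp = pd.DataFrame(
        {"date": use["timestamp"].dt.normalize().to_numpy(), "label": labels}
    )
    counts = (
        tmp.groupby("date")["label"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=[FLY, REST, FORAGE], fill_value=0)
    )
    n = counts.sum(axis=1)
    out = pd.DataFrame(
        {
            "bird_id": bird_id,
            "date": counts.index,
            "p_fly": counts[FLY].to_numpy() / n.to_numpy(),
            "p_rest": counts[REST].to_numpy() / n.to_numpy(),
            "p_forage": counts[FORAGE].to_numpy() / n.to_numpy(),
            "n_daytime_blocks": n.to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def daily_profiles_all(
    series_list: list[ImmersionSeries],
    thresholds=DEFAULT_THRESHOLDS,
    include_night: bool = False,
) -> pd.DataFrame:
    """Concatenated daily profiles for a collection of bird-winters."""
    frames = [daily_profiles(s, thresholds, include_night) for s in series_list]
    return pd.concat(frames, ignore_index=True)


def write_profiles_csv(profiles: pd.DataFrame, path, seed="NA") -> None:
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# carryover v{__version__} seed={seed}\n")
        profiles.to_csv(fh, index=False, date_format="%Y-%m-%d")


def read_profiles_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", parse_dates=["date"])
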