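"""Synthetic field data: encounter histories, phenology tables, immersion series.

Every downstream stage of the pipeline (activity classification, breakpoint
regression, boosting, trend contrasts, multi-event capture-mark-recapture)
consumes one of the three outputs produced here.  All randomness flows through
a single ``numpy`` generator seeded from the configuration, so identical
config + seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    EVENTS,
    FEATURE_REGISTRY,
    RP_STATES,
    STATES,
    ConfigError,
    SimulationConfig,
)

_STATE_INDEX = {s: i for i, s in enumerate(STATES)}
_EVENT_INDEX = {e: i for i, e in enumerate(EVENTS)}
_SEEN_EVENT_FOR_STATE = {"SUCCESS": 1, "FAIL": 2, "SKIP": 3}


@dataclass
class EncounterHistory:
    """One bird's event sequence over breeding occasions.

    ``events`` holds integer codes into :data:`carryover.config.EVENTS`;
    occasions before ``first_occasion`` are structurally NOT_SEEN and carry no
    information (the model conditions on first capture).
    """

    bird_id: str
    sex: str
    events: np.ndarray
    first_occasion: int = 0

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=int)
        if self.events[self.first_occasion] == 0:
            raise ValueError(
                f"{self.bird_id}: event at first occasion must be an encounter"
            )

    @property
    def event_names(self) -> list[str]:
        return [EVENTS[e] for e in self.events]


@dataclass
class ImmersionSeries:
    """Saltwater-immersion record for one bird-winter.

    ``blocks`` has columns ``timestamp`` (block start), ``wet_fraction`` in
    [0, 1] and ``is_daytime``; rows are strictly increasing with constant
    spacing ``block_minutes``.
    """

    bird_id: str
    season_year: int
    block_minutes: int
    blocks: pd.DataFrame


# ---------------------------------------------------------------------------
# encounter histories


def simulate_encounter_histories(
    config: SimulationConfig,
    n_birds: int | None = None,
    seed: int | None = None,
) -> tuple[list[EncounterHistory], dict]:
    """Simulate latent breeding-state paths and their observed events.

    Each bird draws a mixture class, then a latent path over
    SUCCESS/FAIL/SKIP/DEAD driven by survival ``phi`` and the class transition
    matrix ``psi``; events are generated by detection probability ``p_detect``
    with optional state-uncertainty.  The first encounter is always an
    observed state; DEAD is absorbing and emits only NOT_SEEN.

    Returns the histories and a record of the true generating parameters.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    T = config.n_occasions

    if n_birds is None:
        n_logger = config.n_birds_logger
        n_hist = config.n_birds_history_only
        sexes = list(rng.choice(["F", "M"], size=n_logger))
        hist_sexes = ["F"] * config.n_females_history_only + ["M"] * (
            n_hist - config.n_females_history_only
        )
        sexes += hist_sexes
        ids = [f"L{i:03d}" for i in range(n_logger)] + [
            f"H{i:03d}" for i in range(n_hist)
        ]
    else:
        sexes = list(rng.choice(["F", "M"], size=n_birds))
        ids = [f"B{i:04d}" for i in range(n_birds)]

    weights = np.asarray(config.mixture_weights, dtype=float)
    n_classes = len(weights)
    init = config.initial_probs()
    u = config.uncertainty

    histories: list[EncounterHistory] = []
    for bird_id, sex in zip(ids, sexes):
        c = int(rng.choice(n_classes, p=weights)) if n_classes > 1 else 0
        psi = config.psi_for(sex, c)
        first = (
            int(rng.integers(0, T - 1)) if config.staggered_entry else 0
        )
        events = np.zeros(T, dtype=int)
        state = RP_STATES[int(rng.choice(3, p=init))]
        for t in range(first, T):
            if t > first and state != "DEAD":
                if rng.random() >= config.phi_for(state, sex):
                    state = "DEAD"
                else:
                    row = psi[_STATE_INDEX[state]]
                    state = RP_STATES[int(rng.choice(3, p=row))]
            if state == "DEAD":
                events[t] = 0
                continue
            if t == first:
                seen = True  # conditioned on first capture
            else:
                seen = rng.random() < config.p_detect
            if not seen:
                events[t] = 0
            elif u > 0 and rng.random() < u:
                events[t] = _EVENT_INDEX["SEEN_UNKNOWN"]
            else:
                events[t] = _SEEN_EVENT_FOR_STATE[state]
        histories.append(EncounterHistory(bird_id, sex, events, first))

    truth = {
        "phi": config.phi,
        "psi": np.asarray(config.psi_for("F", 0)).tolist()
        if config.psi_by_class is None and not isinstance(config.psi, dict)
        else "structured",
        "p_detect": config.p_detect,
        "mixture_weights": list(weights),
        "uncertainty": u,
        "initial_state_probs": init.tolist(),
    }
    return histories, truth


# ---------------------------------------------------------------------------
# phenology


def simulate_phenology(
    config: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Draw per-group Gaussian event dates, rounded to whole days.

    The within-season ordering lay < hatch < fledge < colony departure <
    wintering-ground arrival < wintering-ground departure < colony arrival is
    enforced by rejection sampling (bounded attempts per bird).  Group sizes
    honour ``rp_category_counts``; the RP label of the season *following* the
    tracked winter is attached to each record.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    order = [
        "prior_lay_date",
        "prior_hatch_date",
        "prior_fledge_date",
        "colony_departure",
        "wg_arrival",
        "wg_departure",
        "colony_arrival",
    ]
    rows = []
    i = 0
    for grp in RP_STATES:
        params = config.phenology_means_sds[grp]
        missing = [f for f in FEATURE_REGISTRY if f not in params]
        if missing:
            raise ConfigError(f"group {grp} missing phenology features {missing}")
        for _ in range(int(config.rp_category_counts[grp])):
            for attempt in range(config.max_rejections + 1):
                draw = {
                    f: int(round(rng.normal(params[f][0], params[f][1])))
                    for f in order
                }
                vals = [draw[f] for f in order]
                if all(a < b for a, b in zip(vals, vals[1:])):
                    break
            else:
                raise ConfigError(
                    f"could not satisfy event ordering for group {grp} "
                    f"after {config.max_rejections} attempts"
                )
            rows.append(
                {
                    "bird_id": f"L{i:03d}",
                    "season_year": config.base_year + i % 5,
                    "sex": rng.choice(["F", "M"]),
                    "rp": grp,
                    **draw,
                }
            )
            i += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# immersion series

_ACT_FLY, _ACT_REST, _ACT_FORAGE = 0, 1, 2


def simulate_immersion(
    config: SimulationConfig,
    phenology: pd.DataFrame,
    seed: int | None = None,
) -> list[ImmersionSeries]:
    """Generate per-block wet fractions over each bird's winter window.

    The winter window runs from colony departure to colony arrival.  For each
    daytime block an activity is drawn from the bird's RP-group day-specific
    (fly, rest, forage) proportions; the emitted wet fraction is 0 for FLY, 1
    for REST and uniform on the configured foraging band for FORAGE.  Night
    blocks are emitted wet (sitting on the water) with the daytime flag off.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    bpd = 1440 // config.block_minutes  # blocks per day
    hours = (
        np.arange(bpd) * config.block_minutes / 60.0
    )  # block start hour within day
    day_mask = (hours >= config.sunrise_hour) & (hours < config.sunset_hour)
    n_day_blocks = int(day_mask.sum())
    lo, hi = config.forage_band

    out: list[ImmersionSeries] = []
    for rec in phenology.itertuples(index=False):
        n_days = int(rec.colony_arrival) - int(rec.colony_departure)
        if n_days <= 0:
            raise ConfigError(f"{rec.bird_id}: empty winter window")
        profile = config.activity_profiles[rec.rp]
        props = profile.proportions(np.arange(n_days))  # (n_days, 3)
        if profile.noise_sd > 0:
            noise = rng.normal(0.0, profile.noise_sd, size=(n_days, 2))
            fly = np.clip(props[:, 0] + noise[:, 0], 0.0, 1.0)
            forage = np.clip(props[:, 2] + noise[:, 1], 0.0, 1.0)
            rest = np.clip(1.0 - fly - forage, 0.0, 1.0)
            props = np.stack([fly, rest, forage], axis=1)
            props /= props.sum(axis=1, keepdims=True)

        # categorical draw per daytime block via inverse CDF
        cdf = np.cumsum(props, axis=1)  # (n_days, 3)
        uni = rng.random((n_days, n_day_blocks))
        acts = (uni[:, :, None] > cdf[:, None, :]).sum(axis=2)  # (n_days, nb)

        wet = np.ones((n_days, bpd))
        day_cols = np.where(day_mask)[0]
        wet_day = np.where(
            acts == _ACT_FLY,
            0.0,
            np.where(
                acts == _ACT_REST,
                1.0,
                rng.uniform(lo, hi, size=acts.shape),
            ),
        )
        wet[:, day_cols] = wet_day

        anchor = pd.Timestamp(
            year=int(rec.season_year),
            month=config.season_anchor[0],
            day=config.season_anchor[1],
        )
        start = anchor + pd.Timedelta(days=int(rec.colony_departure))
        ts = pd.date_range(
            start, periods=n_days * bpd, freq=f"{config.block_minutes}min"
        )
        blocks = pd.DataFrame(
            {
                "timestamp": ts,
                "wet_fraction": wet.ravel(),
                "is_daytime": np.tile(day_mask, n_days),
            }
        )
        out.append(
            ImmersionSeries(
                bird_id=rec.bird_id,
                season_year=int(rec.season_year),
                block_minutes=config.block_minutes,
                blocks=blocks,
            )
        )
    return out


# ---------------------------------------------------------------------------
# CSV writers (schemas consumed by the pipeline)


def _header(seed) -> str:
    from . import __version__

    return f"# carryover v{__version__} seed={seed}\n"


def write_immersion_csv(series: list[ImmersionSeries], path, seed="NA") -> None:
    frames = []
    for s in series:
        df = s.blocks.copy()
        df.insert(0, "bird_id", s.bird_id)
        frames.append(df)
    big = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(_header(seed))
        big.to_csv(fh, index=False, date_format="%Y-%m-%dT%H:%M:%S")


def write_phenology_csv(phenology: pd.DataFrame, path, seed="NA") -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed))
        phenology.to_csv(fh, index=False)


def write_encounters_csv(histories: list[EncounterHistory], path, seed="NA") -> None:
    rows = []
    for h in histories:
        for occ, ev in enumerate(h.events):
            rows.append(
                {
                    "bird_id": h.bird_id,
                    "sex": h.sex,
                    "occasion": occ,
                    "event": EVENTS[ev],
                }
            )
    with open(path, "w") as fh:
        fh.write(_header(seed))
        pd.DataFrame(rows).to_csv(fh, index=False)


def read_immersion_csv(path) -> list[ImmersionSeries]:
    df = pd.read_csv(path, comment="#", parse_dates=["timestamp"])
    out = []
    for bird_id, sub in df.groupby("bird_id", sort=False):
        sub = sub.reset_index(drop=True)
        step = sub["timestamp"].diff().dropna()
        block_minutes = int(step.iloc[0].total_seconds() // 60) if len(step) else 10
        out.append(
            ImmersionSeries(
                bird_id=str(bird_id),
                season_year=int(sub["timestamp"].iloc[0].year),
                block_minutes=block_minutes,
                blocks=sub[["timestamp", "wet_fraction", "is_daytime"]],
            )
        )
    return out


def read_phenology_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_encounters_csv(path) -> list[EncounterHistory]:
    df = pd.read_csv(path, comment="#")
    out = []
    for bird_id, sub in df.groupby("bird_id", sort=False):
        sub = sub.sort_values("occasion")
        events = np.array([_EVENT_INDEX[e] for e in sub["event"]], dtype=int)
        first = int(np.argmax(events != 0))
        out.append(
            EncounterHistory(
                bird_id=str(bird_id),
                sex=str(sub["sex"].iloc[0]),
                events=events,
                first_occasion=first,
            )
        )
    return out


def config_to_dict(config: SimulationConfig) -> dict:
    """JSON-serialisable view of a configuration (for run manifests)."""
    d = dataclasses.asdict(config)

    def conv(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, dict):
            return {str(k): conv(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [conv(x) for x in v]
        return v

    return {k: conv(v) for k, v in d.items()}
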