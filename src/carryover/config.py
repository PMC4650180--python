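"""Simulation configuration: the study conditions every synthetic dataset obeys.

Reproductive performance (RP) of a bird-season takes one of three values:
``SUCCESS`` (raised a chick), ``FAIL`` (failed during incubation) and ``SKIP``
(did not lay).  The generator reproduces the structure of the field study it
emulates: 111 logger bird-seasons split 64/29/18 across RP categories, plus 88
additional history-only individuals (41 of them female) that enter only the
capture-mark-recapture stage.

All dates are integer day offsets from a season anchor (1 March), which keeps
the phenology arithmetic calendar-free; timestamps are materialised only when
immersion series are written out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

RP_STATES = ("SUCCESS", "FAIL", "SKIP")
#: Latent states of the multi-event model; DEAD is absorbing.
STATES = ("SUCCESS", "FAIL", "SKIP", "DEAD")
EVENTS = ("NOT_SEEN", "SEEN_SUCCESS", "SEEN_FAIL", "SEEN_SKIP", "SEEN_UNKNOWN")
SEXES = ("F", "M")

#: Annual-cycle phenology features used by the classifier, in canonical order.
FEATURE_REGISTRY = (
    "prior_lay_date",
    "prior_hatch_date",
    "prior_fledge_date",
    "colony_departure",
    "colony_arrival",
    "wg_arrival",
    "wg_departure",
)


class ConfigError(ValueError):
    """Raised when a simulation or pipeline configuration is inconsistent."""


@dataclass
class GroupActivityProfile:
    """Daily (fly, rest, forage) daytime proportions for one RP group.

    Flying and foraging proportions are piecewise-linear functions of winter
    day (knots as ``(day, value)`` pairs); resting takes the remainder so the
    three proportions sum to one by construction.  Gaussian day-to-day noise
    of standard deviation ``noise_sd`` is added independently to the fly and
    forage proportions before renormalisation.
    """

    fly_knots: Sequence[tuple[float, float]]
    forage_knots: Sequence[tuple[float, float]]
    noise_sd: float = 0.03

    def proportions(self, day: np.ndarray) -> np.ndarray:
        """Noise-free (fly, rest, forage) proportions at winter day(s)."""
        day = np.atleast_1d(np.asarray(day, dtype=float))
        fx, fy = zip(*self.fly_knots)
        gx, gy = zip(*self.forage_knots)
        fly = np.interp(day, fx, fy)
        forage = np.interp(day, gx, gy)
        rest = 1.0 - fly - forage
        out = np.stack([fly, rest, forage], axis=-1)
        if (out < -1e-12).any() or (out > 1 + 1e-12).any():
            raise ConfigError("activity proportions leave [0, 1]")
        return np.clip(out, 0.0, 1.0)


def _default_phenology() -> dict:
    # Means in day offsets from 1 March; prior-season breeding events are
    # earliest for birds that go on to breed successfully (early birds do
    # better), latest for birds that subsequently skip.
    base = {
        "SUCCESS": dict(
            prior_lay_date=(68, 5),
            prior_hatch_date=(119, 5),
            prior_fledge_date=(189, 6),
            colony_departure=(205, 6),
            wg_arrival=(230, 7),
            wg_departure=(345, 8),
            colony_arrival=(385, 7),
        ),
        "FAIL": dict(
            prior_lay_date=(74, 5),
            prior_hatch_date=(125, 5),
            prior_fledge_date=(194, 6),
            colony_departure=(209, 6),
            wg_arrival=(234, 7),
            wg_departure=(348, 8),
            colony_arrival=(389, 7),
        ),
        "SKIP": dict(
            prior_lay_date=(81, 6),
            prior_hatch_date=(132, 6),
            prior_fledge_date=(200, 7),
            colony_departure=(214, 6),
            wg_arrival=(239, 7),
            wg_departure=(352, 8),
            colony_arrival=(395, 7),
        ),
    }
    return base


def _default_activity() -> dict:
    # Skipping birds winter hyperactive: more flying, much more foraging and
    # less resting than successful breeders; failed birds sit in between.
    # The kink at winter day 60 is the mid-winter activity breakpoint.
    return {
        "SUCCESS": GroupActivityProfile(
            fly_knots=[(0, 0.30), (60, 0.22), (170, 0.32)],
            forage_knots=[(0, 0.14), (170, 0.16)],
        ),
        "FAIL": GroupActivityProfile(
            fly_knots=[(0, 0.34), (60, 0.26), (170, 0.36)],
            forage_knots=[(0, 0.20), (170, 0.22)],
        ),
        "SKIP": GroupActivityProfile(
            fly_knots=[(0, 0.38), (60, 0.30), (170, 0.40)],
            forage_knots=[(0, 0.30), (170, 0.36)],
        ),
    }


def _default_psi() -> np.ndarray:
    # Year-to-year breeding-state transitions (rows: from SUCCESS/FAIL/SKIP).
    # Skipping birds have the highest chance of breeding successfully next
    # year, mirroring the carry-over pattern the analysis is built to detect.
    return np.array(
        [
            [0.60, 0.30, 0.10],
            [0.50, 0.30, 0.20],
            [0.79, 0.11, 0.10],
        ]
    )


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Parameters
    ----------
    rp_category_counts
        Logger bird-seasons per RP category (default 64/29/18, total 111).
    n_birds_history_only, n_females_history_only
        Extra individuals monitored for breeding only (default 88, of which
        41 female); they contribute encounter histories but no logger data.
    n_occasions
        Number of annual breeding occasions in the encounter histories.
    phi
        Annual adult survival probability; scalar, per-state mapping, or
        ``(state, sex)`` mapping.
    psi
        3x3 row-stochastic transition matrix among SUCCESS/FAIL/SKIP,
        optionally per sex (``{"F": ..., "M": ...}``).
    p_detect
        Per-occasion detection probability of an alive bird.
    initial_state_probs
        State distribution at first capture (default proportional to the
        64/29/18 RP composition).
    mixture_weights, psi_by_class
        Finite-mixture heterogeneity: class weights and class-specific
        transition matrices.  A single class reduces exactly to the
        homogeneous generator.
    uncertainty
        Probability that an observed bird's state is recorded as
        SEEN_UNKNOWN rather than its true state.
    phenology_means_sds
        Per-RP-group ``{feature: (mean, sd)}`` of event-date offsets.
    activity_profiles
        Per-RP-group :class:`GroupActivityProfile`.
    block_minutes, sunrise_hour, sunset_hour
        Immersion logging block length (must divide 1440) and the fixed
        daytime window.
    forage_band
        Wet-fraction band emitted for foraging blocks (uniform draw).
    """

    rp_category_counts: Mapping[str, int] = field(
        default_factory=lambda: {"SUCCESS": 64, "FAIL": 29, "SKIP": 18}
    )
    n_birds_history_only: int = 88
    n_females_history_only: int = 41
    n_occasions: int = 6
    phi: float | Mapping = 0.90
    psi: np.ndarray | Mapping = field(default_factory=_default_psi)
    p_detect: float = 0.85
    initial_state_probs: Sequence[float] | None = None
    mixture_weights: Sequence[float] = (1.0,)
    psi_by_class: Sequence[np.ndarray] | None = None
    uncertainty: float = 0.0
    staggered_entry: bool = False
    phenology_means_sds: Mapping[str, Mapping[str, tuple]] = field(
        default_factory=_default_phenology
    )
    activity_profiles: Mapping[str, GroupActivityProfile] = field(
        default_factory=_default_activity
    )
    block_minutes: int = 10
    sunrise_hour: int = 8
    sunset_hour: int = 18
    forage_band: tuple[float, float] = (0.2, 0.8)
    base_year: int = 2009
    season_anchor: tuple[int, int] = (3, 1)  # (month, day)
    max_rejections: int = 1000
    seed: int = 0

    # -- resolved views -------------------------------------------------

    @property
    def n_birds_logger(self) -> int:
        return int(sum(self.rp_category_counts.values()))

    def phi_for(self, state: str, sex: str) -> float:
        if isinstance(self.phi, Mapping):
            if (state, sex) in self.phi:
                return float(self.phi[(state, sex)])
            if state in self.phi:
                return float(self.phi[state])
            raise ConfigError(f"phi not defined for state {state!r}")
        return float(self.phi)

    def psi_for(self, sex: str, mixture_class: int = 0) -> np.ndarray:
        if self.psi_by_class is not None:
            mat = np.asarray(self.psi_by_class[mixture_class], dtype=float)
        elif isinstance(self.psi, Mapping):
            mat = np.asarray(self.psi[sex], dtype=float)
        else:
            mat = np.asarray(self.psi, dtype=float)
        return mat

    def initial_probs(self) -> np.ndarray:
        if self.initial_state_probs is not None:
            pr = np.asarray(self.initial_state_probs, dtype=float)
        else:
            counts = np.array(
                [self.rp_category_counts[s] for s in RP_STATES], dtype=float
            )
            pr = counts / counts.sum()
        return pr

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if any(int(v) < 0 for v in self.rp_category_counts.values()):
            raise ConfigError("rp_category_counts must be non-negative")
        if set(self.rp_category_counts) != set(RP_STATES):
            raise ConfigError(f"rp_category_counts must cover {RP_STATES}")
        if self.n_birds_history_only < 0 or self.n_females_history_only < 0:
            raise ConfigError("history-only counts must be non-negative")
        if self.n_females_history_only > self.n_birds_history_only:
            raise ConfigError("more history-only females than individuals")
        if self.n_occasions < 2:
            raise ConfigError("n_occasions must be at least 2")
        if 1440 % self.block_minutes != 0:
            raise ConfigError("block_minutes must divide 1440")
        if not 0 <= self.sunrise_hour < self.sunset_hour <= 24:
            raise ConfigError("need 0 <= sunrise < sunset <= 24")
        if not (0 <= self.forage_band[0] < self.forage_band[1] <= 1):
            raise ConfigError("forage_band must be an ordered sub-band of [0,1]")
        if not 0 <= self.p_detect <= 1:
            raise ConfigError("p_detect must be a probability")
        if not 0 <= self.uncertainty <= 1:
            raise ConfigError("uncertainty must be a probability")
        w = np.asarray(self.mixture_weights, dtype=float)
        if w.min() < 0 or abs(w.sum() - 1.0) > 1e-12:
            raise ConfigError("mixture_weights must be a probability vector")
        if self.psi_by_class is not None and len(self.psi_by_class) != len(w):
            raise ConfigError("psi_by_class length must match mixture_weights")
        n_classes = len(w)
        sexes_to_check = SEXES if isinstance(self.psi, Mapping) else ("F",)
        for c in range(n_classes):
            for sex in sexes_to_check:
                mat = self.psi_for(sex, c)
                if mat.shape != (3, 3):
                    raise ConfigError("psi must be 3x3")
                if (mat < 0).any() or np.abs(mat.sum(axis=1) - 1.0).max() > 1e-12:
                    raise ConfigError("psi rows must each sum to 1 (within 1e-12)")
        for state in RP_STATES:
            for sex in SEXES:
                ph = self.phi_for(state, sex)
                if not 0 <= ph <= 1:
                    raise ConfigError("phi must be a probability")
        pr = self.initial_probs()
        if (pr < 0).any() or abs(pr.sum() - 1.0) > 1e-12:
            raise ConfigError("initial_state_probs must sum to 1")
        for grp in RP_STATES:
            if grp not in self.phenology_means_sds:
                raise ConfigError(f"phenology means missing for group {grp}")
            for feat, (mu, sd) in self.phenology_means_sds[grp].items():
                if sd < 0:
                    raise ConfigError(f"negative SD for {grp}/{feat}")
            if grp not in self.activity_profiles:
                raise ConfigError(f"activity profile missing for group {grp}")
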