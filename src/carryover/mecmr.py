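"""Multi-event capture-mark-recapture (MECMR) model of breeding-state dynamics.

Encounter histories record, per breeding occasion, one of five events:
NOT_SEEN, SEEN_SUCCESS, SEEN_FAIL, SEEN_SKIP or SEEN_UNKNOWN.  Underneath,
each bird follows a latent Markov chain over SUCCESS / FAIL / SKIP / DEAD:
it survives an interval with probability phi (state- and/or sex-dependent),
moves among breeding states by the row-stochastic transition matrix psi
(optionally sex- and year-dependent, optionally mixture-class-specific), and
if alive is detected with probability p; a detected bird's state is recorded
correctly, or as SEEN_UNKNOWN with a fixed uncertainty probability.  DEAD is
absorbing and emits only NOT_SEEN.

The likelihood of a history conditions on the first encounter and is computed
by the hidden-Markov forward recursion; finite-mixture heterogeneity sums
class likelihoods weighted by pi before logging.  Fitting is by quasi-Newton
maximisation on the link scale (logit for probabilities, multinomial logit
for psi rows) from several jittered starts, with Hessian-based standard
errors propagated to the natural scale by the delta method.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit
from statsmodels.tools.numdiff import approx_fprime, approx_hess1

from .simulate import EncounterHistory

N_ALIVE = 3  # SUCCESS, FAIL, SKIP
DEAD = 3
_LINK_BOUND = 15.0


# ---------------------------------------------------------------------------
# specification and parameter layout


@dataclass
class MecmrSpec:
    """Structure of a MECMR model (which effects each parameter carries).

    ``uncertainty`` is the fixed probability that a detected bird's breeding
    state is recorded as SEEN_UNKNOWN; it is configuration, not an estimated
    parameter.  Year dependence enters as fixed occasion effects: a common
    shift of the non-reference transition logits per interval (interval 0 is
    the reference).  Mixture heterogeneity gives each latent class its own
    transition matrix, weighted by pi.
    """

    phi_by_state: bool = False
    phi_by_sex: bool = False
    p_by_sex: bool = False
    psi_by_sex: bool = False
    psi_by_year: bool = False
    n_mixture_classes: int = 1
    uncertainty: float = 0.0
    name: str = ""

    def label(self) -> str:
        if self.name:
            return self.name
        bits = []
        bits.append("phi(" + "+".join(
            [x for x, on in (("state", self.phi_by_state), ("sex", self.phi_by_sex)) if on]
        ) + ")" if (self.phi_by_state or self.phi_by_sex) else "phi(.)")
        bits.append("p(sex)" if self.p_by_sex else "p(.)")
        psi_terms = [x for x, on in (("sex", self.psi_by_sex), ("year", self.psi_by_year)) if on]
        bits.append("psi(state" + ("+" + "+".join(psi_terms) if psi_terms else "") + ")")
        if self.n_mixture_classes > 1:
            bits.append(f"mix{self.n_mixture_classes}")
        return " ".join(bits)

    def toggles(self) -> frozenset:
        on = {
            k
            for k, v in asdict(self).items()
            if isinstance(v, bool) and v
        }
        if self.n_mixture_classes > 1:
            on.add(f"mixture{self.n_mixture_classes}")
        return frozenset(on)


class _Layout:
    """Maps the flat link-scale vector theta onto natural-scale parameters."""

    def __init__(self, spec: MecmrSpec, n_occasions: int):
        self.spec = spec
        self.n_occasions = n_occasions
        self.n_intervals = n_occasions - 1
        C = spec.n_mixture_classes
        self.C = C
        self.n_phi = (3 if spec.phi_by_state else 1) * (2 if spec.phi_by_sex else 1)
        self.n_p = 2 if spec.p_by_sex else 1
        self.n_psi_sex = 2 if spec.psi_by_sex else 1
        self.n_psi = C * self.n_psi_sex * 3 * 2
        self.n_year = (self.n_intervals - 1) if spec.psi_by_year else 0
        self.n_pi = C - 1
        self.n_params = self.n_phi + self.n_p + self.n_psi + self.n_year + self.n_pi
        idx = np.cumsum([0, self.n_phi, self.n_p, self.n_psi, self.n_year, self.n_pi])
        (self.s_phi, self.s_p, self.s_psi, self.s_year, self.s_pi) = (
            slice(idx[i], idx[i + 1]) for i in range(5)
        )

    def default_theta(self) -> np.ndarray:
        th = np.zeros(self.n_params)
        th[self.s_phi] = logit(0.85)
        th[self.s_p] = logit(0.7)
        return th

    def natural(self, theta: np.ndarray):
        """Return (phi[2,3], p[2], psi[C,2,n_intervals,3,3], pi[C])."""
        spec = self.spec
        C = self.C
        phi_raw = expit(theta[self.s_phi])
        shape = (3 if spec.phi_by_state else 1, 2 if spec.phi_by_sex else 1)
        phi = np.broadcast_to(phi_raw.reshape(shape), (3, 2)).T.copy()  # (sex, state)
        p_raw = expit(theta[self.s_p])
        p = np.broadcast_to(p_raw, (2,)).copy() if spec.p_by_sex else np.full(2, p_raw[0])

        eta = theta[self.s_psi].reshape(C, self.n_psi_sex, 3, 2)
        deltas = np.zeros(self.n_intervals)
        if self.n_year:
            deltas[1:] = theta[self.s_year]
        full = np.zeros((C, self.n_psi_sex, self.n_intervals, 3, 3))
        for t in range(self.n_intervals):
            e = np.concatenate(
                [eta + deltas[t], np.zeros((C, self.n_psi_sex, 3, 1))], axis=-1
            )
            e = e - e.max(axis=-1, keepdims=True)
            ex = np.exp(e)
            full[:, :, t] = ex / ex.sum(axis=-1, keepdims=True)
        if self.n_psi_sex == 1:
            full = np.broadcast_to(full, (C, 2) + full.shape[2:]).copy()

        if C > 1:
            w = np.concatenate([[0.0], theta[self.s_pi]])
            w = w - w.max()
            pi = np.exp(w) / np.exp(w).sum()
        else:
            pi = np.ones(1)
        return phi, p, full, pi

    def natural_named(self, theta: np.ndarray):
        """Flat natural-scale vector with names (for SEs and CIs)."""
        phi, p, psi, pi = self.natural(theta)
        names, vals = [], []
        states = ("SUCCESS", "FAIL", "SKIP")
        phi_states = states if self.spec.phi_by_state else ("ALL",)
        phi_sexes = ("F", "M") if self.spec.phi_by_sex else ("ALL",)
        for si, s in enumerate(phi_states):
            for xi, x in enumerate(phi_sexes):
                names.append(f"phi[{s},{x}]")
                vals.append(phi[xi if self.spec.phi_by_sex else 0,
                                si if self.spec.phi_by_state else 0])
        for xi, x in enumerate(("F", "M") if self.spec.p_by_sex else ("ALL",)):
            names.append(f"p[{x}]")
            vals.append(p[xi if self.spec.p_by_sex else 0])
        psi_sexes = ("F", "M") if self.spec.psi_by_sex else ("ALL",)
        for c in range(self.C):
            for xi, x in enumerate(psi_sexes):
                for i, sf in enumerate(states):
                    for j, st in enumerate(states):
                        tag = f"psi[{sf}->{st}"
                        if self.spec.psi_by_sex:
                            tag += f",{x}"
                        if self.C > 1:
                            tag += f",c{c}"
                        names.append(tag + "]")
                        vals.append(psi[c, xi if self.spec.psi_by_sex else 0, 0, i, j])
        for c in range(self.C - 1 if self.C > 1 else 0):
            names.append(f"pi[c{c + 1}]")
            vals.append(pi[c + 1])
        return names, np.array(vals, dtype=float)


# ---------------------------------------------------------------------------
# forward likelihood


def _obs_matrix(p: float, u: float) -> np.ndarray:
    """P(event | state) for alive states and DEAD; columns index events."""
    O = np.zeros((4, 5))
    for s in range(N_ALIVE):
        O[s, 0] = 1.0 - p
        O[s, 1 + s] = p * (1.0 - u)
        O[s, 4] = p * u
    O[DEAD, 0] = 1.0
    return O


def _first_capture_weights(u: float) -> np.ndarray:
    """State weights at first capture given each (observed) event."""
    B = np.zeros((5, N_ALIVE))
    for s in range(N_ALIVE):
        B[1 + s, s] = 1.0 - u
        B[4, s] = u
    rows = B.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        B = np.where(rows > 0, B / rows, 0.0)
    return B


def _transition_matrix(phi: np.ndarray, psi_t: np.ndarray) -> np.ndarray:
    T = np.zeros((4, 4))
    T[:N_ALIVE, :N_ALIVE] = phi[:, None] * psi_t
    T[:N_ALIVE, DEAD] = 1.0 - phi
    T[DEAD, DEAD] = 1.0
    return T


def _forward_batch(
    events: np.ndarray,
    first: int,
    phi: np.ndarray,
    p: float,
    psi: np.ndarray,
    u: float,
) -> np.ndarray:
    """Vectorised forward likelihood for a batch of equally-released histories.

    ``events``: (n, T) integer event codes; ``psi``: (n_intervals, 3, 3).
    Returns per-history likelihoods conditional on the first encounter.
    """
    n, T = events.shape
    B0 = _first_capture_weights(u)
    alpha = np.zeros((n, 4))
    alpha[:, :N_ALIVE] = B0[events[:, first]]
    O = _obs_matrix(p, u)
    for t in range(first + 1, T):
        Tm = _transition_matrix(phi, psi[t - 1])
        alpha = alpha @ Tm
        alpha = alpha * O[:, events[:, t]].T
    return alpha.sum(axis=1)


def _validate_simplex(mat: np.ndarray, what: str) -> None:
    mat = np.asarray(mat, dtype=float)
    if (mat < -1e-12).any() or np.abs(mat.sum(axis=-1) - 1.0).max() > 1e-9:
        raise ValueError(f"{what} rows must be probabilities summing to 1")


def history_loglik(history: EncounterHistory, params: Mapping) -> float:
    """Log-likelihood contribution of one encounter history.

    ``params`` carries natural-scale values: ``phi`` (scalar or length-3 per
    alive state), ``psi`` (3x3, or a list of class matrices), ``p``, optional
    ``mixture_weights`` and ``uncertainty``.  Mixture class likelihoods are
    combined as sum_c pi_c L_c before taking the log.  Returns ``-inf`` for
    an impossible history.
    """
    events = np.asarray(history.events, dtype=int)[None, :]
    first = history.first_occasion
    if history.events[first] == 0:
        raise ValueError("history must start with an observed event")
    phi = np.broadcast_to(np.asarray(params["phi"], dtype=float), (N_ALIVE,)).copy()
    if (phi < 0).any() or (phi > 1).any():
        raise ValueError("phi must lie in [0, 1]")
    p = float(params["p"])
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    u = float(params.get("uncertainty", 0.0))
    psi_in = params["psi"]
    psi_list = (
        [np.asarray(m, dtype=float) for m in psi_in]
        if isinstance(psi_in, (list, tuple))
        else [np.asarray(psi_in, dtype=float)]
    )
    for m in psi_list:
        _validate_simplex(m, "psi")
    pi = np.asarray(params.get("mixture_weights", [1.0] * len(psi_list)), dtype=float)
    _validate_simplex(pi[None, :], "mixture_weights")
    T = events.shape[1]
    L = 0.0
    for c, psi_c in enumerate(psi_list):
        psi_stack = np.broadcast_to(psi_c, (T - 1, 3, 3))
        L += pi[c] * _forward_batch(events, first, phi, p, psi_stack, u)[0]
    return float(np.log(L)) if L > 0 else -np.inf


# ---------------------------------------------------------------------------
# data packing


def _pack(histories: Sequence[EncounterHistory]):
    """Group histories by (sex, first occasion) and collapse duplicates."""
    T = len(histories[0].events)
    groups: dict[tuple[int, int], list[np.ndarray]] = {}
    for h in histories:
        if len(h.events) != T:
            raise ValueError("all histories must span the same occasions")
        sex_idx = 0 if h.sex == "F" else 1
        groups.setdefault((sex_idx, h.first_occasion), []).append(h.events)
    packed = {}
    for key, evs in groups.items():
        arr = np.vstack(evs)
        uniq, counts = np.unique(arr, axis=0, return_counts=True)
        packed[key] = (uniq, counts.astype(float))
    return packed, T


def _data_signature(histories: Sequence[EncounterHistory]) -> str:
    h = hashlib.sha256()
    for hist in sorted(histories, key=lambda x: x.bird_id):
        h.update(hist.bird_id.encode())
        h.update(hist.sex.encode())
        h.update(np.ascontiguousarray(hist.events).tobytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# fitting


@dataclass
class MecmrFit:
    """Maximum-likelihood fit of one MECMR model."""

    spec: MecmrSpec
    theta: np.ndarray
    loglik: float
    n_params: int
    aic: float
    se: np.ndarray | None
    natural: dict
    natural_se: dict | None
    converged: bool
    n_starts: int
    boundary: list
    data_signature: str
    n_histories: int
    cov: np.ndarray | None = field(default=None, repr=False)
    layout: object = field(default=None, repr=False)

    def wald_ci(self, level: float = 0.95) -> pd.DataFrame:
        """Wald intervals for every reported (probability) parameter.

        Intervals are built on the logit scale and back-transformed, the
        usual convention for capture-recapture parameters: it respects the
        [0, 1] range and behaves better than a symmetric natural-scale
        interval when an estimate sits near a boundary.
        """
        if self.natural_se is None:
            raise ValueError("standard errors unavailable (non-PD Hessian)")
        from scipy.special import expit, logit
        from scipy.stats import norm

        z = float(norm.ppf(1 - (1 - level) / 2))
        rows = []
        for k, v in self.natural.items():
            s = self.natural_se[k]
            if 0 < v < 1 and s > 0:
                s_link = s / (v * (1 - v))  # delta method onto the logit scale
                lo = float(expit(logit(v) - z * s_link))
                hi = float(expit(logit(v) + z * s_link))
            else:  # boundary estimate: interval degenerates
                lo, hi = v, v
            rows.append({"param": k, "estimate": v, "se": s, "lo": lo, "hi": hi})
        return pd.DataFrame(rows)


class MecmrModel:
    """Estimator wrapper: configure a spec, ``fit`` encounter histories.

    Parameters mirror :class:`MecmrSpec` plus optimisation controls; fitted
    attributes (trailing underscore) expose the MLE, covariance and
    natural-scale summaries.
    """

    def __init__(
        self,
        phi_by_state: bool = False,
        phi_by_sex: bool = False,
        p_by_sex: bool = False,
        psi_by_sex: bool = False,
        psi_by_year: bool = False,
        n_mixture_classes: int = 1,
        uncertainty: float = 0.0,
        n_starts: int = 10,
        jitter_sd: float = 0.5,
        random_state=None,
        name: str = "",
    ):
        self.phi_by_state = phi_by_state
        self.phi_by_sex = phi_by_sex
        self.p_by_sex = p_by_sex
        self.psi_by_sex = psi_by_sex
        self.psi_by_year = psi_by_year
        self.n_mixture_classes = n_mixture_classes
        self.uncertainty = uncertainty
        self.n_starts = n_starts
        self.jitter_sd = jitter_sd
        self.random_state = random_state
        self.name = name

    def get_params(self, deep=True):
        return {
            k: getattr(self, k)
            for k in (
                "phi_by_state", "phi_by_sex", "p_by_sex", "psi_by_sex",
                "psi_by_year", "n_mixture_classes", "uncertainty",
                "n_starts", "jitter_sd", "random_state", "name",
            )
        }

    def set_params(self, **kw):
        for k, v in kw.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @property
    def spec(self) -> MecmrSpec:
        return MecmrSpec(
            phi_by_state=self.phi_by_state,
            phi_by_sex=self.phi_by_sex,
            p_by_sex=self.p_by_sex,
            psi_by_sex=self.psi_by_sex,
            psi_by_year=self.psi_by_year,
            n_mixture_classes=self.n_mixture_classes,
            uncertainty=self.uncertainty,
            name=self.name,
        )

    # --------------------------------------------------------------

    def _nll(self, theta, layout, packed):
        phi, p, psi, pi = layout.natural(theta)
        u = self.uncertainty
        total = 0.0
        for (sex_idx, first), (ev, counts) in packed.items():
            L = np.zeros(len(counts))
            for c in range(layout.C):
                L += pi[c] * _forward_batch(
                    ev, first, phi[sex_idx], p[sex_idx], psi[c, sex_idx], u
                )
            total += float(counts @ np.log(np.maximum(L, 1e-300)))
        return -total

    def fit(self, histories: Sequence[EncounterHistory], compute_se: bool = True):
        if len(histories) == 0:
            raise ValueError("no histories supplied")
        packed, T = _pack(histories)
        layout = _Layout(self.spec, T)
        n_events = sum(
            (len(h.events) - h.first_occasion - 1) for h in histories
        )
        if layout.n_params >= max(n_events, 1):
            warnings.warn(
                f"{layout.n_params} parameters for {n_events} post-release "
                "events: model may be unidentifiable"
            )
        rng = np.random.default_rng(self.random_state)
        base = layout.default_theta()
        bounds = [(-_LINK_BOUND, _LINK_BOUND)] * layout.n_params
        best = None
        for s in range(max(int(self.n_starts), 1)):
            theta0 = base if s == 0 else base + rng.normal(
                0, self.jitter_sd, layout.n_params
            )
            if not np.isfinite(self._nll(theta0, layout, packed)):
                continue
            res = optimize.minimize(
                self._nll,
                theta0,
                args=(layout, packed),
                method="L-BFGS-B",
                bounds=bounds,
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise RuntimeError("no finite-likelihood starting point found")

        self.layout_ = layout
        self.theta_ = best.x
        self.loglik_ = -float(best.fun)
        self.n_params_ = layout.n_params
        self.aic_ = 2 * layout.n_params - 2 * self.loglik_
        self.converged_ = bool(best.success)
        self.data_signature_ = _data_signature(histories)
        self.n_histories_ = len(histories)
        names, vals = layout.natural_named(self.theta_)
        self.natural_ = dict(zip(names, vals))
        # survival/detection estimates indistinguishable from 0 or 1
        self.boundary_ = [
            n
            for n, v in zip(names[: layout.n_phi + layout.n_p],
                            vals[: layout.n_phi + layout.n_p])
            if v <= 1e-6 or v >= 1 - 1e-6
        ]

        self.cov_ = None
        self.natural_se_ = None
        self.se_ = None
        if compute_se:
            try:
                H = approx_hess1(self.theta_, self._nll, args=(layout, packed))
                evals = np.linalg.eigvalsh((H + H.T) / 2)
                if evals.min() <= 0:
                    warnings.warn("non-positive-definite Hessian: SEs unavailable")
                else:
                    self.cov_ = np.linalg.inv((H + H.T) / 2)
                    self.se_ = np.sqrt(np.diag(self.cov_))
                    J = approx_fprime(
                        self.theta_,
                        lambda th: layout.natural_named(th)[1],
                        centered=True,
                    )
                    cov_nat = J @ self.cov_ @ J.T
                    ses = np.sqrt(np.clip(np.diag(cov_nat), 0, None))
                    self.natural_se_ = dict(zip(names, ses))
            except np.linalg.LinAlgError:
                warnings.warn("Hessian inversion failed: SEs unavailable")
        return self

    def result(self) -> MecmrFit:
        return MecmrFit(
            spec=self.spec,
            theta=self.theta_.copy(),
            loglik=self.loglik_,
            n_params=self.n_params_,
            aic=self.aic_,
            se=None if self.se_ is None else self.se_.copy(),
            natural=dict(self.natural_),
            natural_se=None if self.natural_se_ is None else dict(self.natural_se_),
            converged=self.converged_,
            n_starts=self.n_starts,
            boundary=list(self.boundary_),
            data_signature=self.data_signature_,
            n_histories=self.n_histories_,
            cov=None if self.cov_ is None else self.cov_.copy(),
            layout=self.layout_,
        )


def fit_mecmr(
    histories: Sequence[EncounterHistory],
    spec: MecmrSpec | None = None,
    n_starts: int = 10,
    seed=None,
    compute_se: bool = True,
) -> MecmrFit:
    """Fit a MECMR model and return its :class:`MecmrFit` summary."""
    spec = spec or MecmrSpec()
    model = MecmrModel(
        phi_by_state=spec.phi_by_state,
        phi_by_sex=spec.phi_by_sex,
        p_by_sex=spec.p_by_sex,
        psi_by_sex=spec.psi_by_sex,
        psi_by_year=spec.psi_by_year,
        n_mixture_classes=spec.n_mixture_classes,
        uncertainty=spec.uncertainty,
        n_starts=n_starts,
        random_state=seed,
        name=spec.name,
    ).fit(histories, compute_se=compute_se)
    return model.result()


# ---------------------------------------------------------------------------
# derived quantities


def model_table(fits: Sequence[MecmrFit]) -> pd.DataFrame:
    """AIC-ranked model comparison with delta-AIC and nesting flags."""
    if not fits:
        raise ValueError("no fits supplied")
    sigs = {f.data_signature for f in fits}
    if len(sigs) != 1:
        raise ValueError("fits were made on different datasets")
    rows = sorted(fits, key=lambda f: f.aic)
    best = rows[0].aic
    toggles = [f.spec.toggles() for f in rows]
    out = []
    for i, f in enumerate(rows):
        nested_in = [
            rows[j].spec.label()
            for j in range(len(rows))
            if j != i and toggles[i] < toggles[j]
        ]
        out.append(
            {
                "model": f.spec.label(),
                "n_params": f.n_params,
                "loglik": f.loglik,
                "aic": f.aic,
                "delta_aic": f.aic - best,
                "converged": f.converged,
                "nested_in": ";".join(nested_in),
            }
        )
    return pd.DataFrame(out)


def stationary_distribution(psi: np.ndarray) -> np.ndarray:
    """Stationary (left-eigenvector) distribution of a 3x3 chain.

    Raises on reducible or periodic chains, where the long-run distribution
    is undefined or start-dependent.
    """
    psi = np.asarray(psi, dtype=float)
    _validate_simplex(psi, "psi")
    evals, vecs = np.linalg.eig(psi.T)
    close = np.isclose(evals, 1.0, atol=1e-9)
    if close.sum() != 1:
        raise ValueError("reducible transition matrix: stationary distribution not unique")
    if (np.abs(evals[~close]) > 1 - 1e-12).any():
        raise ValueError("periodic transition matrix: no limiting distribution")
    v = np.real(vecs[:, close][:, 0])
    v = v / v.sum()
    if (v < -1e-12).any():
        raise ValueError("invalid stationary vector")
    return np.clip(v, 0, None) / np.clip(v, 0, None).sum()


def _psi_from_fit(fit: MecmrFit, theta: np.ndarray, sex: int, mixture_class: int):
    _, _, psi, _ = fit.layout.natural(theta)
    return psi[mixture_class, sex, 0]


def longrun_success(
    fit: MecmrFit,
    mode: str = "next_year",
    n_boot: int = 1000,
    seed=None,
    sex: int = 0,
    mixture_class: int = 0,
) -> pd.DataFrame:
    """Per-state probability of breeding successfully, with 95% CI.

    ``next_year`` reports the one-step transition probability into SUCCESS
    from each current state; ``stationary`` reports the equilibrium
    probability of the SUCCESS state of the survival-conditioned chain (the
    same from every starting state).  Confidence intervals are percentile
    intervals over parametric-bootstrap draws of the MLE sampling
    distribution.
    """
    if mode not in ("next_year", "stationary"):
        raise ValueError(f"unknown mode {mode!r}")
    if not fit.converged:
        warnings.warn("fit did not converge; derived quantities may be unreliable")
    states = ("SUCCESS", "FAIL", "SKIP")
    psi = _psi_from_fit(fit, fit.theta, sex, mixture_class)

    def quantity(mat):
        if mode == "next_year":
            return mat[:, 0]
        return np.full(3, stationary_distribution(mat)[0])

    est = quantity(psi)
    lo = np.full(3, np.nan)
    hi = np.full(3, np.nan)
    if fit.cov is not None and n_boot > 0:
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(
            fit.theta, fit.cov, size=n_boot, check_valid="ignore", method="svd"
        )
        samples = []
        for th in draws:
            try:
                samples.append(quantity(_psi_from_fit(fit, th, sex, mixture_class)))
            except ValueError:
                continue
        if samples:
            arr = np.vstack(samples)
            lo = np.percentile(arr, 2.5, axis=0)
            hi = np.percentile(arr, 97.5, axis=0)
    return pd.DataFrame(
        {
            "from_state": states,
            "prob_success": est,
            "ci_lo": lo,
            "ci_hi": hi,
            "mode": mode,
        }
    )


def empirical_transition_matrix(
    histories: Sequence[EncounterHistory],
) -> tuple[np.ndarray, np.ndarray, int]:
    """Observed year-to-year RP state-change frequencies.

    Counts consecutive occasions where both states were determinately
    observed (SEEN_SUCCESS/FAIL/SKIP); pairs interrupted by NOT_SEEN or
    SEEN_UNKNOWN are excluded and reported as the third return value.
    Returns (row-normalised 3x3 matrix, raw count matrix, n_excluded).
    """
    counts = np.zeros((3, 3))
    excluded = 0
    for h in histories:
        ev = np.asarray(h.events)
        for t in range(h.first_occasion, len(ev) - 1):
            a, b = ev[t], ev[t + 1]
            det_a, det_b = 1 <= a <= 3, 1 <= b <= 3
            if det_a and det_b:
                counts[a - 1, b - 1] += 1
            elif det_a and not det_b:
                excluded += 1  # origin observed, follow-up missed/indeterminate
    if counts.sum() == 0:
        raise ValueError("no consecutive observed state pairs")
    rowsum = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(rowsum > 0, counts / rowsum, np.nan)
    return freq, counts, excluded
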