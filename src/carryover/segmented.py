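"""Segmented (breakpoint) regression of daily flight activity against date.

Fits piecewise-linear models y = a + b x + sum_j d_j (x - tau_j)_+ by the
iterative-linearisation scheme of segmented regression: the model is
augmented with indicator terms whose coefficients measure the gap at the
current breakpoint guess, and each breakpoint is updated by the ratio of the
indicator coefficient to the hinge coefficient until the update is below
tolerance.  Because the profile RSS surface is multimodal, the fit is
re-initialised from nonparametric-bootstrap refits ("bootstrap restarting"),
keeping the best solution found.  The number of breakpoints is chosen by an
information criterion over k = 0..max_k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


@dataclass
class BreakpointFit:
    """Result of a segmented fit (possibly after model selection)."""

    n_breakpoints: int
    tau: np.ndarray
    tau_se: np.ndarray
    intercept: float
    slopes: np.ndarray  # per-segment slopes, length n_breakpoints + 1
    rss: float
    converged: bool
    n_restarts_used: int
    selection_scores: dict = field(default_factory=dict)


def _hinge_design(x: np.ndarray, tau: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for t in tau:
        cols.append(np.clip(x - t, 0.0, None))
    return np.column_stack(cols)


def _ols_rss(X: np.ndarray, y: np.ndarray):
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


class SegmentedRegression(RegressorMixin, BaseEstimator):
    """Piecewise-linear regression with a fixed number of breakpoints.

    Parameters
    ----------
    n_breakpoints : int
        Number of slope changes to fit (0 gives ordinary least squares).
    n_restarts : int
        Bootstrap-restart attempts used to escape local optima.
    max_iter, tol : int, float
        Iterative-linearisation controls; the fit is flagged non-converged
        (best iterate kept) if the breakpoint update never falls below
        ``tol``.
    random_state : int or None
        Seeds the bootstrap resampling.

    Attributes
    ----------
    breakpoints_ : ndarray of shape (n_breakpoints,)
        Estimated breakpoint positions, strictly increasing, strictly inside
        the observed x-range.
    breakpoint_ses_ : ndarray
        Delta-method standard errors of the breakpoints.
    intercept_, coef_ : float, ndarray
        Intercept, and hinge coefficients ``[b, d_1 .. d_k]`` of the model
        ``a + b x + sum d_j (x - tau_j)_+``.
    slopes_ : ndarray of shape (n_breakpoints + 1,)
        Per-segment slopes (cumulative sums of the hinge coefficients).
    rss_ : float
    converged_ : bool
    n_restarts_used_ : int
    """

    def __init__(
        self,
        n_breakpoints: int = 1,
        n_restarts: int = 10,
        max_iter: int = 50,
        tol: float = 1e-6,
        random_state=None,
    ):
        self.n_breakpoints = n_breakpoints
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _iterate(self, x, y, tau0, lo, hi):
        """One iterative-linearisation run from starting breakpoints tau0.

        Returns (tau, rss, converged); rss is inf if the run degenerates.
        """
        k = len(tau0)
        tau = np.sort(np.asarray(tau0, dtype=float))
        min_gap = max((hi - lo) * 1e-3, 1e-9)

        def _separate(t):
            t = np.clip(np.sort(t), lo, hi)
            if k > 1 and np.min(np.diff(t)) < min_gap:
                # collapse of two breakpoints makes the design singular
                t = np.clip(np.maximum.accumulate(t + np.arange(k) * min_gap), lo, hi)
            return t

        _, rss = _ols_rss(_hinge_design(x, tau), y)
        best = (rss, tau.copy(), False)
        for _ in range(self.max_iter):
            U = [np.clip(x - t, 0.0, None) for t in tau]
            V = [-(x > t).astype(float) for t in tau]
            X = np.column_stack([np.ones_like(x), x] + U + V)
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            d = beta[2 : 2 + k]
            g = beta[2 + k :]
            with np.errstate(divide="ignore", invalid="ignore"):
                step = np.where(np.abs(d) > 1e-12, g / d, 0.0)
            # step-halving keeps the RSS non-increasing (the raw update can
            # oscillate around the optimum)
            new_tau, new_rss = tau, rss
            for _halve in range(12):
                cand = _separate(tau + step)
                _, rss_c = _ols_rss(_hinge_design(x, cand), y)
                if rss_c <= rss + 1e-15:
                    new_tau, new_rss = cand, rss_c
                    break
                step = step / 2
            delta = np.max(np.abs(new_tau - tau))
            tau, rss = new_tau, new_rss
            if rss < best[0]:
                best = (rss, tau.copy(), False)
            if delta < self.tol:
                return tau, rss, True
        return best[1], best[0], False

    def _tau_ses(self, x, y, tau):
        """Delta-method SEs from the augmented design at the solution."""
        k = len(tau)
        U = [np.clip(x - t, 0.0, None) for t in tau]
        V = [-(x > t).astype(float) for t in tau]
        X = np.column_stack([np.ones_like(x), x] + U + V)
        beta, rss = _ols_rss(X, y)
        n, p = X.shape
        if n <= p:
            return np.full(k, np.nan)
        sigma2 = rss / (n - p)
        try:
            cov = sigma2 * np.linalg.pinv(X.T @ X)
        except np.linalg.LinAlgError:
            return np.full(k, np.nan)
        ses = np.empty(k)
        for j in range(k):
            di, gi = 2 + j, 2 + k + j
            d = beta[di]
            if abs(d) < 1e-12:
                ses[j] = np.nan
                continue
            g = beta[gi]
            var = (
                cov[gi, gi] / d**2
                + g**2 * cov[di, di] / d**4
                - 2 * g * cov[gi, di] / d**3
            )
            ses[j] = np.sqrt(var) if var > 0 else np.nan
        return ses

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        k = int(self.n_breakpoints)
        if x.shape != y.shape:
            raise ValueError("x and y must have equal length")
        order = np.argsort(x)
        x, y = x[order], y[order]
        if len(x) < 2 * (k + 2):
            raise ValueError(
                f"need at least {2 * (k + 2)} points for {k} breakpoints, got {len(x)}"
            )
        if np.ptp(y) == 0:
            raise ValueError("degenerate fit: all responses identical")
        rng = np.random.default_rng(self.random_state)
        self.n_features_in_ = 1

        if k == 0:
            beta, rss = _ols_rss(np.column_stack([np.ones_like(x), x]), y)
            self.breakpoints_ = np.empty(0)
            self.breakpoint_ses_ = np.empty(0)
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:].copy()
            self.slopes_ = np.array([beta[1]])
            self.rss_ = rss
            self.converged_ = True
            self.n_restarts_used_ = 0
            return self

        xs = np.sort(np.unique(x))
        lo, hi = xs[2], xs[-3]  # breakpoints constrained inside the data
        if lo >= hi:
            raise ValueError("x-range too narrow to place interior breakpoints")

        tau0 = np.quantile(x, np.linspace(0, 1, k + 2)[1:-1])
        tau0 = np.clip(tau0, lo, hi)
        tau, rss, conv = self._iterate(x, y, tau0, lo, hi)
        best = (rss, tau, conv)
        restarts_used = 0
        n = len(x)
        for _ in range(int(self.n_restarts)):
            idx = rng.integers(0, n, size=n)
            xb, yb = x[idx], y[idx]
            ob = np.argsort(xb)
            xb, yb = xb[ob], yb[ob]
            if np.ptp(yb) == 0 or len(np.unique(xb)) < k + 4:
                continue
            try:
                tau_b, _, _ = self._iterate(xb, yb, best[1], lo, hi)
            except np.linalg.LinAlgError:
                continue
            tau_r, rss_r, conv_r = self._iterate(x, y, tau_b, lo, hi)
            restarts_used += 1
            if rss_r < best[0] - 1e-12:
                best = (rss_r, tau_r, conv_r)

        rss, tau, conv = best[0], best[1], best[2]
        beta, rss = _ols_rss(_hinge_design(x, tau), y)
        self.breakpoints_ = tau
        self.breakpoint_ses_ = self._tau_ses(x, y, tau)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.slopes_ = np.cumsum(beta[1:])
        self.rss_ = float(rss)
        self.converged_ = bool(conv)
        self.n_restarts_used_ = restarts_used
        return self

    def predict(self, X):
        check_is_fitted(self, "rss_")
        x = np.asarray(X, dtype=float).ravel()
        return _hinge_design(x, self.breakpoints_) @ np.concatenate(
            [[self.intercept_], self.coef_]
        )

    def to_result(self, selection_scores=None) -> BreakpointFit:
        check_is_fitted(self, "rss_")
        return BreakpointFit(
            n_breakpoints=len(self.breakpoints_),
            tau=self.breakpoints_.copy(),
            tau_se=self.breakpoint_ses_.copy(),
            intercept=self.intercept_,
            slopes=self.slopes_.copy(),
            rss=self.rss_,
            converged=self.converged_,
            n_restarts_used=self.n_restarts_used_,
            selection_scores=dict(selection_scores or {}),
        )


def fit_segmented(
    x, y, n_breakpoints: int, n_restarts: int = 10, seed=None
) -> BreakpointFit:
    """Fit a piecewise-linear model with a fixed breakpoint count."""
    est = SegmentedRegression(
        n_breakpoints=n_breakpoints, n_restarts=n_restarts, random_state=seed
    ).fit(x, y)
    return est.to_result()


def select_n_breakpoints(
    x,
    y,
    max_k: int = 2,
    criterion: str = "BIC",
    n_restarts: int = 10,
    seed=None,
) -> BreakpointFit:
    """Choose the breakpoint count k in 0..max_k by information criterion.

    A k-breakpoint model spends 2 + 2k mean parameters plus one variance;
    ties in the criterion are broken toward smaller k.  The winning fit is
    returned with per-k criterion values in ``selection_scores``.
    """
    if max_k < 0:
        raise ValueError("max_k must be >= 0")
    criterion = criterion.upper()
    if criterion not in ("BIC", "AIC"):
        raise ValueError(f"unknown criterion {criterion!r}")
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    scores: dict[int, float] = {}
    fits: dict[int, SegmentedRegression] = {}
    for k in range(max_k + 1):
        if n < 2 * (k + 2):
            break
        est = SegmentedRegression(
            n_breakpoints=k, n_restarts=n_restarts, random_state=seed
        ).fit(x, y)
        n_params = 2 + 2 * k + 1
        # floor the RSS so numerically-exact fits of different k tie (and the
        # tie then resolves toward the smaller model via the penalty)
        rss = max(est.rss_, float(np.var(y)) * n * 1e-20, np.finfo(float).tiny)
        if criterion == "BIC":
            scores[k] = n * np.log(rss / n) + n_params * np.log(n)
        else:
            scores[k] = n * np.log(rss / n) + 2 * n_params
        fits[k] = est
    if not fits:
        raise ValueError("too few points for any candidate model")
    smin = min(scores.values())
    tol = 1e-9 * max(1.0, abs(smin))
    best_k = min(k for k, s in scores.items() if s <= smin + tol)
    return fits[best_k].to_result(selection_scores=scores)
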