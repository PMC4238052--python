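"""Psychometric fitting and behavioral summaries.

The choice curve P(fast | speed) is modeled with a four-parameter
Naka-Rushton function

    P(s) = lower + (upper - lower) * s^e / (s^e + s50^e)

fit by binomial maximum likelihood. The two asymptotes absorb lapses, so
curves need not reach 0/1. The point of subjective equality (PSE) — the
speed at which "fast" and "slow" choices are equally likely — is the
numerical root of P(s) = 0.5, which for symmetric asymptotes equals s50.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .task import TaskConfig

__all__ = [
    "NakaRushtonPsychometric", "PsychometricFit", "UndefinedPSEError",
    "naka_rushton", "fit_psychometric", "compute_pse", "behavioral_rates",
    "fit_behavior",
]

_EPS = 1e-9


class UndefinedPSEError(ValueError):
    """Raised when 0.5 does not lie between the fitted asymptotes."""


def naka_rushton(s, lower: float, upper: float, s50: float,
                 exponent: float) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    # log-space form: s^e / (s^e + s50^e) = 1 / (1 + (s50/s)^e),
    # stable for steep exponents where s^e overflows
    with np.errstate(divide="ignore"):
        z = exponent * (np.log(s50) - np.log(s))
    ratio = 1.0 / (1.0 + np.exp(np.clip(z, -700.0, 700.0)))
    return lower + (upper - lower) * ratio


def _binomial_nll(params, s, k, n):
    lower, upper, s50, e = params
    p = np.clip(naka_rushton(s, lower, upper, s50, e), _EPS, 1 - _EPS)
    return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


class NakaRushtonPsychometric(RegressorMixin, BaseEstimator):
    """Binomial maximum-likelihood Naka-Rushton psychometric curve.

    Parameters
    ----------
    exponent_starts : tuple of float
        Multi-start grid for the exponent; the fit is non-convex and a
        single start can latch onto a shallow or step-like solution.
    max_lapse : float
        Upper bound on ``lower`` and on ``1 - upper``.
    degenerate_loglik_margin : float
        The fit is flagged degenerate when it improves on a constant-rate
        model by less than this many log-likelihood units (the curve is
        then unidentifiable — e.g. responses constant at 0.5).

    Attributes
    ----------
    lower_, upper_, s50_, exponent_ : float
        Fitted parameters.
    pse_ : float
        Speed at which P = 0.5 (NaN when degenerate/undefined).
    loglik_ : float
        Maximized binomial log-likelihood.
    degenerate_ : bool
        True when the curve is unidentifiable from the data.

    Examples
    --------
    >>> speeds = np.array([2, 4, 6, 8, 10, 12, 14, 16.])
    >>> p = naka_rushton(speeds, 0.0, 1.0, 9.0, 4.0)
    >>> est = NakaRushtonPsychometric().fit(speeds, p,
    ...                                     sample_weight=np.full(8, 500))
    >>> round(est.pse_, 1)
    9.0
    """

    def __init__(self, exponent_starts=(1.0, 2.0, 4.0, 8.0, 16.0),
                 max_lapse: float = 0.45,
                 degenerate_loglik_margin: float = 2.0):
        self.exponent_starts = exponent_starts
        self.max_lapse = max_lapse
        self.degenerate_loglik_margin = degenerate_loglik_margin

    def fit(self, X, y, sample_weight=None):
        """Fit to per-speed proportions.

        Parameters
        ----------
        X : array-like of shape (n_speeds,) or (n_speeds, 1)
            Stimulus speeds in deg/s.
        y : array-like of shape (n_speeds,)
            Proportion of "fast" choices at each speed, in [0, 1].
        sample_weight : array-like, optional
            Number of completed trials per speed (defaults to 1 each).
        """
        s = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if s.size != y.size:
            raise ValueError("X and y must have the same length")
        if np.unique(s).size < 4:
            raise ValueError("need at least 4 distinct speeds")
        if np.any(s <= 0):
            raise ValueError("speeds must be positive")
        if np.any((y < 0) | (y > 1)):
            raise ValueError("proportions must lie in [0, 1]")
        n = (np.ones_like(y) if sample_weight is None
             else np.asarray(sample_weight, dtype=float).reshape(-1))
        if np.any(n < 1):
            raise ValueError("need at least 1 trial per speed")
        k = y * n

        # constant-rate reference model for the degeneracy check
        p0 = np.clip(k.sum() / n.sum(), _EPS, 1 - _EPS)
        loglik_const = float(np.sum(k * np.log(p0) + (n - k) * np.log1p(-p0)))

        bounds = [(0.0, self.max_lapse), (1 - self.max_lapse, 1.0),
                  (0.5 * s.min(), 2.0 * s.max()), (0.25, 64.0)]
        s50_starts = np.quantile(s, [0.35, 0.5, 0.65])
        best = None
        for e0 in self.exponent_starts:
            for s50_0 in s50_starts:
                x0 = [max(y.min(), 0.01), min(y.max(), 0.99),
                      float(s50_0), float(e0)]
                x0[0] = min(x0[0], self.max_lapse)
                x0[1] = max(x0[1], 1 - self.max_lapse)
                res = minimize(_binomial_nll, x0, args=(s, k, n),
                               method="L-BFGS-B", bounds=bounds)
                if best is None or res.fun < best.fun:
                    best = res
        self.lower_, self.upper_, self.s50_, self.exponent_ = best.x
        self.loglik_ = -float(best.fun)
        self.n_trials_per_speed_ = n
        self.speeds_ = s

        all_same = np.all(k == 0) or np.all(k == n)
        self.degenerate_ = bool(
            all_same
            or (self.loglik_ - loglik_const) < self.degenerate_loglik_margin
            or not (self.lower_ < 0.5 < self.upper_))
        self.pse_ = np.nan if self.degenerate_ else self._solve_pse()
        return self

    def _solve_pse(self) -> float:
        f = lambda x: naka_rushton(x, self.lower_, self.upper_,
                                   self.s50_, self.exponent_) - 0.5
        lo, hi = float(self.speeds_.min()), float(self.speeds_.max())
        if f(lo) * f(hi) > 0:  # root outside the tested range
            lo, hi = 1e-6, 100.0 * hi
            if f(lo) * f(hi) > 0:
                return np.nan
        return float(brentq(f, lo, hi, xtol=1e-10))

    def predict(self, X) -> np.ndarray:
        """Predicted P(choice = fast) at the given speeds."""
        check_is_fitted(self, "s50_")
        s = np.asarray(X, dtype=float).reshape(-1)
        return naka_rushton(s, self.lower_, self.upper_, self.s50_,
                            self.exponent_)


@dataclass
class PsychometricFit:
    """Fitted boundary-specific choice curve and its PSE."""

    boundary: str
    lower: float
    upper: float
    s50: float
    exponent: float
    pse: float
    loglik: float
    degenerate: bool
    n_trials_per_speed: np.ndarray
    speeds: np.ndarray

    def predict(self, speeds) -> np.ndarray:
        return naka_rushton(speeds, self.lower, self.upper, self.s50,
                            self.exponent)

    def to_dict(self) -> dict:
        return {
            "boundary": self.boundary, "lower": self.lower,
            "upper": self.upper, "s50": self.s50,
            "exponent": self.exponent, "pse": self.pse,
            "loglik": self.loglik, "degenerate": self.degenerate,
            "n_trials_per_speed": np.asarray(
                self.n_trials_per_speed).tolist(),
            "speeds": np.asarray(self.speeds).tolist(),
        }


def fit_psychometric(speeds, p_fast, n, boundary: str = "") -> PsychometricFit:
    """Fit one boundary's choice curve from per-speed proportions."""
    est = NakaRushtonPsychometric().fit(speeds, p_fast, sample_weight=n)
    return PsychometricFit(
        boundary=boundary, lower=float(est.lower_), upper=float(est.upper_),
        s50=float(est.s50_), exponent=float(est.exponent_),
        pse=float(est.pse_), loglik=est.loglik_, degenerate=est.degenerate_,
        n_trials_per_speed=est.n_trials_per_speed_, speeds=est.speeds_)


def compute_pse(fit: PsychometricFit, bracket=(1e-6, 1e3)) -> float:
    """Numerical root of P(s) = 0.5; unique by monotonicity.

    Raises :class:`UndefinedPSEError` when 0.5 is not strictly between
    the asymptotes.
    """
    if not fit.lower < 0.5 < fit.upper:
        raise UndefinedPSEError(
            f"0.5 outside asymptote range ({fit.lower:.3f}, {fit.upper:.3f})")
    f = lambda x: float(fit.predict(x) - 0.5)
    return float(brentq(f, *bracket, xtol=1e-10))


def _per_trial(trials: pd.DataFrame) -> pd.DataFrame:
    """Collapse a long (per-epoch) table to one row per trial."""
    if "epoch" in trials.columns:
        keys = [c for c in ("session_id", "trial_index") if c in trials]
        return trials.drop_duplicates(subset=keys, keep="first")
    return trials


def behavioral_rates(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-(boundary, speed) choice, error, and fixation-break rates.

    ``p_fast`` and ``error_rate`` are computed over completed trials;
    ``fixation_break_rate`` over all trials. Cells with zero completed
    trials report NaN rates (missing, not 0).
    """
    t = _per_trial(trials)
    rows = []
    for (boundary, speed), g in t.groupby(["boundary", "speed"], sort=True):
        total = len(g)
        fix = int((g["outcome"] == "fixation_break").sum())
        comp = g[g["outcome"] != "fixation_break"]
        n_comp = len(comp)
        if n_comp:
            p_fast = float((comp["choice"] == "fast").mean())
            err = float((comp["outcome"] == "incorrect").mean())
        else:
            p_fast = err = np.nan
        rows.append({
            "boundary": boundary, "speed": speed, "n_total": total,
            "n_completed": n_comp, "p_fast": p_fast, "error_rate": err,
            "fixation_break_rate": fix / total if total else np.nan,
        })
    return pd.DataFrame(rows)


def fit_behavior(trials: pd.DataFrame, config: TaskConfig | None = None,
                 per_session: bool = False
                 ) -> dict[str, PsychometricFit] | pd.DataFrame:
    """Boundary-specific psychometric fits from a trial table.

    With ``per_session=False`` (default) trials are pooled across sessions
    per boundary — the group-curve entry point. With ``per_session=True``
    a tidy frame of per-session fits is returned (one row per session and
    boundary), the entry point for PSE histograms.
    """
    t = _per_trial(trials)
    t = t[t["outcome"] != "fixation_break"]

    def _fit_one(sub: pd.DataFrame, boundary: str) -> PsychometricFit:
        agg = sub.groupby("speed").agg(
            n=("choice", "size"),
            k=("choice", lambda c: (c == "fast").sum()))
        return fit_psychometric(agg.index.to_numpy(),
                                (agg["k"] / agg["n"]).to_numpy(),
                                agg["n"].to_numpy(), boundary=boundary)

    if not per_session:
        return {b: _fit_one(g, b) for b, g in t.groupby("boundary")}
    rows = []
    for (sid, b), g in t.groupby(["session_id", "boundary"]):
        fit = _fit_one(g, b)
        rows.append({"session_id": sid, "boundary": b, "pse": fit.pse,
                     "s50": fit.s50, "exponent": fit.exponent,
                     "lower": fit.lower, "upper": fit.upper,
                     "degenerate": fit.degenerate})
    return pd.DataFrame(rows)
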