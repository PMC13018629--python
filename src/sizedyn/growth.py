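"""Population growth curves: logistic / Gompertz fits in log space and mu(t).

Biomass B(t) is assumed to follow logistic growth

    dB/dt = mu_max B (1 - B/B_max),
    B(t)  = B_max / (1 + exp(-mu_max (t - t_s))),

where ``t_s`` marks the entry into stationary phase (the sigmoid midpoint).
Parameters are fitted by minimizing the sum of squared residuals between
log-measurements and the log of the model, which weights the exponential
phase sensibly for data spanning decades of optical density.  The per-capita
growth rate follows analytically:

    mu(t) = (1/B) dB/dt = mu_max / (1 + exp(mu_max (t - t_s))).

A Gompertz alternative ``B(t) = B_max exp(-exp(-r (t - t_m)))`` with
``mu(t) = r exp(-r (t - t_m))`` is fitted with the same objective.

Sustained-exponential-growth experiments repeatedly dilute the culture with
fresh medium; OD measurements must be dilution-corrected upstream (measured
value times dilution factor).  Inside the annotated dilution window the OD
derivative is treated as zero and mu(t) is held at its value at the window
start; points inside the window are excluded from the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "GrowthCurve",
    "GrowthFit",
    "logistic_solution",
    "logistic_rate",
    "gompertz_solution",
    "gompertz_rate",
    "fit_growth",
    "growth_rate",
]


def logistic_solution(t, t_s, B_max, mu_max):
    """Closed-form logistic biomass; overflow-safe, bounded in (0, B_max)."""
    return B_max * expit(mu_max * (np.asarray(t, dtype=float) - t_s))


def logistic_rate(t, t_s, mu_max):
    """Per-capita growth rate of the logistic curve; mu(t_s) = mu_max/2."""
    return mu_max * expit(-mu_max * (np.asarray(t, dtype=float) - t_s))


def gompertz_solution(t, t_m, B_max, r):
    """Gompertz biomass B_max exp(-exp(-r (t - t_m))); B(t_m) = B_max/e."""
    return B_max * np.exp(-np.exp(-r * (np.asarray(t, dtype=float) - t_m)))


def gompertz_rate(t, t_m, r):
    """Per-capita growth rate of the Gompertz curve, r exp(-r (t - t_m))."""
    return r * np.exp(-r * (np.asarray(t, dtype=float) - t_m))


@dataclass
class GrowthCurve:
    """A dilution-corrected OD600 time series.

    ``dilution_window`` is an optional ``(t_start, t_end)`` during which the
    culture was repeatedly diluted to sustain exponential growth; those
    points are excluded from fitting, and mu(t) is frozen there.
    """

    times_h: np.ndarray
    od600: np.ndarray
    dilution_window: tuple[float, float] | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.times_h.shape != self.od600.shape:
            raise ValueError("times and OD must have matching shapes")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od600 <= 0):
            raise ValueError("OD values must be positive")
        if self.dilution_window is not None:
            lo, hi = self.dilution_window
            if not (lo < hi):
                raise ValueError("dilution window must have t_start < t_end")
            if lo < self.times_h[0] or hi > self.times_h[-1]:
                raise ValueError("dilution window outside the sampled range")


@dataclass
class GrowthFit:
    """Fitted growth model; ``sse_log`` is the log-space objective at optimum.

    ``model`` is 'logistic' (parameters mu_max_per_h, B_max, t_s_h) or
    'gompertz' (r_per_h, B_max, t_m_h).
    """

    model: str
    B_max: float
    sse_log: float
    mu_max_per_h: float | None = None
    t_s_h: float | None = None
    r_per_h: float | None = None
    t_m_h: float | None = None
    dilution_window: tuple[float, float] | None = None

    def _freeze(self, t):
        t = np.asarray(t, dtype=float)
        if self.dilution_window is None:
            return t
        lo, hi = self.dilution_window
        return np.where((t >= lo) & (t <= hi), lo, t)

    def B(self, t):
        """Fitted biomass at time t, held constant inside the dilution window."""
        te = self._freeze(t)
        if self.model == "logistic":
            return logistic_solution(te, self.t_s_h, self.B_max, self.mu_max_per_h)
        return gompertz_solution(te, self.t_m_h, self.B_max, self.r_per_h)

    def mu(self, t):
        """Growth rate mu(t), held at its window-start value inside dilutions."""
        te = self._freeze(t)
        if self.model == "logistic":
            return self.mu_max_per_h * expit(-self.mu_max_per_h * (te - self.t_s_h))
        return gompertz_rate(te, self.t_m_h, self.r_per_h)


def growth_rate(fit: GrowthFit, t):
    """Growth rate of a fitted curve at time(s) t (see :meth:`GrowthFit.mu`)."""
    return fit.mu(t)


def _log_model(theta, t, model):
    t_loc, ln_bmax, ln_rate = theta
    rate = np.exp(ln_rate)
    if model == "logistic":
        # ln(B_max) - ln(1 + e^{-mu(t - ts)}) via logaddexp for stability
        return ln_bmax - np.logaddexp(0.0, -rate * (t - t_loc))
    return ln_bmax - np.exp(-rate * (t - t_loc))


def fit_growth(curve: GrowthCurve, model: str = "logistic", n_starts: int = 8) -> GrowthFit:
    """Fit a logistic or Gompertz curve by log-space least squares.

    Uses a derivative-free simplex from ``n_starts`` deterministic starts
    built from data-driven heuristics (carrying capacity near the maximum
    OD, rate from the steepest log-slope, midpoint at the half-maximum
    crossing).  Points inside the dilution window are excluded.  Raises on
    degenerate (constant) data or if no start converges.
    """
    if model not in ("logistic", "gompertz"):
        raise ValueError(f"unknown model {model!r}")
    t_all, od_all = curve.times_h, curve.od600
    if curve.dilution_window is not None:
        lo, hi = curve.dilution_window
        keep = ~((t_all >= lo) & (t_all <= hi))
        t, od = t_all[keep], od_all[keep]
    else:
        t, od = t_all, od_all
    if len(t) < 4:
        raise ValueError("need at least 4 points outside the dilution window")
    if np.ptp(od) == 0:
        raise ValueError("constant OD: growth model is unidentifiable")

    ln_od = np.log(od)
    bmax0 = od.max()
    slopes = np.diff(ln_od) / np.diff(t)
    rate0 = float(np.clip(slopes.max(), 0.05, 20.0))
    half = bmax0 / 2.0
    above = np.nonzero(od >= half)[0]
    t_loc0 = float(t[above[0]]) if len(above) else float(np.median(t))

    offsets = [
        (0.0, 0.0, 0.0),
        (0.5, 0.0, 0.0),
        (-0.5, 0.0, 0.0),
        (0.0, 0.25, 0.0),
        (0.0, 0.0, 0.7),
        (0.0, 0.0, -0.7),
        (1.0, 0.1, 0.4),
        (-1.0, -0.1, -0.4),
    ][: max(1, n_starts)]

    def objective(theta):
        r = ln_od - _log_model(theta, t, model)
        return float(r @ r)

    best = None
    for dt_loc, dlnb, dlnr in offsets:
        x0 = np.array([t_loc0 + dt_loc, np.log(bmax0) + dlnb, np.log(rate0) + dlnr])
        res = minimize(
            objective, x0, method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-14},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError("growth fit failed to converge from any start")

    t_loc, ln_bmax, ln_rate = best.x
    common = dict(B_max=float(np.exp(ln_bmax)), sse_log=float(best.fun),
                  dilution_window=curve.dilution_window)
    if model == "logistic":
        return GrowthFit(model=model, mu_max_per_h=float(np.exp(ln_rate)),
                         t_s_h=float(t_loc), **common)
    return GrowthFit(model=model, r_per_h=float(np.exp(ln_rate)),
                     t_m_h=float(t_loc), **common)
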