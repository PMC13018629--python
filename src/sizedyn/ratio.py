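"""Smoothed OD and CFU trends with confidence bands, and their ratio.

Replicated OD600 and CFU measurements are smoothed nonparametrically on the
log scale with a Gaussian-process regression (squared-exponential kernel
plus white noise, hyperparameters by marginal-likelihood maximization) and
back-transformed, yielding a most-probable mean trajectory with pointwise
95% half-widths on a common time grid.

Given the OD trend x +/- dx and the CFU trend y +/- dy, the ratio and its
uncertainty follow first-order absolute propagation:

    z = x / y,        dz = |dx / y| + |x dy / y^2|.

The absolute-sum form is conservative relative to quadrature addition (by
up to a factor sqrt(2) for equal contributions).  The OD/CFU ratio tracks
the population mean cell size, so its peak along a growth curve mirrors the
transient cell-volume peak after resuspension in fresh medium.

CFU replicate hierarchies (biological x technical) are flattened by
averaging technical replicates within each biological replicate, so the
smoother sees biological-replicate-level observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

__all__ = [
    "ReplicatedSeries",
    "TrendWithBand",
    "PeakReport",
    "aggregate_cfu_replicates",
    "smooth_trend",
    "ratio_with_uncertainty",
    "peak_locate",
]

_Z95 = 1.959963984540054


@dataclass
class ReplicatedSeries:
    """Long-form replicated measurements: one row per (time, replicate)."""

    times_h: np.ndarray
    values: np.ndarray
    kind: str = ""

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_h.shape != self.values.shape:
            raise ValueError("times and values must have matching shapes")
        if np.any(self.values <= 0):
            raise ValueError("values must be positive (log-scale smoothing)")


@dataclass
class TrendWithBand:
    """A smoothed positive trajectory with pointwise 95% half-widths."""

    grid_times_h: np.ndarray
    mean: np.ndarray
    halfwidth: np.ndarray
    kind: str = ""


@dataclass
class PeakReport:
    """Location of the maximum of a trend and its fold change from start."""

    t_peak_h: float
    peak_value: float
    fold_increase_vs_start: float
    interior: bool


def aggregate_cfu_replicates(cfu: pd.DataFrame) -> ReplicatedSeries:
    """Average technical replicates within each biological replicate.

    Expects columns ``time_h``, ``bio_rep``, ``tech_rep``, ``cfu_per_ml``
    and returns biological-replicate-level observations.
    """
    g = cfu.groupby(["time_h", "bio_rep"], sort=True)["cfu_per_ml"].mean().reset_index()
    return ReplicatedSeries(
        g["time_h"].to_numpy(), g["cfu_per_ml"].to_numpy(), kind="cfu"
    )


def smooth_trend(series: ReplicatedSeries, grid, seed: int = 0) -> TrendWithBand:
    """Gaussian-process smoothing of log-values with a 95% band.

    Requires at least 4 distinct time points.  Noise-free constant input
    short-circuits to the constant with a zero band (the GP marginal
    likelihood is degenerate there).  Deterministic given ``seed``.
    """
    grid = np.asarray(grid, dtype=float)
    t = series.times_h
    if len(np.unique(t)) < 4:
        raise ValueError("need at least 4 distinct time points to smooth")
    ly = np.log(series.values)
    if np.ptp(ly) < 1e-12:
        const = float(np.exp(ly[0]))
        return TrendWithBand(
            grid, np.full_like(grid, const), np.zeros_like(grid), series.kind
        )
    span = float(np.ptp(t))
    kernel = (
        ConstantKernel(1.0, (1e-4, 1e4))
        * RBF(length_scale=span / 3.0, length_scale_bounds=(span / 50.0, span * 10.0))
        + WhiteKernel(noise_level=1e-2, noise_level_bounds=(1e-12, 1.0))
    )
    gpr = GaussianProcessRegressor(
        kernel=kernel,
        normalize_y=True,
        n_restarts_optimizer=2,
        random_state=seed,
    )
    gpr.fit(t[:, None], ly)
    m, sd = gpr.predict(grid[:, None], return_std=True)
    # subtract the fitted white-noise floor: the band should cover the mean
    # trajectory, not single future measurements
    noise = gpr.kernel_.k2.noise_level if hasattr(gpr.kernel_, "k2") else 0.0
    sd = np.sqrt(np.maximum(sd**2 - noise, 0.0))
    upper = np.exp(m + _Z95 * sd)
    lower = np.exp(m - _Z95 * sd)
    return TrendWithBand(grid, np.exp(m), (upper - lower) / 2.0, series.kind)


def ratio_with_uncertainty(od_trend: TrendWithBand, cfu_trend: TrendWithBand) -> TrendWithBand:
    """Ratio trend z = x/y with first-order absolute error propagation.

    Both trends must share the same grid.  dz = |dx/y| + |x dy / y^2|; the
    propagation is exact to first order and homogeneous of degree one in
    (x, dx).
    """
    if od_trend.grid_times_h.shape != cfu_trend.grid_times_h.shape or not np.allclose(
        od_trend.grid_times_h, cfu_trend.grid_times_h
    ):
        raise ValueError("trends are on different grids")
    x, dx = od_trend.mean, od_trend.halfwidth
    y, dy = cfu_trend.mean, cfu_trend.halfwidth
    z = x / y
    dz = np.abs(dx / y) + np.abs(x * dy / y**2)
    return TrendWithBand(od_trend.grid_times_h.copy(), z, dz, kind="ratio")


def peak_locate(trend: TrendWithBand) -> PeakReport:
    """Argmax of a trend and its fold increase over the grid start.

    ``interior`` is False for monotone or flat trends (no interior peak).
    """
    m = trend.mean
    i = int(np.argmax(m))
    interior = 0 < i < len(m) - 1 and m[i] > m[0] and m[i] > m[-1]
    return PeakReport(
        t_peak_h=float(trend.grid_times_h[i]),
        peak_value=float(m[i]),
        fold_increase_vs_start=float(m[i] / m[0]),
        interior=bool(interior),
    )
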