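"""Stochastic single-cell growth-division simulator and synthetic-data generator.

Each cell grows exponentially, ds/dt = mu(t) s, and divides in half with
hazard k(t) mu(t) s.  Because size added per unit time is ds/dt = mu s, the
hazard *per unit added size* is exactly k(t): a cell born at size b divides
after adding an exponentially distributed increment (mean 1/k for constant
k) — the adder division strategy.  The simulator exploits this by tracking,
per cell, the cumulative division hazard on the size-accumulation clock and
inverting it against a unit-exponential threshold, so division sampling is
exact in distribution up to the (sub-stepped) tabulation of k and mu on a
fine time grid.

The simulated ensemble is a fixed set of ``n0`` single-cell lineages: at
each division the size halves and one daughter is followed (the other is
statistically identical).  This is the ensemble whose moment dynamics the
mean-field model describes.  The population-level observation channels are
computed exactly from the same rates rather than by counting lineages:

* biomass (OD proxy): division conserves total size, so B(t) = B(0) e^{M(t)}
  with M(t) = integral of mu — exact;
* cell count (CFU proxy): the expected total division intensity of the full
  branching population is k(t) mu(t) B(t), so N(t) = n0 + integral of
  k mu B dt — exact in expectation.

Note a subtlety this makes visible: the full branching population's mean
size N/B relaxes to 1/k, whereas the per-lineage mean relaxes to
2/(k (1+CV^2)); the mean-field value 2/k neglects the size fluctuations
(see docs/methods.md for the quantitative gap).

Per-cell microscopy-like measurements subsample lineage sizes, map volume
to capsule dimensions at a fixed condition-dependent width, apply
multiplicative log-normal noise to length and width, and emit the tabular
dialect the geometry module consumes.  :func:`render_mask` rasterizes
sphero-cylinders into binary masks for the mask-measurement pathway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .geometry import capsule_area
from .sizemodel import DivisionSchedule

__all__ = [
    "SimConfig",
    "PopulationState",
    "SimResult",
    "Observation",
    "resolve_mu",
    "simulate_population",
    "observe",
    "render_mask",
]


@dataclass
class SimConfig:
    """Study conditions for a synthetic growth-curve experiment.

    Defaults emulate a rich-medium (LB-like) growth curve: overnight cells
    of ~1 um^3 resuspended 1:1000, logistic growth rate with mu_max = 2/h
    entering stationary phase near t_s = 4 h, and a division coefficient
    rising from 0.4 to 2.0 um^-3 (steady sizes 5 -> 1 um^3) as nutrients
    deplete, relaxing back in deep stationary phase.
    """

    schedule: DivisionSchedule = field(
        default_factory=lambda: DivisionSchedule(0.4, 2.0, 3.0, 2.5, 8.0)
    )
    mu_spec: object = ("logistic", 2.0, 4.0)  # or a float, or a callable mu(t)
    n0: int = 200
    s0_mean_um3: float = 1.0
    s0_log_sd: float = 0.3
    t_end_h: float = 10.0
    snapshot_times_h: Sequence[float] | None = None  # default: every 0.5 h
    dt_h: float = 0.005
    seed: int = 0
    condition: str = "synthetic"
    # measurement channel
    subsample_per_snapshot: int = 300
    noise_log_sd: float = 0.03  # multiplicative noise on length and width
    width_um: float = 0.9
    pixel_area_um2: float = 0.005
    # population channels
    od_per_um3: float = 1e-5
    od_replicates: int = 3
    od_noise_log_sd: float = 0.02
    cfu_per_count: float = 1e4
    cfu_bio_replicates: int = 3
    cfu_tech_replicates: int = 4
    cfu_bio_noise_log_sd: float = 0.10
    cfu_tech_noise_log_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n0 < 1:
            raise ValueError("n0 must be at least 1")
        if self.dt_h <= 0 or self.t_end_h <= 0:
            raise ValueError("time step and horizon must be positive")
        if self.s0_mean_um3 <= 0:
            raise ValueError("initial mean size must be positive")
        if self.snapshot_times_h is None:
            self.snapshot_times_h = np.arange(0.0, self.t_end_h + 1e-9, 0.5)
        self.snapshot_times_h = np.asarray(self.snapshot_times_h, dtype=float)
        if np.any(self.snapshot_times_h < 0) or np.any(
            self.snapshot_times_h > self.t_end_h + 1e-9
        ):
            raise ValueError("snapshot times must lie within [0, t_end]")


@dataclass
class PopulationState:
    """Lineage sizes at one snapshot, with division bookkeeping.

    ``cumulative_divisions`` counts division events across the whole
    ensemble since t = 0; ``expected_count`` and ``biomass_um3`` are the
    exact population-level observables (see module docstring).
    """

    time_h: float
    sizes_um3: np.ndarray
    cumulative_divisions: int
    biomass_um3: float
    expected_count: float


@dataclass
class SimResult:
    """Simulation output.

    ``added_sizes_um3`` holds the size added between birth and division for
    every division of a cell born during the simulation, with the matching
    birth times in ``added_birth_times_h``.  Increments of cells born close
    to the horizon are right-censored (their divisions may not complete by
    ``t_end``); restrict to early birth times for unbiased adder statistics.
    """

    states: list[PopulationState]
    added_sizes_um3: np.ndarray
    added_birth_times_h: np.ndarray
    divisions_per_lineage: np.ndarray
    config: SimConfig


def resolve_mu(mu_spec) -> Callable:
    """Turn a mu specification into a vectorized callable mu(t).

    Accepts a callable, a constant (float), or a tuple
    ``("logistic", mu_max, t_s)``.
    """
    if callable(mu_spec):
        return mu_spec
    if isinstance(mu_spec, (int, float)):
        const = float(mu_spec)
        if const < 0:
            raise ValueError("constant growth rate must be non-negative")
        return lambda t: np.full_like(np.asarray(t, dtype=float), const)
    if isinstance(mu_spec, (tuple, list)) and mu_spec[0] == "logistic":
        from .growth import logistic_rate

        _, mu_max, t_s = mu_spec
        return lambda t: logistic_rate(t, t_s, mu_max)
    raise ValueError(f"cannot interpret mu specification {mu_spec!r}")


def simulate_population(config: SimConfig) -> SimResult:
    """Run the lineage-ensemble simulation.

    Between divisions sizes follow s(t) = s(t0) exp(int mu); divisions are
    placed by inverting the cumulative hazard on the added-size clock
    against unit-exponential thresholds (at most one division per cell per
    time step; the step is small so double events are O(dt^2)).  All
    randomness comes from ``config.seed``; identical configs give identical
    output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    mu_fn = resolve_mu(cfg.mu_spec)
    if isinstance(cfg.schedule, DivisionSchedule):
        k_fn = cfg.schedule.k
    elif callable(cfg.schedule):
        k_fn = cfg.schedule
    else:
        const_k = float(cfg.schedule)
        k_fn = lambda t: np.full_like(np.asarray(t, dtype=float), const_k)

    n_steps = int(round(cfg.t_end_h / cfg.dt_h))
    dt = cfg.t_end_h / n_steps if n_steps else cfg.dt_h
    nodes = np.linspace(0.0, cfg.t_end_h, n_steps + 1)
    mu_nodes = np.asarray(mu_fn(nodes), dtype=float)
    if np.any(mu_nodes < 0):
        raise ValueError("growth rate must be non-negative")
    k_mids = np.asarray(k_fn(nodes[:-1] + 0.5 * dt), dtype=float)
    if np.any(k_mids < 0):
        raise ValueError("division coefficient must be non-negative")
    # trapezoid growth factors and exact-channel tabulation
    step_logs = 0.5 * (mu_nodes[:-1] + mu_nodes[1:]) * dt
    M = np.concatenate([[0.0], np.cumsum(step_logs)])

    snap_idx = np.rint(cfg.snapshot_times_h / dt).astype(int)
    if np.any(np.abs(snap_idx * dt - cfg.snapshot_times_h) > 1e-8):
        raise ValueError("snapshot times must align with the simulation grid")
    snap_lookup: dict[int, float] = {
        int(i): float(t) for i, t in zip(snap_idx, cfg.snapshot_times_h)
    }

    # initial log-normal sizes with the requested arithmetic mean
    log_mu = math.log(cfg.s0_mean_um3) - 0.5 * cfg.s0_log_sd**2
    sizes = rng.lognormal(log_mu, cfg.s0_log_sd, cfg.n0)
    birth = sizes.copy()
    birth_time = np.zeros(cfg.n0)
    born_in_sim = np.zeros(cfg.n0, dtype=bool)
    hazard = np.zeros(cfg.n0)
    thresholds = rng.exponential(1.0, cfg.n0)
    n_div_per_lineage = np.zeros(cfg.n0, dtype=int)
    total_divisions = 0
    added_records: list[np.ndarray] = []
    added_birth_records: list[np.ndarray] = []

    B0 = float(sizes.sum())
    biomass = B0 * np.exp(M)
    # expected count: total division intensity of the branching population
    # is k mu B (one new cell per event), so N(t) = n0 + int k mu B dt
    kmuB_nodes = np.asarray(k_fn(nodes), dtype=float) * mu_nodes * biomass
    exp_count = cfg.n0 + np.concatenate(
        [[0.0], np.cumsum(0.5 * (kmuB_nodes[:-1] + kmuB_nodes[1:]) * dt)]
    )

    states: list[PopulationState] = []

    def record(step: int) -> None:
        states.append(
            PopulationState(
                time_h=snap_lookup[step],
                sizes_um3=sizes.copy(),
                cumulative_divisions=total_divisions,
                biomass_um3=float(biomass[step]),
                expected_count=float(exp_count[step]),
            )
        )

    if 0 in snap_lookup:
        record(0)
    for i in range(n_steps):
        g = math.exp(step_logs[i])
        km = k_mids[i]
        new_sizes = sizes * g
        d_hazard = km * (new_sizes - sizes)
        hazard_end = hazard + d_hazard
        div = hazard_end >= thresholds
        if div.any():
            idx = np.nonzero(div)[0]
            s_at_div = sizes[idx] + (thresholds[idx] - hazard[idx]) / km
            tracked = born_in_sim[idx]
            if tracked.any():
                added_records.append(s_at_div[tracked] - birth[idx[tracked]])
                added_birth_records.append(birth_time[idx[tracked]])
            total_divisions += len(idx)
            n_div_per_lineage[idx] += 1
            born_in_sim[idx] = True
            birth[idx] = s_at_div / 2.0
            birth_time[idx] = nodes[i] + 0.5 * dt
            new_sizes[idx] = new_sizes[idx] / 2.0
            hazard_end[idx] = km * (new_sizes[idx] - birth[idx])
            thresholds[idx] = rng.exponential(1.0, len(idx))
        sizes = new_sizes
        hazard = hazard_end
        if (i + 1) in snap_lookup:
            record(i + 1)

    added = (
        np.concatenate(added_records) if added_records else np.empty(0, dtype=float)
    )
    added_births = (
        np.concatenate(added_birth_records)
        if added_birth_records
        else np.empty(0, dtype=float)
    )
    return SimResult(
        states=states,
        added_sizes_um3=added,
        added_birth_times_h=added_births,
        divisions_per_lineage=n_div_per_lineage,
        config=cfg,
    )


@dataclass
class Observation:
    """Synthetic observations in the pipeline's tabular dialects."""

    od: pd.DataFrame  # condition, time_h, replicate, od600_corrected, in_dilution_window
    cfu: pd.DataFrame  # time_h, bio_rep, tech_rep, cfu_per_ml
    cells: pd.DataFrame  # cell_id, condition, time_h, projected_area_um2, length_um


def _volume_to_capsule(volumes: np.ndarray, width_um: float):
    """Map volumes to (L, w) at fixed width; small cells fall back to spheres."""
    w = np.full_like(volumes, width_um, dtype=float)
    L = 4.0 * volumes / (math.pi * w**2) + w / 3.0
    small = L < w
    if small.any():
        w_s = np.cbrt(6.0 * volumes[small] / math.pi)
        w[small] = w_s
        L[small] = w_s
    return L, w


def observe(result: SimResult, seed: int | None = None) -> Observation:
    """Generate OD-like, CFU-like and per-cell measurement tables.

    OD replicates are the exact biomass times ``od_per_um3`` with
    multiplicative log-normal noise; CFU replicates likewise from the exact
    expected count, with separate biological and technical noise.  Per-cell
    rows subsample each snapshot's lineage sizes (the full ensemble if the
    subsample is larger), map volume to capsule length and width, corrupt
    both with measurement noise, and report projected area and length.
    """
    cfg = result.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)

    od_rows = []
    cfu_rows = []
    cell_rows = []
    cell_counter = 0
    for st in result.states:
        od_true = st.biomass_um3 * cfg.od_per_um3
        for rep in range(cfg.od_replicates):
            od_rows.append(
                {
                    "condition": cfg.condition,
                    "time_h": st.time_h,
                    "replicate": rep,
                    "od600_corrected": od_true
                    * math.exp(rng.normal(0.0, cfg.od_noise_log_sd)),
                    "in_dilution_window": 0,
                }
            )
        cfu_true = st.expected_count * cfg.cfu_per_count
        for bio in range(cfg.cfu_bio_replicates):
            bio_factor = math.exp(rng.normal(0.0, cfg.cfu_bio_noise_log_sd))
            for tech in range(cfg.cfu_tech_replicates):
                cfu_rows.append(
                    {
                        "time_h": st.time_h,
                        "bio_rep": bio,
                        "tech_rep": tech,
                        "cfu_per_ml": cfu_true
                        * bio_factor
                        * math.exp(rng.normal(0.0, cfg.cfu_tech_noise_log_sd)),
                    }
                )
        n_cells = len(st.sizes_um3)
        take = min(cfg.subsample_per_snapshot, n_cells)
        idx = (
            rng.choice(n_cells, size=take, replace=False)
            if take < n_cells
            else np.arange(n_cells)
        )
        vols = st.sizes_um3[idx]
        L, w = _volume_to_capsule(vols, cfg.width_um)
        if cfg.noise_log_sd > 0:
            L = L * rng.lognormal(0.0, cfg.noise_log_sd, take)
            w = w * rng.lognormal(0.0, cfg.noise_log_sd, take)
            w = np.minimum(w, L)  # keep capsule geometry valid
        A_p = capsule_area(L, w)
        for j in range(take):
            cell_rows.append(
                {
                    "cell_id": f"c{cell_counter + j}",
                    "condition": cfg.condition,
                    "time_h": st.time_h,
                    "projected_area_um2": A_p[j],
                    "length_um": L[j],
                }
            )
        cell_counter += take

    return Observation(
        od=pd.DataFrame(od_rows),
        cfu=pd.DataFrame(cfu_rows),
        cells=pd.DataFrame(cell_rows),
    )


def render_mask(
    length_um: float,
    width_um: float,
    angle_deg: float = 0.0,
    pixel_area_um2: float = 0.005,
) -> np.ndarray:
    """Rasterize a sphero-cylinder into a binary pixel mask.

    The capsule is the set of points within w/2 of a centred segment of
    length L - w, rotated by ``angle_deg``; a pixel is foreground if its
    centre lies inside.  Raises for sub-pixel widths (degenerate shapes).
    """
    if width_um > length_um:
        raise ValueError("width exceeds length")
    if pixel_area_um2 <= 0:
        raise ValueError("pixel area must be positive")
    px = math.sqrt(pixel_area_um2)
    if width_um < 2.0 * px:
        raise ValueError("sub-pixel width: shape cannot be rasterized")
    half_seg = (length_um - width_um) / 2.0
    r = width_um / 2.0
    half_extent = length_um / 2.0 + 2.0 * px
    n = int(math.ceil(2.0 * half_extent / px))
    coords = (np.arange(n) + 0.5) * px - half_extent
    X, Y = np.meshgrid(coords, coords, indexing="xy")
    theta = math.radians(angle_deg)
    # rotate pixel centres into the capsule frame
    Xr = math.cos(theta) * X + math.sin(theta) * Y
    Yr = -math.sin(theta) * X + math.cos(theta) * Y
    ax = np.clip(Xr, -half_seg, half_seg)
    dist2 = (Xr - ax) ** 2 + Yr**2
    return dist2 <= r * r
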