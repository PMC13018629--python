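"""Mean-field cell-size dynamics under growth and size-proportional division.

Single cells grow exponentially, ds/dt = mu(t) s, and divide in half with
hazard k(t) mu(t) s, where k(t) is the time-varying division coefficient
(units um^-3).  Averaging and closing the moment hierarchy at first order
(<s^2> ~ <s>^2) gives the mean-size equation

    d<s>/dt = mu(t) <s> - k(t) mu(t) <s>^2 / 2,

a Riccati equation whose fixed point for constant rates is <s> = 2/k: with
constant k, growth and division synchronize and the steady-state mean size
is independent of mu.

k(t) is parametrized as a double sigmoid rising from a basal value k0 to
kmax around t1* and relaxing back to k0 around t2* (both transitions with
rate lambda), encoding the assumption that the beginning and the end of a
growth curve are the same physiological condition (stationary phase):

    k(t) = k0 + (kmax - k0) [sigma(lambda (t - t1*)) - sigma(lambda (t - t2*))].

The general n-th moment obeys

    d<s^n>/dt = n mu <s^n> - k mu (1 - 2^-n) <s^{n+1}>,

which is unclosed; :func:`integrate_moments` closes it at a chosen order by
<s^{n+1}> ~ <s^n><s>.  Order 1 reproduces the mean-size equation exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import expit

__all__ = [
    "DivisionSchedule",
    "MeanSizeTrajectory",
    "k_of_t",
    "integrate_mean_size",
    "integrate_moments",
]


@dataclass(frozen=True)
class DivisionSchedule:
    """Double-sigmoid division coefficient k(t).

    Parameters: basal ``k0`` and maximal ``kmax`` coefficients (um^-3),
    transition rate ``lambda`` (h^-1), rise midpoint ``t1*`` and fall
    midpoint ``t2*`` (h), with t1* <= t2*.  k(t) tends to k0 at both ends.
    """

    k0_per_um3: float
    kmax_per_um3: float
    lambda_per_h: float
    t1_star_h: float
    t2_star_h: float

    def __post_init__(self) -> None:
        if self.k0_per_um3 <= 0 or self.kmax_per_um3 <= 0:
            raise ValueError("k0 and kmax must be positive")
        if self.lambda_per_h <= 0:
            raise ValueError("lambda must be positive")
        if self.t1_star_h > self.t2_star_h:
            raise ValueError("t1* must not exceed t2*")

    def k(self, t):
        """Evaluate k(t); accepts scalars or arrays."""
        t = np.asarray(t, dtype=float)
        lam = self.lambda_per_h
        rise = expit(lam * (t - self.t1_star_h))
        fall = expit(lam * (t - self.t2_star_h))
        return self.k0_per_um3 + (self.kmax_per_um3 - self.k0_per_um3) * (rise - fall)

    def __call__(self, t):
        return self.k(t)


def k_of_t(schedule: DivisionSchedule, t):
    """Division coefficient k(t) of a schedule (see :meth:`DivisionSchedule.k`)."""
    return schedule.k(t)


@dataclass
class MeanSizeTrajectory:
    """Mean cell size <s>(t) on a time grid, with its initial value."""

    times_h: np.ndarray
    mean_size_um3: np.ndarray
    initial_size_um3: float


def _as_k_fn(schedule) -> Callable:
    if callable(schedule):
        return schedule
    raise TypeError("schedule must be a DivisionSchedule or a callable k(t)")


def integrate_moments(
    mu_fn: Callable,
    schedule,
    closure_order: int,
    initial_moments: Sequence[float],
    t_grid,
    rtol: float = 1e-10,
    atol: float = 1e-13,
) -> np.ndarray:
    """Integrate the size-moment hierarchy closed at ``closure_order``.

    ``initial_moments`` supplies <s>(0) ... <s^order>(0).  The top moment
    <s^{order+1}> is closed as <s^order><s> (mean-field style); at order 1
    this is exactly the closed mean-size equation.  Returns an array of
    shape ``(order, len(t_grid))``.
    """
    if closure_order < 1:
        raise ValueError("closure_order must be >= 1")
    m0 = np.asarray(initial_moments, dtype=float)
    if m0.shape != (closure_order,):
        raise ValueError("initial_moments must have length closure_order")
    if np.any(m0 <= 0):
        raise ValueError("initial moments must be positive")
    k_fn = _as_k_fn(schedule)
    t_grid = np.asarray(t_grid, dtype=float)
    n = closure_order
    pref = 1.0 - 0.5 ** np.arange(1, n + 1)  # division prefactors (1 - 2^-j)
    orders = np.arange(1, n + 1, dtype=float)

    def rhs(t, m):
        mu = float(mu_fn(t))
        k = float(k_fn(t))
        m_up = np.empty(n)
        m_up[:-1] = m[1:]
        m_up[-1] = m[-1] * m[0]  # closure
        return orders * mu * m - k * mu * pref * m_up

    sol = solve_ivp(
        rhs, (t_grid[0], t_grid[-1]), m0, t_eval=t_grid,
        method="RK45", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"moment integration failed: {sol.message}; state={sol.y[:, -1]}")
    return sol.y


def integrate_mean_size(
    mu_fn: Callable,
    schedule,
    s0: float,
    t_grid,
    rtol: float = 1e-10,
    atol: float = 1e-13,
) -> MeanSizeTrajectory:
    """Integrate the closed mean-size equation on ``t_grid``.

    ``mu_fn`` and the schedule (object or callable) are evaluated at
    arbitrary times by the adaptive solver; ``s0`` is the mean size at
    ``t_grid[0]``.  Positivity is preserved by the dynamics (the vector
    field vanishes at s = 0).
    """
    if s0 <= 0:
        raise ValueError("initial mean size must be positive")
    k_fn = schedule.k if isinstance(schedule, DivisionSchedule) else _as_k_fn(schedule)
    t_grid = np.asarray(t_grid, dtype=float)
    y = integrate_moments(mu_fn, k_fn, 1, [s0], t_grid, rtol=rtol, atol=atol)
    return MeanSizeTrajectory(t_grid, y[0], float(s0))
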