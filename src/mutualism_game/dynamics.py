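"""Replicator dynamics, direction fields and best-response analysis.

The two-strategy replicator equation for the mutualist frequency is

    dx/dt = x (1 - x) (W_M(x) - W_N(x)),

with the frequency-dependent mean fitnesses from :mod:`.game_core`; in
the simplified game ``W_N`` vanishes, so selection follows the sign of
``W_M``.  Trajectories are integrated with a fixed-step classical
Runge-Kutta (RK4) scheme with post-step clamping to [0, 1], chosen over
adaptive steppers for exact run-to-run reproducibility.

The best-response correspondence of the pairwise game plays the focal
strategy against a mixed opponent who is a mutualist with probability
``q``: the mutualist expected payoff is
``(1-q)(b_mn - c_t) + q(b_mn/2 - c_t)`` and the non-mutualist's is 0, so
the best response is pure mutualism when that payoff is positive, pure
non-mutualism when negative, and the whole interval at indifference.
Intersections of the two players' correspondences with the symmetry
diagonal ``x1 = x2`` recover the ESS set of the replicator dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .game_core import mean_mutualist_fitness, mean_nonmutualist_fitness
from .params import GameParams, Strategy

__all__ = [
    "Trajectory",
    "BestResponseCurve",
    "replicator_rhs",
    "integrate_trajectory",
    "direction_field",
    "best_response",
    "best_response_curve",
]

#: Payoff differences below this magnitude count as indifference.
INDIFFERENCE_TOL = 1e-12


@dataclass(frozen=True)
class Trajectory:
    """A replicator-dynamics time series of the mutualist frequency."""

    times: np.ndarray
    x_values: np.ndarray
    params: GameParams
    dt: float

    @property
    def terminal_x(self) -> float:
        return float(self.x_values[-1])


@dataclass(frozen=True)
class BestResponseCurve:
    """Best-response sets over a grid of opponent mixed strategies.

    ``responses[i]`` is the frozenset of pure best replies to opponent
    mix ``grid[i]``; both strategies appear when the focal player is
    indifferent (the best-response set is then the whole interval).
    """

    grid: np.ndarray
    responses: tuple[frozenset, ...]


def replicator_rhs(params: GameParams, x: float) -> float:
    """Right-hand side x(1-x)(W_M(x) - W_N(x)) of the replicator equation."""
    x = float(x)
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"x must lie in [0, 1], got {x}")
    gap = mean_mutualist_fitness(params, x) - mean_nonmutualist_fitness(params, x)
    return x * (1.0 - x) * gap


def integrate_trajectory(
    params: GameParams,
    x0: float,
    t_end: float,
    dt: float = 0.01,
) -> Trajectory:
    """Integrate the replicator dynamics from ``x0`` over ``[0, t_end]``.

    Fixed-step RK4 with each step clamped to [0, 1]; the final partial
    step (if ``t_end`` is not a multiple of ``dt``) is taken exactly.
    """
    if not 0.0 <= x0 <= 1.0:
        raise ValueError(f"x0 must lie in [0, 1], got {x0}")
    if dt <= 0.0 or t_end <= 0.0:
        raise ValueError("dt and t_end must be > 0")

    n_full, remainder = divmod(t_end, dt)
    steps = [dt] * int(n_full)
    if remainder > 1e-12 * dt:
        steps.append(remainder)

    times = [0.0]
    xs = [float(x0)]
    x = float(x0)
    t = 0.0
    for h in steps:
        k1 = replicator_rhs(params, x)
        k2 = replicator_rhs(params, _clamp(x + 0.5 * h * k1))
        k3 = replicator_rhs(params, _clamp(x + 0.5 * h * k2))
        k4 = replicator_rhs(params, _clamp(x + h * k3))
        x = _clamp(x + h * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0)
        if not np.isfinite(x):
            raise ArithmeticError(
                f"non-finite state at t={t + h:.6g} (step size {h:.6g})"
            )
        t += h
        times.append(t)
        xs.append(x)
    return Trajectory(
        times=np.asarray(times), x_values=np.asarray(xs), params=params, dt=dt
    )


def _clamp(x: float) -> float:
    return min(max(x, 0.0), 1.0)


def direction_field(params: GameParams, grid) -> np.ndarray:
    """Sign (-1, 0, +1) of dx/dt at each grid frequency.

    Sign changes occur only at equilibria of the dynamics; magnitudes
    below ``INDIFFERENCE_TOL`` report 0.
    """
    grid = np.asarray(grid, dtype=float)
    rates = np.array([replicator_rhs(params, g) for g in np.atleast_1d(grid)])
    signs = np.sign(rates)
    signs[np.abs(rates) <= INDIFFERENCE_TOL] = 0.0
    return signs.astype(int)


def best_response(params: GameParams, opponent_mix: float) -> frozenset:
    """Pure best replies to an opponent playing mutualist with probability ``q``.

    Uses pairwise (``n = 1``) game semantics.  Returns a frozenset of
    :class:`Strategy`; both members when indifferent.
    """
    q = float(opponent_mix)
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"opponent_mix must lie in [0, 1], got {q}")
    payoff = (1.0 - q) * (params.b_mn - params.c_t) + q * (
        params.b_mn / 2.0 - params.c_t
    )
    if payoff > INDIFFERENCE_TOL:
        return frozenset({Strategy.MUTUALIST})
    if payoff < -INDIFFERENCE_TOL:
        return frozenset({Strategy.NON_MUTUALIST})
    return frozenset({Strategy.MUTUALIST, Strategy.NON_MUTUALIST})


def best_response_curve(params: GameParams, grid) -> BestResponseCurve:
    """Best-response correspondence evaluated over a grid of opponent mixes."""
    grid = np.asarray(grid, dtype=float)
    responses = tuple(best_response(params, q) for q in np.atleast_1d(grid))
    return BestResponseCurve(grid=grid, responses=responses)
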