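"""Regime classification, interior equilibria and stability/ESS analysis.

Because the non-mutualist mean payoff is identically zero in the
simplified game, the direction of selection at frequency ``x`` is the
sign of the mutualist mean fitness ``W_M(x)``, which is strictly
decreasing in ``x`` (more mutualist competitors means a smaller share of
the microbial pool).  Three generic regimes follow from comparing the
trade cost with the two extreme shares:

* ``c_t > b_mn``          -- mutualism never pays: non-mutualist fixation;
* ``c_t < b_mn/(n+1)``    -- mutualism pays even in an all-mutualist
  neighbourhood: mutualist fixation (equivalently ``b_mn/c_t > n + 1``);
* ``b_mn/(n+1) < c_t < b_mn`` -- mutualism pays only when rare: a unique
  stable interior equilibrium ``x*`` where both genotypes coexist.

Closed forms for the interior equilibrium exist for small
neighbourhoods: ``x* = 2 (1 - c_t/b_mn)`` for ``n = 1`` and
``x* = (3 - sqrt(12 c_t/b_mn - 3)) / 2`` for ``n = 2``.  For larger
``n`` the equilibrium condition is a higher-degree polynomial with no
practical radical solution (none exists at all for ``n >= 4``), so a
bracketing root finder on ``W_M`` is used; monotonicity guarantees the
root is unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import brentq

from .game_core import mean_mutualist_fitness
from .params import GameParams

__all__ = [
    "Regime",
    "RegimeResult",
    "Equilibrium",
    "EquilibriumReport",
    "NoClosedFormError",
    "classify_regime",
    "interior_equilibrium_closed_form",
    "interior_equilibrium_numeric",
    "stability_report",
]

#: Relative tolerance within which c_t is considered to sit exactly on a
#: regime boundary (the analysis uses strict inequalities; equalities are
#: structurally unstable and reported as such rather than silently binned).
DEFAULT_BOUNDARY_TOL = 1e-9


class Regime(str, Enum):
    NON_MUTUALIST_FIXATION = "non_mutualist_fixation"
    MUTUALIST_FIXATION = "mutualist_fixation"
    COEXISTENCE = "coexistence"
    DEGENERATE_BOUNDARY = "degenerate_boundary"


@dataclass(frozen=True)
class RegimeResult:
    """Regime label plus the two boundary values it was judged against."""

    label: Regime
    upper_threshold: float  # c_t = b_mn: above it mutualism never pays
    lower_threshold: float  # c_t = b_mn/(n+1): below it mutualism always pays

    def __eq__(self, other):  # allow comparison against a bare Regime label
        if isinstance(other, Regime):
            return self.label is other
        return NotImplemented

    def __hash__(self):
        return hash((self.label, self.upper_threshold, self.lower_threshold))


@dataclass(frozen=True)
class Equilibrium:
    x: float
    stable: bool
    origin: str  # "boundary" or "interior"


@dataclass(frozen=True)
class EquilibriumReport:
    """All equilibria of the replicator dynamics with stability labels.

    ``ess`` describes the evolutionarily stable population composition:
    ``"all_non_mutualist"``, ``"all_mutualist"``, ``"mixed"`` (coexistence
    at ``interior_x_star``), or ``"degenerate"`` on a regime boundary.
    """

    params: GameParams
    regime: RegimeResult
    equilibria: tuple[Equilibrium, ...]
    ess: str
    interior_x_star: float | None = field(default=None)


class NoClosedFormError(NotImplementedError):
    """Raised when no closed-form interior equilibrium is implemented.

    Radical solutions beyond ``n = 2`` are impractical (and impossible
    for ``n >= 4``); use :func:`interior_equilibrium_numeric`.
    """


def _isclose_rel(a: float, b: float, tol: float) -> bool:
    return abs(a - b) <= tol * max(abs(a), abs(b), 1e-300)


def classify_regime(
    params: GameParams, tol: float = DEFAULT_BOUNDARY_TOL
) -> RegimeResult:
    """Classify the cost-benefit regime of a parameter set.

    ``tol`` is the relative tolerance for declaring ``c_t`` equal to a
    threshold (``DEGENERATE_BOUNDARY``).
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    upper = params.b_mn
    lower = params.b_mn / (params.n + 1)
    if _isclose_rel(params.c_t, upper, tol) or _isclose_rel(params.c_t, lower, tol):
        label = Regime.DEGENERATE_BOUNDARY
    elif params.c_t > upper:
        label = Regime.NON_MUTUALIST_FIXATION
    elif params.c_t < lower:
        label = Regime.MUTUALIST_FIXATION
    else:
        label = Regime.COEXISTENCE
    return RegimeResult(label=label, upper_threshold=upper, lower_threshold=lower)


def interior_equilibrium_closed_form(params: GameParams) -> float:
    """Closed-form coexistence equilibrium ``x*`` for ``n in {1, 2}``.

    Raises
    ------
    ValueError
        If the parameters are not in the COEXISTENCE regime.
    NoClosedFormError
        If ``n >= 3`` (use :func:`interior_equilibrium_numeric`).
    """
    regime = classify_regime(params)
    if regime.label is not Regime.COEXISTENCE:
        raise ValueError(
            f"closed-form x* requires the coexistence regime, got {regime.label.value}"
        )
    ratio = params.c_t / params.b_mn
    if params.n == 1:
        return 2.0 * (1.0 - ratio)
    if params.n == 2:
        return (3.0 - np.sqrt(12.0 * ratio - 3.0)) / 2.0
    raise NoClosedFormError(
        f"no closed-form interior equilibrium implemented for n={params.n}; "
        "use interior_equilibrium_numeric"
    )


def interior_equilibrium_numeric(
    params: GameParams, tol: float = 1e-10
) -> float | None:
    """Unique interior root of ``W_M`` in (0, 1), or ``None`` if absent.

    The root exists iff ``W_M(0) > 0 > W_M(1)``; strict monotonicity of
    ``W_M`` makes it unique, so Brent's bracketing method converges to
    absolute tolerance ``tol``.
    """
    w0 = mean_mutualist_fitness(params, 0.0)
    w1 = mean_mutualist_fitness(params, 1.0)
    if not (np.isfinite(w0) and np.isfinite(w1)):
        raise ArithmeticError(
            f"non-finite mean fitness at the boundary: W_M(0)={w0}, W_M(1)={w1}"
        )
    if not (w0 > 0.0 > w1):
        return None
    root = brentq(
        lambda x: mean_mutualist_fitness(params, x), 0.0, 1.0, xtol=tol, rtol=8.9e-16
    )
    return float(min(max(root, 0.0), 1.0))


def stability_report(params: GameParams, tol: float = DEFAULT_BOUNDARY_TOL) -> EquilibriumReport:
    """Full equilibrium-and-stability report for the replicator dynamics.

    Fixation at ``x = 0`` is stable iff a lone mutualist cannot invade
    (``W_M(0) = b_mn - c_t < 0``); fixation at ``x = 1`` is stable iff an
    all-mutualist population resists invasion (``W_M(1) = b_mn/(n+1) -
    c_t > 0``).  In the coexistence regime both fixations are unstable
    and the unique interior equilibrium is stable (selection pushes up
    below ``x*`` and down above it), making the mixed composition the ESS.
    """
    regime = classify_regime(params, tol=tol)
    w0 = mean_mutualist_fitness(params, 0.0)
    w1 = mean_mutualist_fitness(params, 1.0)

    x_star: float | None = None
    if regime.label is Regime.COEXISTENCE:
        x_star = interior_equilibrium_numeric(params)

    equilibria = [
        Equilibrium(x=0.0, stable=w0 < 0.0, origin="boundary"),
        Equilibrium(x=1.0, stable=w1 > 0.0, origin="boundary"),
    ]
    if x_star is not None:
        equilibria.append(Equilibrium(x=x_star, stable=True, origin="interior"))

    if regime.label is Regime.NON_MUTUALIST_FIXATION:
        ess = "all_non_mutualist"
    elif regime.label is Regime.MUTUALIST_FIXATION:
        ess = "all_mutualist"
    elif regime.label is Regime.COEXISTENCE:
        ess = "mixed"
    else:
        ess = "degenerate"

    return EquilibriumReport(
        params=params,
        regime=regime,
        equilibria=tuple(equilibria),
        ess=ess,
        interior_x_star=x_star,
    )
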