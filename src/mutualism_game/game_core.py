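"""Payoff matrices and frequency-dependent mean fitness.

The pairwise game (``n = 1``) has full payoff matrix

====================  =============================  =============================
focal \\ opponent      non-mutualist                  mutualist
====================  =============================  =============================
non-mutualist         ``b_an/2 - c_r``               ``b_an/2 - c_r``
mutualist             ``b_an/2 - c_r + b_mn - c_t``  ``b_an/2 - c_r + b_mn/2 - c_t``
====================  =============================  =============================

Subtracting the strategy-independent baseline ``b_an/2 - c_r`` gives the
simplified matrix whose non-mutualist row is identically zero.  With a
neighbourhood of ``n`` competitors the ``b_mn`` pool is divided equally
among the focal mutualist and its ``k`` mutualist neighbours, so a
mutualist with ``k`` mutualist neighbours nets ``b_mn/(k+1) - c_t``.

When neighbourhoods are assembled at random from a well-mixed population
with mutualist frequency ``x``, the mutualist neighbour count is
binomial, ``k ~ Binomial(n, x)``, and the expected mutualist payoff has
the closed form

    W_M(x) = b_mn * (1 - (1-x)**(n+1)) / (x * (n+1)) - c_t,

with the removable singularity at ``x = 0`` filled by its limit
``b_mn - c_t`` (a lone mutualist keeps the whole pool).  The identity
between the closed form and the binomial expectation follows from
``E[1/(k+1)] = (1 - (1-x)**(n+1)) / ((n+1) * x)`` for a binomial count.
"""

from __future__ import annotations

import numpy as np

from .params import GameParams, Strategy, Variant

__all__ = [
    "pairwise_payoff",
    "neighbourhood_payoff",
    "mean_mutualist_fitness",
    "mean_nonmutualist_fitness",
]


def _as_strategy(value) -> Strategy:
    try:
        return Strategy(value)
    except ValueError:
        raise ValueError(
            f"unknown strategy {value!r}; expected one of "
            f"{[s.value for s in Strategy]}"
        ) from None


def _as_variant(value) -> Variant:
    try:
        return Variant(value)
    except ValueError:
        raise ValueError(
            f"unknown variant {value!r}; expected one of "
            f"{[v.value for v in Variant]}"
        ) from None


def pairwise_payoff(
    params: GameParams,
    focal: Strategy | str,
    opponent: Strategy | str,
    variant: Variant | str = Variant.SIMPLIFIED,
) -> float:
    """Payoff of ``focal`` against ``opponent`` in the two-player game.

    Always uses pairwise (``n = 1``) semantics: the two plants split the
    freely available pool in half, and two mutualists split ``b_mn`` in
    half, regardless of ``params.n``.

    Parameters
    ----------
    params : GameParams
    focal, opponent : Strategy or str
    variant : Variant or str
        ``"full"`` keeps the baseline ``b_an/2 - c_r``; ``"simplified"``
        subtracts it.
    """
    focal = _as_strategy(focal)
    opponent = _as_strategy(opponent)
    variant = _as_variant(variant)

    if focal is Strategy.NON_MUTUALIST:
        simplified = 0.0
    elif opponent is Strategy.NON_MUTUALIST:
        simplified = params.b_mn - params.c_t
    else:
        simplified = params.b_mn / 2.0 - params.c_t

    if variant is Variant.SIMPLIFIED:
        return simplified
    return simplified + (params.b_an / 2.0 - params.c_r)


def neighbourhood_payoff(params: GameParams, focal: Strategy | str, k: int) -> float:
    """Realized simplified payoff in a neighbourhood with ``k`` mutualist
    neighbours among the ``n`` competitors.

    A non-mutualist nets 0.  A focal mutualist shares ``b_mn`` equally
    with its ``k`` mutualist neighbours and pays the trade cost:
    ``b_mn/(k+1) - c_t``.  ``k = 0`` recovers the lone-mutualist payoff
    ``b_mn - c_t``; ``k = n`` the all-mutualist payoff
    ``b_mn/(n+1) - c_t``.
    """
    focal = _as_strategy(focal)
    if isinstance(k, bool) or not isinstance(k, (int, np.integer)):
        raise TypeError(f"k must be an integer, got {k!r}")
    if not 0 <= k <= params.n:
        raise ValueError(f"k must satisfy 0 <= k <= n={params.n}, got {k}")
    if focal is Strategy.NON_MUTUALIST:
        return 0.0
    return params.b_mn / (k + 1) - params.c_t


def _expected_share(x: np.ndarray, n: int) -> np.ndarray:
    """E[1/(k+1)] for k ~ Binomial(n, x): (1-(1-x)^(n+1)) / ((n+1) x).

    Evaluated via expm1/log1p to keep full precision near x = 0, where
    the expression has a removable singularity with limit 1.
    """
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    interior = (x > 0.0) & (x < 1.0)
    xi = x[interior]
    out[interior] = -np.expm1((n + 1) * np.log1p(-xi)) / ((n + 1) * xi)
    out[x == 1.0] = 1.0 / (n + 1)
    return out


def mean_mutualist_fitness(params: GameParams, x) -> float | np.ndarray:
    """Expected simplified payoff of a mutualist at population frequency ``x``.

    Returns ``b_mn * (1 - (1-x)**(n+1)) / (x*(n+1)) - c_t``, the
    expectation of ``b_mn/(k+1) - c_t`` over the binomial neighbour
    count ``k ~ Binomial(n, x)``; the value at ``x = 0`` is the
    continuous limit ``b_mn - c_t``.  Accepts scalars or arrays.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError(f"x must lie in [0, 1], got {x!r}")
    result = params.b_mn * _expected_share(arr, params.n) - params.c_t
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(result)
    return result


def mean_nonmutualist_fitness(
    params: GameParams, x, variant: Variant | str = Variant.SIMPLIFIED
) -> float | np.ndarray:
    """Expected payoff of a non-mutualist: frequency-independent.

    Zero in the simplified game; the neighbourhood baseline
    ``b_an/(n+1) - c_r`` in the full game.
    """
    variant = _as_variant(variant)
    arr = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError(f"x must lie in [0, 1], got {x!r}")
    value = 0.0 if variant is Variant.SIMPLIFIED else params.baseline()
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(value)
    return np.full_like(arr, value)
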