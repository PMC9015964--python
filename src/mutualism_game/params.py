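"""Core parameter and label types for the host-host mutualism game.

The model describes a well-mixed plant population with two heritable
strategies: *mutualists* partner with a soil microbe (mycorrhizae,
rhizobia) and receive nutrients in exchange for carbon, while
*non-mutualists* forgo the partnership.  Five constants define one game
instance:

``b_an``
    fitness benefit of the freely available soil-nutrient pool, shared
    by every competitor regardless of strategy;
``b_mn``
    fitness benefit of the microbially obtained nutrient pool, shared
    only among the mutualists competing for it;
``c_r``
    cost of root production, paid by every plant;
``c_t``
    cost of trading carbon to the microbe, paid by mutualists only;
``n``
    number of competitors in the focal plant's local neighbourhood
    (``n + 1`` plants divide each contested pool; ``n = 1`` is the
    pairwise game).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = ["Strategy", "Variant", "GameParams"]


class Strategy(str, Enum):
    """The two heritable host strategies."""

    MUTUALIST = "mutualist"
    NON_MUTUALIST = "non_mutualist"


class Variant(str, Enum):
    """Payoff-matrix variant.

    ``FULL`` keeps the strategy-independent baseline ``b_an/(n+1) - c_r``
    in every cell; ``SIMPLIFIED`` subtracts it, so every non-mutualist
    entry is exactly zero and only the net benefit of mutualism remains.
    """

    FULL = "full"
    SIMPLIFIED = "simplified"


@dataclass(frozen=True)
class GameParams:
    """One instance of the mutualism game.

    Parameters
    ----------
    b_mn : float
        Fitness benefit of microbially obtained nutrients (>= 0).
    c_t : float
        Fitness cost of trade with the microbe (>= 0).
    b_an : float, optional
        Fitness benefit of freely available nutrients (>= 0).  Only the
        full payoff variant depends on it.
    c_r : float, optional
        Fitness cost of root production (>= 0).  Only the full payoff
        variant depends on it.
    n : int, optional
        Neighbourhood size: number of competitors per focal plant
        (integer >= 1; default 1, the pairwise game).
    """

    b_mn: float
    c_t: float
    b_an: float = 0.0
    c_r: float = 0.0
    n: int = 1

    def __post_init__(self) -> None:
        for name in ("b_mn", "c_t", "b_an", "c_r"):
            value = getattr(self, name)
            if not isinstance(value, (int, float, np.floating, np.integer)):
                raise TypeError(f"{name} must be a real number, got {value!r}")
            value = float(value)
            if not math.isfinite(value) or value < 0.0:
                raise ValueError(f"{name} must be finite and >= 0, got {value}")
            object.__setattr__(self, name, value)
        if isinstance(self.n, bool) or not isinstance(self.n, (int, np.integer)):
            raise TypeError(f"n must be an integer, got {self.n!r}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        object.__setattr__(self, "n", int(self.n))

    def baseline(self) -> float:
        """Strategy-independent payoff component ``b_an/(n+1) - c_r``.

        This is the net benefit from the freely available nutrient pool
        after equal division among the ``n + 1`` neighbourhood members,
        minus the universal root cost.  Subtracting it from the full
        matrix yields the simplified matrix.
        """
        return self.b_an / (self.n + 1) - self.c_r

    def to_dict(self) -> dict:
        return {
            "b_mn": self.b_mn,
            "c_t": self.c_t,
            "b_an": self.b_an,
            "c_r": self.c_r,
            "n": self.n,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GameParams":
        known = {k: data[k] for k in ("b_mn", "c_t", "b_an", "c_r", "n") if k in data}
        n = known.get("n")
        if n is not None:
            if isinstance(n, float):
                if not n.is_integer():
                    raise ValueError(f"n must be an integer, got {n}")
                known["n"] = int(n)
        return cls(**known)
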