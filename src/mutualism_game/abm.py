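"""Finite-population Wright-Fisher simulator and Monte-Carlo oracle.

A population of ``pop_size`` plants carries the two heritable
strategies.  Each non-overlapping generation:

1. every plant is placed in a fresh random neighbourhood of ``n``
   competitors drawn uniformly without replacement from the rest of the
   population, and receives its realized simplified payoff
   (:func:`~mutualism_game.game_core.neighbourhood_payoff`) plus a
   constant ``fitness_floor`` that keeps reproduction weights positive;
2. ``pop_size`` offspring are sampled with replacement, each choosing a
   parent with probability proportional to its floored payoff
   (payoff-proportional multinomial resampling).

Because payoffs depend on a neighbourhood only through its mutualist
count, step 1 is realized by drawing each focal mutualist's count of
mutualist neighbours from the exact hypergeometric law of uniform
without-replacement sampling, which is distributionally identical to
enumerating neighbour identities and much faster.  The additive floor
cancels from payoff *differences*, so the deterministic (infinite
population) limit keeps its interior fixed point where ``W_M = W_N``;
the floor only rescales the strength of selection relative to drift,
which is why recovery tolerances are statistical (Monte-Carlo standard
errors), not exact.

Frequencies 0 and 1 are absorbing: with no variation, reproduction
cannot recreate the lost strategy (there is no mutation).

Randomness derives from a single master seed via
``numpy.random.SeedSequence`` spawning one child stream per replicate,
so results are bit-for-bit reproducible and replicates independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .equilibria import Regime, classify_regime, interior_equilibrium_numeric
from .params import GameParams

__all__ = [
    "SimConfig",
    "SimResult",
    "RecoveryReport",
    "sample_neighbourhood_payoffs",
    "run_simulation",
    "parameter_recovery",
]


def default_fitness_floor(params: GameParams) -> float:
    """Default additive floor ``c_t + 1``.

    The most negative simplified payoff is ``b_mn/(n+1) - c_t >= -c_t``,
    so ``c_t + 1`` guarantees every reproduction weight is >= 1.
    """
    return params.c_t + 1.0


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one Wright-Fisher experiment."""

    params: GameParams
    pop_size: int = 2000
    x0: float = 0.5
    generations: int = 200
    replicates: int = 50
    seed: int = 0
    fitness_floor: float | None = None  # None -> c_t + 1

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError(f"pop_size must be >= 2, got {self.pop_size}")
        if self.pop_size < self.params.n + 1:
            raise ValueError(
                f"pop_size={self.pop_size} cannot host neighbourhoods of "
                f"n={self.params.n} competitors (need >= n+1 plants)"
            )
        if not 0.0 <= self.x0 <= 1.0:
            raise ValueError(f"x0 must lie in [0, 1], got {self.x0}")
        count = self.pop_size * self.x0
        if abs(count - round(count)) > 1e-9:
            raise ValueError(
                f"pop_size*x0 = {count} does not round to an integer mutualist count"
            )
        if self.generations < 1 or self.replicates < 1:
            raise ValueError("generations and replicates must be >= 1")
        floor = self.effective_floor()
        min_payoff = min(0.0, self.params.b_mn / (self.params.n + 1) - self.params.c_t)
        if floor + min_payoff <= 0.0:
            raise ValueError(
                f"fitness_floor={floor} does not make all reproduction weights "
                f"positive (minimum payoff {min_payoff})"
            )

    def effective_floor(self) -> float:
        if self.fitness_floor is None:
            return default_fitness_floor(self.params)
        return float(self.fitness_floor)

    @property
    def initial_mutualists(self) -> int:
        return int(round(self.pop_size * self.x0))


@dataclass(frozen=True)
class SimResult:
    """Outcome of a Wright-Fisher experiment.

    ``trajectories`` has shape ``(replicates, generations + 1)`` with the
    mutualist frequency at every generation (column 0 is the initial
    state).  ``replicate_seeds`` records the per-replicate child-stream
    entropy for full reproducibility.
    """

    config: SimConfig
    trajectories: np.ndarray
    terminal_frequencies: np.ndarray = field(init=False)
    fixed_at: np.ndarray = field(init=False)  # 0.0, 1.0 or nan per replicate
    replicate_seeds: tuple = ()

    def __post_init__(self) -> None:
        terminal = self.trajectories[:, -1].copy()
        fixed = np.full(terminal.shape, np.nan)
        fixed[terminal == 0.0] = 0.0
        fixed[terminal == 1.0] = 1.0
        object.__setattr__(self, "terminal_frequencies", terminal)
        object.__setattr__(self, "fixed_at", fixed)

    def summary(self) -> dict:
        terminal = self.terminal_frequencies
        sd = float(np.std(terminal, ddof=1)) if terminal.size > 1 else 0.0
        return {
            "mean_terminal_frequency": float(np.mean(terminal)),
            "sd_terminal_frequency": sd,
            "se_terminal_frequency": sd / np.sqrt(terminal.size),
            "replicates": int(terminal.size),
            "fraction_fixed_mutualist": float(np.mean(terminal == 1.0)),
            "fraction_fixed_non_mutualist": float(np.mean(terminal == 0.0)),
        }


@dataclass(frozen=True)
class RecoveryReport:
    """Comparison of simulated terminal frequencies against the analytic target."""

    regime: Regime
    target: float
    mean_terminal: float
    bias: float
    se: float
    tolerance_se: float
    passed: bool
    notes: tuple[str, ...] = ()


def sample_neighbourhood_payoffs(
    params: GameParams,
    strategies: np.ndarray,
    rng: np.random.Generator,
    fitness_floor: float = 0.0,
) -> np.ndarray:
    """Realized floored payoff of every individual under fresh random
    neighbourhoods.

    ``strategies`` is a boolean/0-1 vector (1 = mutualist).  Each focal
    plant's ``n`` competitors are drawn uniformly without replacement
    from the other ``pop_size - 1`` plants; only the mutualist count
    matters for the payoff, so it is drawn directly from the matching
    hypergeometric distribution.  Non-mutualists earn the floor alone.
    """
    strategies = np.asarray(strategies)
    pop_size = strategies.size
    if pop_size < params.n + 1:
        raise ValueError(
            f"population of {pop_size} cannot host neighbourhoods of "
            f"n={params.n} competitors"
        )
    is_mut = strategies.astype(bool)
    n_mut = int(np.count_nonzero(is_mut))
    payoffs = np.full(pop_size, fitness_floor, dtype=float)
    if n_mut:
        # mutualist neighbours of a focal mutualist: n draws from a pool of
        # n_mut-1 mutualists and pop_size-n_mut non-mutualists
        k = rng.hypergeometric(n_mut - 1, pop_size - n_mut, params.n, size=n_mut)
        payoffs[is_mut] += params.b_mn / (k + 1.0) - params.c_t
    return payoffs


def _run_replicate(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    params = config.params
    pop_size = config.pop_size
    floor = config.effective_floor()
    m = config.initial_mutualists
    freqs = np.empty(config.generations + 1)
    freqs[0] = m / pop_size
    for gen in range(1, config.generations + 1):
        if m == 0 or m == pop_size:
            freqs[gen:] = m / pop_size  # absorbing: no variation left
            break
        strategies = np.zeros(pop_size, dtype=bool)
        strategies[:m] = True  # individuals are exchangeable within a strategy
        payoffs = sample_neighbourhood_payoffs(params, strategies, rng, floor)
        total = payoffs.sum()
        if total <= 0.0 or not np.isfinite(total):
            raise ValueError(
                "total reproduction weight is not positive; raise fitness_floor"
            )
        # multinomial parent choice: offspring count of the mutualist class
        # is binomial in its share of total weight
        m = int(rng.binomial(pop_size, payoffs[strategies].sum() / total))
        freqs[gen] = m / pop_size
    return freqs


def run_simulation(config: SimConfig) -> SimResult:
    """Run all replicates of a Wright-Fisher experiment.

    Bit-for-bit reproducible for identical configs (including seed).
    """
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(config.replicates)
    trajectories = np.empty((config.replicates, config.generations + 1))
    for i, child in enumerate(children):
        trajectories[i] = _run_replicate(config, np.random.default_rng(child))
    return SimResult(
        config=config,
        trajectories=trajectories,
        replicate_seeds=tuple(tuple(c.entropy if isinstance(c.entropy, tuple) else (c.entropy,)) + tuple(c.spawn_key) for c in children),
    )


def parameter_recovery(
    sim: SimResult, params: GameParams | None = None, tolerance_se: float = 3.0
) -> RecoveryReport:
    """Check that the simulation recovers the analytic prediction.

    The target is the interior equilibrium ``x*`` in the coexistence
    regime and the corresponding absorbing frequency (0 or 1) in the
    fixation regimes; the check passes when the mean terminal frequency
    lies within ``tolerance_se`` Monte-Carlo standard errors of the
    target (with a degenerate-SE fallback to exact agreement).
    """
    if params is None:
        params = sim.config.params
    regime = classify_regime(params)
    notes: list[str] = []
    if regime.label is Regime.COEXISTENCE:
        target = interior_equilibrium_numeric(params)
    elif regime.label is Regime.MUTUALIST_FIXATION:
        target = 1.0
        notes.append("fixation regime: recovery target is the absorbing state 1")
    elif regime.label is Regime.NON_MUTUALIST_FIXATION:
        target = 0.0
        notes.append("fixation regime: recovery target is the absorbing state 0")
    else:
        target = np.nan
        notes.append("degenerate boundary regime: no well-defined recovery target")
    if sim.config.pop_size < 100:
        notes.append(
            "small population: genetic drift dominates selection and the "
            "terminal distribution is wide; interpret the check cautiously"
        )
    stats = sim.summary()
    mean_terminal = stats["mean_terminal_frequency"]
    se = stats["se_terminal_frequency"]
    bias = mean_terminal - target if np.isfinite(target) else np.nan
    if not np.isfinite(target):
        passed = False
    elif se > 0.0:
        passed = abs(bias) <= tolerance_se * se
    else:
        passed = bias == 0.0
    return RecoveryReport(
        regime=regime.label,
        target=float(target),
        mean_terminal=mean_terminal,
        bias=float(bias),
        se=se,
        tolerance_se=tolerance_se,
        passed=bool(passed),
        notes=tuple(notes),
    )
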