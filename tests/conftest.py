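import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mutualism_game import GameParams

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def coexistence_params() -> GameParams:
    """Pairwise game with B_MN > c_t > B_MN/2: stable interior x* = 0.5."""
    return GameParams(b_mn=4.0, c_t=3.0, n=1)


@pytest.fixture
def mutualist_fixation_params() -> GameParams:
    """c_t < B_MN/2: mutualism is dominant."""
    return GameParams(b_mn=4.0, c_t=1.0, n=1)


@pytest.fixture
def non_mutualist_fixation_params() -> GameParams:
    """c_t > B_MN: mutualism never pays."""
    return GameParams(b_mn=4.0, c_t=5.0, n=1)


def binomial_mean_fitness_oracle(params: GameParams, x: float) -> float:
    """Brute-force binomial expectation of the mutualist payoff.

    Independent of the closed form under test: sums
    C(n,k) x^k (1-x)^(n-k) [b_mn/(k+1) - c_t] over k = 0..n.
    """
    from math import comb

    n = params.n
    total = 0.0
    for k in range(n + 1):
        weight = comb(n, k) * x**k * (1.0 - x) ** (n - k)
        total += weight * (params.b_mn / (k + 1) - params.c_t)
    return total


@pytest.fixture
def binomial_oracle():
    return binomial_mean_fitness_oracle


def random_coexistence_params(rng: np.random.Generator, n: int) -> GameParams:
    """Draw a parameter set strictly inside the coexistence wedge."""
    b_mn = rng.uniform(0.5, 20.0)
    lo, hi = b_mn / (n + 1), b_mn
    # keep away from the boundaries so the regime is unambiguous
    c_t = lo + (0.05 + 0.9 * rng.uniform()) * (hi - lo)
    return GameParams(b_mn=b_mn, c_t=c_t, n=n)
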