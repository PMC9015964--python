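"""Regime classification, interior equilibria and stability."""

import numpy as np
import pytest

from mutualism_game import (
    GameParams,
    NoClosedFormError,
    Regime,
    classify_regime,
    interior_equilibrium_closed_form,
    interior_equilibrium_numeric,
    mean_mutualist_fitness,
    stability_report,
)
from conftest import random_coexistence_params


class TestClassifyRegime:
    @pytest.mark.parametrize(
        "params, expected",
        [
            (GameParams(b_mn=4, c_t=5, n=1), Regime.NON_MUTUALIST_FIXATION),
            (GameParams(b_mn=4, c_t=1, n=1), Regime.MUTUALIST_FIXATION),
            (GameParams(b_mn=4, c_t=3, n=1), Regime.COEXISTENCE),
            # larger neighbourhood moves the lower threshold down: the
            # mutualist-fixation criterion is b_mn/c_t > n + 1
            (GameParams(b_mn=4, c_t=1, n=5), Regime.COEXISTENCE),
            (GameParams(b_mn=4, c_t=0.5, n=5), Regime.MUTUALIST_FIXATION),
            # exactly on a boundary
            (GameParams(b_mn=4, c_t=4, n=1), Regime.DEGENERATE_BOUNDARY),
            (GameParams(b_mn=4, c_t=2, n=1), Regime.DEGENERATE_BOUNDARY),
            (GameParams(b_mn=3, c_t=1, n=2), Regime.DEGENERATE_BOUNDARY),
            # a game without microbial benefit
            (GameParams(b_mn=0, c_t=1, n=1), Regime.NON_MUTUALIST_FIXATION),
            (GameParams(b_mn=0, c_t=0, n=1), Regime.DEGENERATE_BOUNDARY),
        ],
    )
    def test_labels(self, params, expected):
        assert classify_regime(params).label is expected

    def test_thresholds_reported(self):
        result = classify_regime(GameParams(b_mn=6, c_t=3, n=2))
        assert result.upper_threshold == pytest.approx(6.0)
        assert result.lower_threshold == pytest.approx(2.0)

    def test_label_matches_boundary_sign_pattern(self):
        """The inequality classification agrees with the signs of the
        mutualist mean fitness at x = 0 and x = 1; (-, +) never occurs."""
        rng = np.random.default_rng(11)
        for _ in range(2000):
            params = GameParams(
                b_mn=rng.uniform(0.01, 10),
                c_t=rng.uniform(0.0, 12),
                n=int(rng.integers(1, 9)),
            )
            label = classify_regime(params).label
            w0 = mean_mutualist_fitness(params, 0.0)
            w1 = mean_mutualist_fitness(params, 1.0)
            assert not (w0 < 0.0 < w1)
            if label is Regime.MUTUALIST_FIXATION:
                assert w0 > 0.0 and w1 > 0.0
            elif label is Regime.NON_MUTUALIST_FIXATION:
                assert w0 < 0.0 and w1 < 0.0
            elif label is Regime.COEXISTENCE:
                assert w0 > 0.0 > w1


class TestClosedForm:
    def test_pairwise_equilibrium(self):
        # x* = 2 (1 - c_t / b_mn)
        assert interior_equilibrium_closed_form(
            GameParams(b_mn=4, c_t=3, n=1)
        ) == pytest.approx(0.5)

    def test_two_competitor_equilibrium(self):
        # x* = (3 - sqrt(12 c_t/b_mn - 3)) / 2
        assert interior_equilibrium_closed_form(
            GameParams(b_mn=12, c_t=7, n=2)
        ) == pytest.approx(0.5)

    def test_requires_coexistence_regime(self):
        with pytest.raises(ValueError, match="coexistence"):
            interior_equilibrium_closed_form(GameParams(b_mn=4, c_t=5, n=1))
        # exactly on the mutualist-fixation threshold: degenerate, the
        # formula would return the boundary value 1, not an interior point
        with pytest.raises(ValueError, match="coexistence"):
            interior_equilibrium_closed_form(GameParams(b_mn=3, c_t=1, n=2))

    def test_no_closed_form_beyond_two_competitors(self):
        with pytest.raises(NoClosedFormError, match="numeric"):
            interior_equilibrium_closed_form(GameParams(b_mn=8, c_t=3, n=3))


class TestNumericEquilibrium:
    def test_agrees_with_closed_forms(self):
        """Brent root of W_M matches the radical solutions for n in {1, 2}."""
        rng = np.random.default_rng(23)
        for _ in range(100):
            params = random_coexistence_params(rng, n=int(rng.integers(1, 3)))
            closed = interior_equilibrium_closed_form(params)
            numeric = interior_equilibrium_numeric(params, tol=1e-12)
            assert numeric == pytest.approx(closed, abs=1e-8)
            assert 0.0 < numeric < 1.0

    def test_none_outside_coexistence(self):
        assert interior_equilibrium_numeric(GameParams(b_mn=4, c_t=5, n=3)) is None
        assert interior_equilibrium_numeric(GameParams(b_mn=4, c_t=0.5, n=1)) is None

    def test_large_neighbourhood_against_grid_scan_oracle(self):
        """n = 6 root checked against an independent fine-grid sign scan."""
        params = GameParams(b_mn=10, c_t=2, n=6)  # b_mn/c_t = 5 < 7: coexistence
        root = interior_equilibrium_numeric(params, tol=1e-10)
        # oracle: bracket the sign change of the binomial-sum fitness on a
        # fine grid, independent of the solver
        xs = np.linspace(1e-9, 1.0, 2_000_001)
        values = params.b_mn * (1 - (1 - xs) ** 7) / (xs * 7) - params.c_t
        idx = np.nonzero(np.diff(np.sign(values)))[0][0]
        assert xs[idx] <= root <= xs[idx + 1]

    def test_comparative_statics(self):
        """x* falls with the trade cost and rises with the benefit."""
        base = GameParams(b_mn=10, c_t=4, n=2)
        x_base = interior_equilibrium_numeric(base)
        assert interior_equilibrium_numeric(GameParams(b_mn=10, c_t=5, n=2)) < x_base
        assert interior_equilibrium_numeric(GameParams(b_mn=11, c_t=4, n=2)) > x_base

    def test_limits_toward_regime_boundaries(self):
        """x* -> 0 as c_t -> b_mn; x* -> 1 as c_t -> b_mn/(n+1)."""
        n = 2
        for eps, lo_expect, hi_expect in [(1e-4, 0.01, 0.99), (1e-6, 1e-3, 0.999)]:
            near_upper = GameParams(b_mn=4, c_t=4 * (1 - eps), n=n)
            near_lower = GameParams(b_mn=4, c_t=4 / 3 * (1 + eps), n=n)
            assert interior_equilibrium_numeric(near_upper) < lo_expect
            assert interior_equilibrium_numeric(near_lower) > hi_expect


class TestStabilityReport:
    def test_non_mutualist_fixation(self):
        report = stability_report(GameParams(b_mn=4, c_t=5, n=1))
        stable = {e.x: e.stable for e in report.equilibria}
        assert stable == {0.0: True, 1.0: False}
        assert report.ess == "all_non_mutualist"
        assert report.interior_x_star is None

    def test_mutualist_fixation(self):
        report = stability_report(GameParams(b_mn=4, c_t=1, n=1))
        stable = {e.x: e.stable for e in report.equilibria}
        assert stable == {0.0: False, 1.0: True}
        assert report.ess == "all_mutualist"

    def test_coexistence(self):
        report = stability_report(GameParams(b_mn=4, c_t=3, n=1))
        stable = {e.x: e.stable for e in report.equilibria}
        assert stable[0.0] is False and stable[1.0] is False
        assert report.interior_x_star == pytest.approx(0.5)
        interior = [e for e in report.equilibria if e.origin == "interior"]
        assert len(interior) == 1 and interior[0].stable
        assert report.ess == "mixed"

    def test_boundaries_always_present(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            params = GameParams(
                b_mn=rng.uniform(0.1, 8), c_t=rng.uniform(0, 10), n=int(rng.integers(1, 6))
            )
            xs = [e.x for e in stability_report(params).equilibria]
            assert 0.0 in xs and 1.0 in xs
            interior = [x for x in xs if 0.0 < x < 1.0]
            assert len(interior) <= 1
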