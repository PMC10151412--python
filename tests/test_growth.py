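"""Mass-equivalent radius, time-doubling pairs, and exponent inference."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rangex as rx
from rangex import (
    average_growth_curves,
    bootstrap_mu_i,
    consistency_pairs,
    infer_kernel_exponent,
    mass_equivalent_radius,
)


def _power_curve(beta, A=1.0, t_max=400):
    return rx.make_fixture("power-law-curve", beta=beta, A=A, t_max=t_max)


class TestMassEquivalentRadius:
    def test_unit_radius_at_disc_mass(self):
        assert mass_equivalent_radius(math.pi * 3.0, 3.0) == pytest.approx(1.0)

    def test_square_root_scaling(self):
        assert mass_equivalent_radius(4000, 2.5) == pytest.approx(
            2 * mass_equivalent_radius(1000, 2.5))

    def test_reference_value(self):
        # K = 10, rb = 1 (rho = 10/pi): M = 1000 -> ell = 10
        rho = 10 / math.pi
        assert mass_equivalent_radius(1000, rho) == pytest.approx(10.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mass_equivalent_radius(100, 0.0)
        with pytest.raises(ValueError):
            mass_equivalent_radius(-1, 1.0)


class TestAverageGrowthCurves:
    def test_identical_runs_average_to_themselves(self):
        c = _power_curve(0.5, t_max=50)
        mean = average_growth_curves([c, c, c])
        np.testing.assert_allclose(mean["ell"], c["ell"])

    def test_pointwise_arithmetic(self):
        a = pd.DataFrame({"t": [0, 1, 2], "M": [1, 4, 16], "ell": [1.0, 2.0, 4.0]})
        b = pd.DataFrame({"t": [0, 1, 2], "M": [1, 16, 64], "ell": [1.0, 4.0, 8.0]})
        mean = average_growth_curves([a, b])
        np.testing.assert_allclose(mean["ell"], [1.0, 3.0, 6.0])

    def test_truncates_to_shortest_run(self):
        a = _power_curve(0.5, t_max=50)
        b = _power_curve(0.5, t_max=80)
        mean = average_growth_curves([a, b])
        assert mean["t"].iloc[-1] == 50


class TestConsistencyPairs:
    def test_algebra_for_quadratic_growth(self):
        pairs = consistency_pairs(_power_curve(2.0, t_max=100), d=2)
        t = pairs["t"].to_numpy()
        np.testing.assert_allclose(pairs["x"], t.astype(float) ** 2)
        np.testing.assert_allclose(pairs["y"], t.astype(float) ** 9 / 256)

    def test_constant_radius_gives_linear_rhs(self):
        t = np.arange(1, 101)
        curve = pd.DataFrame({"t": t, "M": np.full(100, 50), "ell": np.full(100, 3.0)})
        pairs = consistency_pairs(curve, d=2)
        # ell(t/2)**(2d) is the constant 3**4, so the RHS is exactly linear in t
        np.testing.assert_allclose(pairs["y"], pairs["t"] * 3.0**4)

    def test_only_even_late_half_times_used(self):
        pairs = consistency_pairs(_power_curve(1.0, t_max=100), d=2)
        t = pairs["t"].to_numpy()
        assert (t % 2 == 0).all()
        assert t.min() >= 50
        assert t.max() == 100

    def test_short_trajectory_warns_and_returns_empty(self):
        # a window whose half-times all predate the recorded grid
        curve = pd.DataFrame({"t": [5, 6, 7, 8], "M": [1, 2, 3, 4],
                              "ell": [1.0, 1.4, 1.7, 2.0]})
        with pytest.warns(UserWarning, match="too short"):
            pairs = consistency_pairs(curve, d=2)
        assert len(pairs) == 0


class TestInferKernelExponent:
    @given(beta=st.floats(0.3, 3.0))
    @settings(deadline=None, max_examples=40)
    def test_exponent_recovery_identity(self, beta):
        # ell = A t**beta gives nu = 1/beta + 2d exactly
        fit = infer_kernel_exponent(consistency_pairs(_power_curve(beta), d=2), d=2)
        assert fit.nu == pytest.approx(1 / beta + 4, rel=1e-9)
        assert fit.mu_i == pytest.approx(1 / beta + 2, rel=1e-9)

    @pytest.mark.parametrize("mu", [1.5, 2.5])
    def test_asymptotic_power_law_recovers_mu(self, mu):
        beta = 1 / (mu - 2)
        fit = infer_kernel_exponent(consistency_pairs(_power_curve(beta), d=2), d=2)
        assert fit.mu_i == pytest.approx(mu, rel=1e-9)

    def test_marginal_kernel_recovered_in_the_steep_growth_limit(self):
        # mu -> d corresponds to beta -> infinity; mu_i = 1/beta + d
        # converges to d from above (short window keeps ell**(2d) finite)
        fit = infer_kernel_exponent(consistency_pairs(_power_curve(50.0, t_max=60), d=2), d=2)
        assert fit.mu_i == pytest.approx(2.0 + 1 / 50.0, rel=1e-9)

    def test_linear_growth_maps_to_marginal_kernel(self):
        fit = infer_kernel_exponent(consistency_pairs(_power_curve(1.0), d=2), d=2)
        assert fit.mu_i == pytest.approx(3.0, rel=1e-9)

    def test_overlay_scaling_changes_only_prefactor(self):
        pairs = consistency_pairs(_power_curve(0.7), d=2)
        fit = infer_kernel_exponent(pairs, d=2)
        scaled = pairs.assign(y=pairs["y"] * 37.5)
        fit2 = infer_kernel_exponent(scaled, d=2)
        assert fit2.nu == pytest.approx(fit.nu, rel=1e-12)
        assert fit2.B == pytest.approx(fit.B * 37.5, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        flat = pd.DataFrame({"x": np.full(10, 2.0), "y": np.arange(1.0, 11.0)})
        with pytest.raises(ValueError, match="degenerate"):
            infer_kernel_exponent(flat, d=2)
        with pytest.raises(ValueError):
            infer_kernel_exponent(pd.DataFrame({"x": [1.0] * 3, "y": [1.0] * 3}), d=2)


class TestBootstrap:
    def test_identical_values_zero_width_ci(self):
        mean, (lo, hi) = bootstrap_mu_i([2.0] * 10)
        assert mean == lo == hi == 2.0

    def test_ci_width_matches_clt(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(2.0, 0.1, size=200)
        mean, (lo, hi) = bootstrap_mu_i(vals, n_boot=4000, seed=3)
        expected = 2 * 1.96 * 0.1 / np.sqrt(200)
        assert (hi - lo) == pytest.approx(expected, rel=0.2)

    def test_ci_contains_ensemble_mean(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(2.5, 0.3, size=50)
        mean, (lo, hi) = bootstrap_mu_i(vals, seed=9)
        assert lo <= mean <= hi
        assert mean == pytest.approx(vals.mean())

    def test_deterministic_given_seed(self):
        vals = np.linspace(1.9, 2.1, 30)
        assert bootstrap_mu_i(vals, seed=5) == bootstrap_mu_i(vals, seed=5)

    def test_small_n_boot_warns(self):
        with pytest.warns(UserWarning, match="n_boot"):
            bootstrap_mu_i([1.0, 2.0], n_boot=50)
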