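"""Short-range chain kinetics: closed form, matrix exponential, peaks."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cyclopk.shortrange import (
    AdjustmentStrategy,
    apply_hydrophobic_adjustment,
    bateman_plasma,
    default_time_grid,
    metabolite_fraction,
    peak,
    simulate_shortrange,
    three_compartment_system,
)

rates = st.floats(min_value=0.05, max_value=30.0)


class TestBatemanClosedForm:
    def test_zero_at_origin(self):
        assert bateman_plasma(2.88, 2.1, 1.0, 0.0) == 0.0

    def test_equal_rate_degenerate_form(self):
        # k_gi = k_plasma = 1 at t = 1 gives k*t*e^{-kt} = e^{-1}
        assert bateman_plasma(1.0, 1.0, 1.0, 1.0) == pytest.approx(math.exp(-1))

    def test_hydrophilic_complex_peak_value(self):
        """Published peak of the hydrophilic complex: 0.43 ng/mL."""
        est = peak(2.88, 2.1, 1.0)
        assert bateman_plasma(2.88, 2.1, 1.0, est.tmax) == pytest.approx(0.43, abs=0.005)

    @given(rates, st.floats(min_value=1e-10, max_value=1e-6))
    def test_degenerate_rate_continuity(self, k, rel_gap):
        """Two-exponential form converges to k*t*e^{-kt} as the rates merge."""
        t = 1.0 / k  # evaluate near the peak where the limit matters most
        near = bateman_plasma(k * (1 + rel_gap), k, 1.0, t)
        limit = k * t * math.exp(-k * t)
        assert near == pytest.approx(limit, abs=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            bateman_plasma(1.0, 2.0, 1.0, -0.1)


class TestPeak:
    @pytest.mark.parametrize(
        "k_gi, k_plasma, tmax_expected",
        [(23.1, 7.2, 0.07), (2.88, 2.1, 0.40)],
    )
    def test_published_peak_times(self, k_gi, k_plasma, tmax_expected):
        assert peak(k_gi, k_plasma).tmax == pytest.approx(tmax_expected, abs=0.005)

    def test_equal_rate_limit(self):
        assert peak(3.0, 3.0, 1.0).tmax == pytest.approx(1.0 / 3.0)

    @given(rates, rates)
    def test_matches_dense_grid_argmax(self, k_gi, k_plasma):
        est = peak(k_gi, k_plasma, 1.0)
        grid = np.linspace(0.0, 5.0 * est.tmax, 4001)
        values = bateman_plasma(k_gi, k_plasma, 1.0, grid)
        step = grid[1] - grid[0]
        assert abs(grid[int(np.argmax(values))] - est.tmax) <= step
        assert est.cmax >= values.max() - 1e-12

    @given(rates, rates)
    def test_cmax_bounded_by_initial_mass(self, k_gi, k_plasma):
        assert 0.0 < peak(k_gi, k_plasma, 1.0).cmax <= 1.0


class TestLinearSystemSolver:
    def test_scalar_decay_via_chain(self):
        """The GI compartment of the chain decays as pure e^{-kt}."""
        traj = simulate_shortrange(0.7, 1.3, 1.0, np.linspace(0.0, 5.0, 101))
        assert traj.gi == pytest.approx(np.exp(-0.7 * traj.times), abs=1e-10)

    def test_total_conversion_at_long_times(self):
        traj = simulate_shortrange(23.1, 7.2, 1.0, np.array([0.0, 5.0, 10.0]))
        assert traj.gi[-1] == pytest.approx(0.0, abs=1e-12)
        assert traj.plasma[-1] == pytest.approx(0.0, abs=1e-12)
        assert traj.metabolite[-1] == pytest.approx(1.0, abs=1e-9)

    @given(rates, rates)
    def test_mass_conservation_and_nonnegativity(self, k_gi, k_plasma):
        traj = simulate_shortrange(k_gi, k_plasma, 1.0, default_time_grid(10.0, 0.05))
        total = traj.gi + traj.plasma + traj.metabolite
        assert np.abs(total - 1.0).max() < 1e-8
        for series in (traj.gi, traj.plasma, traj.metabolite):
            assert series.min() >= -1e-10

    def test_plasma_matches_closed_form(self):
        grid = default_time_grid(10.0, 0.01)
        traj = simulate_shortrange(2.88, 2.1, 1.0, grid)
        assert np.abs(traj.plasma - bateman_plasma(2.88, 2.1, 1.0, grid)).max() < 1e-9

    def test_equal_rates_fall_back_to_expm(self):
        # defective rate matrix: eigendecomposition is ill-conditioned
        grid = np.linspace(0.0, 4.0, 41)
        traj = simulate_shortrange(1.0, 1.0, 1.0, grid)
        assert traj.plasma == pytest.approx(grid * np.exp(-grid), abs=1e-9)

    def test_dimension_mismatch_rejected(self):
        from cyclopk.shortrange import LinearCompartmentSystem

        with pytest.raises(ValueError):
            LinearCompartmentSystem(
                rate_matrix=np.eye(3) * -1.0,
                initial_concentrations=np.array([1.0, 0.0]),
                labels=("a", "b", "c"),
            )

    def test_mass_creating_matrix_rejected(self):
        from cyclopk.shortrange import LinearCompartmentSystem

        with pytest.raises(ValueError):
            LinearCompartmentSystem(
                rate_matrix=np.array([[0.5, 0.0], [0.0, -1.0]]),
                initial_concentrations=np.array([1.0, 0.0]),
                labels=("a", "b"),
            )


class TestMetaboliteFraction:
    @pytest.mark.parametrize(
        "c_a, c_b, c0, expected", [(1.0, 0.0, 1.0, 0.0), (0.0, 0.0, 1.0, 1.0)]
    )
    def test_mass_balance_endpoints(self, c_a, c_b, c0, expected):
        assert metabolite_fraction(c_a, c_b, c0) == pytest.approx(expected)

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError):
            metabolite_fraction(0.8, 0.5, 1.0)

    def test_roundoff_clipped(self):
        assert metabolite_fraction(1.0 + 1e-12, 0.0, 1.0) == 0.0


class TestHydrophobicAdjustment:
    def test_identity(self):
        system = three_compartment_system(5.28, 1.56, 1.0)
        adjusted = apply_hydrophobic_adjustment(system, 1.0, 1.0)
        assert np.allclose(adjusted.system.rate_matrix, system.rate_matrix)
        assert np.allclose(
            adjusted.system.initial_concentrations, system.initial_concentrations
        )

    def test_initial_concentration_scaling(self):
        system = three_compartment_system(5.28, 1.56, 1.0)
        adjusted = apply_hydrophobic_adjustment(
            system, 4.38, 2.5, AdjustmentStrategy.OUTPUT_SCALE
        )
        assert adjusted.system.initial_concentrations[0] == pytest.approx(
            1.0 / 4.38
        )  # = 0.2283
        assert adjusted.plasma_output_factor == 2.5
        # kinetics untouched under output scaling
        assert np.allclose(adjusted.system.rate_matrix, system.rate_matrix)

    def test_slow_elimination_divides_plasma_rate(self):
        system = three_compartment_system(5.28, 1.56, 1.0)
        adjusted = apply_hydrophobic_adjustment(
            system, 4.38, 2.5, AdjustmentStrategy.SLOW_ELIMINATION
        )
        a = adjusted.system.rate_matrix
        assert a[2, 1] == pytest.approx(1.56 / 2.5)
        assert a[1, 1] == pytest.approx(-1.56 / 2.5)
        assert adjusted.plasma_output_factor == 1.0
        # still a valid conservative system
        assert np.all(a.sum(axis=0) <= 1e-12)

    def test_unknown_strategy_rejected(self):
        system = three_compartment_system(1.0, 2.0, 1.0)
        with pytest.raises(ValueError, match="strategy"):
            apply_hydrophobic_adjustment(system, 4.38, 2.5, "both_at_once")
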