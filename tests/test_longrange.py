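"""Periodic-dosing simulation: RK4, dose trains, limit cycles."""

import math

import numpy as np
import pytest

from cyclopk.longrange import (
    DoseRegimen,
    IntegrationError,
    dose_train,
    limit_cycle_metrics,
    rk4_integrate,
    simulate_longrange,
)
from cyclopk.parameters import CompoundParameters


def _regimen(**overrides):
    base = dict(
        dose_amount=0.49, period=6.0, pulse_shape="rectangular", pulse_width=0.5
    )
    base.update(overrides)
    return DoseRegimen(**base)


class TestDoseTrain:
    def test_zero_dose(self):
        reg = _regimen(dose_amount=0.0)
        assert dose_train(reg, np.linspace(0, 24, 100)).max() == 0.0

    def test_pulse_integral_equals_dose(self):
        """4 pulses in 24 h deliver 4 x amount x scale regardless of width."""
        reg = _regimen(dissolution_scale=0.5)
        t = np.linspace(0, 24, 240001)
        integral = np.trapezoid(dose_train(reg, t), t)
        assert integral == pytest.approx(4 * 0.49 * 0.5, rel=1e-3)

    def test_bolus_has_no_continuous_rate(self):
        reg = _regimen(pulse_shape="bolus")
        assert dose_train(reg, 0.1) == 0.0

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            _regimen(pulse_width=7.0)


class TestRK4:
    def test_exponential_decay(self):
        _, states = rk4_integrate(lambda t, y: -y, [1.0], 0.0, 1.0, 0.01)
        assert abs(states[-1, 0] - math.exp(-1)) < 1e-8

    def test_zero_input_zero_state(self):
        _, states = rk4_integrate(lambda t, y: -0.3 * y, [0.0, 0.0], 0.0, 10.0, 0.1)
        assert np.all(states == 0.0)

    def test_fourth_order_convergence(self):
        """Halving dt shrinks the decay-problem error ~16-fold."""
        errors = []
        for dt in (0.02, 0.01):
            _, states = rk4_integrate(lambda t, y: -y, [1.0], 0.0, 1.0, dt)
            errors.append(abs(states[-1, 0] - math.exp(-1)))
        ratio = errors[0] / errors[1]
        assert 12.0 < ratio < 20.0

    def test_nonfinite_state_raises(self):
        with np.errstate(over="ignore"), pytest.raises(IntegrationError, match="t ="):
            rk4_integrate(lambda t, y: y**2, [10.0], 0.0, 5.0, 0.1)


@pytest.fixture()
def nc(study_compounds):
    return study_compounds["NC"]


class TestSimulateLongrange:
    def test_period_detection_all_compounds(self, study_config):
        """Forced linear system locks onto the dosing period (6 h / 24 h)."""
        for cc in study_config.compounds:
            reg = study_config.regimens[cc.name].to_regimen()
            state = simulate_longrange(cc.to_parameters(), reg)
            summary = limit_cycle_metrics(state, reg)
            assert not summary.empty
            assert summary.detected_period == pytest.approx(reg.period, abs=0.02)
            assert summary.convergence_ratio < 1e-3

    def test_nonnegativity_and_lag(self, nc):
        reg = _regimen()
        state = simulate_longrange(nc, reg)
        assert state.gi.min() >= 0.0
        assert state.plasma.min() >= 0.0
        # plasma peaks after the GI does within the first period
        first = state.times < reg.period
        t_gi = state.times[first][np.argmax(state.gi[first])]
        t_pl = state.times[first][np.argmax(state.plasma[first])]
        assert t_pl > t_gi

    def test_superposition(self, nc):
        """Linearity: doubling the dose exactly doubles the trajectory."""
        lo = simulate_longrange(nc, _regimen(dose_amount=0.49), horizon=36.0)
        hi = simulate_longrange(nc, _regimen(dose_amount=0.98), horizon=36.0)
        assert np.abs(hi.plasma - 2.0 * lo.plasma).max() < 1e-8
        assert np.abs(hi.gi - 2.0 * lo.gi).max() < 1e-8

    def test_asymptotic_periodicity(self, nc):
        reg = _regimen()
        state = simulate_longrange(nc, reg, horizon=15 * reg.period)
        per_steps = int(round(reg.period / 0.01))
        tail = state.plasma[-2 * per_steps :]
        diff = np.abs(tail[per_steps:] - tail[:per_steps]).max()
        assert diff < 1e-6 * state.plasma.max()

    def test_limit_cycle_mean_plasma_level(self, nc):
        """On the cycle, mean plasma = (dose per period)/(T * k_plasma)."""
        reg = _regimen(pulse_shape="bolus")
        state = simulate_longrange(nc, reg, horizon=20 * reg.period)
        k_plasma = math.log(2) / (nc.t_half_plasma / 60.0)
        per_steps = int(round(reg.period / 0.01))
        mean_y = state.plasma[-per_steps:].mean()
        expected = reg.dose_per_period / (reg.period * k_plasma)
        assert mean_y == pytest.approx(expected, rel=0.01)

    def test_bolus_is_narrow_pulse_limit(self, nc):
        """Plasma under narrowing rectangular pulses converges to bolus."""
        bolus = simulate_longrange(nc, _regimen(pulse_shape="bolus"), horizon=36.0)
        gaps = []
        for width in (0.5, 0.1, 0.02):
            rect = simulate_longrange(nc, _regimen(pulse_width=width), horizon=36.0)
            # compare on the shared grid, skipping the first pulse
            mask = rect.times > 1.0
            gaps.append(np.abs(rect.plasma[mask] - bolus.plasma[mask]).max())
        assert gaps[0] > gaps[1] > gaps[2]

    def test_short_horizon_rejected(self, nc):
        with pytest.raises(ValueError, match="5 dosing periods"):
            simulate_longrange(nc, _regimen(), horizon=12.0)

    def test_coarse_dt_refused_and_warned(self):
        fast = CompoundParameters(
            name="fast",
            t_half_gi=1.0,  # 1 min half-life -> k ~ 41.6 / h
            t_half_plasma=96.0,
            dissolution_time=15.0,
            cmax_exp=1.0,
            cmax_exp_sd=0.1,
            tmax_exp=1.0,
        )
        with pytest.raises(ValueError, match="fastest timescale"):
            simulate_longrange(fast, _regimen(), dt=0.1)
        with pytest.warns(UserWarning, match="fastest timescale"):
            simulate_longrange(fast, _regimen(), dt=0.005)


class TestLimitCycleMetrics:
    def test_zero_dose_sentinel(self, study_compounds):
        reg = _regimen(dose_amount=0.0)
        state = simulate_longrange(study_compounds["NC"], reg)
        summary = limit_cycle_metrics(state, reg)
        assert summary.empty
        assert math.isnan(summary.detected_period)

    def test_insufficient_span_rejected(self, study_compounds):
        reg = _regimen()
        state = simulate_longrange(study_compounds["NC"], reg, horizon=6 * reg.period)
        with pytest.raises(ValueError, match="burn-in"):
            limit_cycle_metrics(state, reg, burn_in_cycles=10)

    def test_phase_plane_closes(self, study_compounds):
        """Successive cycles of (x, y) overlay each other after burn-in."""
        reg = _regimen()
        state = simulate_longrange(study_compounds["NC"], reg, horizon=15 * reg.period)
        per_steps = int(round(reg.period / 0.01))
        xy = np.column_stack([state.gi, state.plasma])
        last, prev = xy[-per_steps:], xy[-2 * per_steps : -per_steps]
        gap = np.linalg.norm(last - prev, axis=1).max()
        assert gap < 1e-6 * np.linalg.norm(xy[-per_steps:], axis=1).max()
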