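import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breathloop.dosing import (DeliveryConfig, DoseCommand, GasPath,
                               estimate_delay, propagate, schedule_dose,
                               target_valve_phase)
from breathloop.errors import InvalidInputError, NoResponseError
from breathloop.signals import UniformSeries
from breathloop.tracker import OscillationState


def valid_state(amplitude=2.0, phase=0.0, period=60.0):
    return OscillationState(amplitude, phase, period, True)


class TestTargetValvePhase:
    def test_inphase_no_delay(self):
        assert target_valve_phase("inphase", 60, 0) == 0.0

    def test_antiphase_no_delay(self):
        assert target_valve_phase("antiphase", 60, 0) == pytest.approx(math.pi)

    def test_nine_second_lead(self):
        # valve peak leads peak ventilation by 9 s of a 60 s cycle
        assert target_valve_phase("inphase", 60, 9.0) == pytest.approx(
            2 * math.pi - 0.3 * math.pi)

    def test_invalid_period(self):
        with pytest.raises(InvalidInputError):
            target_valve_phase("inphase", 0, 9)


class TestScheduleDose:
    def test_no_oscillation_no_dose(self):
        assert schedule_dose(valid_state(amplitude=0.0), DeliveryConfig()).u == 0.0

    def test_below_deadband_no_dose(self):
        cfg = DeliveryConfig()
        for amp in np.linspace(0, cfg.A_min - 1e-6, 7):
            assert schedule_dose(valid_state(amplitude=amp), cfg).u == 0.0

    def test_window_centre_dose(self):
        # at window centre (s = 0.5), u = C_pk = min(c_max, kC*A) = 0.02
        cfg = DeliveryConfig()
        theta_pk = target_valve_phase(cfg.mode, 60.0, cfg.total_delay)
        cmd = schedule_dose(valid_state(amplitude=2.0, phase=theta_pk), cfg)
        assert cmd.u == pytest.approx(0.02)

    def test_quarter_window_dose(self):
        # s = 0.25 gives (1 - cos(pi/2))/2 = 1/2 of the peak
        cfg = DeliveryConfig()
        theta_pk = target_valve_phase(cfg.mode, 60.0, cfg.total_delay)
        width_frac = min(max(cfg.w_max * 2.0 / cfg.A_ref, cfg.w_min), cfg.w_max)
        half = math.pi * width_frac
        phase = (theta_pk - half + 0.25 * 2 * half) % (2 * math.pi)
        cmd = schedule_dose(valid_state(amplitude=2.0, phase=phase), cfg)
        assert cmd.u == pytest.approx(0.01)

    def test_amplitude_doubles_peak_and_width(self):
        cfg = DeliveryConfig(A_min=0.0, kC=0.005, w_max=0.8, A_ref=4.0)

        def profile(amp):
            thetas = np.linspace(0, 2 * math.pi, 7200, endpoint=False)
            u = np.array([schedule_dose(valid_state(amp, th), cfg).u for th in thetas])
            width = (u > 0).sum() / len(thetas)
            return u.max(), width

        peak1, width1 = profile(1.0)
        peak2, width2 = profile(2.0)
        assert peak2 == pytest.approx(2 * peak1, rel=1e-3)
        assert width2 == pytest.approx(2 * width1, rel=1e-2)

    def test_profile_starts_and_ends_at_zero(self):
        cfg = DeliveryConfig()
        theta_pk = target_valve_phase(cfg.mode, 60.0, cfg.total_delay)
        half = math.pi * 0.5  # A=2 -> w_max window
        for edge in (theta_pk - half + 1e-9, theta_pk + half - 1e-9):
            cmd = schedule_dose(valid_state(2.0, edge % (2 * math.pi)), cfg)
            assert cmd.u < 1e-6

    def test_invalid_tracker_state_fails_safe(self):
        state = OscillationState(5.0, 0.0, 60.0, valid=False)
        assert schedule_dose(state, DeliveryConfig()).u == 0.0

    @given(amp=st.floats(0, 50), phase=st.floats(0, 2 * math.pi),
           period=st.floats(40, 90), kc=st.floats(0, 0.2))
    @settings(deadline=None, max_examples=200)
    def test_hard_cap_always_respected(self, amp, phase, period, kc):
        cfg = DeliveryConfig(kC=kc)
        cmd = schedule_dose(valid_state(amp, phase, period), cfg)
        assert 0.0 <= cmd.u <= cfg.c_max

    def test_commanded_profile_slope_bound(self):
        # consecutive 1 Hz commands differ by <= C_pk*pi*dt/W_min
        cfg = DeliveryConfig()
        amp, period = 2.0, 60.0
        c_pk = min(cfg.c_max, cfg.kC * amp)
        w = min(max(cfg.w_max * amp / cfg.A_ref, cfg.w_min), cfg.w_max) * period
        bound = c_pk * math.pi / (cfg.w_min * period)
        us = []
        for t in range(60):
            phase = (2 * math.pi * t / period) % (2 * math.pi)
            us.append(schedule_dose(valid_state(amp, phase, period), cfg).u)
        diffs = np.abs(np.diff(us))
        assert np.all(diffs <= max(bound, c_pk * math.pi / w) + 1e-9)


class TestGasPath:
    def test_zero_command_zero_output(self):
        cmd = UniformSeries(0, np.zeros(400), dt=0.05)
        inspired, alveolar = propagate(cmd, DeliveryConfig())
        assert np.all(inspired.values == 0)
        assert np.all(alveolar.values == 0)

    def test_step_onset_after_valve_delay(self):
        cfg = DeliveryConfig()
        dt = 0.05
        n = int(60 / dt)
        u = np.where(np.arange(n) * dt >= 10.0, 0.04, 0.0)
        cmd = UniformSeries(0, u, dt=dt)
        inspired, _ = propagate(cmd, cfg)
        plateau = inspired.values[-1]
        first = inspired.times[np.flatnonzero(inspired.values > 0.05 * plateau)[0]]
        assert first == pytest.approx(10.0 + cfg.d_valve_inspired, abs=2 * dt + 0.06)

    def test_first_order_mixing_632_percent(self):
        cfg = DeliveryConfig(d_valve_inspired=0.0, d_inspired_alveolar=0.0, mix_tau=1.0)
        dt = 0.05
        n = int(20 / dt)
        cmd = UniformSeries(0, np.full(n, 0.04), dt=dt)
        inspired, _ = propagate(cmd, cfg)
        # one time constant after onset the response is at 1 - 1/e
        idx = int(round(cfg.mix_tau / dt)) - 1  # step applied during first dt
        assert inspired.values[idx] == pytest.approx(0.04 * (1 - math.exp(-1)), rel=0.01)

    def test_alveolar_lags_inspired(self):
        cfg = DeliveryConfig()
        dt = 0.05
        u = np.where(np.arange(int(40 / dt)) * dt >= 5.0, 0.03, 0.0)
        inspired, alveolar = propagate(UniformSeries(0, u, dt=dt), cfg)
        shift = int(round(cfg.d_inspired_alveolar / dt))
        np.testing.assert_allclose(alveolar.values[shift:],
                                   inspired.values[:-shift], atol=1e-12)


class TestEstimateDelay:
    def _step(self, t_on, dt=1.0, n=60, height=1.0):
        t = np.arange(n) * dt
        return UniformSeries(0, np.where(t >= t_on, height, 0.0), dt=dt)

    def test_pure_shift_recovered(self):
        cmd = self._step(10)
        resp = self._step(17)
        assert estimate_delay(cmd, resp) == pytest.approx(7.0)

    def test_identical_series_zero_delay(self):
        cmd = self._step(10)
        assert estimate_delay(cmd, cmd) == 0.0

    def test_recovers_configured_valve_delay(self):
        cfg = DeliveryConfig()
        dt = 0.05
        n = int(120 / dt)
        u = np.where(np.arange(n) * dt >= 30.0, 0.04, 0.0)
        cmd = UniformSeries(0, u, dt=dt)
        inspired, _ = propagate(cmd, cfg)
        assert estimate_delay(cmd, inspired) == pytest.approx(
            cfg.d_valve_inspired, abs=0.5)

    def test_no_response_raises(self):
        cmd = self._step(10)
        flat = UniformSeries(0, np.zeros(60))
        with pytest.raises(NoResponseError):
            estimate_delay(cmd, flat)

    def test_all_zero_command_rejected(self):
        flat = UniformSeries(0, np.zeros(60))
        with pytest.raises(InvalidInputError):
            estimate_delay(flat, flat)


class TestConfigValidation:
    def test_bad_c_max_rejected(self):
        with pytest.raises(InvalidInputError):
            DeliveryConfig(c_max=1.5)

    def test_bad_window_order_rejected(self):
        with pytest.raises(InvalidInputError):
            DeliveryConfig(w_min=0.7, w_max=0.3)

    def test_bad_mode_rejected(self):
        with pytest.raises(InvalidInputError):
            DeliveryConfig(mode="sideways")

    def test_negative_dose_rejected(self):
        with pytest.raises(InvalidInputError):
            DoseCommand(-0.01)
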