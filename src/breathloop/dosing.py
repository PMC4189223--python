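"""Dose scheduling and the valve-to-alveolus gas transport model.

The controller converts tracker state into a commanded inspired CO2
fraction once per second.  The dose is a smooth "1 - cos" pulse per
breathing cycle: zero at both ends, peaking mid-window, with both the
peak concentration and the window duration proportional to the tracked
oscillation amplitude (small oscillations get a small short dose; stable
breathing gets none).  The pulse is placed in *valve* time: its centre
phase leads the physiological target (peak ventilation for therapy,
trough for the antiphase control arm) by the total valve-to-alveolus
transport delay, so the peak alveolar concentration arrives on target.

The transport path is modelled as a pure delay (valve to inspired gas,
measured in the original apparatus as 8.8 s on average), a first-order
mixing lag, and a short further delay to the alveolus (residual of the
9 s total motor-to-end-tidal delay).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, NoResponseError
from .signals import UniformSeries
from .tracker import OscillationState

__all__ = [
    "DeliveryConfig",
    "DoseCommand",
    "target_valve_phase",
    "schedule_dose",
    "GasPath",
    "propagate",
    "estimate_delay",
]

logger = logging.getLogger(__name__)

_MODES = ("inphase", "antiphase")


@dataclass(frozen=True)
class DeliveryConfig:
    """Dose-law constants and gas-path parameters.

    c_max : hard cap on commanded inspired CO2 fraction (cylinder limit).
    kC : peak fraction commanded per L/min of oscillation amplitude.
    A_ref : amplitude (L/min) at which the window reaches w_max of the cycle.
    w_min, w_max : administration window as a fraction of the period.
    A_min : deadband (L/min); below it no CO2 is delivered.
    mode : 'inphase' (peak alveolar CO2 at peak ventilation — therapy) or
        'antiphase' (at trough ventilation — the control condition).
    d_valve_inspired, d_inspired_alveolar : pure transport delays, s.
    mix_tau : first-order mixing time constant at the mouthpiece, s.
    """

    c_max: float = 0.05
    kC: float = 0.01
    A_ref: float = 2.0
    w_min: float = 0.15
    w_max: float = 0.5
    A_min: float = 0.5
    mode: str = "inphase"
    d_valve_inspired: float = 8.8
    d_inspired_alveolar: float = 0.2
    mix_tau: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.c_max < 1):
            raise InvalidInputError(f"c_max must lie in (0, 1), got {self.c_max}")
        if not (0 <= self.w_min <= self.w_max <= 1):
            raise InvalidInputError(
                f"need 0 <= w_min <= w_max <= 1, got {self.w_min}, {self.w_max}")
        if self.kC < 0 or self.A_ref <= 0 or self.A_min < 0:
            raise InvalidInputError("kC, A_ref, A_min must be non-negative (A_ref > 0)")
        if min(self.d_valve_inspired, self.d_inspired_alveolar, self.mix_tau) < 0:
            raise InvalidInputError("delays and mix_tau must be >= 0")
        if self.mode not in _MODES:
            raise InvalidInputError(f"mode must be one of {_MODES}, got {self.mode!r}")

    @property
    def total_delay(self) -> float:
        """Valve movement to alveolar arrival, seconds."""
        return self.d_valve_inspired + self.d_inspired_alveolar


@dataclass(frozen=True)
class DoseCommand:
    """Commanded inspired CO2 fraction at the valve for the next second."""

    u: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.u < 1.0) or not math.isfinite(self.u):
            raise InvalidInputError(f"dose command must lie in [0, 1), got {self.u}")


def target_valve_phase(mode: str, period: float, total_delay: float) -> float:
    """Clock phase at which the valve aperture should peak.

    The physiological target is peak ventilation (phase 0) for therapy or
    trough ventilation (phase pi) for the antiphase control; the valve
    must lead it by the transport delay: ``(target - 2*pi*D/P) mod 2*pi``.
    """
    if period <= 0:
        raise InvalidInputError(f"period must be positive, got {period}")
    if mode not in _MODES:
        raise InvalidInputError(f"mode must be one of {_MODES}, got {mode!r}")
    target = 0.0 if mode == "inphase" else math.pi
    return (target - 2 * math.pi * total_delay / period) % (2 * math.pi)


def schedule_dose(state: OscillationState, cfg: DeliveryConfig) -> DoseCommand:
    """Per-second dose law: amplitude-graded, phase-led 1 - cos pulse.

    Fail-safe: an invalid tracker state or sub-deadband amplitude yields
    u = 0 (the device defaults to air).  Within the administration window
    the command is ``C_pk * (1 - cos(2*pi*s)) / 2`` with s in [0, 1] the
    fractional position, so the profile starts and ends at exactly zero.
    """
    if not state.valid:
        logger.warning("dose requested with invalid tracker state; commanding air")
        return DoseCommand(0.0)
    A = state.amplitude
    if A < cfg.A_min:
        return DoseCommand(0.0)
    P = state.period
    theta_pk = target_valve_phase(cfg.mode, P, cfg.total_delay)
    width_frac = min(max(cfg.w_max * A / cfg.A_ref, cfg.w_min), cfg.w_max)
    half_angle = math.pi * width_frac  # half the window, in phase units
    c_pk = min(cfg.c_max, cfg.kC * A)
    d = (state.phase - theta_pk + half_angle) % (2 * math.pi)
    if d > 2 * half_angle:
        return DoseCommand(0.0)
    s = d / (2 * half_angle)
    return DoseCommand(c_pk * 0.5 * (1.0 - math.cos(2 * math.pi * s)))


class GasPath:
    """Stateful valve-to-alveolus transport model stepped at the
    integration rate: pure delay, then first-order mixing, then a short
    further pure delay to the lung."""

    def __init__(self, cfg: DeliveryConfig, dt: float):
        if dt <= 0:
            raise InvalidInputError("dt must be positive")
        self.cfg = cfg
        self.dt = dt
        n1 = int(round(cfg.d_valve_inspired / dt))
        n2 = int(round(cfg.d_inspired_alveolar / dt))
        self._ring1 = [0.0] * n1
        self._ring2 = [0.0] * n2
        self._i1 = 0
        self._i2 = 0
        self._y = 0.0  # mixed (inspired) fraction
        self._alpha = 1.0 if cfg.mix_tau <= 0 else 1.0 - math.exp(-dt / cfg.mix_tau)

    def step(self, u: float) -> tuple[float, float]:
        """Advance one dt with valve command ``u``; returns
        (inspired fraction at the mouth, fraction at the alveolus)."""
        if self._ring1:
            delayed = self._ring1[self._i1]
            self._ring1[self._i1] = u
            self._i1 = (self._i1 + 1) % len(self._ring1)
        else:
            delayed = u
        self._y += (delayed - self._y) * self._alpha
        if self._ring2:
            alveolar = self._ring2[self._i2]
            self._ring2[self._i2] = self._y
            self._i2 = (self._i2 + 1) % len(self._ring2)
        else:
            alveolar = self._y
        return self._y, alveolar


def propagate(commands: UniformSeries, cfg: DeliveryConfig) -> tuple[UniformSeries, UniformSeries]:
    """Run a valve-command series through the transport model.

    Returns the inspired fraction at the mouth and the fraction presented
    to the lung store, both on the command's time grid.
    """
    path = GasPath(cfg, commands.dt)
    inspired = np.empty(len(commands))
    alveolar = np.empty(len(commands))
    for i, u in enumerate(commands.values):
        inspired[i], alveolar[i] = path.step(float(u))
    mk = lambda v, name: UniformSeries(t0=commands.t0, values=v, dt=commands.dt,
                                       units="fraction", name=name)
    return mk(inspired, "fico2_frac"), mk(alveolar, "fico2_alv_frac")


def estimate_delay(command: UniformSeries, response: UniformSeries,
                   threshold_frac: float = 0.05) -> float:
    """Onset-to-rise delay: time from the first nonzero command sample to
    the response first crossing ``threshold_frac`` of its eventual plateau
    (final value).  Resolution is one sample of the response grid."""
    if not (0 < threshold_frac < 1):
        raise InvalidInputError("threshold_frac must lie in (0, 1)")
    cmd = command.values
    nz = np.flatnonzero(cmd != 0)
    if nz.size == 0:
        raise InvalidInputError("command contains no onset (all zero)")
    t_on = command.times[nz[0]]
    resp = response.values
    plateau = float(resp[-1])
    if plateau <= 0:
        raise NoResponseError("response plateau is non-positive; no rise detected")
    thresh = threshold_frac * plateau
    above = np.flatnonzero(resp >= thresh)
    if above.size == 0:
        raise NoResponseError(
            f"response never crossed {threshold_frac:.0%} of its plateau")
    t_cross = response.times[int(above[0])]
    return float(max(t_cross - t_on, 0.0))
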