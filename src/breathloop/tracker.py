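"""Real-time tracking of the ventilatory oscillation "clock".

Once per second the tracker estimates, from the trailing window of
ventilation samples, the amplitude, phase and period of the dominant
oscillation.  Phase is reported on a clock face: 0 rad at peak
ventilation (12 o'clock), advancing through mid-fall (3), trough (6) and
mid-rise (9).  The controller uses this state to time CO2 doses ahead of
the predicted end-tidal trough.

The estimator is a single-bin sliding discrete Fourier analysis: the
period is found by banded grid search over single-bin power, and the
amplitude/phase come from the Fourier coefficient of the mean-subtracted
trailing window of one current period.  The phase advances continuously
at 2*pi/P per second and is re-anchored each update toward the measured
coefficient phase, with the correction slew-limited so the clock never
jumps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidCallError, InvalidInputError
from .signals import UniformSeries

__all__ = [
    "TrackerConfig",
    "OscillationState",
    "PeriodEstimate",
    "estimate_period",
    "OscillationTracker",
]

_CLOCK_LABELS = ("12", "3", "6", "9")


@dataclass(frozen=True)
class TrackerConfig:
    """Tunable parameters of the oscillation tracker.

    band : (lo, hi) seconds — admissible period range searched on a 1 s grid.
    period_blend : exponential blending weight applied to each new period
        estimate (1.0 = no smoothing, jump to the new grid estimate).
    phase_slew : maximum re-anchoring correction, rad/s.
    power_ratio_threshold : minimum fraction of window variance the best
        single bin must explain for the period estimate to be confident.
    """

    band: tuple[float, float] = (40.0, 90.0)
    period_blend: float = 0.3
    phase_slew: float = 0.2
    power_ratio_threshold: float = 0.25

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (0 < lo < hi):
            raise InvalidInputError(f"period band must satisfy 0 < lo < hi, got {self.band}")
        if not (0 < self.period_blend <= 1):
            raise InvalidInputError("period_blend must lie in (0, 1]")
        if self.phase_slew <= 0:
            raise InvalidInputError("phase_slew must be positive")


@dataclass(frozen=True)
class OscillationState:
    """Tracker output for one second.

    amplitude is in the units of the tracked signal (L/min for
    ventilation); phase is radians in [0, 2*pi) with 0 at peak; period is
    seconds.  ``valid`` is False during warm-up (before one full analysis
    window has been seen); an invalid state must never trigger a dose.
    """

    amplitude: float
    phase: float
    period: float
    valid: bool
    period_confident: bool = True

    @property
    def clock(self) -> str:
        """Quadrant label: 12 (peak), 3 (falling), 6 (trough), 9 (rising)."""
        quadrant = int(((self.phase + math.pi / 4) % (2 * math.pi)) // (math.pi / 2))
        return _CLOCK_LABELS[quadrant]


@dataclass(frozen=True)
class PeriodEstimate:
    period: float
    power_ratio: float
    confident: bool


def _single_bin_power(x: np.ndarray, periods: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Explained variance and amplitude of the best-fitting single
    sinusoid at each candidate period.

    This is the mean-corrected single-bin periodogram (a least-squares
    fit of intercept + cos + sin at one frequency, as in Lomb-Scargle):
    unlike the raw Fourier coefficient it stays unbiased when the window
    holds a non-integer number of cycles, which is the normal situation
    for a short real-time window.
    """
    n = x.size
    k = np.arange(n)
    xm = x - x.mean()
    powers = np.empty(periods.size)
    amps = np.empty(periods.size)
    for i, p in enumerate(periods):
        w = 2 * np.pi / p
        c = np.cos(w * k)
        s = np.sin(w * k)
        cm = c - c.mean()
        sm = s - s.mean()
        g = np.array([[cm @ cm, cm @ sm], [cm @ sm, sm @ sm]])
        rhs = np.array([cm @ xm, sm @ xm])
        try:
            ab = np.linalg.solve(g, rhs)
        except np.linalg.LinAlgError:
            powers[i] = 0.0
            amps[i] = 0.0
            continue
        powers[i] = float(ab @ rhs) / n  # explained variance
        amps[i] = float(np.hypot(*ab))
    return powers, amps


def estimate_period(window: UniformSeries | np.ndarray,
                    band: tuple[float, float] = (40.0, 90.0),
                    *,
                    prev_period: float | None = None,
                    blend: float = 1.0,
                    power_ratio_threshold: float = 0.25) -> PeriodEstimate:
    """Find the oscillation period maximising single-bin Fourier power.

    Candidates are the integer seconds in ``band``.  When ``prev_period``
    is given the grid winner is exponentially blended:
    ``P = prev + blend * (grid - prev)``.  The confidence flag reports
    whether the winning bin explains at least ``power_ratio_threshold``
    of the window variance (white noise spreads power across bins and is
    flagged low-confidence).
    """
    x = window.values if isinstance(window, UniformSeries) else np.asarray(window, dtype=float)
    lo, hi = band
    if not (0 < lo < hi):
        raise InvalidInputError(f"invalid period band {band}")
    if x.size < hi:
        raise InvalidInputError(
            f"window of {x.size} samples is shorter than the upper band edge {hi:g} s; "
            "period estimate not yet valid")
    periods = np.arange(math.ceil(lo), math.floor(hi) + 1)
    powers, _ = _single_bin_power(x, periods)
    best = int(np.argmax(powers))
    p_grid = float(periods[best])
    var = float(np.var(x))
    ratio = powers[best] / var if var > 0 else 0.0
    period = p_grid if prev_period is None else prev_period + blend * (p_grid - prev_period)
    return PeriodEstimate(period=float(period), power_ratio=float(ratio),
                          confident=ratio >= power_ratio_threshold)


def _wrap_pi(angle: float) -> float:
    """Wrap to (-pi, pi]."""
    return float((angle + math.pi) % (2 * math.pi) - math.pi)


class OscillationTracker:
    """Streaming amplitude/phase/period estimator, one update per second.

    The same object serves live simulation and CSV replay: feed it
    ``(t, ventilation)`` pairs at 1 Hz and read back the full
    :class:`OscillationState`.  Output at time t uses only samples <= t.
    """

    def __init__(self, config: TrackerConfig | None = None):
        self.config = config or TrackerConfig()
        hi = self.config.band[1]
        self._buffer_len = int(2 * math.ceil(hi))
        self._buf: list[float] = []
        self._last_t: float | None = None
        self._period: float | None = None
        self._theta: float | None = None
        self._state = OscillationState(0.0, 0.0, float("nan"), False, False)

    @property
    def state(self) -> OscillationState:
        return self._state

    def update(self, t: float, ve: float) -> OscillationState:
        cfg = self.config
        if self._last_t is not None and t <= self._last_t:
            raise InvalidCallError(
                f"tracker requires strictly increasing time, got {t} after {self._last_t}")
        dt_update = 1.0 if self._last_t is None else t - self._last_t
        self._last_t = t
        self._buf.append(float(ve))
        if len(self._buf) > self._buffer_len:
            del self._buf[: len(self._buf) - self._buffer_len]

        hi = cfg.band[1]
        if len(self._buf) < hi:
            self._state = OscillationState(0.0, 0.0, float("nan"), False, False)
            return self._state

        search = np.asarray(self._buf[-int(math.ceil(hi)):], dtype=float)
        est = estimate_period(search, cfg.band, prev_period=self._period,
                              blend=cfg.period_blend,
                              power_ratio_threshold=cfg.power_ratio_threshold)
        self._period = est.period

        # single-bin coefficient over one current period
        n = max(2, int(round(self._period)))
        x = np.asarray(self._buf[-n:], dtype=float)
        xm = x - x.mean()
        w = 2 * math.pi / self._period
        tj = t - (n - 1 - np.arange(n))
        a_c = 2.0 / n * float(np.sum(xm * np.cos(w * tj)))
        a_s = 2.0 / n * float(np.sum(xm * np.sin(w * tj)))
        amplitude = math.hypot(a_c, a_s)
        # x ~ A*cos(w*t - psi); theta = 0 at peak
        theta_raw = (w * t - math.atan2(a_s, a_c)) % (2 * math.pi)

        if self._theta is None:
            theta = theta_raw
        else:
            predicted = self._theta + w * dt_update
            err = _wrap_pi(theta_raw - predicted)
            max_corr = cfg.phase_slew * dt_update
            theta = predicted + max(-max_corr, min(max_corr, err))
        self._theta = theta % (2 * math.pi)

        self._state = OscillationState(amplitude=amplitude, phase=self._theta,
                                       period=self._period, valid=True,
                                       period_confident=est.confident)
        return self._state

    def replay(self, series: UniformSeries) -> list[OscillationState]:
        """Feed a recorded 1 Hz ventilation series through the live path."""
        if abs(series.dt - 1.0) > 1e-9:
            raise InvalidInputError("replay requires a 1 Hz series")
        return [self.update(t, v) for t, v in zip(series.times, series.values)]
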