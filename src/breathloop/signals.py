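"""Uniformly sampled physiological time series and oscillation metrics.

Periodic-breathing studies analyse ventilation and end-tidal CO2 as 1 Hz
resampled signals.  This module provides the shared container
(:class:`UniformSeries`), interpolation onto the integer-second grid, the
coefficient of variation (SD/mean) used as the oscillation-severity metric,
and a fixed-period least-squares sinusoid fit used to quantify how
sinusoidal an oscillation is.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidInputError, UndefinedMetricError

__all__ = [
    "UniformSeries",
    "SineFit",
    "resample_1hz",
    "coefficient_of_variation",
    "fit_sine",
    "series_to_frame",
    "frame_to_series",
    "write_csv",
    "read_csv",
]


@dataclass(frozen=True)
class UniformSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    t0 : float
        Time of the first sample, seconds.
    values : ndarray
        Ordered samples; must be finite and non-empty.
    dt : float
        Sample interval in seconds (default 1.0, the analysis rate).
    units : str
        Unit label, e.g. ``"L/min"``, ``"kPa"``, ``"fraction"``.
    name : str
        Signal name used as the CSV column header.
    """

    t0: float
    values: np.ndarray
    dt: float = 1.0
    units: str = ""
    name: str = "signal"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise InvalidInputError("UniformSeries requires a 1-D array with >= 1 sample")
        if not np.all(np.isfinite(vals)):
            raise InvalidInputError("UniformSeries values must all be finite")
        if not (self.dt > 0):
            raise InvalidInputError(f"dt must be positive, got {self.dt}")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def t_end(self) -> float:
        """Time of the last sample."""
        return self.t0 + self.dt * (self.values.size - 1)

    def window(self, t_start: float, t_end: float) -> "UniformSeries":
        """Sub-series of samples with t_start <= t <= t_end (inclusive)."""
        if t_start > t_end:
            raise InvalidInputError("window start must not exceed end")
        i0 = int(math.ceil((t_start - self.t0) / self.dt - 1e-9))
        i1 = int(math.floor((t_end - self.t0) / self.dt + 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, len(self) - 1)
        if i1 < i0:
            raise InvalidInputError("window contains no samples")
        return replace(self, t0=self.t0 + i0 * self.dt, values=self.values[i0 : i1 + 1])

    def tail(self, duration: float) -> "UniformSeries":
        """Trailing sub-series of the final ``duration`` seconds
        (``duration/dt`` samples, covering whole cycles exactly)."""
        n = int(round(duration / self.dt))
        if n < 1 or n > len(self):
            raise InvalidInputError(
                f"trailing window of {duration} s needs {n} samples; series has {len(self)}")
        return replace(self, t0=self.t0 + (len(self) - n) * self.dt,
                       values=self.values[-n:])


@dataclass(frozen=True)
class SineFit:
    """Least-squares fit of ``m + a*sin(2*pi*t/P + phi)`` at fixed period P."""

    mean: float
    amplitude: float
    phase: float
    period: float
    r2: float
    degenerate: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise InvalidInputError("SineFit amplitude must be >= 0")
        if not (0.0 <= self.r2 <= 1.0):
            raise InvalidInputError("SineFit r2 must lie in [0, 1]")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        return self.mean + self.amplitude * np.sin(2 * np.pi * np.asarray(t) / self.period + self.phase)


def resample_1hz(times, values, *, units: str = "", name: str = "signal") -> UniformSeries:
    """Linearly interpolate an irregular recording onto the 1 Hz grid.

    The output grid spans ``[ceil(times[0]), floor(times[-1])]`` in whole
    seconds; no extrapolation is performed.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 2:
        raise InvalidInputError("resample_1hz requires at least 2 points")
    if t.shape != v.shape:
        raise InvalidInputError("times and values must have equal length")
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("times must be strictly increasing")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
        raise InvalidInputError("times and values must be finite")
    t_first = math.ceil(t[0] - 1e-9)
    t_last = math.floor(t[-1] + 1e-9)
    if t_last < t_first:
        raise InvalidInputError("recording spans no integer second")
    grid = np.arange(t_first, t_last + 1, dtype=float)
    return UniformSeries(t0=float(t_first), values=np.interp(grid, t, v), dt=1.0,
                         units=units, name=name)


def coefficient_of_variation(series: UniformSeries, window: float | None = None) -> float:
    """Population SD divided by mean over the (trailing) analysis window.

    ``window`` selects the final ``window`` seconds of the series; ``None``
    uses the whole series.  The divide-by-n (population) SD is used: the
    metric describes a fully observed window, not a sample estimate.
    """
    seg = series if window is None else series.tail(window)
    mean = float(np.mean(seg.values))
    if mean <= 0:
        raise UndefinedMetricError(
            f"coefficient of variation undefined for window mean {mean:.6g} <= 0")
    return float(np.std(seg.values)) / mean


def fit_sine(series: UniformSeries, period: float) -> SineFit:
    """Fit ``m + a*sin(2*pi*t/P + phi)`` at fixed P by linear least squares.

    The model is linear in the sin/cos basis.  A constant (zero-variance)
    series returns amplitude 0 and, by convention, r2 = 0 with the
    ``degenerate`` flag set, avoiding the 0/0 in the variance ratio.
    """
    if period <= 0:
        raise InvalidInputError("period must be positive")
    span = series.dt * (len(series) - 1)
    if span < 2 * period:
        raise InvalidInputError(
            f"series spans {span:.1f} s; need >= 2 periods ({2 * period:.1f} s)")
    t = series.times
    y = series.values
    w = 2 * np.pi / period
    X = np.column_stack([np.ones_like(t), np.sin(w * t), np.cos(w * t)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    m, bs, bc = coef
    amp = float(np.hypot(bs, bc))
    # a*sin(wt + phi) = a sin cos(phi) + a cos sin(phi)
    phi = float(np.arctan2(bc, bs) % (2 * np.pi))
    resid = y - X @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0:
        return SineFit(mean=float(m), amplitude=0.0, phase=0.0, period=period,
                       r2=0.0, degenerate=True)
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return SineFit(mean=float(m), amplitude=amp, phase=phi, period=period,
                   r2=float(min(max(r2, 0.0), 1.0)))


# ---------------------------------------------------------------------------
# CSV dialect: header ``time_s,<name>[,...]``, one row per sample, UTF-8,
# '.' decimal separator, values printed at 6 significant digits.

def series_to_frame(bundle: dict[str, UniformSeries]) -> pd.DataFrame:
    """Assemble aligned series into a wide frame with a ``time_s`` column."""
    if not bundle:
        return pd.DataFrame({"time_s": []})
    lengths = {len(s) for s in bundle.values()}
    t0s = {s.t0 for s in bundle.values()}
    dts = {s.dt for s in bundle.values()}
    if len(lengths) != 1 or len(t0s) != 1 or len(dts) != 1:
        raise InvalidInputError("bundle series must share t0, dt and length")
    first = next(iter(bundle.values()))
    data = {"time_s": first.times}
    for name, s in bundle.items():
        data[name] = s.values
    return pd.DataFrame(data)


def frame_to_series(df: pd.DataFrame, units: dict[str, str] | None = None) -> dict[str, UniformSeries]:
    if "time_s" not in df.columns:
        raise InvalidInputError(f"expected a 'time_s' column, got {list(df.columns)}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size >= 2:
        dts = np.diff(t)
        if not np.allclose(dts, dts[0], rtol=0, atol=1e-6):
            raise InvalidInputError("time_s column is not uniformly spaced")
        dt = float(dts[0])
    else:
        dt = 1.0
    units = units or {}
    out = {}
    for col in df.columns:
        if col == "time_s":
            continue
        out[col] = UniformSeries(t0=float(t[0]), values=df[col].to_numpy(dtype=float),
                                 dt=dt, units=units.get(col, ""), name=col)
    return out


def write_csv(bundle: dict[str, UniformSeries], path) -> None:
    """Write a signal bundle in the package CSV dialect (6 sig. digits)."""
    df = series_to_frame(bundle)
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.6g")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def read_csv(path, units: dict[str, str] | None = None) -> dict[str, UniformSeries]:
    df = pd.read_csv(path)
    return frame_to_series(df, units=units)
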