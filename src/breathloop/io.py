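"""Trace bundle persistence in the package CSV dialect.

A simulation run is written as a directory containing ``traces.csv``
(wide: ``time_s,ve_lpm,petco2_kpa,fico2_frac,qdot_lpm,valve_frac``),
``controller.csv`` (``time_s,amp_lpm,phase_rad,period_s,u_frac``) and
``segments.json``.  Round-trips are exact at 6 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

from .errors import InvalidInputError
from .physiology import SimOutput
from .signals import UniformSeries, read_csv, write_csv

__all__ = ["write_traces", "read_traces"]

TRACE_COLUMNS = ("ve_lpm", "petco2_kpa", "fico2_frac", "qdot_lpm", "valve_frac")
CONTROLLER_COLUMNS = ("amp_lpm", "phase_rad", "period_s", "u_frac")

_UNITS = {"ve_lpm": "L/min", "petco2_kpa": "kPa", "fico2_frac": "fraction",
          "qdot_lpm": "L/min", "valve_frac": "fraction", "amp_lpm": "L/min",
          "phase_rad": "rad", "period_s": "s", "u_frac": "fraction"}


def write_traces(output: SimOutput, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_csv({k: output.series[k] for k in TRACE_COLUMNS}, out_dir / "traces.csv")
    write_csv({k: output.controller[k] for k in CONTROLLER_COLUMNS},
              out_dir / "controller.csv")
    meta = {"cycle": output.cycle, "dt": output.dt,
            "segments": [list(s) for s in output.segments]}
    (out_dir / "segments.json").write_text(json.dumps(meta, indent=2) + "\n",
                                           encoding="utf-8")
    return out_dir


def read_traces(in_dir) -> SimOutput:
    in_dir = Path(in_dir)
    traces_path = in_dir / "traces.csv"
    if not traces_path.exists():
        raise InvalidInputError(f"no traces.csv in {in_dir}")
    series = read_csv(traces_path, units=_UNITS)
    missing = [c for c in TRACE_COLUMNS if c not in series]
    if missing:
        raise InvalidInputError(
            f"traces.csv is missing expected columns {missing}; "
            f"expected {('time_s',) + TRACE_COLUMNS}")
    controller: dict[str, UniformSeries] = {}
    ctl_path = in_dir / "controller.csv"
    if ctl_path.exists():
        controller = read_csv(ctl_path, units=_UNITS)
    meta_path = in_dir / "segments.json"
    cycle, dt, segments = 60.0, 1.0, []
    if meta_path.exists():
        meta = json.loads(meta_path.read_text(encoding="utf-8"))
        cycle = meta.get("cycle", 60.0)
        dt = meta.get("dt", 1.0)
        segments = [tuple(s) for s in meta.get("segments", [])]
    return SimOutput(series=series, controller=controller, segments=segments,
                     cycle=cycle, dt=dt)
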