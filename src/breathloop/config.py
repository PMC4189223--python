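"""Validated run configuration, JSON/YAML loading and seed derivation.

A single :class:`RunConfig` describes a whole study: the virtual subject
or cohort, the protocol, tracker settings, the delivery configuration,
integration step and the master seed.  Unknown keys are rejected and
every violation is reported, not just the first.

Seed splitting: one master seed makes a whole study bit-reproducible.
Component streams are derived as ``SeedSequence([master, *path])`` with
fixed integer paths (0 = cohort draw, (1, i) = measurement noise of
subject i), so adding a component never perturbs existing streams.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import physiology
from .dosing import DeliveryConfig
from .errors import InvalidInputError
from .tracker import TrackerConfig

__all__ = [
    "SubjectSettings",
    "CohortSettings",
    "TrackerSettings",
    "DeliverySettings",
    "ProtocolSettings",
    "RunConfig",
    "load_config",
    "save_config",
    "derive_seed",
]


def derive_seed(master: int, *path: int) -> int:
    """Deterministic child seed below 2**31 for a component stream."""
    return int(np.random.SeedSequence([int(master), *map(int, path)])
               .generate_state(1)[0] % (2**31))


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SubjectSettings(_Strict):
    hf: bool = True
    gain: float | None = Field(default=None, gt=0)
    delay: float | None = Field(default=None, ge=0)
    baseline_q: float = Field(default=6.9, gt=0)
    delta_q: float = Field(default=2.46, ge=0)
    baseline_ve: float = Field(default=7.8, gt=0)
    pet0: float = Field(default=4.84, gt=0)
    lung_store: float = Field(default=3.0, gt=0)
    tissue_store: float = Field(default=15.0, gt=0)
    dissociation_slope: float = Field(default=0.047, gt=0)
    dead_fraction: float = Field(default=0.3, ge=0, lt=1)
    ve_floor: float = Field(default=0.0, ge=0)
    p_b: float = Field(default=physiology.BAROMETRIC_KPA, gt=0)

    def to_subject(self) -> physiology.VirtualSubject:
        over = self.model_dump()
        over["set_point"] = over.pop("pet0")
        hf = over.pop("hf")
        for key in ("gain", "delay"):
            if over[key] is None:
                del over[key]
        return physiology.default_subject(hf=hf, **over)


class CohortSettings(_Strict):
    n_hf: int = Field(default=6, ge=0)
    n_nonhf: int = Field(default=6, ge=0)
    stability_margin: float = Field(default=0.8, gt=0, le=1)

    def to_spec(self, seed: int) -> physiology.CohortSpec:
        return physiology.CohortSpec(n_hf=self.n_hf, n_nonhf=self.n_nonhf,
                                     seed=seed, stability_margin=self.stability_margin)


class TrackerSettings(_Strict):
    band_lo: float = Field(default=40.0, gt=0)
    band_hi: float = Field(default=90.0, gt=0)
    period_blend: float = Field(default=0.3, gt=0, le=1)
    phase_slew: float = Field(default=0.2, gt=0)
    power_ratio_threshold: float = Field(default=0.25, ge=0, le=1)

    @model_validator(mode="after")
    def _band_order(self):
        if self.band_lo >= self.band_hi:
            raise ValueError(f"band_lo ({self.band_lo}) must be < band_hi ({self.band_hi})")
        return self

    def to_tracker(self) -> TrackerConfig:
        return TrackerConfig(band=(self.band_lo, self.band_hi),
                             period_blend=self.period_blend,
                             phase_slew=self.phase_slew,
                             power_ratio_threshold=self.power_ratio_threshold)


class DeliverySettings(_Strict):
    """Config keys mirror DeliveryConfig field names exactly."""

    c_max: float = Field(default=0.05, gt=0, lt=1)
    kC: float = Field(default=0.01, ge=0)
    A_ref: float = Field(default=2.0, gt=0)
    w_min: float = Field(default=0.15, ge=0, le=1)
    w_max: float = Field(default=0.5, ge=0, le=1)
    A_min: float = Field(default=0.5, ge=0)
    mode: str = Field(default="inphase", pattern="^(inphase|antiphase)$")
    d_valve_inspired: float = Field(default=8.8, ge=0)
    d_inspired_alveolar: float = Field(default=0.2, ge=0)
    mix_tau: float = Field(default=1.0, ge=0)

    @model_validator(mode="after")
    def _window_order(self):
        if self.w_min > self.w_max:
            raise ValueError(f"w_min ({self.w_min}) must be <= w_max ({self.w_max})")
        return self

    def to_delivery(self) -> DeliveryConfig:
        return DeliveryConfig(**self.model_dump())


class ProtocolSettings(_Strict):
    settle_cycles: int = Field(default=3, ge=0)
    metric_cycles: int = Field(default=5, ge=1)
    washout_cycles: int = Field(default=2, ge=1)
    cycle_s: float = Field(default=60.0, gt=0)


class RunConfig(_Strict):
    """Top-level study configuration (all fields optional; `{}` is the
    all-defaults study)."""

    subject: SubjectSettings = Field(default_factory=SubjectSettings)
    cohort: CohortSettings = Field(default_factory=CohortSettings)
    protocol: ProtocolSettings = Field(default_factory=ProtocolSettings)
    tracker: TrackerSettings = Field(default_factory=TrackerSettings)
    delivery: DeliverySettings = Field(default_factory=DeliverySettings)
    dt: float = Field(default=0.05, gt=0, le=0.2)
    seed: int = Field(default=0, ge=0)
    noise_sd: float = Field(default=0.0, ge=0)
    out_dir: str | None = None

    @model_validator(mode="after")
    def _dt_divides_second(self):
        n = round(1.0 / self.dt)
        if abs(n * self.dt - 1.0) > 1e-9:
            raise ValueError(f"dt ({self.dt}) must divide 1 s exactly")
        return self


def load_config(path) -> RunConfig:
    """Load and validate a JSON (or YAML) run configuration."""
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"config file not found: {path}")
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text) if text.strip() else {}
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise InvalidInputError(f"could not parse {path}: {exc}") from exc
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        msgs = [f"{'.'.join(str(loc) for loc in e['loc'])}: {e['msg']}"
                for e in exc.errors()]
        raise InvalidInputError(
            f"invalid configuration ({len(msgs)} violation(s)):\n  " + "\n  ".join(msgs)
        ) from exc


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(cfg.model_dump_json(indent=2) + "\n", encoding="utf-8")
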