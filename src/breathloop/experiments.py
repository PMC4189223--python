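"""Study orchestration: protocol arms, oscillation metrics and the
cohort comparison report.

The protocol mirrors the pacemaker study: a quiet baseline, an untreated
arm with square-wave cardiac-output alternation only, a therapeutic arm
with dynamic CO2 timed so peak alveolar CO2 coincides with peak
ventilation, a washout (alternation, no dose), and an antiphase control
arm dosed at trough ventilation.  Each metric-bearing arm runs a
settling period followed by at least five 60 s cycles; metrics
(mean, coefficient of variation and fixed-period sine-fit r2 of
end-tidal CO2 and ventilation) are computed over the final five complete
cycles.  Cohort-level contrasts use paired t tests, as the study did.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

from .dosing import DeliveryConfig
from .errors import InvalidInputError, UndefinedMetricError
from .physiology import Segment, SimOutput, VirtualSubject, simulate
from .signals import coefficient_of_variation, fit_sine
from .tracker import TrackerConfig

__all__ = [
    "ArmMetrics",
    "ArmsResult",
    "ComparisonReport",
    "PairedT",
    "run_arms",
    "arm_metrics_from_output",
    "percent_increase",
    "attenuation_fraction",
    "paired_t",
    "report",
    "default_protocol",
]

ARMS = ("baseline", "untreated", "inphase", "antiphase")
_METRICS = ("mean_pet", "cov_pet", "mean_ve", "cov_ve", "sine_r2_pet", "sine_r2_ve")

#: Contrasts mirroring the study's comparison table.
CONTRASTS = (
    ("untreated", "baseline"),
    ("inphase", "baseline"),
    ("inphase", "untreated"),
    ("antiphase", "baseline"),
    ("antiphase", "untreated"),
    ("antiphase", "inphase"),
)


@dataclass(frozen=True)
class ArmMetrics:
    """Per-arm oscillation metrics over the analysis window."""

    arm: str
    mean_pet: float
    cov_pet: float
    mean_ve: float
    cov_ve: float
    sine_r2_pet: float
    sine_r2_ve: float

    def __post_init__(self) -> None:
        if self.cov_pet < 0 or self.cov_ve < 0:
            raise InvalidInputError("coefficients of variation must be >= 0")
        for r2 in (self.sine_r2_pet, self.sine_r2_ve):
            if not (0.0 <= r2 <= 1.0):
                raise InvalidInputError("sine-fit r2 must lie in [0, 1]")


@dataclass
class ArmsResult:
    metrics: list[ArmMetrics]
    output: SimOutput

    def __getitem__(self, arm: str) -> ArmMetrics:
        for m in self.metrics:
            if m.arm == arm:
                return m
        raise KeyError(arm)


def default_protocol(settle_cycles: int = 3, metric_cycles: int = 5,
                     washout_cycles: int = 2) -> list[Segment]:
    """Baseline, untreated, in-phase, washout, antiphase — each
    metric-bearing arm runs settle + metric cycles."""
    n = settle_cycles + metric_cycles
    return [
        Segment("baseline", n, alternate=False),
        Segment("untreated", n, alternate=True),
        Segment("inphase", n, alternate=True, dose_mode="inphase"),
        Segment("washout", washout_cycles, alternate=True),
        Segment("antiphase", n, alternate=True, dose_mode="antiphase"),
    ]


def arm_metrics_from_output(output: SimOutput, arm: str,
                            metric_cycles: int = 5) -> ArmMetrics:
    """Metrics over the final ``metric_cycles`` complete driver cycles of
    the named segment."""
    t0, t1 = output.segment_span(arm)
    window = metric_cycles * output.cycle
    if t1 - t0 < window:
        raise InvalidInputError(
            f"segment {arm!r} spans {t1 - t0:.0f} s < analysis window {window:.0f} s")
    pet = output.series["petco2_kpa"].window(t1 - window, t1)
    ve = output.series["ve_lpm"].window(t1 - window, t1)
    fit_pet = fit_sine(pet, output.cycle)
    fit_ve = fit_sine(ve, output.cycle)
    return ArmMetrics(
        arm=arm,
        mean_pet=float(np.mean(pet.values)),
        cov_pet=coefficient_of_variation(pet),
        mean_ve=float(np.mean(ve.values)),
        cov_ve=coefficient_of_variation(ve),
        sine_r2_pet=fit_pet.r2,
        sine_r2_ve=fit_ve.r2,
    )


def run_arms(subject: VirtualSubject,
             delivery: DeliveryConfig | None = None,
             tracker_config: TrackerConfig | None = None,
             *,
             seed: int | None = None,
             settle_cycles: int = 3,
             metric_cycles: int = 5,
             washout_cycles: int = 2,
             cycle: float = 60.0,
             dt: float = 0.05,
             noise_sd: float = 0.0) -> ArmsResult:
    """Run the four-arm protocol on one calibrated subject.

    Arms are simulated as one continuous timeline (the tracker and the
    CO2 stores carry over, with a washout between the dosed arms), so no
    dose can leak into undosed segments.
    """
    protocol = default_protocol(settle_cycles, metric_cycles, washout_cycles)
    output = simulate(subject, protocol, delivery, tracker_config,
                      cycle=cycle, dt=dt, seed=seed, noise_sd=noise_sd)
    metrics = [arm_metrics_from_output(output, arm, metric_cycles) for arm in ARMS]
    return ArmsResult(metrics=metrics, output=output)


def percent_increase(base: float, raised: float) -> float:
    """100 * (raised - base) / base."""
    if base <= 0:
        raise InvalidInputError(f"base must be positive, got {base}")
    return 100.0 * (raised - base) / base


def attenuation_fraction(cov_baseline: float, cov_untreated: float,
                         cov_treated: float) -> float:
    """Fraction of the induced oscillation removed by therapy:
    (untreated - treated) / (untreated - baseline)."""
    denom = cov_untreated - cov_baseline
    if denom <= 0:
        raise InvalidInputError(
            f"untreated CoV ({cov_untreated}) must exceed baseline CoV ({cov_baseline})")
    return (cov_untreated - cov_treated) / denom


class PairedT(NamedTuple):
    t: float
    df: int
    p: float


def paired_t(a: Sequence[float], b: Sequence[float]) -> PairedT:
    """Paired t test: t = mean(d) / (sd_sample(d)/sqrt(n)), d = a - b,
    two-sided p from the t distribution with n - 1 df.

    Identical inputs (all differences zero) carry no evidence of a
    difference and return t = 0, p = 1; a nonzero constant difference has
    zero variance and the statistic is undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError("paired_t requires two equal-length 1-D sequences")
    n = a.size
    if n < 2:
        raise UndefinedMetricError(f"paired t test undefined for n={n} < 2")
    d = a - b
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        if np.all(d == 0):
            return PairedT(0.0, n - 1, 1.0)
        raise UndefinedMetricError(
            "paired t test undefined for zero-variance nonzero differences")
    t = float(np.mean(d)) / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return PairedT(t, n - 1, min(p, 1.0))


@dataclass
class ComparisonReport:
    """Cohort summary: per-arm mean +/- SD of every metric, paired-t
    contrasts, and the attenuation / percent-increase summaries."""

    n: int
    arms: dict[str, dict[str, tuple[float, float]]]
    contrasts: list[dict]
    summaries: dict[str, float]
    degenerate: bool = False
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "arms": {arm: {m: list(v) for m, v in d.items()}
                     for arm, d in self.arms.items()},
            "contrasts": self.contrasts,
            "summaries": self.summaries,
            "degenerate": self.degenerate,
            "notes": self.notes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ComparisonReport":
        return cls(
            n=d["n"],
            arms={arm: {m: tuple(v) for m, v in metrics.items()}
                  for arm, metrics in d["arms"].items()},
            contrasts=d["contrasts"],
            summaries=d["summaries"],
            degenerate=d["degenerate"],
            notes=list(d.get("notes", [])),
        )

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def render(self) -> str:
        """Aligned text table (CoV to 2 decimals, ventilation to 1)."""
        lines = [f"Cohort comparison (n={self.n})", ""]
        hdr = f"{'Arm':<12}{'PetCO2 kPa':>14}{'CoV Pet':>10}{'VE L/min':>12}{'CoV VE':>10}"
        lines.append(hdr)
        lines.append("-" * len(hdr))
        for arm in ARMS:
            if arm not in self.arms:
                continue
            d = self.arms[arm]
            mp, sp = d["mean_pet"]
            cp, scp = d["cov_pet"]
            mv, sv = d["mean_ve"]
            cv, scv = d["cov_ve"]
            lines.append(f"{arm:<12}{mp:>7.2f}±{sp:<5.2f}{cp:>5.2f}±{scp:<4.2f}"
                         f"{mv:>6.1f}±{sv:<5.1f}{cv:>5.2f}±{scv:<4.2f}")
        if self.contrasts:
            lines += ["", f"{'Contrast':<26}{'Metric':<12}{'t':>8}{'df':>4}{'p':>10}"]
            for c in self.contrasts:
                lines.append(f"{c['arm_a'] + ' vs ' + c['arm_b']:<26}{c['metric']:<12}"
                             f"{c['t']:>8.3f}{c['df']:>4d}{c['p']:>10.2g}")
        else:
            lines.append("\n[contrasts omitted: fewer than 2 subjects or arms]")
        if self.summaries:
            lines.append("")
            for k, v in self.summaries.items():
                lines.append(f"{k}: {v:.3g}")
        return "\n".join(lines)


def report(cohort_metrics: Sequence[Sequence[ArmMetrics]]) -> ComparisonReport:
    """Aggregate per-subject arm metrics into the cohort report.

    ``cohort_metrics`` holds one list of :class:`ArmMetrics` per subject.
    With fewer than 2 subjects, or with arms missing, the affected
    contrasts are omitted and flagged rather than raised.
    """
    n = len(cohort_metrics)
    if n == 0:
        raise InvalidInputError("report requires at least one subject")
    # metric arrays per arm: arm -> metric -> per-subject values
    table: dict[str, dict[str, list[float]]] = {}
    for subject_metrics in cohort_metrics:
        for am in subject_metrics:
            table.setdefault(am.arm, {m: [] for m in _METRICS})
            for m in _METRICS:
                table[am.arm][m].append(getattr(am, m))

    arms_summary: dict[str, dict[str, tuple[float, float]]] = {}
    for arm, metrics in table.items():
        arms_summary[arm] = {}
        for m, vals in metrics.items():
            v = np.asarray(vals)
            sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
            arms_summary[arm][m] = (float(np.mean(v)), sd)

    notes: list[str] = []
    degenerate = n < 2 or len(table) < 2
    contrasts: list[dict] = []
    if not degenerate:
        complete = {arm for arm, m in table.items() if len(m["cov_ve"]) == n}
        for arm_a, arm_b in CONTRASTS:
            if arm_a not in complete or arm_b not in complete:
                notes.append(f"contrast {arm_a} vs {arm_b} skipped: incomplete arms")
                continue
            for m in _METRICS:
                try:
                    res = paired_t(table[arm_a][m], table[arm_b][m])
                except UndefinedMetricError as exc:
                    notes.append(f"{arm_a} vs {arm_b} [{m}]: {exc}")
                    continue
                contrasts.append({"arm_a": arm_a, "arm_b": arm_b, "metric": m,
                                  "t": res.t, "df": res.df, "p": res.p})
    else:
        notes.append("contrasts omitted: need >= 2 subjects and >= 2 arms")

    summaries: dict[str, float] = {}
    have = arms_summary
    if {"baseline", "untreated"} <= have.keys():
        # a noiseless baseline sits at exact equilibrium (CoV ~ 0); the
        # relative increase is only meaningful against a finite baseline
        for sig in ("cov_ve", "cov_pet"):
            base = have["baseline"][sig][0]
            if base >= 1e-4:
                summaries[f"percent_increase_{sig}"] = percent_increase(
                    base, have["untreated"][sig][0])
            else:
                notes.append(f"percent increase in {sig} omitted: baseline CoV "
                             f"{base:.2g} is numerically zero (quiet equilibrium)")
    if {"baseline", "untreated", "inphase"} <= have.keys():
        try:
            summaries["attenuation_cov_ve"] = attenuation_fraction(
                have["baseline"]["cov_ve"][0], have["untreated"]["cov_ve"][0],
                have["inphase"]["cov_ve"][0])
            summaries["attenuation_cov_pet"] = attenuation_fraction(
                have["baseline"]["cov_pet"][0], have["untreated"]["cov_pet"][0],
                have["inphase"]["cov_pet"][0])
        except InvalidInputError as exc:
            notes.append(f"attenuation summary skipped: {exc}")

    return ComparisonReport(n=n, arms=arms_summary, contrasts=contrasts,
                            summaries=summaries, degenerate=degenerate, notes=notes)
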