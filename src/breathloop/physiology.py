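"""Closed-loop CO2-store / chemoreflex model of pacemaker-driven
periodic breathing, and a synthetic cohort generator.

The virtual subject is the minimal structure reproducing the observed
causal chain of the pacemaker experiments — a cardiac-output step is
followed by a rise in end-tidal CO2 and then, one chemoreflex delay
later, by a rise in ventilation:

* a lung CO2 store (volume ``V_L``) filled by pulmonary blood flow and
  emptied by alveolar ventilation::

      V_L * dFA/dt = VA*(FI - FA) + s_b*Q*(Pv - P_B*FA)

* a lumped tissue store (capacity ``C_T``) charged by metabolic CO2
  production and discharged into the lung by the circulation::

      C_T * dPv/dt = VCO2 - s_b*Q*(Pv - P_B*FA)

* a delayed linear chemoreflex, floored at ``VE_floor``::

      VE(t) = max(VE_floor, VE0 + G*(Pet(t - tau) - P_set)),
      VA = (1 - f_D)*VE,  Pet = P_B*FA

Square-wave alternation of the cardiac output Q (30 s high / 30 s low)
forces the loop, producing driven 60 s oscillations in end-tidal CO2 and
ventilation.  At the calibrated operating point the alveolar gas
equation ``VA*(FA - FI) = VCO2`` holds exactly, and the loop is
parameterised subcritically: the oscillation is driven, not
self-sustained, mirroring subjects screened to be free of spontaneous
periodic breathing.

End-tidal CO2 is the continuous alveolar fraction times barometric
pressure — no intra-breath structure is rendered, since all analysis
operates on 1 Hz resampled signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .dosing import DeliveryConfig, GasPath, schedule_dose
from .errors import IntegrationError, InvalidInputError
from .signals import UniformSeries
from .tracker import OscillationTracker, TrackerConfig

__all__ = [
    "BAROMETRIC_KPA",
    "GAIN_RATIO_HF_NONHF",
    "VirtualSubject",
    "SimState",
    "Segment",
    "SimOutput",
    "CohortSpec",
    "ParamStat",
    "default_subject",
    "calibrate",
    "equilibrium_state",
    "qdot_driver",
    "chemoreflex_ve",
    "rhs",
    "step",
    "simulate",
    "static_loop_gain",
    "critical_gain",
    "generate_cohort",
]

BAROMETRIC_KPA = 101.0

#: Ratio of heart-failure to non-heart-failure chemoreflex gain.  The
#: printed group gains (608.4 vs 385.9 L/min/kPa) are implausible as
#: absolute loop gains; only their ratio is carried over.
GAIN_RATIO_HF_NONHF = 608.4 / 385.9

#: Absolute default chemoreflex gains, L/min per kPa.  Chosen subcritical
#: for the default operating point (gain margin ~1.8 for the cohort-mean
#: subject; see docs/methods.md for the linearised loop analysis), with
#: the HF:non-HF ratio fixed to GAIN_RATIO_HF_NONHF.
GAIN_HF_DEFAULT = 7.0
GAIN_NONHF_DEFAULT = GAIN_HF_DEFAULT / GAIN_RATIO_HF_NONHF


@dataclass(frozen=True)
class VirtualSubject:
    """Parameters of one simulated patient.

    gain : chemoreflex gain G, L/min ventilation per kPa end-tidal CO2.
    delay : chemoreflex delay tau, s (end-tidal peak to ventilation peak;
        circulatory lung-to-chemoreceptor transit is lumped in).
    baseline_q / delta_q : resting cardiac output and alternation
        amplitude (half the high-low difference), L/min.
    vco2 : metabolic CO2 production, L/min (filled by :func:`calibrate`).
    lung_store : effective lung CO2 volume V_L, litres.
    tissue_store : tissue CO2 capacity C_T, L/kPa.
    dissociation_slope : blood CO2 dissociation slope s_b, L CO2 per
        L blood per kPa.
    set_point / baseline_ve : chemoreflex operating point (filled by
        :func:`calibrate` so the baseline is an equilibrium).
    dead_fraction : dead-space fraction of each breath, [0, 1).
    ve_floor : lowest attainable ventilation, L/min.
    """

    gain: float
    delay: float
    baseline_q: float
    delta_q: float
    baseline_ve: float
    set_point: float
    vco2: float = float("nan")
    lung_store: float = 3.0
    tissue_store: float = 15.0
    dissociation_slope: float = 0.047
    dead_fraction: float = 0.3
    ve_floor: float = 0.0
    hf: bool = True
    p_b: float = BAROMETRIC_KPA

    def __post_init__(self) -> None:
        for name in ("baseline_q", "baseline_ve", "lung_store", "tissue_store",
                     "dissociation_slope", "set_point", "p_b"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be positive, got {getattr(self, name)}")
        if self.delta_q < 0 or self.delay < 0 or self.ve_floor < 0:
            raise InvalidInputError("delta_q, delay and ve_floor must be >= 0")
        if not (0 <= self.dead_fraction < 1):
            raise InvalidInputError(f"dead_fraction must lie in [0, 1), got {self.dead_fraction}")

    @property
    def calibrated(self) -> bool:
        return math.isfinite(self.vco2)


@dataclass(frozen=True)
class SimState:
    """Instantaneous state of the closed loop."""

    FA: float   # alveolar CO2 fraction
    Pv: float   # mixed-venous CO2 partial pressure, kPa
    Pet: float  # end-tidal CO2, kPa
    VE: float   # ventilation, L/min
    FI: float   # inspired CO2 fraction at the lung
    Q: float    # cardiac output, L/min


def calibrate(subject: VirtualSubject, baseline_ve: float | None = None,
              pet0: float | None = None) -> VirtualSubject:
    """Anchor the subject at a steady state with the target baseline
    ventilation and end-tidal CO2.

    The steady-state alveolar gas equation with FI = 0 fixes the metabolic
    rate, ``VCO2 = (1 - f_D) * VE0 * Pet0 / P_B``, and the chemoreflex set
    point is placed at Pet0 so the baseline is an exact equilibrium.
    """
    ve0 = subject.baseline_ve if baseline_ve is None else baseline_ve
    p0 = subject.set_point if pet0 is None else pet0
    if not ve0 > 0:
        raise InvalidInputError(f"baseline ventilation must be positive, got {ve0}")
    if not (0 < p0 < subject.p_b):
        raise InvalidInputError(
            f"target end-tidal CO2 must lie in (0, {subject.p_b}), got {p0}")
    vco2 = (1.0 - subject.dead_fraction) * ve0 * p0 / subject.p_b
    return replace(subject, baseline_ve=ve0, set_point=p0, vco2=vco2)


def default_subject(hf: bool = True, **overrides) -> VirtualSubject:
    """Cohort-mean virtual subject, calibrated.

    Hemodynamics use the whole-group printed means (resting cardiac
    output 6.9 L/min, alternation amplitude 2.46 L/min, baseline
    ventilation 7.8 L/min, end-tidal CO2 4.84 kPa); gain and delay take
    the group defaults (HF: G = 7.0 L/min/kPa, tau = 22.4 s).
    """
    params = dict(
        gain=GAIN_HF_DEFAULT if hf else GAIN_NONHF_DEFAULT,
        delay=22.4 if hf else 16.9,
        baseline_q=6.9,
        delta_q=2.46,
        baseline_ve=7.8,
        set_point=4.84,
        hf=hf,
    )
    params.update(overrides)
    return calibrate(VirtualSubject(**params))


def equilibrium_state(subject: VirtualSubject, fi: float = 0.0) -> SimState:
    """Exact fixed point of the loop at constant Q = baseline_q."""
    if not subject.calibrated:
        raise InvalidInputError("subject must be calibrated first")
    va = (1.0 - subject.dead_fraction) * subject.baseline_ve
    fa = fi + subject.vco2 / va
    pet = subject.p_b * fa
    pv = pet + subject.vco2 / (subject.dissociation_slope * subject.baseline_q)
    return SimState(FA=fa, Pv=pv, Pet=pet, VE=subject.baseline_ve, FI=fi,
                    Q=subject.baseline_q)


def qdot_driver(t: float, q0: float, dq: float, cycle: float = 60.0,
                phase0: float = 0.0) -> float:
    """Square-wave cardiac output: q0 + dq for the first half-cycle,
    q0 - dq for the second, repeating every ``cycle`` seconds."""
    if cycle <= 0:
        raise InvalidInputError(f"cycle must be positive, got {cycle}")
    frac = ((t - phase0) % cycle) / cycle
    return q0 + dq if frac < 0.5 else q0 - dq


def chemoreflex_ve(subject: VirtualSubject, pet_delayed: float) -> float:
    """Delayed linear chemoreflex with a hard ventilation floor."""
    return max(subject.ve_floor,
               subject.baseline_ve + subject.gain * (pet_delayed - subject.set_point))


def rhs(state: SimState, subject: VirtualSubject, fi: float, q: float,
        ve: float) -> tuple[float, float]:
    """Time derivatives (dFA/dt, dPv/dt) in per-minute units."""
    va = (1.0 - subject.dead_fraction) * ve
    transfer = subject.dissociation_slope * q * (state.Pv - subject.p_b * state.FA)
    dfa = (va * (fi - state.FA) + transfer) / subject.lung_store
    dpv = (subject.vco2 - transfer) / subject.tissue_store
    return dfa, dpv


def step(state: SimState, subject: VirtualSubject, fi_command: float, q: float,
         dt: float, pet_delayed: float) -> SimState:
    """One explicit Euler step of ``dt`` seconds.

    ``pet_delayed`` is Pet(t - tau) supplied by the caller's delay buffer.
    """
    if not (0 < dt <= 0.2):
        raise InvalidInputError(f"dt must lie in (0, 0.2], got {dt}")
    ve = chemoreflex_ve(subject, pet_delayed)
    dfa, dpv = rhs(state, subject, fi_command, q, ve)
    dt_min = dt / 60.0  # rates are per minute
    fa = state.FA + dfa * dt_min
    pv = state.Pv + dpv * dt_min
    for name, value in (("alveolar fraction FA", fa), ("venous CO2 Pv", pv)):
        if not math.isfinite(value):
            raise IntegrationError(f"{name} became non-finite")
    if not (0.0 <= fa < 1.0):
        raise IntegrationError(f"alveolar fraction FA left [0, 1): {fa}")
    if pv <= 0:
        raise IntegrationError(f"venous CO2 Pv became non-positive: {pv}")
    return SimState(FA=fa, Pv=pv, Pet=subject.p_b * fa, VE=ve, FI=fi_command, Q=q)


# ---------------------------------------------------------------------------
# Protocol segments and the closed-loop simulator


@dataclass(frozen=True)
class Segment:
    """One protocol segment: ``n_cycles`` driver cycles with the cardiac
    alternation on or off and an optional dose mode."""

    name: str
    n_cycles: int
    alternate: bool
    dose_mode: str | None = None  # None | 'inphase' | 'antiphase'

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise InvalidInputError("segment needs >= 1 cycle")
        if self.dose_mode not in (None, "inphase", "antiphase"):
            raise InvalidInputError(f"unknown dose mode {self.dose_mode!r}")


@dataclass
class SimOutput:
    """1 Hz output bundle of one simulation run."""

    series: dict[str, UniformSeries]
    controller: dict[str, UniformSeries]
    segments: list[tuple[str, float, float]]  # (name, t_start, t_end)
    cycle: float
    dt: float

    def segment_span(self, name: str) -> tuple[float, float]:
        for seg_name, t0, t1 in self.segments:
            if seg_name == name:
                return t0, t1
        raise KeyError(f"no segment named {name!r}")


def _arm_segments(arm: str, n_cycles: int) -> list[Segment]:
    presets = {
        "baseline": Segment("baseline", n_cycles, alternate=False),
        "untreated": Segment("untreated", n_cycles, alternate=True),
        "inphase": Segment("inphase", n_cycles, alternate=True, dose_mode="inphase"),
        "antiphase": Segment("antiphase", n_cycles, alternate=True, dose_mode="antiphase"),
        "washout": Segment("washout", n_cycles, alternate=True),
    }
    if arm not in presets:
        raise InvalidInputError(f"unknown arm {arm!r}; choose from {sorted(presets)}")
    return [presets[arm]]


def simulate(subject: VirtualSubject,
             protocol: list[Segment] | str,
             delivery: DeliveryConfig | None = None,
             tracker_config: TrackerConfig | None = None,
             *,
             n_cycles: int = 8,
             cycle: float = 60.0,
             dt: float = 0.05,
             seed: int | None = None,
             noise_sd: float = 0.0) -> SimOutput:
    """Integrate the closed loop through a protocol.

    ``protocol`` is either a list of :class:`Segment` or an arm name
    (``baseline``/``untreated``/``inphase``/``antiphase``), in which case
    a single segment of ``n_cycles`` driver cycles is run.  The tracker
    is updated and the dose command recomputed once per second; the
    command is held for the second and propagated through the gas path at
    the integration rate.  Outputs are recorded on the 1 Hz grid.

    ``seed`` controls the optional ventilation measurement noise
    (``noise_sd`` L/min, applied to the tracker input only).
    """
    if not subject.calibrated:
        raise InvalidInputError("subject must be calibrated before simulation")
    if isinstance(protocol, str):
        protocol = _arm_segments(protocol, n_cycles)
    if not protocol:
        raise InvalidInputError("protocol must contain at least one segment")
    n_sub = round(1.0 / dt)
    if n_sub < 5 or abs(n_sub * dt - 1.0) > 1e-9:
        raise InvalidInputError(f"dt must divide 1 s exactly and be <= 0.2 s, got {dt}")

    delivery = delivery or DeliveryConfig()
    tracker = OscillationTracker(tracker_config)
    gas = GasPath(delivery, dt)
    rng = np.random.default_rng(seed) if noise_sd > 0 else None

    # segment boundaries in whole seconds
    bounds: list[tuple[str, float, float]] = []
    t_acc = 0.0
    for seg in protocol:
        bounds.append((seg.name, t_acc, t_acc + seg.n_cycles * cycle))
        t_acc += seg.n_cycles * cycle
    total = int(round(t_acc))

    delay_steps = max(1, int(round(subject.delay / dt)))
    state = equilibrium_state(subject)
    ring = [state.Pet] * delay_steps
    ridx = 0

    n_rec = total + 1
    rec = {k: np.empty(n_rec) for k in
           ("ve_lpm", "petco2_kpa", "fico2_frac", "qdot_lpm", "valve_frac")}
    ctl = {k: np.empty(n_rec) for k in ("amp_lpm", "phase_rad", "period_s", "u_frac")}

    seg_i = 0
    fi_mouth = 0.0
    for sec in range(n_rec):
        t = float(sec)
        while seg_i + 1 < len(protocol) and t >= bounds[seg_i][2]:
            seg_i += 1
        seg = protocol[seg_i]

        ve_meas = state.VE if rng is None else state.VE + noise_sd * rng.standard_normal()
        tr_state = tracker.update(t, ve_meas)
        u = 0.0
        if seg.dose_mode is not None and tr_state.valid:
            cfg = delivery if delivery.mode == seg.dose_mode else replace(delivery, mode=seg.dose_mode)
            u = schedule_dose(tr_state, cfg).u

        q_now = qdot_driver(t, subject.baseline_q, subject.delta_q, cycle) \
            if seg.alternate else subject.baseline_q
        rec["ve_lpm"][sec] = state.VE
        rec["petco2_kpa"][sec] = state.Pet
        rec["fico2_frac"][sec] = fi_mouth
        rec["qdot_lpm"][sec] = q_now
        rec["valve_frac"][sec] = u
        ctl["amp_lpm"][sec] = tr_state.amplitude
        ctl["phase_rad"][sec] = tr_state.phase
        ctl["period_s"][sec] = tr_state.period if tr_state.valid else 0.0
        ctl["u_frac"][sec] = u

        if sec == total:
            break
        for k in range(n_sub):
            tk = t + k * dt
            q = qdot_driver(tk, subject.baseline_q, subject.delta_q, cycle) \
                if seg.alternate else subject.baseline_q
            fi_mouth, fi_alv = gas.step(u)
            pet_delayed = ring[ridx]
            state = step(state, subject, fi_alv, q, dt, pet_delayed)
            ring[ridx] = state.Pet
            ridx = (ridx + 1) % delay_steps

    units = {"ve_lpm": "L/min", "petco2_kpa": "kPa", "fico2_frac": "fraction",
             "qdot_lpm": "L/min", "valve_frac": "fraction",
             "amp_lpm": "L/min", "phase_rad": "rad", "period_s": "s",
             "u_frac": "fraction"}
    series = {k: UniformSeries(0.0, v, 1.0, units[k], k) for k, v in rec.items()}
    controller = {k: UniformSeries(0.0, v, 1.0, units[k], k) for k, v in ctl.items()}
    return SimOutput(series=series, controller=controller, segments=bounds,
                     cycle=cycle, dt=dt)


# ---------------------------------------------------------------------------
# Linearised loop analysis (used to keep the cohort subcritical)


def _plant_denominator(subject: VirtualSubject) -> float:
    """VA0 + s_b*Q0*P_B, L/min — the lung-store restoring coefficient."""
    va0 = (1.0 - subject.dead_fraction) * subject.baseline_ve
    return va0 + subject.dissociation_slope * subject.baseline_q * subject.p_b


def static_loop_gain(subject: VirtualSubject) -> float:
    """Dimensionless DC loop gain of the linearised chemoreflex loop."""
    return ((1.0 - subject.dead_fraction) * subject.gain * subject.set_point
            / _plant_denominator(subject))


def critical_gain(subject: VirtualSubject) -> float:
    """Chemoreflex gain at which the linearised loop reaches its
    stability boundary (unit gain at the phase-crossover frequency of
    the delay + lung-store lag).  Infinite when the delay is zero."""
    if subject.delay <= 0:
        return float("inf")
    d = _plant_denominator(subject)
    pole = d / (60.0 * subject.lung_store)  # rad/s
    w = math.pi / subject.delay
    for _ in range(100):
        w_new = (math.pi - math.atan(w / pole)) / subject.delay
        if abs(w_new - w) < 1e-12:
            w = w_new
            break
        w = w_new
    t0_crit = math.sqrt(1.0 + (w / pole) ** 2)
    return t0_crit * d / ((1.0 - subject.dead_fraction) * subject.set_point)


# ---------------------------------------------------------------------------
# Synthetic cohort


@dataclass(frozen=True)
class ParamStat:
    """Target mean and SD of one subject parameter, with a physiologic
    floor below which draws are truncated."""

    mean: float
    sd: float
    floor: float


def _default_group_stats(hf: bool) -> dict[str, ParamStat]:
    # Printed group statistics; gains use the group defaults with the
    # printed relative spread.
    if hf:
        return {
            "delta_q": ParamStat(1.23, 0.86, 0.2),
            "delay": ParamStat(22.4, 3.1, 5.0),
            "baseline_q": ParamStat(4.5, 2.1, 2.0),
            "baseline_ve": ParamStat(8.1, 1.8, 3.0),
            "pet0": ParamStat(4.6, 0.7, 3.0),
            "gain": ParamStat(GAIN_HF_DEFAULT, GAIN_HF_DEFAULT * 233.5 / 608.4, 1.0),
        }
    return {
        "delta_q": ParamStat(3.68, 2.58, 0.2),
        "delay": ParamStat(16.9, 6.6, 5.0),
        "baseline_q": ParamStat(7.6, 2.8, 2.0),
        "baseline_ve": ParamStat(7.5, 1.5, 3.0),
        "pet0": ParamStat(5.1, 0.2, 3.0),
        "gain": ParamStat(GAIN_NONHF_DEFAULT, GAIN_NONHF_DEFAULT * 118.7 / 385.9, 1.0),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout: group sizes, seed, per-group parameter statistics
    and the subcriticality margin applied to drawn gains."""

    n_hf: int = 6
    n_nonhf: int = 6
    seed: int = 0
    hf_stats: dict[str, ParamStat] = field(default_factory=lambda: _default_group_stats(True))
    nonhf_stats: dict[str, ParamStat] = field(default_factory=lambda: _default_group_stats(False))
    stability_margin: float = 0.8

    def __post_init__(self) -> None:
        if self.n_hf < 0 or self.n_nonhf < 0:
            raise InvalidInputError("group sizes must be >= 0")
        for stats_ in (self.hf_stats, self.nonhf_stats):
            for name, st in stats_.items():
                if st.sd < 0:
                    raise InvalidInputError(f"{name}: SD must be >= 0")
        if not (0 < self.stability_margin <= 1):
            raise InvalidInputError("stability_margin must lie in (0, 1]")


_trunc_loc_cache: dict[tuple[float, float, float], float] = {}


def _matched_truncnorm(stat: ParamStat):
    """Floor-truncated normal whose *truncated* mean equals the target.

    Plain truncation at the floor inflates the mean; the underlying
    location is solved so the printed group mean is recovered exactly in
    expectation (the scale stays at the printed SD).
    """
    if stat.sd == 0:
        return None
    key = (stat.mean, stat.sd, stat.floor)
    loc = _trunc_loc_cache.get(key)
    if loc is None:
        def gap(mu: float) -> float:
            a = (stat.floor - mu) / stat.sd
            return stats.truncnorm.mean(a, np.inf, loc=mu, scale=stat.sd) - stat.mean
        loc = float(optimize.brentq(gap, stat.mean - 12 * stat.sd, stat.mean))
        _trunc_loc_cache[key] = loc
    a = (stat.floor - loc) / stat.sd
    return stats.truncnorm(a, np.inf, loc=loc, scale=stat.sd)


def _draw(stat: ParamStat, n: int, rng: np.random.Generator) -> np.ndarray:
    dist = _matched_truncnorm(stat)
    if dist is None:
        return np.full(n, stat.mean)
    return dist.rvs(size=n, random_state=rng)


def generate_cohort(spec: CohortSpec) -> list[VirtualSubject]:
    """Draw a calibrated synthetic cohort.

    Parameters are drawn per group from floor-truncated, mean-matched
    normals around the printed group statistics.  Drawn chemoreflex
    gains are capped at ``stability_margin`` times the subject's linear
    critical gain: subjects whose loop would self-oscillate are excluded
    by construction, mirroring the study's screening exclusion of
    spontaneous periodic breathing.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_hf, rng_non = (np.random.default_rng(child) for child in ss.spawn(2))
    cohort: list[VirtualSubject] = []
    for hf, n, stats_, rng in ((True, spec.n_hf, spec.hf_stats, rng_hf),
                               (False, spec.n_nonhf, spec.nonhf_stats, rng_non)):
        if n == 0:
            continue
        draws = {name: _draw(st, n, rng) for name, st in stats_.items()}
        for i in range(n):
            subj = calibrate(VirtualSubject(
                gain=float(draws["gain"][i]),
                delay=float(draws["delay"][i]),
                baseline_q=float(draws["baseline_q"][i]),
                delta_q=float(draws["delta_q"][i]),
                baseline_ve=float(draws["baseline_ve"][i]),
                set_point=float(draws["pet0"][i]),
                hf=hf,
            ))
            g_cap = spec.stability_margin * critical_gain(subj)
            if subj.gain > g_cap:
                subj = replace(subj, gain=g_cap)
            cohort.append(subj)
    return cohort
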