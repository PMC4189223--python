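# Methods

## The model

The virtual patient is the smallest structure that reproduces the causal
chain observed when cardiac output is alternated by pacemaker in a
human: a step rise in cardiac output, followed by a rise in end-tidal
CO₂, followed — one chemoreflex delay later — by a rise in ventilation.
It has three elements:

1. **Lung CO₂ store.** The alveolar CO₂ fraction `FA` integrates the
   imbalance between what the circulation delivers and what alveolar
   ventilation removes:

   `V_L dFA/dt = V̇A (FI − FA) + s_b Q (Pv − P_B FA)`

   with `V_L` the effective lung gas store (default 3.0 L), `s_b` the
   slope of the blood CO₂ dissociation curve (0.047 L CO₂ · L blood⁻¹ ·
   kPa⁻¹), `Q` cardiac output and `P_B` barometric pressure (101.0 kPa).
   End-tidal CO₂ is the continuous alveolar value, `Pet = P_B·FA`; no
   intra-breath structure is rendered because every analysis in the
   workflow operates on 1 Hz resampled signals.

2. **Tissue CO₂ store.** A single lumped compartment of capacity `C_T`
   (15 L/kPa) charged by metabolic production `V̇CO₂` and discharged into
   the lung by the circulation. Its time constant (`C_T/(s_b·Q)` ≈ 45
   min at rest) makes the mixed-venous pressure `Pv` quasi-static over a
   60 s cycle; it matters for the slow drift under sustained dosing.

3. **Delayed linear chemoreflex.** `V̇E(t) = max(V̇E_floor, V̇E0 +
   G·(Pet(t−τ) − P_set))`, with alveolar ventilation `V̇A = (1−f_D)·V̇E`
   (dead-space fraction `f_D = 0.3`). The delay `τ` lumps circulatory
   transit and neural response, because only the total end-tidal-peak to
   ventilation-peak lag is observable; the simulated lag recovers `τ`
   to within the 1 Hz sampling grid.

**Calibration.** Given a target operating point (`V̇E0`, `Pet0`), the
steady-state alveolar gas equation with zero inspired CO₂ fixes
`V̇CO₂ = (1−f_D)·V̇E0·Pet0/P_B`, and the set point is placed at `Pet0`.
The baseline is then an exact fixed point: mass balance
`V̇A(FA−FI) = V̇CO₂ = s_b·Q·(Pv−P_B·FA)` holds to floating-point
precision, which the tests assert at 10⁻⁹ L/min.

**Driver.** Cardiac output is a square wave: `Q0 + ΔQ` for 30 s,
`Q0 − ΔQ` for 30 s. The default subject uses the cohort-mean printed
hemodynamics (`Q0 = 6.9`, `ΔQ = 2.46`, `V̇E0 = 7.8` L/min,
`Pet0 = 4.84` kPa).

## Choice of chemoreflex gain

The reported group "gain" values (608.4 vs 385.9 L/min/kPa) cannot be
absolute loop gains — at that strength the loop would be violently
unstable — so only their ratio (≈1.58, heart-failure : non-heart-failure)
is used. The absolute defaults are set from a linearised stability
analysis. Linearising around the operating point, the loop transfer is a
first-order lung-store lag (pole `p = (V̇A0 + s_b Q0 P_B)/V_L`) in series
with the delay `e^{−iωτ}`, with DC loop gain
`T0 = (1−f_D)·G·Pet0/(V̇A0 + s_b Q0 P_B)`. The loop must be
*subcritical*: the experimental preparation is a driven oscillator, not
a self-oscillating one (subjects showing spontaneous periodic breathing
at baseline were screened out). For the default heart-failure operating
point the critical gain is ≈12.9 L/min/kPa; the default `G = 7.0` (HF)
gives a gain margin ≈1.8 while keeping the loop resonant enough near the
60 s driving period that the alternation produces a pronounced
oscillation (ventilation CoV ≈ 0.4 for the default subject). The
non-heart-failure default is `7.0/1.58 ≈ 4.44` L/min/kPa.

## Oscillation tracker

Every second the tracker:

1. re-estimates the period by grid search over integer periods
   40–90 s, maximising the variance explained by a single-frequency
   least-squares sinusoid fit (a mean-corrected single-bin periodogram,
   as in Lomb–Scargle) over the trailing 90 s window, then blends the
   winner exponentially with the previous estimate (weight 0.3). A raw
   truncated Fourier coefficient is biased when the window holds a
   non-integer number of cycles — with 1.5 cycles in the window,
   spectral-leakage interference can push off-period bins above the true
   one — which the least-squares formulation removes exactly;
2. computes the quadrature amplitude/phase over the trailing *one
   current period* of mean-subtracted ventilation — the shortest window
   giving an unbiased estimate, and the most responsive, which is what a
   real-time device needs;
3. advances the clock phase by `2π/P` and re-anchors it toward the
   measured coefficient phase with the correction clipped at 0.2 rad/s,
   so the displayed clock never jumps (a hard re-anchor would kink the
   dose profile).

On pure in-band sinusoids the tracker recovers amplitude to <1% and
phase to <6° once valid (asserted in tests). The period estimate carries
a confidence flag: if the best bin explains <25% of the window variance
(as for white noise) it is marked low-confidence. Warm-up is one full
search window (90 s); until then the state is invalid and, fail-safe,
commands no dose.

## Dose law and gas path

With tracked amplitude `A`, period `P` and phase `θ`:

- below the deadband `A_min = 0.5` L/min, no CO₂ is delivered;
- peak commanded fraction `C_pk = min(c_max, kC·A)` with `kC = 0.01` per
  L/min and cylinder cap `c_max = 0.05`;
- window width `W = clamp(w_max·A/A_ref, w_min, w_max)·P` (defaults
  0.15–0.5 of the cycle, `A_ref = 2` L/min), so duration and peak both
  grow with oscillation size;
- within the window the command is `C_pk·(1 − cos 2πs)/2`, `s ∈ [0,1]`,
  zero at both edges;
- the window is centred, *in valve time*, at
  `θ_pk = (θ_target − 2πD/P) mod 2π`, `θ_target = 0` (peak ventilation,
  therapy) or `π` (trough, antiphase control), with `D` the total
  transport delay — the phase lead is applied exactly once.

The proportionality constants `kC`, `A_ref` and the window clamps are
design choices of this package (no published values exist); the defaults
give the default subject's untreated oscillation (A ≈ 4 L/min) a peak
dose of ≈0.04, comfortably under the cap. The transport path is a pure
8.8 s valve→inspired delay (the printed group-mean measurement), a
first-order mixing lag (τ = 1 s, exact exponential update), and a 0.2 s
inspired→alveolar delay (the residual of the printed 9 s total
motor-to-end-tidal delay).

## Protocol, metrics and statistics

`run_arms` executes one continuous timeline — baseline (no alternation),
untreated, in-phase, washout (2 cycles, alternation without dose),
antiphase — so tracker state and CO₂ stores carry over and no dose can
leak into undosed segments (asserted as an exact zero). Each
metric-bearing arm runs 3 settling + 5 measurement cycles; metrics are
computed over the final five *complete* cycles to avoid partial-cycle
bias. The oscillation metric is the coefficient of variation with the
population (divide-by-n) SD — the window is fully observed, not sampled
— making the sinusoid identity CoV = (a/√2)/m exact for tests.
Sinusoidality is the r² of a fixed-period least-squares sine fit; a
constant series reports amplitude 0 and r² = 0 by convention (flagged)
to avoid 0/0. Cohort contrasts use hand-rolled paired t tests (two-sided
p, df = n−1; sidedness is the conservative choice), verified against an
independent reference implementation in the test suite. Identical paired
samples return t = 0, p = 1 (no evidence of a difference); a nonzero
constant difference has zero variance and raises instead.

## Synthetic cohort

The generator draws 6 + 6 subjects (configurable) around the printed
group statistics: alternation amplitude (HF 1.23 ± 0.86, non-HF
3.68 ± 2.58 L/min), chemoreflex delay (22.4 ± 3.1 vs 16.9 ± 6.6 s),
resting cardiac output (4.5 ± 2.1 vs 7.6 ± 2.8 L/min), baseline
ventilation (8.1 ± 1.8 vs 7.5 ± 1.5 L/min) and end-tidal CO₂ (4.6 ± 0.7
vs 5.1 ± 0.2 kPa). Draws are floor-truncated at physiologic minima
(e.g. ΔQ ≥ 0.2 L/min, τ ≥ 5 s); because plain truncation inflates the
mean, the underlying location of each truncated normal is solved so the
*truncated* mean equals the printed mean (scale kept at the printed SD).
A large-sample test confirms group means within 3 standard errors.
Gains are drawn around the group defaults with the printed relative
spread, then capped per subject at 80% of that subject's linear critical
gain — the generator's analogue of the study's screening exclusion of
subjects with spontaneous periodic breathing. One master seed fans out
to per-component streams (`SeedSequence([master, path...])`: 0 = cohort,
(1, i) = subject-i noise), so a whole study is bit-reproducible and
adding a component never perturbs existing streams.

What the generator does **not** emulate: breath-by-breath and
behavioural variability (the noiseless baseline arm has CoV ≈ 0, whereas
real subjects showed ≈0.10 from natural variability — relative
"percent-increase" summaries are therefore suppressed for numerically
zero baselines), inter-subject differences in stores and dead space
(fixed at defaults), measurement noise and drift of the gas analysers,
and apnoeic events (the ventilation floor defaults to 0 but the default
operating points do not reach it). Passing cohort tests therefore
demonstrate the controller logic and the direction and significance of
arm contrasts under the modelled physiology, not the study's numerical
group values, which reflect unmodelled human heterogeneity.

## Numerics

- Fixed-step explicit Euler at `dt = 0.05 s` with ring-buffer delay
  lines for `Pet(t−τ)` and the transport delays. The delays dominate the
  dynamics; the store ODEs are mild (fastest time constant ≈5 s, ≈100×
  the step). Halving `dt` changes the CoV of a fixed driven run by
  <0.1% (asserted <1%).
- `dt` must divide 1 s exactly so the 1 Hz control/recording grid falls
  on integration steps.
- The first-order mixing lag uses the exact exponential update, so the
  63.2% step-response point lands at one time constant irrespective of
  `dt`.
- Degenerate inputs fail loudly and specifically: non-finite or
  non-physical states name the offending quantity; CoV of a
  non-positive-mean window is refused; a tracker fed non-monotone time
  raises; config violations are reported exhaustively with the offending
  key and bound.

## Problem sizes

Default runs used throughout the package and its checks: 10 driver
cycles (600 s) for single-arm period measurements with 3 cycles
discarded as transient; a 34-cycle (2040 s) five-segment protocol per
subject; a 12-subject cohort for the comparison table. These sizes give
fully converged driven oscillations (the transient decays within ~2
cycles at the default gain margin) while keeping a full cohort study
around half a minute on one core.

## Known limitations

- The chemoreflex is linear with a hard floor; real CO₂ responses are
  curvilinear near the apnoeic threshold, so very large driven
  oscillations clip differently than in patients.
- O₂ dynamics, cerebrovascular CO₂ reactivity and sleep-state effects
  are out of scope; so is self-sustained (undriven) periodic breathing —
  the cohort is deliberately subcritical.
- The printed antiphase ventilation CoV appears once as 0.024 and once
  as 0.24; the package asserts only the *direction* (antiphase does not
  attenuate), never either printed value.
- Valve hydraulics, O₂ dilution by the CO₂ mixture and mask dead space
  are not modelled; the transport path is delay + first-order mixing.
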