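import dataclasses

import numpy as np
import pytest

from breathloop.errors import IntegrationError, InvalidInputError
from breathloop.physiology import (CohortSpec, Segment, VirtualSubject,
                                   calibrate, chemoreflex_ve, critical_gain,
                                   default_subject, equilibrium_state,
                                   generate_cohort, qdot_driver, rhs, simulate,
                                   static_loop_gain, step)
from breathloop.signals import coefficient_of_variation
from breathloop.tracker import estimate_period


class TestQdotDriver:
    def test_zero_amplitude_constant(self):
        for t in (0, 17.3, 59.9, 240):
            assert qdot_driver(t, 6.9, 0.0) == 6.9

    def test_printed_group_means(self):
        # Q0 = 6.9, dQ = 2.46: high phase 9.36, low phase 4.44 L/min
        assert qdot_driver(10, 6.9, 2.46) == pytest.approx(9.36)
        assert qdot_driver(40, 6.9, 2.46) == pytest.approx(4.44)

    def test_mean_over_cycle_is_q0(self):
        t = np.arange(0, 60, 0.5)
        vals = [qdot_driver(x, 6.9, 2.46) for x in t]
        assert np.mean(vals) == pytest.approx(6.9)

    def test_invalid_cycle(self):
        with pytest.raises(InvalidInputError):
            qdot_driver(0, 6.9, 2.46, cycle=0)


class TestCalibrate:
    def test_printed_operating_point(self):
        # VE0 = 7.8 L/min, Pet0 = 4.84 kPa, f_D = 0.3, P_B = 101 kPa
        s = calibrate(VirtualSubject(gain=7, delay=22.4, baseline_q=6.9,
                                     delta_q=0, baseline_ve=7.8, set_point=4.84))
        assert s.vco2 == pytest.approx(0.7 * 7.8 * 4.84 / 101)
        assert s.vco2 == pytest.approx(0.2616, abs=5e-4)

    def test_no_deadspace_half_barometric(self):
        s = calibrate(VirtualSubject(gain=5, delay=20, baseline_q=5, delta_q=0,
                                     baseline_ve=2.0, set_point=50.5,
                                     dead_fraction=0.0))
        assert s.vco2 == pytest.approx(1.0)

    def test_closed_loop_equilibrium_holds_600s(self):
        s = default_subject(delta_q=0.0)
        out = simulate(s, "baseline", n_cycles=10)
        assert np.max(np.abs(out.series["petco2_kpa"].values - 4.84)) < 0.01

    def test_out_of_range_targets_rejected(self):
        base = VirtualSubject(gain=7, delay=20, baseline_q=6, delta_q=0,
                              baseline_ve=7, set_point=5)
        with pytest.raises(InvalidInputError):
            calibrate(base, pet0=200.0)
        with pytest.raises(InvalidInputError):
            calibrate(base, baseline_ve=-1.0)


class TestStep:
    def test_fixed_point_at_equilibrium(self):
        s = default_subject()
        st0 = equilibrium_state(s)
        st1 = step(st0, s, 0.0, s.baseline_q, 0.05, st0.Pet)
        assert abs(st1.FA - st0.FA) < 1e-12
        assert abs(st1.Pv - st0.Pv) < 1e-12

    def test_alveolar_gas_equation_at_steady_state(self):
        # VA*(FA - FI) = VCO2 = s_b*Q*(Pv - P_B*FA), each to 1e-9 L/min
        s = default_subject()
        st = equilibrium_state(s)
        va = (1 - s.dead_fraction) * st.VE
        assert va * (st.FA - st.FI) == pytest.approx(s.vco2, abs=1e-9)
        transfer = s.dissociation_slope * st.Q * (st.Pv - s.p_b * st.FA)
        assert transfer == pytest.approx(s.vco2, abs=1e-9)

    def test_euler_step_matches_rhs_oracle(self):
        # independent recomputation of one explicit step from a perturbed state
        s = default_subject()
        st = equilibrium_state(s)
        perturbed = dataclasses.replace(st, FA=st.FA * 1.1, Pv=st.Pv * 0.95)
        dt, fi, q, pet_delayed = 0.1, 0.01, 8.0, 5.2
        ve = chemoreflex_ve(s, pet_delayed)
        dfa, dpv = rhs(perturbed, s, fi, q, ve)
        nxt = step(perturbed, s, fi, q, dt, pet_delayed)
        assert nxt.FA == pytest.approx(perturbed.FA + dfa * dt / 60, abs=1e-15)
        assert nxt.Pv == pytest.approx(perturbed.Pv + dpv * dt / 60, abs=1e-12)

    def test_nonphysical_state_raises(self):
        s = default_subject()
        bad = dataclasses.replace(equilibrium_state(s), FA=0.999)
        with pytest.raises(IntegrationError):
            # massive venous offload pushes FA over 1 within one step
            step(dataclasses.replace(bad, Pv=1e6), s, 0.0, s.baseline_q, 0.2, 5.0)

    def test_dt_bounds_enforced(self):
        s = default_subject()
        st = equilibrium_state(s)
        with pytest.raises(InvalidInputError):
            step(st, s, 0.0, s.baseline_q, 0.5, st.Pet)


class TestSimulate:
    def test_no_driver_all_constant(self, subject):
        s = default_subject(delta_q=0.0)
        out = simulate(s, "untreated", n_cycles=6)
        tail = out.series["ve_lpm"].window(120, 360).values
        assert np.ptp(tail) < 1e-9

    def test_ventilation_lags_pet_by_chemoreflex_delay(self, untreated_run):
        pet = untreated_run.series["petco2_kpa"].window(180, 600).values
        ve = untreated_run.series["ve_lpm"].window(180, 600).values
        petm, vem = pet - pet.mean(), ve - ve.mean()
        lags = np.arange(0, 40)
        cc = [np.corrcoef(petm[: len(petm) - l or None], vem[l:])[0, 1] for l in lags]
        best = lags[int(np.argmax(cc))]
        assert abs(best - 22.4) <= 2.0

    def test_driven_period_equals_driver_cycle(self, untreated_run):
        ve = untreated_run.series["ve_lpm"].window(180, 600)
        est = estimate_period(ve, (40, 90))
        assert est.period == 60.0

    def test_cov_pet_increases_with_alternation_amplitude(self):
        covs = []
        for dq in (1.2, 2.46, 4.9):
            s = default_subject(delta_q=dq)
            out = simulate(s, "untreated", n_cycles=8)
            covs.append(coefficient_of_variation(
                out.series["petco2_kpa"].window(180, 480)))
        assert covs[0] < covs[1] < covs[2]

    def test_state_bounds_hold_throughout(self, untreated_run):
        ve = untreated_run.series["ve_lpm"].values
        fi = untreated_run.series["fico2_frac"].values
        assert np.all(ve >= 0)
        assert np.all((fi >= 0) & (fi < 1))

    def test_integration_converges_under_dt_halving(self):
        s = default_subject()
        covs = []
        for dt in (0.05, 0.025):
            out = simulate(s, "untreated", n_cycles=8, dt=dt)
            covs.append(coefficient_of_variation(
                out.series["petco2_kpa"].window(180, 480)))
        assert abs(covs[1] - covs[0]) / covs[0] < 0.01

    def test_uncalibrated_subject_rejected(self):
        raw = VirtualSubject(gain=7, delay=20, baseline_q=6, delta_q=1,
                             baseline_ve=7, set_point=5)
        with pytest.raises(InvalidInputError):
            simulate(raw, "untreated")

    def test_bad_segment_rejected(self):
        with pytest.raises(InvalidInputError):
            Segment("x", 0, alternate=True)
        with pytest.raises(InvalidInputError):
            Segment("x", 3, alternate=True, dose_mode="both")


class TestGenerateCohort:
    def test_empty_groups(self):
        assert generate_cohort(CohortSpec(n_hf=0, n_nonhf=0)) == []

    def test_fixed_seed_bit_identical(self):
        a = generate_cohort(CohortSpec(seed=77))
        b = generate_cohort(CohortSpec(seed=77))
        assert a == b

    def test_groups_labelled_and_calibrated(self):
        cohort = generate_cohort(CohortSpec(n_hf=3, n_nonhf=4, seed=5))
        assert sum(s.hf for s in cohort) == 3
        assert all(s.calibrated for s in cohort)

    def test_all_subjects_subcritical(self):
        cohort = generate_cohort(CohortSpec(n_hf=30, n_nonhf=30, seed=11))
        for s in cohort:
            assert s.gain <= 0.8 * critical_gain(s) + 1e-9
            assert static_loop_gain(s) > 0

    def test_large_sample_means_match_specification(self):
        # law-of-large-numbers check on the printed-statistics fields
        spec = CohortSpec(n_hf=10_000, n_nonhf=10_000, seed=99)
        cohort = generate_cohort(spec)
        for hf, stats in ((True, spec.hf_stats), (False, spec.nonhf_stats)):
            group = [s for s in cohort if s.hf == hf]
            for attr, key in (("delta_q", "delta_q"), ("delay", "delay"),
                              ("baseline_q", "baseline_q"),
                              ("baseline_ve", "baseline_ve"),
                              ("set_point", "pet0")):
                vals = np.array([getattr(s, attr) for s in group])
                st = stats[key]
                se = st.sd / np.sqrt(len(group))
                assert abs(vals.mean() - st.mean) <= 3 * se, (hf, attr)

    def test_hf_gain_exceeds_nonhf_on_average(self):
        cohort = generate_cohort(CohortSpec(n_hf=200, n_nonhf=200, seed=4))
        g_hf = np.mean([s.gain for s in cohort if s.hf])
        g_non = np.mean([s.gain for s in cohort if not s.hf])
        assert g_hf > g_non
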