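"""Synthetic-study generator: schedules, input functions, noise, cohorts."""

import dataclasses

import numpy as np
import pytest

from psapet.kinetics import TimeActivityCurve, derive_constants
from psapet.synthetic import (DEFAULT_PLASMA_SPEC, CohortSpec, GroupSpec,
                              InjectionEvent, InjectionSchedule, NoiseSpec,
                              add_noise, default_cohort_spec, epilepsy_frames,
                              generate_cohort_tacs, make_cohort,
                              make_plasma_input, make_schedule_fixture,
                              multi_injection_frames,
                              single_injection_schedule, validation_frames)


class TestScheduleFixture:
    def test_three_injections_at_protocol_times(self):
        s = make_schedule_fixture()
        assert len(s) == 3
        assert s.times == (0.0, 42.0, 70.0)

    def test_partial_saturation_coinjection_mass(self):
        assert make_schedule_fixture().events[1].hot_mass == pytest.approx(4.05)

    def test_displacement_is_cold_only(self):
        e = make_schedule_fixture().events[2]
        assert e.hot_mass == 0.0 and e.cold_mass == pytest.approx(330.0)

    def test_event_validation(self):
        with pytest.raises(ValueError):
            InjectionEvent(time=0.0)  # no mass at all
        with pytest.raises(ValueError):
            InjectionEvent(time=0.0, hot_mass=1.0, hot_activity=100.0,
                           specific_activity=500.0)  # inconsistent SA
        with pytest.raises(ValueError):
            InjectionSchedule(events=(InjectionEvent(time=5.0, hot_mass=1.0),))


class TestPlasmaInput:
    def test_zero_before_delay(self):
        plasma = make_plasma_input(DEFAULT_PLASMA_SPEC,
                                   single_injection_schedule(4.5))
        assert plasma.hot(0.0) == 0.0
        assert plasma.hot(DEFAULT_PLASMA_SPEC.delay * 0.99) == 0.0
        assert plasma.hot(1.0) > 0.0

    def test_superposition_across_injections(self):
        from psapet.plasma import AnalyticPlasmaInput
        sched = make_schedule_fixture()
        full = make_plasma_input(DEFAULT_PLASMA_SPEC, sched)
        t = np.linspace(0.0, 90.0, 901)
        spec = DEFAULT_PLASMA_SPEC
        hot_sum = np.zeros_like(t)
        cold_sum = np.zeros_like(t)
        for e in sched.events:
            single = AnalyticPlasmaInput([(e.time, e.hot_mass, e.cold_mass)],
                                         spec.amplitudes, spec.rates,
                                         spec.delay, spec.rise, spec.scale)
            hot_sum += single.hot(t)
            cold_sum += single.cold(t)
        assert np.array_equal(full.hot(t), hot_sum)
        assert np.array_equal(full.cold(t), cold_sum)

    def test_mass_linearity(self):
        a = make_plasma_input(DEFAULT_PLASMA_SPEC, single_injection_schedule(1.0))
        b = make_plasma_input(DEFAULT_PLASMA_SPEC, single_injection_schedule(3.0))
        t = np.linspace(0, 30, 301)
        assert np.allclose(b.hot(t), 3.0 * a.hot(t), rtol=1e-12)


class TestFrames:
    def test_epilepsy_protocol(self):
        start, dur = epilepsy_frames()
        assert len(start) == 14
        assert start[-1] + dur[-1] == pytest.approx(33.0)
        assert np.allclose(dur[:2], 0.5) and np.allclose(dur[2:4], 1.0)

    def test_validation_frames_reach_60min(self):
        start, dur = validation_frames()
        assert start[-1] + dur[-1] == pytest.approx(60.0)

    def test_multi_injection_frames_cover_schedule(self):
        start, dur = multi_injection_frames()
        assert start[0] == 0.0
        assert start[-1] + dur[-1] > 70.0
        assert np.all(np.diff(start) > 0)


class TestNoise:
    def _tac(self, conc=10.0, n=5):
        return TimeActivityCurve(frame_start=np.arange(n, dtype=float),
                                 frame_duration=np.ones(n),
                                 conc=np.full(n, conc))

    def test_zero_scale_is_identity(self):
        tac = self._tac()
        out = add_noise(tac, NoiseSpec(scale=0.0, seed=1))
        assert np.array_equal(out.conc, tac.conc)

    def test_seed_reproducibility(self):
        tac = self._tac()
        a = add_noise(tac, NoiseSpec(scale=0.5, seed=42))
        b = add_noise(tac, NoiseSpec(scale=0.5, seed=42))
        assert np.array_equal(a.conc, b.conc)
        c = add_noise(tac, NoiseSpec(scale=0.5, seed=43))
        assert not np.array_equal(a.conc, c.conc)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(model="poissonish")

    def test_mean_preserved_monte_carlo(self):
        """10 000 noisy replicates of one frame: the sample mean stays within
        3 standard errors of the noise-free value (clipping bias negligible
        at this SNR)."""
        n = 10_000
        conc, dur, scale = 10.0, 3.0, 0.3
        tac = TimeActivityCurve(frame_start=np.arange(n, dtype=float) * 4.0,
                                frame_duration=np.full(n, dur),
                                conc=np.full(n, conc))
        out = add_noise(tac, NoiseSpec(scale=scale, seed=11))
        se = scale * np.sqrt(conc / dur) / np.sqrt(n)
        assert abs(out.conc.mean() - conc) < 3 * se

    def test_negative_frames_floored_and_counted(self):
        tac = TimeActivityCurve(frame_start=[0.0, 1.0], frame_duration=[1.0, 1.0],
                                conc=[0.01, 0.01])
        out = add_noise(tac, NoiseSpec(scale=5.0, seed=0))
        assert np.all(out.conc >= 0)
        assert out.n_clipped >= 1


class TestCohort:
    def test_default_group_sizes(self):
        cohort = make_cohort(default_cohort_spec(), seed=0)
        assert sum(a.group == "control" for a in cohort) == 7
        assert sum(a.group == "epileptic" for a in cohort) == 8

    def test_zero_dispersion_pins_group_mean(self):
        g = GroupSpec(name="control", n=4,
                      b_max={"hippocampus": (20.0, 0.0)},
                      inv_kd_vr={"hippocampus": (0.12, 0.0)})
        spec = CohortSpec(groups=(g,))
        cohort = make_cohort(spec, seed=5)
        for a in cohort:
            p = a.params["hippocampus"]
            assert p.b_max == 20.0
            assert derive_constants(p).inv_kd_vr == pytest.approx(0.12)

    def test_group_means_converge_at_large_n(self):
        spec = default_cohort_spec()
        groups = tuple(dataclasses.replace(g, n=1000) for g in spec.groups)
        cohort = make_cohort(dataclasses.replace(spec, groups=groups), seed=0)
        for name, target in (("control", 19.23), ("epileptic", 14.17)):
            vals = [a.params["hippocampus"].b_max
                    for a in cohort if a.group == name]
            assert np.mean(vals) == pytest.approx(target, rel=0.01)

    def test_seed_determinism(self):
        a = make_cohort(default_cohort_spec(), seed=9)
        b = make_cohort(default_cohort_spec(), seed=9)
        assert all(x.params["hippocampus"] == y.params["hippocampus"]
                   and x.injected_mass == y.injected_mass
                   for x, y in zip(a, b))

    def test_reference_dv_matches_target(self):
        for a in make_cohort(default_cohort_spec(), seed=2):
            p = a.params["hippocampus"]
            assert a.reference.dv == pytest.approx(p.k1 / p.k2, rel=1e-12)

    def test_injected_mass_in_protocol_range(self):
        for a in make_cohort(default_cohort_spec(), seed=3):
            assert 3.6 <= a.injected_mass <= 4.6

    def test_empty_cohort_is_valid(self):
        g = GroupSpec(name="control", n=0, b_max={"hippocampus": (20.0, 1.0)},
                      inv_kd_vr={"hippocampus": (0.12, 0.01)})
        assert make_cohort(CohortSpec(groups=(g,)), seed=0) == []


class TestCohortTacs:
    def test_full_cohort_produces_15_pairs_of_14_frames(self):
        cohort = make_cohort(default_cohort_spec(), seed=1)
        pairs = generate_cohort_tacs(cohort)
        assert len(pairs) == 15
        assert all(len(p.target) == 14 and len(p.reference) == 14
                   for p in pairs)

    def test_composition_matches_direct_simulation(self, row_a):
        """A cohort TAC equals the core simulation framed identically."""
        from psapet.kinetics import (ReferenceParameters, frame_average,
                                     simulate_target_tac)
        from psapet.synthetic import CohortAnimal, make_plasma_input
        animal = CohortAnimal(animal_id="x", group="control",
                              params={"hippocampus": row_a},
                              reference=ReferenceParameters(k1r=row_a.k1,
                                                            k2r=row_a.k2),
                              injected_mass=4.2)
        pair = generate_cohort_tacs([animal])[0]
        plasma = make_plasma_input(DEFAULT_PLASMA_SPEC,
                                   single_injection_schedule(4.2))
        sim = simulate_target_tac(row_a, plasma, np.array([0.0, 33.0]))
        direct = frame_average(sim, epilepsy_frames(), "total")
        assert np.allclose(pair.target.conc, direct.conc, rtol=1e-9)

    def test_noise_free_zero_dose_impossible(self):
        with pytest.raises(ValueError):
            single_injection_schedule(0.0)
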