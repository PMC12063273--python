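"""Generator contracts: latent SDs, schedules, determinism, waveform round trips."""

import copy

import numpy as np
import pytest

from gaitprop import (build_schedule, generate_cohort, load_params,
                      process_cohort, process_waveform_condition, sample_cohort,
                      synthesize_waveforms)
from gaitprop.synthetic_gait import (GeneratorParams, condition_means,
                                     steps_per_leg, synthesize_step_metrics)


@pytest.fixture(scope="module")
def params():
    return load_params()


def _zero_noise(params):
    p = GeneratorParams.from_dict(copy.deepcopy(
        {"stroke": params.stroke, "control": params.control,
         "gait": params.gait, "waveform": params.waveform}))
    for grp in ("stroke", "control"):
        for metric in ("peak", "impulse"):
            mp = p.group(grp)[metric]
            for k in list(mp):
                if k.endswith("_sd") or k.endswith("_cv"):
                    mp[k] = 0.0
            if "share_at_cws" in mp:
                mp["share_at_cws"] = dict(mp["share_at_cws"], sd=0.0)
    p.stroke["cws"] = dict(p.stroke["cws"], sd=0.0)
    p.control["cws"] = dict(p.control["cws"], sd=0.0)
    return p


class TestCohortSampling:
    def test_latent_sd_matches_configuration(self, params):
        """Empirical SD of the symmetry slope latents ~ configured 0.093/0.057."""
        big = copy.deepcopy(params)
        big.stroke["n_participants"] = 10000
        cohort = sample_cohort(big, "stroke", seed=5)
        for metric, sd in (("peak", 0.093), ("impulse", 0.057)):
            devs = np.array([p.latents[metric].slope_dev for p in cohort])
            assert devs.std() == pytest.approx(sd, rel=0.02)
            assert abs(devs.mean()) < 3 * sd / np.sqrt(len(devs))

    def test_zero_sd_gives_zero_latents(self, params):
        cohort = sample_cohort(_zero_noise(params), "stroke", seed=5)
        for p in cohort:
            for metric in ("peak", "impulse"):
                assert p.latents[metric].slope_dev == 0.0
                assert p.latents[metric].total_intercept_dev == 0.0

    def test_same_seed_identical_cohort(self, params):
        a = sample_cohort(params, "stroke", seed=9)
        b = sample_cohort(params, "stroke", seed=9)
        for pa, pb in zip(a, b):
            assert pa.meta == pb.meta
            assert pa.latents == pb.latents


class TestSchedule:
    def test_stroke_schedule_rules(self, params):
        cohort = sample_cohort(params, "stroke", seed=5)
        part = cohort[0]
        part.meta.cws = 0.8
        part.max_speed = 1.0
        sched = build_schedule(part, params, np.random.default_rng(0))
        speeds = sorted(e.belt_speed for e in sched.entries)
        assert speeds == [0.2, 0.4, 0.6, 0.8, 0.9, 1.0]
        for e in sched.entries:
            assert e.duration_s == (180.0 if e.belt_speed <= 0.4 else 120.0)
        assert [e.belt_speed for e in sched.entries if e.is_cws] == [0.8]

    def test_control_has_nine_conditions(self, params):
        cohort = sample_cohort(params, "control", seed=5)
        sched = build_schedule(cohort[0], params, np.random.default_rng(0))
        assert len(sched.entries) == 8  # 7-speed grid + CWS
        assert sum(e.is_cws for e in sched.entries) == 1

    def test_cws_at_floor_gives_single_low_condition(self, params):
        cohort = sample_cohort(params, "stroke", seed=5)
        part = cohort[0]
        part.meta.cws = 0.2
        part.max_speed = 0.4
        sched = build_schedule(part, params, np.random.default_rng(0))
        low = [e for e in sched.entries if e.belt_speed <= part.meta.cws]
        assert len(low) == 1 and low[0].is_cws


class TestStepMetrics:
    def test_zero_noise_steps_on_the_fixed_effect_line(self, params):
        p0 = _zero_noise(params)
        cohort = sample_cohort(p0, "stroke", seed=5)
        part = cohort[0]
        sched = build_schedule(part, p0, np.random.default_rng(0))
        entry = sched.entries[0]
        rec = synthesize_step_metrics(part, entry, p0, np.random.default_rng(1))
        means, _ = condition_means(part, "peak", entry.belt_speed, p0)
        for leg in ("left", "right"):
            peaks = [s.peak for s in rec.steps[leg]]
            assert np.ptp(peaks) == 0.0
            assert peaks[0] == pytest.approx(means[leg])

    def test_step_count_from_cadence_model(self, params):
        # 120 s at speed 1.0 -> cadence 100 steps/min, 105 s usable
        assert steps_per_leg(1.0, 120.0, params) == int(105 * 100 / 60 / 2)

    def test_generated_control_slope_matches_printed_value(self, params):
        """OLS slope of per-leg control peak vs speed ~ 1.73 N/kg per m/s."""
        big = copy.deepcopy(params)
        big.control["n_participants"] = 200
        cohort = generate_cohort(big, "control", seed=6)
        xs, ys = [], []
        for prec in cohort.participants:
            for cond in prec.conditions:
                for leg in ("left", "right"):
                    xs.append(cond.entry.belt_speed)
                    ys.append(cond.truth_means[leg]["peak"])
        slope = np.polyfit(xs, ys, 1)[0]
        assert slope == pytest.approx(1.73, rel=0.02)

    def test_metrics_mode_determinism(self, params):
        a = generate_cohort(params, "stroke", seed=7)
        b = generate_cohort(params, "stroke", seed=7)
        for pa, pb in zip(a.participants, b.participants):
            for ca, cb in zip(pa.conditions, pb.conditions):
                assert [s.peak for s in ca.steps["left"]] == \
                       [s.peak for s in cb.steps["left"]]
                assert [s.impulse for s in ca.steps["right"]] == \
                       [s.impulse for s in cb.steps["right"]]


class TestWaveforms:
    def test_waveform_maximum_equals_target_peak_times_mass(self, params):
        p0 = _zero_noise(params)
        cohort = generate_cohort(p0, "stroke", seed=8)
        prec = cohort.participants[0]
        cond = prec.conditions[0]
        rec, _, truth = synthesize_waveforms(prec.participant, cond, p0)
        mass = prec.participant.meta.body_mass_kg
        for leg, chan in (("left", rec.ap_left), ("right", rec.ap_right)):
            # discrete sampling clips the analytic maximum by < 1e-4 relative
            assert chan.max() == pytest.approx(truth[leg][0].peak * mass, rel=1e-4)

    def test_full_pipeline_recovers_injected_step_metrics(self, params):
        """Trim -> filter -> resample -> events -> metrics within 2 %."""
        from gaitprop import detect_stance_phases, preprocess_condition
        cohort = generate_cohort(params, "stroke", seed=9)
        prec = cohort.participants[2]
        cond = prec.conditions[0]
        rec, markers, truth = synthesize_waveforms(prec.participant, cond, params)
        steps = process_waveform_condition(rec, markers, cond.entry.belt_speed)
        rec_t, markers_t = preprocess_condition(rec, markers)
        phases = detect_stance_phases(markers_t, cond.entry.belt_speed)
        for leg in ("left", "right"):
            got = [s for s in steps if s.leg == leg and s.valid]
            valid_phases = [p for p in phases[leg] if p.valid]
            assert len(got) >= len([t for t in truth[leg] if t.injected]) - 1
            matched = 0
            for phase, s in zip(valid_phases, got):
                ic_time = phase.ic_index / markers_t.fs_marker + 10.0
                near = [t for t in truth[leg] if abs(t.ic_time - ic_time) < 0.05]
                if not near:
                    continue
                matched += 1
                assert s.peak == pytest.approx(near[0].peak, rel=0.02)
                assert s.impulse == pytest.approx(near[0].impulse, rel=0.02)
            assert matched >= len(got) - 1

    def test_end_to_end_table_matches_metrics_mode(self, params):
        """Waveform-route condition means agree with metrics-route within 2 %."""
        small = copy.deepcopy(params)
        small.stroke["n_participants"] = 2
        cohort = generate_cohort(small, "stroke", seed=13)
        t_metrics, _ = process_cohort(cohort)
        t_wave, _ = process_cohort(cohort, small, mode="waveforms")
        key = ["participant_id", "condition_id", "leg"]
        m = t_metrics.set_index(key).sort_index()
        w = t_wave.set_index(key).sort_index()
        assert len(m) == len(w)
        for col in ("peak", "impulse"):
            rel = np.abs(w[col] - m[col]) / m[col]
            assert rel.max() < 0.02

    def test_injected_crossover_count_matches(self, params):
        p = copy.deepcopy(params)
        p.gait["crossover_rate"] = 0.1
        cohort = generate_cohort(p, "stroke", seed=11)
        prec = cohort.participants[0]
        cond = prec.conditions[0]
        injected = sum(not s.valid for leg in ("left", "right")
                       for s in cond.steps[leg])
        assert injected > 0
        flagged = sum(s.reason == "crossover" for leg in ("left", "right")
                      for s in cond.steps[leg])
        assert flagged == injected
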