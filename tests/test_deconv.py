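"""Online deconvolution loop: detection, back-projection, scale fitting."""

import numpy as np
import pandas as pd
import pytest

from pupildeconv import (
    DeconvConfig,
    DeconvState,
    EventLog,
    ImpulseResponseParams,
    OnlinePupilDeconvolver,
    PulseList,
    choose_baseline,
    impulse_response,
    make_pulse_recording,
    model_error,
    reconstruct_trace,
    run,
    strongest_pulse_offsets,
)

from conftest import make_recording


class TestChooseBaseline:
    def test_never_exceeds_flat_diameter(self, flat_recording):
        cfg = DeconvConfig()
        assert choose_baseline(flat_recording, cfg) <= 3.0

    def test_fixed_value_below_minimum_accepted(self):
        rec = make_recording(np.full(300, 2.8))
        cfg = DeconvConfig(baseline_mode="fixed", baseline_value=2.5)
        assert choose_baseline(rec, cfg) == 2.5

    def test_percentile_mode_matches_percentile_then_clamp_oracle(self, rng):
        d = 3.0 + 0.3 * rng.random(2000)
        rec = make_recording(d)
        cfg = DeconvConfig(baseline_percentile=5.0)
        oracle = min(np.percentile(d, 5.0), d.min())
        assert choose_baseline(rec, cfg) == pytest.approx(oracle, abs=1e-12)


class TestOnlineLoop:
    def test_flat_noiseless_trace_yields_no_pulses(self, flat_recording):
        res = run(flat_recording)
        assert len(res.pulses) == 0
        np.testing.assert_allclose(res.modeled.diameter, res.baseline, atol=1e-12)

    def test_insertion_back_projected_500ms_before_detection(self):
        # literal single-frame rule: residual first crosses threshold at
        # t = 10.0 s -> the new pulse is proposed at 9.5 s
        n = 900
        d = np.full(n, 4.0)
        d[600:] = 4.2  # step exactly at frame 600 = 10.0 s
        rec = make_recording(d)
        cfg = DeconvConfig(persistence_frames=1, refine_onset=False,
                           baseline_mode="fixed", baseline_value=4.0,
                           warmup_s=0.5)
        res = run(rec, cfg)
        assert res.insertions["t_detect_s"].iloc[0] == pytest.approx(10.0)
        assert res.insertions["proposed_onset_s"].iloc[0] == pytest.approx(9.5)
        assert res.pulses.onsets[0] == pytest.approx(9.5)

    def test_persistent_residual_insertions_respect_refractory(self):
        # a steep staircase keeps the residual super-threshold; insertions
        # must still be spaced by at least the refractory period
        n = 1200
        d = np.full(n, 4.0)
        d[240:] += np.linspace(0, 3.0, n - 240)
        rec = make_recording(d)
        cfg = DeconvConfig(persistence_frames=1, refine_onset=False,
                           refractory_s=0.1)
        res = run(rec, cfg)
        detect = res.insertions["t_detect_s"].to_numpy()
        assert len(detect) >= 3
        assert np.all(np.diff(detect) >= 0.1 - 1e-9)

    def test_single_pulse_noiseless_scale_recovered(self):
        rec = make_pulse_recording([3.0], [0.35], 8.0, noise_sd_mm=0.0)
        res = run(rec)
        assert len(res.pulses) == 1
        assert res.pulses.onsets[0] == pytest.approx(3.0, abs=1 / 60.0)
        assert res.pulses.scales[0] == pytest.approx(0.35, abs=1e-6)

    def test_observed_at_baseline_gives_zero_scales(self, flat_recording):
        # NNLS at the boundary: nothing to explain, nothing fitted
        res = run(flat_recording)
        assert res.pulses.scales.size == 0

    def test_two_separated_pulses_match_independent_fits(self):
        rec = make_pulse_recording([2.0, 8.0], [0.3, 0.5], 14.0, noise_sd_mm=0.0)
        res = run(rec)
        solo_a = run(make_pulse_recording([2.0], [0.3], 14.0, noise_sd_mm=0.0))
        solo_b = run(make_pulse_recording([8.0], [0.5], 14.0, noise_sd_mm=0.0))
        assert len(res.pulses) == 2
        assert res.pulses.scales[0] == pytest.approx(solo_a.pulses.scales[0],
                                                     abs=1e-6)
        assert res.pulses.scales[1] == pytest.approx(solo_b.pulses.scales[0],
                                                     abs=1e-6)

    def test_rerun_is_bit_identical(self):
        rec = make_pulse_recording([2.0, 5.0], [0.3, 0.4], 9.0, seed=3)
        a, b = run(rec), run(rec)
        np.testing.assert_array_equal(a.pulses.onsets, b.pulses.onsets)
        np.testing.assert_array_equal(a.pulses.scales, b.pulses.scales)
        np.testing.assert_array_equal(a.modeled.diameter, b.modeled.diameter)
        np.testing.assert_array_equal(a.residuals, b.residuals)

    def test_modeled_trace_consistent_with_offline_reconstruction(self):
        rec = make_pulse_recording([2.0, 4.5, 7.0], [0.3, 0.45, 0.2], 12.0, seed=1)
        res = run(rec)
        offline = reconstruct_trace(res.pulses, rec.time, res.irf_params,
                                    res.baseline)
        np.testing.assert_allclose(res.modeled.diameter, offline.diameter,
                                   atol=1e-9)

    def test_raising_threshold_never_adds_pulses(self):
        rec = make_pulse_recording([2.0, 5.0, 8.0], [0.25, 0.4, 0.3], 12.0, seed=9)
        counts = [len(run(rec, DeconvConfig(residual_threshold_frac=f)).pulses)
                  for f in (0.001, 0.0025, 0.01, 0.05)]
        assert counts == sorted(counts, reverse=True)

    def test_scale_optimisation_never_increases_windowed_error(self):
        rec = make_pulse_recording([2.0], [0.4], 6.0, seed=5)
        state = DeconvState(t0=0.0, dt=1 / 60.0, baseline=4.0, reference_mm=4.0)
        for z in rec.diameter:
            state.step(float(z))
        w0, w1 = state._window()
        before = model_error(state.modeled[w0:w1], state.observed[w0:w1])
        state.optimize_scales()
        after = model_error(state.modeled[w0:w1], state.observed[w0:w1])
        assert after <= before + 1e-12


class TestOnlineContract:
    def test_out_of_order_sample_rejected(self):
        state = DeconvState(t0=0.0, dt=1 / 60.0, baseline=3.0, reference_mm=3.0)
        state.push(0.0, 3.0)
        state.push(1 / 60.0, 3.0)
        with pytest.raises(ValueError, match="out-of-order"):
            state.push(0.5 / 60.0, 3.0)

    def test_streaming_push_matches_batch_run(self):
        rec = make_pulse_recording([2.0], [0.4], 6.0, seed=2)
        batch = run(rec)
        state = DeconvState(t0=float(rec.time[0]), dt=rec.dt,
                            baseline=choose_baseline(rec, batch.config),
                            reference_mm=batch.reference_mm,
                            config=batch.config, n_hint=16)  # force growth path
        for t, z in zip(rec.time, rec.diameter):
            state.push(float(t), float(z))
        res = state.finalize()
        np.testing.assert_array_equal(res.pulses.onsets, batch.pulses.onsets)
        np.testing.assert_array_equal(res.pulses.scales, batch.pulses.scales)


class TestStrongestPulseOffsets:
    def _events(self, onsets):
        rows = []
        for i, t in enumerate(onsets):
            rows.append({"trial_id": i, "event": "memory_array", "onset_s": t,
                         "vwm_load": "low" if i % 2 == 0 else "high"})
            rows.append({"trial_id": i, "event": "response", "onset_s": t + 1.5,
                         "vwm_load": "low" if i % 2 == 0 else "high",
                         "correct": True, "rt_s": 0.5})
        return EventLog(pd.DataFrame(rows), condition_cols=["vwm_load"])

    def test_pulse_exactly_at_onsets_gives_zero_offset(self):
        onsets = [2.0, 6.0, 10.0, 14.0]
        pulses = PulseList.from_arrays(onsets, [0.3] * 4)
        tab = strongest_pulse_offsets(pulses, self._events(onsets))
        assert np.allclose(tab["mean_offset_s"], 0.0)

    def test_pulses_100ms_after_onsets(self):
        onsets = [2.0, 6.0, 10.0, 14.0]
        pulses = PulseList.from_arrays([t + 0.1 for t in onsets], [0.3] * 4)
        tab = strongest_pulse_offsets(pulses, self._events(onsets))
        assert np.allclose(tab["mean_offset_s"], 0.1)

    def test_matches_brute_force_scan(self, rng):
        onsets = [2.0, 6.0, 10.0, 14.0]
        events = self._events(onsets)
        p_on = rng.uniform(0, 16, 30)
        p_sc = rng.uniform(0, 1, 30)
        pulses = PulseList.from_arrays(p_on, p_sc)
        tab = strongest_pulse_offsets(pulses, events, window_s=1.0)
        # exhaustive per-event max over pulses, then per-condition average
        expected = {}
        for i, t in enumerate(onsets):
            cand = [(s, o) for o, s in zip(pulses.onsets, pulses.scales)
                    if abs(o - t) <= 1.0]
            cond = "low" if i % 2 == 0 else "high"
            if cand:
                s, o = max(cand)
                expected.setdefault(cond, []).append(o - t)
        for _, row in tab.iterrows():
            exp = np.mean(expected[row["vwm_load"]])
            assert row["mean_offset_s"] == pytest.approx(exp, abs=1e-12)

    def test_event_without_pulse_is_skipped_and_counted(self):
        onsets = [2.0, 6.0]
        pulses = PulseList.from_arrays([2.0], [0.3])
        tab = strongest_pulse_offsets(pulses, self._events(onsets))
        assert int(tab["n_skipped"].sum()) == 1


class TestEstimatorInterface:
    def test_fit_exposes_fitted_attributes(self):
        rec = make_pulse_recording([2.0], [0.4], 6.0, seed=1)
        est = OnlinePupilDeconvolver().fit(rec)
        assert len(est.pulses_) == 1
        assert est.modeled_.diameter.shape == rec.diameter.shape
        # effective static level sits at the quiet tonic diameter
        assert est.baseline_ == pytest.approx(4.0, abs=0.02)

    def test_get_set_params_round_trip(self):
        est = OnlinePupilDeconvolver(residual_threshold_frac=0.005)
        params = est.get_params()
        assert params["residual_threshold_frac"] == 0.005
        est.set_params(back_offset_s=0.4)
        assert est._config().back_offset_s == 0.4
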