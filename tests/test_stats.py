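"""Mixed-model scanning, feature extraction, classification, behaviour."""

import numpy as np
import pandas as pd
import pytest

from pupildeconv import (
    EpochSet,
    TrialClassifier,
    classify_trials,
    cowans_k,
    extract_features,
    impulse_response,
    inverse_efficiency,
    lme_scan,
    rt_filter,
    simulate_epoch_cohort,
)


class TestLmeScan:
    def test_injected_effect_found(self):
        es = simulate_epoch_cohort(n_participants=8, trials_per_level=12,
                                   epoch_len_s=1.0, effect_mm=0.3,
                                   effect_window=(0.3, 0.7), noise_sd_mm=0.05,
                                   participant_slope_sd_mm=0.03, seed=5)
        runs, table = lme_scan(es, ["load"])
        assert len(runs) == 1
        assert runs[0].start_s == pytest.approx(0.3, abs=0.05)
        assert runs[0].end_s == pytest.approx(0.7, abs=0.05)

    def test_sign_flips_when_condition_labels_swapped(self):
        # well-conditioned random effects (interior REML optimum) so the
        # label swap is an exact reparametrisation of the same model
        es = simulate_epoch_cohort(n_participants=10, trials_per_level=12,
                                   epoch_len_s=0.4, effect_mm=0.2,
                                   effect_window=(0.0, 0.4), noise_sd_mm=0.05,
                                   participant_intercept_sd_mm=0.1,
                                   participant_slope_sd_mm=0.1, seed=8)
        _, table = lme_scan(es, ["load"])
        swapped = EpochSet(times=es.times, data=es.data,
                           meta=es.meta.assign(
                               load=es.meta["load"].map(
                                   {"low": "high", "high": "low"})))
        _, table_sw = lme_scan(swapped, ["load"])
        np.testing.assert_allclose(table_sw["load"], -table["load"],
                                   rtol=1e-3, atol=1e-3)

    def test_brief_effect_suppressed_by_duration_rule(self):
        # a 150-ms effect is shorter than the 200-ms minimum run duration
        es = simulate_epoch_cohort(n_participants=8, trials_per_level=12,
                                   epoch_len_s=1.0, effect_mm=0.4,
                                   effect_window=(0.4, 0.55), noise_sd_mm=0.05,
                                   seed=6)
        runs, _ = lme_scan(es, ["load"])
        assert runs == []

    def test_interaction_term_detects_crossover(self):
        # effect present only when both factors are high
        rng = np.random.default_rng(7)
        times = np.arange(30) / 60.0
        data, meta = [], []
        for p in range(8):
            for a in ("low", "high"):
                for b in ("low", "high"):
                    for _ in range(8):
                        tr = rng.normal(0, 0.05, times.size)
                        if a == "high" and b == "high":
                            tr += 0.4
                        data.append(tr)
                        meta.append({"participant": p, "f1": a, "f2": b})
        es = EpochSet(times=times, data=np.vstack(data), meta=pd.DataFrame(meta))
        runs, _ = lme_scan(es, ["f1", "f2"])
        assert any(r.factor == "f1:f2" for r in runs)

    def test_requires_participants_and_two_levels(self):
        es = simulate_epoch_cohort(n_participants=1, trials_per_level=5,
                                   epoch_len_s=0.3, seed=1)
        with pytest.raises(ValueError):
            lme_scan(es, ["load"])


class TestExtractFeatures:
    def _epoch_set(self, data, times):
        n = np.atleast_2d(data).shape[0]
        return EpochSet(times=times, data=np.atleast_2d(data),
                        meta=pd.DataFrame({"trial_id": range(n)}))

    def test_kernel_epoch_peaks_at_onset_plus_t_max(self):
        times = np.arange(0, 4.0, 1 / 60.0)
        epoch = 0.3 * impulse_response(times - 1.0)
        es = self._epoch_set(epoch, times)
        f = extract_features(es, {"w": (0.5, 3.5)})
        assert f["w_max_dil"].item() == pytest.approx(0.3, rel=1e-3)
        # grid-rounded analytic peak latency: onset + 0.93 s
        assert f["w_dil_lat_s"].item() == pytest.approx(1.93, abs=1 / 60.0)

    def test_constant_zero_epoch_ties_break_to_window_start(self):
        times = np.arange(0, 2.0, 1 / 60.0)
        es = self._epoch_set(np.zeros_like(times), times)
        f = extract_features(es, {"w": (0.5, 1.5)})
        assert f["w_max_dil"].item() == 0.0
        assert f["w_max_con"].item() == 0.0
        assert f["w_dil_lat_s"].item() == pytest.approx(0.5, abs=1 / 60.0)
        assert f["w_con_lat_s"].item() == pytest.approx(0.5, abs=1 / 60.0)

    def test_pure_constriction_triangle(self):
        times = np.arange(0, 2.0, 1 / 60.0)
        apex = 1.0
        tri = -0.2 * np.clip(1 - np.abs(times - apex) / 0.5, 0, None)
        es = self._epoch_set(tri, times)
        f = extract_features(es, {"w": (0.0, 1.9)})
        assert f["w_max_con"].item() == pytest.approx(-0.2, abs=1e-9)
        assert f["w_con_lat_s"].item() == pytest.approx(apex, abs=1 / 60.0)

    def test_latency_tracks_time_axis_shift(self):
        times = np.arange(0, 2.0, 1 / 60.0)
        epoch = impulse_response(times - 0.2)
        for shift in (0.0, -0.5):
            es = self._epoch_set(epoch, times + shift)
            f = extract_features(es, {"w": (0.0 + shift, 1.9 + shift)})
            assert f["w_dil_lat_s"].item() == pytest.approx(
                0.2 + 0.93 + shift, abs=1.5 / 60.0)

    def test_window_outside_epoch_named_in_error(self):
        times = np.arange(0, 1.0, 1 / 60.0)
        es = self._epoch_set(np.zeros_like(times), times)
        with pytest.raises(ValueError, match="probe"):
            extract_features(es, {"probe": (0.5, 3.0)})


def gaussian_features(n_participants=6, n_trials=40, d_prime=4.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        for i in range(n_trials):
            label = "high" if i % 2 else "low"
            mu = d_prime / 2 if label == "high" else -d_prime / 2
            rows.append({"participant": p, "label": label,
                         "x1": rng.normal(mu, 1), "x2": rng.normal(0, 1)})
    return pd.DataFrame(rows)


class TestClassifyTrials:
    def test_separated_gaussians_classified_near_perfectly(self):
        f = gaussian_features(d_prime=4.0)
        res = classify_trials(f, "label", ["x1", "x2"], seed=1)
        assert res.mean_accuracy >= 0.95
        assert res.mean_auc_insample >= 0.99

    def test_constant_feature_gives_majority_rate(self):
        rng = np.random.default_rng(3)
        n = 50
        labels = np.array(["a"] * 30 + ["b"] * 20)
        f = pd.DataFrame({"participant": 0, "label": labels,
                          "x1": np.ones(n)})
        res = classify_trials(f, "label", ["x1"], seed=0)
        assert res.mean_accuracy == pytest.approx(0.6, abs=0.02)

    def test_auc_invariant_under_monotone_feature_transform(self):
        f = gaussian_features(d_prime=1.5, seed=2)
        res_a = classify_trials(f, "label", ["x1"], seed=0)
        g = f.assign(x1=np.exp(f["x1"] / 2))
        res_b = classify_trials(g, "label", ["x1"], seed=0)
        per_a = res_a.per_participant.set_index("participant")["auc_insample"]
        per_b = res_b.per_participant.set_index("participant")["auc_insample"]
        np.testing.assert_allclose(per_a, per_b, atol=1e-9)

    def test_single_class_participant_excluded(self):
        f = gaussian_features(n_participants=3)
        f.loc[f["participant"] == 2, "label"] = "low"
        res = classify_trials(f, "label", ["x1", "x2"])
        assert res.excluded_participants == [2]
        assert len(res.per_participant) == 2

    def test_estimator_wrapper(self):
        f = gaussian_features(d_prime=3.0)
        clf = TrialClassifier(seed=0).fit(
            f[["x1", "x2"]].to_numpy(), f["label"].to_numpy(),
            participant=f["participant"].to_numpy())
        assert clf.mean_accuracy_ >= 0.9
        preds = clf.predict(f[["x1", "x2"]].to_numpy())
        assert set(preds) <= {"low", "high"}


class TestBehaviouralIndices:
    @pytest.mark.parametrize("n,hit,fa,expected", [
        (4, 1.0, 0.0, 4.0),
        (4, 0.6, 0.6, 0.0),
        (6, 0.5, 0.5, 0.0),
        (4, 0.8, 0.3, 2.0),
    ])
    def test_cowans_k_formula(self, n, hit, fa, expected):
        assert cowans_k(n, hit, fa) == pytest.approx(expected, abs=1e-12)

    def test_cowans_k_rejects_bad_rates(self):
        with pytest.raises(ValueError):
            cowans_k(4, 1.2, 0.0)

    @pytest.mark.parametrize("rt,acc,expected", [
        (800.0, 1.0, 800.0),
        (1000.0, 0.8, 1250.0),
    ])
    def test_inverse_efficiency_formula(self, rt, acc, expected):
        assert inverse_efficiency(rt, acc) == pytest.approx(expected, abs=1e-12)

    def test_inverse_efficiency_halved_accuracy_doubles(self):
        assert inverse_efficiency(900.0, 0.4) == pytest.approx(
            2 * inverse_efficiency(900.0, 0.8))

    def test_inverse_efficiency_undefined_at_zero(self):
        with pytest.raises(ValueError):
            inverse_efficiency(500.0, 0.0)

    def test_rt_filter_bounds_and_counts(self):
        trials = pd.DataFrame({"rt_s": [0.1, 0.19, 0.2, 0.5, 1.0, 2.5, 3.0]})
        kept = rt_filter(trials)
        assert list(kept["rt_s"]) == [0.2, 0.5, 1.0, 2.5]
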