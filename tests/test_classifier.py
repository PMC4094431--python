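"""Fisher selection, LDA, LooCV window choice and auto-calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import erdbci as e
from erdbci.classifier import _calibrate_pair
from conftest import FS, make_trial_store


class TestFisherScore:
    def test_identical_groups_score_zero(self, rng):
        x = rng.standard_normal(20)
        assert e.fisher_score(x, x) == 0.0

    def test_textbook_value(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal(100000)
        b = rng.standard_normal(100000) + 1.0
        # means 0 and 1, unit variances -> 1 / (1 + 1) = 0.5
        assert e.fisher_score(a, b) == pytest.approx(0.5, abs=0.02)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_direct_formula(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.standard_normal(9), 2 * r.standard_normal(13) + r.uniform(-2, 2)
        expected = (a.mean() - b.mean()) ** 2 / (a.var(ddof=1) + b.var(ddof=1))
        assert e.fisher_score(a, b) == pytest.approx(expected, abs=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            e.fisher_score([1.0], [0.0, 1.0])


class TestTrainLDA:
    def test_symmetric_boundary_at_zero(self, rng):
        x = np.concatenate([rng.standard_normal(500) - 1, rng.standard_normal(500) + 1])
        y = np.array(["nc"] * 500 + ["mi"] * 500)
        w, b = e.train_lda(x, y, "mi")
        assert -b / w == pytest.approx(0.0, abs=0.1)

    def test_matches_closed_form(self, rng):
        x = np.concatenate([2 * rng.standard_normal(40) + 1, 2 * rng.standard_normal(60) + 3])
        y = np.array(["nc"] * 40 + ["mi"] * 60)
        w, b = e.train_lda(x, y, "mi")
        pooled = (40 * x[:40].var() + 60 * x[40:].var()) / 100
        assert w == pytest.approx((x[40:].mean() - x[:40].mean()) / pooled, abs=1e-12)

    def test_duplicating_data_changes_nothing(self, rng):
        x = rng.standard_normal(30)
        y = np.array(["nc"] * 15 + ["mi"] * 15)
        w1, b1 = e.train_lda(x, y, "mi")
        w2, b2 = e.train_lda(np.tile(x, 2), np.tile(y, 2), "mi")
        assert (w1, b1) == pytest.approx((w2, b2))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            e.train_lda(np.arange(4.0), np.array(["mi"] * 4), "mi")


def synthetic_tracks(rng, n_per_class, separated_windows, sep=3.0, n_samples=1024):
    """Per-trial feature tracks over [3,7) whose classes separate only in
    the given 0.5 s windows."""
    tracks, labels = [], []
    for cls in ("nc", "mi"):
        for _ in range(n_per_class):
            x = rng.standard_normal(n_samples)
            if cls == "mi":
                for w in separated_windows:
                    x[w * 128 : (w + 1) * 128] += sep
            tracks.append(x)
            labels.append(cls)
    return tracks, np.array(labels)


class TestLoocvWindowSelect:
    def test_avoids_windows_without_separability(self, rng):
        """Classes separating only from 4.5 s onward (windows 3-7): the
        selection must land in the separating half, never in windows 0-2.
        (A single separating 0.5 s window is invisible to the median of the
        4 s curve, so sustained separability is the recoverable case.)"""
        tracks, labels = synthetic_tracks(rng, 10, separated_windows=range(3, 8))
        window, curves = e.loocv_window_select(tracks, labels, FS, positive_label="mi")
        assert window in range(3, 8)
        assert curves.shape == (8, 1024)
        assert np.median(curves[window]) > 0.75

    def test_everywhere_separable_ties_to_window_zero(self, rng):
        tracks, labels = synthetic_tracks(rng, 8, separated_windows=range(8), sep=10.0)
        window, curves = e.loocv_window_select(tracks, labels, FS, positive_label="mi")
        assert window == 0
        assert np.median(curves[0]) == pytest.approx(1.0, abs=0.02)

    def test_shuffled_labels_near_chance(self, rng):
        tracks, labels = synthetic_tracks(rng, 10, separated_windows=[4])
        shuffled = rng.permutation(labels)
        while np.unique(shuffled, return_counts=True)[1].min() < 5:
            shuffled = rng.permutation(labels)
        _, curves = e.loocv_window_select(tracks, shuffled, FS, positive_label="mi")
        assert np.median(np.median(curves, axis=1)) == pytest.approx(0.5, abs=0.15)

    def test_matches_bruteforce_oracle(self, rng):
        """Independent re-implementation: explicit fold loop, explicit window
        means, explicit LDA formula."""
        tracks, labels = synthetic_tracks(rng, 6, separated_windows=[2], sep=1.0)
        window, curves = e.loocv_window_select(tracks, labels, FS, positive_label="mi")
        n = len(tracks)
        oracle = np.zeros((8, 1024))
        for w in range(8):
            for i in range(n):
                tr = [tracks[j] for j in range(n) if j != i]
                lb = np.array([labels[j] for j in range(n) if j != i])
                means = np.array([t[w * 128 : (w + 1) * 128].mean() for t in tr])
                mi, nc = means[lb == "mi"], means[lb == "nc"]
                s2 = (len(mi) * mi.var() + len(nc) * nc.var()) / len(means)
                ww = (mi.mean() - nc.mean()) / max(s2, 1e-12)
                bb = -ww * (mi.mean() + nc.mean()) / 2
                pred_mi = ww * np.asarray(tracks[i]) + bb > 0
                oracle[w] += pred_mi == (labels[i] == "mi")
        oracle /= n
        np.testing.assert_allclose(curves, oracle, atol=1e-12)
        assert window == int(np.argmax(np.median(oracle, axis=1)))


class TestCalibration:
    def test_first_model_exactly_at_nine_clean_tpc(self):
        user = e.SimUser(e.preset("strong"), seed=11)
        store = e.TrialStore(e.BandPowerConfig().feature_ids)
        donor = make_trial_store(user, 9)
        all_trials = [t for lbl in donor.trials for t in donor.trials[lbl]]
        order = np.random.default_rng(0).permutation(len(all_trials))
        for idx in order:
            store.add(all_trials[idx])
            model = e.calibrate(store)
            counts = [store.count(lbl) for lbl in (e.NON_CONTROL, e.LEFT, e.RIGHT)]
            if min(counts) >= 9:
                assert model is not None
                break
            assert model is None
        else:
            pytest.fail("never reached nine clean trials per class")

    def test_recalibration_needs_five_new_tpc(self):
        user = e.SimUser(e.preset("strong"), seed=12)
        store = make_trial_store(user, 9)
        model = e.calibrate(store)
        assert model is not None and model.calib_count == 1
        extra = make_trial_store(
            e.SimUser(e.preset("strong"), seed=13), 5, labels=(e.NON_CONTROL, model.selected_class)
        )
        # interleave classes; after the 4th pair no recalibration, after the 5th yes
        nc = extra.trials[e.NON_CONTROL]
        mi = extra.trials[model.selected_class]
        for k in range(4):
            store.add(nc[k]); store.add(mi[k])
            assert e.calibrate(store, previous=model) is None
        store.add(nc[4]); store.add(mi[4])
        model2 = e.calibrate(store, previous=model)
        assert model2 is not None and model2.calib_count == 2

    def test_calibration_is_deterministic(self):
        s1 = make_trial_store(e.SimUser(e.preset("strong"), seed=21), 9)
        s2 = make_trial_store(e.SimUser(e.preset("strong"), seed=21), 9)
        m1, m2 = e.calibrate(s1), e.calibrate(s2)
        assert m1.to_json() == m2.to_json()

    def test_selects_hand_with_planted_erd(self):
        hits = 0
        for seed in range(30, 40):
            store = make_trial_store(e.SimUser(e.preset("strong"), seed), 9)
            if e.select_control_class(store) == e.RIGHT:
                hits += 1
        assert hits >= 9

    def test_symmetric_user_selection_never_fails(self):
        params = e.SimUserParams(
            erd_depth={
                e.RIGHT: {("C3", "mu"): 0.4},
                e.LEFT: {("C4", "mu"): 0.4},
            }
        )
        store = make_trial_store(e.SimUser(params, seed=5), 9)
        assert e.select_control_class(store) in (e.LEFT, e.RIGHT)


class TestApplyAndBias:
    def test_class_means_map_to_plus_minus_one(self):
        store = make_trial_store(e.SimUser(e.preset("strong"), seed=41), 9)
        model = _calibrate_pair(store, e.RIGHT, FS, fit_ar_model=False)
        # reconstruct the training window means of the kept trials
        kept_feats = {lbl: [] for lbl in (e.RIGHT, e.NON_CONTROL)}
        trials = store.trials[e.RIGHT] + store.trials[e.NON_CONTROL]
        labels = np.array([t.label for t in trials])
        feats = np.stack([t.feature_means for t in trials])
        kept, _ = e.reject_feature_outliers(feats, labels)
        j = e.BandPowerConfig().feature_ids.index(model.feature_id)
        w0, w1 = model.train_window * 128, (model.train_window + 1) * 128
        for i in kept:
            kept_feats[trials[i].label].append(trials[i].feature_track[w0:w1, j].mean())
        out_mi, _ = model.apply(np.mean(kept_feats[e.RIGHT]))
        out_nc, _ = model.apply(np.mean(kept_feats[e.NON_CONTROL]))
        assert out_mi == pytest.approx(1.0, abs=1e-9)
        assert out_nc == pytest.approx(-1.0, abs=1e-9)
        mid, _ = model.apply((np.mean(kept_feats[e.RIGHT]) + np.mean(kept_feats[e.NON_CONTROL])) / 2)
        assert mid == pytest.approx(0.0, abs=1e-9)

    def _nc_track(self, model, rng, shift=0.0, seconds=40):
        # feature values whose outputs are standard normal around -1 + shift
        target = (np.array([-1.0 + shift]) - model.out_shift) / model.out_scale
        x = (target - model.bias) / model.weight + (0.3 / abs(model.weight)) * rng.standard_normal(
            seconds * FS
        )
        ids = e.BandPowerConfig().feature_ids
        j = ids.index(model.feature_id)
        values = np.zeros((seconds * FS, 6))
        values[:, j] = x
        return e.FeatureTrack(values, ids, FS)

    def test_bias_adaptation_caps_false_positive_rate(self, strong_model, rng):
        track = self._nc_track(strong_model, rng)
        adapted = e.adapt_bias(strong_model, track)
        out, _ = adapted.apply(track)
        assert np.mean(out > 0.5) <= 0.1
        assert adapted.weight == strong_model.weight

    def test_uniform_output_drift_shifts_bias_equally(self, strong_model, rng):
        base = self._nc_track(strong_model, rng)
        m0 = e.adapt_bias(strong_model, base)
        drift = e.FeatureTrack(
            base.values + 0.5 / (strong_model.out_scale * strong_model.weight),
            base.feature_ids,
            FS,
        )
        m1 = e.adapt_bias(strong_model, drift)
        assert m1.out_shift - m0.out_shift == pytest.approx(-0.5, abs=1e-6)

    def test_adaptation_is_idempotent(self, strong_model, rng):
        track = self._nc_track(strong_model, rng)
        once = e.adapt_bias(strong_model, track)
        twice = e.adapt_bias(once, track)
        assert twice.out_shift == pytest.approx(once.out_shift, abs=1e-9)

    def test_short_run_rejected(self, strong_model, rng):
        with pytest.raises(ValueError, match="30 s"):
            e.adapt_bias(strong_model, self._nc_track(strong_model, rng, seconds=20))

    def test_model_json_roundtrip(self, strong_model):
        clone = e.ClassifierModel.from_json(strong_model.to_json())
        assert clone.to_json() == strong_model.to_json()
        assert clone.feature_id == strong_model.feature_id
        np.testing.assert_allclose(clone.ar.coeffs, strong_model.ar.coeffs)
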