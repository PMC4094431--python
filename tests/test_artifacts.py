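"""Trial screening, feature-outlier rejection and AR-residual detection."""

import numpy as np
import pytest
from scipy import stats as spstats

import erdbci as e
from erdbci.artifacts import _ar_residuals
from conftest import FS


def gaussian_epoch(rng, sd=10.0, seconds=7.0, n_ch=3):
    return e.EEGSegment(
        sd * rng.standard_normal((int(seconds * FS), n_ch)), FS, ["C3", "Cz", "C4"]
    )


class TestScreening:
    def test_clean_gaussian_trial_passes(self, rng):
        history = [gaussian_epoch(rng) for _ in range(10)]
        verdict = e.screen_trial_stats(gaussian_epoch(rng), history)
        assert verdict.clean
        assert verdict.reasons == frozenset()

    def test_large_spike_flags_amplitude(self, rng):
        epoch = gaussian_epoch(rng)
        epoch.data[100, 0] = 500.0
        verdict = e.screen_trial_stats(epoch, [])
        assert "amplitude" in verdict.reasons

    def test_heavy_tailed_epoch_flags_kurtosis(self, rng):
        history = [gaussian_epoch(rng) for _ in range(12)]
        # Student-t with 2.2 dof: kurtosis far beyond any Gaussian trial's
        heavy = e.EEGSegment(
            5.0 * rng.standard_t(2.2, (7 * FS, 3)), FS, ["C3", "Cz", "C4"]
        )
        heavy.data = np.clip(heavy.data, -90, 90)  # stay under the amplitude cut
        verdict = e.screen_trial_stats(heavy, history)
        assert "kurtosis" in verdict.reasons
        # oracle: the z-score of the trial kurtosis against history is extreme
        hist_k = np.array(
            [spstats.kurtosis(h.data, axis=0, bias=True) for h in history]
        )
        trial_k = spstats.kurtosis(heavy.data, axis=0, bias=True)
        z = (trial_k - hist_k.mean(0)) / hist_k.std(0, ddof=1)
        assert np.max(np.abs(z)) > 20

    def test_short_history_uses_amplitude_only(self, rng):
        heavy = e.EEGSegment(5.0 * rng.standard_t(2.2, (7 * FS, 3)), FS, ["C3", "Cz", "C4"])
        heavy.data = np.clip(heavy.data, -90, 90)
        assert e.screen_trial_stats(heavy, [gaussian_epoch(rng)]).clean

    def test_empty_epoch_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            e.screen_trial_stats(e.EEGSegment(np.zeros((0, 3)), FS, ["C3", "Cz", "C4"]), [])


class TestFeatureOutliers:
    def test_identical_trials_kept(self):
        feats = np.ones((12, 6))
        labels = np.array(["a"] * 6 + ["b"] * 6)
        kept, rejected = e.reject_feature_outliers(feats, labels)
        assert rejected.size == 0 and kept.size == 12

    def test_single_planted_outlier_rejected(self, rng):
        feats = 0.1 * rng.standard_normal((20, 6))
        labels = np.array(["a"] * 20)
        sd = feats[:19, 2].std(ddof=1)
        feats[19, 2] = feats[:19, 2].mean() + 10 * sd
        kept, rejected = e.reject_feature_outliers(feats, labels)
        assert list(rejected) == [19]

    def test_infinite_k_rejects_nothing(self, rng):
        feats = rng.standard_normal((14, 6)) * 100
        labels = np.array(["a"] * 7 + ["b"] * 7)
        _, rejected = e.reject_feature_outliers(feats, labels, k=np.inf)
        assert rejected.size == 0

    def test_verdict_is_permutation_invariant(self, rng):
        feats = rng.standard_normal((16, 6))
        feats[3] += 8.0
        labels = np.array(["a"] * 8 + ["b"] * 8)
        _, rej = e.reject_feature_outliers(feats, labels)
        perm = rng.permutation(16)
        _, rej_p = e.reject_feature_outliers(feats[perm], labels[perm])
        assert set(perm[rej_p]) == set(rej)


class TestARModel:
    @staticmethod
    def simulate_ar(coeffs, n, rng, sd=1.0):
        order = len(coeffs)
        x = np.zeros(n + 200)
        noise = sd * rng.standard_normal(n + 200)
        for t in range(order, n + 200):
            x[t] = np.dot(coeffs, x[t - order : t][::-1]) + noise[t]
        return x[200:]

    # a stable AR(11) with substantial structure
    TRUE_A = np.array([0.6, -0.3, 0.15, -0.05, 0.1, 0.0, -0.08, 0.05, 0.0, 0.02, -0.01])

    def test_recovers_known_process(self, rng):
        x = self.simulate_ar(self.TRUE_A, 60 * FS, rng)
        seg = e.EEGSegment(x[:, None], FS, ["C3"])
        model = e.fit_ar([seg])
        assert np.max(np.abs(model.coeffs[0] - self.TRUE_A)) <= 0.1

    def test_white_noise_has_no_structure(self, rng):
        seg = e.EEGSegment(rng.standard_normal((60 * FS, 1)), FS, ["C3"])
        model = e.fit_ar([seg])
        assert np.max(np.abs(model.coeffs[0])) <= 0.05

    def test_training_residuals_rarely_exceed_threshold(self, rng):
        x = self.simulate_ar(self.TRUE_A, 60 * FS, rng)
        seg = e.EEGSegment(x[:, None], FS, ["C3"])
        model = e.fit_ar([seg])
        resid = _ar_residuals(x, model.coeffs[0])[11:]
        frac = np.mean(np.abs(resid) > model.residual_threshold[0])
        assert frac <= 0.011  # 99th-percentile threshold by construction

    def test_own_process_flag_rate_low(self, rng):
        train = self.simulate_ar(self.TRUE_A, 60 * FS, rng)
        model = e.fit_ar([e.EEGSegment(train[:, None], FS, ["C3"])])
        fresh = self.simulate_ar(self.TRUE_A, 60 * FS, rng)
        flags = e.detect_artifact_online(
            e.EEGSegment(fresh[:, None], FS, ["C3"]), model, hold=0.0
        )
        assert flags.mean() <= 0.02

    def test_step_transient_flagged_within_50ms_and_held(self, rng):
        train = self.simulate_ar(self.TRUE_A, 60 * FS, rng)
        model = e.fit_ar([e.EEGSegment(train[:, None], FS, ["C3"])])
        fresh = self.simulate_ar(self.TRUE_A, 20 * FS, rng)
        onset = 10 * FS
        fresh[onset:] += 300.0
        flags = e.detect_artifact_online(e.EEGSegment(fresh[:, None], FS, ["C3"]), model)
        first = np.flatnonzero(flags)[0]
        assert (first - onset) / FS <= 0.05
        # hold: after any raw exceedance the flag persists 0.5 s
        last_raw = onset  # the step edge certainly exceeds
        assert flags[last_raw : last_raw + FS // 2].all()

    def test_streaming_equals_batch_detection(self, rng):
        train = self.simulate_ar(self.TRUE_A, 60 * FS, rng)
        model = e.fit_ar([e.EEGSegment(train[:, None], FS, ["C3"])])
        x = self.simulate_ar(self.TRUE_A, 10 * FS, rng)
        x[5 * FS] += 200.0
        whole = e.detect_artifact_online(e.EEGSegment(x[:, None], FS, ["C3"]), model)
        det = e.OnlineArtifactDetector(model)
        parts = [
            det.process(e.EEGSegment(x[a:b, None], FS, ["C3"]))
            for a, b in [(0, 777), (777, 1500), (1500, len(x))]
        ]
        np.testing.assert_array_equal(np.concatenate(parts), whole)

    def test_agrees_with_yule_walker_estimate(self, rng):
        """Independent route: statsmodels' Yule-Walker solver on the same
        long realization should land on the same coefficients."""
        from statsmodels.regression.linear_model import yule_walker

        x = self.simulate_ar(self.TRUE_A, 120 * FS, rng)
        model = e.fit_ar([e.EEGSegment(x[:, None], FS, ["C3"])])
        rho, _ = yule_walker(x, order=11, method="mle")
        assert np.max(np.abs(model.coeffs[0] - rho)) <= 0.05

    def test_too_little_data_rejected(self, rng):
        seg = e.EEGSegment(rng.standard_normal((5 * FS, 1)), FS, ["C3"])
        with pytest.raises(ValueError, match="10 s"):
            e.fit_ar([seg])
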