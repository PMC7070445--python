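"""Tests of the sliding-window LDA decoder, forward models, evidence
projections, congruency contrasts, and the latency bootstrap."""

import numpy as np
import pytest
from scipy import stats as sps

import cuedecode as cd
from cuedecode.containers import LDAComponent
from cuedecode.decoding import (SlidingWindowLDA, congruency_effect,
                                congruency_evidence, forward_model,
                                latency_bootstrap, project_component,
                                shrinkage_lda)
from cuedecode.synthetic import DesignSpec, EEGSimParams, simulate_session


def _gaussian_epochs(rng, n=400, n_ch=10, delta=1.5, n_t=6, fs=100.0):
    """Two Gaussian classes, identity covariance, Mahalanobis sep delta.

    Each trial is constant over time so that window averaging leaves
    the per-trial separation (and hence the ideal AUC) unchanged.
    """
    y = np.repeat([-1, 1], n // 2)
    mu = np.zeros(n_ch)
    mu[0] = delta
    X = rng.standard_normal((n, n_ch, 1)).repeat(n_t, axis=2)
    X += (y[:, None] * mu[None, :] / 2)[:, :, None]
    times = np.arange(n_t) / fs
    return X, y, times


class TestSlidingLDA:
    def test_label_shuffled_data_at_chance(self, small_session, rng):
        table, epochs, _, _ = small_session
        y = rng.permutation(table["direction"].to_numpy())
        lda = SlidingWindowLDA(reps=3, folds=4, random_state=1)
        lda.fit(epochs, y)
        assert abs(lda.auc_.mean() - 0.5) < 0.02
        assert np.all(np.abs(lda.auc_ - 0.5) < 0.15)  # single-window noise

    def test_two_gaussian_closed_form_auc(self, rng):
        """Cross-validated AUC matches the two-Gaussian closed form.

        For classes N(+-mu/2, I) with Mahalanobis separation delta, the
        optimal linear score differs by delta between classes with unit
        variance in each, so AUC = Phi(delta / sqrt(2))."""
        delta = 1.5
        X, y, times = _gaussian_epochs(rng, n=400, delta=delta)
        lda = SlidingWindowLDA(window=0.05, step=0.05, reps=5, folds=6,
                               random_state=2)
        lda.fit(X, y, times=times)
        assert lda.auc_.mean() == pytest.approx(
            sps.norm.cdf(delta / np.sqrt(2)), abs=0.03)

    def test_planted_latency_recovered(self, small_session):
        table, epochs, _, _ = small_session
        lda = SlidingWindowLDA(reps=5, random_state=3)
        lda.fit(epochs, table["direction"].to_numpy())
        peak_t, peak_auc = lda.peak()
        assert abs(peak_t - 0.32) <= 0.046 + 1e-9  # within one window step
        assert peak_auc > 0.6

    def test_windows_labelled_by_first_time_point(self, small_session):
        _, epochs, _, _ = small_session
        lda = SlidingWindowLDA(reps=1, subsample_frac=1.0, random_state=0)
        starts = lda.fit(epochs, np.resize([-1, 1], epochs.n_trials)
                         ).window_starts_
        assert starts[0] == pytest.approx(epochs.times[0])
        np.testing.assert_allclose(np.diff(starts), 0.046, atol=1e-9)
        assert starts[-1] + 0.092 <= epochs.times[-1] + 1 / epochs.fs

    def test_auc_invariant_to_channel_affine_transform(self, rng):
        X, y, times = _gaussian_epochs(rng, n=300, delta=2.0)
        lda = SlidingWindowLDA(window=0.05, step=0.05, reps=3, folds=4,
                               random_state=5)
        auc1 = lda.fit(X, y, times=times).auc_.mean()
        scale = rng.uniform(0.5, 2.0, size=(1, X.shape[1], 1))
        shift = rng.uniform(-1, 1, size=(1, X.shape[1], 1))
        lda2 = SlidingWindowLDA(window=0.05, step=0.05, reps=3, folds=4,
                                random_state=5)
        auc2 = lda2.fit(X * scale + shift, y, times=times).auc_.mean()
        assert abs(auc1 - auc2) < 0.01

    def test_singular_covariance_without_regularization(self, rng):
        X = rng.standard_normal((20, 30))   # fewer trials than channels
        y = np.resize([-1, 1], 20)
        with pytest.raises(np.linalg.LinAlgError, match="gamma"):
            shrinkage_lda(X, y, gamma=0.0)
        w, b = shrinkage_lda(X, y, gamma=0.1)   # regularized path works
        assert np.isfinite(w).all()

    def test_window_longer_than_epoch_rejected(self, rng):
        X, y, times = _gaussian_epochs(rng, n=40, n_t=4)
        with pytest.raises(ValueError, match="window"):
            SlidingWindowLDA(window=1.0).fit(X, y, times=times)

    def test_sklearn_params_roundtrip(self):
        lda = SlidingWindowLDA(gamma=0.2, reps=7)
        params = lda.get_params()
        assert params["gamma"] == 0.2
        clone = SlidingWindowLDA(**params)
        assert clone.get_params() == params


class TestForwardModel:
    def test_single_source_pattern_recovered(self, rng):
        """With x = s*m + tiny noise the forward model recovers m."""
        n, n_ch = 300, 16
        m = rng.standard_normal(n_ch)
        s = rng.standard_normal(n)
        X = (s[:, None] * m[None, :])[:, :, None] + \
            0.01 * rng.standard_normal((n, n_ch, 1))
        comp_w = rng.standard_normal(n_ch)  # arbitrary readout
        comp = LDAComponent(w=comp_w, bias=0.0, window_start=0.0,
                            window_len=0.02, gamma=0.1)
        a = forward_model(comp, X, times=np.array([0.0]))
        corr = np.corrcoef(a, m)[0, 1]
        assert abs(corr) > 0.99

    def test_pattern_invariant_to_weight_scaling(self, rng):
        X = rng.standard_normal((100, 8, 3))
        t = np.arange(3) / 100
        w = rng.standard_normal(8)
        a1 = forward_model(LDAComponent(w, 0.0, 0.0, 0.03, 0.1), X, t)
        a2 = forward_model(LDAComponent(5 * w, 0.0, 0.0, 0.03, 0.1), X, t)
        np.testing.assert_allclose(a1, a2, atol=1e-12)

    def test_white_noise_pattern_proportional_to_weights(self, rng):
        """Under identity covariance the forward model is proportional
        to the backward weights."""
        X = rng.standard_normal((5000, 10, 2))
        t = np.arange(2) / 100
        w = rng.standard_normal(10)
        a = forward_model(LDAComponent(w, 0.0, 0.0, 0.02, 0.1), X, t)
        corr = np.corrcoef(a, w)[0, 1]
        assert corr > 0.95

    def test_zero_variance_channel_zeroed_with_warning(self, rng):
        X = rng.standard_normal((50, 4, 2))
        X[:, 2, :] = 7.0
        t = np.arange(2) / 100
        with pytest.warns(UserWarning, match="zero-variance"):
            a = forward_model(LDAComponent(np.ones(4), 0.0, 0.0, 0.02, 0.1),
                              X, t)
        assert a[2] == 0.0


class TestProjection:
    def test_projection_reproduces_training_discriminant(self, rng):
        X, y, times = _gaussian_epochs(rng, n=100, n_t=4, fs=100)
        Xw = X[:, :, :2].mean(axis=-1)
        w, b = shrinkage_lda(Xw, y, 0.1)
        comp = LDAComponent(w, b, times[0], 0.02, 0.1)
        ev = project_component(comp, X, times, step=0.02)
        np.testing.assert_allclose(ev.y[:, 0], Xw @ w + b, atol=1e-12)

    def test_linearity_in_data(self, rng):
        X, y, times = _gaussian_epochs(rng, n=50, n_t=4)
        comp = LDAComponent(rng.standard_normal(10), 0.7, times[0], 0.02, 0.1)
        y1 = project_component(comp, X, times).y
        y2 = project_component(comp, 2 * X, times).y
        np.testing.assert_allclose(y2 - comp.bias, 2 * (y1 - comp.bias),
                                   atol=1e-10)

    def test_channel_mismatch_rejected(self, rng):
        comp = LDAComponent(np.ones(5), 0.0, 0.0, 0.02, 0.1)
        with pytest.raises(ValueError, match="channel"):
            project_component(comp, rng.standard_normal((10, 7, 4)),
                              np.arange(4) / 100)

    def test_evidence_separates_classes_at_signal_latency(self, small_session):
        table, epochs, _, _ = small_session
        y = table["direction"].to_numpy()
        lda = SlidingWindowLDA(reps=3, random_state=7).fit(epochs, y)
        comp = lda.component_at(0.32)
        ev = project_component(comp, epochs)
        from sklearn.metrics import roc_auc_score
        sig_i = np.argmin(np.abs(ev.window_starts - 0.32))
        base_i = np.argmin(np.abs(ev.window_starts + 0.4))
        auc_sig = roc_auc_score((y == 1).astype(int), ev.y[:, sig_i])
        auc_base = roc_auc_score((y == 1).astype(int), ev.y[:, base_i])
        assert auc_sig > 0.6
        assert abs(auc_base - 0.5) < 0.15  # chance up to 120-trial noise


class TestCongruency:
    def _cohort_courses(self, gain, n_subj=8, seed=0, trials=25):
        rng = np.random.default_rng(seed)
        courses = []
        for _ in range(n_subj):
            spec = DesignSpec(trials_per_cell=trials)
            eeg = EEGSimParams(n_channels=12, congruency_gain=gain)
            table, ep, _, _ = simulate_session(spec, eeg=eeg,
                                               seed=rng.integers(2**31 - 1))
            courses.append(congruency_evidence(
                ep, table["direction"].to_numpy(),
                table["congruent"].to_numpy(), train_window_start=0.276,
                seed=rng.integers(2**31 - 1)))
        return np.asarray(courses)

    def test_planted_congruency_gain_detected_at_latency(self):
        courses = self._cohort_courses(gain=1.6, n_subj=10, seed=42)
        tmap, res = congruency_effect(courses, n_perm=500, seed=1)
        sig = res.significant(0.05)
        assert sig, "planted congruency effect not detected"
        starts = np.arange(courses.shape[1]) * 0.046 - 0.5
        covered = np.concatenate([starts[c.bins.ravel()] for c in sig
                                  if c.sign > 0])
        assert np.any((covered >= 0.32 - 0.092) & (covered <= 0.32 + 0.092))

    def test_no_modulation_yields_no_cluster(self):
        """A postcue-style simulation (no EEG congruency modulation)
        produces no significant cluster in most null runs."""
        hits = 0
        for i in range(10):
            courses = self._cohort_courses(gain=1.0, n_subj=8, seed=100 + i,
                                           trials=20)
            _, res = congruency_effect(courses, n_perm=300, seed=i)
            hits += bool(res.significant(0.05))
        assert hits <= 1

    def test_missing_congruency_class_rejected(self, small_session):
        table, epochs, _, _ = small_session
        with pytest.raises(ValueError, match="congruency"):
            congruency_evidence(epochs, table["direction"].to_numpy(),
                                np.ones(len(table), dtype=bool),
                                train_window_start=0.3)


class TestLatencyBootstrap:
    def _synthetic_courses(self, rng, onset_bin, n_subj=15, n_bins=30,
                           width=6, amp=1.5):
        data = rng.standard_normal((n_subj, n_bins)) * 0.5
        data[:, onset_bin:onset_bin + width] += amp
        return data

    def test_identical_conditions_give_null_difference(self, rng):
        a = self._synthetic_courses(rng, onset_bin=10)
        starts = np.arange(30) * 0.046
        res = latency_bootstrap(a, a.copy(), starts, n_boot=100,
                                n_perm_inner=150, seed=3)
        assert abs(res.mean_difference) <= 0.046
        assert res.p_value > 0.1

    def test_planted_offset_recovered(self, rng):
        """Onsets planted ~120 ms apart are recovered by the bootstrap."""
        starts = np.arange(30) * 0.046
        b = self._synthetic_courses(rng, onset_bin=8)    # earlier
        a = self._synthetic_courses(rng, onset_bin=11)   # ~0.138 s later
        res = latency_bootstrap(a, b, starts, n_boot=100, n_perm_inner=150,
                                seed=4)
        assert res.mean_difference == pytest.approx(3 * 0.046, abs=0.05)
        assert res.p_value < 0.05
        assert not res.unreliable

    def test_no_original_effect_rejected(self, rng):
        null = rng.standard_normal((15, 30)) * 0.1
        with pytest.raises(ValueError, match="no significant effect"):
            latency_bootstrap(null, null, np.arange(30) * 0.046,
                              n_boot=10, n_perm_inner=100, seed=0)
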