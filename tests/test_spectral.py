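"""Time-frequency, coherence and cluster-statistics tests."""

import itertools

import numpy as np
import pytest
import scipy.stats

from hebbnet import (
    band_average,
    baseline_correct,
    cluster_permutation_test,
    evoked_induced_split,
    morlet_kernel,
    morlet_tfr,
    peak_amplitude_test,
    peak_serp_amplitude,
    wavelet_coherence,
)

SFREQ = 2000.0


def sinusoid(freq, n=6000, amp=1.0, phase=0.0):
    t = np.arange(n) / SFREQ
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestMorlet:
    def test_kernel_has_unit_energy(self):
        for f in (4.0, 30.0, 100.0):
            k = morlet_kernel(f, SFREQ)
            energy = np.sum(np.abs(k) ** 2) / SFREQ
            assert energy == pytest.approx(1.0, rel=0.01)

    def test_pure_sinusoid_peaks_at_its_frequency(self):
        tfr = morlet_tfr(sinusoid(30.0), SFREQ)
        mean_power = np.where(tfr.valid, tfr.power[0], 0.0).mean(axis=1)
        peak = tfr.freqs[np.argmax(mean_power)]
        assert peak == 30.0
        # symmetric falloff around the peak
        i = int(peak - tfr.freqs[0])
        assert mean_power[i - 3] == pytest.approx(mean_power[i + 3], rel=0.35)
        assert mean_power[i] > 5 * mean_power[i - 10]

    def test_zero_signal_zero_power(self):
        tfr = morlet_tfr(np.zeros(6000), SFREQ)
        assert np.all(tfr.power == 0.0)

    def test_power_scales_quadratically_with_amplitude(self):
        p1 = morlet_tfr(sinusoid(25.0), SFREQ).power
        p2 = morlet_tfr(sinusoid(25.0, amp=2.0), SFREQ).power
        np.testing.assert_allclose(p2, 4.0 * p1, rtol=1e-9)

    def test_epoch_shorter_than_wavelet_support_raises(self):
        with pytest.raises(ValueError, match="at least"):
            morlet_tfr(np.zeros(1000), SFREQ)  # 0.5 s < support at 4 Hz

    def test_edge_bins_flagged_invalid(self):
        tfr = morlet_tfr(sinusoid(10.0), SFREQ)
        fi = int(np.flatnonzero(tfr.freqs == 4.0)[0])
        assert not tfr.valid[fi, 0]  # 4 Hz support longer than first bin offset
        assert tfr.valid[fi, len(tfr.times) // 2]

    def test_agrees_with_mne_morlet_power_peak(self):
        mne = pytest.importorskip("mne")
        x = sinusoid(28.0) + 0.1 * np.random.default_rng(0).normal(size=6000)
        freqs = np.arange(10.0, 50.0)
        ours = morlet_tfr(x, SFREQ, freqs=freqs)
        out = mne.time_frequency.tfr_array_morlet(
            x[None, None, :], SFREQ, freqs, n_cycles=6.0, output="power", verbose=False
        )[0, 0]
        mid = slice(2000, 4000)
        ours_spec = ours.power[0][:, 100:200].mean(axis=1)
        mne_spec = out[:, mid].mean(axis=1)
        assert np.argmax(ours_spec) == np.argmax(mne_spec)
        # spectral shape agreement up to normalization
        corr = np.corrcoef(ours_spec, mne_spec)[0, 1]
        assert corr > 0.99


class TestEvokedInducedSplit:
    def test_identical_trials_have_no_induced_power(self):
        trials = np.tile(sinusoid(25.0), (6, 1))
        total, evoked, induced = evoked_induced_split(
            trials, SFREQ, onset_s=1.5, baseline_window=None
        )
        assert np.abs(induced.power).max() < 1e-10 * total.power.max()

    def test_random_phase_oscillation_is_induced_not_evoked(self):
        rng = np.random.default_rng(1)
        trials = np.stack(
            [sinusoid(25.0, phase=rng.uniform(0, 2 * np.pi)) for _ in range(40)]
        )
        total, evoked, induced = evoked_induced_split(
            trials, SFREQ, onset_s=1.5, baseline_window=None
        )
        fi = int(np.flatnonzero(total.freqs == 25.0)[0])
        mid = slice(100, 200)
        assert evoked.power[fi, mid].mean() < 0.15 * total.power[fi, mid].mean()
        assert induced.power[fi, mid].mean() > 0.8 * total.power[fi, mid].mean()

    def test_induced_plus_evoked_equals_total_before_baseline(self):
        rng = np.random.default_rng(2)
        trials = rng.normal(size=(5, 6000))
        total, evoked, induced = evoked_induced_split(
            trials, SFREQ, onset_s=1.5, baseline_window=None
        )
        np.testing.assert_allclose(
            induced.power + evoked.power, total.power, rtol=1e-10, atol=1e-12
        )

    def test_baseline_window_mean_is_zero_after_correction(self):
        rng = np.random.default_rng(3)
        trials = rng.normal(size=(8, 6000))
        _, _, induced = evoked_induced_split(trials, SFREQ, onset_s=1.5)
        mask = (induced.times >= -0.5) & (induced.times <= -0.1)
        np.testing.assert_allclose(
            induced.power[:, mask].mean(axis=1), 0.0, atol=1e-10
        )

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError, match="2 trials"):
            evoked_induced_split(np.zeros((1, 6000)), SFREQ, onset_s=1.5)


class TestCoherence:
    def _coeffs(self, trials):
        return morlet_tfr(trials, SFREQ, freqs=np.arange(10.0, 41.0)).coeffs

    def test_identical_channels_have_unit_coherence(self):
        rng = np.random.default_rng(0)
        trials = rng.normal(size=(8, 6000))
        c = self._coeffs(trials)
        coh = wavelet_coherence(c, c).coherence
        np.testing.assert_allclose(coh, 1.0, atol=1e-9)

    def test_independent_noise_coherence_near_one_over_n(self):
        rng = np.random.default_rng(1)
        n_trials, reps = 10, 25
        vals = []
        for _ in range(reps):
            a = rng.normal(size=(n_trials, 4000))
            b = rng.normal(size=(n_trials, 4000))
            fa = morlet_tfr(a, SFREQ, freqs=np.arange(15.0, 31.0, 5)).coeffs
            fb = morlet_tfr(b, SFREQ, freqs=np.arange(15.0, 31.0, 5)).coeffs
            vals.append(wavelet_coherence(fa, fb).coherence[:, 50:150].mean())
        assert np.mean(vals) == pytest.approx(1.0 / n_trials, rel=0.25)

    def test_common_component_peaks_at_its_frequency(self):
        rng = np.random.default_rng(2)
        freqs = np.arange(15.0, 46.0)
        common = [sinusoid(28.0, n=4000, phase=rng.uniform(0, 2 * np.pi)) for _ in range(12)]
        a = np.stack([c + 0.8 * rng.normal(size=4000) for c in common])
        b = np.stack([c + 0.8 * rng.normal(size=4000) for c in common])
        fa = morlet_tfr(a, SFREQ, freqs=freqs).coeffs
        fb = morlet_tfr(b, SFREQ, freqs=freqs).coeffs
        coh = wavelet_coherence(fa, fb).coherence
        spec = coh[:, 80:120].mean(axis=1)
        assert freqs[np.argmax(spec)] == pytest.approx(28.0, abs=2.0)

    def test_invariant_to_global_amplitude_rescaling_of_both_channels(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(6, 4000))
        b = a + 0.5 * rng.normal(size=(6, 4000))
        fa = morlet_tfr(a, SFREQ, freqs=np.arange(20.0, 31.0)).coeffs
        fb = morlet_tfr(b, SFREQ, freqs=np.arange(20.0, 31.0)).coeffs
        c1 = wavelet_coherence(fa, fb).coherence
        c2 = wavelet_coherence(fa * 3.7, fb * 3.7).coherence
        np.testing.assert_allclose(c1, c2, rtol=1e-9)

    def test_trial_count_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            wavelet_coherence(np.zeros((3, 2, 2), complex), np.zeros((4, 2, 2), complex))


def brute_force_cluster_p(diff, threshold):
    """Independent oracle: exhaustive sign-flip enumeration, 1-D time strip.

    Returns the p-value of the largest observed cluster by |mass|, counting
    permutations whose maximum cluster |mass| reaches it.
    """

    def clusters(tvals):
        out = []
        for sign in (1, -1):
            run = []
            for i, t in enumerate(tvals):
                if sign * t > threshold:
                    run.append(i)
                elif run:
                    out.append(sum(tvals[j] for j in run))
                    run = []
            if run:
                out.append(sum(tvals[j] for j in run))
        return out

    def tstat(d):
        m = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sd > 0, m / (sd / np.sqrt(d.shape[0])), np.where(m != 0, np.inf, 0.0))

    obs = clusters(tstat(diff))
    if not obs:
        return None, 1.0
    obs_max = max(abs(c) for c in obs)
    n = diff.shape[0]
    count = 0
    for signs in itertools.product([1.0, -1.0], repeat=n):
        d = diff * np.array(signs)[:, None]
        cl = clusters(tstat(d))
        mx = max((abs(c) for c in cl), default=0.0)
        if mx >= obs_max:
            count += 1
    return obs_max, count / 2**n


class TestClusterPermutation:
    def test_identical_conditions_give_no_clusters(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5, 3, 20))
        res = cluster_permutation_test(x, x.copy(), n_perm=200)
        assert res.clusters == []
        assert res.p_min == 1.0

    def test_constant_offset_gives_one_saturated_cluster(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(4, 2, 12))
        res = cluster_permutation_test(base + 5.0, base, n_perm=1000)
        # exhaustive test over 16 sign patterns: identity and its mirror tie
        assert res.exhaustive
        positive = [cl for cl in res.clusters if cl.mass > 0]
        # every bin of both area strips is suprathreshold
        assert sum(len(cl.bins) for cl in positive) == 2 * 12
        assert res.p_min <= 2 / 16 + 1e-12

    def test_p_matches_exhaustive_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        diff = rng.normal(0.4, 1.0, size=(4, 6))
        a = rng.normal(size=(4, 6))
        res = cluster_permutation_test(a + diff, a, n_perm=1000)
        df = 3
        thr = scipy.stats.t.ppf(0.975, df)
        obs_max, p_oracle = brute_force_cluster_p((a + diff) - a, thr)
        if obs_max is None:
            assert res.clusters == []
        else:
            assert res.exhaustive
            assert abs(res.clusters[0].mass) == pytest.approx(obs_max, rel=1e-9)
            assert res.clusters[0].p == pytest.approx(p_oracle, abs=1e-12)

    def test_agrees_with_mne_cluster_test(self):
        mne = pytest.importorskip("mne")
        rng = np.random.default_rng(3)
        diff = rng.normal(0.8, 1.0, size=(6, 25))
        res = cluster_permutation_test(
            diff + rng.normal(size=(6, 25)) * 0.0 + 1.0, np.ones((6, 25)), n_perm=200
        )
        # same contrast as a one-sample test on diff
        thr = scipy.stats.t.ppf(0.975, 5)
        t_obs, clusters, pvals, _ = mne.stats.permutation_cluster_1samp_test(
            diff, threshold=thr, tail=0, n_permutations=128, seed=0, verbose=False
        )
        ours = cluster_permutation_test(diff, np.zeros_like(diff), n_perm=200)
        assert ours.exhaustive
        # largest-cluster mass agrees
        mne_masses = sorted(
            (abs(t_obs[c].sum()) for c in clusters), reverse=True
        )
        assert abs(ours.clusters[0].mass) == pytest.approx(mne_masses[0], rel=1e-9)
        assert ours.p_min == pytest.approx(min(pvals), abs=0.02)

    def test_area_strips_are_separate_unless_adjacency_given(self):
        t = np.zeros((4, 2, 10))
        t[:, 0, 2:5] = 3.0
        t[:, 1, 2:5] = 3.0
        a = t + np.random.default_rng(4).normal(0, 0.1, t.shape)
        res = cluster_permutation_test(a, np.zeros_like(a), n_perm=64)
        top_areas = [cl.areas for cl in res.clusters if cl.mass > 0]
        assert all(len(ar) == 1 for ar in top_areas)
        res2 = cluster_permutation_test(
            a, np.zeros_like(a), n_perm=64, adjacency=[(0, 1)]
        )
        assert any(len(cl.areas) == 2 for cl in res2.clusters if cl.mass > 0)

    def test_type_one_error_controlled_under_null(self):
        rng = np.random.default_rng(5)
        rejections = 0
        reps = 100
        for _ in range(reps):
            x = rng.normal(size=(4, 1, 15))
            y = rng.normal(size=(4, 1, 15))
            res = cluster_permutation_test(x, y, n_perm=64)
            if res.p_min <= 0.05:
                rejections += 1
        # exchangeable null: empirical rate <= alpha + 2 * MC error
        assert rejections / reps <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="pairs"):
            cluster_permutation_test(np.zeros((1, 2, 3)), np.zeros((1, 2, 3)))


class TestPeakAmplitude:
    def test_peak_window_extraction(self):
        serp = np.zeros((2, 3, 1000))
        serp[:, :, 500] = 7.0  # outside 50-500 ms window from onset 100
        serp[:, :, 300] = 5.0  # inside
        val = peak_serp_amplitude(serp, 1000.0, onset_step=100, window_s=(0.05, 0.35))
        assert val == 5.0

    def test_identical_conditions_give_t_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        t, p = peak_amplitude_test(x, x.copy())
        assert t == 0.0 and p == 1.0

    def test_constant_offset_is_degenerate_with_warning(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="degenerate"):
            t, p = peak_amplitude_test(x + 0.5, x)
        assert t == np.inf and p == 0.0

    def test_matches_hand_computed_paired_t(self):
        word = np.array([10.0, 12.0, 9.0, 14.0, 11.0])
        pseudo = np.array([8.0, 11.0, 9.5, 10.0, 10.5])
        t, p = peak_amplitude_test(word, pseudo)
        d = word - pseudo
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert t == pytest.approx(t_hand, rel=1e-12)
        p_hand = 2 * scipy.stats.t.sf(abs(t_hand), 4)
        assert p == pytest.approx(p_hand, rel=1e-12)


class TestBandAverage:
    def test_band_selection_inclusive(self):
        freqs = np.arange(4.0, 101.0)
        power = np.tile(freqs[:, None], (1, 5))
        band = band_average(power, freqs, (20.0, 40.0))
        assert band[0] == pytest.approx(30.0)  # mean of 20..40

    def test_empty_band_raises(self):
        with pytest.raises(ValueError, match="no frequency"):
            band_average(np.zeros((3, 4)), np.array([4.0, 5.0, 6.0]), (50.0, 60.0))
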