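"""coupling: POI, trial scoring, HRF regressor, BOLD preprocessing, GLM,
Monte-Carlo cluster threshold, end-to-end coupling recovery."""

import numpy as np
import pytest
import scipy.ndimage
import scipy.stats

from alphabold.coupling import (
    ClusterThreshold,
    DesignMatrix,
    Poi,
    build_alpha_regressor,
    cluster_threshold_mc,
    couple,
    define_poi,
    fit_glm,
    hrf_double_gamma,
    poi_alpha_timecourse,
    preprocess_bold_minimal,
    score_trials,
)
from alphabold.inverse import SourceStatMap, build_source_space
from alphabold.io_core import TrialRecord, VolumeSeries
from alphabold.synth import CouplingSimSpec, simulate_bold
from alphabold.io_core import Marker


def _trial(i, modality="visual", congruence="n/a", correctness="correct",
           response=1, decision="n/a"):
    ve = "happy" if modality != "auditory" else "none"
    ae = "none"
    if modality == "audiovisual":
        ae = "happy" if congruence == "CON" else "angry"
    return TrialRecord(
        trial_id=i, marker_index=i, modality=modality, visual_emotion=ve,
        auditory_emotion=ae, congruence=congruence,
        response_code=response, correctness=correctness,
        inc_decision=decision, included=correctness != "omitted",
    )


# ---------------------------------------------------------------- POI

class TestDefinePoi:
    def _map(self, src, supra_ids, stat_val=-5.0):
        stat = np.zeros(src.n_vertices)
        p = np.ones(src.n_vertices)
        stat[supra_ids] = stat_val
        p[supra_ids] = 0.001
        return SourceStatMap(stat=stat, p=p, contrast="av_vs_baseline",
                             band_hz=(8, 13), window_ms=(200, 400))

    def test_single_blob_recovered(self):
        src = build_source_space(150)
        from alphabold.inverse import geodesic_patch
        blob = geodesic_patch(src, [0, -1, 0], 20.0, hemi="lh")
        smap = self._map(src, blob)
        pois = define_poi(smap, src)
        assert len(pois) == 1
        assert set(pois[0].vertex_ids) == set(blob)
        assert pois[0].weights.sum() == pytest.approx(1.0)

    def test_no_supra_threshold_rejected(self):
        src = build_source_space(60)
        smap = self._map(src, [])
        with pytest.raises(ValueError, match="no supra-threshold"):
            define_poi(smap, src)

    def test_two_blobs_labeled_by_centroid(self):
        src = build_source_space(150)
        from alphabold.inverse import geodesic_patch
        occ = geodesic_patch(src, [0, -1, -0.3], 16.0, hemi="lh")
        fro = geodesic_patch(src, [0, 1, 0.4], 16.0, hemi="rh")
        smap = self._map(src, np.concatenate([occ, fro]))
        pois = define_poi(smap, src)
        labels = sorted(p.label for p in pois)
        assert labels == ["occipital-lh", "prefrontal-rh"]

    def test_weights_normalized_nonnegative(self):
        with pytest.raises(ValueError, match="non-negative"):
            Poi(np.array([1, 2]), np.array([0.5, -0.5]), "x")


# ---------------------------------------------------------------- scoring

class TestScoreTrials:
    def test_inc_incorrect_included(self):
        trials = [_trial(0, "audiovisual", "INC", "incorrect",
                         decision="neither")]
        out, _ = score_trials(trials)
        assert out[0].included

    def test_con_incorrect_confound(self):
        trials = [_trial(0, "audiovisual", "CON", "incorrect")]
        out, summary = score_trials(trials)
        assert not out[0].included
        assert summary["confound_trial_ids"] == [0]

    def test_no_response_excluded_and_confound(self):
        trials = [_trial(0, correctness="omitted", response=None)]
        out, summary = score_trials(trials)
        assert not out[0].included
        assert 0 in summary["confound_trial_ids"]

    def test_summary_table_layout(self):
        trials = (
            [_trial(i, "auditory") for i in range(8)]
            + [_trial(i + 8, "auditory", correctness="incorrect")
               for i in range(2)]
            + [_trial(i + 10, "visual") for i in range(10)]
            + [_trial(i + 20, "audiovisual", "CON") for i in range(10)]
            + [_trial(i + 30, "audiovisual", "INC", decision="face")
               for i in range(5)]
            + [_trial(i + 35, "audiovisual", "INC", decision="voice")
               for i in range(3)]
            + [_trial(i + 38, "audiovisual", "INC", correctness="incorrect",
                      decision="neither") for i in range(2)]
        )
        _, s = score_trials(trials)
        assert s["auditory_pct"] == pytest.approx(80.0)
        assert s["visual_pct"] == pytest.approx(100.0)
        assert s["congruent_pct"] == pytest.approx(100.0)
        assert s["inc_face_pct"] == pytest.approx(50.0)
        assert s["inc_voice_pct"] == pytest.approx(30.0)
        assert s["inc_neither_pct"] == pytest.approx(20.0)


# ---------------------------------------------------------------- regressor

class TestAlphaRegressor:
    def test_zero_values_zero_column(self):
        col = build_alpha_regressor(np.zeros(5), 10.0 + np.arange(5) * 8.0,
                                    2.0, 100)
        assert np.all(col == 0)

    def test_single_event_equals_hrf_oracle(self):
        col = build_alpha_regressor(np.array([1.0]), np.array([4.0]), 2.0, 30)
        t = np.arange(30) * 2.0 - 4.0
        expected = hrf_double_gamma(t)
        assert np.abs(col - expected).max() < 1e-9

    def test_two_events_superpose(self):
        a = build_alpha_regressor(np.array([1.5]), np.array([4.0]), 2.0, 40)
        b = build_alpha_regressor(np.array([-0.5]), np.array([20.0]), 2.0, 40)
        ab = build_alpha_regressor(np.array([1.5, -0.5]),
                                   np.array([4.0, 20.0]), 2.0, 40)
        assert np.allclose(ab, a + b, atol=1e-12)

    def test_hrf_shape(self):
        t = np.arange(0.0, 32.0, 0.1)
        h = hrf_double_gamma(t)
        assert h.max() == pytest.approx(1.0, abs=1e-6)
        assert t[np.argmax(h)] == pytest.approx(6.0, abs=0.1)
        assert h[(t > 14) & (t < 20)].min() < 0  # undershoot

    def test_design_matrix_rejects_zero_column(self):
        with pytest.raises(ValueError, match="all-zero"):
            DesignMatrix(np.zeros((10, 1)), ["alpha"], 2.0)


# ---------------------------------------------------------------- preprocessing

class TestPreprocessBold:
    def test_constant_volume_unchanged_by_smoothing(self):
        vol = VolumeSeries(np.full((10, 10, 6, 8), 7.0), 2.0,
                           np.diag([3.0, 3.0, 3.0, 1.0]))
        pre = preprocess_bold_minimal(vol, fwhm_mm=4.0, n_discard=2)
        # constant in space and time: smoothing exact, detrend removes only
        # the (zero) drift, mean restored
        assert np.allclose(pre.data, 7.0, atol=1e-9)

    def test_linear_drift_removed(self):
        t = np.arange(100, dtype=float)
        data = np.zeros((4, 4, 2, 100)) + 3.0 * t
        vol = VolumeSeries(data, 2.0, np.diag([3.0, 3.0, 3.0, 1.0]))
        pre = preprocess_bold_minimal(vol, fwhm_mm=0.0)
        assert pre.data[0, 0, 0].var() < 1e-6 * data[0, 0, 0, 2:].var()

    def test_two_volumes_discarded(self):
        vol = VolumeSeries(np.random.default_rng(0).standard_normal((4, 4, 4, 50)),
                           2.0, np.diag([3.0, 3.0, 3.0, 1.0]))
        pre = preprocess_bold_minimal(vol)
        assert pre.n_volumes == 48
        assert pre.n_discarded_leading == 2


# ---------------------------------------------------------------- GLM

class TestFitGlm:
    def _vol(self, Y):
        # Y: voxels x time -> (v,1,1,t) volume
        v, t = Y.shape
        return VolumeSeries(Y.reshape(v, 1, 1, t), 2.0,
                            np.diag([3.0, 3.0, 3.0, 1.0]))

    def test_noiseless_beta_exact(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        vol = self._vol(2.0 * x[None, :])
        X = DesignMatrix(x[:, None], ["alpha"], 2.0)
        out = fit_glm(vol, X)["alpha"]
        assert out.beta[0, 0, 0] == pytest.approx(2.0, abs=1e-12)

    def test_orthogonal_voxel_zero_beta(self):
        n = 60
        x = np.sin(2 * np.pi * np.arange(n) / 10.0)
        y = np.cos(2 * np.pi * np.arange(n) / 10.0)  # orthogonal over cycles
        vol = self._vol(y[None, :])
        X = DesignMatrix(x[:, None], ["alpha"], 2.0)
        out = fit_glm(vol, X)["alpha"]
        assert abs(out.beta[0, 0, 0]) < 1e-10
        assert abs(out.t[0, 0, 0]) < 1e-6

    def test_tmap_matches_bruteforce_ols(self):
        rng = np.random.default_rng(1)
        n, v = 80, 30
        X = np.column_stack([rng.standard_normal(n),
                             rng.standard_normal(n), np.ones(n)])
        Y = rng.standard_normal((v, n))
        vol = self._vol(Y)
        dm = DesignMatrix(X, ["alpha", "conf", "intercept"], 2.0)
        out = fit_glm(vol, dm, contrasts={"alpha": np.array([1.0, 0, 0])})
        t_pkg = out["alpha"].t.ravel()
        # brute-force normal equations per voxel
        xtx_inv = np.linalg.inv(X.T @ X)
        t_ref = np.empty(v)
        for i in range(v):
            beta = xtx_inv @ X.T @ Y[i]
            resid = Y[i] - X @ beta
            s2 = resid @ resid / (n - 3)
            t_ref[i] = beta[0] / np.sqrt(s2 * xtx_inv[0, 0])
        assert np.abs(t_pkg - t_ref).max() < 1e-8

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(50)
        y = 3.0 * x + 0.5 * rng.standard_normal(50)
        vol = self._vol(y[None, :])
        out1 = fit_glm(vol, DesignMatrix(x[:, None], ["alpha"], 2.0))["alpha"]
        out2 = fit_glm(vol, DesignMatrix(5.0 * x[:, None], ["alpha"], 2.0))["alpha"]
        assert out2.beta[0, 0, 0] == pytest.approx(out1.beta[0, 0, 0] / 5.0)
        assert out2.t[0, 0, 0] == pytest.approx(out1.t[0, 0, 0], abs=1e-10)

    def test_orthogonal_confound_leaves_beta(self):
        rng = np.random.default_rng(3)
        n = 64
        x = np.sin(2 * np.pi * np.arange(n) / 8.0)
        conf = np.cos(2 * np.pi * np.arange(n) / 8.0)
        y = 1.7 * x + 0.1 * rng.standard_normal(n)
        vol = self._vol(y[None, :])
        b1 = fit_glm(vol, DesignMatrix(x[:, None], ["alpha"], 2.0))["alpha"]
        b2 = fit_glm(vol, DesignMatrix(np.column_stack([x, conf]),
                                       ["alpha", "conf"], 2.0))["alpha"]
        assert abs(b1.beta[0, 0, 0] - b2.beta[0, 0, 0]) < 1e-10


# ---------------------------------------------------------------- MC threshold

class TestClusterThresholdMc:
    def test_matches_bruteforce_resimulation(self):
        # independent re-simulation with a different generator/seed
        grid, p, it = (10, 10, 10), 0.05, 2000
        out = cluster_threshold_mc(grid, voxel_p=p, fwhm_mm=0.0,
                                   n_iter=it, seed=0)
        rng = np.random.RandomState(1234)  # legacy generator: independent path
        z = scipy.stats.norm.isf(p)
        struct = scipy.ndimage.generate_binary_structure(3, 1)
        maxes = []
        for _ in range(it):
            noise = rng.randn(*grid)
            lab, nl = scipy.ndimage.label(noise > z, structure=struct)
            maxes.append(np.bincount(lab.ravel())[1:].max() if nl else 0)
        ref = int(np.percentile(maxes, 95.0, method="higher")) + 1
        assert abs(out.min_cluster_size - ref) <= 1

    def test_threshold_nondecreasing_in_fwhm(self):
        sizes = []
        for fwhm in (0.0, 2.0, 4.0):
            out = cluster_threshold_mc((10, 10, 10), fwhm_mm=fwhm,
                                       voxel_size_mm=3.0, n_iter=300, seed=1)
            sizes.append(out.min_cluster_size)
        assert sizes[0] <= sizes[1] <= sizes[2]

    def test_degenerate_p_rejected(self):
        with pytest.raises(ValueError, match="voxel_p"):
            cluster_threshold_mc((5, 5, 5), voxel_p=1.0, n_iter=10)


# ---------------------------------------------------------------- coupling

def _bold_setup(gain, noise_sd, seed=0, n_events=24, drift=0.0):
    fs = 250.0
    onsets = 10.0 + 10.0 * np.arange(n_events)
    markers = [Marker(int(o * fs), "stimulus", modality="visual",
                      visual_emotion="happy") for o in onsets]
    rng = np.random.default_rng(seed)
    alpha = -0.5 - np.abs(rng.standard_normal(n_events))
    mask = np.zeros((12, 12, 6), dtype=bool)
    mask[3:6, 3:6, 2:4] = True
    spec = CouplingSimSpec(coupled_mask=mask, gain=gain, noise_sd=noise_sd,
                           drift_amp=drift, seed=seed)
    vol = simulate_bold(markers, alpha, spec, grid_shape=(12, 12, 6),
                        sampling_rate_hz=fs)
    reg = build_alpha_regressor(alpha, onsets, 2.0, vol.n_volumes)
    return vol, reg, mask


class TestCouple:
    def test_noiseless_negative_coupling_r_minus_one(self):
        vol, reg, mask = _bold_setup(gain=-2.0, noise_sd=0.0)
        stats, _ = couple(vol, reg)
        assert np.allclose(stats.r[mask], -1.0, atol=1e-6)

    def test_noisy_coupling_detected_with_cluster_threshold(self):
        detected, fp_rates = [], []
        thresh = cluster_threshold_mc((12, 12, 6), voxel_p=0.05,
                                      n_iter=500, seed=0)
        for seed in range(5):
            vol, reg, mask = _bold_setup(gain=-2.0, noise_sd=1.0, seed=seed)
            stats, surviving = couple(vol, reg, voxel_p=0.05,
                                      threshold=thresh)
            neg = surviving & (stats.t < 0)
            detected.append(np.mean(neg[mask]))
            crit = scipy.stats.t.isf(0.05, stats.df)
            # one-sided negative tail, matching the coupling hypothesis
            fp_rates.append(np.mean(stats.t[~mask] < -crit))
        assert np.mean(detected) >= 0.9
        assert np.mean(fp_rates) <= 0.06

    def test_null_gain_few_clusters(self):
        thresh = cluster_threshold_mc((12, 12, 6), voxel_p=0.05,
                                      n_iter=500, seed=0)
        n_surv = []
        for seed in range(5):
            vol, reg, mask = _bold_setup(gain=0.0, noise_sd=1.0, seed=seed)
            _, surviving = couple(vol, reg, voxel_p=0.05, threshold=thresh)
            n_surv.append(surviving.sum())
        assert np.median(n_surv) <= thresh.min_cluster_size * 2

    def test_sign_recovery_across_seeds(self):
        signs = []
        for seed in range(20):
            vol, reg, mask = _bold_setup(gain=-2.0, noise_sd=1.0, seed=seed,
                                         n_events=16)
            stats, _ = couple(vol, reg)
            signs.append(np.mean(stats.t[mask] < 0))
        assert np.mean(np.asarray(signs) > 0.5) >= 0.95


# ---------------------------------------------------------------- POI alpha

@pytest.fixture(scope="module")
def inv_setup(small_leadfield):
    from alphabold.inverse import NoiseCov, build_inverse
    C = NoiseCov(np.eye(63), (-2000.0, 0.0), 1000)
    return build_inverse(small_leadfield, C, snr=5.0)


class TestPoiAlphaTimecourse:
    def _segments(self, small_leadfield, small_src, depth, n_trials=32,
                  seed=0):
        from alphabold.inverse import geodesic_patch
        from alphabold.synth import SourceSimSpec, simulate_sources
        from alphabold.timefreq import segment_trials
        from conftest import make_recording
        fs = 250.0
        occ = np.concatenate(
            [geodesic_patch(small_src, [0, -1, -0.3], 18.0, hemi=h)
             for h in ("lh", "rh")])
        fro = np.concatenate(
            [geodesic_patch(small_src, [0, 1, 0.4], 15.0, hemi=h)
             for h in ("lh", "rh")])
        spec = SourceSimSpec(source_space=small_src, occipital_patch=occ,
                             frontal_patch=fro, suppression_depth=depth,
                             seed=seed)
        onsets = 6.0 + 6.0 * np.arange(n_trials)
        markers = [Marker(int(o * fs), "stimulus", modality="visual",
                          visual_emotion="happy") for o in onsets]
        trials = [_trial(i) for i in range(n_trials)]
        n = int(fs * (onsets[-1] + 8))
        act = simulate_sources(spec, markers, fs, n)
        data = small_leadfield.matrix[:, act.vertex_ids] @ act.time_courses
        data *= 8.0 / np.sqrt(np.mean(data**2))
        rng = np.random.default_rng(seed)
        data += 1.0 * rng.standard_normal(data.shape)
        rec = make_recording(data, sfreq=fs,
                             labels=list(small_leadfield.channel_labels))
        segs, _ = segment_trials(rec, markers, trials, amp_thresh_uv=1e9)
        return segs, occ

    def test_suppression_gives_negative_values(self, small_src,
                                               small_leadfield, inv_setup):
        segs, occ = self._segments(small_leadfield, small_src, depth=0.5)
        poi = Poi(occ, np.ones(len(occ)), "occipital")
        vals = poi_alpha_timecourse(inv_setup, segs, poi)
        t, p = scipy.stats.ttest_1samp(vals, 0.0)
        assert t < 0
        assert p / 2 < 0.01  # one-sided

    def test_depth_zero_mean_near_zero(self, small_src, small_leadfield,
                                       inv_setup):
        segs, occ = self._segments(small_leadfield, small_src, depth=0.0,
                                   seed=3)
        poi = Poi(occ, np.ones(len(occ)), "occipital")
        vals = poi_alpha_timecourse(inv_setup, segs, poi)
        t, _ = scipy.stats.ttest_1samp(vals, 0.0)
        assert abs(t) < 2.0

    def test_single_vertex_degenerate_weighting(self, small_src,
                                                small_leadfield, inv_setup):
        segs, occ = self._segments(small_leadfield, small_src, depth=0.5)
        poi = Poi(np.array([occ[0]]), np.array([1.0]), "one")
        vals = poi_alpha_timecourse(inv_setup, segs, poi)
        # oracle: compute that vertex's power directly
        from alphabold.timefreq import StfftSpec, stfft_power
        kernel = inv_setup.kernel[occ[0]]
        nn = inv_setup.noise_norm[occ[0]]
        expected = []
        for i in range(segs.n_segments):
            z = (kernel @ segs.data[i]) / nn
            p, centers = stfft_power(z, segs.sampling_rate_hz,
                                     t0_ms=segs.times_ms[0], spec=StfftSpec())
            sel = (centers >= 200) & (centers <= 400)
            expected.append(p[sel].mean())
        assert np.allclose(vals, expected, atol=1e-12)
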