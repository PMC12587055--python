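"""fMRI sensitivity: nuisance regression, fALFF, INC, connectivity,
spatial ICA, the alpha-regressor GLM and phase-randomized surrogates."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal, stats

from eegfmri import sensitivity as sn
from eegfmri.hrf import hrf_kernel, single_gamma_hrf
from eegfmri.simulate import (
    BlockDesign,
    FMRISimConfig,
    demo_parcellation,
    gen_fmri_series,
)
from eegfmri.volumes import Parcellation, VolumeSeries


def white_series(shape=(10, 10, 6), nt=300, tr=1.05, seed=0, mean=0.0):
    rng = np.random.default_rng(seed)
    return VolumeSeries(mean + rng.standard_normal(shape + (nt,)), tr=tr)


class TestNuisanceRegression:
    def test_pure_drift_removed_and_frames_dropped(self):
        nt = 100
        shape = (6, 6, 4)
        # drift built to lie exactly in the post-crop cosine span
        tk = np.arange(nt - 5)
        core = np.cos(np.pi * (tk + 0.5) / (nt - 5))
        drift = np.concatenate([np.zeros(5), core])
        data = np.broadcast_to(100.0 + 5 * drift, shape + (nt,)).copy()
        vol = VolumeSeries(data, tr=1.0)
        out, motion = sn.nuisance_regress(vol, np.zeros((nt, 6)))
        assert out.n_frames == nt - 5
        assert motion.shape[0] == nt - 5
        assert out.data.std(axis=-1).max() < 1e-6
        assert abs(out.data.mean() - 100.0) < 1e-6  # mean re-added

    def test_in_band_signal_unharmed(self):
        nt, tr = 300, 1.0
        t = np.arange(nt) * tr
        sig = np.sin(2 * np.pi * 0.05 * t)  # well above the 0.01 Hz cutoff
        data = np.broadcast_to(sig, (4, 4, 2, nt)).copy()
        vol = VolumeSeries(data, tr=tr)
        out, _ = sn.nuisance_regress(vol, np.zeros((nt, 6)))
        amp = np.sqrt(2) * out.data[0, 0, 0].std()
        assert abs(amp - 1.0) < 0.02

    def test_misaligned_motion_rejected(self):
        vol = white_series(nt=50)
        with pytest.raises(ValueError):
            sn.nuisance_regress(vol, np.zeros((40, 6)))


class TestFALFF:
    def test_in_band_sinusoid_high(self):
        nt, tr = 300, 1.05
        t = np.arange(nt) * tr
        f0 = 16 / (nt * tr)  # ~0.051 Hz, bin-centered (minimal leakage)
        data = np.broadcast_to(np.sin(2 * np.pi * f0 * t), (3, 3, 2, nt)).copy()
        _, mean = sn.falff(VolumeSeries(data, tr=tr))
        assert mean >= 0.95

    def test_out_of_band_sinusoid_low(self):
        nt, tr = 300, 1.05
        t = np.arange(nt) * tr
        data = np.broadcast_to(np.sin(2 * np.pi * 0.2 * t), (3, 3, 2, nt)).copy()
        _, mean = sn.falff(VolumeSeries(data, tr=tr))
        assert mean <= 0.05

    def test_white_noise_flat_spectrum_expectation(self):
        _, mean = sn.falff(white_series(seed=1))
        assert abs(mean - 0.28) < 0.02

    def test_long_tr_uses_nyquist_with_warning(self):
        vol = white_series(nt=85, tr=3.52, seed=2)
        with pytest.warns(UserWarning):
            values, mean = sn.falff(vol)
        assert 0 < mean < 1

    def test_constant_voxel_excluded(self):
        vol = white_series(shape=(3, 3, 1), nt=100, seed=3)
        vol.data[0, 0, 0] = 5.0
        values, mean = sn.falff(vol)
        assert np.isnan(values).sum() == 1
        assert np.isfinite(mean)

    def test_range_invariant(self):
        values, _ = sn.falff(white_series(seed=4))
        ok = values[np.isfinite(values)]
        assert np.all((ok >= 0) & (ok <= 1))


class TestINC:
    def two_roi_parc(self, shape=(10, 10, 2)):
        labels = np.zeros(shape, dtype=np.int16)
        labels[:5] = 1
        labels[5:] = 2
        return Parcellation(labels, names={1: "A", 2: "B"}, background_label=0)

    def test_identical_voxels_unity(self):
        parc = self.two_roi_parc()
        tc = np.random.default_rng(0).standard_normal(200)
        data = np.broadcast_to(tc, (10, 10, 2, 200)).copy()
        val, _ = sn.inc(VolumeSeries(data, tr=1.0), parc, "A")
        assert abs(val - 1.0) < 1e-9

    def test_iid_noise_self_inclusion_bias(self):
        # N iid voxels: E[corr(voxel, ROI mean)] ~ 1/sqrt(N)
        labels = np.zeros((10, 10, 1), dtype=np.int16)
        labels[:] = 1
        parc = Parcellation(labels, names={1: "A"}, background_label=0)
        vals = []
        for seed in range(5):
            vol = white_series(shape=(10, 10, 1), nt=400, seed=seed)
            v, _ = sn.inc(vol, parc, "A")
            vals.append(v)
        assert abs(np.mean(vals) - 0.1) < 0.03

    def test_shared_signal_closed_form(self):
        # voxel = s*latent + sigma*noise, all in-band -> s/sqrt(s^2+sigma^2)
        rng = np.random.default_rng(5)
        nt, tr = 400, 1.0
        sos = signal.butter(2, [0.01, 0.08], btype="bandpass", fs=1.0, output="sos")
        latent = signal.sosfiltfilt(sos, rng.standard_normal(nt))
        latent /= latent.std()
        nvox = 200
        noise = signal.sosfiltfilt(sos, rng.standard_normal((nvox, nt)), axis=1)
        noise /= noise.std(axis=1, keepdims=True)
        s, sig = 3.0, 2.0
        data = (s * latent + sig * noise).reshape(20, 10, 1, nt)
        labels = np.ones((20, 10, 1), dtype=np.int16)
        parc = Parcellation(labels, names={1: "A"}, background_label=0)
        val, _ = sn.inc(VolumeSeries(data, tr=tr), parc, "A")
        assert abs(val - s / np.hypot(s, sig)) < 0.04


class TestConnectivity:
    def test_diagonal_and_symmetry(self):
        cfg = FMRISimConfig(seed=6)
        vol, parc, gt = gen_fmri_series(cfg)
        conn = sn.pairwise_connectivity(vol, parc, motion=gt.motion_params)
        M = conn.to_numpy()
        assert np.allclose(np.diag(M), 1.0)
        assert np.allclose(M, M.T)
        assert np.all(np.abs(M) <= 1 + 1e-12)

    def test_two_roi_shared_latent_closed_form(self):
        # r = a*b*s^2 / sqrt((a^2 s^2 + sig^2)(b^2 s^2 + sig^2))
        rng = np.random.default_rng(7)
        nt, tr = 600, 1.0
        sos = signal.butter(2, [0.015, 0.07], btype="bandpass", fs=1.0, output="sos")

        def bl(x):
            y = signal.sosfiltfilt(sos, x, axis=-1)
            return y / y.std(axis=-1, keepdims=True)

        latent = bl(rng.standard_normal(nt))
        a, b, s, sig = 1.0, 0.6, 2.0, 1.5
        shape = (10, 10, 2)
        labels = np.zeros(shape, dtype=np.int16)
        labels[:5] = 1
        labels[5:] = 2
        parc = Parcellation(labels, names={1: "A", 2: "B"}, background_label=0)
        data = np.empty(shape + (nt,))
        nv = 100
        data[:5] = (a * s * latent + sig * bl(rng.standard_normal((nv, nt)))).reshape(5, 10, 2, nt)
        data[5:] = (b * s * latent + sig * bl(rng.standard_normal((nv, nt)))).reshape(5, 10, 2, nt)
        conn = sn.pairwise_connectivity(
            VolumeSeries(data, tr=tr), parc, tissue_rois=(), band=(0.015, 0.07)
        )
        # ROI means average away most voxel noise: sig_eff = sig/sqrt(nv)
        se = sig / np.sqrt(nv)
        expected = a * b * s**2 / np.sqrt((a**2 * s**2 + se**2) * (b**2 * s**2 + se**2))
        assert abs(conn.loc["A", "B"] - expected) < 0.1

    def test_group_compare_null_calibration(self):
        rng = np.random.default_rng(8)
        n_roi, n_sub = 6, 8
        names = [f"r{i}" for i in range(n_roi)]
        frac = []
        for rep in range(20):
            mats_a, mats_b = [], []
            for s in range(n_sub):
                M = np.corrcoef(rng.standard_normal((n_roi, 80)))
                N = np.corrcoef(rng.standard_normal((n_roi, 80)))
                mats_a.append(pd.DataFrame(M, index=names, columns=names))
                mats_b.append(pd.DataFrame(N, index=names, columns=names))
            _, q = sn.group_compare(mats_a, mats_b)
            iu = np.triu_indices(n_roi, 1)
            frac.append((q.to_numpy()[iu] < 0.05).mean())
        assert np.mean(frac) <= 0.05

    def test_too_few_subjects_refused(self):
        m = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError):
            sn.group_compare([m, m], [m, m])


class TestSpatialICA:
    def planted(self, seed=0):
        rng = np.random.default_rng(seed)
        shape, nt = (12, 12, 6), 150
        nv = np.prod(shape)
        # sparse blobs: spatial ICA's model is super-Gaussian maps
        maps = np.zeros((3,) + shape)
        maps[0, 1:5, 1:5, 1:4] = 1.0  # "visual" blob
        maps[1, 7:11, 7:11, 2:5] = 1.0
        maps[2, 1:5, 7:11, 1:4] = 1.0
        tcs = rng.standard_normal((3, nt))
        data = np.tensordot(tcs.T, maps.reshape(3, -1), axes=1).T.reshape(shape + (nt,))
        data = 5 * data + rng.standard_normal(shape + (nt,))
        return VolumeSeries(data, tr=1.0), maps

    def test_planted_sources_recovered(self):
        vol, maps = self.planted()
        zmaps, tcs, mask = sn.spatial_ica(vol, n_components=6, random_state=0)
        for m in maps:
            _, score, _ = sn.match_network(zmaps, m[mask])
            assert score >= 0.9

    def test_template_matching_and_threshold(self):
        vol, maps = self.planted(seed=1)
        zmaps, _, mask = sn.spatial_ica(vol, n_components=6, random_state=0)
        idx, score, _ = sn.match_network(zmaps, maps[0][mask])
        best = np.abs(zmaps[idx]) > 1.4  # display-threshold rule
        truth = maps[0][mask] > 0
        jaccard = (best & truth).sum() / (best | truth).sum()
        assert jaccard > 0.5


class TestDesign:
    def test_constant_alpha_degenerate(self):
        blocks = BlockDesign(16, 16, 3)
        with pytest.warns(UserWarning):
            d = sn.build_design(blocks, np.ones(96), 1.0, 1.0, 96)
        assert d.degenerate

    def test_alpha_orthogonal_to_sticks(self):
        blocks = BlockDesign(16, 16, 3)
        rng = np.random.default_rng(0)
        d = sn.build_design(blocks, 1 + 0.3 * rng.standard_normal(96), 1.0, 1.0, 96)
        alpha = d.frame["alpha"].to_numpy()
        for c in d.stick_columns:
            assert abs(alpha @ d.frame[c].to_numpy()) < 1e-8

    def test_hrf_shape(self):
        t = np.linspace(0, 30, 3001)
        h = single_gamma_hrf(t)
        assert h.sum() > 0
        peak = t[np.argmax(h)]
        assert 4.0 <= peak <= 7.0
        # FWHM close to the requested 5.2 s
        above = t[h >= 0.5]
        assert abs((above[-1] - above[0]) - 5.2) < 0.1


class TestGLM:
    def glm_inputs(self, beta, seed=0, nt=300):
        cfg = FMRISimConfig(alpha_beta=beta, seed=seed, n_volumes=nt,
                            drift_amp=1.0, motion_amp=0.1)
        blocks = BlockDesign()
        vol, parc, gt = gen_fmri_series(cfg, blocks=blocks)
        clean, motion = sn.nuisance_regress(vol, gt.motion_params)
        design = sn.build_design(
            blocks, gt.extras["alpha_envelope_frames"][5:], 1.0 / cfg.tr,
            cfg.tr, clean.n_frames, motion=motion,
        )
        return clean, parc, design, gt

    def test_null_beta_calibrated(self):
        # pure white-noise voxels with a real design: Z approx N(0, 1)
        rng = np.random.default_rng(1)
        blocks = BlockDesign()
        nt = 320
        design = sn.build_design(blocks, 1 + 0.3 * rng.standard_normal(nt),
                                 1.0, 1.0, nt)
        vol = VolumeSeries(rng.standard_normal((10, 10, 4, nt)), tr=1.0)
        res = sn.fit_glm(vol, design)
        assert abs(res.alpha_z.mean()) < 0.1
        assert 0.9 < res.alpha_z.std() < 1.1

    def test_negative_coupling_yields_negative_visual_z(self):
        clean, parc, design, _ = self.glm_inputs(beta=3.0)
        res = sn.fit_glm(clean, design, parc=parc)
        assert res.roi_summary.loc["visual", "mean_z"] < -3.0
        for roi in ("somatomotor", "white_matter", "csf"):
            assert res.roi_summary.loc[roi, "mean_z"] > res.roi_summary.loc["visual", "mean_z"] + 2

    def test_z_monotone_in_effect_size(self):
        zs = []
        for beta in (1.0, 2.5, 5.0):
            clean, parc, design, _ = self.glm_inputs(beta=beta, seed=3)
            res = sn.fit_glm(clean, design, parc=parc)
            zs.append(res.roi_summary.loc["visual", "mean_z"])
        assert zs[0] > zs[1] > zs[2]  # increasingly negative


class TestSurrogates:
    def test_planted_coupling_beats_surrogates(self):
        cfg = FMRISimConfig(alpha_beta=3.0, seed=4)
        blocks = BlockDesign()
        vol, parc, gt = gen_fmri_series(cfg, blocks=blocks)
        clean, motion = sn.nuisance_regress(vol, gt.motion_params)
        design = sn.build_design(
            blocks, gt.extras["alpha_envelope_frames"][5:], 1.0 / cfg.tr,
            cfg.tr, clean.n_frames, motion=motion,
        )
        res = sn.surrogate_gain(clean, design, n_trials=100, seed=0,
                                parc=parc, roi="visual")
        assert res.exceedance_probability <= 0.01
        assert res.true_gain > np.percentile(res.surrogate_gains, 99)

    def test_null_exceedance_spread(self):
        # without coupling the exceedance probability is not concentrated
        rng = np.random.default_rng(5)
        blocks = BlockDesign()
        nt = 320
        probs = []
        for seed in range(10):
            design = sn.build_design(
                blocks, 1 + 0.3 * np.random.default_rng(seed).standard_normal(nt),
                1.0, 1.0, nt,
            )
            vol = VolumeSeries(
                np.random.default_rng(100 + seed).standard_normal((6, 6, 3, nt)),
                tr=1.0,
            )
            res = sn.surrogate_gain(vol, design, n_trials=40, seed=seed)
            probs.append(res.exceedance_probability)
        probs = np.array(probs)
        assert 0.15 < probs.mean() < 0.85
        assert probs.max() - probs.min() > 0.3
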