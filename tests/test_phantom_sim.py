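"""Phantom generator: gamma-variate model, truth consistency, datasets."""

import numpy as np
import pytest
from scipy.special import gamma as gamma_fn

import scintiroi as sr
from scintiroi.errors import ConfigError
from scintiroi.phantom_sim import PhantomConfig, StructureSpec, load_truth, save_truth


class TestGammaVariate:
    def test_zero_at_and_before_onset(self):
        times = np.array([0.0, 2.0, 5.0, 5.0001, 10.0])
        out = sr.gamma_variate_tac(5.0, 3.0, 1.0, 2.0, times)
        assert np.all(out[:3] == 0)
        assert out[3] > 0 and out[4] > 0

    @pytest.mark.parametrize("t0,alpha,beta", [(5.0, 3.0, 1.0), (2.0, 2.5, 0.8),
                                               (0.0, 4.0, 2.0)])
    def test_peak_at_t0_plus_alpha_beta(self, t0, alpha, beta):
        # oracle: dense numeric argmax
        times = np.linspace(t0, t0 + 40 * beta, 40001)
        out = sr.gamma_variate_tac(t0, alpha, beta, 1.0, times)
        t_peak = times[np.argmax(out)]
        step = times[1] - times[0]
        assert abs(t_peak - (t0 + alpha * beta)) <= step

    @pytest.mark.parametrize("alpha,beta,K", [(3.0, 1.0, 2.0), (2.0, 0.8, 5.0)])
    def test_integral_matches_closed_form(self, alpha, beta, K):
        # oracle: K * beta**(alpha+1) * Gamma(alpha+1)
        t0 = 4.0
        times = np.linspace(t0, t0 + 50 * beta, 20001)
        out = sr.gamma_variate_tac(t0, alpha, beta, K, times)
        num = np.trapezoid(out, times)
        closed = K * beta ** (alpha + 1) * gamma_fn(alpha + 1)
        assert abs(num - closed) / closed < 0.005
        assert sr.gamma_variate_auc(alpha, beta, K) == pytest.approx(closed)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigError):
            sr.gamma_variate_tac(0, -1.0, 1.0, 1.0, np.arange(5.0))
        with pytest.raises(ConfigError):
            sr.gamma_variate_tac(0, 1.0, 0.0, 1.0, np.arange(5.0))
        with pytest.raises(ConfigError):
            sr.gamma_variate_tac(0, 1.0, 1.0, 1.0, np.array([2.0, 1.0]))

    def test_scale_for_peak_gives_requested_peak(self):
        K = sr.scale_for_peak(50.0, 3.0, 1.2)
        peak_val = sr.gamma_variate_tac(0.0, 3.0, 1.2, K, np.array([3.6]))[0]
        assert peak_val == pytest.approx(50.0, rel=1e-9)


def _single_structure_config(**kwargs):
    pa = StructureSpec("PA", (30, 30), (6, 5), t0=6.0, alpha=3.0, beta=0.8,
                       peak=100.0)
    defaults = dict(image_size=(64, 64), n_frames=60, mode="IMP",
                    structures=[pa], background=0.0, noise=False, seed=0)
    defaults.update(kwargs)
    return PhantomConfig(**defaults)


class TestMakePhantom:
    def test_noiseless_frame_totals_are_area_times_tac(self):
        cfg = _single_structure_config()
        series, truth = sr.make_phantom(cfg)
        area = truth.masks["PA"].sum()
        p = truth.params["PA"]
        tac = sr.gamma_variate_tac(p["t0"], p["alpha"], p["beta"], p["K"],
                                   series.times)
        np.testing.assert_allclose(series.frames.sum(axis=(1, 2)), area * tac,
                                   rtol=1e-10)

    def test_noiseless_conservation_with_background(self, imp_noiseless):
        series, truth = imp_noiseless
        n_px = np.prod(series.image_shape)
        expect = np.full(series.n_frames, truth.background * n_px)
        for name, p in truth.params.items():
            tac = sr.gamma_variate_tac(p["t0"], p["alpha"], p["beta"], p["K"],
                                       series.times)
            expect += truth.masks[name].sum() * tac
        np.testing.assert_allclose(series.frames.sum(axis=(1, 2)), expect,
                                   rtol=1e-9)

    def test_same_seed_is_deterministic(self):
        a, _ = sr.make_phantom(sr.imp_config(seed=5, image_size=64))
        b, _ = sr.make_phantom(sr.imp_config(seed=5, image_size=64))
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_poisson_mean_matches_noiseless(self):
        # oracle: Poisson sample mean -> noiseless value, 200 replicates
        cfg = _single_structure_config(image_size=(32, 32), background=2.0)
        cfg.structures[0] = StructureSpec("PA", (15, 15), (5, 4), t0=3.0,
                                          alpha=3.0, beta=0.8, peak=40.0)
        clean, _ = sr.make_phantom(cfg)
        t = int(np.argmax(clean.frames.sum(axis=(1, 2))))
        reps = []
        for s in range(200):
            noisy, _ = sr.make_phantom(
                PhantomConfig(**{**cfg.__dict__, "noise": True, "seed": s})
            )
            reps.append(noisy.frames[t])
        reps = np.stack(reps)
        mean = reps.mean(axis=0)
        se = np.sqrt(np.maximum(clean.frames[t], 1e-12) / 200)
        z = np.abs(mean - clean.frames[t]) / se
        # per-pixel 3 SE check; allow the expected Gaussian tail fraction
        assert (z <= 3).mean() >= 0.99
        assert abs(mean.mean() - clean.frames[t].mean()) <= 3 * se.mean() / np.sqrt(
            mean.size
        )

    def test_truth_centers_are_mask_centroids(self, ecd_noiseless):
        _, truth = ecd_noiseless
        for name, mask in truth.masks.items():
            rr, cc = np.nonzero(mask)
            assert truth.centers[name][0] == pytest.approx(rr.mean(), abs=0.5)
            assert truth.centers[name][1] == pytest.approx(cc.mean(), abs=0.5)

    def test_overlapping_pa_aao_rejected(self):
        cfg = _single_structure_config()
        cfg.structures.append(
            StructureSpec("AAo", (30, 33), (5, 5), t0=15.0, alpha=3.0,
                          beta=1.3, peak=60.0)
        )
        with pytest.raises(ConfigError, match="disjoint"):
            sr.make_phantom(cfg)

    def test_out_of_bounds_structure_rejected(self):
        cfg = _single_structure_config()
        cfg.structures[0] = StructureSpec("PA", (2, 30), (6, 5), t0=6.0,
                                          alpha=3.0, beta=0.8, peak=10.0)
        with pytest.raises(ConfigError, match="bounds"):
            sr.make_phantom(cfg)

    def test_slow_injection_widens_and_conserves_activity(self):
        fast = _single_structure_config()
        slow = _single_structure_config(injection_speed=3.0)
        sf, tf = sr.make_phantom(fast)
        ss, ts = sr.make_phantom(slow)
        assert ts.slow and not tf.slow
        # activity (analytic per-pixel AUC) is conserved, peak is lower
        assert ts.pixel_auc["PA"] == pytest.approx(tf.pixel_auc["PA"], rel=1e-9)
        assert ss.frames.max() < sf.frames.max()


class TestMakeDataset:
    def test_case_count_and_seed_contract(self):
        a = sr.make_dataset(6, seed=1, image_size=64)
        b = sr.make_dataset(6, seed=1, image_size=64)
        c = sr.make_dataset(6, seed=2, image_size=64)
        assert len(a) == 6
        np.testing.assert_array_equal(a[0][0].frames, b[0][0].frames)
        assert not np.array_equal(a[0][0].frames, c[0][0].frames)
        # geometry varies between cases
        assert a[0][1].pa_center != a[1][1].pa_center

    def test_slow_fraction_flag_count(self):
        ranges = sr.DatasetRanges(slow_fraction=0.2)
        cases = sr.make_dataset(20, ranges=ranges, seed=3, image_size=64,
                                noise=False)
        n_slow = sum(truth.slow for _, truth in cases)
        assert n_slow == 4

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ConfigError):
            sr.make_dataset(2, ranges=sr.DatasetRanges(slow_fraction=1.5))
        with pytest.raises(ConfigError):
            sr.make_dataset(0)

    def test_truth_roundtrip(self, tmp_path, imp_noiseless):
        _, truth = imp_noiseless
        save_truth(truth, tmp_path / "t")
        back = load_truth(tmp_path / "t")
        assert back.pa_center == pytest.approx(truth.pa_center)
        assert back.slow == truth.slow
        for name in truth.masks:
            np.testing.assert_array_equal(back.masks[name], truth.masks[name])
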