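"""NFRET pipeline: preprocessing, SBT modelling, normalization, mixture fits."""

import math

import numpy as np
import pytest

from fastfuse.pixel_fret import (
    ChannelImage,
    FretImageSet,
    Histogram,
    NFRETImage,
    SBTModel,
    colocalization_coefficients,
    compute_nfret,
    estimate_sbt,
    fit_nfret_gaussians,
    nfret_histogram,
    preprocess,
    summarize_condition,
    summarize_image,
    NFRETSummary,
)
from fastfuse.synthetic import FretSimConfig, simulate_fret_images

from conftest import make_imageset


def make_control_stack(source, intensities, ratio_fn, noise_sd=0.0, seed=0, shape=(64, 64)):
    """Single-fluorophore control: I_fret = bt(I)*I (+ noise) exactly."""
    rng = np.random.default_rng(seed)
    src = rng.choice(intensities, size=shape).astype(float)
    fret = ratio_fn(src) * src
    if noise_sd > 0:
        fret = np.clip(fret + rng.normal(0, noise_sd, shape), 0, None)
    blank = np.zeros(shape)
    if source == "donor":
        return make_imageset(src, blank, fret)
    return make_imageset(blank, src, fret)


class TestPreprocess:
    def test_uniform_image_minus_own_background_is_zero(self, uniform_set):
        out = preprocess(uniform_set, background=50.0, blur_sigma=0.0)
        assert np.all(out.donor.pixels == 0.0)
        assert np.all(out.fret.pixels == 0.0)

    def test_zero_background_zero_sigma_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(10, 50, (32, 32))
        s = make_imageset(img, img, img)
        out = preprocess(s, background=("constant", 0.0), blur_sigma=0.0)
        np.testing.assert_array_equal(out.donor.pixels, img)

    def test_blur_conserves_total_intensity_of_interior_spot(self):
        img = np.zeros((64, 64))
        img[32, 32] = 1000.0
        s = make_imageset(img, img, img)
        out = preprocess(s, background=("constant", 0.0), blur_sigma=1.0)
        assert out.donor.pixels.sum() == pytest.approx(1000.0, rel=1e-3)

    def test_region_background(self):
        img = np.full((32, 32), 7.0)
        img[:4, :4] = 3.0
        s = make_imageset(img, img, img)
        out = preprocess(s, background=(0, 4, 0, 4), blur_sigma=0.0)
        assert out.donor.pixels[16, 16] == pytest.approx(4.0)

    def test_negative_sigma_rejected(self, uniform_set):
        with pytest.raises(ValueError):
            preprocess(uniform_set, blur_sigma=-1.0)

    def test_bad_percentile_rejected(self, uniform_set):
        with pytest.raises(ValueError):
            preprocess(uniform_set, background=75.0)


class TestEstimateSBT:
    def test_constant_ratio_recovered_exactly(self):
        stack = make_control_stack("donor", np.arange(60, 400), lambda i: 0.15)
        m = estimate_sbt([stack], "donor", kind="exponential")
        assert m.params[0] == pytest.approx(0.15, abs=1e-6)
        assert abs(m.params[1]) < 1e-4

    def test_zero_fret_signal_gives_zero_ratio(self):
        stack = make_control_stack("acceptor", np.arange(60, 400), lambda i: 0.0)
        m = estimate_sbt([stack], "acceptor", kind="constant")
        assert m.params[0] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_exponential_ratio_recovered_within_ten_percent(self, seed):
        bt = lambda i: 0.05 * np.exp(0.002 * i)
        stack = make_control_stack(
            "donor", np.arange(60, 600), bt, noise_sd=1.0, seed=seed, shape=(128, 128)
        )
        m = estimate_sbt([stack], "donor", kind="exponential")
        assert m.params[0] == pytest.approx(0.05, rel=0.10)
        assert m.params[1] == pytest.approx(0.002, rel=0.10)

    def test_too_few_pixels_rejected(self):
        stack = make_control_stack("donor", np.arange(60, 400), lambda i: 0.15, shape=(16, 16))
        with pytest.raises(ValueError):
            estimate_sbt([stack], "donor")

    def test_linear_kind(self):
        stack = make_control_stack("donor", np.arange(60, 400), lambda i: 0.1 + 1e-4 * i)
        m = estimate_sbt([stack], "donor", kind="linear")
        assert m.params[0] == pytest.approx(0.1, rel=1e-6)
        assert m.params[1] == pytest.approx(1e-4, rel=1e-6)


class TestComputeNfret:
    def test_simple_arithmetic_no_sbt(self):
        s = make_imageset(np.full((16, 16), 9.0), np.full((16, 16), 4.0), np.full((16, 16), 6.0))
        nf = compute_nfret(s, SBTModel.zero("donor"), SBTModel.zero("acceptor"), min_intensity=1.0)
        assert nf.values[8, 8] == pytest.approx(6.0 / math.sqrt(36.0))

    def test_constant_sbt_correction_hand_value(self):
        s = make_imageset(np.full((16, 16), 20.0), np.full((16, 16), 10.0), np.full((16, 16), 10.0))
        bt_d = SBTModel("donor", "constant", (0.2, 0.0))
        bt_a = SBTModel("acceptor", "constant", (0.3, 0.0))
        nf = compute_nfret(s, bt_d, bt_a, min_intensity=1.0)
        # Fc = 10 - 4 - 3 = 3; NFRET = 3 / sqrt(200)
        assert nf.values[0, 0] == pytest.approx(3.0 / math.sqrt(200.0))

    def test_gain_invariance(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(20, 200, (32, 32))
        a = rng.uniform(20, 200, (32, 32))
        f = 0.3 * np.sqrt(d * a) + 0.15 * d + 0.1 * a
        bt_d = SBTModel("donor", "constant", (0.15, 0.0))
        bt_a = SBTModel("acceptor", "constant", (0.1, 0.0))
        base = compute_nfret(make_imageset(d, a, f), bt_d, bt_a, min_intensity=1.0)
        for gain in (0.25, 7.0):
            scaled = compute_nfret(
                make_imageset(gain * d, gain * a, gain * f), bt_d, bt_a, min_intensity=1.0
            )
            rel = np.abs(scaled.values - base.values) / np.abs(base.values)
            assert np.nanmax(rel) < 1e-9

    def test_low_intensity_pixels_masked(self):
        d = np.full((16, 16), 100.0)
        d[0, 0] = 1.0
        s = make_imageset(d, np.full((16, 16), 100.0), np.full((16, 16), 10.0))
        nf = compute_nfret(s, SBTModel.zero("donor"), SBTModel.zero("acceptor"), min_intensity=5.0)
        assert not nf.valid_mask[0, 0]
        assert nf.values[0, 0] == 0.0

    def test_negative_corrected_fret_floored(self):
        s = make_imageset(np.full((16, 16), 100.0), np.full((16, 16), 100.0), np.full((16, 16), 5.0))
        bt_d = SBTModel("donor", "constant", (0.5, 0.0))
        nf = compute_nfret(s, bt_d, SBTModel.zero("acceptor"), min_intensity=1.0)
        assert np.all(nf.values >= 0.0)

    def test_mismatched_channel_dimensions_rejected(self):
        with pytest.raises(ValueError):
            make_imageset(np.zeros((32, 32)), np.zeros((32, 32)), np.zeros((16, 16)))


class TestHistogram:
    def _img(self, values, mask=None):
        values = np.asarray(values, dtype=float)
        mask = np.ones_like(values, dtype=bool) if mask is None else mask
        return NFRETImage(values=values, valid_mask=mask)

    def test_single_value_occupies_single_bin(self):
        h = nfret_histogram(self._img(np.full((16, 16), 1.0)))
        assert np.count_nonzero(h.counts) == 1
        idx = np.argmax(h.counts)
        assert h.bin_centers[idx] - h.bin_width / 2 <= 1.0 < h.bin_centers[idx] + h.bin_width / 2

    def test_default_layout_is_8bit_over_0_to_10(self):
        h = nfret_histogram(self._img(np.full((16, 16), 0.5)))
        assert len(h.counts) == 256
        assert h.bin_width == pytest.approx(0.03906, abs=5e-6)
        assert h.display_range == (0.0, 10.0)

    def test_out_of_range_values_saturate_top_bin(self):
        vals = np.full((16, 16), 50.0)  # far above range
        h = nfret_histogram(self._img(vals))
        assert h.counts[-1] == vals.size

    def test_counts_conserved(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 12, (64, 64))
        mask = rng.uniform(size=(64, 64)) > 0.3
        h = nfret_histogram(NFRETImage(values=vals, valid_mask=mask))
        assert h.counts.sum() == mask.sum()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            nfret_histogram(NFRETImage(values=np.zeros((16, 16)),
                                       valid_mask=np.zeros((16, 16), dtype=bool)))


def _gauss(x, a, m, s):
    return a * np.exp(-0.5 * ((x - m) / s) ** 2)


class TestGaussianMixtureFit:
    def _hist_from_curve(self, fn):
        centers = (np.arange(256) + 0.5) * (10.0 / 256.0)
        counts = fn(centers)
        return Histogram(bin_centers=centers, counts=counts,
                         bin_width=10.0 / 256.0, display_range=(0.0, 10.0))

    def test_exact_single_gaussian_fits_perfectly(self):
        h = self._hist_from_curve(lambda x: _gauss(x, 500.0, 2.0, 0.4))
        cands, best = fit_nfret_gaussians(h)
        k1 = [c for c in cands if c.k == 1][0]
        assert k1.r_squared == pytest.approx(1.0, abs=1e-6)
        assert best.r_squared >= k1.r_squared

    def test_exact_two_component_mixture_attains_r2(self):
        h = self._hist_from_curve(
            lambda x: _gauss(x, 400.0, 0.8, 0.15) + _gauss(x, 150.0, 3.0, 0.5)
        )
        cands, best = fit_nfret_gaussians(h)
        by_k = {c.k: c for c in cands}
        assert by_k[2].r_squared >= 0.999

    def test_sampled_gaussian_mean_recovered(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(2.0, 0.4, 100_000)
        img = NFRETImage(values=vals.reshape(250, 400),
                         valid_mask=np.ones((250, 400), dtype=bool))
        summary = summarize_image(img)
        assert summary.mnfret == pytest.approx(2.0, abs=0.02)

    def test_bimodal_dominant_component(self):
        rng = np.random.default_rng(6)
        vals = np.concatenate([
            rng.normal(0.5, 0.1, 70_000), rng.normal(3.0, 0.3, 30_000)
        ])
        img = NFRETImage(values=vals.reshape(250, 400),
                         valid_mask=np.ones((250, 400), dtype=bool))
        summary = summarize_image(img)
        assert summary.best_fit.k >= 2
        assert summary.mnfret == pytest.approx(0.5, abs=0.05)

    def test_too_few_nonzero_bins_rejected(self):
        centers = (np.arange(256) + 0.5) * (10.0 / 256.0)
        counts = np.zeros(256)
        counts[3:8] = 10.0
        h = Histogram(centers, counts, 10.0 / 256.0, (0.0, 10.0))
        with pytest.raises(ValueError):
            fit_nfret_gaussians(h)

    def test_narrow_distribution_pixel_mean_fallback(self):
        vals = np.full((32, 32), 0.05)  # single occupied bin
        img = NFRETImage(values=vals, valid_mask=np.ones((32, 32), dtype=bool))
        with pytest.raises(ValueError):
            summarize_image(img)
        s = summarize_image(img, on_narrow="pixel_mean")
        assert s.best_fit is None
        assert s.mnfret == pytest.approx(0.05)
        assert s.pixel_amplitude == vals.size


def _fake_summary(mnfret, amplitude):
    return NFRETSummary(
        histogram=None, candidate_fits=[], best_fit=None,
        mnfret=mnfret, pixel_amplitude=amplitude,
    )


class TestSummarizeCondition:
    def test_identical_images(self):
        ss = {"exp1": [_fake_summary(0.3, 100.0) for _ in range(10)],
              "exp2": [_fake_summary(0.3, 100.0) for _ in range(10)]}
        cond = summarize_condition(ss)
        assert cond.mnfret_mean == pytest.approx(0.3)
        assert cond.mnfret_median == pytest.approx(0.3)
        assert cond.mnfret_sd == pytest.approx(0.0, abs=1e-12)
        assert cond.amplitude_se == 0.0
        assert cond.n_images == 20

    def test_propagated_se_matches_hand_formula(self):
        e1 = [_fake_summary(0.2, a) for a in (90.0, 110.0, 100.0)]
        e2 = [_fake_summary(0.4, a) for a in (200.0, 180.0, 220.0)]
        cond = summarize_condition({"exp1": e1, "exp2": e2})
        se1 = np.std([90, 110, 100], ddof=1) / math.sqrt(3)
        se2 = np.std([200, 180, 220], ddof=1) / math.sqrt(3)
        assert cond.amplitude_se == pytest.approx(math.sqrt(se1**2 + se2**2) / 2)
        assert cond.mnfret_mean == pytest.approx(0.3)  # mean of experiment means

    def test_single_image_rejected(self):
        with pytest.raises(ValueError):
            summarize_condition({"exp1": [_fake_summary(0.3, 1.0)]})

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_condition({})


class TestColocalization:
    def test_identical_images(self):
        rng = np.random.default_rng(7)
        img = rng.uniform(0, 100, (32, 32))
        a = ChannelImage(img, "donor")
        b = ChannelImage(img.copy(), "acceptor")
        r = colocalization_coefficients(a, b)
        assert r.pearson == pytest.approx(1.0)
        assert r.manders_m1 == pytest.approx(1.0)
        assert r.manders_m2 == pytest.approx(1.0)

    def test_disjoint_puncta(self):
        a_img = np.zeros((32, 32)); a_img[4:8, 4:8] = 100.0
        b_img = np.zeros((32, 32)); b_img[20:24, 20:24] = 100.0
        r = colocalization_coefficients(
            ChannelImage(a_img, "donor"), ChannelImage(b_img, "acceptor"),
            threshold_a=1.0, threshold_b=1.0,
        )
        assert r.manders_m1 == 0.0
        assert r.manders_m2 == 0.0

    def test_constant_images_report_undefined_pearson(self):
        a = ChannelImage(np.full((32, 32), 5.0), "donor")
        b = ChannelImage(np.full((32, 32), 5.0), "acceptor")
        r = colocalization_coefficients(a, b, threshold_a=1.0, threshold_b=1.0)
        assert r.pearson is None
        assert "undefined" in r.note

    def test_coclustered_exceeds_segregated(self):
        cfg = FretSimConfig(shape=(128, 128))
        co, _ = simulate_fret_images("interacting", n_images=1, config=cfg, seed=8)
        seg, _ = simulate_fret_images("non_interacting", n_images=1, config=cfg, seed=9)
        r_co = colocalization_coefficients(co[0].donor, co[0].acceptor)
        r_seg = colocalization_coefficients(seg[0].donor, seg[0].acceptor)
        assert r_co.pearson > r_seg.pearson
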