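import numpy as np
import pytest

from vesselab.abstraction import (
    BilateralParams,
    LayerDecomposition,
    QuantizationParams,
    bilateral,
    extract_detail,
    extract_large_scale,
    filter_pipeline,
    quantize_luminance,
    recombine,
)
from vesselab.colorspaces import (
    NormalizedColorImage,
    gaussian_to_normalized,
    rgb_to_gaussian,
    rgb_to_ycbcr,
)
from vesselab.config import load_config


def naive_bilateral(f, p):
    """Per-pixel double-loop evaluation of the normalized bilateral form."""
    h, w = f.shape
    r = p.window_radius
    pad = np.pad(f, r, mode="reflect")
    out = np.empty_like(f)
    for y in range(h):
        for x in range(w):
            acc = den = 0.0
            fc = f[y, x]
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    fn = pad[y + r + dy, x + r + dx]
                    wgt = np.exp(-(dx * dx + dy * dy) / (2 * p.sigma_s**2)) * np.exp(
                        -((fn - fc) ** 2) / (2 * p.sigma_r**2)
                    )
                    acc += wgt * fn
                    den += wgt
            out[y, x] = acc / den
    return out


def gaussian_convolution(f, sigma_s, r):
    """Truncated spatial-Gaussian convolution (range kernel disabled)."""
    pad = np.pad(f, r, mode="reflect")
    h, w = f.shape
    num = np.zeros_like(f)
    den = 0.0
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            wgt = np.exp(-(dx * dx + dy * dy) / (2 * sigma_s**2))
            num += wgt * pad[r + dy : r + dy + h, r + dx : r + dx + w]
            den += wgt
    return num / den


class TestBilateral:
    def test_identity_on_constants(self):
        img = np.full((16, 16), 0.42)
        out = bilateral(img, BilateralParams(sigma_s=2, sigma_r=0.1, window_radius=4))
        assert np.allclose(out, 0.42, atol=1e-12)

    @pytest.mark.parametrize(
        "shape,params",
        [
            ((12, 12), BilateralParams(sigma_s=1.5, sigma_r=0.08, window_radius=3)),
            ((24, 18), BilateralParams(sigma_s=2.0, sigma_r=0.15, window_radius=4)),
            ((48, 48), BilateralParams(sigma_s=3.0, sigma_r=0.1, window_radius=5)),
        ],
    )
    def test_matches_naive_double_loop(self, rng, shape, params):
        img = rng.random(shape)
        assert np.allclose(bilateral(img, params), naive_bilateral(img, params),
                           atol=1e-9)

    def test_large_sigma_r_reduces_to_gaussian_convolution(self, rng):
        img = rng.random((20, 20))
        p = BilateralParams(sigma_s=2.0, sigma_r=1e4, window_radius=5)
        ref = gaussian_convolution(img, 2.0, 5)
        assert np.allclose(bilateral(img, p), ref, atol=1e-6)

    def test_step_edge_preserved_and_plateaus_flattened(self, rng):
        img = np.where(np.arange(40)[None, :] < 20, 0.2, 0.8) * np.ones((40, 1))
        img = img + rng.normal(0, 0.01, img.shape)
        p = BilateralParams(sigma_s=2.0, sigma_r=0.05, window_radius=5)
        out = bilateral(img, p)
        # edge midpoint displaced < 1 px: crossing of the 0.5 level per row
        for row in out:
            crossings = np.flatnonzero(np.diff(row > 0.5))
            assert crossings.size == 1 and abs(crossings[0] - 19.5) <= 1.0
        # plateau variance reduced at least 10x
        assert out[:, 5:15].var() < img[:, 5:15].var() / 10
        assert out[:, 25:35].var() < img[:, 25:35].var() / 10

    def test_output_within_input_range(self, rng):
        img = rng.random((16, 16))
        out = bilateral(img, BilateralParams(sigma_s=2, sigma_r=0.2, window_radius=4))
        assert out.min() >= img.min() - 1e-12 and out.max() <= img.max() + 1e-12


class TestLayers:
    def test_large_scale_is_single_bilateral_pass(self, rng):
        g = rgb_to_gaussian(rng.random((12, 12, 3)))
        p = BilateralParams(sigma_s=2, sigma_r=0.1, window_radius=3)
        assert np.array_equal(extract_large_scale(g, p), bilateral(g.e, p))

    def test_large_scale_reduces_total_variation(self, rng):
        g = rgb_to_gaussian(rng.random((20, 20, 3)))
        p = BilateralParams(sigma_s=2, sigma_r=0.3, window_radius=4)
        out = extract_large_scale(g, p)
        tv = lambda a: np.abs(np.diff(a, axis=0)).sum() + np.abs(np.diff(a, axis=1)).sum()
        assert tv(out) <= tv(g.e)

    def test_constant_normalized_color_gives_neutral_detail(self):
        nc = NormalizedColorImage(c_lambda=np.full((10, 10), 0.3))
        p = BilateralParams(sigma_s=2, sigma_r=0.1, window_radius=3)
        assert np.allclose(extract_detail(nc, p), 1.0, atol=1e-12)

    def test_detail_peaks_at_bright_dot(self):
        c = np.full((15, 15), 0.2)
        c[7, 7] = 0.8
        nc = NormalizedColorImage(c_lambda=c)
        det = extract_detail(nc, BilateralParams(sigma_s=2, sigma_r=0.5, window_radius=4))
        assert np.unravel_index(np.argmax(det), det.shape) == (7, 7)

    def test_detail_energy_shrinks_as_sigma_r_vanishes(self, rng):
        c = rng.random((16, 16))
        nc = NormalizedColorImage(c_lambda=c)
        energies = []
        for sr in (0.5, 0.1, 0.02, 0.004):
            det = extract_detail(nc, BilateralParams(sigma_s=2, sigma_r=sr, window_radius=3))
            energies.append(np.abs(det - 1.0).sum())
        assert energies == sorted(energies, reverse=True)
        assert energies[-1] < energies[0] / 10


class TestRecombine:
    def test_neutral_layers_return_color(self, rng):
        color = rng.random((8, 8, 3))
        layers = LayerDecomposition(color, np.ones((8, 8)), np.ones((8, 8)))
        assert np.allclose(recombine(layers), color, atol=1e-12)

    def test_zero_factor_gives_black(self, rng):
        color = rng.random((6, 6, 3))
        det = np.ones((6, 6))
        det[2, 3] = 0.0
        ls = np.ones((6, 6))
        out = recombine(LayerDecomposition(color, ls, det))
        assert np.all(out[2, 3] == 0.0)

    def test_clipped_for_adversarial_detail(self, rng):
        color = rng.random((9, 9, 3))
        det = 2.0 * np.ones((9, 9))
        ls = 0.5 + 0.5 * rng.random((9, 9))
        out = recombine(LayerDecomposition(color, ls, det))
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestQuantization:
    def test_levels_are_fixed_points(self):
        q = QuantizationParams(n_bins=8)
        dq = q.Delta_q
        levels = np.arange(9) * dq
        img = np.repeat(levels[None, :, None], 3, axis=2)
        y_out, _, _ = rgb_to_ycbcr(quantize_luminance(img, q))
        assert np.allclose(y_out.ravel(), np.clip(levels, 0, 1), atol=1e-9)

    def test_deviation_bounded_by_half_bin(self, rng):
        q = QuantizationParams(n_bins=8)
        img = rng.random((20, 20, 3))
        y_in, _, _ = rgb_to_ycbcr(img)
        y_out, _, _ = rgb_to_ycbcr(quantize_luminance(img, q))
        q_nearest = np.round(y_in / q.Delta_q) * q.Delta_q
        assert np.all(np.abs(y_out - q_nearest) <= q.Delta_q / 2 + 1e-12)

    def test_sharp_kappa_limit_matches_hard_binning(self):
        # away from the level points (where hard binning jumps), the
        # kappa -> inf limit maps every value to its bin's center value
        dq = 1 / 8
        h = np.linspace(0.0, 1.0, 640, endpoint=False) + 1 / 1280
        h = h[np.abs(h / dq - np.round(h / dq)) > 1e-3]
        img = np.repeat(h[None, :, None], 3, axis=2)
        qp = QuantizationParams(n_bins=8, kappa_q=1e4 / dq)
        y_out, _, _ = rgb_to_ycbcr(quantize_luminance(img, qp))
        hard = np.floor(h / dq) * dq + dq / 2
        assert np.abs(y_out.ravel() - hard).max() < dq / 100

    def test_monotone_nondecreasing(self):
        h = np.linspace(0, 1, 2001)
        img = np.repeat(h[None, :, None], 3, axis=2)
        for kappa in (4 / 0.125, 8 / 0.125, 100 / 0.125):
            qp = QuantizationParams(n_bins=8, kappa_q=kappa)
            y_out, _, _ = rgb_to_ycbcr(quantize_luminance(img, qp))
            assert np.all(np.diff(y_out.ravel()) >= -1e-12)

    def test_chrominance_untouched(self, rng):
        img = rng.random((10, 10, 3))
        _, cb_in, cr_in = rgb_to_ycbcr(img)
        out = quantize_luminance(img, QuantizationParams(n_bins=8))
        _, cb_out, cr_out = rgb_to_ycbcr(out)
        # clipping to [0,1] can perturb chroma only where RGB saturates
        interior = np.all((out > 1e-9) & (out < 1 - 1e-9), axis=2)
        assert np.allclose(cb_out[interior], cb_in[interior], atol=1e-9)
        assert np.allclose(cr_out[interior], cr_in[interior], atol=1e-9)


class TestFilterPipeline:
    def test_near_identity_configuration(self, vessel_image):
        img, _ = vessel_image
        cfg = load_config(
            None,
            {
                "abstraction": {"use_large_scale": False},
                "detail": {"gain": 0.0},
                "quant": {"n_bins": 256, "kappa_q": 1e6 * 256},
            },
        )
        layers = {}
        out = filter_pipeline(img, cfg, debug_layers=layers)
        assert np.abs(out - layers["light_bias"]).max() < 1 / 255

    def test_deterministic(self, vessel_image):
        img, _ = vessel_image
        cfg = load_config(None)
        a = filter_pipeline(img, cfg)
        b = filter_pipeline(img, cfg)
        assert np.array_equal(a, b)

    def test_output_contract(self, vessel_image):
        img, _ = vessel_image
        out = filter_pipeline(img)
        assert out.shape == img.shape and out.dtype == np.float64
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_background_smoothed_wall_contrast_kept(self, vessel_image):
        img, truth = vessel_image
        out = filter_pipeline(img)
        y_in, _, _ = rgb_to_ycbcr(img)
        y_out, _, _ = rgb_to_ycbcr(out)
        bg = ~truth.vessel_mask
        assert y_out[bg].var() < y_in[bg].var()
        wall = np.zeros_like(bg)
        for wm in truth.wall_masks:
            wall |= wm
        gmag = lambda y: np.hypot(*np.gradient(y))
        assert gmag(y_out)[wall].mean() >= 0.9 * gmag(y_in)[wall].mean()

    def test_stage_error_is_annotated(self):
        from vesselab.abstraction import PipelineError

        bad = np.full((32, 32, 3), np.nan)
        with pytest.raises((PipelineError, ValueError)):
            filter_pipeline(bad)
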