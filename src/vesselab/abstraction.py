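"""Salient-region image abstraction.

The filtering pipeline turns a cluttered immunostained image into an
abstracted one in which stained vessel walls stand out against a
flattened background:

1. light-bias removal (Niblack surface division on the intensity),
2. Gaussian color model + normalized color,
3. bilateral decoupling into a large-scale layer (one bilateral pass of
   the E channel) and a detail layer (residual of the normalized color
   after repeated bilateral passes),
4. element-wise recombination with the original color layer,
5. soft luminance quantization with a tanh transition of sharpness
   ``kappa_q`` inside bins of width ``Delta_q``.

The bilateral filter here is the explicit normalized form

    J(x) = (1/k(x)) * sum_{n in Omega} s(n - x) r(f(n) - f(x)) f(n)

with Gaussian spatial kernel ``s`` and range kernel ``r``, truncated to
a square window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from vesselab.colorspaces import (
    _check_plane,
    _check_rgb,
    gaussian_to_normalized,
    intensity_eq2,
    rgb_to_gaussian,
    rgb_to_ycbcr,
    ycbcr_to_rgb,
    GaussianColorImage,
    NormalizedColorImage,
)
from vesselab.illumination import niblack_surface, remove_light_bias

__all__ = [
    "BilateralParams",
    "LayerDecomposition",
    "QuantizationParams",
    "bilateral",
    "extract_large_scale",
    "extract_detail",
    "recombine",
    "quantize_luminance",
    "filter_pipeline",
]


@dataclass
class BilateralParams:
    """Bilateral kernel widths and window truncation.

    sigma_s : spatial standard deviation, pixels.
    sigma_r : range standard deviation, intensity units (unit-range data).
    window_radius : half-width of the square support Omega;
        ``window_radius >= 2 * sigma_s`` is recommended.
    """

    sigma_s: float = 3.0
    sigma_r: float = 0.1
    window_radius: int = 7

    def __post_init__(self) -> None:
        if self.sigma_s <= 0 or self.sigma_r <= 0:
            raise ValueError("sigma_s and sigma_r must be positive")
        if self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")


@dataclass
class LayerDecomposition:
    """Decoupled layers awaiting recombination."""

    color_layer: np.ndarray  # (H, W, 3) original color
    large_scale: np.ndarray  # (H, W) bilateral of E
    detail: np.ndarray  # (H, W) detail gain, neutral at 1


@dataclass
class QuantizationParams:
    """Soft luminance quantization parameters.

    ``n_bins`` bins of width ``Delta_q = 1 / n_bins`` on [0, 1];
    ``kappa_q`` controls the sharpness of the tanh transition between
    bins (defaults to ``8 / Delta_q``, i.e. sharpness scaled to the bin
    width).
    """

    n_bins: int = 8
    kappa_q: float | None = None

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.kappa_q is None:
            self.kappa_q = 8.0 / self.Delta_q
        if self.kappa_q <= 0:
            raise ValueError("kappa_q must be positive")

    @property
    def Delta_q(self) -> float:
        return 1.0 / self.n_bins


def bilateral(img: np.ndarray, params: BilateralParams) -> np.ndarray:
    """Edge-preserving bilateral filter of a scalar plane.

    Implements the normalized weighted average over the truncated square
    window directly (via window shifts, reflect-padded), so the output
    matches the per-pixel definition exactly.  Output values stay inside
    ``[min(f), max(f)]`` because the weights are a convex combination.
    """
    f = _check_plane(img)
    r = params.window_radius
    if 2 * r + 1 > 2 * min(f.shape):
        raise ValueError(
            f"degenerate window: radius {r} for image shape {f.shape}"
        )
    pad = np.pad(f, r, mode="reflect")
    num = np.zeros_like(f)
    den = np.zeros_like(f)
    inv2ss = 1.0 / (2.0 * params.sigma_s**2)
    inv2sr = 1.0 / (2.0 * params.sigma_r**2)
    h, w = f.shape
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            shifted = pad[r + dy : r + dy + h, r + dx : r + dx + w]
            ws = np.exp(-(dx * dx + dy * dy) * inv2ss)
            wr = np.exp(-((shifted - f) ** 2) * inv2sr)
            num += ws * wr * shifted
            den += ws * wr
    return num / den


def extract_large_scale(g: GaussianColorImage, params: BilateralParams) -> np.ndarray:
    """Large-scale layer: a single bilateral pass of the E channel."""
    return bilateral(g.e, params)


def extract_detail(
    nc: NormalizedColorImage,
    params: BilateralParams,
    n_iters: int = 2,
    gain: float = 1.0,
) -> np.ndarray:
    """Detail layer from the normalized-color bilateral residual.

    The normalized color ``C_lambda`` is bilaterally smoothed ``n_iters``
    times; the residual (original minus smoothed) carries the fine stain
    detail.  The layer is expressed multiplicatively — neutral regions sit
    at 1 — so that recombination acts as a sharpness-restoring gain:

        detail = clip(1 + gain * (C_lambda - bilateral^n(C_lambda)), 0, 2)
    """
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    smooth = nc.c_lambda
    for _ in range(n_iters):
        smooth = bilateral(smooth, params)
    residual = nc.c_lambda - smooth
    return np.clip(1.0 + gain * residual, 0.0, 2.0)


def _normalize01(plane: np.ndarray) -> np.ndarray:
    """Scale a non-negative plane into [0, 1] by its maximum.

    Dividing by the peak (rather than min-max stretching) keeps the
    layer's ratios intact: the stained walls stay brown instead of being
    driven to black, which the recombined color must preserve for any
    downstream color-based clustering.
    """
    hi = plane.max()
    if hi > 0:
        return np.clip(plane / hi, 0.0, 1.0)
    return np.clip(plane, 0.0, 1.0)


def recombine(layers: LayerDecomposition, base_gamma: float = 0.3) -> np.ndarray:
    """Element-by-element product of color, large-scale, and detail layers.

    The large-scale layer is scaled into [0, 1] by its maximum and its
    contrast compressed with exponent ``base_gamma`` before the product;
    compressing the base layer is standard practice in bilateral
    base/detail recombination — a linear product would multiply the
    image by its own smoothed intensity and so square every intensity
    variation, over-darkening textured regions.  ``base_gamma = 1``
    recovers the plain product.  The result is clipped into [0, 1] per
    channel.
    """
    if base_gamma <= 0:
        raise ValueError("base_gamma must be positive")
    color = _check_rgb(layers.color_layer)
    ls = _check_plane(layers.large_scale, "large_scale")
    det = _check_plane(layers.detail, "detail")
    if ls.shape != color.shape[:2] or det.shape != color.shape[:2]:
        raise ValueError("layer shapes disagree")
    gain = (_normalize01(ls) ** base_gamma * det)[..., None]
    return np.clip(color * gain, 0.0, 1.0)


def quantize_luminance(img: np.ndarray, params: QuantizationParams) -> np.ndarray:
    """Soft luminance quantization; chrominance is untouched.

    The BT.601 luminance ``h`` of the image is mapped to

        Q = q_nearest + (Delta_q / 2) * tanh(kappa_q * (h - q_nearest))

    where ``q_nearest`` is the quantization level (multiple of
    ``Delta_q``) closest to ``h``.  ``|Q - q_nearest| <= Delta_q / 2``
    everywhere and the map is monotone nondecreasing, so no value crosses
    more than one bin.
    """
    rgb = _check_rgb(img)
    y, cb, cr = rgb_to_ycbcr(rgb)
    dq = params.Delta_q
    q_nearest = np.round(y / dq) * dq
    q = q_nearest + 0.5 * dq * np.tanh(params.kappa_q * (y - q_nearest))
    q = np.clip(q, 0.0, 1.0)
    return np.clip(ycbcr_to_rgb(q, cb, cr), 0.0, 1.0)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def filter_pipeline(img: np.ndarray, config=None, debug_layers: dict | None = None) -> np.ndarray:
    """Full abstraction pipeline on an RGB image.

    Composition: Niblack light-bias removal -> Gaussian color model +
    normalized color -> large-scale and detail layers -> recombination
    -> soft luminance quantization.  Deterministic for a fixed config.

    Parameters
    ----------
    img : (H, W, 3) array
    config : RunConfig or None
        Effective configuration; defaults are used when None.
    debug_layers : dict, optional
        When given, intermediate layers are stored into it under the
        stage names.
    """
    from vesselab.config import load_config

    cfg = config if config is not None else load_config(None)
    rgb = _check_rgb(img)

    def _stage(name, fn):
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise PipelineError(name, exc) from exc
        if debug_layers is not None:
            debug_layers[name] = out
        return out

    def _bias_correct():
        intensity = intensity_eq2(rgb)
        surface = niblack_surface(
            intensity,
            window_radius=cfg["niblack"]["window_radius"],
            k=cfg["niblack"]["k"],
        )
        corrected = remove_light_bias(intensity, surface)
        gain = corrected.values / np.maximum(intensity.values, 1e-6)
        return np.clip(rgb * gain[..., None], 0.0, 1.0)

    corrected_rgb = _stage("light_bias", _bias_correct)

    bparams = BilateralParams(
        sigma_s=cfg["bilateral"]["sigma_s"],
        sigma_r=cfg["bilateral"]["sigma_r"],
        window_radius=cfg["bilateral"]["window_radius"],
    )
    g = _stage("gaussian_color", lambda: rgb_to_gaussian(corrected_rgb))
    nc = _stage(
        "normalized_color",
        lambda: gaussian_to_normalized(g, epsilon=cfg["normalized"]["epsilon"]),
    )
    if cfg["abstraction"]["use_large_scale"]:
        large = _stage("large_scale", lambda: extract_large_scale(g, bparams))
    else:
        large = np.ones(corrected_rgb.shape[:2])
    det = _stage(
        "detail",
        lambda: extract_detail(
            nc, bparams, n_iters=cfg["detail"]["n_iters"], gain=cfg["detail"]["gain"]
        ),
    )
    recombined = _stage(
        "recombine",
        lambda: recombine(
            LayerDecomposition(color_layer=corrected_rgb, large_scale=large, detail=det),
            base_gamma=cfg["abstraction"]["base_gamma"],
        ),
    )
    qparams = QuantizationParams(
        n_bins=cfg["quant"]["n_bins"], kappa_q=cfg["quant"]["kappa_q"]
    )
    return _stage("quantize", lambda: quantize_luminance(recombined, qparams))
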