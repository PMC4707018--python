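"""Illumination-bias estimation and contrast enhancement.

Slide scanners introduce smooth brightness gradients across the field.
Two independent corrections are provided, used by the two pipelines:

* Niblack's local threshold surface ``T = m + k s`` (windowed mean and
  standard deviation, ``k`` negative) tracks the illumination field; the
  filtering pipeline divides the intensity by this surface.
* Sigmoid contrast enhancement remaps intensities through a logistic
  curve; the segmentation pipeline applies it to the Y channel.

All windowed statistics use reflect padding at the borders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from vesselab.colorspaces import IntensityImage, _check_plane

__all__ = [
    "ThresholdSurface",
    "SigmoidParams",
    "niblack_surface",
    "remove_light_bias",
    "sigmoid_enhance",
]


@dataclass
class ThresholdSurface:
    """Niblack threshold surface ``T = m + k s`` over a square window."""

    t: np.ndarray
    window_radius: int
    k: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.t.shape


@dataclass
class SigmoidParams:
    """Logistic remap parameters: ``1 / (1 + exp(-gain (x - midpoint)))``.

    ``midpoint`` may be a number in [0, 1], ``"median"`` (image median at
    call time), or ``"otsu"`` (Otsu cut of the image, which places the
    transition between the stained and unstained populations so the
    sigmoid's saturation flattens illumination drift within each class).
    """

    gain: float = 10.0
    midpoint: float | str = "otsu"

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError(f"gain must be positive, got {self.gain}")
        if not isinstance(self.midpoint, str) and not 0 <= self.midpoint <= 1:
            raise ValueError(f"midpoint must lie in [0, 1], got {self.midpoint}")


def _as_plane(img) -> np.ndarray:
    if isinstance(img, IntensityImage):
        img = img.values
    return _check_plane(img)


def niblack_surface(
    img, window_radius: int = 15, k: float = -0.2
) -> ThresholdSurface:
    """Niblack threshold surface from windowed mean and standard deviation.

    Per pixel, ``T = m + k s`` with ``m``/``s`` the mean and standard
    deviation over the ``(2r+1)^2`` neighborhood (mirror/reflect padded).

    Parameters
    ----------
    img : 2-D array or IntensityImage
    window_radius : int
        Half-width ``r`` of the square window; must satisfy
        ``2 r + 1 <= min(H, W)``.
    k : float
        Niblack constant, negative in the illumination-removal role.
    """
    values = _as_plane(img)
    if window_radius < 1:
        raise ValueError(f"window_radius must be >= 1, got {window_radius}")
    size = 2 * window_radius + 1
    if size > min(values.shape):
        raise ValueError(
            f"window {size}x{size} larger than image {values.shape}"
        )
    m = uniform_filter(values, size=size, mode="mirror")
    m2 = uniform_filter(values**2, size=size, mode="mirror")
    # var may dip slightly negative from round-off on flat patches
    var = np.maximum(m2 - m**2, 0.0)
    t = m + k * np.sqrt(var)
    return ThresholdSurface(t=t, window_radius=window_radius, k=k)


def remove_light_bias(
    img, surface: ThresholdSurface, epsilon: float = 1e-6
) -> IntensityImage:
    """Divide intensity by the threshold surface and rescale to [0, 1].

    The ratio image ``img / max(T, epsilon)`` flattens the smooth
    illumination field the surface tracks; the result is renormalized by
    its maximum so downstream stages see unit-range intensities.
    """
    values = _as_plane(img)
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    if surface.t.shape != values.shape:
        raise ValueError(
            f"surface shape {surface.t.shape} != image shape {values.shape}"
        )
    ratio = values / np.maximum(surface.t, epsilon)
    peak = ratio.max()
    if peak > 0:
        ratio = ratio / peak
    return IntensityImage(values=ratio, provenance="eq2")


def sigmoid_enhance(img, params: SigmoidParams | None = None) -> IntensityImage:
    """Sigmoid contrast enhancement with min-max renormalization.

    ``out = 1 / (1 + exp(-gain (img - midpoint)))`` followed by a min-max
    rescale to [0, 1].  The map is strictly increasing, so pixel rank
    order is preserved exactly.
    """
    values = _as_plane(img)
    if params is None:
        params = SigmoidParams()
    if params.midpoint == "median":
        mid = float(np.median(values))
    elif params.midpoint == "otsu":
        from vesselab.region_analysis import otsu_threshold

        mid = otsu_threshold(values) if values.max() > values.min() else float(values.flat[0])
    else:
        mid = float(params.midpoint)
    out = 1.0 / (1.0 + np.exp(-params.gain * (values - mid)))
    lo, hi = out.min(), out.max()
    if hi > lo:
        out = (out - lo) / (hi - lo)
    return IntensityImage(values=out, provenance="luminance")
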