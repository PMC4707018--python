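"""Color transforms for immunostained-tissue images.

All images are float arrays with values nominally in ``[0, 1]``; RGB
images are ``(H, W, 3)`` in R, G, B channel order.  The module provides

* the chromaticity-weighted intensity channel,
* the RGB -> Gaussian color model transform (opponent channels
  approximating Gaussian-weighted spectral derivatives at
  lambda0 ~ 520 nm, sigma_lambda ~ 55 nm),
* the illumination-invariant normalized color ``C_lambda = E_lambda / E``,
* full-range BT.601 YCbCr, forward and inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAUSSIAN_COLOR_MATRIX",
    "GaussianColorImage",
    "NormalizedColorImage",
    "IntensityImage",
    "rgb_to_gaussian",
    "gaussian_to_normalized",
    "intensity_eq2",
    "rgb_to_ycbcr",
    "ycbcr_to_rgb",
]

#: Linear RGB -> (E, E_lambda, E_lambda_lambda) transform of the Gaussian
#: color model.  Rows map to the smoothed-intensity channel E and the
#: first and second opponent (spectral-derivative) channels.
GAUSSIAN_COLOR_MATRIX = np.array(
    [
        [0.06, 0.63, 0.27],
        [0.30, 0.04, -0.35],
        [0.34, -0.60, 0.17],
    ]
)

# Full-range BT.601 luma/chroma coefficients.
_BT601 = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168735892, -0.331264108, 0.5],
        [0.5, -0.418687589, -0.081312411],
    ]
)


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB array, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("RGB image contains non-finite values")
    return img


def _check_plane(img: np.ndarray, name: str = "image") -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected 2-D {name}, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError(f"{name} contains non-finite values")
    return img


@dataclass
class GaussianColorImage:
    """Opponent-channel planes of the Gaussian color model.

    ``e`` is the smoothed spectral intensity, ``e_lambda`` and
    ``e_lambda2`` the first and second spectral derivatives; the latter
    two may be negative.  ``lambda0`` / ``sigma_lambda`` record the
    nominal wavelength (nm) and scale (nm) of the model and are metadata
    only — the fixed transform matrix is used regardless.
    """

    e: np.ndarray
    e_lambda: np.ndarray
    e_lambda2: np.ndarray
    lambda0: float = 520.0
    sigma_lambda: float = 55.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.e.shape


@dataclass
class NormalizedColorImage:
    """Illumination-invariant normalized color ``C_lambda = E_lambda / E``."""

    c_lambda: np.ndarray
    epsilon_guard: float = 1e-6

    @property
    def shape(self) -> tuple[int, int]:
        return self.c_lambda.shape


@dataclass
class IntensityImage:
    """A single scalar plane with a provenance tag.

    ``provenance`` is one of ``"eq2"`` (chromaticity-weighted intensity),
    ``"luminance"`` (BT.601 Y) or ``"gaussian_e"`` (the E channel).
    """

    values: np.ndarray
    provenance: str = "eq2"

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def rgb_to_gaussian(img: np.ndarray) -> GaussianColorImage:
    """Transform an RGB image into the Gaussian color model.

    Applies the fixed linear map :data:`GAUSSIAN_COLOR_MATRIX` per pixel:
    ``(E, E_lambda, E_lambda_lambda)^T = M (R, G, B)^T``.

    Parameters
    ----------
    img : (H, W, 3) array
        RGB image; all values must be finite.

    Returns
    -------
    GaussianColorImage
    """
    img = _check_rgb(img)
    planes = img @ GAUSSIAN_COLOR_MATRIX.T
    return GaussianColorImage(
        e=planes[..., 0], e_lambda=planes[..., 1], e_lambda2=planes[..., 2]
    )


def gaussian_to_normalized(
    g: GaussianColorImage, epsilon: float = 1e-6
) -> NormalizedColorImage:
    """Compute the reflectance invariant ``C_lambda = E_lambda / E``.

    The division is guarded: wherever ``E < epsilon`` the denominator is
    clamped to ``epsilon``, so the result is finite everywhere.  ``E`` is
    near zero only for near-black pixels, which carry no stain signal.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    c_lambda = g.e_lambda / np.maximum(g.e, epsilon)
    return NormalizedColorImage(c_lambda=c_lambda, epsilon_guard=epsilon)


def intensity_eq2(img: np.ndarray) -> IntensityImage:
    """Chromaticity-weighted intensity channel.

    Each channel is weighted by its own chromaticity fraction::

        I = (R^2 + G^2 + B^2) / (R + G + B)

    Black pixels (``R + G + B == 0``) map to 0 by convention.
    """
    img = _check_rgb(img)
    s = img.sum(axis=2)
    sq = (img**2).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(s > 0, sq / np.where(s > 0, s, 1.0), 0.0)
    return IntensityImage(values=out, provenance="eq2")


def rgb_to_ycbcr(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full-range BT.601 YCbCr transform.

    Returns ``(Y, Cb, Cr)`` planes with Y in ``[0, 1]`` and chroma
    centered at 0.5 for in-range RGB input.
    """
    img = _check_rgb(img)
    ycc = img @ _BT601.T
    return ycc[..., 0], ycc[..., 1] + 0.5, ycc[..., 2] + 0.5


def ycbcr_to_rgb(y: np.ndarray, cb: np.ndarray, cr: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_ycbcr` (exact up to round-off)."""
    ycc = np.stack([np.asarray(y, float),
                    np.asarray(cb, float) - 0.5,
                    np.asarray(cr, float) - 0.5], axis=-1)
    inv = np.linalg.inv(_BT601)
    return ycc @ inv.T
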