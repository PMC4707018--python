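"""Parametric generator of IHC-like vascular images with exact ground truth.

Vessels in a CD31-stained section appear as dark brown walls (annuli)
around pale lumens, sitting on a pinkish tissue background with stained
non-vessel clutter, a smooth illumination gradient, and sensor noise.
The generator draws elliptical annuli (random eccentricity and rotation,
non-overlapping by rejection-sampled placement), textured walls,
near-white lumens, small stained clutter blobs, a multiplicative linear
illumination ramp, and finally additive Gaussian noise.  Ground-truth
masks (wall plus lumen per vessel) are recorded before the noise stage,
so truth never depends on the noise level.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate",
    "generate_suite",
    "generate_from_manifest",
]

#: difficulty sweep used by :func:`generate_suite`: (clutter_density,
#: noise_sigma) pairs, from clean to cluttered-and-noisy.
SUITE_GRID: tuple[tuple[float, float], ...] = tuple(
    (c, s) for c in (0.0, 0.03, 0.06, 0.09, 0.12) for s in (0.01, 0.02)
)


@dataclass
class SyntheticSpec:
    """Full parameterization of one synthetic vascular image.

    Radii and thickness are in pixels; colors are RGB triples in [0, 1];
    ``clutter_density`` is the fraction of the background covered by
    stained non-vessel blobs; ``texture_amp``/``texture_scale`` control
    the fine stain-tinted mottling of the tissue background (amplitude
    of the mixing field and its correlation length in pixels);
    ``illumination_ramp`` is the maximum relative brightness change
    across the image; ``noise_sigma`` the per-channel Gaussian noise
    standard deviation.  A spec plus its seed fully determines the
    generated (image, truth) pair.
    """

    height: int = 128
    width: int = 128
    n_vessels: int = 5
    lumen_radius_range: tuple[float, float] = (6.0, 12.0)
    wall_thickness_range: tuple[float, float] = (3.0, 5.0)
    wall_color_mean: tuple[float, float, float] = (0.45, 0.30, 0.20)
    lumen_color_mean: tuple[float, float, float] = (0.95, 0.93, 0.90)
    background_color_mean: tuple[float, float, float] = (0.85, 0.75, 0.78)
    clutter_density: float = 0.06
    texture_amp: float = 0.25
    texture_scale: float = 1.5
    noise_sigma: float = 0.02
    illumination_ramp: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("image dimensions must be positive")
        if self.n_vessels < 0:
            raise ValueError("n_vessels must be >= 0")
        lo, hi = self.lumen_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid lumen_radius_range")
        lo, hi = self.wall_thickness_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid wall_thickness_range")
        for color in (self.wall_color_mean, self.lumen_color_mean, self.background_color_mean):
            if not all(0 <= c <= 1 for c in color):
                raise ValueError("colors must lie in [0, 1]")
        if not 0 <= self.clutter_density < 1:
            raise ValueError("clutter_density must lie in [0, 1)")
        if self.noise_sigma < 0 or self.illumination_ramp < 0:
            raise ValueError("noise_sigma and illumination_ramp must be >= 0")
        if self.texture_amp < 0 or self.texture_scale <= 0:
            raise ValueError("texture_amp must be >= 0 and texture_scale > 0")


@dataclass
class GroundTruth:
    """Exact vessel masks: per-vessel (wall + lumen) and their union."""

    vessel_mask: np.ndarray
    n_vessels: int
    per_vessel_masks: list = field(default_factory=list)
    lumen_masks: list = field(default_factory=list)
    wall_masks: list = field(default_factory=list)


def _ellipse_mask(h, w, cy, cx, a, b, theta):
    yy, xx = np.mgrid[0:h, 0:w]
    u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate(spec: SyntheticSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic vascular image and its ground truth.

    Vessels are placed by rejection sampling with a minimum
    center-to-center distance so their outer ellipses never overlap;
    after 10^4 failed placement attempts the packing is declared
    infeasible and a ``RuntimeError`` is raised.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    # --- vessel geometry (rejection-sampled, non-overlapping) ---
    placed = []  # (cy, cx, a_lumen, b_lumen, thickness, theta, bound_radius)
    attempts = 0
    while len(placed) < spec.n_vessels:
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError(
                f"could not place {spec.n_vessels} vessels on a {h}x{w} canvas "
                f"after 10000 attempts; reduce n_vessels or radii"
            )
        r = rng.uniform(*spec.lumen_radius_range)
        ecc = rng.uniform(1.0, 2.0)
        a, b = r, r / ecc
        t = rng.uniform(*spec.wall_thickness_range)
        theta = rng.uniform(0, np.pi)
        bound = max(a, b) + t
        cy = rng.uniform(bound + 1, h - bound - 1)
        cx = rng.uniform(bound + 1, w - bound - 1)
        if all(
            np.hypot(cy - p[0], cx - p[1]) > bound + p[6] + 4 for p in placed
        ):
            placed.append((cy, cx, a, b, t, theta, bound))

    per_vessel, lumens, walls = [], [], []
    for cy, cx, a, b, t, theta, _ in placed:
        outer = _ellipse_mask(h, w, cy, cx, a + t, b + t, theta)
        lumen = _ellipse_mask(h, w, cy, cx, a, b, theta)
        per_vessel.append(outer)
        lumens.append(lumen & outer)
        walls.append(outer & ~lumen)
    vessel_mask = np.zeros((h, w), bool)
    for m in per_vessel:
        vessel_mask |= m
    truth = GroundTruth(
        vessel_mask=vessel_mask,
        n_vessels=spec.n_vessels,
        per_vessel_masks=per_vessel,
        lumen_masks=lumens,
        wall_masks=walls,
    )

    # --- background: base color, stain-tinted mottling, clutter blobs ---
    img = np.empty((h, w, 3))
    img[:] = spec.background_color_mean
    if spec.texture_amp > 0:
        # fine tissue texture: patches of partial stain uptake mixed into
        # the background color (one-sided, so the mottling only darkens)
        g = gaussian_filter(rng.standard_normal((h, w)), spec.texture_scale)
        g = g / max(g.std(), 1e-12)
        t = np.clip(spec.texture_amp * g, 0.0, 0.8)
        stain_tint = np.clip(np.array(spec.wall_color_mean) + 0.05, 0, 1)
        img = img * (1.0 - t[..., None]) + stain_tint * t[..., None]
    bg_area = int((~vessel_mask).sum())
    if spec.clutter_density > 0 and bg_area > 0:
        clutter_color = np.clip(np.array(spec.wall_color_mean) + 0.08, 0, 1)
        target = spec.clutter_density * bg_area
        covered = 0.0
        clutter = np.zeros((h, w), bool)
        for _ in range(5000):
            if covered >= target:
                break
            rr = rng.uniform(1.5, 3.5)
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            blob = _ellipse_mask(h, w, cy, cx, rr, rr / rng.uniform(1.0, 2.0),
                                 rng.uniform(0, np.pi))
            blob &= ~vessel_mask
            covered += int((blob & ~clutter).sum())
            clutter |= blob
        shade = rng.uniform(0.85, 1.1, size=(h, w, 1))
        img = np.where(clutter[..., None], clutter_color * shade, img)

    # --- vessels: textured walls, pale lumens ---
    wall_tex = 1.0 + 0.12 * gaussian_filter(rng.standard_normal((h, w)), 1.5)
    for lumen, wall in zip(truth.lumen_masks, truth.wall_masks):
        img = np.where(
            wall[..., None], np.array(spec.wall_color_mean) * wall_tex[..., None], img
        )
        img = np.where(lumen[..., None], spec.lumen_color_mean, img)

    # --- multiplicative illumination ramp along a random direction ---
    if spec.illumination_ramp > 0:
        phi = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:h, 0:w]
        proj = (xx - w / 2) * np.cos(phi) + (yy - h / 2) * np.sin(phi)
        span = proj.max() - proj.min()
        ramp = 1.0 + spec.illumination_ramp * ((proj - proj.min()) / span - 0.5)
        img = img * ramp[..., None]

    # --- sensor noise last; truth already frozen ---
    if spec.noise_sigma > 0:
        img = img + rng.normal(0, spec.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0), truth


def generate_suite(
    base_spec: SyntheticSpec, n_images: int = 10, seed: int = 0
) -> tuple[list[tuple[np.ndarray, GroundTruth]], list[dict]]:
    """Difficulty-sweep suite of images with a reproducibility manifest.

    The clutter density and noise sigma of ``base_spec`` are overridden
    by a fixed grid (clean through cluttered/noisy); each image draws
    from its own pseudo-random stream derived from ``(seed, index)``, so
    the suite is order-independent and any single image can be re-made
    from its manifest entry alone.

    Returns ``(pairs, manifest)`` where manifest entries record index,
    per-image seed, clutter density, and noise sigma.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if n_images == 1:
        # a singleton suite is the base spec itself
        img, truth = generate(base_spec)
        entry = {
            "index": 0,
            "seed": base_spec.seed,
            "clutter_density": base_spec.clutter_density,
            "noise_sigma": base_spec.noise_sigma,
            "height": base_spec.height,
            "width": base_spec.width,
            "n_vessels": base_spec.n_vessels,
        }
        return [(img, truth)], [entry]
    pairs, manifest = [], []
    for i in range(n_images):
        clutter, noise = SUITE_GRID[i % len(SUITE_GRID)]
        img_seed = int((seed * 100_003 + 7919 * i + 1) % (2**31))
        spec_i = replace(
            base_spec, clutter_density=clutter, noise_sigma=noise, seed=img_seed
        )
        pairs.append(generate(spec_i))
        manifest.append(
            {
                "index": i,
                "seed": img_seed,
                "clutter_density": clutter,
                "noise_sigma": noise,
                "height": spec_i.height,
                "width": spec_i.width,
                "n_vessels": spec_i.n_vessels,
            }
        )
    return pairs, manifest


def generate_from_manifest(
    base_spec: SyntheticSpec, entry: dict
) -> tuple[np.ndarray, GroundTruth]:
    """Re-render a suite image byte-for-byte from its manifest entry."""
    spec = replace(
        base_spec,
        height=entry["height"],
        width=entry["width"],
        n_vessels=entry["n_vessels"],
        clutter_density=entry["clutter_density"],
        noise_sigma=entry["noise_sigma"],
        seed=entry["seed"],
    )
    return generate(spec)
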