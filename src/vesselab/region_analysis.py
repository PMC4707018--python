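"""Vessel-candidate discrimination after the GPAC partition.

A vessel in an immunostained section appears as a stained (gray/brown)
wall around a pale (white) lumen.  After GPAC yields a preliminary
foreground, candidate regions are typed by their white-vs-gray pixel
composition into five spatiochromatic types, from Type 1 (all white)
through Type 3 (half white, half gray) to Type 5 (all gray), and passed
through an aspect-ratio test:

* SAR (surrounding area ratio) = gray surrounding-tissue pixels divided
  by the candidate-region area; a Type 5 region is assigned SAR = 1 by
  convention and routed to background.
* AIR (area image ratio) = candidate area divided by the image size.

A region is accepted as vessel when SAR falls in a configured band and
AIR is below a cap.  Type 3 regions — the half/half pattern the test
exists to catch — are re-segmented once by Niblack local thresholding
(the refinement step) before the final verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from vesselab.colorspaces import _check_plane, _check_rgb, rgb_to_ycbcr
from vesselab.illumination import SigmoidParams, niblack_surface, sigmoid_enhance
from vesselab.gpac import AffinityGraphSpec, evolve, initialize_contour

__all__ = [
    "LabelMap",
    "RegionRecord",
    "TypeThresholds",
    "otsu_threshold",
    "classify_pixels",
    "region_type",
    "aspect_ratio_test",
    "refine_region",
    "segment_pipeline",
]

_STRUCT8 = np.ones((3, 3), bool)  # 8-connectivity


@dataclass
class LabelMap:
    """Integer-labeled connected regions; 0 is background."""

    labels: np.ndarray
    n_regions: int

    @classmethod
    def from_mask(cls, mask: np.ndarray, min_area: int = 0) -> "LabelMap":
        """8-connected components of a boolean mask, small specks dropped."""
        lab, k = ndimage.label(mask, structure=_STRUCT8)
        if min_area > 1 and k:
            counts = np.bincount(lab.ravel(), minlength=k + 1)
            keep = np.flatnonzero(counts[1:] >= min_area) + 1
            remap = np.zeros(k + 1, dtype=lab.dtype)
            remap[keep] = np.arange(1, keep.size + 1)
            lab = remap[lab]
            k = keep.size
        return cls(labels=lab, n_regions=int(k))


@dataclass
class RegionRecord:
    """Per-region shape and composition statistics with the verdict."""

    label: int
    area_px: int
    white_px: int = 0
    gray_px: int = 0
    type: int = 0
    sar: float = 0.0
    air: float = 0.0
    accepted: bool = False
    needs_refinement: bool = False


@dataclass
class TypeThresholds:
    """White-fraction cuts partitioning [0, 1] into the five type bands.

    The verbal bands (All / Almost / Half / Few / None of white) are made
    numeric: ``w <= c1`` is Type 5 (none white), ``w > c4`` is Type 1
    (all white), with Types 4, 3, 2 in between.
    """

    white_fraction_cuts: tuple = (0.05, 0.35, 0.65, 0.95)

    def __post_init__(self) -> None:
        c = tuple(self.white_fraction_cuts)
        if len(c) != 4 or not all(0 < a < 1 for a in c) or list(c) != sorted(c) or len(set(c)) != 4:
            raise ValueError(f"cuts must be 4 strictly increasing values in (0,1), got {c}")
        self.white_fraction_cuts = c


def otsu_threshold(img: np.ndarray) -> float:
    """Otsu's threshold: minimize within-class variance over 256 levels.

    The image range is split into 256 equal bins; every interior bin edge
    is a candidate threshold and the within-class variance of the actual
    pixel values on either side is evaluated exactly (via per-bin partial
    sums).  Ties break toward the lower threshold.  Pixels strictly above
    the returned value form the upper class.
    """
    f = _check_plane(img)
    lo, hi = float(f.min()), float(f.max())
    if hi <= lo:
        raise ValueError("Otsu threshold undefined for a constant image")
    nbins = 256
    edges = np.linspace(lo, hi, nbins + 1)
    idx = np.clip(np.digitize(f.ravel(), edges[1:-1]), 0, nbins - 1)
    cnt = np.bincount(idx, minlength=nbins).astype(float)
    s1 = np.bincount(idx, weights=f.ravel(), minlength=nbins)
    s2 = np.bincount(idx, weights=f.ravel() ** 2, minlength=nbins)
    c_cnt, c_s1, c_s2 = np.cumsum(cnt), np.cumsum(s1), np.cumsum(s2)
    n = c_cnt[-1]
    # candidate threshold after bin k (k = 0..nbins-2): lower class = bins <= k
    n0, n1 = c_cnt[:-1], n - c_cnt[:-1]
    t1, t2 = c_s1[:-1], c_s2[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        var0 = np.where(n0 > 0, c_s2[:-1] - t1**2 / np.where(n0 > 0, n0, 1), 0.0)
        var1 = np.where(
            n1 > 0, (c_s2[-1] - t2) - (c_s1[-1] - t1) ** 2 / np.where(n1 > 0, n1, 1), 0.0
        )
    within = var0 + var1  # class-size-weighted: sums of squared deviations
    k = int(np.argmin(within))
    return float(edges[k + 1])


def _otsu_values(values: np.ndarray) -> float:
    """Otsu cut on a 1-D sample of values (same binning as the 2-D form)."""
    return otsu_threshold(values.reshape(1, -1))


def classify_pixels(
    img: np.ndarray, candidates: LabelMap, dilation_radius: int = 5
) -> dict[int, tuple[int, int]]:
    """Split each (dilated) candidate region into white and gray pixels.

    Each candidate is dilated by a disk of ``dilation_radius`` so the
    surrounding tissue ring is included; within that area, pixels whose
    luminance exceeds the Otsu cut of the local patch are white
    (lumen-like), the rest gray (stained tissue).  Returns per-label
    ``(white_px, gray_px)`` counts.
    """
    rgb = _check_rgb(img)
    y, _, _ = rgb_to_ycbcr(rgb)
    r = int(dilation_radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = (yy**2 + xx**2) <= r**2
    out: dict[int, tuple[int, int]] = {}
    slices = ndimage.find_objects(candidates.labels)
    for lab in range(1, candidates.n_regions + 1):
        sl = slices[lab - 1]
        if sl is None:
            out[lab] = (0, 0)
            continue
        sl = tuple(
            slice(max(0, s.start - r), min(dim, s.stop + r))
            for s, dim in zip(sl, candidates.labels.shape)
        )
        mask = candidates.labels[sl] == lab
        dil = ndimage.binary_dilation(mask, structure=disk)
        patch = y[sl][dil]
        if patch.max() > patch.min():
            cut = _otsu_values(patch)
            white = int(np.count_nonzero(patch > cut))
        else:
            white = 0  # flat patch: no lumen contrast, all gray
        out[lab] = (white, int(patch.size - white))
    return out


def region_type(rec: RegionRecord, cuts: TypeThresholds | None = None) -> int:
    """Spatiochromatic type 1-5 from the region's white fraction.

    ``w = white / (white + gray)``; ``w > c4`` is Type 1 (all white) down
    to ``w <= c1`` Type 5 (none white), with Type 3 the half/half band.
    """
    if cuts is None:
        cuts = TypeThresholds()
    total = rec.white_px + rec.gray_px
    if total < 1:
        raise ValueError("region has no classified pixels")
    w = rec.white_px / total
    c1, c2, c3, c4 = cuts.white_fraction_cuts
    if w > c4:
        return 1
    if w > c3:
        return 2
    if w > c2:
        return 3
    if w > c1:
        return 4
    return 5


def aspect_ratio_test(
    records: list[RegionRecord],
    image_size: int,
    sar_band: tuple[float, float] = (0.5, 4.0),
    air_max: float = 0.2,
) -> list[RegionRecord]:
    """SAR/AIR aspect-ratio test, applied in place and returned.

    * Type 5 regions get SAR = 1 by convention and become background.
    * Otherwise SAR = gray_px / area_px and AIR = area_px / image_size;
      a region is accepted when SAR lies in ``sar_band`` and
      AIR <= ``air_max``.
    * Type 3 (half/half) regions are flagged ``needs_refinement``.
    """
    if image_size <= 0:
        raise ValueError("image_size must be positive")
    low, high = sar_band
    for rec in records:
        if rec.type == 5:
            rec.sar = 1.0
            rec.air = rec.area_px / image_size
            rec.accepted = False
            rec.needs_refinement = False
            continue
        rec.sar = rec.gray_px / rec.area_px
        rec.air = rec.area_px / image_size
        rec.accepted = (low <= rec.sar <= high) and (rec.air <= air_max)
        rec.needs_refinement = rec.type == 3
    return records


def refine_region(
    img: np.ndarray,
    rec: RegionRecord,
    mask: np.ndarray,
    niblack_window: int = 7,
    niblack_k: float = -0.2,
    dilation_radius: int = 5,
    min_hole: int = 16,
) -> np.ndarray:
    """Niblack re-segmentation of a half-white/half-gray candidate.

    Within the region's bounding box (padded by the dilation radius) the
    luminance is thresholded by the local Niblack surface; stained (dark)
    pixels form the vessel wall and enclosed holes — the lumen — are
    filled back in, so an annular vessel initially captured as a partial
    blob is recovered as wall + interior.  Only components overlapping
    the original mask are kept.  Returns the refined full-size mask; a
    pure Type 1 region is returned unchanged.
    """
    if rec.type == 1:
        return mask
    rgb = _check_rgb(img)
    y, _, _ = rgb_to_ycbcr(rgb)
    r = int(dilation_radius)
    obj = ndimage.find_objects(mask.astype(int))[0]
    sl = tuple(
        slice(max(0, s.start - r), min(dim, s.stop + r))
        for s, dim in zip(obj, mask.shape)
    )
    patch = y[sl]
    win = min(niblack_window, (min(patch.shape) - 1) // 2)
    if win < 1:
        return mask
    surf = niblack_surface(patch, window_radius=win, k=niblack_k)
    dark = patch <= surf.t
    # keep wall components touching the original capture, then close the lumen
    lab, k = ndimage.label(dark, structure=_STRUCT8)
    keep = np.unique(lab[(lab > 0) & mask[sl]])
    wall = np.isin(lab, keep[keep > 0])
    refined = ndimage.binary_fill_holes(wall)
    # drop speck holes reopened by noise
    holes = refined & ~wall
    hlab, hk = ndimage.label(holes, structure=_STRUCT8)
    if hk:
        hcounts = np.bincount(hlab.ravel(), minlength=hk + 1)
        small = np.flatnonzero(hcounts[1:] < min_hole) + 1
        # holes are already filled; nothing further needed for small ones
        del small
    out = np.zeros_like(mask)
    out[sl] = refined
    return out


def _sorted_records(records: list[RegionRecord]) -> list[RegionRecord]:
    return sorted(records, key=lambda r: r.label)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def segment_pipeline(img: np.ndarray, config=None):
    """Full vessel segmentation on an RGB image.

    Stages: YCbCr + sigmoid enhancement -> GPAC partition (stained side)
    -> hole filling and connected components -> white/gray pixel
    classification -> spatiochromatic typing -> SAR/AIR test ->
    one-pass refinement of Type 3 regions -> accepted-region label map.
    Deterministic for a fixed config and seed.

    Returns
    -------
    (LabelMap, list[RegionRecord])
        Label map of accepted vessel regions and the records of *all*
        candidate regions (accepted or not), sorted by label.
    """
    from vesselab.config import load_config

    cfg = config if config is not None else load_config(None)
    rgb = _check_rgb(img)
    h, w = rgb.shape[:2]

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(name, exc) from exc

    def _enhance():
        y, _, _ = rgb_to_ycbcr(rgb)
        params = SigmoidParams(
            gain=cfg["sigmoid"]["gain"], midpoint=cfg["sigmoid"]["midpoint"]
        )
        return sigmoid_enhance(y, params).values

    enhanced = _stage("enhance", _enhance)

    def _partition():
        spec = AffinityGraphSpec(block_size=cfg["gpac"]["block_size"])
        init = initialize_contour(
            enhanced.shape,
            mode=cfg["gpac"]["init_mode"],
            feature=enhanced,
            seed=cfg["gpac"]["seed"],
        )
        state = evolve(
            enhanced,
            spec,
            init,
            max_iters=cfg["gpac"]["max_iters"],
            tol=cfg["gpac"]["tol"],
            curvature_weight=cfg["gpac"]["curvature_weight"],
        )
        fg = state.mask
        # the stained (vessel-wall) side is the darker one
        if fg.any() and (~fg).any() and enhanced[fg].mean() > enhanced[~fg].mean():
            fg = ~fg
        return fg

    stained = _stage("gpac", _partition)

    def _candidates():
        filled = ndimage.binary_fill_holes(stained)
        return LabelMap.from_mask(filled, min_area=cfg["regions"]["min_area"])

    candidates = _stage("components", _candidates)

    dil = cfg["regions"]["dilation_radius"]
    counts = _stage("classify", lambda: classify_pixels(rgb, candidates, dil))

    cuts = TypeThresholds(tuple(cfg["regions"]["white_fraction_cuts"]))
    records: list[RegionRecord] = []
    areas = np.bincount(candidates.labels.ravel(), minlength=candidates.n_regions + 1)
    for lab in range(1, candidates.n_regions + 1):
        white, gray = counts[lab]
        rec = RegionRecord(label=lab, area_px=int(areas[lab]), white_px=white, gray_px=gray)
        rec.type = region_type(rec, cuts)
        records.append(rec)

    sar_band = tuple(cfg["regions"]["sar_band"])
    air_max = cfg["regions"]["air_max"]
    _stage(
        "aspect_ratio",
        lambda: aspect_ratio_test(records, h * w, sar_band=sar_band, air_max=air_max),
    )

    def _refine():
        final = np.zeros((h, w), dtype=np.int32)
        next_label = 0
        for rec in records:
            mask = candidates.labels == rec.label
            if rec.needs_refinement:
                new_mask = refine_region(
                    rgb,
                    rec,
                    mask,
                    dilation_radius=dil,
                    min_hole=cfg["regions"]["min_hole"],
                )
                if new_mask.any():
                    sub = LabelMap.from_mask(new_mask, min_area=1)
                    sub_counts = classify_pixels(rgb, sub, dil)
                    # re-type and re-test the refined capture (largest piece)
                    areas_sub = np.bincount(sub.labels.ravel(), minlength=sub.n_regions + 1)
                    main = int(np.argmax(areas_sub[1:])) + 1
                    white, gray = sub_counts[main]
                    rec.area_px = int(areas_sub[main])
                    rec.white_px, rec.gray_px = white, gray
                    rec.type = region_type(rec, cuts)
                    aspect_ratio_test([rec], h * w, sar_band=sar_band, air_max=air_max)
                    rec.needs_refinement = False
                    mask = sub.labels == main
                else:
                    rec.accepted = False
            if rec.accepted:
                next_label += 1
                final[mask & (final == 0)] = next_label
        return LabelMap(labels=final, n_regions=next_label)

    final_map = _stage("refine", _refine)
    return final_map, _sorted_records(records)
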