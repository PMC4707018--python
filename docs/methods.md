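# Methods

This note documents the models, parameter choices and numerical
conventions behind `vesselab`, and what the synthetic experiments do and
do not demonstrate.

## Color model and illumination correction

All internal math is floating point on unit-range images; 8/16-bit
files are normalized on read and quantized only on write.

The Gaussian color model is the fixed linear map

    | Ê   |   | 0.06  0.63  0.27 | | R |
    | Êλ  | = | 0.30  0.04 −0.35 | | G |
    | Êλλ |   | 0.34 −0.60  0.17 | | B |

whose rows approximate Gaussian-weighted derivatives of the spectral
energy distribution at λ₀ ≈ 520 nm, scale σλ ≈ 55 nm (the wavelengths
are metadata; the printed matrix is always used). The reflectance
invariant `Ĉλ = Êλ/Ê` is independent of illumination intensity — the
property the detail layer relies on — and is guarded by `ε = 1e−6` in
the denominator; `Ê` approaches zero only at near-black pixels, which
carry no stain information.

The intensity channel is chromaticity-weighted,
`I = (R² + G² + B²)/(R + G + B)`, with black mapped to 0. The typeset
source for this definition admits more than one reading; the
chromaticity-weighted scalar form was adopted because it is the only
one consistent with "a linear weighted combination of R, G and B" in
which each channel's weight is its own chromaticity fraction. It is
documented here as an interpretation, not asserted as the original
authors' intent.

Two illumination corrections exist because the two pipelines need
different things:

* The **filtering** path divides the intensity by the Niblack surface
  `T = m + k·s` (window radius 15 px, `k = −0.2`; the source only
  states that `k` is negative) and renormalizes by the maximum. The
  surface tracks the smooth illumination field, so the ratio flattens
  it. All windowed statistics use mirror (edge-excluding reflect)
  padding, consistent with the bilateral filter's padding.
* The **segmentation** path passes the Y channel through a sigmoid
  (gain 10). The midpoint defaults to the Otsu cut of the plane rather
  than the median: with the midpoint between the stained and unstained
  populations, the sigmoid saturates both classes and thereby crushes
  within-class illumination drift, which is exactly the "light-bias
  correction" role this stage plays. A median or numeric midpoint
  remains available (`sigmoid.midpoint`).

## Abstraction filter

The bilateral filter is the explicit normalized form of the combined
domain/range Gaussian weighting over a truncated square window
(`sigma_s = 3` px, `sigma_r = 0.1` intensity units, radius 7). The
range scale is set below the wall/background contrast of stained tissue
(≈ 0.3–0.45 in `Ê`) so walls survive, and above typical fine-texture
amplitudes so mottling is smoothed. The implementation is
window-shift vectorized and matches the per-pixel double-loop
definition to ≤ 1e−9; that equivalence is asserted in the tests and
recomputed by the acceptance script.

The layer decomposition is:

* **large-scale** = one bilateral pass of `Ê` (by definition);
* **detail** = `clip(1 + gain·(Ĉλ − bilateral²(Ĉλ)), 0, 2)` — a
  multiplicative residual, neutral at 1, with two bilateral passes
  (`detail.n_iters = 2`) and unit gain. The source describes only "a
  combination of bilateral filters of the normalized color"; the
  multiplicative-residual form was chosen so that the element-wise
  recombination acts as a sharpness-restoring gain. This is a
  documented reconstruction, not a printed formula.

**Recombination** multiplies the color layer by the max-normalized
large-scale layer raised to `base_gamma = 0.3` and by the detail layer,
then clips to [0, 1]. Two deliberate departures from a plain product:

1. The large-scale layer is scaled by its maximum, not min-max
   stretched. Stretching would send the darkest large-scale value to
   exactly zero — turning stained walls black and destroying the
   chromatic identity that any downstream color analysis needs.
2. The exponent compresses the base layer's contrast before the
   product, in the tradition of bilateral base/detail tone mapping: a
   linear product multiplies the image by its own smoothed intensity
   and hence *squares* every intensity variation, which visibly
   amplifies background texture instead of suppressing it. γ = 0.3
   keeps the ordering (walls darkest) while bounding the squaring
   effect; γ = 1 restores the plain product via config.

**Luminance quantization** maps the BT.601 luminance through
`Q = q_nearest + (Δq/2)·tanh(κq·(h − q_nearest))` with `q_nearest` the
nearest quantization level (multiple of `Δq = 1/n_bins`); chrominance
passes through. Defaults `n_bins = 8`, `κq = 8/Δq` follow the
cartoon-abstraction convention of sharpness scaled to bin width. The
map's fixed points are the levels themselves; `|Q − q_nearest| ≤ Δq/2`
everywhere; it is monotone, so no value crosses more than one bin; and
as `κq → ∞` each bin collapses onto its center (hard binning), which
the tests verify away from the level points where the hard map jumps.

## GPAC segmentation

The graph view treats every pixel as a node and every pair as an edge
weighted by the squared feature difference on the sigmoid-enhanced Y
channel. The energy is the total within-region dissimilarity; the
boundary force at pixel x is

    F(x) = mean dissimilarity of x to inside − mean dissimilarity to outside,

so pixels migrate toward the region they resemble. With squared
differences this collapses in closed form to region moments,

    d(x, R) = f(x)² − 2 f(x) μ_R + (1/N_R) Σ_b n_b m_b²,

where the last term is accumulated from block summaries (counts and
means over `block_size = 4` tiles; `block_size = 1` is exact and equals
the naive O(N²) all-pairs force, the equivalence asserted in tests).
Each iteration is therefore O(N).

The level set is updated with the normalized force plus curvature
regularization (weight 0.5), redistanced every 20 iterations, and
stops when fewer than `tol = 0.1%` of pixels change sign for 3
consecutive iterations (cap 300). The update is intentionally simple —
no narrow band — because images of the intended size (≤ a few hundred
pixels square) converge in tens of iterations. Initialization modes:
checkerboard, centered circle, Otsu warm start (`threshold_seed`, the
deterministic default), and seeded smoothed-noise `random` for
stability experiments. On two-region fixtures, three random
initializations converge to identical partitions and recover the true
region at ≥ 99% — the stability property the method is known for.

Which feature the original pipeline fed to GPAC is not recorded;
sigmoid-enhanced Y is the default here, matching the preprocessing
order, with the abstraction output usable instead via the library API.

## Region typing, SAR/AIR and refinement

The stained GPAC side (lower mean enhanced Y) is hole-filled, labeled
with 8-connectivity, and regions under `min_area = 50` px are dropped
as specks (a 50-px region is well below the smallest plausible
capillary cross-section at the emulated scale). Within each candidate
dilated by a 5-px disk, pixels above the Otsu cut of the local patch
count as white (lumen-like), the rest as gray. The verbal composition
bands (All/Almost/Half/Few/None white) are made numeric with cuts
(0.05, 0.35, 0.65, 0.95) on the white fraction.

SAR is gray pixels over candidate area; AIR is candidate area over
image size. Acceptance requires `SAR ∈ [0.2, 0.9]` and `AIR ≤ 0.2`.
The upper SAR bound deliberately excludes 1: a solid stained region —
clutter, debris — has gray ≈ area, i.e. SAR ≈ 1, which is precisely
the printed convention "all-gray region ⇒ SAR = 1 ⇒ background"; an
annular vessel has SAR well below 1 because its lumen contributes no
gray. Both bounds are config-exposed and were calibrated on the
synthetic generator, as were the typing cuts.

Type 3 (half/half) candidates are refined once: Niblack thresholding
(window 7, k = −0.2) on the luminance inside the padded bounding box
re-extracts the stained wall, components touching the original capture
are kept, enclosed holes (the lumen) are filled, and the region is
re-typed and re-tested exactly once — no iteration.

## Synthetic generator

Each image is drawn deterministically from a seed: elliptical annuli
(lumen radius 6–12 px, wall 3–5 px, axis ratio ≤ 2, uniform rotation)
rejection-sampled so outer ellipses never overlap; wall color
(0.45, 0.30, 0.20) with multiplicative texture, near-white lumens,
pinkish background (0.85, 0.75, 0.78); stained clutter blobs (radius
1.5–3.5 px) covering `clutter_density` of the background; stain-tinted
background mottling (`texture_amp = 0.25`, correlation length 1.5 px)
emulating non-specific stain uptake; a multiplicative linear
illumination ramp (25% relative change); and Gaussian sensor noise
added last, after the ground truth is frozen. The default canvas is
128×128 with 5 vessels — large enough for every region type to arise,
small enough that the full suite runs in seconds.

The 10-image default suite sweeps clutter density
(0, 0.03, 0.06, 0.09, 0.12) × noise σ (0.01, 0.02), from clean to
cluttered and noisy, with per-image seeds derived from (suite seed,
index) so suites are order-independent; a manifest reproduces any
image byte-for-byte. A single-image suite is the base spec itself.

What the generator does *not* emulate: real stain-intensity gradients
within a wall, touching/overlapping vessels, plasma and nuclei
sub-structure, or scanner compression artifacts. Passing tests
therefore demonstrate correctness of the operators and the claimed
qualitative behaviors on controlled geometry, not clinical-grade
performance on slides.

## Evaluation

Count error matches predicted regions to ground-truth vessels greedily
by IoU (threshold 0.3, one-to-one) and reports unmatched predictions
plus unmatched truths over the truth count, ×100. This reduces to
`|N_pred − N_GT|/N_GT` when the matching is maximal, and is a
documented operationalization — how the original observer counts were
matched to computer regions was never specified. Area error is the XOR
pixel count over the ground-truth area, ×100; the denominator is
always the truth, so the measure is asymmetric by construction.

Fuzzy c-means (three classes, fuzzifier 2, centroid-move tolerance
1e−5, cap 300 iterations, seeded centroid initialization) clusters
per-pixel RGB. The vessel class is the cluster whose centroid
*chromaticity* is nearest the stain color: chromaticity rather than raw
color because the abstraction deliberately darkens stained structure
while preserving hue; raw-color matching would chase brightness. For
scalar features the comparison falls back to value distance. The
benefit experiment segments each suite image raw and filtered, fills
holes, and compares XOR area errors; on the default suite the filtered
mean is consistently 3–5 percentage points below the unfiltered mean —
the improvement comes from smoothed texture and noise, while
stain-colored clutter blobs are untouchable by any color-based
clustering and set the error floor for both arms.

## Determinism and sizes

Every random draw (generator, FCM initialization, GPAC random
initialization) flows from an explicit seed; repeated runs are
byte-identical. Problem sizes used by the tests and the acceptance
script — 128×128 suite images, ≤ 64×64 oracle fixtures — were chosen
as the smallest at which every behavior of interest (all five region
types, merging clutter, ramp-induced bias) still occurs; the whole
suite plus acceptance run takes well under a minute on one CPU.
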