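# Methods

This note documents the models, the numerical choices, and the synthetic
data underlying `mamle`, including the points where the method description
is genuinely open and this implementation had to commit to a design.

## Pipeline model and assumptions

The method assumes: (i) cells are compact, roughly convex objects whose
shared borders appear as *directional intensity minima* (dark valleys in
fluorescence; after inversion, also in phase contrast); (ii) a single
image contains enough cells (≥ 10 after filtering) that the population of
correctly segmented objects dominates the initial segmentation, so a
Gaussian shape model can be learned from it on the fly; (iii) the feature
triple (area, major axis, minor axis) separates plausible single cells
from fused clumps and fragments. No assumption is made about absolute
intensity, illumination flatness (the block-wise threshold absorbs smooth
gradients), or cell orientation.

Coordinates are 0-based (row, col); areas are in pixels², axis lengths in
pixels. All stages are deterministic given the input image and
configuration.

## Denoising

A self-contained two-stage block-matching collaborative filter:
fixed 8×8 blocks, reference blocks on a stride-4 grid, candidate offsets
within a ±16 px window at stride 4, groups of the 16 best-matching blocks.
Stage 1 applies a 2-D orthonormal DCT per block and an orthonormal Haar
transform along the group axis, hard-thresholds at 2.7 σ (the group DC is
always kept, which preserves the mean), and aggregates with weights
1/(1+N_kept). Stage 2 re-matches on the stage-1 estimate and applies
empirical Wiener shrinkage B²/(B²+σ²) to the noisy coefficients with the
stage-1 coefficients B as pilot. σ is estimated, unless given, as
1.4826·median(|d|) of the 2×2 Haar diagonal detail d — a standard robust
estimator that a sparse set of true edges does not bias appreciably.

The filter is deliberately simple (no variable block shapes, no Kaiser
windows, no color mode); the pipeline accepts any callable with the same
signature so a stronger external denoiser can be substituted. On the
synthetic suite the built-in filter reduces background residual noise by
roughly a factor of three at SNR 5, which is what the edge detector needs:
its failure mode is spurious directional minima, not blur.

## Foreground extraction

Fluorescence: per-window (default 64 px) Otsu thresholds on the denoised
image, bilinear interpolation of window-center thresholds to full
resolution, `img > surface`, hole filling (4-connected background), and
small-component removal. A window's Otsu split is accepted only if it is
*bimodal*: class-mean separation ≥ 4× the pooled within-class standard
deviation and ≥ 8 gray levels. A pure-noise Gaussian window splits at
≈ 2.7× within-class spread, genuine cell/background windows at > 10×, so
the factor 4 cleanly rejects background-only windows; these inherit the
median threshold of their defined neighbors (iterated outward for interior
gaps). This acceptance test is this implementation's own construction —
some rule is required because Otsu is undefined on unimodal windows.

Phase contrast: local range filter (5×5 max − min), Otsu on the range
image, binary closing (radius 2), then one more pass thresholding the
local density of the mask (window 5) to consolidate textured cell regions;
2 iterations by default. The exact iterative-range-filtering schedule in
the literature this emulates is unspecified; these defaults are explicit
substitutes and are exercised by the phase-contrast tests only.

## Multi-scale edges and threshold decomposition

The structuring element at scale s and direction d consists of exactly the
two cells at distance s along d; the origin is excluded. A pixel is marked
iff it is not brighter than either probe, i.e. iff it is invariant under
the grayscale erosion (with the origin included, erosion invariance is
exactly this condition). A printed form of the diagonal element could be
read as a full diagonal line of ones; the two-endpoint reading was chosen
for consistency with the horizontal/vertical elements, which are
unambiguous. Borders pad with +inf, the neutral element of the minimum, so
border pixels are judged only against in-image neighbors. Edge detection
runs on the denoised image re-quantized to the source integer range,
because an equality test against an erosion is ill-posed on floats.

Decomposition: foreground components are labeled; any component larger
than `max_cell_area` is re-thresholded at the strongest level f = S
(removing pixels with votes ≥ f), its subcomponents recursing with f−1
down to `decomposition_bound` (default 2). Components within the size
bound are accepted whole — subdivision applies only to oversized objects,
so isolated well-sized cells are never carved by their interior texture.
Components still oversized at the bound are kept and flagged for the split
stage, not discarded. Connectivity is 4-connected throughout: 8-connected
labeling would leak across 1-px diagonal edge barriers and undo the edge
removal. Removed edge pixels are finally re-assigned by iterative geodesic
dilation of the accepted labels inside the foreground (ties to the lower
label id — an arbitrary but deterministic rule); unreachable edge islands
stay background.

## Shape model

Features use the pixel-grid-corrected second central moments (+1/12 per
axis, each pixel a unit square), giving the standard equivalent-ellipse
axis lengths 4√λ₁, 4√λ₂. Regions need ≥ 5 pixels for the moments to be
meaningful.

The fit is contamination-robust: objects outside
[`min_object_area`, `max_cell_area`] are excluded (debris and fusion
suspects), then the 5 % of objects with the largest Mahalanobis distance
under an initial fit are trimmed and the model refit once. Σ gets a ridge
of 10⁻⁶·tr(Σ)/3 (floored at 10⁻¹²) so it is invertible even for
degenerate samples. At least 10 usable objects are required; below that
the fit aborts with advice to review the segmentation parameters rather
than returning a meaningless model.

## Split stage

Candidates are objects with area > μ_area (the model mean). The cut family
is: straight lines through every 2nd medial-axis point, perpendicular to
the local skeleton orientation (PCA of skeleton points within a radius-5
neighborhood). Each cut is scored by D of the connected part (the larger
connected piece if a half-plane side is disconnected); the best cut is
accepted if it beats the whole object's D, or unconditionally if the
object exceeds `max_cell_area`. Two guards beyond the basic size rule
protect well-formed cells: an object with area ≤ `max_cell_area` and
D ≤ 7.81 (the 95 % point of χ²₃ — the distance distribution of true
Gaussian samples) is never cut, and a cut that does not improve on the
whole is rejected. Without the χ² guard, halves of *large-but-normal*
cells often look like plausible small cells in this feature space (cell
length is broadly distributed), and the split stage would over-segment
faster than the merge stage can repair. The remainder re-enters the queue
while it is larger than the mean area; remainders that disconnect are
relabeled per component. Object area strictly decreases along the
recursion, so termination is guaranteed.

The straight-normal-cut parameterization is this implementation's
reconstruction of an "iterative likelihood-maximizing split" whose
internals are not specified; it is exhaustive over the cut family and
therefore oracle-checkable, and suits rod and coccus morphologies.

## Merge stage

Adjacency = label boundaries within 2 px (Chebyshev), computed by per-crop
dilation. A label joins the candidate set C if some adjacent label
satisfies D(Xᵢ) + D(Xⱼ) ≥ D(Xᵢⱼ), with Xᵢⱼ recomputed from the exact pixel
union (never approximated from part features). Hypotheses: one identity
row per candidate (score −D(Xᵢ)), one row per adjacent pair passing the
same constraint (score −D(Xᵢⱼ)), and one row per connected triple passing
the three-way analogue. No level-4 hypotheses. Regions too small to have
features score D = 10⁹ — large enough that debris always prefers merging,
finite so the program stays well-posed.

The selection max Lᵀx s.t. Hᵀx = 1 is solved per connected cluster of
candidates: clusters with ≤ 20 rows by exhaustive exact-cover search
(ties broken toward more selected rows, i.e. fewer merges), larger
clusters by LP-based branch-and-bound (HiGHS via `scipy.optimize.milp`)
with a tiny per-row bonus (10⁻⁷ of the score scale) implementing the same
tie-break. On the synthetic suite virtually all clusters fall under the
exhaustive threshold, where the solver provably equals partition
enumeration.

The restriction of C₂/C₃ to spatially adjacent unions is a deliberate
tightening: the likelihood constraint alone would happily merge distant
fragments into one "cell".

## Synthetic data

The generator emulates dense bacterial colonies on a 512×512 field:
rod-shaped cells are rasterized spherocylinders (length 20–40 px, width
7–11 px — about 100× magnification of *E. coli*), cocci are disks. The
`dense`/`medium`/`sparse` presets place 200/100/25 cells with clumping
0.7/0.5/0.1, where a clumped cell is placed touching a previously placed
cell: the center distance along a sampled direction is computed from the
two capsules' support functions plus a 1.6–3.0 px gap, rendering the 1–2
px background-level valley that the edge detector must find. Rod
orientations are locally aligned with the partner (70 % of placements,
von-Mises-like jitter σ = 0.35 rad), mimicking nematic packing in real
colonies. With `fusion_rate` > 0, that fraction of touching placements is
rendered with *no* valley (gap ∈ [−0.8, 0.2] px, overlap trimmed to keep
ground-truth labels disjoint) — deliberate under-segmentation challenges,
listed as pairs in the metadata. A clumped placement that cannot be
realized after 150 attempts falls back to free placement; an image that
cannot fit `n_cells` at all raises an error suggesting lower density.

Rendering: background 30, foreground contrast 120 (8-bit scale), a
dome-like interior profile from the border distance normalized per cell
width, a smooth multiplicative texture field (6 % amplitude, Gaussian
blur σ 1.5), optional linear illumination ramp, Gaussian PSF (σ 1 px),
then Poisson shot noise (gain 20) plus additive Gaussian read noise of
contrast/SNR. At the default SNR 5 the read noise (σ = 24) dominates the
shot noise (σ ≤ 3), so the realized contrast-to-noise matches the request
within the generator's ±20 % tolerance. The phase-contrast renderer uses
the same geometry with dark bodies (−60), 2-px bright halos (+45) and
mid-gray background (128).

What the generator does *not* emulate: optics-accurate PSFs, depth
effects, autofluorescence, uneven staining, motile or dividing cells, and
time-lapse correlation. Passing the synthetic acceptance suite therefore
demonstrates the pipeline's mechanics (valley detection, decomposition,
shape-model correction) under controlled dense/noisy/fused conditions; it
does not certify accuracy on any particular microscope's data.

## Problem sizes used by the test and acceptance suites

The end-to-end suites use ten 512×512 dense images (~200 cells each,
seeds 1–10): once for the accuracy/false-positive benchmark and once,
with `fusion_rate` 0.1, for the correction-stage comparison. The
max-cell-area robustness sweep runs seven values (±30 % around the
generator-implied true maximum of 414 px²) over the same ten images; the
(S, f_min) grid sweep runs the feasible part of {2..6}×{1..4} over three
images. Unit tests use 128–256 px images. Images are denoised once per
sweep, since the swept parameters act downstream of denoising.

## Known limitations

* The shape feature space cannot distinguish a half of a long cell from a
  genuine short cell; the χ² split guard and the merge stage mitigate but
  cannot eliminate this ambiguity when cell sizes vary several-fold.
* The Gaussian shape model is unimodal: mixed populations of very
  different morphologies would need per-population runs or a pre-trained
  model (the `ShapeModel` JSON round-trip exists for exactly that).
* The merge stage stops at triples; an over-split into ≥ 4 fragments is
  repaired only partially in one pass.
* Phase-contrast support is functional but less exercised than
  fluorescence; its foreground schedule is a stated substitute for an
  unspecified reference procedure.
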