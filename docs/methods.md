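# Methods

## Coordinate and orientation conventions

All geometry lives in a single pixel frame: voxel indices are 0-based, a
spot coordinate is a (sub-voxel) position in that frame, and outline
vertices share the image x/y axes. In-memory stacks are always
`(channel, z, y, x)`; readers normalise whatever axis order a TIFF
declares and fall back to an explicit `axis_order` override when the
metadata is ambiguous.

"Clockwise" for the four anchor clicks is defined by the shoelace sign of
the `(x, y)` vertex sequence (negative signed area). Outlines supplied in
either orientation are normalised before the click order is checked, and a
click sequence that does not advance clockwise from the nuclear side is a
hard error that asks the user to re-click, rather than silently producing
swapped segments.

Distances are computed in the x–y plane only. The outline is drawn on one
slice and applied through the whole stack, so the boundary is a vertical
prism wall and the 3D distance to it equals the planar distance; the z
coordinate is carried through all outputs but never enters a distance.
Points exactly on the outline count as inside (a spot on the invasive edge
legitimately has distance 0). Distances are reported in pixels by default;
an optional micrometer conversion uses the voxel size (x/y size for the
in-plane quantities, z size for the z coordinate).

## Spot detection

Detection reduces each RNA channel of the masked stack to a list of
sub-voxel spot centers:

1. Gaussian pre-smoothing, default sigma 1.0 voxel per axis. Defaults are
   deliberately isotropic in voxel units — with ~0.1 × 0.1 × 0.3 µm voxels
   the physical smoothing is anisotropic, which matches the optics; a
   per-axis sigma is available when that trade-off is wrong for a dataset.
   Filters use periodic (wrap) padding: edge replication would inflate the
   smoothed noise variance near the frame border and generate spurious
   border maxima, while the cell mask keeps real signal away from the
   frame so wrap-around leakage is negligible. Wrap padding also makes
   detection exactly equivariant under integer scene translations.
2. Acceptance floor `max(isodata(masked voxels), median + k·scale)`, with
   `k = 5` by default. The isodata threshold is the Ridler–Calvard fixed
   point `T = (mean(v<T) + mean(v≥T))/2`, iterated from the global mean to
   a 0.5-intensity-level tolerance; it is undefined (an error) on a
   constant volume, in which case only the robust floor applies. The
   robust scale is `1.4826 × MAD` of the masked smoothed voxels, a
   consistent sigma estimate that ignores the bright spot tail.
3. Candidates are 3×3×3 local maxima inside the mask above the floor.
4. Minimum-separation pruning (default 3 voxels, per-axis/Chebyshev)
   keeps the brighter peak; exact ties resolve to the earlier (z, y, x)
   scan position, and plateaus of equal adjacent maxima always collapse.
5. Centers are refined by an intensity-weighted centroid in the 3×3×3
   window, with weights `window − min(window)` so the refinement — like
   every step above — is invariant to adding a constant to the image.
   No Gaussian PSF fitting is attempted: centroid refinement is adequate
   at the ~1-voxel localization the downstream distances need, and
   keeps the detector free of optimization failure modes.

Spots detected in the rna1 channel carry type 1, rna2 type 2, and are
returned in scan order, not brightness order.

## Normalization and statistics

Per image, the normalization length `L` is the mean of `Nd_i + Id_i` over
all spots of both types; each type's polarity index `M` is the mean of
`Id_i / L` over that type's spots. `M` is undefined (NaN, never 0) for a
type with no spots. Individual normalized distances can exceed 1 in
irregular cells; they are histogrammed as-is (20 fixed bins on [0, 1],
out-of-range values left out rather than clipped, since clipping would
bias the edge bins), and a per-image `M` outside [0, 1] raises a warning,
not an error.

The cross-image comparison is a two-sided Wilcoxon matched-pairs
signed-rank test on the per-image (M_RNA1, M_RNA2) pairs. Pairs with an
undefined member are dropped; zero differences are dropped (classic
convention); tied absolute differences receive midranks. For n ≤ 25
usable pairs the null distribution is exact — computed by dynamic
programming over doubled midranks, equivalent to full sign-flip
enumeration — and above that a normal approximation with continuity and
tie-variance correction is used. The reported statistic is min(W+, W−).
Using one pair per image, rather than pooling all spots, prevents cells
with many transcripts from dominating the comparison.

Kernel density estimates of the per-image M values use a Gaussian kernel
with Silverman's bandwidth, evaluated on 512 points over [−0.2, 1.2]; the
bandwidth is floored at one grid step so near-degenerate inputs still
yield a resolvable, normalized curve, and the bandwidth is recorded in the
output metadata. With fewer than two distinct M values the KDE is skipped
with a warning while histograms are still produced.

## Synthetic scenes

The generator emulates the acquisition conventions of the real
experiment: 4 channels (nuclear, cellmask, rna1, rna2), anisotropic
0.1 × 0.1 × 0.3 µm voxels, spots rendered as anisotropic Gaussian PSFs
(σ_xy = 1.3, σ_z = 1.5 voxels — about half the optical PSF at the target
sampling), Poisson shot noise plus Gaussian read noise over a uniform
background (defaults: gain 1, read sigma 2, background 100 counts). Spot
peak amplitude is specified as a peak SNR over the background noise scale.

The cell mask is a stadium capsule — an elongated body with two identical
semicircular caps — with the nuclear cap at the rear and the invasive cap
at the front. The front-back symmetry of this shape is load-bearing:
uniformly placed spots then have expected polarity index exactly 0.5,
which anchors the normalization checks. Spot positions follow a truncated
exponential along the front-back axis whose rate is solved from a target
axial mean; a polarity bias β ∈ [0, 1] maps linearly to target means from
0.5 (uniform) down to 0.05 (strongly invasive). Spots keep a 2-px margin
from the mask edge. Because the caps are curved, the realized pipeline M
differs slightly from the axial-law mean (e.g. a nominal 0.25 target
realizes ≈ 0.21–0.23 depending on cell proportions); the exact expectation
for any geometry is computed by deterministic quadrature of the placement
law against brute-force boundary distances, and closure of pipeline M to
that expectation is verified at n = 2000 spots within 0.02.

Multi-image studies jitter the frame length per image (±~20%) so cells
differ in scale, which the scale-invariant normalization must absorb. A
planted "effect" sets the two types' axial targets to 0.5 − effect and
0.5. Statistical-calibration runs (type-I error, power) use the
geometry-only fast path — spots planted and measured against the drawn
boundary without voxel rendering — because rendering and re-detecting
thousands of stacks would only re-test what the detection criteria already
establish. Rendering is exercised by the detection tests and the
end-to-end runs.

The independent ground-truth oracle (`true_distance_table`) re-derives the
boundary segments with plain numpy (shoelace orientation, nearest-vertex
snapping) and takes distances as minima over 10⁴ (configurable)
arclength-uniform boundary samples — a deliberately separate code path
from the shapely-backed measurement, so the two can check each other.

What the generator does not emulate: realistic cytoplasmic
autofluorescence texture, probe clustering at transcription sites,
follower cells, depth-dependent attenuation, or a measured PSF. Passing
tests therefore demonstrate correctness of the algorithmics and the
statistics under the stated noise model, not robustness to every real
imaging artifact; detection parameters (especially `noise_k` and the
smoothing sigma) should be inspected on real data.

## Problem sizes and determinism

The test suite and the acceptance script run on desk-scale scenes
(8–12 z-slices, 64–192 px frames, 10–500 spots; 12-image studies, 50–100
replicates for calibration loops), chosen so the full suite completes in
well under a minute while leaving Monte-Carlo tolerances (±0.02–0.03 on
M; count-based bounds on rejection rates) comfortably above sampling
noise. Every stochastic step is seeded; regenerating any scene or study
from the same parameters and seed is bit-identical, and the CLI writes its
configuration, a content hash and counts into every output directory.

## Known limitations

- Dense spot clusters closer than the minimum separation merge into one
  detection; transcription-site decomposition is out of scope.
- Leader-cell and nucleus segmentation remain manual (outline + clicks),
  as in the workflow this package automates around.
- Only two RNA species are compared; multi-condition omnibus testing and
  mixed-effects models across spheroids are out of scope.
- Lateral (side1/side2) distances are recorded in all outputs but not
  summarized.
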