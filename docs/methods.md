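# Methods

`ddft3d` implements, as a tested pipeline exercised on synthetic data,
an in-silico workflow for reconstructing and longitudinally comparing
the equine deep digital flexor tendon (DDFT) from multiplanar MRI
segmentations:
per-plane segmentation → volumetric interpolation → Boolean fusion of the
three planes → wrap/smooth refinement → thickness and volume morphometry
→ rigid registration and signed part comparison → cohort statistics.
This note records the models, conventions and numerical choices behind
each stage, and what the synthetic phantom does and does not emulate.

## Coordinate frame and units

Everything is in millimeters in a right-handed patient frame: x
medial–lateral, y dorso-palmar, z proximo-distal (proximal → distal along
+z). A voxel with index `(i, j, k)` is the box whose center sits at
`origin + (index + 0.5) * spacing`. STL carries no units; the package
declares mm for every mesh it reads or writes.

## Synthetic phantom

The phantom is an analytic signed-distance solid emulating the DDFT
segment between the middle phalanx and the distal interphalangeal joint:
bilobed proximally (union of two discs, lobe radius 6 mm, centers 7 mm
apart, so the lobes merge across a waist), blending smoothly into a flat
rounded sheet distally (3 mm thick, 28 mm wide), over a 60 mm length with
a parabolic sagittal bend (radius 80 mm) emulating the course around the
navicular region. Defaults give an enclosed volume of ≈ 7,800 mm³,
within the 5,000–17,000 mm³ span of real tendons, lobe-region thickness
≈ 12 mm and sheet thickness tapering from 3 mm toward zero at the rim.
An optional band-limited sinusoidal perturbation (`roughness_mm`, seeded)
produces distinct phantoms per seed without changing the gross anatomy.

Lesions are two-level, matching the segmentation rules the pipeline must
exercise: tendon tissue is *hypointense*, lesions mark voxels
*hyperintense*. A `core` lesion is an interior ellipsoid that must leave
an intact rim (reaching the surface is an error); a `surface_split`
lesion must contact the surface. No MR signal physics is simulated.

Longitudinal change displaces the surface along its outward normals on
the signed-distance representation: the follow-up solid is
`{x : sdf(x) < a(x)}` with `a` a sum of Gaussian patches plus a uniform
term. This avoids mesh self-intersection bookkeeping; erosion deeper
than the local interior radius is rejected. The zero field reproduces
the baseline grid bit for bit.

What the phantom does **not** emulate: partial-volume grayscale (sampling
is binary occupancy), operator variability in livewire seed placement,
inter-plane motion (planes are perfectly co-registered unless an explicit
misalignment offset is passed), magic-angle artifacts, and the distal
insertion where the real tendon blends into bone. Passing tests
therefore demonstrate geometric correctness of the pipeline, not
robustness to scanner or operator noise.

## Tri-planar sampling

Each plane (sagittal: slices along x, axial: along z, dorsal: along y)
is sampled with its in-plane pixel spacing and spacing-between-slices;
defaults are the high-field-like geometry (0.31 mm in-plane, 3.6 mm
between slices). A pixel is foreground iff the solid occupies at least
half of its voxel (exact separable overlap integration, threshold 0.5 —
symmetric and unbiased for convex shapes). Slice count is
`ceil(extent / spacing)`.

## Per-plane reconstruction (shape-based interpolation)

Within each slice the boundary can be traced by a livewire: minimum-cost
paths between seeds on the 8-connected lattice, per-pixel cost
`1 − g/g_max + 1e-3` with `g` a Gaussian-derivative gradient magnitude
(σ = 1 px; a Sobel band drifts inward on diagonal edges), diagonal steps
weighted by their Euclidean length, ties broken by row-major node order.

The hyper/hypointense rule is applied volumetrically: hyperintense
components 6-adjacent to background are excluded (an absence of data,
leaving a concavity); fully interior components (rimmed core lesions)
are included.

The slice stack becomes a solid by shape-based interpolation: per-slice
signed Euclidean distance fields, linear interpolation along the slice
axis between slice centers, thresholded at zero. Three conventions
complete the definition where slices carry no in-plane correspondence:

1. **Empty flanking slices.** An acquired-but-empty slice asserts
   background everywhere but still localizes the end of the solid.
   Its field is chamfer-extended from the neighboring slice and kept
   strictly positive, so end caps taper into the inter-slice gap instead
   of being cut flat at the last foreground slice center. A single-slice
   stack extrudes by one slice thickness.
2. **Background-side saturation.** The in-plane distance is a valid
   proxy for the 3-D field only while consecutive footprints overlap.
   Positive (background) values are clipped at half the slice spacing,
   so a feature that vanishes between slices (e.g. a lobe ending
   mid-gap) caps midway between slice centers rather than being crushed
   toward the last slice containing it. Cone- and cylinder-like
   geometry produces small positive values and is untouched: identical
   circles reconstruct the analytic cylinder and radii 5→3 mm the
   analytic frustum within 5%.
3. **Fusion margin (optional, default off).** Boolean intersection
   keeps the innermost surface over the three planes, so each plane's
   residual half-voxel conservatism along its own slice axis accumulates
   in the fused part. `slice_axis_margin_mm` dilates a plane's solid
   along its slice axis only; the pipeline uses a quarter of the slice
   spacing. The two other planes resolve that axis in-plane at 0.31 mm
   and trim the excess, so the margin converts per-plane underfill into
   fused-part accuracy. Faithful single-plane reconstruction uses
   margin 0.

Surfaces are extracted by marching cubes on the zero-padded binary
volume. The raw marching-cubes output is kept un-"processed": it is
already vertex-merged and manifold, and further merging can pinch
degenerate triangles into non-manifold edges.

## Part building

Boolean intersection runs on a shared voxelization (parity fill of each
closed surface by per-slice cross-section rings with even/odd
containment; default pitch 0.5 mm, the pipeline uses 0.31 mm) followed by
re-meshing — robust to the near-coincident surfaces of independently
segmented planes, at the cost of sub-voxel exactness. An empty
intersection returns an empty mesh, not an error.

Cropping clips to the slab between two planes (points + distally
directed unit normals; the proximal plane must lie proximal of the
distal one). If the slab contains the mesh the input passes through
unchanged; otherwise the mesh is re-meshed from its voxelization
restricted to the slab, which re-caps it watertight. Crop planes are
configuration inputs; the synthetic pipeline derives them from phantom
ground truth when used. Cropping defaults to after the intersection,
with a switch to crop each plane first.

Wrap (gap closing 0.5 mm, smallest detail 1 mm) is realized as:
conservative surface voxelization (triangles subdivided below half a
voxel, pitch = smallest detail / 2 capped at 0.5 mm) → morphological
closing with a ball of radius gap/2 → hole filling → isosurface at the
signed mid-shell level (distance-to-outside minus distance-to-interior),
which keeps the output centered on the input surface instead of inflated
by the voxel shell. It closes holes and gaps smaller than the gap
closing distance and handles open input.

Smoothing is volume-compensated Taubin relaxation; the single
"factor" knob maps to shrink weight `0.5 * factor` (matched inflate
step) over a fixed 10 iterations. Factor 0 is the identity; 0.7 is the
pipeline default. Volume changes stay within a few percent on convex
fixtures.

## Morphometry

Volume is the signed divergence-theorem volume of the watertight mesh,
reported positive with automatic orientation correction; open meshes are
errors.

Thickness follows the wall-thickness convention: from each vertex, the
chord along the inward area-weighted vertex normal to the first exit
through the opposite surface (exact Möller–Trumbore ray casting; origins
nudged 1 µm inward so the chord does not re-hit the starting fan). Rays
that find no exit within the bounding diameter are flagged and inherit
the nearest valid neighbor's value across mesh edges; summaries (min /
median / max, median by midpoint-mean for even counts) use unflagged
values only, so grazing rays cannot corrupt the minimum. On strongly
curved rims the inward normal can run along the solid, producing long
chords; these are honest chords under this convention, which is why the
per-part maximum exceeds the local anatomical diameter. A vertex-mask
parameter supports seeded subsampling on very dense meshes.

The maximal-inscribed-sphere alternative definition is noted but not
implemented as the default.

## Registration and part comparison

Global registration is rigid ICP (no scaling — the two scans are the
same physical structure, and scaling would corrupt thickness-change
semantics): a seeded 90% random subsample of moving vertices, drawn once
per call, is matched each iteration to exact nearest points on the fixed
surface (centroid k-d tree with a guaranteed ball-refinement pass over
point-to-triangle distances), pairs beyond the 5 mm threshold are
rejected, and the least-squares rigid transform (Kabsch/SVD with proper
rotation) is composed; iteration stops at the cap (100) or when the RMS
residual changes by < 1e-6 mm. RMS history, accepted-pair count and the
seed are returned; zero accepted pairs raises a registration failure
with diagnostics.

Part comparison evaluates, at every follow-up vertex, the exact
point-to-triangle distance to the baseline surface, signed by the
baseline's nearest-face outward normal: positive = follow-up outside
baseline (thickening), negative = inside (thinning). The comparison is
directed (follow-up → baseline) by default; a symmetric option merges
the reverse direction with negated signs. The maximum unsigned value is
the directed Hausdorff distance and matches an exhaustive all-pairs
oracle on small meshes. The ±1.5 mm change alarm is boundary-inclusive.
Color maps use a diverging blue–white–red palette centered at zero with
end-color clamping; per-vertex values also export as CSV.

## Cohort statistics

Change scores are ternary (+1 improved / 0 unchanged / −1 worse), one
MRI and one clinical score per non-baseline scan. Transitions are
consecutive scan pairs per tendon; deltas are later − earlier, volume
change as percent of the earlier volume. Concordance partitions scored
transitions into both-+1 / both-0 / both-−1 / discordant. When a single
score is needed, the policy flag chooses MRI (default), clinical, or
concordant-only.

Pearson correlation uses the product-moment r with a two-sided p from
the t distribution (n − 2 d.f.); constant inputs are errors. The odds
ratio is `ad/bc` with Haldane–Anscombe 0.5-correction when any cell is
zero and a Woolf 95% interval on the (possibly corrected) cells; the
2×2 construction for thickness change is rows = |combined score| = 1
vs 0, columns = comparison exceeds ±1.5 mm vs not — a declared
convention, since the source table construction is not published.
Wilcoxon rank-sum is exact by enumeration for tie-free pooled n ≤ 20,
otherwise the normal approximation with midrank ties and continuity
correction. Shapiro–Wilk is the standard coefficient approximation.
Two-sided p-values throughout; no multiple-testing correction.

The synthetic cohort generator imposes a monotone effect of the combined
score on the change in median thickness (+0.8 mm per score unit, chosen
to match the improved-group median change; Gaussian noise σ = 0.35 mm)
and a multiplicative volume effect (8% per score unit, σ = 4%), with
baseline thickness 3.5 ± 0.9 mm and volume 10,576 ± 3,698 mm³. Scores
come from configured marginals (exact counts assigned by a seeded
permutation, or probabilities), with a 15% clinical-discordance rate;
scores are sampled, not generated by a disease model, since no
generative model of scores is available. At these settings the
score–thickness correlation is recovered (r > 0, p < 0.05) in ≥ 90% of
seeded replicates.

## Problem sizes and tolerances

The test suite and the acceptance script run the full high-field-like
study on the default 60 mm phantom at a 0.3 mm truth grid, 0.31 mm
reconstruction and intersection pitch, and 0.5 mm wrap pitch; thickness
maps on final parts use a seeded 6,000-vertex subsample. Unit fixtures
(slabs, spheres, cylinders, frustums) are sized so analytic volumes and
thicknesses are known; mesh-volume and comparison tolerances in the
tests (1–5%) reflect voxelization and tessellation error at those
pitches, not statistical variation. Coarser phantoms (0.5–1.0 mm grids,
45 mm length) back the registration and multi-seed fusion-benefit
properties.

## Known limitations

* Boolean fusion is voxel-based; surfaces closer than the pitch are not
  resolved exactly (an exact-mesh backend could be plugged in).
* The wall-thickness convention yields long chords on curved rims (see
  above); min/median are robust to this, the maximum is by construction
  a chord statistic, not a diameter.
* The 3 mm distal sheet genuinely straddles the 3.6 mm dorsal slice
  spacing in places; those bands fall below the 0.5 occupancy threshold
  in two adjacent slices and are unrecoverable from the binarized
  stacks, bounding achievable fused Dice at ≈ 0.95 under the default
  geometry.
* Registration assumes substantial initial overlap (same anatomy, small
  displacement); there is no global pre-alignment search.
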