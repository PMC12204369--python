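# Methods

This note documents the models, estimators, parameter choices and known
limitations of `chromodomain3d`. Everything quantitative stated here is
computed by the test suite or the acceptance script; nothing is quoted
from external measurements.

## Coordinate and data conventions

All voxel grids are indexed `(channel, z, y, x)`, 0-based, with physical
spacing `(z, y, x)` in micrometres carried on every container. Stacks
are OME-TIFF (spacing and channel names round-trip through the OME
metadata; the file UUID is derived from the voxel content so identical
data produce byte-identical files). Label masks are 16-bit TIFFs,
feature tables CSV, statistics reports JSON.

## Z interpolation

SIM stacks are anisotropic: 0.06 μm laterally, 0.15 μm axially. Between
each pair of adjacent real slides two slides are inserted, each the
distance-weighted average of its neighbours with weights 2/3 (closer
slide) and 1/3 (farther slide). N real slides become 3N−2 slides at
0.05 μm spacing, close to the lateral pitch. Interpolated values stay
in floating point — re-quantizing to integer ADU would add rounding
bias to the downstream intensity features for no benefit. Real slides
are preserved bit-identically at stride 3, which the synthetic recovery
tests exploit to sample native-grid voxels exactly. Single-slide stacks
pass through unchanged with a warning so flat fixtures can reuse the
pipeline. Properties enforced by tests: per-pixel convexity, linearity
in the input intensities, and recoverability of the real slides.

## Nucleus segmentation

Segmentation is 2D, slide by slide, because even balanced stacks are
tens of times wider than they are deep. Per slide: intensities strictly
above the DAPI gate (default 500 ADU) are ON; ON pixels form 8-connected
components; the 15 largest (ties broken by the smallest (y, x)
coordinate in the region) are refined by hole filling, 10 binary
dilations with the full 3×3 element, and a second hole filling; a
refined region is a nucleus if it has at least 100,000 pixels and
circularity 4πA/P² above 0.4. Circularity is the 2D analogue of the 3D
sphericity used for domains — the shape filter runs on 2D slices, so a
2D score is the dimensionally consistent choice. The perimeter comes
from scikit-image's regionprops estimator.

Boundaries are extracted with Sobel filters along y and x on the 0/1
mask, combined as the gradient magnitude and binarized at any nonzero
response, restricted to ON pixels that touch background through a
4-neighbour. The last restriction matters at concavities: the raw Sobel
response also fires on interior pixels whose only background contact is
diagonal, which would break the invariant that every boundary voxel is
adjacent to background. On solid convex regions at least two pixels
thick the result equals the erosion-difference boundary exactly (tested
against that oracle); the gradient cancels on one-pixel-thin
structures, which do not occur for nuclei.

The 100,000-pixel gate assumes ~1500×1500-pixel slides at 0.06 μm. On
smaller synthetic fields the same gate would exceed the slide area, so
the synthetic preset scales it to 5,000 pixels (and narrows the shift
search window); every threshold is a config key and the published
values are the defaults.

## Channel alignment

The ER channel carries a small systematic lateral offset relative to
H3K27ac. For every integer shift (dy, dx) in a square window (default
±20 px) the Pearson correlation between the overlapping portions of the
two images is evaluated; the argmax is the estimated displacement of
the moving channel, with ties broken by smallest |dy|+|dx| and then
lexicographically. One global shift per stack is estimated on the
maximum-intensity Z projections — the offset is an optical property,
not a per-slide one — and the moving channel is translated back by it
on every slide, vacated pixels zero-filled. Per-slide estimates can be
retained for QC but are not applied. Pearson correlation makes the
estimate invariant to affine intensity rescaling; constant images raise
a degenerate-input error. Integer shifts only: subpixel registration
would interpolate intensities and contaminate the per-voxel
correlation feature.

## Domain detection

The ON threshold is data driven: intensities of the H3K27ac channel at
voxels *outside* the nucleus mask form the background sample, and the
threshold is its 99.9th percentile (linear interpolation between order
statistics) — the value exceeded by the top 0.1% of background. A
background sample under 1,000 voxels raises an unreliable-threshold
error. In-nucleus voxels above the threshold are grouped into 3D
connected components under the full 26-neighbourhood (the 3D analogue
of 2D 8-connectivity; 6 and 18 are config options). Each component is
refined independently on a padded bounding box — 3D hole fill, two
dilations with the 3×3×3 element, hole fill — then clipped back to the
nucleus mask so refinement cannot leak into the background used for
thresholding. Components whose refined volume lies in [10, 100,000]
voxels become domains, with per-channel intensity vectors sampled from
the aligned stack in (z, y, x) raster order.

The size filter applies after refinement, so the two-dilation step sets
an effective minimum: even a single ON voxel refines to a 5×5×5 block
(125 voxels) and passes the lower bound. The refinement also adds a
deterministic shell (two voxels plus the diffraction skirt above
threshold) around every true structure; at domain scales of 0.1–1 μm³
this inflates detected volumes severalfold. Condition comparisons are
unaffected (both sides inflate alike), but recovery tests compare
detected voxels against the *expected detection support* — the
noise-free imaging model (support → PSF blur → threshold) refined with
the same morphology — rather than the raw geometric support, so they
measure noise robustness and labeling fidelity, not the known halo.

## Per-domain features

* **Volume** — raw voxel count, and count × voxel volume in μm³.
* **Sphericity** — φ = π^⅓ (6V)^⅔ / S with physical V and S, so φ is
  dimensionless on anisotropic grids. S defaults to the area of the
  marching-cubes iso-surface at level 0.5 of the domain indicator
  smoothed with a 0.8-voxel Gaussian: meshing the raw binary grid
  inherits the voxel staircase and overestimates S by up to ~10%
  (biasing φ low), while the smoothed-indicator level set tracks the
  true interface — on digitized spheres of radius 10–20 voxels the area
  error is under 2% and |φ−1| decreases monotonically with radius.
  Counting exposed voxel faces is available as `voxel_faces` and is the
  automatic fallback for domains too thin to mesh (under two voxels in
  any bounding dimension); it overestimates S and is flagged in the
  output. Very small near-spherical shapes (radius ~5 voxels) can
  exceed φ = 1 by a few percent from residual estimator error.
* **Cross-channel correlation** — Pearson r of the per-voxel H3K27ac
  and ER intensities over the domain, voxels in raster order; zero
  variance yields a NaN sentinel that is excluded from statistics and
  counted in QC. Because the detected domain includes the refinement
  halo (background in both channels), the measured r is diluted toward
  zero relative to the coupling inside the true structure; the dilution
  is common to all conditions and monotone in the underlying coupling.
* **Boundary distance** — Euclidean distance with per-axis spacing
  scaling from the domain centroid to the nearest nuclear-boundary
  voxel (`nearest`-voxel anchoring available). The centroid gives one
  representative value per domain, matching the one-number-per-domain
  feature design.
* **Length** — voxel centres are mapped to physical coordinates, the
  principal axis of their covariance is taken (SVD), and length is the
  extent of the projections plus one voxel pitch along that axis, so a
  single voxel has length one pitch and an n-voxel straight line has n
  pitches.

## Statistics

Two-sample comparisons use Welch's t by default (the pooled-variance
form is a config option) with one-sided alternatives; per-batch t
statistics are reported with the sign convention that positive means
higher in the first condition of the declared pair. Because imaging
features are generally non-Gaussian, the pipeline always runs the
nonparametric battery — Kruskal–Wallis across conditions, and when the
omnibus p < 0.05, all pairwise Mann–Whitney U tests with Bonferroni
correction (raw p × number of pairs, capped at 1) — with Shapiro–Wilk
and Kolmogorov–Smirnov results attached as annotation only.
Significance codes are \*, \*\*, \*\*\* at 0.05, 0.01, 0.001.

Heterogeneity within single cells is the Gini index of each feature
over the domains of that cell, G = Σᵢⱼ|xᵢ−xⱼ| / (2n²μ), computed via
the sorted-rank identity (exactly the pairwise formula, verified by
brute force in tests); Gini distributions are then compared across
conditions with the same nonparametric battery. Volume-class
distributions split domains into four classes at the quartiles of the
pooled volume distribution (the class boundaries are not externally
prescribed, so quartiles are the neutral default; fixed edges can be
passed, and the edges used are always written to the report).
Length-vs-volume relationships use ordinary least squares of volume on
length with r², p and standard error reported.

## Synthetic data model

The generator renders what the analysis assumes, at native (0.15 μm Z)
spacing so the interpolation stage is always exercised:

* **Nucleus** — one ellipsoid per field (default semi-axes 0.8 × 6 × 6
  μm in a 12 × 256 × 256 field); DAPI 800 ADU inside vs 100 outside, so
  the 500 gate bites with margin on both sides of the PSF edge.
* **Domains** — "closed" domains are spheres (radius uniform in
  0.15–0.28 μm); "open" domains are curved tubes (persistent random-walk
  spines, mostly in-plane because nuclei are thin axially; radius
  0.12–0.18 μm, length 1.2–2.2 μm), larger in volume and lower in
  analytic sphericity (sphere φ = 1; tube φ from the closed form for a
  cylinder). Domains are placed disjointly with a 2-voxel separation
  halo inside the nucleus, within a configurable normalized radial band:
  the closed-rich preset places domains peripherally (0.55–1.0,
  emulating lamina-proximal heterochromatin) and the open-rich preset
  interiorly (0–0.75), which is what gives the boundary-distance
  contrast its direction.
* **Intensities** — H3K27ac: dim nucleoplasm floor (100 ADU), strong
  in-domain signal (3000 ± 800 per voxel), and a brighter, heterogeneous
  extranuclear background (150 plus a |N(0, 40)| smooth field). The
  background asymmetry is essential to the thresholding model: the
  top-0.1-percentile rule only isolates domains if the nucleoplasm floor
  sits below the background tail. The bright component stays outside a
  1.5 μm perinuclear shell because the 10-iteration nucleus dilation
  swallows that shell into the mask — bright same-distribution voxels
  there would register as spurious boundary domains. ER: a diffuse
  nucleoplasmic pool (600 ± 100) at the same mean as the in-domain
  level, so domain edges carry no ER intensity step; extranuclear 300.
* **Coupling** — inside each domain the ER voxel values are
  `er_level + er_sigma · (ρ·ĥ + √(1−ρ²)·ŵ)`, where ĥ is the
  PSF-blurred H3K27ac field standardized over the domain support and ŵ
  an equally blurred independent field orthogonalized against ĥ over
  that support. Mixing after blur, with orthogonalization, makes the
  realized support correlation exactly ρ (mixing before blur would let
  the blur destroy the white independent component and drive the
  realized correlation toward 1 regardless of ρ; without
  orthogonalization the chance correlation of the two blurred fields
  over small supports scatters the realized value by ±0.3).
* **Optics and noise** — Gaussian PSF with σ = (0.075, 0.05, 0.05) μm,
  SIM-scale; white camera noise (σ = 20 ADU) added after blur; values
  clipped at 0; optional integer (dy, dx) translation of the ER channel
  for the registration stage to recover.

Per-cell seeds are derived from the experiment seed with spawn keys, so
an experiment is reproducible file-by-file, byte-for-byte.

What the generator does **not** emulate: SIM reconstruction artefacts
(honeycomb patterns, negative ringing), spatially varying illumination,
nucleoli and other DAPI substructure, touching nuclei, chromatic
aberration beyond a rigid lateral shift, and photobleaching. Passing
tests therefore demonstrate that the pipeline recovers the stated
structure under an idealized but non-trivial imaging model — not that
it is robust to every artefact of real microscopes.

## Problem sizes used in tests

Unit tests run on 96 × 96 × 8 fields (about 0.1 s per cell to generate
and 1 s to process). The end-to-end acceptance experiment uses the full
generator defaults — 2 conditions × 3 cells × 2 batches of 256 × 256 ×
12 stacks with a (2, −3) ER shift — chosen so the pooled comparison has
roughly 120 domains per condition, enough for the Bonferroni-corrected
contrasts to resolve at p < 0.001 while the whole suite stays
interactive (about a minute for the experiment, half a minute for
everything else).

## Known limitations

* The per-slide nucleus gate rejects slides whose cross-section falls
  below the pixel threshold, truncating the mask at the axial poles of
  the nucleus (a ~1% volume effect on the default geometry).
* The 10-iteration nucleus dilation places the recorded boundary
  ~0.6 μm outside the DAPI edge, shifting all boundary distances by a
  common offset; comparisons are unaffected.
* Detected domain volumes include the refinement halo (see above);
  absolute volumes are estimator-specific and should be compared within
  a pipeline, not across pipelines.
* Mann–Whitney p-values use the normal approximation with tie
  correction, appropriate at the sample sizes produced here.
* The nonparametric battery treats domains as independent observations
  within a condition; batch structure is addressed by the per-batch t
  summaries, not by a mixed model.
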