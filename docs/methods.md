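# Methods

## Scope and data model

`nichequant` quantifies multi-channel 3D stacks of the ventricular–
subventricular zone (V-SVZ) neurogenic niche: laminin (vessel basement
membrane), DCX (migrating neuroblast chains), GFAP (type B stem cells),
Ki67 (cycling cells) and DAPI (nuclei). Stacks are stored as plain
multi-page TIFF (pages = z) with voxel spacing in a JSON sidecar
(`spacing_um = [dz, dy, dx]`), never embedded in TIFF tags — this avoids
TIFF-dialect ambiguity and makes a missing spacing a hard error rather
than a silent default. Arrays are ordered `(z, y, x)`; the `z = 0` face
is the apical (ependymal) surface, so a cell's apical depth is the z
coordinate of its centroid in micrometres. For real data a user-supplied
reference surface can replace this convention.

## Segmentation and the niche volume

Channels are thresholded with Otsu's method (default) or a fixed
threshold, optionally after Gaussian smoothing with a sigma given in µm
and converted per axis by the voxel spacing (default 0.5 µm). Smoothing
matters in practice: on sparse channels (nuclei occupying < 1% of the
volume) Otsu on raw noisy data can place the threshold inside the
background mode; a sub-voxel smooth restores a clean bimodal histogram.
Voxels strictly above the threshold are foreground; a morphological
opening of configurable radius removes specks.

The densities reported downstream need a denominator — the total niche
volume — which is not derivable from any single stain. We define it as
the morphologically closed (default radius 5 µm), per-slice hole-filled
union of all stained channels, computed on a padded array so closing
never erodes the border; the result always contains every channel mask.
A user-supplied niche mask can replace this rule (the phantom pipeline
uses the full slab, since the generator fills the whole grid).

Connected components use 26-connectivity by default (tubes and chains
continue across diagonals); labels are sorted by descending voxel count
with deterministic tie-breaking.

## Vessel morphometrics

**Centerline extraction.** Classical 3D topological thinning is parity
sensitive on binary tubes: a tube whose cross-section is an even number
of voxels wide has no central voxel, and the thinning implementation
available to us erases such tubes entirely (a 2×2×N rod thins to the
empty set) or leaves two-voxel-thick ribbons. Since phantom tubes — and
real capillaries a few voxels wide — hit these cases routinely, we
extract centerlines instead by **EDT-penalised geodesic tracing** on the
voxel adjacency graph (26-neighbour edges, lengths in µm):

1. resample anisotropic masks to isotropic spacing (finest axis, linear
   interpolation) so distances are honest;
2. per connected component, find the two geodesically most distant
   voxels (two farthest-point sweeps from the maximum-EDT seed) and
   join them with a shortest path whose edge costs are divided by
   `(EDT² + ε)`, which pulls the path onto the medial core of the tube
   (ε = 0.25 µm² keeps surface costs finite);
3. iteratively add branches from the voxel farthest (in µm geodesic
   distance) from the current skeleton, stopping when the residual
   reach falls below the spur threshold — by default `2 ×` the local
   vessel diameter at the attachment point, which suppresses end-cap
   and surface artefacts exactly where thinning pipelines prune spurs;
   an explicit `prune_length_um` overrides it;
4. free branch ends are trimmed of their strictly EDT-climbing prefix,
   snapping endpoints from end-cap corners onto the medial core.

The result is deterministic, lies inside the mask, yields one connected
skeleton per mask component, and arrives already decomposed into
node-to-node branches (attachment points split existing branches, so
junctions have degree ≥ 3). A known limitation of the shortest-path
tree: closed vascular loops cannot be represented as cycles; a loop
would be traced as an open path. Branches with coincident endpoints are
flagged and excluded from tortuosity medians.

**Tortuosity** is path length over chord length per branch. Voxel paths
staircase along curved tubes and overestimate smooth arc length by a few
percent, so path length is measured on the polyline after a centred
5-point moving average with pinned endpoints (a straight path is
unchanged, so straight tubes still measure exactly 1). On phantoms this
recovers 1.0 for straight tubes, π/2 within < 1% for a semicircle of
radius 40 µm, and the quadrature arc length of a sine tube within < 1%.
The unit of analysis is the skeleton branch; per-sample summaries use
the median, matching how such skewed object-level metrics are normally
reported.

**Diameter** is the standard skeleton-radius estimator: the mean over
branch voxels of twice the mask's Euclidean distance transform. On a
voxel lattice the discrete cylinder of nominal radius r contains all
lattice points up to the next attainable lattice norm, so recovered
diameters carry an upward quantisation bias of up to one voxel —
phantoms with 3 µm and 4.5 µm radii at 1 µm spacing recover 6 and 9 µm
within ± 1 µm. Vessels with mean diameter < 10 µm are classified as
capillaries (config key `capillary_max_diameter_um`). Diameter
distributions can be weighted per branch (each branch's mean once) or
per voxel (local diameters repeated), since published vessel counts do
not disambiguate the unit; both feed the KS comparison unchanged.

**Density** is the vessel voxel count over the niche voxel count, with a
containment check (vessels must lie inside the niche).

## Chain metrics

DCX+ objects are 26-connected components above a minimum volume
(default 50 µm³). Eccentricity is `1 − PC_mid / PC_max` with principal
components taken as the **standard deviations** (square roots of the
eigenvalues) of the µm-scaled voxel-cloud covariance. The SD convention
yields the intuitive semi-axis ratio — a 10:5:2 µm ellipsoid scores
0.5 — while the raw-eigenvalue alternative (config
`eccentricity_convention: variance`) would score 0.75; the two agree
exactly on the anchor cases (line → 1, circle/sphere → 0), which is all
the definition pins down, so the choice is surfaced rather than hidden.
Numerically, eigenvalues below 10⁻⁹ of the largest are clamped to zero
and component ties within 10⁻⁹ relative are treated as exact, so the
anchor cases come out exactly 1 and exactly 0 despite floating-point
round-off; a cloud of coincident points has no defined eccentricity and
is flagged NaN. Chain density is DCX voxels over niche voxels, with an
optional ROI mask (the "anterior" region is an explicit mask input, not
inferred anatomy).

## Cells and proximity

Nuclei are DAPI components within volume bounds (default 20–2000 µm³,
spanning roughly 3.3–15.7 µm equivalent diameter). A cell is
marker-positive when `|nucleus ∩ marker| / |nucleus| ≥` the overlap
threshold (default 0.3, boundary inclusive; raising the threshold never
adds positives). The apical filter keeps cells whose centroid depth is
≤ 5 µm. Marker counts intersect an optional ROI on the centroid.

The vessel distance map is the anisotropy-aware Euclidean distance
transform of the vessel-mask complement, in µm; the laminin mask itself
operationalises the "vessel surface", with no erosion, since laminin
stains the basement membrane at the surface. Cell distances support
centroid and surface modes (surface = minimum over boundary voxels,
never larger than centroid; surface is the default, centroid is kept
for sensitivity checks); chain distances always use the object surface.
An object overlapping the vessel mask reports 0 µm with a warning.

## Time-lapse population slope

Movies are sequences of 2D frames at a fixed capture interval (default
5 minutes; the default simulated movie length is 980 frames, matching
the 4-day protocol the package targets). Each frame is thresholded
(Otsu per frame, or fixed) and counted as connected components above a
minimum area; constant frames are unsegmentable and flagged. The
population slope is the OLS slope of count versus frame index —
identity tracking is deliberately not required, because the statistic
only needs counts. Slope per hour = slope per frame × 60/interval.
R² of a zero-variance series is defined as 0.

The simulator draws one fate per cell per frame (divide with
probability p, die with probability q, else persist; a multinomial per
frame), renders cells as non-overlapping disks, and records true counts.
The recorded expected slope is the OLS slope of the **exact mean
trajectory** `n₀(1 + p − q)^t`. Because OLS is linear in the data, the
fitted slope's expectation equals this value exactly at any horizon;
the familiar linear-regime rate `n₀(p − q)` per frame (also recorded)
is its small-`(p−q)·T` limit but understates the expectation by tens of
percent once `(p − q)·T ≈ 1`, so Monte-Carlo checks compare against the
exact value.

## Statistics

Object-level morphometrics (tortuosity, diameter, eccentricity) are
summarised per sample by the median and compared with the Wilcoxon
rank-sum test: midrank ties, exhaustive enumeration of the null when
`min(n_A, n_B) ≤ 8` (ties handled exactly), tie-corrected normal
approximation otherwise. The implementation is written out rather than
delegated because the available library routine's exact mode does not
accommodate ties; its size is calibrated empirically (type-I error
0.05 ± 0.01 at α = 0.05 over 10⁴ null pairs of n = 20).

Diameter distributions are compared with the two-sample KS test
(asymptotic p). Densities, counts and slopes use mean ± SEM and a
two-way age × sex ANOVA on an effect-coded linear model with **type-II
sums of squares** — robust to the mild imbalance of 4–6 animals per
group, and identical to type-I on balanced designs (tested). Degenerate
designs are guarded explicitly: a zero effect over a zero error term
reports F = 0 (p = 1), a nonzero effect over a zero error term reports
F = ∞ (p → 0), and an empty design cell raises an error naming the
cell. Post hoc correction is Sidak (`p' = 1 − (1 − p)^m`) or Tukey HSD
(studentized range over the pooled error term), selectable per metric.
Reports emit both object-level pools and per-animal summaries, labelled,
so pseudo-replication is always visible.

## Phantom generator

The generator is the package's oracle. Geometry is computed in µm and
rasterised with a single rule: a voxel is foreground iff its centre lies
inside the object (no antialiasing), which makes volume fractions
analytic up to voxelisation. Tube membership is evaluated against a
densely sampled centreline polyline (step = half the finest spacing)
with the radius compensated by the half-step sampling error, so lattice
points lying exactly on the tube surface — common on integer lattices —
are included, as the continuous rule demands. Cylinder volume fractions
re-measured by voxel counting then match πr²L/V within a few percent
for radii ≥ 3 voxels (tolerance stated as ±10%).

Centreline kinds: straight, sine (amplitude/wavelength), helix, and
constant-speed circular arc; analytic tortuosity is recorded from the
clipped polyline. Cells are spheres placed on voxels satisfying the
requested apical depth (± half the z spacing) and vessel distance
(± half a voxel diagonal, measured on the truth vessel EDT), with
centre separation ≥ sum of radii + 2 µm so 26-connected components
never merge; the truth records the *achieved* values, which recovery
tests then reproduce exactly up to segmentation error. Chains are
rotated ellipsoids; GFAP halos are enlarged spheres around flagged
nuclei. Intensities are two-level (background 20, foreground 200) with
additive Gaussian noise clipped at zero. All randomness flows from a
single seed through independent spawned streams, so a fixed seed fixes
every output byte (including the written TIFFs).

What the phantom does **not** emulate: microscope point-spread
functions, depth-dependent attenuation and bleaching, tile-stitching
artefacts, touching/overlapping somata, non-Gaussian noise, and curved
apical surfaces. Passing recovery tests therefore demonstrates estimator
correctness on well-posed geometry, not robustness to every real-world
degradation; the segmentation knobs (smoothing, opening, fixed
thresholds) are the levers for real data.

## Default parameters

| key | default | meaning |
|---|---|---|
| `apical_threshold_um` | 5.0 | max centroid depth for an apical cell |
| `capillary_max_diameter_um` | 10.0 | capillary classification cutoff |
| `gfap_overlap_fraction` | 0.3 | nucleus/GFAP overlap for GFAP+ |
| `nucleus_min/max_volume_um3` | 20 / 2000 | nucleus detection bounds |
| `smoothing_sigma_um` | 0.5 | Gaussian pre-smoothing |
| `niche_closing_radius_um` | 5.0 | closing radius for the niche union |
| `min_chain_volume_um3` | 50.0 | chain size floor |
| `spur_prune_factor` | 2.0 | spur threshold in local diameters |
| `connectivity` | 26 | component connectivity |
| `eccentricity_convention` | sd | principal components as SDs |
| `cell_distance_mode` | surface | cell-to-vessel distance mode |
| `timelapse_interval_min` | 5.0 | capture interval |

The 5 µm apical cutoff and the 10 µm capillary cutoff are the field's
standard operating definitions for this niche; the overlap fraction and
size bounds are artifact decisions surfaced as config keys.

## Problem sizes

Validation phantoms are sized so the whole suite runs in seconds on one
CPU: tube phantoms of 41×41×100 voxels at 1 µm isotropic spacing (tube
length ≈ 100 µm, 5–20× the diameter, enough for end effects to be
negligible), distance-map oracles on grids up to 25³ against explicit
minimum-over-voxels search, 50-seed Monte-Carlo runs of 200-frame count
series for the slope, and 10⁴ null replicates for the rank-sum size
check. The end-to-end pipeline demonstration uses four to eight samples
of 20–24 z-planes each. Larger stacks change runtime, not code paths:
every stage is linear or near-linear in voxel count except geodesic
tracing, whose graph covers only foreground voxels.
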