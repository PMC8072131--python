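# nichequant

3D image quantification of the ventricular–subventricular zone (V-SVZ)
stem-cell niche.

The adult V-SVZ lines the lateral ventricle wall and hosts neural stem
cells (GFAP+ type B), transit-amplifying progenitors (Ki67+ cycling
cells) and migrating neuroblasts (DCX+), all organised around a planar
vascular plexus labelled by laminin. Whole-mount preparations image the
entire niche as one multi-channel z-stack, and the biology of interest —
how vessels and progenitors change with age and sex — is read out through
a handful of morphometric statistics. `nichequant` implements that
readout as a tested, reusable pipeline for anyone analysing such stacks
(or any comparable 3D vessel/cell imaging data):

* **Vessel tortuosity** `τ = L_path / L_chord` per skeleton branch
  (τ ≥ 1; 1 = perfectly straight), from centerlines extracted inside the
  segmented laminin mask.
* **Vessel diameter** `d = mean(2·EDT)` along each branch, where EDT is
  the Euclidean distance transform of the vessel mask; vessels with
  `d < 10 µm` are classified as capillaries.
* **Vessel / chain density** = foreground voxels over total niche
  voxels (a volume fraction in [0, 1]).
* **Chain eccentricity** `e = 1 − PC_mid / PC_max` of each DCX+ object's
  voxel cloud (principal components = SDs along principal axes);
  `e = 1` for a line, `e = 0` for a circle or sphere.
* **Cell classification**: DAPI nuclei are GFAP+ when the nucleus/GFAP
  mask overlap reaches a configurable fraction (default 0.3), and
  *apical* when the centroid lies within 5 µm of the ependymal surface.
* **Minimum distances** from cell centroids/surfaces and chain surfaces
  to the nearest vessel voxel, via an anisotropy-aware distance map.
* **Population slope**: the OLS slope of cell count versus frame index
  in time-lapse movies (cells/frame, convertible to cells/hour).
* **Statistics battery**: Wilcoxon rank-sum (exact for small samples),
  two-sample Kolmogorov–Smirnov, two-way age × sex ANOVA (type-II SS)
  with Sidak or Tukey post hoc correction.

Because whole-mount datasets are terabyte-scale and not publicly
deposited, the package ships a first-class **phantom generator**: it
rasterises tubes with analytically known tortuosity/radius/volume
fraction, nuclei at known depths and vessel distances, ellipsoidal
chains with known principal-axis ratios, and birth–death time-lapse
movies with known expected slope. Every estimator is validated as a
parameter-recovery problem against this ground truth.

## Worked example

```python
import numpy as np
import nichequant as nq

spec = nq.PhantomSpec(
    shape=(24, 64, 96), spacing_um=(1.0, 1.0, 1.0),
    vessels=(nq.VesselSpec(kind="sine", radius_um=3.0, amplitude_um=8.0, wavelength_um=48.0),),
    cells=(nq.CellGroupSpec(count=6, nucleus_radius_um=2.5, depth_um=3.0, gfap=True),),
    chains=(nq.ChainGroupSpec(count=2, semi_axes_um=(9.0, 3.0, 3.0)),),
    noise=nq.NoiseSpec(sigma=15.0), seed=7,
)
channels, truth = nq.generate_niche_phantom(spec)

seg = lambda name: nq.segment_channel(channels[name], smoothing_sigma_um=0.7)
vessel = seg("laminin")
graph, branches = nq.measure_vessels(vessel)
niche = nq.BinaryMask3D(np.ones(spec.shape, bool), spec.spacing_um)

cells = nq.detect_nuclei(seg("dapi"), 20.0, 2000.0)
nq.classify_gfap(cells, seg("gfap"), 0.3)
apical = nq.filter_apical(cells, 5.0)
chains = nq.extract_chains(seg("dcx"), min_volume_um3=50.0)

counts = nq.simulate_birth_death_counts(100, 0.01, 0.005, 200, seed=7)
slope = nq.population_slope(counts, interval_min=5.0)
```

printing each measurement next to the generator's truth:

```
median tortuosity   1.217   (generator truth 1.231)
mean diameter (um)  5.63    (generator truth 6.00)
vessel density      0.0234  (generator truth 0.0223)
apical GFAP+ cells  6 of 6 nuclei   (generator truth 6 of 6)
chain eccentricity  0.649   (generator truth 0.667)
population slope    0.726 cells/frame = 8.7 cells/hour
```

The tortuosity of the sinusoidal vessel is recovered within ~1%, the
6 µm tube diameter within half a voxel, the volume fraction within 5%,
all six shallow GFAP+ stem cells are found and pass the 5 µm apical
filter, and the chain eccentricity of the 9:3 ellipsoids lands within 3%
of the analytic value 2/3. The population slope of the birth–death
movie scatters around its exact expectation of 0.84 cells/frame
(n₀ = 100, p_div = 0.01, p_death = 0.005 over 200 frames; this single
seed fits 0.73) and converts to cells/hour via the 5-minute capture
interval.

## Command line

A thin CLI wraps the library:

```sh
nichequant phantom generate --spec spec.json --out phantom/ --seed 1
nichequant segment phantom/laminin.tif --out mask.tif
nichequant vessels mask.tif --out branches.csv
nichequant run-all --config run.json --out results/ --seed 1
```

`run-all` executes phantom → segmentation → vessel/chain/cell metrics →
distance maps → time-lapse → statistics, writing per-object CSV tables,
a JSON statistics report, and a manifest with SHA-256 hashes of every
output; the same config and seed reproduce identical hashes.

## Documentation

`docs/methods.md` describes the model and estimators, the phantom
generator and what it does and does not emulate, all tunable parameters
with defaults, and numerical design choices.
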