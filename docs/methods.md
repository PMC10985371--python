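# Methods

## The geometric model

The analysis treats a compound eye locally as a sphere of radius R tiled by
a near-hexagonal lattice of ommatidia at center-to-center spacing D. Each
crystalline cone is a roughly frustum-shaped cell whose long axis is radial;
its center of mass is the operational "center" of the ommatidium. Under this
model the interommatidial angle is Δφ ≈ D/R radians, the diffraction limit
of one facet is θ = 1.22·λ/D (Rayleigh criterion for a circular aperture),
and the Barlow ratio Δφ/θ measures sampling relative to diffraction:
Δφ/θ = D²/(1.22·λ·R), so an eye at the classical optimum satisfies
D² ≈ 1.22·λ·R. Snyder's eye parameter p = D·Δφ (μm·rad) is an equivalent
design measure; at λ = 0.5 μm, p = 0.61·(Δφ/θ) is an algebraic identity
(0.61 = 1.22 × 0.5), which the code asserts per record rather than storing
twice.

Assumptions worth stating: the local sphere approximation is good over the
~4-ring (60-cone) neighborhoods used for fitting, even on eyes whose global
radius varies across regions; cone centers of mass track facet centers up to
a systematic inward offset (see "bias bound" below); and a hexagonal
first-ring of exactly six neighbors is assumed eye-wide, which fails at eye
borders and motivates the edge flag.

## Pipeline stages and parameters

| Parameter | Default | Meaning |
|---|---|---|
| `voxel_size_um` | 0.6 | isotropic voxel pitch of the imaging |
| `wavelength_um` | 0.5 | λ for the diffraction limit (peak sunlight / insect photoreceptor sensitivity) |
| `cluster_size` | 60 | points per local sphere fit (focal cone + 59 nearest ≈ 4 hexagonal rings) |
| `k_neighbors` | 6 | hexagonal first ring, used for both D and Δφ |
| `connectivity` | 26 | full 3D neighborhood for component labeling |
| `min_voxels` | 50 | size floor removing noise specks before analysis |
| `overlap_threshold` | 0.25 | fraction of cones that must share a voxel for the consensus shape |
| `edge_factor` | 1.8 | neighbor-distance multiple of the eye-wide median that flags an edge cone |

**Segmentation.** Connected-component labeling runs through
`skimage.measure.label` with a deterministic relabeling pass (components
numbered by raster order of their first voxel), so label assignment is
reproducible across runs and platforms. Size-band filtering replaces manual
cleanup of non-cone objects: anything outside `[min_voxels, max_voxels]` is
returned to background and reported with a reason. Centers of mass are
unweighted means of member-voxel centers; a voxel's center is
`(index + 0.5)·voxel_size + origin`.

**Local sphere fits.** The algebraic (linearized) least-squares sphere is
solved after centering and scaling the cluster to unit RMS radius, then
refined by one Gauss–Newton step on the geometric residuals. This is
deterministic, has no initialization sensitivity, and is exact on noiseless
spheres; a condition number above 1e8 on the design matrix marks the cluster
coplanar and the record is excluded as `degenerate_fit` rather than fitted
badly. With fewer centers than `cluster_size`, one global fit serves all
records and every record carries a warning flag.

**Neighbor queries.** Distance ties (exact on lattice-perfect synthetic
data) break by ascending cone label, making neighbor sets and hence all
derived metrics deterministic.

**Angles.** For each focal cone, radial vectors to the focal cone and each
of its six neighbors all originate at the focal cone's own fitted sphere
center — one consistent origin per record — and angles use
`atan2(‖v×w‖, v·w)`, stable near 0° and 180°. Outputs are degrees; all
internal trigonometry is radians.

**Exclusions.** Δφ > 90° is biologically implausible (it occurs at eye
borders and image defects) and excludes the record with reason `angle>90`.
Degenerate fits exclude with `degenerate_fit`. The edge flag (any neighbor
distance > 1.8× the eye-wide median neighbor distance) marks border cones
whose "six nearest neighbors" reach into the second lattice ring; it does
not by itself exclude, but edge cones are left out of the consensus shape by
default, where they are the main source of shape deviation.

**Bias bound.** Because centers of mass sit below the facet surface by up to
a cone length, center-to-center distances underestimate the facet diameter
by at most `L·Δφ` (radians) — ~1.1 μm at the defaults — reported as a
per-record diagnostic column, not corrected for.

**Typical cone.** Each cone's voxels are centered on their center of mass
and rotated by the minimal rotation taking the outward radial axis to +z
(tip toward −z; the antipodal case rotates 180° about +x by convention).
Resampling is inverse-mapping nearest-voxel: a canonical-grid voxel is kept
when its center, rotated back, lands in an occupied source voxel — this
leaves no holes, unlike forward rounding. The consensus keeps voxels
occupied by at least `ceil(threshold·N)` of N cones (floored at 1), which
preserves "at least 25%" semantics exactly for small N; the cutoff guards
against float artifacts like `0.1·10 > 1`. Rotation before overlay is a
deliberate choice: on a curved eye, merely centering the cones blurs the
consensus tangentially; `rotate=False` gives the plain-overlay behavior.

**Shape statistics.** Slice "diameter" is the equivalent-circle diameter
`2·sqrt(area/π)` of the slice's voxel area — robust to ragged voxel edges —
and the "maximum diameter at the top" is implemented as the maximum over all
slices, robust to a rounded distal cap. The cone ratio reads the slice
`round(0.10·n_slices)` above the proximal end; the aspect-ratio definition
(maximum slice diameter / length) is a package choice, documented here
because no single convention exists. Boundaries are exposed both as
6-connectivity surface voxels and as an alpha-shape mesh (Delaunay
tetrahedra with circumradius ≤ 3 voxel widths); the mesh wraps voxel
centers, so its enclosed volume undershoots the voxel volume by about half
a voxel of shell.

**Summaries and correlations.** Quantiles use linear interpolation with
quartiles at p = 0.25/0.75; the median of an odd-length sample is its middle
element exactly. The optimal Barlow band is the closed interval [0.4, 1.0].
Pearson correlations report two-sided p from t = r·√((n−2)/(1−r²)) with
n − 2 degrees of freedom. Note on notation: with n = 7 individuals the
degrees of freedom are 5, although such results are sometimes written
"r(7)"; this implementation always uses df = n − 2 and reports n and df
explicitly.

## The synthetic generator

The phantom is a spherical cap bearing a hexagonal lattice: a planar lattice
of the requested spacing in the tangent plane at the cap pole, mapped to the
sphere by an azimuthal **equidistant** projection (planar radius ρ →
colatitude ρ/R). This projection preserves arc length along meridians
exactly, so the nominal spacing and the nominal angle Δφ = spacing/R are
exact ground truth; the only distortion is tangential, sin(θ)/θ ≥ 0.994
inside a 15° cap. (A gnomonic mapping was considered and rejected: its
radial compression cos²θ reaches −6.7% at the default cap edge, which would
corrupt the ground truth the generator exists to provide.) Jitter is
tangential Gaussian noise per center; the truth records the unjittered
lattice.

Cones are solid frusta with a linear taper, axis radial, tip inward, and are
positioned with their **analytic centroid on the reference sphere**, so the
center of mass that segmentation measures coincides with the recorded true
center and recovery errors reflect the pipeline, not the phantom. The
real-anatomy offset (centers below the facet surface) is deliberately not
baked in; it is what the `L·Δφ` bias bound diagnoses on real data. Voxel
noise is independent salt/pepper label flipping under the spec seed
(flipped-on background voxels carry one reserved noise label; segmentation
consumes the volume as a binary mask and relabels, so label semantics are
restored downstream).

Defaults (R = 1000 μm, spacing 25 μm, cap 15°, cone 44 μm long tapering
20 → 7 μm, 0.6 μm voxels) sit in the biologically reported regime for
butterfly eyes and yield ~397 cones of which ~325 are interior.

What the generator does **not** emulate: correlated reconstruction artifacts
(rings, streaks), grayscale/intensity contrast and the classification step
that produces the binary mask, cone-shape curvature beyond a linear taper,
eye-wide gradients in facet size, and non-spherical (e.g. ellipsoidal)
local curvature. Passing recovery tests therefore validates the geometry
and shape machinery under the stated model, not robustness to real
segmentation noise beyond the jitter/flip levels tested.

## Numerical choices and degenerate inputs

* All randomness flows through `numpy.random.default_rng` seeded from the
  spec/config seed; identical spec + seed reproduces volumes and truth
  bit-for-bit, and pipeline reruns produce byte-identical CSV output.
* Empty foreground labels to zero objects (not an error); an all-excluded
  metrics table and an empty consensus input are errors.
* Overlapping frusta in the generator raise an error naming the colliding
  pair rather than silently merging.
* `rint`-style half-integer rounding is avoided in resampling (see inverse
  mapping above).
* Sphere-fit degeneracy threshold (condition number 1e8) is conservative:
  well-conditioned 60-point caps sit around 10²–10³ after normalization,
  coplanar clusters at ~10¹⁶.

## Problem sizes

The test suite and the acceptance script run phantoms at three scales: the
full default cap (0.6 μm voxels, 133 Mvoxels, ~400 cones) for the headline
recovery check, an 8° cap at 1 μm voxels (~120 cones) for most integration
tests, and center-only lattices (no rasterization) for geometry and
statistics tests. These sizes were chosen so the complete suite exercises
every stage at full resolution at least once while staying fast enough to
run habitually.

## Known limitations

* Interommatidial angles assume exactly six meaningful neighbors; at eye
  borders the estimate mixes in second-ring neighbors and is only flagged,
  not corrected.
* The Barlow-band fraction inherits any bias in Δφ at borders; summaries
  should be read over included (and, where reported, interior) cones.
* The typical cone averages away real within-eye shape variation by design;
  per-cone shape tables are the tool for studying that variation.
* No wave-optics modeling of light propagation through the cone is
  attempted; the outputs are geometric.
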