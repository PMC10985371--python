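# eyemetrics

Compound-eye morphometrics from 3D volumes of crystalline cones.

Modern micro-CT of insect eyes resolves every crystalline cone — the tapered
transparent cell that funnels light from each facet lens onto its rhabdom —
across an entire eye at sub-micrometre voxels. `eyemetrics` turns a labeled
(or binary/probability) cone volume into the optical design parameters of the
eye, per ommatidium:

* **D** — ommatidial (facet) diameter: the mean distance from a cone's center
  of mass to its six nearest neighbors;
* **Δφ** — interommatidial angle: the mean angle between a cone's radial
  vector and those of its six nearest neighbors, where radial vectors
  originate at the center of a least-squares sphere fitted to the cone's
  60-point neighborhood (the local eye radius **R**);
* **θ** — diffraction-limited resolving power, `θ = 1.22·λ/D` with
  λ = 0.5 μm by default;
* **Barlow ratio** — `Δφ/θ`, dimensionless; ≈1 at the classical optimum
  balancing angular sampling against diffraction, with [0.4, 1.0] treated as
  the optimal band; >1 means the visual scene is undersampled;
* **Snyder eye parameter** — `p = D·Δφ` (μm·rad), which equals
  `0.61·(Δφ/θ)` identically at λ = 0.5 μm.

It also builds a consensus **"typical cone"** per eye — all cones centered,
rotated onto their radial axes and overlaid, keeping voxels occupied by at
least 25% of cones — and measures cone length, **cone ratio** (slice diameter
10% up from the proximal tip over the maximum diameter; smaller = more
pointed) and **aspect ratio** (maximum diameter over length), plus eye-level
summaries (medians, IQRs, optimal-band fractions) and Pearson correlations
against body-size metadata such as wingspan.

A synthetic spherical-eye generator with exact ground truth (hexagonal cone
lattice on a spherical cap, tapered frustum cones, optional jitter and voxel
noise) makes the whole pipeline testable end to end with no external data.

## Worked example

```python
import eyemetrics as em

# a spherical cap phantom: R = 1000 μm, 25 μm facet lattice, 44 μm cones,
# 0.6 μm voxels — ground truth Δφ = degrees(25/1000) = 1.432°
volume, truth = em.generate_phantom(em.DEFAULT_SPEC)
results = em.analyze_volume(volume, em.PipelineConfig())

m = results["metrics"]
interior = truth.interior_mask() & ~m["excluded"].to_numpy()
sub = m.loc[interior]
print(f"cones: {results['n_objects']}, interior: {len(sub)}")
print(f"median D      = {sub['D_um'].median():.2f} um")
print(f"median dphi   = {sub['delta_phi_deg'].median():.3f} deg")
print(f"median theta  = {sub['theta_deg'].median():.3f} deg")
print(f"median Barlow = {sub['barlow_ratio'].median():.3f}")
print(f"median R      = {sub['R_local_um'].median():.1f} um")
typ = results["typical_cone"]
print(f"typical cone: L = {typ.length_um:.1f} um, "
      f"cone ratio = {typ.cone_ratio:.3f}, aspect = {typ.aspect_ratio:.3f}")
```

prints

```
cones: 397, interior: 325
median D      = 24.95 um
median dphi   = 1.429 deg
median theta  = 1.401 deg
median Barlow = 1.020
median R      = 1000.2 um
typical cone: L = 44.4 um, cone ratio = 0.427, aspect = 0.453
```

The pipeline recovers the phantom's lattice spacing (25 μm) to 0.2%, its
nominal interommatidial angle (1.432°) to 0.3% and its sphere radius
(1000 μm) to 0.02%. The Barlow ratio ≈ 1.02 follows from the chosen
geometry: `Δφ/θ = D²/(1.22·λ·R)` ≈ 625/610. The typical-cone ratio 0.427
matches the linear-taper closed form `0.35 + 0.10·(1 − 0.35) = 0.415` for a
7/20 μm bottom/top frustum to within discretization.

The same analysis runs from the shell:

```sh
eyemetrics simulate --cap 15 --out phantom
eyemetrics segment  --in phantom.tif --out seg
eyemetrics geometry --centers seg_centers.csv --out metrics.csv
eyemetrics cones    --labels seg_labels.tif --out-dir cones/
eyemetrics report   --metrics metrics.csv --out-dir report/
# or everything at once, with a JSON run manifest:
eyemetrics run --in phantom.tif --out-dir out/
```

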