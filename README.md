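# otomorph

3D morphometry of the developing human inner ear from labeled
(segmented) micro-CT volumes: cochlear-duct centerline length, endolymph
volume and volume/length ratio, distances between the five vestibular
sensory organs, linear growth trends over gestational weeks, and rigid
registration of 2D labeled histological sections into the 3D volume.

The package is aimed at quantitative anatomists and developmental
biologists who have a voxel segmentation of the membranous labyrinth
(scala media, perilymphatic compartments, vestibular sensory epithelia)
and want reproducible, scriptable measurements of how the labyrinth
grows — the kind of measurements usually done interactively in
commercial 3D software, here re-implemented as a tested, open pipeline.
Because real specimen scans of this kind are rarely shareable, every
stage is validated against synthetic voxel phantoms whose geometry
(lengths, volumes, centres) is known analytically.

## The measurements

**Duct length.** The scala media is a coiled tube; its length is the arc
length of its centerline. The pipeline conditions the binary duct mask —
resample ×2, grow 5 voxels, 3 steps of contour smoothing, shrink 5
voxels — then thins it to a one-voxel-wide skeleton (3D medial-axis
thinning), converts the skeleton to a spatial graph with physical edge
lengths, keeps the single longest endpoint-to-endpoint path, relaxes it
with an anchored Laplacian smoother (smoothing 0.85, adherence 0.05,
200 iterations), extends the ends to the mask boundary, and sums the
segment lengths:

L = Σᵢ ‖xᵢ₊₁ − xᵢ‖   (μm, reported also in mm)

**Volume.** Exact voxel counting on the raw label, `V = N · Δx·Δy·Δz`,
reported in μm³ and μl (1 μl = 10⁹ μm³); the ratio `V/L` in μl/mm
approximates the mean luminal cross-section.

**Organ distances.** Each sensory organ is reduced to the unweighted
centre of mass of its voxels; distances are Euclidean norms between
centres, assembled into a symmetric matrix.

**Growth trends.** Ordinary least squares of each quantity against
gestational week: slope, intercept, and r².

**Section registration.** A 2D labeled section maps into the volume via
a 6-DOF rigid transform (unit quaternion + translation). Starting from a
caller-supplied rough pre-alignment, a staged Nelder–Mead search
maximises the mean Dice overlap `2|A∩B|/(|A|+|B|)` between the section
and the corresponding virtual slice of the volume (nearest-neighbour
label sampling).

## Worked example

```python
import otomorph as om

spec = om.PhantomSpec()                      # 2.5-turn duct, 10 μm voxels
volume, truth = om.make_spiral_duct_phantom(spec)
result = om.measure_duct_length(volume, label=1)
print(result.length_um, truth.length_um)
```

Running `python examples/01_duct_length.py` prints:

```
analytic arc length :    19730.1 μm
measured length     :    19619.0 μm  (19.619 mm)
relative error      :       0.56 %
```

i.e. the full pipeline recovers the quadrature arc length of the
analytic spiral to about half a percent at 10 μm voxels. The other
scripts in `examples/` demonstrate volumes and the μl/mm ratio, organ
distance matrices, growth-trend reports over a stage series, section
registration (final Dice 1.000, pose error ~0.01° / 0.05 μm on the
phantom), and file-format round trips. A thin CLI wraps the same
library calls:

```bash
otomorph phantom --out duct.nii --kind duct
otomorph measure-duct duct.nii --out results/
otomorph report GW11=a.nii GW19=b.nii --out report/
```

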