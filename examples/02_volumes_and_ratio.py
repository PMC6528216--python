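"""Endolymph volume and volume/length ratio of the duct.

Volume is measured on the raw label (exact voxel count times voxel
volume), never on the conditioned mask; the ratio is reported in μl/mm,
the units used for developmental comparisons across gestational weeks.
"""

import otomorph as om
from otomorph.morphometry import UM3_PER_UL

spec = om.PhantomSpec()
volume, truth = om.make_spiral_duct_phantom(spec)

v = om.label_volume(volume, 1)
length = om.measure_duct_length(volume, 1).length_um
ratio = om.volume_length_ratio(v, length)

print(f"duct volume  : {v:.4g} μm³ = {v / UM3_PER_UL:.4f} μl "
      f"(analytic {truth.volume_um3 / UM3_PER_UL:.4f} μl)")
print(f"duct length  : {length / 1000.0:.3f} mm")
print(f"volume/length: {ratio:.5f} μl/mm")
# For a tapering tube the ratio approximates the mean cross-sectional
# area; tracking it across stages separates lumen widening from pure
# elongation.
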