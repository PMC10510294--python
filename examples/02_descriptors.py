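"""Extract MIND and macMIND feature maps and verify modality independence.

The descriptors turn local patch self-similarity into per-voxel channel
vectors in (0, 1].  Because every channel is a ratio of patch distances,
they are exactly invariant to I -> a*I + b (a > 0), and approximately
shared between modalities that depict the same structures with different
contrasts.
"""

import numpy as np

from macmind import (
    PhantomConfig, Volume, generate_phantom, macmind, mind_descriptor,
)

case = generate_phantom(PhantomConfig(seed=3, amplitude=0.0))  # aligned pair

mind_a = mind_descriptor(case.vol_a)
feat_a = macmind(case.vol_a)
feat_b = macmind(case.vol_b)
print(f"MIND: {mind_a.n_channels} channels; macMIND: {feat_a.n_channels} "
      f"channels (18 pairs x 32 log-polar bins)")

# exact positive-affine intensity invariance
feat_scaled = macmind(Volume(3.0 * case.vol_a.data + 10.0))
print("max |macMIND(3I+10) - macMIND(I)| =",
      float(np.abs(feat_scaled.data - feat_a.data).max()))

# cross-modality: descriptor space is far closer than intensity space
def norm01(x):
    return (x - x.min()) / (x.max() - x.min())

desc_mse = float(np.square(feat_a.data.astype(np.float64)
                           - feat_b.data.astype(np.float64)).mean())
int_mse = float(np.square(norm01(case.vol_a.data)
                          - norm01(case.vol_b.data)).mean())
print(f"mean squared discrepancy, CT-like vs MR-like:")
print(f"  raw intensities (min-max normalised): {int_mse:.4f}")
print(f"  macMIND channels:                     {desc_mse:.4f}")
print(f"  ratio: {desc_mse / int_mse:.3f}  (<1 means the descriptor sees the "
      f"shared structure, not the modality)")
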