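"""Contrast maps and ODF modulation on a tiny synthetic volume.

Fits a 3-voxel volume (single fibre, 45- and 60-degree crossings), derives
the four scalar contrasts from the mixture fractions and modulates the ODFs
by the anisotropy contrast — the scaling used to restore a magnitude-based
stopping criterion for tractography on unit-normalised ODFs.
"""

import numpy as np

from loresd.estimator import FitConfig, fit_volume
from loresd.response import modulate_odf
from loresd.simulate import (
    DEFAULT_KERNEL,
    add_rician_noise,
    default_scheme,
    ground_truth_odf,
    ground_truth_response,
    simulate_signal,
)

scheme = default_scheme()
H = ground_truth_response(DEFAULT_KERNEL, scheme)
dwi = np.zeros((3, 1, 1, scheme.n_volumes))
for i, angle in enumerate((0.0, 45.0, 60.0)):
    clean = simulate_signal(H, ground_truth_odf(angle), scheme)
    dwi[i, 0, 0] = add_rician_noise(clean, snr=50, seed=10 + i)

out = fit_volume(dwi, np.ones((3, 1, 1), bool), scheme, FitConfig())

print("voxel  angle  intra  extra  free_w  aniso   rmse")
for i, angle in enumerate((0, 45, 60)):
    print(f"{i:>5d}  {angle:>5d}  "
          f"{out['intra'][i,0,0]:.3f}  {out['extra'][i,0,0]:.3f}  "
          f"{out['free_water'][i,0,0]:.3f}   {out['anisotropy'][i,0,0]:.3f}  "
          f"{out['rmse'][i,0,0]:.4f}")

# modulated ODF: coefficients scaled by the voxel's anisotropy contrast
mod = modulate_odf(out["odf"][0, 0, 0], out["anisotropy"][0, 0, 0])
print(f"\nl=0 coefficient before/after modulation: "
      f"{out['odf'][0,0,0,0]:.4f} -> {mod[0]:.4f}")
# All three voxels share one kernel, so intra/extra/free-water values are
# similar; the modulation rescales each ODF by its tissue anisotropy.
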