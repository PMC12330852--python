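"""Fit the local response function and ODF of one simulated voxel.

Builds a white-matter-like phantom (stick + zeppelin + ball kernel convolved
with a single-fibre ODF), adds Rician noise at SNR 20, runs the joint
estimator and prints how well the fibre orientation and microstructural
contrasts are recovered.
"""

from loresd import acc, build_dictionary, contrast_matrix, contrast_value
from loresd.estimator import FitConfig, fit_voxel
from loresd.scheme import ShellSignal
from loresd.simulate import (
    DEFAULT_KERNEL,
    add_rician_noise,
    default_scheme,
    ground_truth_odf,
    ground_truth_response,
    simulate_signal,
)

scheme = default_scheme()                      # b = 0/1/2 ms/um^2, 5/128/128 dirs
H_gt = ground_truth_response(DEFAULT_KERNEL, scheme)
p_gt = ground_truth_odf(crossing_angle=0.0)    # single fibre along z
signal = add_rician_noise(simulate_signal(H_gt, p_gt, scheme), snr=20, seed=1)

config = FitConfig()                           # lmax 8, 10x10 grid, lambda 1e-3
dictionary = build_dictionary(config.grid, scheme, config.lmax)
fit = fit_voxel(ShellSignal.from_amplitudes(signal, scheme, config.lmax),
                dictionary, config)

print(f"converged: {fit.converged} after {fit.n_iterations} iterations")
print(f"ACC to ground-truth ODF: {acc(fit.p, p_gt):.4f}   (1 = perfect)")
print(f"signal RMSE:             {fit.rmse:.4f}   (S0 = 1)")
for name in ("intra", "extra", "free_water", "anisotropy"):
    W = contrast_matrix(name, config.grid)
    print(f"{name:>11s} contrast: {contrast_value(W, fit.f):.3f}")
# The contrasts summarise where the mixture mass sits on the diffusivity
# grid: a coherent fibre voxel shows high intra-axonal and anisotropy values
# and a small free-water fraction.
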