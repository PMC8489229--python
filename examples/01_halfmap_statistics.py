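"""Simulate two half maps from a toy model and estimate per-bin statistics.

The simulation realizes F_half = k(s) F_T + noise with k(s) =
exp(-B_blur |s|^2/4); the statistics table recovers the noise variance
sigma_n^2 (from the half-map difference), the signal-amplitude proxy
k sigma_T (from the excess of <|F_o|^2> over the noise), and the half-map
and full-map FSC per resolution shell.
"""

import numpy as np

import diffem as de

model = de.make_toy_model(n_atoms=8, box=24.0, seed=1)
half1, half2, truth = de.simulate_half_maps(
    model, b_blur=40.0, noise_level=2e-5, d_min=2.0, seed=2
)

f1 = de.fft_map(half1, d_min=2.0)
f2 = de.fft_map(half2, d_min=2.0)
stats = de.bin_statistics(f1, f2, truth.bins)

cols = ["bin", "d_center", "n_coeffs", "sigma_n_sq", "k_sigma_t", "fsc_half", "fsc_full"]
print(stats[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print(f"\ntrue sigma_n^2 (all bins): {truth.sigma_n_sq[0]:.3g}")
print(
    "Each row is one resolution shell (d_center in Angstrom): sigma_n_sq "
    "should sit at the true value above, k_sigma_t traces the blurred "
    "signal amplitude, and FSC falls off toward high resolution as the "
    "signal fades into the noise."
)
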