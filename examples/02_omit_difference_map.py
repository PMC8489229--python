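"""Compute a weighted, sharpened Fo-Fc omit map and find the omitted atom.

One carbon is removed from the model used for F_c (after D and sigma_f^2
are estimated with the complete model, the standard omit recipe); the
strongest positive difference peak should then mark the omitted atom's
position.
"""

import numpy as np

import diffem as de
from diffem.diffmap import fofc_coeffs
from diffem.model import calc_fc
from diffem.scaling import estimate_scales

model = de.make_toy_model(n_atoms=6, box=16.0, seed=11, elements=("C",))
half1, half2, truth = de.simulate_half_maps(
    model, b_blur=20.0, noise_level=1e-6, d_min=1.5, seed=13
)

d_min = 1.5
f1, f2 = de.fft_map(half1, d_min), de.fft_map(half2, d_min)
fo = f1.with_coeffs((f1.coeffs + f2.coeffs) / 2)
stats = de.bin_statistics(f1, f2, truth.bins)
stats = estimate_scales(fo, calc_fc(model, fo), stats.sigma_n_sq.to_numpy(), truth.bins, stats=stats)

omitted = 2
fc_omit = calc_fc(model.without([omitted]), fo)
dF = fofc_coeffs(fo, fc_omit, stats, truth.bins)
diff_map = de.ifft_map(dF)

mask = de.model_mask(model, diff_map, radius=3.0)
normalized, mask_stats = de.normalize_map(diff_map, mask)
peaks = de.find_peaks(normalized, threshold_sigma=3.0, sign="+")

true_pos = model.atoms[omitted].position
print(f"omitted atom at {np.round(true_pos, 2)} A")
print(f"top positive peak at {np.round(peaks[0].position, 2)} A, height {peaks[0].height:.1f} sigma")
print(f"peak-to-atom distance: {np.linalg.norm(peaks[0].position - true_pos):.3f} A")
print(
    "The peak height is in units of the in-mask standard deviation "
    "(sigma), so it is comparable between boxes of different sizes; a "
    "distance well under 0.3 A means the omit map pinpoints the missing atom."
)
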