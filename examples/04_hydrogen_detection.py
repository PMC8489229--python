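"""Hydrogen-omit difference maps at two resolution cutoffs.

Hydrogens are left out of F_c, so each should produce a positive
difference-density peak near its position. The fraction of hydrogens with
a >= 3 sigma peak within 0.3 A is high at atomic resolution and collapses
as the cutoff is lowered, mirroring how hydrogen visibility depends on
resolution in experimental maps.
"""

import numpy as np

import diffem as de
from diffem.diffmap import fofc_coeffs
from diffem.model import calc_fc
from diffem.scaling import estimate_scales

model = de.make_toy_model(6, box=14.0, seed=20, elements=("C",), with_hydrogens=True)
n_h = sum(1 for a in model.atoms if a.is_hydrogen)
print(f"toy model: {len(model)} atoms, {n_h} hydrogens")

for d_min in (1.2, 2.5):
    fractions = []
    for seed in range(5):
        h1, h2, truth = de.simulate_half_maps(
            model, b_blur=15.0, noise_level=1e-3, d_min=d_min, seed=seed
        )
        f1, f2 = de.fft_map(h1, d_min), de.fft_map(h2, d_min)
        fo = f1.with_coeffs((f1.coeffs + f2.coeffs) / 2)
        no_h = model.without_hydrogens()
        stats = de.bin_statistics(f1, f2, truth.bins)
        stats = estimate_scales(
            fo, calc_fc(no_h, fo), stats.sigma_n_sq.to_numpy(), truth.bins, stats=stats
        )
        dF = fofc_coeffs(fo, calc_fc(no_h, fo), stats, truth.bins)
        diff_map = de.ifft_map(dF)
        mask = de.model_mask(no_h, diff_map, radius=3.0)
        normalized, _ = de.normalize_map(diff_map, mask)
        peaks = de.find_peaks(normalized, threshold_sigma=3.0, sign="+")
        report = de.match_hydrogens(peaks, model, max_dist=0.3)
        fractions.append(report.ratio)
    print(f"d_min = {d_min} A: detected H fraction (3 sigma) = {np.mean(fractions):.2f}")

print(
    "At 1.2 A nearly every hydrogen shows a sharp positive peak; at 2.5 A "
    "the hydrogen density merges into the parent carbon and few peaks "
    "survive within the 0.3 A matching distance."
)
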