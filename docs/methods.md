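# Methods

This note records the statistical model implemented by `diffem`, the
numerical choices behind it, what the synthetic-data generator does and does
not emulate, and the package's known limitations.

## Observation model and per-bin statistics

All statistics are computed on Fourier coefficients of real-space maps in
an orthogonal P1 box. The transform convention is
`F(s) = sum(map) exp(+2 pi i s.x) * voxel_volume`, so `F(0)` is the map
integral and atomic structure factors can be compared to map transforms
directly; only ratios enter the statistics, so any consistent convention
would give identical maps. Coefficients live on the numpy `rfftn` half
grid; Friedel-redundant coefficients on the self-conjugate planes (l = 0
and l = N/2) are counted once, consistently for every quantity, so the
slight difference from full-sphere counting cancels in all ratios.

Each coefficient of the averaged full map is modelled as
`F_o = k F_T + F_n` with an isotropic resolution-dependent blur
`k(s) = exp(-B|s|^2/4)` and zero-mean complex Gaussian noise of variance
`sigma_n^2`. Because the two half maps are reconstructed from independent
particle halves, `sigma_n^2(i) = <|F_o1 - F_o2|^2/4>_i` per resolution bin
i, and the signal variance proxy is
`(k sigma_T)^2(i) = max(0, <|F_o|^2>_i - sigma_n^2(i))`. Negative
differences (pure-noise bins) are clipped to zero and flagged; map
coefficients in clipped bins are set to zero rather than left unsharpened,
which prevents dividing noise by a vanishing amplitude at the cost of
discarding shells that carry no detectable signal anyway.

Resolution bins are equal-width in |s| over [0, 1/d_min]. The bin count
defaults to `max(10, N/4)` for an N-point grid edge and bins with fewer
than 50 coefficients are merged into their higher-resolution neighbour;
a coefficient exactly on an internal edge belongs to the lower-|s| bin.
Bins with fewer than 10 coefficients report missing statistics (NaN)
rather than unstable estimates. FSC uses the real part of the cross term;
zero-power bins report missing, never zero. No smoothing or regularization
is applied across bins — all per-bin values are raw.

## Likelihood and scaling

The per-coefficient likelihood of an observation given the model is a 2D
(complex) Gaussian with mean `D_i F_c` and total variance
`S_i = sigma_f^2(i) + sigma_n^2(i)`. The joint per-bin maximizers are
closed form: `D_i = sum Re(F_o conj F_c) / sum |F_c|^2` and
`S_i = <|F_o - D_i F_c|^2>`; tests verify optimality against a grid-search
oracle. `D` is real per bin (no anisotropic or complex D). The split of
`S` into `sigma_f^2 + sigma_n^2` is only needed for map weighting; the
likelihood itself uses total `S`, so clipping `sigma_f^2` at zero never
affects likelihood values. The overall sharpening B is estimated as the
least-squares slope of `ln(<|F_o|>_i / <|F_c,B=0|>_i)` versus `-|s|^2/4`
against a zero-ADP copy of the model, which is far more stable than a
Wilson-plot fit when only low-resolution data are available.

## Difference and expected maps

The Fo−Fc coefficients are
`dF = [sigma_f^2/(sigma_f^2+sigma_n^2)] (F_o - D F_c) / (k sigma_T)`;
the normalized expected map (no model contribution, the D = 0 case) is
`w F_o / (k sigma_T)` with `w = (k sigma_T)^2/((k sigma_T)^2 + sigma_n^2)
= FSC_full`, algebraically equal to `FSC_full^(1/2) E`. The posterior mean
of the (sharpened) true coefficients is the precision-weighted combination
of `F_o` and `D F_c` and is exposed separately; interference terms between
atoms are ignored in the `k sigma_T` derivation, consistent with treating
the signal variance as a sum of atomic contributions. The sharpening is
based on the average B of the region, so regions with very different B
values will be under- or over-sharpened; a position-dependent blur is out
of scope.

## Masking, trimming and normalization

Model masks are hard binary balls of radius 3 Å (default) around every
atom of the symmetry-expanded model; an optional raised-cosine soft edge
is available. Half maps are sharpened by `exp(+B|s|^2/4)`, masked, then
blurred back ("sharpen-mask-unsharpen") so that the blurred tails of
atomic density are not cut away. Note what this does and does not change:
inside the mask the output essentially coincides with plain masking (plain
masking *is* the identity there); the retained signal is the tail density
*outside* the mask, which plain masking deletes permanently. The tests
therefore assert that the processed map keeps strictly more total
integrated atom density and stays closer (L1) to the unmasked original
than plain masking — the operational meaning of "not masking away
signal". Over-sharpening caveat: the sharpened density must remain
resolvable at the grid's d_min, otherwise truncation ringing contaminates
the comparison (and the maps).

Trimming takes the mask bounding box plus padding (default 5 Å), snapped
to dimensions whose prime factors are ≤ 7 (an FFT-performance choice
only). Trimmed maps carry an `origin_shift` so absolute coordinates are
preserved exactly; when coordinates are instead re-referenced to the
trimmed frame, symmetry translations follow `t' = t + (R - I) d`.

In-mask moments are computed two ways — by the whole-box correction
formulas `mu_mask = mu_total/f`, `var_mask = (var_total + mu_total^2)/f -
mu_total^2/f^2` (with the outside-mask region zeroed) and directly over
in-mask voxels — and must agree to ~1e-10; difference maps are divided by
`sqrt(var_mask)`, making sigma levels independent of the box size. With no
mask the Fo−Fc map is left unnormalized. Population variances (ddof = 0)
are used throughout.

## Structure factors

X-ray form factors use the International Tables 4-Gaussian
parameterization as shipped with gemmi. Electron factors use the
Mott–Bethe conversion with `C = 1/(2 pi^2 a0) = 0.0957346 Å`. For the
conversion the table's constant term is replaced by `c' = Z - sum(a)` so
that `f_x(0) = Z` exactly and `(Z - f_x)/|s|^2` telescopes to
`sum_j a_j (1 - exp(-b_j |s|^2/4))/|s|^2`, evaluated with `expm1` and
finite at the origin (limit `sum(a_j b_j)/4`). The hydrogen nucleus offset
`dx` (electron cloud pulled toward the parent atom; |dx| ≤ 0.5 Å) enters
as the phase `Z exp(2 pi i s.dx)`; at exactly s = 0 the directional limit
of the dipole term does not exist and the angular average
`-C Z (2 pi |dx|)^2/6` is used. The offset defaults to zero and is
configurable per hydrogen; chemical dictionaries of nucleus bond lengths
are not included.

`calc_fc` uses exact direct summation up to 10^4 atom copies and a
real-space density-sampling + FFT path beyond. The density path expands
each Mott–Bethe factor as `(C/4) sum_j a_j int_0^{b_j} e^{-(u+B)|s|^2/4}
du` with 24-point Gauss–Legendre quadrature per table Gaussian — an
explicit Gaussian mixture whose real-space form is sampled on the grid. It
requires isotropic B ≳ 5 Å² for accurate sampling and does not support
shifted nuclei; the two paths agree to better than 1% in bin-averaged
amplitude within 0.8/d_min (asserted in tests, with gemmi's independent
electron-factor machinery as an external few-percent cross-check).

## Symmetry

Operators are generated from group generators and closed by breadth-first
multiplication, so closure holds by construction (verified to 1e-8).
Conventions: Cn about +z; Dn adds a 2-fold along +x; T with 2-folds on the
coordinate axes and 3-folds on body diagonals; O with 4-folds on the
coordinate axes; I with a 5-fold on +z and the 2-fold generator in the xz
plane at polar angle arctan(2)/2. These match common reconstruction
conventions for Cn/Dn/O; the T and I orientations are this package's
documented, test-locked choice. The symmetry origin defaults to the box
centre and translations are `t = (I - R) c`.

Special positions are atoms within ε = 0.25 Å (default) of their image
under any non-identity operator, measured as Cartesian distance. Their
stabilizers must be closed subgroups (otherwise an inconsistent-geometry
error); occupancy is divided by the stabilizer order so the expanded model
conserves total scattering, coordinates and anisotropic tensors are
projected onto the invariant subspace by subgroup averaging (idempotent),
and quadratic restraint residuals (positional, weighted by sigma_x;
Frobenius ADP distance, weighted by sigma_B) are provided for use by an
external refinement engine. Refinement itself — gradients, geometry
restraints, riding hydrogens — is outside this package; the pipeline
expects an already-refined model, and the Fo−Fc map is only meaningful
when ADPs have been refined against the unsharpened data.

## Peaks and hydrogen matching

Peaks are 26-neighbourhood local extrema above a sigma threshold, refined
sub-voxel by a per-axis 3-point quadratic fit (offsets clamped to half a
voxel); peaks on the outermost voxel layer are discarded. Hydrogens count
as detected when a positive peak lies within 0.3 Å; each peak matches only
its nearest hydrogen and each hydrogen counts once. Hydrogens with
multiple potential minima (hydroxyl, sulfhydryl, carboxyl — identified by
parent-atom name, or by an explicit flag on synthetic atoms) are excluded
from both numerator and denominator of the detection ratio; the
all-hydrogens-denominator variant is reported alongside since either
convention is defensible.

## Synthetic data

The generator places atoms with ≥ 1.5 Å separation in the central 60% of
a cubic box (B ~ U[10, 40] Å² by default, one riding hydrogen per carbon
at 1.0 Å when requested) and simulates each half map as
`k(s) F_T + noise`, with `F_T` the exact structure factors of the model
(optionally symmetry-expanded) and noise generated as real-space white
noise scaled per shell — so conjugate symmetry is exact and the per-half
coefficient variance is the stated `noise_level`, implying a full-map
`sigma_n^2 = noise_level/2`. All randomness flows from one integer seed
and regeneration is byte-identical.

What this emulates: the per-coefficient statistical model above, exactly.
What it does not: CTF effects, particle-alignment errors (which make real
noise non-white and the blur anisotropic and position-dependent),
solvent/background density, map symmetrization noise correlations, and
model error beyond what the user injects. Passing tests therefore
demonstrate the correctness of the estimators and map algebra under the
stated model, not robustness to those experimental effects.

Default problem sizes in tests and the acceptance script (48³ grids for
variance recovery, ~4–6-atom models at 1.2–2.5 Å for omit and hydrogen
analyses, 10 seeds per condition) were chosen to give well-populated bins
(N_i ≥ 2000 where variance recovery is asserted) while keeping each run in
seconds.

## Numerical choices and degenerate inputs

- FFT-friendliness: trimmed box dimensions rounded up to 7-smooth sizes.
- d_min below the grid Nyquist limit is a hard error; the achievable limit
  is reported.
- Sharpening factors with exp arguments above 700 raise an error rather
  than overflow.
- Bins with zero model power have undefined D; they are flagged, excluded
  from maps and warned about.
- Group closure and orthonormality tolerances: 1e-8 absolute; special
  position projection is idempotent to 1e-12.
- Maps are written as MRC mode 2 with X-fastest axis order; the origin is
  stored in nxstart when it is an integer number of voxels, else in the
  ORIGIN header words.

## Known limitations

Helical symmetry, automatic symmetry-axis detection, position-dependent
(local) blurring, phase-randomized mask-bias FSC corrections, solvent
models, charged scattering factors and any form of atomic refinement are
not implemented. Half-map-correlation masks must come from external tools;
the built-in mask is model-based. Anisotropic blur k is not modelled in
the simulator (isotropic Gaussian only).
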