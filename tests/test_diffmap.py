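"""Difference-map, expected-map and posterior coefficients."""

import numpy as np
import pandas as pd
import pytest

import diffem as de
from diffem.diffmap import expected_map_coeffs, fofc_coeffs, posterior_coeffs
from diffem.model import calc_fc
from diffem.scaling import estimate_scales


def _stats_frame(n_bins, **cols):
    base = {
        "bin": np.arange(n_bins),
        "sigma_n_sq": np.full(n_bins, 0.1),
        "sigma_f_sq": np.full(n_bins, 0.4),
        "k_sigma_t": np.full(n_bins, 2.0),
        "D": np.full(n_bins, 1.0),
    }
    base.update(cols)
    return pd.DataFrame(base)


def _layout(shape=(16, 16, 16), box=16.0, d_min=2.0):
    return de.fft_map(de.MapGrid(np.zeros(shape, dtype=np.float32), [box] * 3), d_min)


@pytest.fixture
def random_sets(rng):
    layout = _layout()
    n = len(layout)
    fo = layout.with_coeffs(rng.standard_normal(n) + 1j * rng.standard_normal(n))
    fc = layout.with_coeffs(rng.standard_normal(n) + 1j * rng.standard_normal(n))
    return fo, fc


class TestFofc:
    def test_perfect_model_gives_zero_map(self, random_sets):
        fo, fc = random_sets
        stats = _stats_frame(4, D=np.full(4, 0.7))
        bins = de.make_bins(fo, n_bins=4, min_count=1)
        dF = fofc_coeffs(fo.with_coeffs(0.7 * fc.coeffs), fc, stats, bins)
        np.testing.assert_allclose(dF.coeffs, 0.0, atol=1e-12)
        assert np.max(np.abs(de.ifft_map(dF).values)) < 1e-12

    def test_zero_sigma_f_annihilates(self, random_sets):
        fo, fc = random_sets
        stats = _stats_frame(3, sigma_f_sq=np.zeros(3))
        bins = de.make_bins(fo, n_bins=3, min_count=1)
        np.testing.assert_allclose(fofc_coeffs(fo, fc, stats, bins).coeffs, 0.0, atol=1e-15)

    def test_linearity_in_residual(self, random_sets):
        fo, fc = random_sets
        bins = de.make_bins(fo, n_bins=3, min_count=1)
        stats = _stats_frame(3)
        d1 = fofc_coeffs(fo, fc, stats, bins).coeffs
        fo2 = fo.with_coeffs(fo.coeffs + (fo.coeffs - 1.0 * fc.coeffs))  # doubles the residual
        d2 = fofc_coeffs(fo2, fc, stats, bins).coeffs
        np.testing.assert_allclose(d2, 2 * d1, rtol=1e-10, atol=1e-12)

    def test_sign_symmetry(self, random_sets):
        fo, fc = random_sets
        bins = de.make_bins(fo, n_bins=3, min_count=1)
        stats = _stats_frame(3)
        a = fofc_coeffs(fo, fc, stats, bins).coeffs
        # swap roles: Fo' = D Fc, D Fc' = Fo  => negated difference
        fo_swap = fo.with_coeffs(1.0 * fc.coeffs)
        fc_swap = fc.with_coeffs(fo.coeffs / 1.0)
        b = fofc_coeffs(fo_swap, fc_swap, stats, bins).coeffs
        np.testing.assert_allclose(b, -a, rtol=1e-10, atol=1e-12)

    def test_dead_bin_zeroed_with_warning(self, random_sets):
        fo, fc = random_sets
        bins = de.make_bins(fo, n_bins=3, min_count=1)
        kst = np.array([2.0, 0.0, 2.0])
        stats = _stats_frame(3, k_sigma_t=kst)
        with pytest.warns(UserWarning, match="zeroed"):
            dF = fofc_coeffs(fo, fc, stats, bins)
        ids = bins.assign(fo.s_norm)
        assert np.all(dF.coeffs[ids == 1] == 0)
        assert np.all(dF.coeffs[ids != 1] != 0)

    def test_missing_stats_column_raises(self, random_sets):
        fo, fc = random_sets
        bins = de.make_bins(fo, n_bins=3, min_count=1)
        stats = _stats_frame(3).drop(columns=["k_sigma_t"])
        with pytest.raises(ValueError, match="k_sigma_t"):
            fofc_coeffs(fo, fc, stats, bins)

    def test_omit_atom_peak(self, carbon_model):
        """Omit one carbon from Fc at 1.5 A: the strongest positive peak of
        the difference map lies within 0.3 A of the omitted atom."""
        hits = 0
        for seed in range(10):
            h1, h2, truth = de.simulate_half_maps(
                carbon_model, b_blur=20, noise_level=1e-6, d_min=1.5, seed=seed
            )
            f1, f2 = de.fft_map(h1, 1.5), de.fft_map(h2, 1.5)
            bins = truth.bins
            fo = f1.with_coeffs((f1.coeffs + f2.coeffs) / 2)
            stats = de.bin_statistics(f1, f2, bins)
            fc_full = calc_fc(carbon_model, fo)
            stats = estimate_scales(fo, fc_full, stats.sigma_n_sq.to_numpy(), bins, stats=stats)
            omitted = 2
            fc_omit = calc_fc(carbon_model.without([omitted]), fo)
            dF = fofc_coeffs(fo, fc_omit, stats, bins)
            peaks = de.find_peaks(de.ifft_map(dF), 3.0, sign="+", normalized=False)
            d = np.linalg.norm(peaks[0].position - carbon_model.atoms[omitted].position)
            if d < 0.3:
                hits += 1
        assert hits >= 9

    def test_model_bias_guard(self, random_sets, rng):
        """With D = 0 the Fo-Fc and expected maps carry no Fc contribution."""
        fo, fc = random_sets
        bins = de.make_bins(fo, n_bins=3, min_count=1)
        stats = _stats_frame(3, D=np.zeros(3))
        a = fofc_coeffs(fo, fc, stats, bins).coeffs
        other = fc.with_coeffs(rng.standard_normal(len(fc)) + 1j * rng.standard_normal(len(fc)))
        b = fofc_coeffs(fo, other, stats, bins).coeffs
        np.testing.assert_array_equal(a, b)

    def test_weight_bounded_by_one(self, random_sets):
        fo, fc = random_sets
        bins = de.make_bins(fo, n_bins=3, min_count=1)
        for sf2, sn2 in [(0.0, 1.0), (1.0, 0.0), (0.5, 0.5), (10.0, 0.1)]:
            stats = _stats_frame(3, sigma_f_sq=np.full(3, sf2), sigma_n_sq=np.full(3, sn2))
            dF = fofc_coeffs(fo, fc, stats, bins)
            w = np.abs(dF.coeffs) * 2.0 / np.abs(fo.coeffs - fc.coeffs)  # kst=2
            assert np.nanmax(w) <= 1.0 + 1e-12


class TestExpectedMap:
    def test_noiseless_unit_signal_variance(self, random_sets):
        fo, _ = random_sets
        bins = de.make_bins(fo, n_bins=3, min_count=1)
        ids = bins.assign(fo.s_norm)
        mean_sq = np.bincount(ids, weights=np.abs(fo.coeffs) ** 2) / np.bincount(ids)
        stats = _stats_frame(3, sigma_n_sq=np.zeros(3), k_sigma_t=np.sqrt(mean_sq))
        out = expected_map_coeffs(fo, stats, bins)
        for i in range(3):
            v = np.mean(np.abs(out.coeffs[ids == i]) ** 2)
            assert v == pytest.approx(1.0, rel=1e-10)

    def test_pure_noise_bin_vanishes(self, random_sets):
        fo, _ = random_sets
        bins = de.make_bins(fo, n_bins=3, min_count=1)
        stats = _stats_frame(3, k_sigma_t=np.zeros(3))
        np.testing.assert_allclose(expected_map_coeffs(fo, stats, bins).coeffs, 0.0)

    def test_output_variance_equals_fsc_full(self):
        """Per-bin variance of the normalized expected map equals FSC_full
        within 2% on simulated data."""
        model = de.make_toy_model(8, box=48.0, seed=5)
        h1, h2, truth = de.simulate_half_maps(
            model, b_blur=40, noise_level=5e-5, d_min=2.0, seed=17, shape=(48, 48, 48)
        )
        f1, f2 = de.fft_map(h1, 2.0), de.fft_map(h2, 2.0)
        bins = truth.bins
        fo = f1.with_coeffs((f1.coeffs + f2.coeffs) / 2)
        stats = de.bin_statistics(f1, f2, bins)
        out = expected_map_coeffs(fo, stats, bins)
        ids = bins.assign(fo.s_norm)
        for i in np.where(bins.counts >= 2000)[0]:
            var = np.mean(np.abs(out.coeffs[ids == i]) ** 2)
            # by construction var = w^2 <|Fo|^2>/kst^2 = w = FSC-like weight;
            # compare against the independently computed FSC_full
            assert var == pytest.approx(stats.fsc_full[i], rel=0.02)

    def test_matches_sqrt_fsc_times_e(self, random_sets):
        """Algebraic identity: w Fo / kst = FSC_full^(1/2) E with
        E = Fo/<|Fo|^2>^(1/2) when the stats are internally consistent."""
        fo, _ = random_sets
        bins = de.make_bins(fo, n_bins=3, min_count=1)
        ids = bins.assign(fo.s_norm)
        mean_sq = np.bincount(ids, weights=np.abs(fo.coeffs) ** 2) / np.bincount(ids)
        sn2 = 0.3 * mean_sq
        kst = np.sqrt(mean_sq - sn2)
        stats = _stats_frame(3, sigma_n_sq=sn2, k_sigma_t=kst)
        out = expected_map_coeffs(fo, stats, bins).coeffs
        fsc_full = kst**2 / mean_sq
        e = fo.coeffs / np.sqrt(mean_sq[ids])
        np.testing.assert_allclose(out, np.sqrt(fsc_full[ids]) * e, rtol=1e-10)


class TestPosterior:
    def test_data_dominate(self, random_sets):
        fo, fc = random_sets
        bins = de.make_bins(fo, n_bins=3, min_count=1)
        stats = _stats_frame(3, sigma_n_sq=np.zeros(3))
        mean, var = posterior_coeffs(fo, fc, stats, bins)
        np.testing.assert_allclose(mean.coeffs, fo.coeffs / 2.0, rtol=1e-12)  # kst = 2
        np.testing.assert_allclose(var, 0.0)

    def test_model_dominates(self, random_sets):
        fo, fc = random_sets
        bins = de.make_bins(fo, n_bins=3, min_count=1)
        stats = _stats_frame(3, sigma_f_sq=np.zeros(3), D=np.full(3, 0.9))
        mean, var = posterior_coeffs(fo, fc, stats, bins)
        np.testing.assert_allclose(mean.coeffs, 0.9 * fc.coeffs / 2.0, rtol=1e-12)
        np.testing.assert_allclose(var, 0.0)

    def test_reduces_to_expected_map_at_d_zero(self, random_sets):
        fo, fc = random_sets
        bins = de.make_bins(fo, n_bins=3, min_count=1)
        ids = bins.assign(fo.s_norm)
        mean_sq = np.bincount(ids, weights=np.abs(fo.coeffs) ** 2) / np.bincount(ids)
        sn2 = 0.4 * mean_sq
        kst = np.sqrt(mean_sq - sn2)
        stats = _stats_frame(3, sigma_n_sq=sn2, k_sigma_t=kst, sigma_f_sq=kst**2, D=np.zeros(3))
        mean, _ = posterior_coeffs(fo, fc, stats, bins)
        expected = expected_map_coeffs(fo, stats, bins)
        # at D = 0 the posterior mean is w Fo / kst with w = sf2/(sf2+sn2);
        # with sf2 = kst^2 this is exactly the expected-map weight
        np.testing.assert_allclose(mean.coeffs, expected.coeffs, rtol=1e-10)

    def test_mean_on_segment(self, random_sets):
        """The posterior mean lies on the segment between Fo/kst and
        D Fc/kst for every coefficient (convexity)."""
        fo, fc = random_sets
        bins = de.make_bins(fo, n_bins=3, min_count=1)
        stats = _stats_frame(3, sigma_f_sq=np.full(3, 0.3), sigma_n_sq=np.full(3, 0.7))
        mean, _ = posterior_coeffs(fo, fc, stats, bins)
        lo = 1.0 * fc.coeffs / 2.0
        hi = fo.coeffs / 2.0
        t = (mean.coeffs - lo) / (hi - lo)
        np.testing.assert_allclose(np.imag(t), 0.0, atol=1e-9)
        assert np.all((np.real(t) > -1e-9) & (np.real(t) < 1 + 1e-9))


def test_coeff_table_round_trips(tmp_path, rng):
    layout = _layout()
    fo = layout.with_coeffs(rng.standard_normal(len(layout)) + 1j * rng.standard_normal(len(layout)))
    bins = de.make_bins(fo, n_bins=3, min_count=1)
    p = tmp_path / "coeffs.tsv"
    from diffem.diffmap import write_coeff_table

    write_coeff_table(fo, bins, p)
    table = pd.read_csv(p, sep="\t")
    assert len(table) == len(fo)
    j = 17
    row = table.iloc[j]
    assert (row.h, row.k, row.l) == tuple(fo.hkl[j])
    assert row.real == pytest.approx(fo.coeffs[j].real, rel=1e-5)
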