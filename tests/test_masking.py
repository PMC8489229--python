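"""Masked-variance identities, sharpen-mask-unsharpen and box trimming."""

import numpy as np
import pytest

import diffem as de
from diffem.masking import ShiftRecord, masked_moments, trim_box, untrim, _fft_friendly


class TestMaskedMoments:
    def test_worked_example(self):
        """values [2,-2,0,0], mask over the first two: f=0.5, var_mask=4
        by both routes."""
        vals = np.array([2.0, -2.0, 0.0, 0.0]).reshape(4, 1, 1)
        mask = np.array([1.0, 1.0, 0.0, 0.0]).reshape(4, 1, 1)
        g = de.MapGrid(vals, [4, 1, 1])
        m = de.MapGrid(mask, [4, 1, 1])
        st = masked_moments(g, m)
        assert st.f == 0.5
        assert st.mu_total == 0.0
        assert st.var_total == 2.0
        assert st.var_mask == pytest.approx(4.0, abs=1e-14)
        assert st.var_mask_direct == pytest.approx(4.0, abs=1e-14)

    def test_full_mask(self, rng):
        vals = rng.standard_normal((8, 8, 8))
        g = de.MapGrid(vals, [8] * 3)
        m = de.MapGrid(np.ones((8, 8, 8)), [8] * 3)
        st = masked_moments(g, m)
        assert st.var_mask == pytest.approx(st.var_total, rel=1e-12)
        assert st.mu_mask == pytest.approx(st.mu_total, rel=1e-12)

    def test_mean_zero_identity(self, rng):
        vals = rng.standard_normal((8, 8, 8))
        mask = (rng.random((8, 8, 8)) < 0.3).astype(float)
        inside = mask > 0.5
        vals[inside] -= vals[inside].mean()  # zero in-mask mean
        vals[~inside] = 0.0
        st = masked_moments(de.MapGrid(vals, [8] * 3), de.MapGrid(mask, [8] * 3))
        assert st.var_mask * st.f == pytest.approx(st.var_total, rel=1e-12)

    def test_formula_equals_direct_on_random_pairs(self):
        """Eqs-route in-mask variance equals the direct computation to
        1e-10 relative on 100 random map/mask pairs."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            shape = tuple(rng.integers(4, 33, size=3))
            vals = rng.standard_normal(shape) * rng.uniform(0.5, 5) + rng.uniform(-2, 2)
            mask = (rng.random(shape) < rng.uniform(0.05, 0.95)).astype(float)
            if mask.sum() < 2:
                mask.flat[:2] = 1.0
            # outside-mask voxels are zero by the masked-map convention
            vals = vals * (mask > 0.5)
            st = masked_moments(
                de.MapGrid(vals, np.array(shape, dtype=float)),
                de.MapGrid(mask, np.array(shape, dtype=float)),
            )
            assert st.var_mask == pytest.approx(st.var_mask_direct, rel=1e-10, abs=1e-12)
            assert st.mu_mask == pytest.approx(st.mu_mask_direct, rel=1e-10, abs=1e-12)

    def test_empty_mask_rejected(self, rng):
        g = de.MapGrid(rng.standard_normal((4, 4, 4)), [4] * 3)
        with pytest.raises(ValueError, match="f = 0"):
            masked_moments(g, de.MapGrid(np.zeros((4, 4, 4)), [4] * 3))


class TestModelMask:
    def test_single_atom_ball_count(self):
        """In-mask voxel count equals the brute-force discrete ball count."""
        box, radius = 16.0, 3.0
        grid = de.MapGrid(np.zeros((16, 16, 16), dtype=np.float32), [box] * 3)
        x = np.array([8.0, 8.0, 8.0])
        model = de.AtomicModel([de.Atom("C", x)], box=np.full(3, box))
        mask = de.model_mask(model, grid, radius=radius)
        idx = np.indices((16, 16, 16)).reshape(3, -1).T * 1.0  # voxel 1 A
        brute = np.sum(np.linalg.norm(idx - x, axis=1) <= radius)
        assert mask.values.sum() == brute

    def test_zero_radius(self):
        grid = de.MapGrid(np.zeros((8, 8, 8), dtype=np.float32), [8.0] * 3)
        model = de.AtomicModel([de.Atom("C", np.array([4.0, 4.0, 4.0]))], box=np.full(3, 8.0))
        mask = de.model_mask(model, grid, radius=0.0)
        assert mask.values.sum() == 1  # only the voxel at the atom centre

    def test_two_distant_atoms_additive(self):
        grid = de.MapGrid(np.zeros((32, 32, 32), dtype=np.float32), [32.0] * 3)
        a = de.AtomicModel([de.Atom("C", np.array([8.0, 8.0, 8.0]))], box=np.full(3, 32.0))
        b = de.AtomicModel([de.Atom("C", np.array([24.0, 24.0, 24.0]))], box=np.full(3, 32.0))
        both = de.AtomicModel(a.atoms + b.atoms, box=np.full(3, 32.0))
        na = de.model_mask(a, grid, 3.0).values.sum()
        nb = de.model_mask(b, grid, 3.0).values.sum()
        nboth = de.model_mask(both, grid, 3.0).values.sum()
        assert nboth == na + nb

    def test_empty_model_rejected(self, random_map):
        with pytest.raises(ValueError):
            de.AtomicModel([])


class TestSharpenMaskUnsharpen:
    def test_identity_mask_is_identity(self, rng):
        vals = rng.standard_normal((16, 16, 16))
        h1 = de.MapGrid(vals.copy(), [16.0] * 3)
        h2 = de.MapGrid(vals.copy(), [16.0] * 3)
        ones = de.MapGrid(np.ones((16, 16, 16)), [16.0] * 3)
        o1, o2, full = de.sharpen_mask_unsharpen(h1, h2, 40.0, ones)
        rel = np.max(np.abs(o1.values - vals)) / np.max(np.abs(vals))
        assert rel < 1e-5

    def test_b_zero_is_plain_masking(self, rng):
        vals = rng.standard_normal((16, 16, 16))
        h = de.MapGrid(vals, [16.0] * 3)
        mask = de.MapGrid((rng.random((16, 16, 16)) < 0.5).astype(float), [16.0] * 3)
        o1, _, _ = de.sharpen_mask_unsharpen(h, h, 0.0, mask)
        np.testing.assert_allclose(o1.values, vals * mask.values, rtol=0, atol=1e-12)

    def test_edge_atom_signal_retained(self):
        """A blurred atom whose tails cross the mask edge: sharpening
        before masking keeps strictly more of the atom's integrated
        density, and the processed map stays closer to the unmasked
        original, than plain masking (which deletes the tails)."""
        box = 24.0
        shape = (24, 24, 24)
        atom_pos = np.array([12.0, 12.0, 12.0])
        model = de.AtomicModel([de.Atom("C", atom_pos, b_iso=30.0)], box=np.full(3, box))
        layout = de.fft_map(de.MapGrid(np.zeros(shape, dtype=np.float32), [box] * 3), 2.0)
        fc = de.calc_fc(model, layout)
        b_blur = 50.0
        blurred = de.ifft_map(layout.with_coeffs(fc.coeffs * np.exp(-b_blur * layout.s_norm**2 / 4)))
        mask = de.model_mask(model, blurred, radius=3.0)
        plain = blurred.values * mask.values
        o1, _, _ = de.sharpen_mask_unsharpen(blurred, blurred, b_blur, mask)
        assert o1.values.sum() > plain.sum()
        assert np.abs(o1.values - blurred.values).sum() < np.abs(plain - blurred.values).sum()

    def test_overflow_guard(self, rng):
        h = de.MapGrid(rng.standard_normal((16, 16, 16)), [8.0] * 3)
        ones = de.MapGrid(np.ones((16, 16, 16)), [8.0] * 3)
        with pytest.raises(ValueError, match="overflow"):
            de.sharpen_mask_unsharpen(h, h, 4000.0, ones)


class TestTrim:
    def test_full_mask_no_trim(self, rng):
        m = de.MapGrid(rng.standard_normal((16, 16, 16)), [16.0] * 3)
        mask = de.MapGrid(np.ones((16, 16, 16)), [16.0] * 3)
        (t,), rec = trim_box([m], mask, padding=2.0)
        assert t.shape == (16, 16, 16)
        assert rec.start == (0, 0, 0)
        np.testing.assert_array_equal(t.values, m.values)

    def test_round_trip_values_and_coordinates(self, rng):
        m = de.MapGrid(rng.standard_normal((64, 64, 64)), [64.0] * 3)
        mask_vals = np.zeros((64, 64, 64))
        mask_vals[27:37, 27:37, 27:37] = 1.0
        mask = de.MapGrid(mask_vals, [64.0] * 3)
        (t,), rec = trim_box([m], mask, padding=5.0)
        assert all(s >= 20 for s in t.shape)
        for s in t.shape:
            assert _fft_friendly(s) == s
        back = untrim(t, rec)
        lo = rec.start
        sz = rec.size
        np.testing.assert_array_equal(
            back.values[lo[0] : lo[0] + sz[0], lo[1] : lo[1] + sz[1], lo[2] : lo[2] + sz[2]],
            t.values,
        )
        # absolute coordinate of an in-mask voxel is invariant
        vox_abs = np.array([30, 31, 32]) * m.voxel_size + m.origin_shift
        vox_in_trim = (vox_abs - t.origin_shift) / t.voxel_size
        np.testing.assert_allclose(vox_in_trim * t.voxel_size + t.origin_shift, vox_abs, atol=1e-9)

    def test_symmetry_ops_after_shift(self):
        """t' = t + (R - I) d reproduces identical absolute positions for
        the expanded copies after a coordinate shift."""
        center = np.array([12.0, 10.0, 8.0])
        ops = de.operators_from_symbol("C4", center)
        shift = np.array([3.0, -2.0, 1.0])
        shifted_ops = ops.shifted(shift)
        x = np.array([5.0, 6.0, 7.0])
        for op, op_s in zip(ops, shifted_ops):
            img_abs = op.apply(x)
            img_shift_frame = op_s.apply(x - shift)
            np.testing.assert_allclose(img_shift_frame + shift, img_abs, atol=1e-9)

    def test_empty_mask_rejected(self, rng):
        m = de.MapGrid(rng.standard_normal((8, 8, 8)), [8.0] * 3)
        with pytest.raises(ValueError, match="empty"):
            trim_box([m], de.MapGrid(np.zeros((8, 8, 8)), [8.0] * 3))

    def test_shift_record_json_round_trip(self, tmp_path, rng):
        m = de.MapGrid(rng.standard_normal((16, 16, 16)), [16.0] * 3)
        mask_vals = np.zeros((16, 16, 16))
        mask_vals[6:10, 6:10, 6:10] = 1.0
        (t,), rec = trim_box([m], de.MapGrid(mask_vals, [16.0] * 3), padding=1.0)
        p = tmp_path / "rec.json"
        rec.to_json(p)
        rec2 = ShiftRecord.from_json(p)
        assert rec2 == rec


class TestNormalize:
    def test_unit_variance_unchanged(self, rng):
        vals = rng.standard_normal((12, 12, 12))
        mask = de.MapGrid(np.ones((12, 12, 12)), [12.0] * 3)
        g = de.MapGrid(vals / vals.std(), [12.0] * 3)
        out, st = de.normalize_map(g, mask)
        np.testing.assert_allclose(out.values, g.values, rtol=1e-10)

    def test_scale_invariance(self, rng):
        vals = rng.standard_normal((12, 12, 12))
        mask_vals = (rng.random((12, 12, 12)) < 0.4).astype(float)
        mask = de.MapGrid(mask_vals, [12.0] * 3)
        g1 = de.MapGrid(vals, [12.0] * 3)
        g2 = de.MapGrid(vals * 10, [12.0] * 3)
        o1, _ = de.normalize_map(g1, mask)
        o2, _ = de.normalize_map(g2, mask)
        np.testing.assert_allclose(o1.values, o2.values, rtol=1e-10)

    def test_box_size_independence(self):
        """The same signal in a tight box and padded into a big box gives
        identical normalized in-mask values."""
        rng = np.random.default_rng(3)
        small = np.zeros((32, 32, 32))
        sig = rng.standard_normal((10, 10, 10))
        small[11:21, 11:21, 11:21] = sig
        mask_small = np.zeros((32, 32, 32))
        mask_small[11:21, 11:21, 11:21] = 1.0
        big = np.zeros((96, 96, 96))
        big[43:53, 43:53, 43:53] = sig
        mask_big = np.zeros((96, 96, 96))
        mask_big[43:53, 43:53, 43:53] = 1.0
        o_small, _ = de.normalize_map(
            de.MapGrid(small, [32.0] * 3), de.MapGrid(mask_small, [32.0] * 3)
        )
        o_big, _ = de.normalize_map(
            de.MapGrid(big, [96.0] * 3), de.MapGrid(mask_big, [96.0] * 3)
        )
        np.testing.assert_allclose(
            o_small.values[11:21, 11:21, 11:21], o_big.values[43:53, 43:53, 43:53], rtol=1e-6
        )

    def test_zero_variance_rejected(self):
        g = de.MapGrid(np.ones((4, 4, 4)), [4.0] * 3)
        mask = de.MapGrid(np.ones((4, 4, 4)), [4.0] * 3)
        with pytest.raises(ValueError):
            de.normalize_map(g, mask)
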