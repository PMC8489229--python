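"""Weighted, sharpened difference-map and expected-map coefficients.

The unknown true coefficients ``F_T`` have a Gaussian posterior given the
observation ``F_o`` (noise variance sigma_n^2) and the model ``D F_c``
(unexplained-signal variance sigma_f^2): a precision-weighted combination
of the two.  Because the blur ``k`` cannot be recovered from the data, the
per-bin signal amplitude ``k sigma_T`` acts as the sharpening proxy, and
the weighted/sharpened Fo-Fc coefficients are

    dF = [sigma_f^2 / (sigma_f^2 + sigma_n^2)] (F_o - D F_c) / (k sigma_T),

while the model-free normalized expected map (the D = 0 special case) is

    F = [(k sigma_T)^2 / ((k sigma_T)^2 + sigma_n^2)] F_o / (k sigma_T)
      = FSC_full^(1/2) E,   E = F_o / <|F_o|^2>^(1/2).

Bins where the ``k sigma_T`` estimate clips to zero (no detectable signal)
produce zero coefficients rather than unsharpened noise; this is logged.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .grid import BinScheme, FourierSet

__all__ = ["fofc_coeffs", "expected_map_coeffs", "posterior_coeffs", "write_coeff_table"]


def write_coeff_table(fs: FourierSet, bins: BinScheme, path) -> None:
    """Dump coefficients as tab-separated text: h, k, l, real, imag, bin."""
    ids = bins.assign(fs.s_norm)
    with open(path, "w") as fh:
        fh.write("h\tk\tl\treal\timag\tbin\n")
        for (h, k, l), c, b in zip(fs.hkl, fs.coeffs, ids):
            fh.write(f"{h}\t{k}\t{l}\t{c.real:.6g}\t{c.imag:.6g}\t{b}\n")


def _per_coeff(stats_col: np.ndarray, ids: np.ndarray) -> np.ndarray:
    return np.asarray(stats_col, dtype=float)[ids]


def _require(stats: pd.DataFrame, cols: list[str], counts: np.ndarray) -> None:
    for col in cols:
        if col not in stats:
            raise ValueError(f"statistics table is missing column {col!r}")
        vals = np.asarray(stats[col], dtype=float)
        bad = (counts > 0) & ~np.isfinite(vals)
        # bins with undefined D are tolerated if flagged; caller zeroes them
        if col in ("D",) and "d_undefined" in stats:
            bad &= ~np.asarray(stats["d_undefined"], dtype=bool)
        if np.any(bad):
            raise ValueError(f"missing {col} for populated bin(s) {np.where(bad)[0].tolist()}")


def fofc_coeffs(
    fo: FourierSet, fc: FourierSet, stats: pd.DataFrame, bins: BinScheme
) -> FourierSet:
    """Weighted and sharpened Fo-Fc coefficients.

    ``dF(s) = [sigma_f^2/(sigma_f^2+sigma_n^2)] (F_o - D F_c) / k sigma_T``
    using the bin of ``s``.  Bins with ``k sigma_T = 0`` or undefined D get
    zero coefficients (warning emitted).
    """
    if not fo.same_layout(fc):
        raise ValueError("F_o and F_c are on different layouts")
    ids = bins.assign(fo.s_norm)
    counts = np.bincount(ids, minlength=bins.n_bins)
    _require(stats, ["sigma_f_sq", "sigma_n_sq", "k_sigma_t", "D"], counts)
    sf2 = _per_coeff(stats["sigma_f_sq"], ids)
    sn2 = _per_coeff(stats["sigma_n_sq"], ids)
    kst = _per_coeff(stats["k_sigma_t"], ids)
    d = _per_coeff(stats["D"], ids)
    dead = ~(kst > 0) | ~np.isfinite(d)
    if np.any(dead):
        warnings.warn(
            f"{int(np.sum(np.bincount(ids[dead], minlength=bins.n_bins) > 0))} bin(s) "
            "with no signal or undefined D; their Fo-Fc coefficients are zeroed"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        total = sf2 + sn2
        w = np.where(total > 0, sf2 / np.where(total > 0, total, 1.0), 0.0)
        delta = w * (fo.coeffs - np.where(dead, 0.0, d) * fc.coeffs) / np.where(dead, 1.0, kst)
    delta = np.where(dead, 0.0, delta)
    return fo.with_coeffs(delta)


def expected_map_coeffs(
    fo: FourierSet, stats: pd.DataFrame, bins: BinScheme
) -> FourierSet:
    """Model-free normalized expected-map coefficients (the D = 0 case):
    ``w F_o / k sigma_T`` with ``w = (k sigma_T)^2/((k sigma_T)^2+sigma_n^2)
    = FSC_full``."""
    ids = bins.assign(fo.s_norm)
    counts = np.bincount(ids, minlength=bins.n_bins)
    _require(stats, ["sigma_n_sq", "k_sigma_t"], counts)
    kst = _per_coeff(stats["k_sigma_t"], ids)
    sn2 = _per_coeff(stats["sigma_n_sq"], ids)
    dead = ~(kst > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = kst**2 / (kst**2 + sn2)
        coeffs = np.where(dead, 0.0, w * fo.coeffs / np.where(dead, 1.0, kst))
    return fo.with_coeffs(coeffs)


def posterior_coeffs(
    fo: FourierSet, fc: FourierSet, stats: pd.DataFrame, bins: BinScheme
) -> tuple[FourierSet, np.ndarray]:
    """Posterior mean of the (sharpened) true coefficients and its per-bin
    variance.

    The posterior of ``k F_T`` given ``F_o`` and ``D F_c`` is Gaussian with
    mean the precision-weighted combination

        m = [sigma_f^2 F_o + sigma_n^2 D F_c] / (sigma_f^2 + sigma_n^2)

    and variance ``sigma_f^2 sigma_n^2 / (sigma_f^2 + sigma_n^2)``; both are
    divided by the ``k sigma_T`` proxy for output on the sharpened scale.
    Reduces to :func:`expected_map_coeffs` at D = 0 and to ``F_o/k sigma_T``
    when sigma_n^2 = 0.
    """
    if not fo.same_layout(fc):
        raise ValueError("F_o and F_c are on different layouts")
    ids = bins.assign(fo.s_norm)
    counts = np.bincount(ids, minlength=bins.n_bins)
    _require(stats, ["sigma_f_sq", "sigma_n_sq", "k_sigma_t", "D"], counts)
    sf2 = _per_coeff(stats["sigma_f_sq"], ids)
    sn2 = _per_coeff(stats["sigma_n_sq"], ids)
    kst = _per_coeff(stats["k_sigma_t"], ids)
    d = np.where(np.isfinite(_per_coeff(stats["D"], ids)), _per_coeff(stats["D"], ids), 0.0)
    dead = ~(kst > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        total = sf2 + sn2
        w = np.where(total > 0, sf2 / np.where(total > 0, total, 1.0), 1.0)
        mean = (w * fo.coeffs + (1.0 - w) * d * fc.coeffs) / np.where(dead, 1.0, kst)
    mean = np.where(dead, 0.0, mean)
    with np.errstate(invalid="ignore", divide="ignore"):
        sf2_b = np.asarray(stats["sigma_f_sq"], dtype=float)
        sn2_b = np.asarray(stats["sigma_n_sq"], dtype=float)
        kst_b = np.asarray(stats["k_sigma_t"], dtype=float)
        tot_b = sf2_b + sn2_b
        var = np.where(
            (tot_b > 0) & (kst_b > 0), sf2_b * sn2_b / np.where(tot_b > 0, tot_b, 1.0) / np.where(kst_b > 0, kst_b, 1.0) ** 2, 0.0
        )
    return fo.with_coeffs(mean), var
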