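"""Maximum-likelihood D / sigma_f^2 estimation and overall-B fitting.

Per Fourier coefficient the likelihood of the observation given the model
is a 2D (complex) Gaussian,

    p(F_o; F_c) = 1/(pi S_i) exp(-|F_o - D_i F_c|^2 / S_i),

with bin-wise scale ``D_i`` (real) and total variance
``S_i = sigma_f^2(i) + sigma_n^2(i)``.  The joint per-bin maximizers are
closed form:

    D_i = sum Re(F_o conj F_c) / sum |F_c|^2,
    S_i = < |F_o - D_i F_c|^2 >,

and the unexplained-signal variance is ``sigma_f^2 = max(0, S - sigma_n^2)``
(the clipping is flagged; S itself is what the likelihood uses, so the
refinement-style evaluation never depends on the split).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import BinScheme, FourierSet

__all__ = ["log_likelihood", "estimate_scales", "estimate_overall_b", "OverallBFit"]


def log_likelihood(
    fo: FourierSet,
    fc: FourierSet,
    d: np.ndarray,
    s_total: np.ndarray,
    bins: BinScheme,
) -> float:
    """Sum over coefficients of ``-ln(pi S_i) - |F_o - D_i F_c|^2 / S_i``.

    ``d`` and ``s_total`` are per-bin arrays; any usable bin with
    ``S_i <= 0`` raises an error naming the bin.
    """
    ids = bins.assign(fo.s_norm)
    d = np.asarray(d, dtype=float)
    s_total = np.asarray(s_total, dtype=float)
    counts = np.bincount(ids, minlength=bins.n_bins)
    bad = (counts > 0) & ~(s_total > 0)
    if np.any(bad):
        raise ValueError(f"non-positive total variance S in bin(s) {np.where(bad)[0].tolist()}")
    resid = np.abs(fo.coeffs - d[ids] * fc.coeffs) ** 2
    return float(np.sum(-np.log(np.pi * s_total[ids]) - resid / s_total[ids]))


@dataclass
class OverallBFit:
    b_overall: float
    intercept: float
    bins_used: np.ndarray
    residuals: np.ndarray


def estimate_scales(
    fo: FourierSet,
    fc: FourierSet,
    sigma_n_sq: np.ndarray,
    bins: BinScheme,
    stats: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Joint maximum-likelihood ``(D_i, S_i)`` per resolution bin.

    Returns (or extends, when ``stats`` is given) a per-bin table with
    columns D, S, sigma_f_sq and flags: ``d_undefined`` marks bins with no
    model power (excluded from maps, with a warning) and ``sf_clipped``
    marks bins where ``S < sigma_n^2``.
    """
    import warnings

    if not fo.same_layout(fc):
        raise ValueError("F_o and F_c are on different layouts")
    ids = bins.assign(fo.s_norm)
    n = bins.n_bins
    counts = np.bincount(ids, minlength=n)
    cross = np.bincount(ids, weights=np.real(fo.coeffs * np.conj(fc.coeffs)), minlength=n)
    pc = np.bincount(ids, weights=np.abs(fc.coeffs) ** 2, minlength=n)
    d = np.full(n, np.nan)
    ok = pc > 0
    d[ok] = cross[ok] / pc[ok]
    if np.any((counts > 0) & ~ok):
        warnings.warn(
            f"bins {np.where((counts > 0) & ~ok)[0].tolist()} have zero model power; "
            "D undefined there and excluded from maps"
        )
    resid = np.abs(fo.coeffs - np.where(np.isfinite(d), d, 0.0)[ids] * fc.coeffs) ** 2
    s_sum = np.bincount(ids, weights=resid, minlength=n)
    s_total = np.full(n, np.nan)
    nz = counts > 0
    s_total[nz] = s_sum[nz] / counts[nz]
    sn2 = np.asarray(sigma_n_sq, dtype=float)
    sigma_f_sq = np.clip(s_total - sn2, 0.0, None)
    out = stats.copy() if stats is not None else pd.DataFrame({"bin": np.arange(n)})
    out["D"] = d
    out["S"] = s_total
    out["sigma_f_sq"] = sigma_f_sq
    out["sf_clipped"] = (s_total - sn2) < 0
    out["d_undefined"] = ~ok
    return out


def estimate_overall_b(
    fo: FourierSet,
    fc_zero_adp: FourierSet,
    bins: BinScheme,
    min_bins: int = 3,
) -> OverallBFit:
    """Overall sharpening B from amplitude decay against a zero-ADP model.

    Least-squares slope of ``ln(<|F_o|>_i / <|F_c|>_i)`` against
    ``-|s|^2/4`` over bins where both means are positive; the slope is
    ``B_overall`` in A^2 (F_o blurred relative to the model gives B > 0).
    """
    if not fo.same_layout(fc_zero_adp):
        raise ValueError("layout mismatch")
    ids = bins.assign(fo.s_norm)
    n = bins.n_bins
    counts = np.bincount(ids, minlength=n)
    mo = np.bincount(ids, weights=np.abs(fo.coeffs), minlength=n)
    mc = np.bincount(ids, weights=np.abs(fc_zero_adp.coeffs), minlength=n)
    usable = (counts > 0) & (mo > 0) & (mc > 0) & (bins.s_center > 0)
    if usable.sum() < min_bins:
        raise ValueError(
            f"only {int(usable.sum())} usable bins (< {min_bins}); "
            "supply an overall B value explicitly"
        )
    y = np.log(mo[usable] / mc[usable])
    x = -bins.s_center[usable] ** 2 / 4.0
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return OverallBFit(float(slope), float(intercept), np.where(usable)[0], resid)
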