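"""Per-resolution-bin statistics from two half maps.

The observation model is ``F_o = k F_T + F_n`` per Fourier coefficient,
with ``F_o = (F_o1 + F_o2)/2`` the average of the two half-map transforms
and ``F_n`` zero-mean complex Gaussian noise of variance ``sigma_n^2``
(the noise variance of the *full* map).  Because the halves are
independent, ``sigma_n^2`` is measured directly as the bin mean of
``|F_o1 - F_o2|^2 / 4``, and the signal-amplitude proxy ``k sigma_T``
follows from ``(k sigma_T)^2 = <|F_o|^2> - sigma_n^2``.

All statistics are raw per-bin values (no smoothing across bins); bins
with fewer than ``MIN_BIN_COUNT`` coefficients report NaN rather than an
unstable estimate.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import BinScheme, FourierSet

__all__ = [
    "noise_variance",
    "fsc",
    "fsc_full_from_half",
    "signal_amplitude",
    "fsc_model",
    "bin_statistics",
    "write_stats",
]

MIN_BIN_COUNT = 10


def _check_layouts(*sets: FourierSet) -> None:
    first = sets[0]
    for other in sets[1:]:
        if not first.same_layout(other):
            raise ValueError("Fourier sets are on different grids or cutoffs")


def _binned_mean(values: np.ndarray, bin_id: np.ndarray, n_bins: int) -> np.ndarray:
    counts = np.bincount(bin_id, minlength=n_bins)
    sums = np.bincount(bin_id, weights=values, minlength=n_bins)
    out = np.full(n_bins, np.nan)
    ok = counts > 0
    out[ok] = sums[ok] / counts[ok]
    return out


def noise_variance(f1: FourierSet, f2: FourierSet, bins: BinScheme) -> np.ndarray:
    """Noise variance of the averaged full map, per bin:
    ``sigma_n^2(i) = < |F_o1 - F_o2|^2 / 4 >_i``."""
    _check_layouts(f1, f2)
    ids = bins.assign(f1.s_norm)
    d = np.abs(f1.coeffs - f2.coeffs) ** 2 / 4.0
    return _binned_mean(d, ids, bins.n_bins)


def fsc(f1: FourierSet, f2: FourierSet, bins: BinScheme) -> np.ndarray:
    """Fourier shell correlation between two coefficient sets,
    ``Re sum F1 conj(F2) / (sum|F1|^2 sum|F2|^2)^(1/2)`` per bin.

    Bins where either set has zero power (or too few coefficients) are
    reported as NaN (missing), not as zero.
    """
    _check_layouts(f1, f2)
    ids = bins.assign(f1.s_norm)
    n = bins.n_bins
    cross = np.bincount(ids, weights=np.real(f1.coeffs * np.conj(f2.coeffs)), minlength=n)
    p1 = np.bincount(ids, weights=np.abs(f1.coeffs) ** 2, minlength=n)
    p2 = np.bincount(ids, weights=np.abs(f2.coeffs) ** 2, minlength=n)
    counts = np.bincount(ids, minlength=n)
    out = np.full(n, np.nan)
    ok = (p1 > 0) & (p2 > 0) & (counts >= MIN_BIN_COUNT)
    out[ok] = cross[ok] / np.sqrt(p1[ok] * p2[ok])
    return out


def fsc_full_from_half(fsc_half: np.ndarray) -> np.ndarray:
    """Correlation of the averaged map with the true signal,
    ``FSC_full = 2 FSC_half / (1 + FSC_half)``."""
    fsc_half = np.asarray(fsc_half, dtype=float)
    return 2.0 * fsc_half / (1.0 + fsc_half)


def signal_amplitude(
    fo: FourierSet, sigma_n_sq: np.ndarray, bins: BinScheme
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin signal amplitude proxy ``k sigma_T``.

    ``(k sigma_T)^2 = max(0, <|F_o|^2> - sigma_n^2)``; negative differences
    (pure-noise bins) are clipped to zero and flagged.  Returns
    ``(k_sigma_t, clipped)``.
    """
    ids = bins.assign(fo.s_norm)
    mean_fo_sq = _binned_mean(np.abs(fo.coeffs) ** 2, ids, bins.n_bins)
    diff = mean_fo_sq - np.asarray(sigma_n_sq, dtype=float)
    clipped = diff < 0
    return np.sqrt(np.clip(diff, 0.0, None)), clipped


def fsc_model(
    fo: FourierSet, fc: FourierSet, bins: BinScheme
) -> tuple[np.ndarray, float]:
    """Map-model FSC per bin plus its coefficient-count-weighted average,
    ``sum N_i FSC_i / sum N_i`` (the FSC-average monitor)."""
    per_bin = fsc(fo, fc, bins)
    counts = np.bincount(bins.assign(fo.s_norm), minlength=bins.n_bins)
    ok = np.isfinite(per_bin)
    if not np.any(ok):
        return per_bin, float("nan")
    avg = float(np.sum(counts[ok] * per_bin[ok]) / np.sum(counts[ok]))
    return per_bin, avg


def bin_statistics(
    f1: FourierSet,
    f2: FourierSet,
    bins: BinScheme,
    fc: FourierSet | None = None,
) -> pd.DataFrame:
    """Assemble the per-bin statistics table from two half maps.

    Columns: bin, s_center (1/A), d_center (A), n_coeffs, sigma_n_sq,
    mean_fo_sq, k_sigma_t, kst_clipped, fsc_half, fsc_full and, when a
    model is given, fsc_model.  D and sigma_f_sq are appended by
    :func:`diffem.scaling.estimate_scales`.
    """
    _check_layouts(f1, f2)
    fo = f1.with_coeffs((f1.coeffs + f2.coeffs) / 2.0)
    ids = bins.assign(f1.s_norm)
    n = bins.n_bins
    counts = np.bincount(ids, minlength=n)
    sn2 = noise_variance(f1, f2, bins)
    mean_fo_sq = _binned_mean(np.abs(fo.coeffs) ** 2, ids, n)
    kst, clipped = signal_amplitude(fo, sn2, bins)
    fsc_half = fsc(f1, f2, bins)
    with np.errstate(invalid="ignore"):
        s_center = bins.s_center
        d_center = np.where(s_center > 0, 1.0 / np.where(s_center > 0, s_center, 1.0), np.inf)
    df = pd.DataFrame(
        {
            "bin": np.arange(n),
            "s_center": s_center,
            "d_center": d_center,
            "n_coeffs": counts,
            "sigma_n_sq": sn2,
            "mean_fo_sq": mean_fo_sq,
            "k_sigma_t": kst,
            "kst_clipped": clipped,
            "fsc_half": fsc_half,
            "fsc_full": fsc_full_from_half(fsc_half),
        }
    )
    if fc is not None:
        per_bin, avg = fsc_model(fo, fc, bins)
        df["fsc_model"] = per_bin
        df.attrs["fsc_average"] = avg
    return df


def write_stats(df: pd.DataFrame, path_tsv: str | Path, path_json: str | Path | None = None) -> None:
    """Write the statistics table as tab-separated text and optionally JSON."""
    df.to_csv(path_tsv, sep="\t", index=False, float_format="%.6g")
    if path_json is not None:
        payload = {"bins": df.replace({np.nan: None}).to_dict(orient="records")}
        if "fsc_average" in df.attrs:
            payload["fsc_average"] = df.attrs["fsc_average"]
        Path(path_json).write_text(json.dumps(payload, indent=1))
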