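"""End-to-end difference-map workflow: half maps + model -> weighted,
sharpened Fo-Fc and normalized expected maps.

Steps (the map-calculation branch of the refinement workflow; external
refinement of the model is assumed to have happened already — the Fo-Fc
map is only sensible when the ADPs are properly refined):

1. read half maps and model; build point-group operators about the box
   centre; expand the model for masking;
2. model mask (3 A default radius), overall B from a zero-ADP model,
   sharpen-mask-unsharpen, average to the full map;
3. trim to the mask bounding box (coordinates and symmetry translations
   recomputed for the shifted frame);
4. per-bin half-map statistics, D/sigma_f^2 estimation against the full
   model, then F_c with the omit selection removed;
5. Fo-Fc and normalized-Fo coefficients, inverse FFT, restoration to the
   original frame, masked-variance normalization;
6. stats table, output maps, machine-readable run summary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import diffmap, halfmap, masking, scaling
from .grid import MapGrid, fft_map, ifft_map, make_bins, read_map, write_map
from .model import AtomicModel, calc_fc, read_model
from .symmetry import SymOpSet, operators_from_symbol, expand_model

__all__ = ["FofcResult", "run_fofc", "run_fofc_from_files"]


@dataclass
class FofcResult:
    fofc_map: MapGrid
    expected_map: MapGrid
    stats: "object"  # pandas DataFrame
    b_overall: float
    normalized: bool
    mask_stats: object | None = None
    outputs: dict[str, str] = field(default_factory=dict)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_fofc(
    half1: MapGrid,
    half2: MapGrid,
    model: AtomicModel,
    mask: MapGrid | None = None,
    pointgroup: str = "C1",
    d_min: float | None = None,
    n_bins: int | None = None,
    b_overall: float | None = None,
    omit_indices=None,
    omit_hydrogens: bool = False,
    normalize: bool = True,
    mask_radius: float = 3.0,
    trim_padding: float = 5.0,
    trim: bool = True,
) -> FofcResult:
    """Compute weighted/sharpened Fo-Fc and normalized expected maps.

    ``omit_indices`` / ``omit_hydrogens`` remove atoms from F_c *after* the
    D/sigma_f^2 estimation pass with the full model, the standard omit-map
    recipe.  Returns maps in the original (untrimmed) frame.
    """
    if half1.shape != half2.shape or not np.allclose(half1.cell, half2.cell):
        raise ValueError("half maps disagree in grid or cell")
    if d_min is None:
        d_min = 2.0 * float(np.max(half1.voxel_size))
    center = half1.origin_shift + half1.cell / 2.0
    ops = operators_from_symbol(pointgroup, center)
    expanded = expand_model(model, ops)
    if mask is None:
        mask = masking.model_mask(expanded, half1, radius=mask_radius)
    if b_overall is None:
        fo_raw = fft_map(
            MapGrid((half1.values + half2.values) / 2.0, half1.cell, half1.origin_shift), d_min
        )
        zero_adp = model.copy()
        for a in zero_adp.atoms:
            a.b_iso = 0.0
            a.b_aniso = None
        fc0 = calc_fc(zero_adp, fo_raw, ops=ops)
        bins0 = make_bins(fo_raw, n_bins=n_bins)
        b_overall = scaling.estimate_overall_b(fo_raw, fc0, bins0).b_overall
    h1m, h2m, _ = masking.sharpen_mask_unsharpen(half1, half2, b_overall, mask)

    record = None
    if trim:
        # trimmed maps keep absolute coordinates via origin_shift, so the
        # model and the (absolute-frame) operators are reused unchanged
        (h1m, h2m, _mask_t), record = masking.trim_box([h1m, h2m, mask], mask, padding=trim_padding)
    work_model = model

    f1 = fft_map(h1m, d_min)
    f2 = fft_map(h2m, d_min)
    bins = make_bins(f1, n_bins=n_bins)
    fo = f1.with_coeffs((f1.coeffs + f2.coeffs) / 2.0)

    fc_full = calc_fc(work_model, fo, ops=ops)
    stats = halfmap.bin_statistics(f1, f2, bins, fc=fc_full)
    stats = scaling.estimate_scales(fo, fc_full, stats["sigma_n_sq"].to_numpy(), bins, stats=stats)
    stats.attrs["b_overall"] = b_overall

    omit_model = work_model
    if omit_indices is not None:
        omit_model = omit_model.without(omit_indices)
    if omit_hydrogens:
        omit_model = omit_model.without_hydrogens()
    if omit_model is not work_model:
        fc_map = calc_fc(omit_model, fo, ops=ops)
    else:
        fc_map = fc_full

    dF = diffmap.fofc_coeffs(fo, fc_map, stats, bins)
    fexp = diffmap.expected_map_coeffs(fo, stats, bins)
    fofc_grid = ifft_map(dF)
    expected_grid = ifft_map(fexp)
    if record is not None:
        fofc_grid = masking.untrim(fofc_grid, record)
        expected_grid = masking.untrim(expected_grid, record)

    mask_stats = None
    if normalize:
        fofc_grid, mask_stats = masking.normalize_map(fofc_grid, mask)
    return FofcResult(
        fofc_map=fofc_grid,
        expected_map=expected_grid,
        stats=stats,
        b_overall=float(b_overall),
        normalized=normalize,
        mask_stats=mask_stats,
    )


def run_fofc_from_files(
    half1_path: str,
    half2_path: str,
    model_path: str,
    outdir: str,
    mask_path: str | None = None,
    **kwargs,
) -> FofcResult:
    """File-based wrapper around :func:`run_fofc`; writes diffmap_fofc.mrc,
    diffmap_normalized_fo.mrc, the stats table and a JSON run summary with
    content checksums."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    half1 = read_map(half1_path)
    half2 = read_map(half2_path)
    model = read_model(model_path)
    mask = read_map(mask_path) if mask_path else None
    result = run_fofc(half1, half2, model, mask=mask, **kwargs)
    files = {
        "fofc": out / "diffmap_fofc.mrc",
        "expected": out / "diffmap_normalized_fo.mrc",
        "stats_tsv": out / "stats.tsv",
        "stats_json": out / "stats.json",
    }
    write_map(result.fofc_map, files["fofc"])
    write_map(result.expected_map, files["expected"])
    halfmap.write_stats(result.stats, files["stats_tsv"], files["stats_json"])
    summary = {
        "b_overall": result.b_overall,
        "normalized": result.normalized,
        "var_mask": None if result.mask_stats is None else result.mask_stats.var_mask,
        "fsc_average": result.stats.attrs.get("fsc_average"),
        "outputs": {k: {"path": str(p), "sha256_16": _checksum(p)} for k, p in files.items()},
    }
    summary_path = out / "run_summary.json"
    summary_path.write_text(json.dumps(summary, indent=1))
    result.outputs = {k: str(p) for k, p in files.items()}
    result.outputs["summary"] = str(summary_path)
    return result
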