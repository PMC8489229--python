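"""Synthetic toy models and half-map simulation with ground truth.

The simulator realizes the per-coefficient observation model used
throughout the package:

    F_half = k(s) F_T + F_noise,   k(s) = exp(-B_blur |s|^2 / 4),

with F_T the electron structure factors of a toy atomic model (optionally
symmetry-expanded) and independent complex Gaussian noise per half map.
Noise is generated as real-space white noise scaled per resolution shell,
so conjugate symmetry holds exactly and the half maps are real.  The
implied full-map noise variance is half the per-half variance and is
recorded in the ground truth.

All randomness flows from a single integer seed; the same seed reproduces
byte-identical half maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import BinScheme, FourierSet, MapGrid, fft_map, ifft_map, make_bins
from .model import Atom, AtomicModel, calc_fc
from .symmetry import SymOpSet

__all__ = ["GroundTruth", "make_toy_model", "simulate_half_maps"]

_DEFAULT_ELEMENTS = ("C", "N", "O")


@dataclass
class GroundTruth:
    f_true: FourierSet
    b_blur: float
    noise_level_half: float | np.ndarray
    sigma_n_sq: np.ndarray  # implied full-map noise variance per bin
    bins: BinScheme
    seed: int
    model: AtomicModel
    symmetry: str

    def k(self, s_norm: np.ndarray) -> np.ndarray:
        return np.exp(-self.b_blur * np.asarray(s_norm) ** 2 / 4.0)


def make_toy_model(
    n_atoms: int,
    box: float = 20.0,
    seed: int = 0,
    elements: tuple[str, ...] = _DEFAULT_ELEMENTS,
    with_hydrogens: bool = False,
    b_range: tuple[float, float] = (10.0, 40.0),
    min_sep: float = 1.5,
) -> AtomicModel:
    """Random toy model inside a cubic box of edge ``box`` Angstrom.

    Heavy atoms keep a minimum pairwise separation of ``min_sep`` (placed
    by rejection sampling in the central 60% of the box so density does not
    wrap), B values are drawn uniformly from ``b_range``.  With
    ``with_hydrogens`` each carbon gets one riding-style hydrogen at 1.0 A.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = 0.2 * box, 0.8 * box
    if n_atoms > 1 and (hi - lo) < min_sep * n_atoms ** (1 / 3):
        raise ValueError(f"box {box} A too small for {n_atoms} atoms at {min_sep} A separation")
    atoms: list[Atom] = []
    positions: list[np.ndarray] = []
    if n_atoms == 1:
        positions.append(np.full(3, box / 2.0))
    else:
        tries = 0
        while len(positions) < n_atoms:
            cand = rng.uniform(lo, hi, size=3)
            if all(np.linalg.norm(cand - p) >= min_sep for p in positions):
                positions.append(cand)
            tries += 1
            if tries > 10000 * n_atoms:
                raise ValueError("box too small for requested separation")
    for i, pos in enumerate(positions):
        el = elements[i % len(elements)]
        atoms.append(
            Atom(
                element=el,
                position=pos,
                b_iso=float(rng.uniform(*b_range)),
                name=f"{el}{i+1}",
                resseq=i + 1,
                resname="TOY",
            )
        )
    if with_hydrogens:
        n_heavy = len(atoms)
        for i in range(n_heavy):
            parent = atoms[i]
            if parent.element != "C":
                continue
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            atoms.append(
                Atom(
                    element="H",
                    position=parent.position + direction,
                    b_iso=parent.b_iso,
                    name=f"H{i+1}",
                    resseq=parent.resseq,
                    resname="TOY",
                )
            )
    return AtomicModel(atoms, box=np.full(3, float(box)))


def _grid_for(box: np.ndarray, d_min: float, oversample: float = 1.2) -> tuple[int, int, int]:
    """Grid dimensions giving voxel <= d_min / (2 * oversample)."""
    from .masking import _fft_friendly

    return tuple(_fft_friendly(int(np.ceil(2 * oversample * b / d_min))) for b in box)


def simulate_half_maps(
    model: AtomicModel,
    b_blur: float = 30.0,
    noise_level: float | np.ndarray = 1e-4,
    d_min: float = 2.0,
    ops: SymOpSet | None = None,
    seed: int = 0,
    shape: tuple[int, int, int] | None = None,
    n_bins: int | None = None,
) -> tuple[MapGrid, MapGrid, GroundTruth]:
    """Simulate two half maps from a toy model.

    ``noise_level`` is the complex-Gaussian variance per coefficient of
    each *half* map (scalar, or per-bin array over the bin scheme built
    here); the implied full-map noise variance ``sigma_n^2 = noise_level/2``
    is recorded in the returned :class:`GroundTruth`.
    """
    if model.box is None:
        raise ValueError("model must carry its box size")
    if np.any(np.asarray(noise_level) < 0):
        raise ValueError("noise_level must be >= 0")
    box = np.asarray(model.box, dtype=float)
    if shape is None:
        shape = _grid_for(box, d_min)
    voxel = box / np.array(shape)
    if d_min < 2 * voxel.max() - 1e-9:
        raise ValueError(f"d_min={d_min} below Nyquist of grid {shape} in box {box}")
    template = MapGrid(np.zeros(shape, dtype=np.float32), box)
    layout = fft_map(template, d_min)
    f_true = calc_fc(model, layout, ops=ops)
    bins = make_bins(f_true, n_bins=n_bins)
    k = np.exp(-b_blur * f_true.s_norm**2 / 4.0)
    signal = f_true.coeffs * k
    rng = np.random.default_rng(seed)
    nvox = int(np.prod(shape))
    dv = float(np.prod(voxel))
    ids = bins.assign(f_true.s_norm)
    level = np.asarray(noise_level, dtype=float)
    per_coeff_level = level[ids] if level.ndim else np.full(len(layout), float(level))
    halves = []
    for _ in range(2):
        white = rng.standard_normal(shape)
        wf = fft_map(MapGrid(white, box), d_min)
        # rfftn of unit white noise has per-coefficient variance nvox*dv^2
        noise = wf.coeffs / np.sqrt(nvox * dv * dv) * np.sqrt(per_coeff_level)
        half = layout.with_coeffs(signal + noise)
        halves.append(ifft_map(half))
    counts = np.bincount(ids, minlength=bins.n_bins).astype(float)
    sn2 = np.full(bins.n_bins, np.nan)
    nz = counts > 0
    sums = np.bincount(ids, weights=per_coeff_level / 2.0, minlength=bins.n_bins)
    sn2[nz] = sums[nz] / counts[nz]
    truth = GroundTruth(
        f_true=f_true,
        b_blur=float(b_blur),
        noise_level_half=noise_level,
        sigma_n_sq=sn2,
        bins=bins,
        seed=seed,
        model=model,
        symmetry=ops.symbol if ops is not None else "C1",
    )
    return halves[0], halves[1], truth
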