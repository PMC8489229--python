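"""Real-space map grids, Fourier coefficients and resolution binning.

Conventions used throughout the package:

* Grids are P1 with an orthogonal box; fractional <-> Cartesian conversion
  is diagonal (``x = index * voxel_size + origin_shift``).
* Structure factors follow the crystallographic sign convention
  ``F(s) = integral rho(x) exp(+2 pi i s.x) dV`` and are volume weighted, so
  ``F(0) = sum(map) * voxel_volume``.  Only ratios of coefficients enter the
  statistics, so any consistent convention would do; this one makes ``F``
  directly comparable with atomic structure factors.
* Fourier coefficients are kept on the numpy ``rfftn`` half grid; the
  conjugate half is implied by the maps being real.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "MapGrid",
    "FourierSet",
    "BinScheme",
    "read_map",
    "write_map",
    "fft_map",
    "ifft_map",
    "make_bins",
]


class MapFormatError(ValueError):
    """Raised when an MRC/CCP4 file cannot be interpreted."""


@dataclass
class MapGrid:
    """A real scalar field on a regular grid in an orthogonal box.

    Parameters
    ----------
    values
        Array of shape ``(n1, n2, n3)``; axis 0 is x.
    cell
        Box edge lengths in Angstrom.
    origin_shift
        Cartesian offset (Angstrom) of voxel ``(0,0,0)`` relative to the
        absolute (deposited) frame.  Kept so that trimming and untrimming
        round-trip atomic coordinates exactly.
    """

    values: np.ndarray
    cell: np.ndarray
    origin_shift: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.cell = np.asarray(self.cell, dtype=float)
        self.origin_shift = np.asarray(self.origin_shift, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("map values must be a 3D array")
        if np.any(self.cell <= 0):
            raise ValueError("cell lengths must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        return self.cell / np.array(self.shape)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def copy(self) -> "MapGrid":
        return MapGrid(self.values.copy(), self.cell.copy(), self.origin_shift.copy())


@dataclass
class FourierSet:
    """Fourier coefficients of a real map, restricted to ``|s| <= 1/d_min``.

    ``coeffs[j]`` is the structure factor at integer grid index ``hkl[j]``
    (signed Miller-like indices on the rfftn half grid), ``s_norm[j]`` the
    corresponding ``|s|`` in 1/Angstrom.  ``bin_id`` is filled by
    :func:`make_bins` / :meth:`with_bins`.
    """

    coeffs: np.ndarray
    hkl: np.ndarray
    s_norm: np.ndarray
    d_min: float
    shape: tuple[int, int, int]
    cell: np.ndarray
    origin_shift: np.ndarray = field(default_factory=lambda: np.zeros(3))
    bin_id: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.coeffs)

    @property
    def svec(self) -> np.ndarray:
        """Reciprocal-space vectors s (n, 3) in 1/Angstrom."""
        return self.hkl / np.asarray(self.cell, dtype=float)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(np.asarray(self.cell) / np.array(self.shape)))

    def same_layout(self, other: "FourierSet") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.cell, other.cell)
            and self.d_min == other.d_min
            and len(self) == len(other)
        )

    def with_coeffs(self, coeffs: np.ndarray) -> "FourierSet":
        """A copy of this layout carrying different coefficient values."""
        if len(coeffs) != len(self):
            raise ValueError("coefficient count does not match layout")
        return replace(self, coeffs=np.asarray(coeffs, dtype=complex))

    def with_bins(self, bins: "BinScheme") -> "FourierSet":
        return replace(self, bin_id=bins.assign(self.s_norm))


@dataclass
class BinScheme:
    """Equal-width shells in ``|s|`` covering ``[0, 1/d_min]``.

    Sparse bins (fewer than ``min_count`` coefficients) are merged into their
    higher-resolution neighbour so that per-bin variance estimates stay
    stable; ``edges`` reflect the merged boundaries.
    """

    edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def s_center(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def assign(self, s_norm: np.ndarray) -> np.ndarray:
        """Bin index per coefficient; a value on an internal edge goes to
        the lower-``|s|`` bin."""
        ids = np.searchsorted(self.edges, s_norm, side="left") - 1
        return np.clip(ids, 0, self.n_bins - 1)


# ---------------------------------------------------------------------------
# Map I/O (MRC/CCP4 2014 via gemmi)

_WORD_NSTART = (5, 6, 7)
_WORD_MODE = 4
_WORD_ORIGIN = (50, 51, 52)


def read_map(path: str | Path) -> MapGrid:
    """Read an MRC/CCP4 volume (modes 0/1/2) into a :class:`MapGrid`.

    Axis order is canonicalized (any mapc/mapr/maps permutation accepted),
    and the origin is taken from the ORIGIN header words if nonzero, else
    from nxstart/nystart/nzstart times the voxel size.
    """
    path = Path(path)
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapFormatError(f"cannot read MRC/CCP4 map {path}: {exc}") from exc
    mode = ccp4.header_i32(_WORD_MODE)
    if mode not in (0, 1, 2):
        raise MapFormatError(f"unsupported MRC mode {mode} in {path} (expected 0/1/2)")
    cell = ccp4.grid.unit_cell
    if not (
        abs(cell.alpha - 90) < 1e-3 and abs(cell.beta - 90) < 1e-3 and abs(cell.gamma - 90) < 1e-3
    ):
        raise MapFormatError(
            f"non-orthogonal cell (alpha,beta,gamma)=({cell.alpha},{cell.beta},{cell.gamma}) "
            "is not supported"
        )
    # canonicalize axis order to X-fastest without regridding the extent
    ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    values = np.array(ccp4.grid, copy=True)
    if not np.all(np.isfinite(values)):
        raise MapFormatError(f"map {path} contains non-finite values")
    cell = ccp4.grid.unit_cell
    cell_arr = np.array([cell.a, cell.b, cell.c])
    voxel = cell_arr / np.array(values.shape)
    origin = np.array([ccp4.header_float(w) for w in _WORD_ORIGIN])
    if np.all(origin == 0):
        nstart = np.array([ccp4.header_i32(w) for w in _WORD_NSTART])
        origin = nstart * voxel
    return MapGrid(values.astype(np.float32), cell_arr, origin)


def write_map(grid: MapGrid, path: str | Path) -> None:
    """Write a :class:`MapGrid` as an MRC/CCP4 mode-2 volume, X-fastest.

    The origin is stored in nxstart/nystart/nzstart when it is an integer
    number of voxels (the common SPA convention), otherwise in the ORIGIN
    float header words.
    """
    ccp4 = gemmi.Ccp4Map()
    g = gemmi.FloatGrid(*grid.shape)
    g.set_unit_cell(gemmi.UnitCell(*grid.cell, 90, 90, 90))
    g.spacegroup = gemmi.find_spacegroup_by_name("P 1")
    np.array(g, copy=False)[...] = grid.values.astype(np.float32)
    ccp4.grid = g
    ccp4.update_ccp4_header()
    voxel = grid.voxel_size
    nstart = grid.origin_shift / voxel
    nstart_round = np.round(nstart)
    if np.allclose(nstart, nstart_round, atol=1e-4):
        for w, v in zip(_WORD_NSTART, nstart_round):
            ccp4.set_header_i32(w, int(v))
    else:
        for w, v in zip(_WORD_ORIGIN, grid.origin_shift):
            ccp4.set_header_float(w, float(v))
    ccp4.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# Fourier transforms


def _half_grid_indices(shape: tuple[int, int, int]) -> tuple[np.ndarray, ...]:
    n1, n2, n3 = shape
    h = np.fft.fftfreq(n1, d=1.0 / n1).astype(int)
    k = np.fft.fftfreq(n2, d=1.0 / n2).astype(int)
    l = np.arange(n3 // 2 + 1)
    return h, k, l


def fft_map(grid: MapGrid, d_min: float) -> FourierSet:
    """Forward transform of a map, keeping coefficients with ``|s| <= 1/d_min``.

    Raises a precondition error when ``d_min`` is beyond the Nyquist limit of
    the grid sampling.
    """
    nyquist = 2.0 * float(np.max(grid.voxel_size))
    if d_min < nyquist - 1e-9:
        raise ValueError(
            f"d_min={d_min} A is below the Nyquist limit of this grid; "
            f"achievable d_min >= {nyquist:.4f} A"
        )
    full = np.conj(np.fft.rfftn(grid.values)) * grid.voxel_volume
    h, k, l = _half_grid_indices(grid.shape)
    s2 = (
        (h[:, None, None] / grid.cell[0]) ** 2
        + (k[None, :, None] / grid.cell[1]) ** 2
        + (l[None, None, :] / grid.cell[2]) ** 2
    )
    keep = s2 <= (1.0 / d_min) ** 2 + 1e-12
    hh, kk, ll = np.meshgrid(h, k, l, indexing="ij")
    hkl = np.stack([hh[keep], kk[keep], ll[keep]], axis=1)
    return FourierSet(
        coeffs=full[keep].astype(complex),
        hkl=hkl,
        s_norm=np.sqrt(s2[keep]),
        d_min=float(d_min),
        shape=grid.shape,
        cell=grid.cell.copy(),
        origin_shift=grid.origin_shift.copy(),
    )


def empty_layout(grid: MapGrid, d_min: float) -> FourierSet:
    """A :class:`FourierSet` template (zero coefficients) for a grid."""
    fs = fft_map(MapGrid(np.zeros(grid.shape, dtype=np.float32), grid.cell, grid.origin_shift), d_min)
    return fs


def ifft_map(fs: FourierSet) -> MapGrid:
    """Inverse transform back to a real map; coefficients outside the stored
    cutoff are treated as zero."""
    n1, n2, n3 = fs.shape
    half = np.zeros((n1, n2, n3 // 2 + 1), dtype=complex)
    idx = (fs.hkl[:, 0] % n1, fs.hkl[:, 1] % n2, fs.hkl[:, 2])
    half[idx] = np.conj(fs.coeffs) / fs.voxel_volume
    values = np.fft.irfftn(half, s=fs.shape, axes=(0, 1, 2))
    return MapGrid(values, np.asarray(fs.cell, dtype=float).copy(), np.asarray(fs.origin_shift, dtype=float).copy())


# ---------------------------------------------------------------------------
# Binning


def make_bins(
    fs: FourierSet,
    n_bins: int | None = None,
    min_count: int = 50,
) -> BinScheme:
    """Equal-width ``|s|`` bins over ``[0, 1/d_min]``.

    Default bin count is ``max(10, N/4)`` for an ``N``-point grid edge; bins
    holding fewer than ``min_count`` coefficients are merged into the next
    higher-resolution bin (the final bin merges downward).
    """
    if n_bins is None:
        n_bins = max(10, min(fs.shape) // 4)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    smax = 1.0 / fs.d_min
    edges = np.linspace(0.0, smax, n_bins + 1)
    scheme = BinScheme(edges, np.zeros(n_bins, dtype=int))
    ids = scheme.assign(fs.s_norm)
    counts = np.bincount(ids, minlength=n_bins)
    # merge sparse bins upward (toward higher |s|)
    keep_edges = [edges[0]]
    merged_counts: list[int] = []
    acc = 0
    for i in range(n_bins):
        acc += int(counts[i])
        if acc >= min_count or i == n_bins - 1:
            keep_edges.append(edges[i + 1])
            merged_counts.append(acc)
            acc = 0
    if len(merged_counts) > 1 and merged_counts[-1] < min_count:
        merged_counts[-2] += merged_counts[-1]
        del merged_counts[-1]
        del keep_edges[-2]
    return BinScheme(np.array(keep_edges), np.array(merged_counts))


def bin_mean(values: np.ndarray, bin_id: np.ndarray, n_bins: int) -> np.ndarray:
    """Per-bin mean of ``values``; empty bins give NaN."""
    counts = np.bincount(bin_id, minlength=n_bins).astype(float)
    sums = np.bincount(bin_id, weights=np.asarray(values, dtype=float), minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
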