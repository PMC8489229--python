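"""Atomic models and electron structure factors via the Mott-Bethe formula.

Electron scattering factors are derived from X-ray (electron-cloud) form
factors f_x through

    f_e(s) = C * (Z * exp(2 pi i s.dx) - f_x(|s|)) / |s|^2

where ``dx`` is the shift of the nucleus relative to the centre of the
electron cloud (nonzero for H atoms, whose electron is pulled toward the
parent atom) and ``C = 1 / (2 pi^2 a0)`` with ``a0`` the Bohr radius.  The
Debye-Waller factor exp(-B|s|^2/4) (or exp(-s^T B s / 4) for anisotropic
ADPs) multiplies the whole expression.

X-ray factors use the International Tables 4-Gaussian parameterization as
tabulated in gemmi.  For the Mott-Bethe evaluation the constant term is
renormalized so that f_x(0) = Z exactly, making (Z - f_x)/|s|^2 finite at
the origin (its limit is sum(a_j b_j)/4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .grid import FourierSet
from .symmetry import SymOpSet

__all__ = [
    "Atom",
    "AtomicModel",
    "MOTT_BETHE_CONST",
    "xray_form_factor",
    "mott_bethe_factor",
    "calc_fc",
    "read_model",
    "write_model",
]

# C = 1/(2 pi^2 a0), Bohr radius a0 = 0.529177 A  (6 significant figures)
MOTT_BETHE_CONST = 0.0957346  # Angstrom


@dataclass
class Atom:
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_iso: float = 20.0
    b_aniso: np.ndarray | None = None
    nucleus_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    is_rotatable_h: bool = False
    name: str = ""
    chain: str = "A"
    resname: str = "UNK"
    resseq: int = 1

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.nucleus_offset = np.asarray(self.nucleus_offset, dtype=float)
        if self.b_aniso is not None:
            self.b_aniso = np.asarray(self.b_aniso, dtype=float)
        if self.z < 1:
            raise ValueError(f"unknown element {self.element!r}")
        if self.b_iso < 0:
            raise ValueError("isotropic B must be non-negative")
        if np.linalg.norm(self.nucleus_offset) > 0.5 + 1e-9:
            raise ValueError("|nucleus offset| must be <= 0.5 A")
        if not self.name:
            self.name = self.element

    @property
    def z(self) -> int:
        return gemmi.Element(self.element).atomic_number

    @property
    def is_hydrogen(self) -> bool:
        return self.z == 1

    def copy(self) -> "Atom":
        return Atom(
            self.element,
            self.position.copy(),
            self.occupancy,
            self.b_iso,
            None if self.b_aniso is None else self.b_aniso.copy(),
            self.nucleus_offset.copy(),
            self.is_rotatable_h,
            self.name,
            self.chain,
            self.resname,
            self.resseq,
        )


@dataclass
class AtomicModel:
    atoms: list[Atom]
    box: np.ndarray | None = None  # cell edges (A) of the map the model sits in

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("model must contain at least one atom")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    def __len__(self) -> int:
        return len(self.atoms)

    def positions(self) -> np.ndarray:
        return np.stack([a.position for a in self.atoms])

    def copy(self) -> "AtomicModel":
        return AtomicModel([a.copy() for a in self.atoms], None if self.box is None else self.box.copy())

    def without(self, indices) -> "AtomicModel":
        """Model with the listed atom indices omitted."""
        drop = set(int(i) for i in np.atleast_1d(indices))
        kept = [a.copy() for i, a in enumerate(self.atoms) if i not in drop]
        return AtomicModel(kept, None if self.box is None else self.box.copy())

    def without_hydrogens(self) -> "AtomicModel":
        kept = [a.copy() for a in self.atoms if not a.is_hydrogen]
        return AtomicModel(kept, None if self.box is None else self.box.copy())

    def shifted(self, shift: np.ndarray) -> "AtomicModel":
        """All positions moved by ``x' = x - shift`` (trimmed-frame view)."""
        m = self.copy()
        for a in m.atoms:
            a.position = a.position - np.asarray(shift, dtype=float)
        return m


# ---------------------------------------------------------------------------
# Form factors


def _it92(element: str):
    el = gemmi.Element(element)
    if el.atomic_number < 1:
        raise KeyError(
            f"no scattering coefficients for element {element!r}; "
            "supported symbols are standard periodic-table elements"
        )
    c = el.it92
    if c is None:
        raise KeyError(f"no IT92 coefficients for element {element!r}")
    return np.asarray(c.a), np.asarray(c.b), float(c.c), el.atomic_number


def xray_form_factor(element: str, s_norm) -> np.ndarray | float:
    """X-ray scattering factor f_x(|s|), 4-Gaussian IT92 parameterization.

    ``s_norm`` is |s| in 1/Angstrom (note stol = |s|/2); f_x(0) = Z for
    neutral atoms within table accuracy.
    """
    a, b, c, _ = _it92(element)
    s = np.asarray(s_norm, dtype=float)
    stol2 = s * s / 4.0
    f = c + np.sum(a * np.exp(-b * stol2[..., None]), axis=-1)
    return f if f.ndim else float(f)


def _mott_bethe_radial(element: str, s_norm: np.ndarray) -> np.ndarray:
    """C (Z - f_x)/|s|^2 with the renormalized table (finite at s=0)."""
    a, b, _, _z = _it92(element)
    # drop the table constant (c' = Z - sum(a)), making f_x(0) = Z exact:
    # Z - f_x then telescopes to sum_j a_j (1 - exp(-b_j s^2/4))
    s2 = np.asarray(s_norm, dtype=float) ** 2
    quarter = s2 / 4.0
    # (Z - f_x)/s^2 = sum_j a_j (1 - exp(-b_j s^2/4)) / s^2, stable via expm1
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = -np.expm1(-b * quarter[..., None])
        ratio = np.where(
            s2[..., None] > 0, terms / np.where(s2[..., None] > 0, s2[..., None], 1.0), b / 4.0
        )
    return MOTT_BETHE_CONST * np.sum(a * ratio, axis=-1)


def mott_bethe_factor(
    element: str,
    s,
    delta_x: np.ndarray | None = None,
    b: float | np.ndarray = 0.0,
) -> np.ndarray | complex:
    """Electron scattering factor for an atom with a shifted nucleus.

    Parameters
    ----------
    s
        Reciprocal vectors, shape (..., 3), in 1/Angstrom.
    delta_x
        Nucleus position minus electron-cloud centre (Angstrom); zero for
        non-hydrogens.
    b
        Isotropic ADP (Angstrom^2) or 3x3 anisotropic tensor.

    The s -> 0 limit is finite and handled by series expansion: the neutral
    part tends to ``C sum(a_j b_j)/4`` and the dipole phase term (whose
    directional limit does not exist at exactly s = 0) is assigned its
    angular average of zero.
    """
    s = np.atleast_2d(np.asarray(s, dtype=float))
    s2 = np.sum(s * s, axis=-1)
    _, _, _, z = _it92(element)
    neutral = _mott_bethe_radial(element, np.sqrt(s2))
    out = neutral.astype(complex)
    if delta_x is not None and np.any(np.asarray(delta_x) != 0):
        dx = np.asarray(delta_x, dtype=float)
        phase = 2j * np.pi * (s @ dx)
        # at exactly s = 0 the directional limit does not exist; use the
        # angular average: first order vanishes, second order gives
        # -(2 pi |dx|)^2 / 6
        limit0 = -z * (2 * np.pi * np.linalg.norm(dx)) ** 2 / 6.0
        with np.errstate(invalid="ignore", divide="ignore"):
            dipole = np.where(
                s2 > 0,
                z * np.expm1(np.where(s2 > 0, phase, 0.0)) / np.where(s2 > 0, s2, 1.0),
                limit0,
            )
        out = out + MOTT_BETHE_CONST * dipole
    out = out * debye_waller(s, b)
    return out if out.shape != (1,) else complex(out[0])


def debye_waller(s: np.ndarray, b: float | np.ndarray) -> np.ndarray:
    """exp(-B|s|^2/4) or exp(-s^T B s/4) for a 3x3 tensor."""
    s = np.asarray(s, dtype=float)
    if np.ndim(b) == 2:
        quad = np.einsum("...i,ij,...j->...", s, np.asarray(b, dtype=float), s)
        return np.exp(-quad / 4.0)
    return np.exp(-float(b) * np.sum(s * s, axis=-1) / 4.0)


# ---------------------------------------------------------------------------
# Structure-factor calculation


def calc_fc(
    model: AtomicModel,
    layout: FourierSet,
    ops: SymOpSet | None = None,
    method: str = "auto",
    direct_limit: int = 10_000,
) -> FourierSet:
    """Electron structure factors of a model on a Fourier layout.

    F_c(s) = sum_ops sum_atoms occ * f_e(s; element, dx, B') *
             exp(2 pi i s.(R_j x + t_j - origin)),  B' = R_j B R_j^T.

    ``method`` selects direct reciprocal-space summation (``"direct"``,
    exact), real-space density sampling + FFT (``"density"``), or ``"auto"``
    which uses direct summation up to ``direct_limit`` atom copies.
    """
    from .symmetry import expand_model

    expanded = expand_model(model, ops) if ops is not None and ops.order > 1 else model
    n_copies = len(expanded)
    if method == "auto":
        method = "direct" if n_copies <= direct_limit else "density"
    if method == "direct":
        coeffs = _calc_fc_direct(expanded, layout)
    elif method == "density":
        coeffs = _calc_fc_density(expanded, layout)
    else:
        raise ValueError(f"unknown method {method!r}")
    return layout.with_coeffs(coeffs)


def _warn_outside(model: AtomicModel, layout: FourierSet, margin: float = 3.0) -> None:
    import warnings

    cell = np.asarray(layout.cell, dtype=float)
    origin = np.asarray(layout.origin_shift, dtype=float)
    for a in model.atoms:
        rel = a.position - origin
        if np.any(rel < -margin) or np.any(rel > cell + margin):
            warnings.warn(
                f"atom {a.chain}/{a.resseq}/{a.name} at {a.position} lies more than "
                f"{margin} A outside the map box", stacklevel=3
            )


def _calc_fc_direct(model: AtomicModel, layout: FourierSet) -> np.ndarray:
    _warn_outside(model, layout)
    svec = layout.svec
    s_norm = layout.s_norm
    origin = np.asarray(layout.origin_shift, dtype=float)
    coeffs = np.zeros(len(layout), dtype=complex)
    # radial factors are shared between atoms of the same element
    radial_cache: dict[str, np.ndarray] = {}
    for atom in model.atoms:
        radial = radial_cache.get(atom.element)
        if radial is None:
            radial = _mott_bethe_radial(atom.element, s_norm)
            radial_cache[atom.element] = radial
        f = radial.astype(complex)
        if np.any(atom.nucleus_offset != 0):
            z = atom.z
            phase = 2j * np.pi * (svec @ atom.nucleus_offset)
            s2 = s_norm**2
            limit0 = -z * (2 * np.pi * np.linalg.norm(atom.nucleus_offset)) ** 2 / 6.0
            with np.errstate(invalid="ignore", divide="ignore"):
                dipole = np.where(
                    s2 > 0,
                    z * np.expm1(np.where(s2 > 0, phase, 0.0)) / np.where(s2 > 0, s2, 1.0),
                    limit0,
                )
            f = f + MOTT_BETHE_CONST * dipole
        dw = debye_waller(svec, atom.b_aniso if atom.b_aniso is not None else atom.b_iso)
        x = atom.position - origin
        coeffs += atom.occupancy * f * dw * np.exp(2j * np.pi * (svec @ x))
    return coeffs


_GL_NODES = 24


def _gaussian_decomposition(element: str, b_extra: float) -> tuple[np.ndarray, np.ndarray]:
    """Represent f_e(s) * exp(-B s^2/4) as a finite sum of Gaussians.

    Uses  (1 - e^{-b t}) / t = integral_0^b e^{-u t} du  (t = s^2/4) with
    Gauss-Legendre quadrature per table Gaussian, so the real-space density
    is an explicit Gaussian mixture.  Requires B > 0 for bounded widths.
    """
    a, b, _, _z = _it92(element)
    nodes, weights = np.polynomial.legendre.leggauss(_GL_NODES)
    amps, widths = [], []
    for aj, bj in zip(a, b):
        u = 0.5 * bj * (nodes + 1.0)  # map [-1,1] -> [0,b_j]
        w = 0.5 * bj * weights
        amps.append(MOTT_BETHE_CONST / 4.0 * aj * w)
        widths.append(u + b_extra)
    return np.concatenate(amps), np.concatenate(widths)


def _calc_fc_density(model: AtomicModel, layout: FourierSet) -> np.ndarray:
    """Sample the model's scattering density on the grid and FFT it.

    Used for large atom counts; agreement with the direct path is asserted
    in tests.  Atoms need isotropic B (anisotropic atoms fall back to their
    equivalent isotropic B here) and B > ~5 A^2 for accurate sampling.
    """
    from .grid import MapGrid, fft_map

    shape = layout.shape
    cell = np.asarray(layout.cell, dtype=float)
    voxel = cell / np.array(shape)
    origin = np.asarray(layout.origin_shift, dtype=float)
    density = np.zeros(shape)
    axes = [np.arange(n) * v for n, v in zip(shape, voxel)]
    for atom in model.atoms:
        biso = atom.b_iso if atom.b_aniso is None else float(np.trace(atom.b_aniso) / 3.0)
        if np.any(atom.nucleus_offset != 0):
            raise NotImplementedError("density path does not support shifted nuclei")
        amps, widths = _gaussian_decomposition(atom.element, biso)
        # f = A e^{-w s^2/4}  <->  rho(r) = A (4 pi / w)^{3/2} e^{-4 pi^2 r^2 / w}
        x = atom.position - origin
        # minimum-image separations per axis (periodic box)
        d2_axes = []
        for ax, c in zip(range(3), cell):
            d = axes[ax] - x[ax]
            d -= np.round(d / c) * c
            d2_axes.append(d * d)
        r2 = d2_axes[0][:, None, None] + d2_axes[1][None, :, None] + d2_axes[2][None, None, :]
        rho = np.zeros(shape)
        for A, w in zip(amps, widths):
            rho += A * (4 * np.pi / w) ** 1.5 * np.exp(-4 * np.pi**2 * r2 / w)
        density += atom.occupancy * rho
    grid = MapGrid(density, cell, origin)
    return fft_map(grid, layout.d_min).coeffs


# ---------------------------------------------------------------------------
# Model I/O (PDB / mmCIF via gemmi)

_ROTATABLE_PARENTS = {"OG", "OG1", "OH", "SG", "OD1", "OD2", "OE1", "OE2", "OXT"}
_U_TO_B = 8.0 * np.pi**2


def read_model(path: str | Path) -> AtomicModel:
    """Read a PDB or mmCIF model.  Element symbols come from the element
    column, or from atom names following PDB v3.3 rules when absent.
    Hydrogens bonded to hydroxyl/sulfhydryl/carboxyl groups are flagged as
    rotatable by parent-atom name."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    atoms: list[Atom] = []
    for mdl in st:
        for chain in mdl:
            for res in chain:
                names = {a.name for a in res}
                for ga in res:
                    el = ga.element.name if ga.element.name != "X" else ga.name.strip()[0]
                    b_aniso = None
                    if ga.aniso.nonzero():
                        u = ga.aniso
                        b_aniso = _U_TO_B * np.array(
                            [
                                [u.u11, u.u12, u.u13],
                                [u.u12, u.u22, u.u23],
                                [u.u13, u.u23, u.u33],
                            ]
                        )
                    rot = False
                    if ga.element.is_hydrogen:
                        rot = _looks_rotatable(ga.name, names)
                    atoms.append(
                        Atom(
                            element=el,
                            position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                            occupancy=ga.occ,
                            b_iso=ga.b_iso,
                            b_aniso=b_aniso,
                            is_rotatable_h=rot,
                            name=ga.name,
                            chain=chain.name,
                            resname=res.name,
                            resseq=res.seqid.num,
                        )
                    )
        break  # first model only
    return AtomicModel(atoms)


def _looks_rotatable(h_name: str, residue_atom_names: set[str]) -> bool:
    # HG of Ser (parent OG), HH of Tyr (OH), HG1 of Thr (OG1), HG of Cys (SG),
    # carboxyl protons (HD2/HE2 on Asp/Glu OD2/OE2), terminal HXT
    pairs = {
        "HG": {"OG", "SG"},
        "HG1": {"OG1"},
        "HH": {"OH"},
        "HD2": {"OD2"},
        "HE2": {"OE2"},
        "HXT": {"OXT"},
    }
    parents = pairs.get(h_name.strip())
    return bool(parents and parents & residue_atom_names)


def write_model(model: AtomicModel, path: str | Path, ops: SymOpSet | None = None) -> None:
    """Write a PDB (or mmCIF if the suffix is .cif) file; point-group
    operators are recorded as MTRIX / _struct_ncs_oper records."""
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(*(model.box if model.box is not None else (1, 1, 1)), 90, 90, 90)
    st.spacegroup_hm = "P 1"
    mdl = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for i, a in enumerate(model.atoms):
        ch = chains.get(a.chain)
        if ch is None:
            ch = gemmi.Chain(a.chain)
            chains[a.chain] = ch
        res = gemmi.Residue()
        res.name = a.resname
        res.seqid = gemmi.SeqId(a.resseq, " ")
        ga = gemmi.Atom()
        ga.name = a.name
        ga.element = gemmi.Element(a.element)
        ga.pos = gemmi.Position(*a.position)
        ga.occ = a.occupancy
        ga.b_iso = a.b_iso
        if a.b_aniso is not None:
            u = a.b_aniso / _U_TO_B
            ga.aniso = gemmi.SMat33f(u[0, 0], u[1, 1], u[2, 2], u[0, 1], u[0, 2], u[1, 2])
        res.add_atom(ga)
        ch.add_residue(res)
    for ch in chains.values():
        mdl.add_chain(ch)
    st.add_model(mdl)
    if ops is not None:
        for j, op in enumerate(ops):
            if op.is_identity():
                continue
            tr = gemmi.Transform()
            tr.mat.fromlist(op.R.tolist())
            tr.vec.fromlist(op.t.tolist())
            st.ncs.append(gemmi.NcsOp(tr, str(j + 1), False))
    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))
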