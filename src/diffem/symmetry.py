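"""Point-group operators, model expansion and special-position handling.

SPA reconstructions are symmetrized with a rotational point group (Cn, Dn,
T, O or I) whose origin is taken to be the centre of the box; each operator
is then ``x -> R x + t`` with ``t = (I - R) c``.  Axis conventions used
here (documented because reconstruction packages vary):

* Cn: rotation axis along +z.
* Dn: Cn plus a 2-fold along +x.
* T: 2-folds along the coordinate axes, 3-folds along the body diagonals.
* O: 4-folds along the coordinate axes.
* I: a 5-fold along +z, with an adjacent 5-fold axis in the xz plane
  (2-fold generator at polar angle arctan(2)/2 from z).

Groups are generated from generators by closure, so the group axioms hold
by construction and are verified by tests.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SymOp",
    "SymOpSet",
    "SpecialPosition",
    "operators_from_symbol",
    "expand_model",
    "find_special_positions",
    "project_special",
    "special_restraint_residuals",
]

_TOL = 1e-8


@dataclass
class SymOp:
    """A rotation/translation pair ``x -> R x + t`` (Cartesian, Angstrom)."""

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if np.abs(self.R @ self.R.T - np.eye(3)).max() > 1e-6:
            raise ValueError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(self.R) - 1.0) > 1e-6:
            raise ValueError("rotation matrix must be proper (det +1)")

    def apply(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x) @ self.R.T + self.t

    def is_identity(self, tol: float = _TOL) -> bool:
        return np.abs(self.R - np.eye(3)).max() < tol and np.abs(self.t).max() < tol


@dataclass
class SymOpSet:
    """A point group: operators (identity first), symbol and origin."""

    ops: list[SymOp]
    symbol: str
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)

    def __len__(self) -> int:
        return len(self.ops)

    def __iter__(self):
        return iter(self.ops)

    @property
    def order(self) -> int:
        return len(self.ops)

    def rotations(self) -> np.ndarray:
        return np.stack([op.R for op in self.ops])

    def recenter(self, center: np.ndarray) -> "SymOpSet":
        """Same rotations with translations recomputed for a new origin."""
        return _ops_with_center(self.rotations(), self.symbol, np.asarray(center, dtype=float))

    def shifted(self, shift: np.ndarray) -> "SymOpSet":
        """Operators for coordinates shifted by ``x' = x - shift``.

        ``t' = t + (R - I) shift`` keeps the absolute-frame images of every
        atom unchanged, which is what box trimming needs.
        """
        shift = np.asarray(shift, dtype=float)
        ops = [SymOp(op.R, op.t + (op.R - np.eye(3)) @ shift) for op in self.ops]
        return SymOpSet(ops, self.symbol, self.center - shift)

    def is_closed(self, tol: float = _TOL) -> bool:
        Rs = self.rotations()
        for a in self.ops:
            for b in self.ops:
                prod = a.R @ b.R
                if not any(np.abs(prod - R).max() < tol for R in Rs):
                    return False
        return True


@dataclass
class SpecialPosition:
    """An atom (by index) whose site is invariant under a subgroup."""

    atom_index: int
    subgroup: SymOpSet
    multiplicity: int
    adjusted_occupancy: float


def _rot_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)


def _close_group(generators: list[np.ndarray], max_order: int = 120) -> list[np.ndarray]:
    ops = [np.eye(3)]
    frontier = [np.eye(3)]

    def seen(R: np.ndarray) -> bool:
        return any(np.abs(R - S).max() < 1e-6 for S in ops)

    while frontier:
        new: list[np.ndarray] = []
        for A in frontier:
            for G in generators:
                P = G @ A
                if not seen(P):
                    ops.append(P)
                    new.append(P)
        frontier = new
        if len(ops) > max_order:
            raise RuntimeError("group closure did not terminate; bad generators")
    return ops


def _group_rotations(symbol: str) -> list[np.ndarray]:
    m = re.fullmatch(r"[Cc](\d+)", symbol)
    if m:
        n = int(m.group(1))
        if n < 1:
            raise ValueError("Cn requires n >= 1")
        return [_rot_axis([0, 0, 1], 2 * np.pi * j / n) for j in range(n)]
    m = re.fullmatch(r"[Dd](\d+)", symbol)
    if m:
        n = int(m.group(1))
        if n < 1:
            raise ValueError("Dn requires n >= 1")
        cn = [_rot_axis([0, 0, 1], 2 * np.pi * j / n) for j in range(n)]
        flip = _rot_axis([1, 0, 0], np.pi)
        return cn + [flip @ R for R in cn]
    if symbol.upper() == "T":
        return _close_group(
            [_rot_axis([0, 0, 1], np.pi), _rot_axis([1, 1, 1], 2 * np.pi / 3)]
        )
    if symbol.upper() == "O":
        return _close_group(
            [_rot_axis([0, 0, 1], np.pi / 2), _rot_axis([1, 1, 1], 2 * np.pi / 3)]
        )
    if symbol.upper() == "I":
        alpha = np.arctan(2.0)  # angle between adjacent 5-fold axes
        two_fold_axis = np.array([np.sin(alpha / 2), 0.0, np.cos(alpha / 2)])
        return _close_group(
            [_rot_axis([0, 0, 1], 2 * np.pi / 5), _rot_axis(two_fold_axis, np.pi)]
        )
    raise ValueError(
        f"unknown point-group symbol {symbol!r}; accepted forms: Cn, Dn, T, O, I"
    )


def _ops_with_center(rotations: np.ndarray, symbol: str, center: np.ndarray) -> SymOpSet:
    eye = np.eye(3)
    ops = [SymOp(R, (eye - R) @ center) for R in rotations]
    # identity first
    ops.sort(key=lambda op: 0 if np.abs(op.R - eye).max() < _TOL else 1)
    return SymOpSet(ops, symbol, center)


def operators_from_symbol(symbol: str, center: np.ndarray | None = None) -> SymOpSet:
    """Build the point group named ``symbol`` about origin ``center``.

    Translations are ``t_j = (I - R_j) c`` so that ``c`` is a fixed point of
    every operator.
    """
    if center is None:
        center = np.zeros(3)
    rotations = np.stack(_group_rotations(symbol))
    return _ops_with_center(rotations, symbol, np.asarray(center, dtype=float))


# ---------------------------------------------------------------------------
# Model expansion and special positions


def expand_model(model, ops: SymOpSet, adjust_special: bool = True, epsilon: float = 0.25):
    """Apply every operator to every atom, returning the expanded model.

    Anisotropic ADP tensors transform as ``B' = R B R^T``; isotropic B is
    rotation invariant.  Chain labels are suffixed with the operator index.
    Atoms on special positions (within ``epsilon``) are emitted once per
    coset with occupancy divided by the stabilizer order when
    ``adjust_special`` is set, so total scattering power is conserved.
    """
    from .model import AtomicModel

    specials = {sp.atom_index: sp for sp in find_special_positions(model, ops, epsilon)} if adjust_special else {}
    new_atoms = []
    for i, atom in enumerate(model.atoms):
        sp = specials.get(i)
        occ = atom.occupancy / sp.subgroup.order if sp else atom.occupancy
        for j, op in enumerate(ops):
            a = atom.copy()
            a.position = op.apply(atom.position)
            if atom.b_aniso is not None:
                a.b_aniso = op.R @ atom.b_aniso @ op.R.T
            a.occupancy = occ
            a.chain = f"{atom.chain}{j}" if j > 0 else atom.chain
            new_atoms.append(a)
    return AtomicModel(new_atoms, box=getattr(model, "box", None))


def find_special_positions(model, ops: SymOpSet, epsilon: float = 0.25) -> list[SpecialPosition]:
    """Atoms whose image under some non-identity operator is within
    ``epsilon`` Angstrom of the original site.

    The stabilizing operators must form a subgroup of the point group;
    a stabilizer that is not closed raises an inconsistent-geometry error.
    Occupancy is adjusted by the stabilizer order, multiplicity is
    ``|G| / |stabilizer|``.
    """
    out: list[SpecialPosition] = []
    for i, atom in enumerate(model.atoms):
        stab = [op for op in ops if np.linalg.norm(atom.position - op.apply(atom.position)) < epsilon]
        if len(stab) <= 1:
            continue
        sub = SymOpSet(stab, ops.symbol + ":site", ops.center)
        if not sub.is_closed(tol=1e-6):
            raise ValueError(
                f"stabilizer of atom {i} ({getattr(atom, 'name', '?')}) is not closed "
                f"within epsilon={epsilon}; inconsistent geometry"
            )
        if ops.order % len(stab) != 0:
            raise ValueError(f"stabilizer order {len(stab)} does not divide group order {ops.order}")
        out.append(
            SpecialPosition(
                atom_index=i,
                subgroup=sub,
                multiplicity=ops.order // len(stab),
                adjusted_occupancy=atom.occupancy / len(stab),
            )
        )
    return out


def project_special(atom, subgroup: SymOpSet):
    """Snap an atom exactly onto its special position.

    Coordinates are replaced by the subgroup average of the orbit and the
    anisotropic tensor by the average of its rotations; the projection is
    idempotent and afterwards both restraint residuals vanish.
    """
    a = atom.copy()
    a.position = np.mean([op.apply(atom.position) for op in subgroup], axis=0)
    if atom.b_aniso is not None:
        a.b_aniso = np.mean([op.R @ atom.b_aniso @ op.R.T for op in subgroup], axis=0)
    return a


def special_restraint_residuals(
    atom, subgroup: SymOpSet, sigma_x: float = 0.01, sigma_b: float = 0.5
) -> tuple[float, float]:
    """Weighted residuals keeping an atom on its special position.

    Positional term ``sum_j |x - (R_j x + t_j)|^2 / sigma_x^2`` and ADP term
    ``sum_j ||B - R_j B R_j^T||_F^2 / sigma_b^2`` (Frobenius distance); both
    are zero for a projected atom.  ``sigma_x`` (Angstrom) and ``sigma_b``
    (Angstrom^2) are user-controllable weights.
    """
    if sigma_x <= 0 or sigma_b <= 0:
        raise ValueError("sigma_x and sigma_b must be positive")
    pos = sum(
        float(np.sum((atom.position - op.apply(atom.position)) ** 2)) for op in subgroup
    ) / sigma_x**2
    adp = 0.0
    if atom.b_aniso is not None:
        for op in subgroup:
            d = atom.b_aniso - op.R @ atom.b_aniso @ op.R.T
            adp += float(np.sum(d * d))
        adp /= sigma_b**2
    return pos, adp
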