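"""Rigid-body superposition and residue-range backbone RMSD.

Atom pairing is by order within the filtered selection — the two
conformations are assumed to be models of the identical sequence, so no
alignment step is needed.  Superposition uses the Kabsch algorithm
(least-squares optimal proper rotation via SVD, with the standard
determinant correction that forbids reflections).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

__all__ = [
    "Atom",
    "CoordinateSet",
    "SuperpositionResult",
    "read_coordinates",
    "kabsch_superpose",
    "range_rmsd",
    "ATOM_SELECTIONS",
]

ATOM_SELECTIONS = {
    "CA": frozenset({"CA"}),
    "backbone": frozenset({"N", "CA", "C", "O"}),
    "all": None,
}


@dataclass(frozen=True)
class Atom:
    res_num: int
    atom_name: str
    x: float
    y: float
    z: float

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class CoordinateSet:
    """An ordered list of atoms (1-based residue numbers, Å coordinates)."""

    atoms: tuple[Atom, ...]
    chain: Optional[str] = None
    source: str = "unknown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple(self.atoms))
        coords = self.coords
        if coords.size and not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.empty((0, 3))
        return np.array([[a.x, a.y, a.z] for a in self.atoms])

    @property
    def residue_numbers(self) -> np.ndarray:
        return np.array([a.res_num for a in self.atoms], dtype=int)

    def select_range(self, start: int, end: int) -> "CoordinateSet":
        """Atoms whose residue number lies in [start, end] (1-based inclusive)."""
        kept = tuple(a for a in self.atoms if start <= a.res_num <= end)
        if not kept:
            raise ValueError(
                f"residue range {start}-{end} not covered by {self.source}"
            )
        return CoordinateSet(atoms=kept, chain=self.chain, source=self.source)


@dataclass(frozen=True)
class SuperpositionResult:
    """A proper rigid-body fit: x ↦ rotation·x + translation, with its RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def read_coordinates(
    path: Union[str, Path],
    chain: Optional[str] = None,
    atom_selection: str = "backbone",
) -> CoordinateSet:
    """Read ATOM records from a PDB file, filtered by chain and selection.

    HETATM records and altlocs other than blank/'A' are skipped; order is
    preserved.  Raises ValueError if nothing survives the filter.
    """
    import gemmi

    if atom_selection not in ATOM_SELECTIONS:
        raise ValueError(
            f"unknown selection {atom_selection!r}; expected one of "
            f"{sorted(ATOM_SELECTIONS)}"
        )
    allowed = ATOM_SELECTIONS[atom_selection]
    st = gemmi.read_pdb(str(path))
    atoms: list[Atom] = []
    for model in st:
        for ch in model:
            if chain is not None and ch.name != chain:
                continue
            for res in ch:
                if res.het_flag != "A":  # HETATM
                    continue
                for atom in res:
                    if atom.altloc not in ("", "\0", "A"):
                        continue
                    if allowed is not None and atom.name not in allowed:
                        continue
                    atoms.append(
                        Atom(
                            res_num=res.seqid.num,
                            atom_name=atom.name,
                            x=atom.pos.x,
                            y=atom.pos.y,
                            z=atom.pos.z,
                        )
                    )
        break  # first model only
    if not atoms:
        raise ValueError(
            f"{path}: no atoms left after filtering "
            f"(chain={chain!r}, selection={atom_selection!r})"
        )
    return CoordinateSet(atoms=tuple(atoms), chain=chain, source=str(path))


def kabsch_superpose(
    mobile: CoordinateSet, target: CoordinateSet
) -> SuperpositionResult:
    """Least-squares optimal proper rotation + translation of mobile onto target.

    Requires equal atom counts (≥ 3) in corresponding order.  Degenerate
    (collinear) point sets produce a warning; the result remains a
    least-squares optimum.
    """
    P = mobile.coords
    Q = target.coords
    if len(P) != len(Q):
        raise ValueError(
            f"atom count mismatch: mobile has {len(P)}, target has {len(Q)}"
        )
    if len(P) < 3:
        raise ValueError("superposition needs at least 3 atom pairs")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-8 * max(S[0], 1.0):
        warnings.warn("degenerate (collinear) coordinates in superposition",
                      stacklevel=2)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])  # reflection guard
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=len(P))


def _plain_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def range_rmsd(
    a: CoordinateSet,
    b: CoordinateSet,
    residue_range: tuple[int, int],
    superpose_on: str = "range",
) -> float:
    """Backbone RMSD (Å) over a residue range, with selectable superposition.

    ``superpose_on`` is ``"range"`` (fit on the range itself), ``"whole"``
    (fit on all atoms, measure on the range) or ``"none"`` (no fit — compare
    coordinates as given).
    """
    if superpose_on not in ("range", "whole", "none"):
        raise ValueError("superpose_on must be 'range', 'whole' or 'none'")
    start, end = residue_range
    a_rng = a.select_range(start, end)
    b_rng = b.select_range(start, end)
    if len(a_rng) != len(b_rng):
        raise ValueError(
            f"range {start}-{end}: atom count mismatch ({len(a_rng)} vs {len(b_rng)})"
        )
    if superpose_on == "none":
        return _plain_rmsd(a_rng.coords, b_rng.coords)
    if superpose_on == "range":
        return kabsch_superpose(a_rng, b_rng).rmsd
    if len(a) != len(b):
        raise ValueError("whole-structure superposition needs equal atom counts")
    fit = kabsch_superpose(a, b)
    return _plain_rmsd(fit.transform(a_rng.coords), b_rng.coords)
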