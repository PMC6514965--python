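"""In-memory molecular model: atoms and the rigid capsomer they form.

A capsomer (the trimeric building block of a giant-virus capsid) is treated as
a rigid collection of point charges with radii.  Internally the model is a
struct-of-arrays for fast vectorised electrostatics; :class:`Atom` objects are
lightweight per-atom views used for construction and inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .errors import GeometryError


@dataclass
class Atom:
    """One atom: identity, position (A), charge (e), radius (A), mass (Da)."""

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_seq: int
    position: np.ndarray
    charge: float = 0.0
    radius: float = 0.0
    mass: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("atom position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")


class CapsomerModel:
    """A rigid body of atoms with charges, radii and masses.

    Parameters are parallel per-atom arrays.  ``charges`` may be ``None`` to
    mean "not assigned yet" (PDB input before a charge scheme is applied);
    operations that need charges raise in that case.
    """

    def __init__(
        self,
        positions: np.ndarray,
        *,
        serials: Optional[Sequence[int]] = None,
        names: Optional[Sequence[str]] = None,
        residue_names: Optional[Sequence[str]] = None,
        chain_ids: Optional[Sequence[str]] = None,
        residue_seqs: Optional[Sequence[int]] = None,
        charges: Optional[np.ndarray] = None,
        radii: Optional[np.ndarray] = None,
        masses: Optional[np.ndarray] = None,
        label: str = "",
    ) -> None:
        pos = np.asarray(positions, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        n = len(pos)
        self.positions = pos
        self.serials = np.asarray(serials if serials is not None else np.arange(1, n + 1), dtype=int)
        self.names = np.asarray(names if names is not None else ["X"] * n, dtype=object)
        self.residue_names = np.asarray(
            residue_names if residue_names is not None else ["UNK"] * n, dtype=object
        )
        self.chain_ids = np.asarray(chain_ids if chain_ids is not None else ["A"] * n, dtype=object)
        self.residue_seqs = np.asarray(
            residue_seqs if residue_seqs is not None else np.ones(n, dtype=int), dtype=int
        )
        self.charges = None if charges is None else np.asarray(charges, dtype=float)
        self.radii = None if radii is None else np.asarray(radii, dtype=float)
        self.masses = np.asarray(masses if masses is not None else np.ones(n), dtype=float)
        self.label = label
        for arr in (self.serials, self.names, self.residue_names, self.chain_ids,
                    self.residue_seqs, self.masses):
            if len(arr) != n:
                raise ValueError("per-atom arrays must all have the same length")
        for arr in (self.charges, self.radii):
            if arr is not None and len(arr) != n:
                raise ValueError("per-atom arrays must all have the same length")
        if self.radii is not None and len(self.radii) and np.any(self.radii <= 0):
            raise ValueError("radii must be > 0 when set")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_atoms(cls, atoms: Iterable[Atom], label: str = "") -> "CapsomerModel":
        atoms = list(atoms)
        if not atoms:
            return cls(np.empty((0, 3)), charges=np.empty(0), radii=None, label=label)
        radii = np.array([a.radius for a in atoms], dtype=float)
        return cls(
            np.array([a.position for a in atoms]),
            serials=[a.serial for a in atoms],
            names=[a.name for a in atoms],
            residue_names=[a.residue_name for a in atoms],
            chain_ids=[a.chain_id for a in atoms],
            residue_seqs=[a.residue_seq for a in atoms],
            charges=np.array([a.charge for a in atoms], dtype=float),
            radii=radii if np.all(radii > 0) else None,
            masses=np.array([a.mass for a in atoms], dtype=float),
            label=label,
        )

    # -- views -------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def __len__(self) -> int:
        return self.n_atoms

    @property
    def atoms(self) -> Iterator[Atom]:
        """Iterate over per-atom views (copies; mutating them does not write back)."""
        for i in range(self.n_atoms):
            yield Atom(
                serial=int(self.serials[i]),
                name=str(self.names[i]),
                residue_name=str(self.residue_names[i]),
                chain_id=str(self.chain_ids[i]),
                residue_seq=int(self.residue_seqs[i]),
                position=self.positions[i].copy(),
                charge=0.0 if self.charges is None else float(self.charges[i]),
                radius=0.0 if self.radii is None else float(self.radii[i]),
                mass=float(self.masses[i]),
            )

    @property
    def center_of_mass(self) -> np.ndarray:
        """Mass-weighted mean position (A)."""
        if self.n_atoms == 0:
            raise GeometryError("center of mass of an empty model is undefined")
        total = self.masses.sum()
        if total <= 0:
            raise GeometryError("total mass is zero")
        return (self.masses[:, None] * self.positions).sum(axis=0) / total

    def copy(self) -> "CapsomerModel":
        return CapsomerModel(
            self.positions.copy(),
            serials=self.serials.copy(),
            names=self.names.copy(),
            residue_names=self.residue_names.copy(),
            chain_ids=self.chain_ids.copy(),
            residue_seqs=self.residue_seqs.copy(),
            charges=None if self.charges is None else self.charges.copy(),
            radii=None if self.radii is None else self.radii.copy(),
            masses=self.masses.copy(),
            label=self.label,
        )

    def with_positions(self, positions: np.ndarray) -> "CapsomerModel":
        """Copy of this model with replaced coordinates (same identity arrays)."""
        out = self.copy()
        pos = np.asarray(positions, dtype=float).reshape(-1, 3)
        if len(pos) != self.n_atoms:
            raise ValueError("position array length mismatch")
        out.positions = pos
        return out

    def translated(self, shift: np.ndarray) -> "CapsomerModel":
        return self.with_positions(self.positions + np.asarray(shift, dtype=float))
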