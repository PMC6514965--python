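"""Structure IO and rigid-body descriptors.

Reads and writes PDB (via gemmi) and PQR (read via MDAnalysis, written with a
plain formatter), assigns formal charges at pH 7, and computes the descriptors
used by the pose-scanning machinery: mass-weighted center of mass and the
pseudo-three-fold axis of the donut-shaped capsomer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .errors import GeometryError, PDBParseError, PQRParseError
from .model import CapsomerModel

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: Default radius (A) assigned to atoms read from radius-less formats (PDB).
DEFAULT_RADIUS = 1.7

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Representative side-chain atom carrying the formal charge of each
#: titratable residue (heavy-atom models; no hydrogens are added).
_CHARGE_SITES = {"ASP": ("CG", -1.0), "GLU": ("CD", -1.0),
                 "LYS": ("NZ", +1.0), "ARG": ("CZ", +1.0)}


@dataclass
class ChargeScheme:
    """How to put charges on a model.

    ``formal_ph7`` places integer formal charges at pH 7 (Asp/Glu -1,
    Lys/Arg +1, His per ``histidine_state``, +-1 on free termini when
    ``include_termini``).  ``pqr_passthrough`` keeps whatever charges the
    input PQR carried.
    """

    mode: str = "formal_ph7"
    histidine_state: str = "neutral"
    include_termini: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("formal_ph7", "pqr_passthrough"):
            raise ValueError(f"unknown charge scheme mode {self.mode!r}")
        if self.histidine_state not in ("neutral", "protonated"):
            raise ValueError(f"unknown histidine state {self.histidine_state!r}")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _validate_pdb_records(path: Path) -> None:
    """Raise PDBParseError naming the offending line for broken ATOM records.

    gemmi is deliberately lenient about malformed coordinate fields, so the
    numeric columns are checked up front.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"{path}: line {lineno}: truncated ATOM/HETATM record")
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PDBParseError(
                        f"{path}: line {lineno}: unparseable {what} coordinate "
                        f"{line[lo:hi]!r}"
                    ) from None


def read_pdb(path: PathLike, model_index: int = 0, *,
             element_masses: bool = False, label: str = "") -> CapsomerModel:
    """Read one model of a PDB file into a :class:`CapsomerModel`.

    Parameters
    ----------
    model_index
        0-based index into the MODEL records (a single-model file has index 0).
    element_masses
        When True, use element masses (Da); default is unit mass per atom, so
        the center of mass is the geometric center.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_records(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if not (0 <= model_index < len(st)):
        raise IndexError(
            f"model_index {model_index} out of range: {path} has {len(st)} model(s)"
        )
    gm = st[model_index]
    serials, names, resnames, chains, resseqs, pos, masses = [], [], [], [], [], [], []
    for chain in gm:
        for res in chain:
            for atom in res:
                serials.append(atom.serial)
                names.append(atom.name)
                resnames.append(res.name)
                chains.append(chain.name)
                resseqs.append(res.seqid.num)
                pos.append([atom.pos.x, atom.pos.y, atom.pos.z])
                w = atom.element.weight if element_masses else 1.0
                masses.append(w if w and w > 0 else 1.0)
    n = len(pos)
    return CapsomerModel(
        np.array(pos, dtype=float).reshape(n, 3),
        serials=serials, names=names, residue_names=resnames,
        chain_ids=chains, residue_seqs=resseqs,
        charges=None, radii=np.full(n, DEFAULT_RADIUS), masses=masses,
        label=label or path.stem,
    )


def write_pdb(model: CapsomerModel, path: PathLike) -> None:
    """Write the model as a single-model PDB file (coordinates to 1e-3 A)."""
    import gemmi

    st = gemmi.Structure()
    st.name = model.label or "capscan"
    gm = gemmi.Model("1")
    chain_objs: dict[str, gemmi.Chain] = {}
    res_keys: dict[tuple, gemmi.Residue] = {}
    for a in model.atoms:
        cid = a.chain_id or "A"
        if cid not in chain_objs:
            chain_objs[cid] = gemmi.Chain(cid)
        key = (cid, a.residue_seq, a.residue_name)
        if key not in res_keys:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_seq, " ")
            chain_objs[cid].add_residue(res)
            res_keys[key] = chain_objs[cid][-1]
        atom = gemmi.Atom()
        atom.name = a.name
        atom.serial = a.serial
        atom.pos = gemmi.Position(*a.position)
        atom.occ = 1.0
        atom.b_iso = 0.0
        res_keys[key].add_atom(atom)
    for chain in chain_objs.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# PQR
# ---------------------------------------------------------------------------

def read_pqr(path: PathLike, *, label: str = "") -> CapsomerModel:
    """Read a whitespace-delimited PQR file (charge and radius after xyz)."""
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
            ag = u.atoms
            charges = np.asarray(ag.charges, dtype=float)
            radii = np.asarray(ag.radii, dtype=float)
        except Exception as exc:
            raise PQRParseError(f"{path}: not a valid PQR file: {exc}") from exc
        try:
            chains = [str(c) for c in ag.chainIDs]
        except Exception:
            try:
                chains = [str(s) for s in ag.segids]
            except Exception:
                chains = ["A"] * len(ag)
    chains = [c if c and c != "SYSTEM" else "A" for c in chains]
    return CapsomerModel(
        np.asarray(ag.positions, dtype=float),
        serials=[int(s) for s in ag.ids],
        names=[str(x) for x in ag.names],
        residue_names=[str(x) for x in ag.resnames],
        chain_ids=chains,
        residue_seqs=[int(x) for x in ag.resids],
        charges=charges,
        radii=radii,
        masses=np.ones(len(ag)),
        label=label or path.stem,
    )


def write_pqr(model: CapsomerModel, path: PathLike) -> None:
    """Write a PQR file; charges/radii printed to 4 decimals.

    Refuses models without assigned charges or radii.
    """
    if model.charges is None:
        raise ValueError(
            "model has no charges assigned; run assign_charges() or read a PQR first"
        )
    if model.radii is None:
        raise ValueError("model has no radii assigned; cannot write PQR")
    with open(path, "w") as fh:
        fh.write("REMARK   1 PQR written by capscan\n")
        for a in model.atoms:
            fh.write(
                f"ATOM  {a.serial:5d} {a.name:<4s} {a.residue_name:<4s}"
                f"{(a.chain_id or 'A')[:1]} {a.residue_seq:4d}    "
                f"{a.position[0]:8.3f} {a.position[1]:8.3f} {a.position[2]:8.3f} "
                f"{a.charge:8.4f} {a.radius:7.4f}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Charges
# ---------------------------------------------------------------------------

def assign_charges(model: CapsomerModel, scheme: ChargeScheme | None = None) -> CapsomerModel:
    """Return a copy of the model with formal charges placed per the scheme.

    Charges are placed on a single representative side-chain heavy atom per
    titratable residue (CG for Asp, CD for Glu, NZ for Lys, CZ for Arg, NE2
    for protonated His); free termini get +-1 on N / OXT (falling back to C)
    when the scheme includes them.  Unknown residue names get charge 0 with a
    logged warning.  Idempotent: charges are recomputed from scratch.
    """
    scheme = scheme or ChargeScheme()
    out = model.copy()
    if scheme.mode == "pqr_passthrough":
        if out.charges is None:
            raise ValueError("pqr_passthrough scheme requires charges already present")
        return out
    n = out.n_atoms
    charges = np.zeros(n)
    if n == 0:
        out.charges = charges
        return out

    # group atom indices by residue, preserving file order
    res_order: list[tuple] = []
    res_atoms: dict[tuple, list[int]] = {}
    for i in range(n):
        key = (str(out.chain_ids[i]), int(out.residue_seqs[i]), str(out.residue_names[i]))
        if key not in res_atoms:
            res_atoms[key] = []
            res_order.append(key)
        res_atoms[key].append(i)

    warned: set[str] = set()

    def _place(idx_list: list[int], atom_name: str, q: float, fallback_last: bool = False) -> None:
        names = [str(out.names[i]) for i in idx_list]
        if atom_name in names:
            charges[idx_list[names.index(atom_name)]] += q
        else:
            charges[idx_list[-1 if fallback_last else 0]] += q

    for (chain, seq, resname), idx in res_atoms.items():
        if resname not in STANDARD_AA:
            if resname not in warned:
                log.warning("unknown residue %s: assigned charge 0", resname)
                warned.add(resname)
            continue
        if resname in _CHARGE_SITES:
            atom_name, q = _CHARGE_SITES[resname]
            _place(idx, atom_name, q)
        elif resname == "HIS" and scheme.histidine_state == "protonated":
            _place(idx, "NE2", +1.0)

    if scheme.include_termini:
        # first/last residue of each chain, in file order
        by_chain: dict[str, list[tuple]] = {}
        for key in res_order:
            by_chain.setdefault(key[0], []).append(key)
        for chain, keys in by_chain.items():
            first, last = keys[0], keys[-1]
            if first[2] in STANDARD_AA:
                _place(res_atoms[first], "N", +1.0)
            if last[2] in STANDARD_AA:
                idx = res_atoms[last]
                names = [str(out.names[i]) for i in idx]
                if "OXT" in names:
                    charges[idx[names.index("OXT")]] += -1.0
                else:
                    _place(idx, "C", -1.0, fallback_last=True)

    out.charges = charges
    return out


def net_charge(model: CapsomerModel) -> float:
    """Sum of atom charges (e).  Empty model -> 0."""
    if model.n_atoms == 0:
        return 0.0
    if model.charges is None:
        raise ValueError("model has no charges assigned")
    return float(model.charges.sum())


# ---------------------------------------------------------------------------
# Rigid-body descriptors
# ---------------------------------------------------------------------------

def center_of_mass(model: CapsomerModel) -> np.ndarray:
    """Mass-weighted mean position (A); default masses are unit."""
    return model.center_of_mass


def principal_c3_axis(model: CapsomerModel) -> np.ndarray:
    """Pseudo-three-fold axis of an oblate (donut-shaped) capsomer.

    Returns the gyration-tensor eigenvector whose eigenvalue is most separated
    from the other two -- for a flat disc this is the small (thickness)
    eigenvalue, whose eigenvector is the symmetry axis.  The sign is fixed so
    the first non-negligible component of (z, x, y) is positive.
    """
    if model.n_atoms < 3:
        raise GeometryError("need at least 3 atoms to define an axis")
    com = model.center_of_mass
    d = model.positions - com
    w = model.masses / model.masses.sum()
    gyr = (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0)
    evals, evecs = np.linalg.eigh(gyr)  # ascending
    scale = float(np.max(np.abs(evals))) or 1.0
    # distinctness: distance of each eigenvalue to its nearest neighbour
    gaps = np.array([
        min(abs(evals[i] - evals[j]) for j in range(3) if j != i) for i in range(3)
    ])
    if np.max(gaps) < 1e-9 * scale:
        raise GeometryError(
            "gyration tensor is degenerate (near-spherical model); "
            "supply the symmetry axis explicitly"
        )
    axis = evecs[:, int(np.argmax(gaps))]
    z, x, y = axis[2], axis[0], axis[1]
    if abs(z) > 1e-9:
        sign = np.sign(z)
    elif abs(x) > 1e-9:
        sign = np.sign(x)
    else:
        sign = np.sign(y) or 1.0
    return axis * sign
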