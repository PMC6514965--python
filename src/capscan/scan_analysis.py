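"""Analysis of force scans and frame ensembles.

Turns raw :class:`~capscan.electrostatics.ForceRecord` series into binding
funnels and effective interaction ranges, extracts inter-capsomer salt
bridges and their formation statistics from frame ensembles, and provides a
single-snapshot MM/PBSA-style binding-energy decomposition (molecular
mechanics Coulomb + Lennard-Jones cross terms, generalized-Born-style polar
solvation, surface-area nonpolar solvation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .constants import COULOMB_KCAL
from .electrostatics import ElectrostaticParams, ForceRecord
from .model import CapsomerModel

#: Heavy-atom salt-bridge partners: acidic side-chain/terminal oxygens vs
#: basic side-chain nitrogens.
ACIDIC_ATOMS = frozenset({"OD1", "OD2", "OE1", "OE2", "OXT"})
BASIC_ATOMS = frozenset({"NZ", "NH1", "NH2", "NE", "ND1", "NE2"})

SALT_BRIDGE_CUTOFF = 4.0  # A, heavy-atom


# ---------------------------------------------------------------------------
# Funnels
# ---------------------------------------------------------------------------

@dataclass
class Funnel:
    """A contiguous same-signed stretch of a force scan around its extremum."""

    operation: str
    lo: float
    hi: float
    extremum_param: float
    extremum_value: float
    sign: str  # "attractive" | "repulsive"

    def contains(self, param: float) -> bool:
        return self.lo <= param <= self.hi


def detect_funnel(records: Sequence[ForceRecord], native_param: float,
                  operation: str = "") -> Funnel:
    """Locate the binding funnel of a scan.

    The funnel is the maximal contiguous run of records sharing the sign of
    the dominant extremum of the axial projection; ties between equally strong
    extrema break toward the one nearest the native parameter, then toward the
    smaller parameter.  Raises on an all-zero scan.
    """
    if len(records) == 0:
        raise ValueError("no records")
    params = np.array([r.scan_param for r in records])
    if np.any(np.diff(params) <= 0):
        raise ValueError("records must be sorted by strictly increasing scan_param")
    ax = np.array([r.axial_projection for r in records])
    amax = np.abs(ax).max()
    if amax == 0:
        raise ValueError("no funnel: all axial projections are zero")
    cand = np.flatnonzero(np.abs(ax) >= amax * (1 - 1e-12))
    order = sorted(cand, key=lambda i: (abs(params[i] - native_param), params[i]))
    peak = order[0]
    sign = np.sign(ax[peak])
    lo = peak
    while lo > 0 and np.sign(ax[lo - 1]) == sign:
        lo -= 1
    hi = peak
    while hi < len(ax) - 1 and np.sign(ax[hi + 1]) == sign:
        hi += 1
    return Funnel(
        operation=operation,
        lo=float(params[lo]),
        hi=float(params[hi]),
        extremum_param=float(params[peak]),
        extremum_value=float(ax[peak]),
        sign="attractive" if sign > 0 else "repulsive",
    )


def effective_range(records: Sequence[ForceRecord],
                    magnitude_floor: float = 1e-3,
                    coherence_floor: float = 0.5) -> float:
    """Largest scan distance up to which the force stays strong and aimed.

    Returns the largest scan parameter such that every record at or below it
    has magnitude >= ``magnitude_floor`` and axial coherence
    (axial_projection / magnitude) >= ``coherence_floor``.  Beyond this range
    force directions are considered incoherent.  If even the first record
    fails, the start of the range is returned with a warning.
    """
    if len(records) == 0:
        raise ValueError("no records")
    params = [r.scan_param for r in records]
    best = None
    for r in records:
        ok = (r.magnitude >= magnitude_floor
              and r.magnitude > 0
              and r.axial_projection / r.magnitude >= coherence_floor)
        if not ok:
            break
        best = r.scan_param
    if best is None:
        warnings.warn("no record meets the effective-range floors; "
                      "returning the start of the scan range")
        return float(params[0])
    return float(best)


# ---------------------------------------------------------------------------
# Salt bridges
# ---------------------------------------------------------------------------

ResidueKey = Tuple[str, int, str]  # (chain, residue_seq, residue_name)


@dataclass
class SaltBridge:
    """One acidic/basic residue pair within the cutoff (minimum atom distance)."""

    acidic: Tuple[str, int, str, str]   # chain, resseq, resname, atom
    basic: Tuple[str, int, str, str]
    distance: float

    @property
    def residue_pair(self) -> Tuple[ResidueKey, ResidueKey]:
        return (self.acidic[:3], self.basic[:3])


def _atom_subset(model: CapsomerModel, wanted: frozenset) -> np.ndarray:
    return np.array(
        [i for i in range(model.n_atoms) if str(model.names[i]) in wanted], dtype=int
    )


def find_salt_bridges(model_a: CapsomerModel, model_b: CapsomerModel,
                      cutoff: float = SALT_BRIDGE_CUTOFF,
                      interface_only: bool = False) -> List[SaltBridge]:
    """Inter-capsomer salt bridges: acidic O within ``cutoff`` of basic N.

    Both directions are searched (acidic atoms of either capsomer against
    basic atoms of the other); one bridge is reported per residue pair, at the
    minimum atom-atom distance.  ``interface_only`` pre-filters each side to
    atoms within 10 A of the partner (a speed knob; results are identical).
    """
    bridges: Dict[tuple, SaltBridge] = {}
    for acid_m, base_m in ((model_a, model_b), (model_b, model_a)):
        ai = _atom_subset(acid_m, ACIDIC_ATOMS)
        bi = _atom_subset(base_m, BASIC_ATOMS)
        if len(ai) == 0 or len(bi) == 0:
            continue
        apos, bpos = acid_m.positions[ai], base_m.positions[bi]
        if interface_only and len(apos) and len(bpos):
            tree_b_all = cKDTree(base_m.positions)
            keep = tree_b_all.query(apos, k=1)[0] <= 10.0
            ai, apos = ai[keep], apos[keep]
            if len(ai) == 0:
                continue
        tree = cKDTree(bpos)
        for a_local, neighbours in enumerate(tree.query_ball_point(apos, cutoff)):
            i = ai[a_local]
            for b_local in neighbours:
                j = bi[b_local]
                d = float(np.linalg.norm(apos[a_local] - bpos[b_local]))
                acid_key = (str(acid_m.chain_ids[i]), int(acid_m.residue_seqs[i]),
                            str(acid_m.residue_names[i]))
                base_key = (str(base_m.chain_ids[j]), int(base_m.residue_seqs[j]),
                            str(base_m.residue_names[j]))
                pair_key = (acid_key, base_key)
                cur = bridges.get(pair_key)
                if cur is None or d < cur.distance:
                    bridges[pair_key] = SaltBridge(
                        acidic=acid_key + (str(acid_m.names[i]),),
                        basic=base_key + (str(base_m.names[j]),),
                        distance=d,
                    )
    return sorted(bridges.values(), key=lambda b: (b.acidic, b.basic))


@dataclass
class SaltBridgeStats:
    """Formation statistics of inter-capsomer salt bridges over an ensemble."""

    per_pair_frequency: Dict[tuple, float]
    per_frame_counts: List[int]
    mean_count: float = field(init=False)

    def __post_init__(self) -> None:
        for f in self.per_pair_frequency.values():
            if not 0.0 <= f <= 1.0:
                raise ValueError("frequencies must lie in [0, 1]")
        self.mean_count = float(np.mean(self.per_frame_counts)) if self.per_frame_counts else 0.0


def salt_bridge_population(
    frames: Sequence[Tuple[CapsomerModel, CapsomerModel]],
    cutoff: float = SALT_BRIDGE_CUTOFF,
) -> SaltBridgeStats:
    """Per-residue-pair formation frequency and per-frame bridge counts."""
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    n0 = (frames[0][0].n_atoms, frames[0][1].n_atoms)
    appearances: Dict[tuple, int] = {}
    counts: List[int] = []
    for a, b in frames:
        if (a.n_atoms, b.n_atoms) != n0:
            raise ValueError("inconsistent topology across frames")
        found = find_salt_bridges(a, b, cutoff=cutoff)
        counts.append(len(found))
        for br in found:
            appearances[br.residue_pair] = appearances.get(br.residue_pair, 0) + 1
    total = len(frames)
    freq = {pair: cnt / total for pair, cnt in appearances.items()}
    return SaltBridgeStats(per_pair_frequency=freq, per_frame_counts=counts)


# ---------------------------------------------------------------------------
# Binding-energy decomposition
# ---------------------------------------------------------------------------

@dataclass
class EnergyDecomposition:
    """MM/PBSA-style binding-energy terms (kcal/mol); total is their sum."""

    polar_solvation: float
    nonpolar_solvation: float
    van_der_waals: float
    coulombic: float
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = (self.polar_solvation + self.nonpolar_solvation
                      + self.van_der_waals + self.coulombic)

    def asdict(self) -> Dict[str, float]:
        return {
            "polar_solvation": self.polar_solvation,
            "nonpolar_solvation": self.nonpolar_solvation,
            "van_der_waals": self.van_der_waals,
            "coulombic": self.coulombic,
            "total": self.total,
        }


@dataclass
class LJParams:
    """Per-atom Lennard-Jones well depths (kcal/mol) and diameters (A)."""

    epsilon: np.ndarray
    sigma: np.ndarray

    @classmethod
    def uniform(cls, n: int, epsilon: float = 0.1, sigma: float = 3.4) -> "LJParams":
        return cls(np.full(n, epsilon), np.full(n, sigma))


def _gb_cross_energy(a: CapsomerModel, b: CapsomerModel,
                     params: ElectrostaticParams) -> float:
    """Still-style generalized-Born cross term using atom radii as Born radii.

    Binding polar solvation = -(1/eps_in - 1/eps_out) * sum_ij qi qj / f_GB,
    f_GB = sqrt(r^2 + ai aj exp(-r^2 / (4 ai aj))).
    """
    ra, rb = a.radii, b.radii
    if ra is None or rb is None:
        raise ValueError("GB polar solvation requires atom radii on both models")
    d2 = ((a.positions[:, None, :] - b.positions[None, :, :]) ** 2).sum(-1)
    aij = ra[:, None] * rb[None, :]
    f = np.sqrt(d2 + aij * np.exp(-d2 / (4.0 * aij)))
    pref = -COULOMB_KCAL * (1.0 / params.eps_protein - 1.0 / params.eps_solvent)
    return float(pref * (a.charges[:, None] * b.charges[None, :] / f).sum())


def _sasa(model: CapsomerModel, point_number: int = 300) -> float:
    """Shrake-Rupley solvent-accessible surface area (A^2) via biotite."""
    from biotite.structure import AtomArray, sasa

    arr = AtomArray(model.n_atoms)
    arr.coord = np.asarray(model.positions, dtype=np.float32)
    arr.element = np.array(["C"] * model.n_atoms)
    radii = model.radii if model.radii is not None else np.full(model.n_atoms, 1.7)
    vals = sasa(arr, vdw_radii=np.asarray(radii, dtype=np.float64),
                point_number=point_number)
    return float(np.nansum(vals))


def binding_energy(
    fixed: CapsomerModel,
    moving: CapsomerModel,
    params: Optional[ElectrostaticParams] = None,
    lj_params: Optional[Tuple[LJParams, LJParams]] = None,
    sasa_params: Tuple[float, float] = (0.00542, 0.0),
    sasa_points: int = 300,
) -> EnergyDecomposition:
    """Single-snapshot binding-energy decomposition of a capsomer complex.

    * coulombic: molecular-mechanics Coulomb cross term (dielectric 1),
    * van_der_waals: 12-6 Lennard-Jones cross term with Lorentz-Berthelot
      combination of the per-atom parameters (uniform defaults if omitted),
    * polar_solvation: generalized-Born-style pairwise cross term screening
      from eps_protein to eps_solvent,
    * nonpolar_solvation: gamma * delta-SASA + b, with (gamma, b) in
      kcal/(mol*A^2) and kcal/mol.

    This is a static decomposition sharing the *structure* of trajectory
    MM/PBSA averages, not a reproduction of any ensemble value.
    """
    params = params or ElectrostaticParams()
    if fixed.charges is None or moving.charges is None:
        raise ValueError("both models need assigned charges")
    if lj_params is None:
        lj_f = LJParams.uniform(fixed.n_atoms)
        lj_m = LJParams.uniform(moving.n_atoms)
    else:
        lj_f, lj_m = lj_params
        for lj, mdl, who in ((lj_f, fixed, "fixed"), (lj_m, moving, "moving")):
            bad = [i for i in range(mdl.n_atoms)
                   if i >= len(lj.epsilon) or i >= len(lj.sigma)
                   or not np.isfinite(lj.epsilon[i]) or not np.isfinite(lj.sigma[i])]
            if bad:
                raise ValueError(f"missing LJ parameters for {who} atoms {bad}")

    d = moving.positions[:, None, :] - fixed.positions[None, :, :]
    r = np.linalg.norm(d, axis=-1)
    r = np.maximum(r, 1e-6)

    coulombic = float(COULOMB_KCAL * (
        moving.charges[:, None] * fixed.charges[None, :] / r).sum())

    sig = 0.5 * (lj_m.sigma[:, None] + lj_f.sigma[None, :])
    eps = np.sqrt(lj_m.epsilon[:, None] * lj_f.epsilon[None, :])
    sr6 = (sig / r) ** 6
    vdw = float((4.0 * eps * (sr6**2 - sr6)).sum())

    polar = _gb_cross_energy(fixed, moving, params)

    gamma, b_const = sasa_params
    sasa_ab = _sasa_complex(fixed, moving, sasa_points)
    dsasa = sasa_ab - _sasa(fixed, sasa_points) - _sasa(moving, sasa_points)
    nonpolar = gamma * dsasa + b_const

    return EnergyDecomposition(
        polar_solvation=polar, nonpolar_solvation=nonpolar,
        van_der_waals=vdw, coulombic=coulombic,
    )


def _sasa_complex(a: CapsomerModel, b: CapsomerModel, point_number: int) -> float:
    from biotite.structure import AtomArray, sasa

    n = a.n_atoms + b.n_atoms
    arr = AtomArray(n)
    arr.coord = np.asarray(np.vstack([a.positions, b.positions]), dtype=np.float32)
    arr.element = np.array(["C"] * n)
    ra = a.radii if a.radii is not None else np.full(a.n_atoms, 1.7)
    rb = b.radii if b.radii is not None else np.full(b.n_atoms, 1.7)
    vals = sasa(arr, vdw_radii=np.concatenate([ra, rb]).astype(np.float64),
                point_number=point_number)
    return float(np.nansum(vals))


def frame_average_energy(
    frames: Sequence[Tuple[CapsomerModel, CapsomerModel]],
    params: Optional[ElectrostaticParams] = None,
    **kwargs,
) -> Tuple[EnergyDecomposition, EnergyDecomposition]:
    """Mean and sample standard deviation of each energy term over frames.

    Returns ``(mean, sd)`` as :class:`EnergyDecomposition` objects (the SD
    "total" field is the SD of the per-frame totals, not a sum of SDs).
    Requires at least two frames.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames for a standard deviation")
    rows = [binding_energy(a, b, params, **kwargs) for a, b in frames]
    terms = ("polar_solvation", "nonpolar_solvation", "van_der_waals", "coulombic")
    data = {t: np.array([getattr(r, t) for r in rows]) for t in terms}
    totals = np.array([r.total for r in rows])
    mean = EnergyDecomposition(**{t: float(data[t].mean()) for t in terms})
    sd = EnergyDecomposition(**{t: float(data[t].std(ddof=1)) for t in terms})
    sd.total = float(totals.std(ddof=1))
    return mean, sd
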