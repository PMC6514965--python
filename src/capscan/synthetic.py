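"""Download-free synthetic fixtures.

The toy capsomer is a pseudo-hexagonal disc of point-charge sites mimicking
the charge pattern of the real trimeric capsomer: positive charges on the six
hexagon vertices, negative charges in every other groove (edge midpoint), so
the pattern has exact C3 symmetry about the disc axis.  It is a point-charge
model, not a protein: it reproduces the *pattern* that drives binding-mode
signs and funnels, letting every downstream operation be tested
deterministically, and makes no attempt to match real force magnitudes.

``make_mode_pair`` arranges two toy capsomers in the three binding-mode
geometries of the flat 2-fold region:

* mode 1 -- same orientation, a charged groove of the moving capsomer capping
  a positive vertex of the fixed one (intra-trisymmetron packing),
* mode 2 -- 60 degree rotated neighbour whose placement yields *two*
  complementary groove/vertex contacts (the strong attractive boundary
  geometry),
* mode 3 -- 60 degree rotated neighbour with two positive vertices facing
  head-on (the repulsive boundary geometry).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .assembly_ops import CapsomerPair, rotation_about_axis
from .model import CapsomerModel

ACIDIC_ATOMS = ("OD1", "OD2", "OE1", "OE2", "OXT")
BASIC_ATOMS = ("NZ", "NH1", "NH2", "NE", "ND1", "NE2")


@dataclass
class ToyCapsomerSpec:
    """Geometry and charges of the toy capsomer.

    ``ring_radius`` is the hexagon circumradius (A).  Groove charges line the
    groove mouths at the edge-midpoint radius (``ring_radius * cos 30``);
    vertex charges sit slightly recessed into the hexagon face (0.92 of the
    circumradius), so the complementary groove/vertex contacts of the native
    binding modes are always the closest interactions in a pose scan.  Net
    charge is ``6 * vertex_charge + 3 * groove_charge`` (zero for the
    defaults).
    """

    ring_radius: float = 30.0
    vertex_charge: float = +1.0
    groove_charge: float = -2.0
    thickness: float = 10.0
    atoms_per_site: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ring_radius <= 0 or self.thickness < 0 or self.atoms_per_site < 1:
            raise ValueError("invalid toy capsomer geometry")

    @property
    def vertex_radius(self) -> float:
        return self.ring_radius * 0.92

    @property
    def groove_radius(self) -> float:
        return self.ring_radius * math.cos(math.radians(30.0))


def _u(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array([math.cos(a), math.sin(a), 0.0])


def make_toy_capsomer(spec: ToyCapsomerSpec | None = None, *,
                      label: str = "T") -> CapsomerModel:
    """Build the C3-symmetric toy capsomer in the z = 0 plane, COM at origin.

    Sites: six LYS residues (charge on NZ) on the vertices at 0, 60, ..., 300
    degrees and three GLU residues (charge on OE1) in the grooves at 30, 150,
    270 degrees.  Each site is a stack of ``atoms_per_site`` atoms across the
    disc thickness; the site charge sits on the first (titratable) atom and
    the rest are neutral CB atoms.  Deterministic: identical specs give
    bit-identical coordinates.
    """
    spec = spec or ToyCapsomerSpec()
    if spec.atoms_per_site == 1:
        z_offsets = [0.0]
    else:
        z_offsets = list(np.linspace(-spec.thickness / 2, spec.thickness / 2,
                                     spec.atoms_per_site))
    sites = [("LYS", "NZ", spec.vertex_charge, spec.vertex_radius, 60.0 * i)
             for i in range(6)]
    sites += [("GLU", "OE1", spec.groove_charge, spec.groove_radius, 30.0 + 120.0 * i)
              for i in range(3)]
    pos, charges, names, resnames, resseqs = [], [], [], [], []
    for resseq, (resname, head, q, radius, angle) in enumerate(sites, start=1):
        base = radius * _u(angle)
        for m, dz in enumerate(z_offsets):
            pos.append(base + np.array([0.0, 0.0, dz]))
            charges.append(q if m == 0 else 0.0)
            names.append(head if m == 0 else "CB")
            resnames.append(resname)
            resseqs.append(resseq)
    n = len(pos)
    return CapsomerModel(
        np.array(pos),
        names=names, residue_names=resnames,
        chain_ids=[label[:1] or "T"] * n, residue_seqs=resseqs,
        charges=np.array(charges), radii=np.full(n, 1.7),
        masses=np.ones(n), label=label,
    )


def _oriented_copy(model: CapsomerModel, orientation_deg: float,
                   center: np.ndarray, label: str) -> CapsomerModel:
    R = rotation_about_axis(np.array([0.0, 0.0, 1.0]), orientation_deg)
    out = model.with_positions(model.positions @ R.T + center)
    out.label = label
    out.chain_ids = np.asarray([label[:1]] * model.n_atoms, dtype=object)
    return out


def make_mode_pair(mode: int, spec: ToyCapsomerSpec | None = None,
                   gap: float = 5.0) -> CapsomerPair:
    """Two toy capsomers arranged in binding-mode 1, 2 or 3 geometry.

    ``gap`` is the closest approach (A) between the facing charge sites.
    """
    spec = spec or ToyCapsomerSpec()
    if gap <= 0:
        raise ValueError("gap must be > 0")
    if mode not in (1, 2, 3):
        raise ValueError(f"unknown binding mode {mode!r}; expected 1, 2 or 3")
    base = make_toy_capsomer(spec)
    fixed = _oriented_copy(base, 0.0, np.zeros(3), "A")
    rv, rg = spec.vertex_radius, spec.groove_radius
    v60 = rv * _u(60.0)
    if mode == 1:
        # same orientation; the moving capsomer's charged groove (local 270 deg)
        # caps the fixed vertex at 60 deg, approached 10 deg past vertical so
        # that orbiting scans stay on the uncharged-groove side of the vertex
        center = v60 + (gap + rg) * _u(100.0)
        moving = _oriented_copy(base, 0.0, center, "B")
    elif mode == 2:
        # 60-deg rotated; the ideal centers for "moving groove caps fixed
        # vertex" and "moving vertex caps fixed groove" coincide at
        # rv*u(60) + rg*u(30), giving two complementary contacts at the gap
        c = rv * _u(60.0) + rg * _u(30.0)
        center = c + gap * _u(74.0)
        moving = _oriented_copy(base, 60.0, center, "C")
    else:
        # 60-deg rotated, edge-on across the uncharged-groove edges: two
        # positive vertex pairs confront head-on with no charged groove in
        # the interface
        center = np.array([0.0, math.sqrt(3.0) * rv + gap, 0.0])
        moving = _oriented_copy(base, 60.0, center, "C")
    return CapsomerPair(fixed=fixed, moving=moving,
                        plane_normal=np.array([0.0, 0.0, 1.0]))


def make_frame_ensemble(
    pair: CapsomerPair,
    n_frames: int,
    jitter_sd: float = 0.0,
    bridge_plant: Sequence[Tuple[Tuple[int, int], float]] = (),
    seed: int = 0,
    cutoff: float = 4.0,
) -> List[Tuple[CapsomerModel, CapsomerModel]]:
    """Synthetic frame ensemble standing in for an MD trajectory.

    Each frame is a (fixed, moving) pair of models with Gaussian coordinate
    jitter.  ``bridge_plant`` entries ``((res_fixed, res_moving), fraction)``
    force the named acidic (fixed side) / basic (moving side) residue pair to
    sit 3.5 A apart in exactly ``round(fraction * n_frames)`` frames and
    beyond the cutoff elsewhere, so planted formation frequencies are exact.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    for (_, _), frac in bridge_plant:
        if not 0.0 <= frac <= 1.0:
            raise ValueError("planted fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    def _site(model: CapsomerModel, resseq: int, wanted: tuple, what: str) -> int:
        hits = [
            i for i in range(model.n_atoms)
            if int(model.residue_seqs[i]) == resseq and str(model.names[i]) in wanted
        ]
        if not hits:
            raise ValueError(f"no {what} atom in residue {resseq} of {model.label!r}")
        return hits[0]

    plans = []
    for (res_f, res_m), frac in bridge_plant:
        ia = _site(pair.fixed, res_f, ACIDIC_ATOMS, "acidic")
        ib = _site(pair.moving, res_m, BASIC_ATOMS, "basic")
        count = int(round(frac * n_frames))
        chosen = set(rng.choice(n_frames, size=count, replace=False).tolist())
        plans.append((ia, ib, chosen))

    frames: List[Tuple[CapsomerModel, CapsomerModel]] = []
    for f in range(n_frames):
        fx = pair.fixed.copy()
        mv = pair.moving.copy()
        if jitter_sd > 0:
            fx.positions = fx.positions + rng.normal(0.0, jitter_sd, fx.positions.shape)
            mv.positions = mv.positions + rng.normal(0.0, jitter_sd, mv.positions.shape)
        for ia, ib, chosen in plans:
            anchor = fx.positions[ia]
            direction = mv.center_of_mass - anchor
            nrm = np.linalg.norm(direction)
            direction = direction / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
            dist = 3.5 if f in chosen else max(2.0 * cutoff, 8.0)
            mv.positions[ib] = anchor + dist * direction
        frames.append((fx, mv))
    return frames
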