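"""Icosahedral symmetron combinatorics for giant-virus capsids.

A giant-virus capsid is tiled by 20 triangular trisymmetrons (capsomers all in
one orientation) and 12 pentagonal pentasymmetrons around the 5-fold vertices.
This module computes the triangulation number T = h^2 + h*k + k^2, the n = k+3
relation between the lattice index k and the trisymmetron edge length for the
giant-virus family (h = 7, three pentasymmetron layers), and counts capsomer
contacts by binding mode:

* mode 1 -- neighbours inside a trisymmetron (same orientation),
* modes 2/3 -- the two alternating contact geometries across a trisymmetron
  boundary, where orientations differ by 60 degrees.

A planar triangular-lattice builder provides brute-force enumeration of the
same counts, serving as an independent check of the closed-form formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt
from typing import List, Tuple

import numpy as np

SiteId = Tuple[int, int]          # (row, col) within a trisymmetron
Contact = Tuple[SiteId, SiteId, int]  # (site_a, site_b, mode)

#: Capsomers in one pentasymmetron: 1 pentamer + 5*6 pseudo-hexamers.
PENTASYMMETRON_CAPSOMERS = 31


def t_number(h: int, k: int) -> int:
    """Triangulation number T = h^2 + h*k + k^2."""
    if h < 1 or k < 0:
        raise ValueError("require h >= 1 and k >= 0")
    return h * h + h * k + k * k


def edge_capsomers(k: int) -> int:
    """Capsomers along one trisymmetron edge: n = k + 3.

    The +3 comes from the three capsomer layers of the pentasymmetron
    asymmetric unit shared by all giant viruses (h = 7).
    """
    if k < 0:
        raise ValueError("require k >= 0")
    return k + 3


def pentasymmetron_size() -> int:
    """Capsomers in one pentasymmetron (1 pentamer + 30 pseudo-hexamers)."""
    return PENTASYMMETRON_CAPSOMERS


def per_trisymmetron_counts(n: int) -> Tuple[int, int, int]:
    """(mode-1 pairs inside one trisymmetron, mode-2 per edge, mode-3 per edge).

    Mode 1: n(n-1)*3/2 nearest-neighbour pairs in a triangular array of
    n(n+1)/2 sites.  Modes 2 and 3: n contacts each across every boundary edge.
    """
    if n < 1:
        raise ValueError("require n >= 1")
    return (n * (n - 1) * 3 // 2, n, n)


@dataclass
class ModeCounts:
    """Whole-virion contact counts per binding mode."""

    N_mode1: int
    N_mode2: int
    N_mode3: int

    def __post_init__(self) -> None:
        if min(self.N_mode1, self.N_mode2, self.N_mode3) < 0:
            raise ValueError("mode counts must be non-negative")
        if self.N_mode2 != self.N_mode3:
            raise ValueError("modes 2 and 3 must pair up one-to-one across boundaries")

    def astuple(self) -> Tuple[int, int, int]:
        return (self.N_mode1, self.N_mode2, self.N_mode3)


def virion_mode_counts(k: int) -> ModeCounts:
    """Whole-virion mode counts from the lattice index k.

    20 trisymmetrons carry the mode-1 contacts and 30 trisymmetron edges carry
    one mode-2 and one mode-3 contact per edge capsomer:

        N_mode1 = (k+3)(k+2) * 30,   N_mode2 = N_mode3 = (k+3) * 30.
    """
    n = edge_capsomers(k)
    return ModeCounts(
        N_mode1=(n * (n - 1) * 3 // 2) * 20,
        N_mode2=n * 30,
        N_mode3=n * 30,
    )


@dataclass
class CapsidGeometry:
    """Lattice indices and derived sizes of an icosahedral capsid."""

    h: int
    k: int
    giant_virus: bool = True
    T: int = field(init=False)
    n: int = field(init=False)

    def __post_init__(self) -> None:
        self.T = t_number(self.h, self.k)
        self.n = edge_capsomers(self.k)
        if self.giant_virus and self.h != 7:
            raise ValueError(
                "the n = k + 3 relation assumes the giant-virus family (h = 7); "
                "pass giant_virus=False for other lattices"
            )


# ---------------------------------------------------------------------------
# Planar lattice enumeration (oracle for the formulas)
# ---------------------------------------------------------------------------

@dataclass
class Site:
    row: int
    col: int
    position: np.ndarray
    orientation: int  # degrees, one of 0, 60, ..., 300


@dataclass
class TrisymmetronLattice:
    """Flat triangular array of n rows of capsomer sites on unit spacing."""

    n: int
    orientation: int
    sites: List[Site]
    contacts: List[Contact]

    @property
    def site_count(self) -> int:
        return len(self.sites)


def build_trisymmetron(n: int, orientation: int = 0) -> TrisymmetronLattice:
    """Build an n-row planar trisymmetron and enumerate its internal contacts.

    Row i (0-based) holds i+1 sites; all sites share one orientation.  Every
    adjacent pair (within a row, or between consecutive rows sharing a lattice
    triangle) is a mode-1 contact.
    """
    if n < 1:
        raise ValueError("require n >= 1")
    if orientation % 60 != 0:
        raise ValueError("orientation must be a multiple of 60 degrees")
    orientation %= 360
    sites: List[Site] = []
    for i in range(n):
        for j in range(i + 1):
            pos = np.array([j - i / 2.0, -i * sqrt(3) / 2.0])
            sites.append(Site(i, j, pos, orientation))
    contacts: List[Contact] = []
    for i in range(n):
        for j in range(i + 1):
            if j + 1 <= i:
                contacts.append(((i, j), (i, j + 1), 1))
            if i + 1 < n:
                contacts.append(((i, j), (i + 1, j), 1))
                contacts.append(((i, j), (i + 1, j + 1), 1))
    return TrisymmetronLattice(n, orientation, sites, contacts)


def classify_boundary_contacts(
    tri_a: TrisymmetronLattice, tri_b: TrisymmetronLattice
) -> List[Contact]:
    """Contacts across the shared edge of two neighbouring trisymmetrons.

    The boundary row of ``tri_b`` faces the bottom edge (row n-1) of ``tri_a``
    staggered by half a spacing, so each of the n edge capsomers of ``tri_a``
    touches two facing capsomers: one in the B-C geometry (mode 2, down-left)
    and one in the A-C geometry (mode 3, down-right).  Site ids on the
    ``tri_b`` side are its own edge-row columns 0..n-1 plus a column-n corner
    dot contributed by the adjoining symmetron at the edge end (corner
    contacts are assigned to the lower-indexed edge by convention).

    Raises if the two lattices have different edge lengths or if their
    orientations do not differ by an odd multiple of 60 degrees (capsomer
    orientation jumps by 60 degrees across a symmetron boundary).
    """
    if tri_a.n != tri_b.n:
        raise ValueError("boundary requires equal edge lengths")
    diff = (tri_b.orientation - tri_a.orientation) % 120
    if diff != 60:
        raise ValueError(
            "not a symmetron boundary: orientations must differ by 60 degrees"
        )
    n = tri_a.n
    contacts: List[Contact] = []
    for j in range(n):
        contacts.append(((n - 1, j), (n - 1, j), 2))
        contacts.append(((n - 1, j), (n - 1, j + 1), 3))
    return contacts


def enumerate_mode_counts(k: int) -> ModeCounts:
    """Whole-virion counts by brute-force planar enumeration.

    Counts mode-1 contacts in a built (k+3)-row trisymmetron times 20, and
    boundary contacts across one built edge times 30; independent of the
    closed-form path in :func:`virion_mode_counts`.
    """
    n = edge_capsomers(k)
    tri_a = build_trisymmetron(n, orientation=0)
    tri_b = build_trisymmetron(n, orientation=60)
    boundary = classify_boundary_contacts(tri_a, tri_b)
    return ModeCounts(
        N_mode1=len(tri_a.contacts) * 20,
        N_mode2=sum(1 for c in boundary if c[2] == 2) * 30,
        N_mode3=sum(1 for c in boundary if c[2] == 3) * 30,
    )
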