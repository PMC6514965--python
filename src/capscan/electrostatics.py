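"""Electrostatic engine: screened-Coulomb pair forces and a finite-difference
linearized Poisson-Boltzmann (PB) solver.

Forces between two charged rigid bodies can be evaluated three ways:

* ``coulomb_uniform`` -- plain Coulomb sum in a uniform solvent dielectric,
* ``debye_huckel``    -- each pair term screened by ``exp(-kr) (1 + kr)``
  (force) / ``exp(-kr)`` (energy), with the inverse Debye length k derived
  from the ionic strength,
* ``fd_pb``           -- force on the moving charges in a potential grid
  obtained by solving the linearized PB equation on a cubic lattice
  (7-point stencil, red-black successive over-relaxation, two-dielectric
  map from the atom radii, Debye-Hueckel Dirichlet boundary).

The sign convention follows binding-funnel usage: a positive axial projection
means the force pulls the moving capsomer toward the fixed one (attractive),
a negative projection pushes it away (repulsive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from .constants import COULOMB_KCAL, T_DEFAULT, debye_kappa, kt_kcal
from .errors import ConvergenceError, GeometryError, OverlapError
from .model import CapsomerModel

#: Minimum allowed interatomic separation (A) between the two bodies for the
#: analytic (non-grid) force models.
MIN_SEPARATION = 0.5


@dataclass
class ElectrostaticParams:
    """Solvent/solute dielectric model and screening parameters."""

    eps_solvent: float = 80.0
    eps_protein: float = 2.0
    ionic_strength: float = 0.15      # mol/L
    temperature: float = T_DEFAULT    # K
    model: str = "debye_huckel"       # coulomb_uniform | debye_huckel | fd_pb
    coulomb_constant: float = COULOMB_KCAL

    def __post_init__(self) -> None:
        if self.eps_solvent <= 0 or self.eps_protein <= 0:
            raise ValueError("dielectric constants must be > 0")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be >= 0")
        if self.model not in ("coulomb_uniform", "debye_huckel", "fd_pb"):
            raise ValueError(f"unknown electrostatic model {self.model!r}")

    @property
    def kappa(self) -> float:
        """Inverse Debye length (1/A); zero for the plain Coulomb model."""
        if self.model == "coulomb_uniform":
            return 0.0
        return debye_kappa(self.ionic_strength, self.eps_solvent, self.temperature)

    @property
    def kt(self) -> float:
        return kt_kcal(self.temperature)


@dataclass
class ForceRecord:
    """Force on the moving capsomer at one scan coordinate.

    ``axial_projection`` is the force component along the (fixed -> moving)
    axis with attraction positive; ``energy`` is the interaction energy in
    kcal/mol.
    """

    scan_param: float
    force: np.ndarray                 # kcal/(mol*A)
    magnitude: float = field(init=False)
    axial_projection: float = 0.0
    energy: float = 0.0

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float).reshape(3)
        self.magnitude = float(np.linalg.norm(self.force))


def _charges_or_raise(model: CapsomerModel, who: str) -> np.ndarray:
    if model.charges is None:
        raise ValueError(f"{who} capsomer has no charges assigned")
    return model.charges


def pair_force(fixed: CapsomerModel, moving: CapsomerModel,
               params: Optional[ElectrostaticParams] = None,
               scan_param: float = 0.0) -> ForceRecord:
    """Total electrostatic force and energy on ``moving`` due to ``fixed``.

    Coulomb sum over all atom pairs in the solvent dielectric; under the
    Debye-Hueckel model each force term carries ``exp(-kr)(1+kr)`` and each
    energy term ``exp(-kr)``.  Raises :class:`OverlapError` when any atom pair
    comes closer than 0.5 A.
    """
    params = params or ElectrostaticParams()
    qf = _charges_or_raise(fixed, "fixed")
    qm = _charges_or_raise(moving, "moving")
    if fixed.n_atoms == 0 or moving.n_atoms == 0:
        return ForceRecord(scan_param, np.zeros(3))
    dvec = moving.positions[:, None, :] - fixed.positions[None, :, :]  # (m, f, 3)
    r = np.linalg.norm(dvec, axis=-1)
    if r.min() <= MIN_SEPARATION:
        i, j = np.unravel_index(int(np.argmin(r)), r.shape)
        raise OverlapError(
            f"atoms overlap: moving #{moving.serials[i]} and fixed "
            f"#{fixed.serials[j]} are {r[i, j]:.3f} A apart (< {MIN_SEPARATION} A)"
        )
    k = params.coulomb_constant / params.eps_solvent
    qq = qm[:, None] * qf[None, :]
    kap = params.kappa
    screen_f = np.exp(-kap * r) * (1.0 + kap * r) if kap > 0 else 1.0
    screen_e = np.exp(-kap * r) if kap > 0 else 1.0
    fmag = k * qq / r**3 * screen_f                     # per-pair radial coefficient
    force = (fmag[:, :, None] * dvec).sum(axis=(0, 1))
    energy = float((k * qq / r * screen_e).sum())

    u = moving.center_of_mass - fixed.center_of_mass
    norm = np.linalg.norm(u)
    if norm < 1e-12:
        raise GeometryError("centers of mass coincide; axial direction undefined")
    axial = float(-force @ (u / norm))
    return ForceRecord(scan_param, force, axial_projection=axial, energy=energy)


def scan_forces(series, fixed: Optional[CapsomerModel] = None,
                params: Optional[ElectrostaticParams] = None) -> List[ForceRecord]:
    """One :class:`ForceRecord` per pose of a :class:`PoseSeries`, in order."""
    from .assembly_ops import PoseSeries  # local import to avoid cycle

    if not isinstance(series, PoseSeries):
        raise TypeError("series must be a PoseSeries")
    if len(series) == 0:
        raise ValueError("empty pose series")
    fixed = fixed if fixed is not None else series.pair.fixed
    params = params or ElectrostaticParams()
    return [
        pair_force(fixed, moved, params, scan_param=pose.scan_param)
        for pose, moved in zip(series.poses, series.moving_models())
    ]


# ---------------------------------------------------------------------------
# Finite-difference linearized PB
# ---------------------------------------------------------------------------

@dataclass
class PotentialGrid:
    """Node-centered cubic scalar field.

    ``values[i, j, k]`` is the potential at ``origin + spacing * (i, j, k)``.
    ``unit`` is either ``"kT/e"`` (solver output) or ``"kcal/(mol*e)"``.
    """

    origin: np.ndarray
    spacing: float
    dims: tuple
    values: np.ndarray
    unit: str = "kT/e"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.dims = tuple(int(d) for d in self.dims)
        self.values = np.asarray(self.values, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if any(d < 2 for d in self.dims):
            raise ValueError("grid dims must be >= 2")
        if self.values.shape != self.dims:
            raise ValueError("values shape must match dims")


def _deposit_charges(model: CapsomerModel, origin: np.ndarray, spacing: float,
                     dims: tuple) -> np.ndarray:
    """Trilinear (cloud-in-cell) distribution of atom charges to grid nodes."""
    rho = np.zeros(dims)
    frac = (model.positions - origin) / spacing
    base = np.floor(frac).astype(int)
    t = frac - base
    for (i, j, k), (tx, ty, tz), q in zip(base, t, model.charges):
        for di, wx in ((0, 1 - tx), (1, tx)):
            for dj, wy in ((0, 1 - ty), (1, ty)):
                for dk, wz in ((0, 1 - tz), (1, tz)):
                    rho[i + di, j + dj, k + dk] += q * wx * wy * wz
    return rho


def solve_pb(model: CapsomerModel, params: Optional[ElectrostaticParams] = None,
             spacing: float = 1.0, padding: float = 15.0,
             dims: Optional[Sequence[int]] = None,
             max_iter: int = 10000, tol: float = 1e-4,
             omega: float = 1.5) -> PotentialGrid:
    """Solve the linearized PB equation around a charged model.

    The dielectric is ``eps_protein`` inside the atom radii and ``eps_solvent``
    outside; ionic screening acts only outside the protein region.  The box
    faces carry a Debye-Hueckel Dirichlet condition summed over the atoms.
    Converged when the largest successive update falls below ``tol`` (kT/e);
    raises :class:`ConvergenceError` otherwise.
    """
    params = params or ElectrostaticParams()
    q = _charges_or_raise(model, "the")
    if model.radii is None:
        raise ValueError("model has no radii assigned (needed for the dielectric map)")
    lo = model.positions.min(axis=0) - padding
    hi = model.positions.max(axis=0) + padding
    if dims is None:
        dims = tuple(int(np.ceil((hi[d] - lo[d]) / spacing)) + 1 for d in range(3))
    else:
        dims = tuple(int(d) for d in dims)
    origin = lo
    nx, ny, nz = dims
    h = spacing
    kt = params.kt
    kap = params.kappa

    # node coordinates
    xs = origin[0] + h * np.arange(nx)
    ys = origin[1] + h * np.arange(ny)
    zs = origin[2] + h * np.arange(nz)

    # protein mask: nodes inside any atom sphere
    inside = np.zeros(dims, dtype=bool)
    for pos, rad in zip(model.positions, model.radii):
        i0 = np.searchsorted(xs, pos[0] - rad)
        i1 = np.searchsorted(xs, pos[0] + rad, side="right")
        j0 = np.searchsorted(ys, pos[1] - rad)
        j1 = np.searchsorted(ys, pos[1] + rad, side="right")
        k0 = np.searchsorted(zs, pos[2] - rad)
        k1 = np.searchsorted(zs, pos[2] + rad, side="right")
        if i0 >= i1 or j0 >= j1 or k0 >= k1:
            continue
        dx = xs[i0:i1, None, None] - pos[0]
        dy = ys[None, j0:j1, None] - pos[1]
        dz = zs[None, None, k0:k1] - pos[2]
        inside[i0:i1, j0:j1, k0:k1] |= dx**2 + dy**2 + dz**2 <= rad**2

    eps = np.where(inside, params.eps_protein, params.eps_solvent)
    lam = np.where(inside, 0.0, params.eps_solvent * kap**2)  # screening term
    src = _deposit_charges(model, origin, h, dims)
    b = (4.0 * math.pi * params.coulomb_constant / kt) * src / h

    # face-centered dielectric: harmonic mean of neighbours
    def hmean(a, bb):
        return 2.0 * a * bb / (a + bb)

    ex = hmean(eps[:-1, :, :], eps[1:, :, :])   # between i and i+1
    ey = hmean(eps[:, :-1, :], eps[:, 1:, :])
    ez = hmean(eps[:, :, :-1], eps[:, :, 1:])

    phi = np.zeros(dims)

    # Debye-Hueckel Dirichlet boundary from all atom charges
    def _bc(points):
        d = np.linalg.norm(points[:, None, :] - model.positions[None, :, :], axis=-1)
        d = np.maximum(d, 1e-6)
        coef = params.coulomb_constant / (params.eps_solvent * kt)
        return coef * (q[None, :] * np.exp(-kap * d) / d).sum(axis=1)

    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    for axis, idx in ((0, 0), (0, nx - 1), (1, 0), (1, ny - 1), (2, 0), (2, nz - 1)):
        sl = [slice(None)] * 3
        sl[axis] = idx
        pts = np.stack([X[tuple(sl)].ravel(), Y[tuple(sl)].ravel(),
                        Z[tuple(sl)].ravel()], axis=1)
        phi[tuple(sl)] = _bc(pts).reshape(phi[tuple(sl)].shape)

    # interior stencil coefficients
    exm = ex[:-1, 1:-1, 1:-1]; exp_ = ex[1:, 1:-1, 1:-1]
    eym = ey[1:-1, :-1, 1:-1]; eyp = ey[1:-1, 1:, 1:-1]
    ezm = ez[1:-1, 1:-1, :-1]; ezp = ez[1:-1, 1:-1, 1:]
    # stencil scaled by h^2: phi_c = (sum eps_f phi_f + C q_c / h) / (sum eps_f + lam h^2)
    diag = exm + exp_ + eym + eyp + ezm + ezp + lam[1:-1, 1:-1, 1:-1] * h * h
    rhs = b[1:-1, 1:-1, 1:-1]

    ii, jj, kk = np.meshgrid(np.arange(nx - 2), np.arange(ny - 2),
                             np.arange(nz - 2), indexing="ij")
    red = (ii + jj + kk) % 2 == 0
    black = ~red

    interior = (slice(1, -1),) * 3
    for it in range(max_iter):
        max_delta = 0.0
        for mask in (red, black):
            nb = (exm * phi[:-2, 1:-1, 1:-1] + exp_ * phi[2:, 1:-1, 1:-1]
                  + eym * phi[1:-1, :-2, 1:-1] + eyp * phi[1:-1, 2:, 1:-1]
                  + ezm * phi[1:-1, 1:-1, :-2] + ezp * phi[1:-1, 1:-1, 2:])
            gs = (nb + rhs) / diag
            cur = phi[interior]
            delta = np.where(mask, omega * (gs - cur), 0.0)
            phi[interior] = cur + delta
            max_delta = max(max_delta, float(np.abs(delta).max()))
        if max_delta < tol:
            break
    else:
        raise ConvergenceError(
            f"PB solver did not converge in {max_iter} iterations "
            f"(last max update {max_delta:.3e} kT/e)"
        )
    return PotentialGrid(origin, h, dims, phi, unit="kT/e")


def grid_force(moving: CapsomerModel, grid: PotentialGrid,
               temperature: float = T_DEFAULT,
               scan_param: float = 0.0) -> ForceRecord:
    """Force on the moving charges in a potential grid: F = -q grad(phi).

    The gradient is taken by centered finite differences on the grid nodes and
    trilinearly interpolated at each atom; for a linear potential this is
    exact.  Output force is in kcal/(mol*A): grids in kT/e are converted with
    kT at ``temperature``, grids already in kcal/(mol*e) pass through.
    Atoms must lie at least 2 grid cells inside the box.
    """
    q = _charges_or_raise(moving, "moving")
    if grid.unit == "kT/e":
        scale = kt_kcal(temperature)
    elif grid.unit in ("kcal/(mol*e)", "kcal/(mol e)"):
        scale = 1.0
    else:
        raise ValueError(f"unknown grid unit {grid.unit!r}")
    h = grid.spacing
    frac = (moving.positions - grid.origin) / h
    limit = np.array(grid.dims) - 1
    if np.any(frac < 2.0) or np.any(frac > limit[None, :] - 2.0):
        bad = int(np.argmax(np.any((frac < 2.0) | (frac > limit - 2.0), axis=1)))
        raise GeometryError(
            f"atom #{moving.serials[bad]} is within 2 grid cells of the box edge"
        )
    g = np.stack(np.gradient(grid.values, h), axis=-1)  # (nx, ny, nz, 3)
    base = np.floor(frac).astype(int)
    t = frac - base
    total = np.zeros(3)
    energy = 0.0
    for (i, j, k), (tx, ty, tz), qi, in zip(base, t, q):
        acc_g = np.zeros(3)
        acc_p = 0.0
        for di, wx in ((0, 1 - tx), (1, tx)):
            for dj, wy in ((0, 1 - ty), (1, ty)):
                for dk, wz in ((0, 1 - tz), (1, tz)):
                    w = wx * wy * wz
                    acc_g += w * g[i + di, j + dj, k + dk]
                    acc_p += w * grid.values[i + di, j + dj, k + dk]
        total += -qi * acc_g * scale
        energy += qi * acc_p * scale
    return ForceRecord(scan_param, total, axial_projection=0.0, energy=energy)


# ---------------------------------------------------------------------------
# OpenDX export
# ---------------------------------------------------------------------------

def export_dx(grid: PotentialGrid, path) -> None:
    """Write the grid as an OpenDX scalar field (readable by VMD/PyMOL)."""
    from gridData import Grid

    g = Grid(grid.values, origin=grid.origin,
             delta=[grid.spacing] * 3)
    g.export(str(path), file_format="dx", typequote='"')


def read_dx(path, unit: str = "kT/e") -> PotentialGrid:
    """Read an OpenDX scalar field back into a :class:`PotentialGrid`."""
    from gridData import Grid

    g = Grid(str(path))
    delta = np.asarray(g.delta)
    spacing = float(delta[0] if delta.ndim == 1 else delta[0, 0])
    return PotentialGrid(np.asarray(g.origin), spacing, g.grid.shape, g.grid, unit=unit)
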