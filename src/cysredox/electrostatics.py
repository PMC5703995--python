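"""Continuum electrostatics: finite-difference Poisson-Boltzmann and
Debye-Hückel energies.

The linearised PB equation is discretised on a regular grid with a 7-point
stencil.  Face dielectrics are harmonically interpolated from the fraction of
the node-to-node segment lying inside the protein cavity (the union of atom
spheres), which suppresses the grid dependence of Born self energies.  Ionic
screening acts only at solvent nodes beyond the Stern layer; Dirichlet
boundary potentials come from the Debye-Hückel expression.  The resulting
symmetric positive-definite system is solved by Jacobi-preconditioned
conjugate gradients.

Potentials are in kcal/(mol e), energies in kcal/mol, distances in angstrom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constants import COULOMB_K, DEFAULT_TEMPERATURE, R_KCAL

# mol/L -> ions per A^3 (per unit concentration)
_CONC_TO_A3 = 6.02214076e-4


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class ElectrostaticParameters:
    """Dielectric / ionic model: eps 78.4 (solvent) and 4 (protein), 0.15 M
    ionic strength, 2 A Stern layer, 298.15 K."""

    eps_solvent: float = 78.4
    eps_protein: float = 4.0
    ionic_strength: float = 0.15  # mol/L
    temperature: float = DEFAULT_TEMPERATURE
    stern: float = 2.0  # A
    coulomb_k: float = COULOMB_K

    def __post_init__(self):
        if self.eps_solvent <= 1 or self.eps_protein <= 1:
            raise ValueError("relative dielectrics must exceed 1")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be >= 0")

    @property
    def rt(self) -> float:
        return R_KCAL * self.temperature

    @property
    def ln10_rt(self) -> float:
        return 2.303 * self.rt

    @property
    def kappa(self) -> float:
        """Inverse Debye length (1/A); ~0.1274 at 0.15 M, 298 K."""
        bjerrum = self.coulomb_k / (self.eps_solvent * self.rt)
        kappa2 = 8.0 * math.pi * bjerrum * _CONC_TO_A3 * self.ionic_strength
        return math.sqrt(kappa2)


def debye_huckel_energy(q1: float, q2: float, r: float,
                        params: ElectrostaticParameters) -> float:
    """Screened-Coulomb pair energy k*q1*q2*exp(-kappa r)/(eps_w r)."""
    if r <= 0:
        raise ValueError("pair separation must be positive")
    return (params.coulomb_k * q1 * q2 *
            math.exp(-params.kappa * r) / (params.eps_solvent * r))


@dataclass
class PotentialGrid:
    origin: np.ndarray     # (3,)
    spacing: float
    phi: np.ndarray        # (nx, ny, nz), kcal/(mol e)

    @property
    def shape(self):
        return self.phi.shape

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        p = np.atleast_2d(points)
        upper = self.origin + (np.array(self.shape) - 1) * self.spacing
        return np.all((p >= self.origin + margin) & (p <= upper - margin), axis=1)

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of the potential at cartesian points."""
        p = np.atleast_2d(points)
        f = (p - self.origin) / self.spacing
        i0 = np.floor(f).astype(int)
        nx, ny, nz = self.shape
        i0 = np.clip(i0, 0, [nx - 2, ny - 2, nz - 2])
        t = f - i0
        out = np.zeros(len(p))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (np.where(dx, t[:, 0], 1 - t[:, 0])
                         * np.where(dy, t[:, 1], 1 - t[:, 1])
                         * np.where(dz, t[:, 2], 1 - t[:, 2]))
                    out += w * self.phi[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
        return out


def _grid_axes(origin: np.ndarray, spacing: float, shape) -> tuple[np.ndarray, ...]:
    return tuple(origin[d] + spacing * np.arange(shape[d]) for d in range(3))


def _mark_inside(field: np.ndarray, axes, centers: np.ndarray,
                 radii: np.ndarray) -> None:
    """Set field nodes lying inside any sphere to True (per-sphere bbox scan)."""
    ax, ay, az = axes
    for c, r in zip(centers, radii):
        ix = np.searchsorted(ax, [c[0] - r, c[0] + r])
        iy = np.searchsorted(ay, [c[1] - r, c[1] + r])
        iz = np.searchsorted(az, [c[2] - r, c[2] + r])
        sx, sy, sz = slice(*ix), slice(*iy), slice(*iz)
        if ix[0] >= ix[1] or iy[0] >= iy[1] or iz[0] >= iz[1]:
            continue
        dx2 = (ax[sx] - c[0]) ** 2
        dy2 = (ay[sy] - c[1]) ** 2
        dz2 = (az[sz] - c[2]) ** 2
        d2 = dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
        field[sx, sy, sz] |= d2 <= r * r

_SEG_FRACTIONS = np.array([0.1, 0.3, 0.5, 0.7, 0.9])


def _face_dielectric(axis: int, origin, spacing, shape, centers, radii,
                     eps_in, eps_out) -> np.ndarray:
    """Harmonic face dielectric from the in-cavity fraction of the
    node-to-node segment, sampled at five points."""
    fshape = list(shape)
    fshape[axis] -= 1
    inside_count = np.zeros(fshape, dtype=np.int8)
    base_axes = _grid_axes(origin, spacing, shape)
    for frac in _SEG_FRACTIONS:
        axes = list(base_axes)
        axes[axis] = axes[axis][:-1] + frac * spacing
        hit = np.zeros(fshape, dtype=bool)
        _mark_inside(hit, tuple(axes), centers, radii)
        inside_count += hit
    f = inside_count / len(_SEG_FRACTIONS)
    return 1.0 / (f / eps_in + (1.0 - f) / eps_out)


def solve_fdpb(atom_positions: np.ndarray,
               atom_radii: np.ndarray,
               charges: list[tuple[np.ndarray, float]],
               params: ElectrostaticParameters,
               spacing: float = 0.5,
               padding: float = 10.0,
               center: np.ndarray | None = None,
               half_extent: float | None = None,
               uniform_eps: float | None = None,
               ionic: bool = True,
               rtol: float = 1e-10) -> PotentialGrid:
    """Solve the linearised PB equation for the given point charges.

    ``atom_positions``/``atom_radii`` define the low-dielectric cavity; pass
    ``uniform_eps`` to override with a homogeneous dielectric (no cavity, no
    screening) — the reference runs used for identical-grid subtraction.
    The grid covers the charges (or an explicit center/half_extent box) with
    ``padding`` angstrom of border; charges must sit >= 5 A inside the grid.
    """
    charge_pos = np.array([np.asarray(p, dtype=float) for p, _ in charges]) \
        if charges else np.zeros((0, 3))
    if center is None:
        ref = charge_pos if len(charge_pos) else np.atleast_2d(atom_positions)
        lo = ref.min(axis=0) - padding
        hi = ref.max(axis=0) + padding
    else:
        center = np.asarray(center, dtype=float)
        lo = center - half_extent
        hi = center + half_extent
    n = np.ceil((hi - lo) / spacing).astype(int) + 1
    origin = lo
    shape = tuple(int(v) for v in n)
    axes = _grid_axes(origin, spacing, shape)
    upper = origin + (n - 1) * spacing
    if len(charge_pos):
        if np.any(charge_pos - origin < 5.0 - 1e-9) or \
           np.any(upper - charge_pos < 5.0 - 1e-9):
            raise ValueError("charges must lie >= 5 A inside the grid")

    eps_w = params.eps_solvent if uniform_eps is None else uniform_eps
    eps_p = params.eps_protein if uniform_eps is None else uniform_eps
    kappa = params.kappa if (ionic and uniform_eps is None) else 0.0

    atom_positions = np.atleast_2d(np.asarray(atom_positions, dtype=float)) \
        if np.size(atom_positions) else np.zeros((0, 3))
    atom_radii = np.atleast_1d(np.asarray(atom_radii, dtype=float))

    if uniform_eps is None and len(atom_positions):
        eps_faces = [
            _face_dielectric(ax, origin, spacing, shape, atom_positions,
                             atom_radii, eps_p, eps_w)
            for ax in range(3)
        ]
        ion_excluded = np.zeros(shape, dtype=bool)
        _mark_inside(ion_excluded, axes, atom_positions,
                     atom_radii + params.stern)
        ion_ok = ~ion_excluded
    else:
        eps_faces = [np.full((shape[0] - 1, shape[1], shape[2]), eps_w),
                     np.full((shape[0], shape[1] - 1, shape[2]), eps_w),
                     np.full((shape[0], shape[1], shape[2] - 1), eps_w)]
        ion_ok = np.ones(shape, dtype=bool)

    # charge spread: trilinear to the 8 surrounding nodes
    q_grid = np.zeros(shape)
    for pos, q in charges:
        f = (np.asarray(pos, dtype=float) - origin) / spacing
        i0 = np.floor(f).astype(int)
        t = f - i0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = ((t[0] if dx else 1 - t[0])
                         * (t[1] if dy else 1 - t[1])
                         * (t[2] if dz else 1 - t[2]))
                    q_grid[i0[0] + dx, i0[1] + dy, i0[2] + dz] += q * w

    # Dirichlet boundary from the DH expression
    phi = np.zeros(shape)
    if charges:
        boundary = np.zeros(shape, dtype=bool)
        boundary[0, :, :] = boundary[-1, :, :] = True
        boundary[:, 0, :] = boundary[:, -1, :] = True
        boundary[:, :, 0] = boundary[:, :, -1] = True
        bpts = np.argwhere(boundary)
        bxyz = origin + bpts * spacing
        vals = np.zeros(len(bpts))
        for pos, q in charges:
            r = np.linalg.norm(bxyz - np.asarray(pos), axis=1)
            r = np.maximum(r, 1e-6)
            vals += params.coulomb_k * q * np.exp(-kappa * r) / (eps_w * r)
        phi[tuple(bpts.T)] = vals

    interior = np.zeros(shape, dtype=bool)
    interior[1:-1, 1:-1, 1:-1] = True
    idx = -np.ones(shape, dtype=np.int64)
    m = int(interior.sum())
    idx[interior] = np.arange(m)

    kappa2_term = np.where(ion_ok, eps_w * kappa ** 2 * spacing ** 2, 0.0)

    diag = kappa2_term.copy()
    rhs = 4.0 * math.pi * params.coulomb_k * q_grid / spacing
    rows, cols, vals = [], [], []

    for axis in range(3):
        ef = eps_faces[axis]
        for side in (-1, 1):
            # neighbour index offset
            shift = [0, 0, 0]
            shift[axis] = side
            nb_idx = np.roll(idx, -side, axis=axis)
            nb_phi = np.roll(phi, -side, axis=axis)
            # face array aligned with node p
            pad = [(0, 0)] * 3
            pad[axis] = (1, 0) if side < 0 else (0, 1)
            ef_full = np.pad(ef, pad)  # zero eps on the outermost virtual face
            diag += np.where(interior, ef_full, 0.0)
            nb_interior = np.roll(interior, -side, axis=axis)
            # off-diagonal where both p and neighbour are interior
            mask = interior & nb_interior
            rows.append(idx[mask])
            cols.append(nb_idx[mask])
            vals.append(-ef_full[mask])
            # boundary neighbour contributes to rhs
            bmask = interior & ~nb_interior
            rhs[bmask] += ef_full[bmask] * nb_phi[bmask]

    rows.append(idx[interior])
    cols.append(idx[interior])
    vals.append(diag[interior])
    A = sp.csr_matrix(
        (np.concatenate(vals),
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(m, m),
    )
    b = rhs[interior]
    pre = sp.diags(1.0 / A.diagonal())
    x, info = spla.cg(A, b, rtol=rtol, atol=0.0, maxiter=20000, M=pre)
    if info != 0:
        res = float(np.linalg.norm(A @ x - b))
        raise ConvergenceError(f"FDPB CG did not converge (info={info}, "
                               f"residual {res:.3e})")
    phi[interior] = x
    return PotentialGrid(origin=np.asarray(origin, dtype=float),
                         spacing=spacing, phi=phi)


def born_desolvation(radius: float, charge: float,
                     params: ElectrostaticParameters,
                     spacing: float = 0.5,
                     padding: float = 10.0) -> float:
    """Grid desolvation penalty of a charge centred in a sphere: the energy
    of the charged-in-protein state minus charged-in-water, by identical-grid
    subtraction (both runs share the charge node's local dielectric, so grid
    self energies cancel).  Analytic value: (k q^2 / 2a)(1/eps_p - 1/eps_w).
    """
    if charge == 0.0:
        return 0.0
    center = np.zeros(3)
    charges = [(center, charge)]
    atoms = np.array([center])
    radii = np.array([radius])
    # charged "in protein": uniform protein dielectric (deeply buried limit)
    phi_prot = solve_fdpb(atoms, radii, charges, params, spacing=spacing,
                          padding=padding, uniform_eps=params.eps_protein)
    # charged "in water": the atom cavity alone, solvent outside, no salt
    phi_wat = solve_fdpb(atoms, radii, charges, params, spacing=spacing,
                         padding=padding, ionic=False)
    dphi = phi_prot.interpolate(center)[0] - phi_wat.interpolate(center)[0]
    return 0.5 * charge * dphi


def born_analytic(radius: float, charge: float,
                  params: ElectrostaticParameters) -> float:
    """Closed-form Born transfer energy (k q^2 / 2a)(1/eps_p - 1/eps_w)."""
    return (params.coulomb_k * charge ** 2 / (2.0 * radius)
            * (1.0 / params.eps_protein - 1.0 / params.eps_solvent))
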