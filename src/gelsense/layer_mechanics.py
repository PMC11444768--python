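"""Effective stiffness felt by a contracting patch on a finite-thickness gel.

A cell adhering to a soft hydrogel bonded to glass does not feel the bulk
modulus alone: when the layer is thin compared with the cell footprint, or
laterally constrained, the rigid support raises the force needed per unit
surface displacement.  This module computes that apparent stiffness ``k``
(force per unit displacement of a rigid circular patch of radius ``a``) for a
linear-elastic layer of thickness ``h`` bonded to a rigid base, and the ratio
``k_infinity / k(h)`` used to attenuate synthetic traction fields.

The solver is an axisymmetric Fourier-harmonic finite-element discretisation
(bilinear quadrilaterals, selective reduced integration so near-incompressible
gels do not lock):

* ``loading="normal"`` — harmonic n = 0, rigid frictionless punch pressed
  vertically; half-space limit ``k = 2 E a / (1 - nu^2)``.
* ``loading="tangential"`` — harmonic n = 1, rigid in-plane translation with
  zero normal traction on the patch; half-space limit ``k = 8 G a / (2 - nu)``.

Every reported stiffness is checked by nested mesh doubling; a drift above
``rtol_mesh`` raises :class:`~gelsense.errors.NumericalError`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConfigError, NumericalError

__all__ = [
    "LayerSpec",
    "PunchSpec",
    "MeshControls",
    "StiffnessResult",
    "halfspace_stiffness",
    "effective_stiffness",
    "stiffness_curve",
    "attenuation_factor",
]

_NU_CAP = 0.499


@dataclass(frozen=True)
class LayerSpec:
    """Linear-elastic layer on a rigid support.

    Parameters
    ----------
    E : float
        Elastic modulus in kPa.
    nu : float
        Poisson ratio.  Gel-realistic values are 0.45-0.5; ``nu == 0.5`` is
        replaced by 0.499 with a warning (the solver needs compressibility).
    h : float
        Layer thickness in µm.
    R_lateral : float
        Radius of a rigid outer wall (zero displacement) in µm, or ``inf``
        for a laterally unbounded layer.
    """

    E: float
    nu: float = 0.48
    h: float = 200.0
    R_lateral: float = math.inf

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ConfigError(f"elastic modulus must be positive, got {self.E}")
        if not 0.0 <= self.nu <= 0.5:
            raise ConfigError(f"Poisson ratio must be in [0, 0.5], got {self.nu}")
        if self.nu >= _NU_CAP:
            warnings.warn(
                f"nu={self.nu} capped at {_NU_CAP} to avoid incompressibility "
                "locking in the numeric solver",
                stacklevel=3,
            )
            object.__setattr__(self, "nu", _NU_CAP)
        if self.h <= 0:
            raise ConfigError(f"thickness must be positive, got {self.h}")
        if self.R_lateral <= 0:
            raise ConfigError("R_lateral must be positive")

    @property
    def G(self) -> float:
        """Shear modulus, same units as ``E``."""
        return self.E / (2.0 * (1.0 + self.nu))


@dataclass(frozen=True)
class PunchSpec:
    """Rigid circular loading patch — an idealised cell adhesion footprint.

    ``a`` is the patch radius in µm (default 25, the order of measured cell
    spread radii); ``loading`` selects vertical indentation or in-plane
    translation.
    """

    a: float = 25.0
    loading: str = "normal"

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ConfigError(f"patch radius must be positive, got {self.a}")
        if self.loading not in ("normal", "tangential"):
            raise ConfigError(
                f"loading must be 'normal' or 'tangential', got {self.loading!r}"
            )


@dataclass(frozen=True)
class MeshControls:
    """Discretisation controls for :func:`effective_stiffness`.

    ``n_a`` bilinear elements span the patch radius, graded toward the contact
    edge (where the stress is singular); element size then grows geometrically
    by ``growth`` outward and downward.  A laterally unbounded layer is
    truncated traction-free at ``r_max_over_a * a``.  ``rtol_mesh`` is the
    allowed stiffness drift under one nested mesh doubling.
    """

    n_a: int = 20
    growth: float = 1.25
    r_max_over_a: float = 20.0
    rtol_mesh: float = 0.02
    check_convergence: bool = True

    def __post_init__(self) -> None:
        if self.n_a < 10:
            raise ConfigError("need at least 10 elements across the patch radius")
        if self.growth <= 1.0:
            raise ConfigError("growth ratio must exceed 1")
        if self.r_max_over_a < 20.0:
            raise ConfigError("truncation radius must be at least 20 patch radii")


@dataclass(frozen=True)
class StiffnessResult:
    """Stiffness of one layer/punch configuration with solver diagnostics."""

    k: float
    k_halfspace: float
    h_over_a: float
    loading: str
    mesh_drift: float
    n_elements: int

    @property
    def ratio(self) -> float:
        """k / k_halfspace; >= 1 for a bonded layer, -> 1 as h/a -> inf."""
        return self.k / self.k_halfspace


def halfspace_stiffness(layer: LayerSpec, punch: PunchSpec) -> float:
    """Closed-form rigid-punch stiffness on an elastic half-space.

    Normal (frictionless flat punch): ``2 E a / (1 - nu^2)``.
    Tangential (shear traction, zero normal traction): ``8 G a / (2 - nu)``.
    """
    if punch.loading == "normal":
        return 2.0 * layer.E * punch.a / (1.0 - layer.nu**2)
    return 8.0 * layer.G * punch.a / (2.0 - layer.nu)


# ---------------------------------------------------------------------------
# Fourier-harmonic axisymmetric FEM
# ---------------------------------------------------------------------------

_GP = 1.0 / math.sqrt(3.0)
_GAUSS4 = [(-_GP, -_GP), (_GP, -_GP), (_GP, _GP), (-_GP, _GP)]


def _graded_fixed(x0: float, x1: float, n: int, growth: float, fine_at_end: bool) -> np.ndarray:
    """n elements over [x0, x1], sizes in geometric progression."""
    sizes = growth ** np.arange(n, dtype=float)
    if fine_at_end:
        sizes = sizes[::-1]
    sizes *= (x1 - x0) / sizes.sum()
    return np.concatenate(([x0], x0 + np.cumsum(sizes)))


def _graded_open(x0: float, x1: float, s_fine: float, growth: float, fine_at_start: bool) -> np.ndarray:
    """Geometric grading from a prescribed fine size until [x0, x1] is filled."""
    length = x1 - x0
    n = max(2, math.ceil(math.log1p(length * (growth - 1.0) / s_fine) / math.log(growth)))
    sizes = s_fine * growth ** np.arange(n, dtype=float)
    sizes *= length / sizes.sum()
    if not fine_at_start:
        sizes = sizes[::-1]
    return np.concatenate(([x0], x0 + np.cumsum(sizes)))


def _build_mesh(a: float, h: float, r_max: float, mesh: MeshControls) -> tuple[np.ndarray, np.ndarray]:
    r_in = _graded_fixed(0.0, a, mesh.n_a, mesh.growth ** 0.5, fine_at_end=True)
    s_edge = r_in[-1] - r_in[-2]
    r_out = _graded_open(a, r_max, s_edge, mesh.growth, fine_at_start=True)
    r = np.concatenate((r_in, r_out[1:]))
    z_rev = _graded_open(0.0, h, s_edge, mesh.growth, fine_at_start=True)
    # grade fine toward the loaded surface z = h
    z = h - z_rev[::-1]
    z[0] = 0.0
    return r, z


def _refine(x: np.ndarray) -> np.ndarray:
    """Nested refinement: insert the midpoint of every interval."""
    mid = 0.5 * (x[:-1] + x[1:])
    out = np.empty(x.size + mid.size)
    out[0::2] = x
    out[1::2] = mid
    return out


def _elastic_d_matrices(E: float, nu: float, harmonic: int) -> tuple[np.ndarray, np.ndarray]:
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    nstr = 4 if harmonic == 0 else 6
    nshear = 1 if harmonic == 0 else 3
    d_mu = np.diag([2.0 * mu] * 3 + [mu] * nshear)
    m = np.zeros(nstr)
    m[:3] = 1.0
    d_lam = lam * np.outer(m, m)
    return d_mu, d_lam


def _b_matrix(harmonic: int, N: np.ndarray, dNr: np.ndarray, dNz: np.ndarray, r: float) -> np.ndarray:
    """Strain-displacement matrix at one integration point.

    Harmonic displacement ansatz: u_r = u cos(n t), u_theta = v sin(n t),
    u_z = w cos(n t).  Strain order (rr, tt, zz, rz[, rt, tz]); node dof
    order (u, w) for n = 0 and (u, v, w) for n = 1.
    """
    n = harmonic
    if n == 0:
        B = np.zeros((4, 8))
        B[0, 0::2] = dNr
        B[1, 0::2] = N / r
        B[2, 1::2] = dNz
        B[3, 0::2] = dNz
        B[3, 1::2] = dNr
        return B
    B = np.zeros((6, 12))
    B[0, 0::3] = dNr
    B[1, 0::3] = N / r
    B[1, 1::3] = n * N / r
    B[2, 2::3] = dNz
    B[3, 0::3] = dNz
    B[3, 2::3] = dNr
    B[4, 0::3] = -n * N / r
    B[4, 1::3] = dNr - N / r
    B[5, 1::3] = dNz
    B[5, 2::3] = -n * N / r
    return B


def _shape(xi: float, eta: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    N = 0.25 * np.array(
        [(1 - xi) * (1 - eta), (1 + xi) * (1 - eta), (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)]
    )
    dNxi = 0.25 * np.array([-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)])
    dNeta = 0.25 * np.array([-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)])
    return N, dNxi, dNeta


def assemble_stiffness(
    r_nodes: np.ndarray, z_nodes: np.ndarray, E: float, nu: float, harmonic: int
) -> sp.csr_matrix:
    """Global stiffness for the tensor-product mesh (free-free, no BCs).

    Selective reduced integration: the shear/deviatoric part uses 2x2 Gauss,
    the dilatational (lambda) part a single centroid point, which keeps
    bilinear quads usable at nu close to 0.5.
    """
    ndpn = 2 if harmonic == 0 else 3
    circ = 2.0 * math.pi if harmonic == 0 else math.pi
    nr, nz = r_nodes.size, z_nodes.size
    d_mu, d_lam = _elastic_d_matrices(E, nu, harmonic)

    rows, cols, vals = [], [], []
    shape4 = [_shape(xi, eta) for xi, eta in _GAUSS4]
    shape1 = _shape(0.0, 0.0)

    for j in range(nz - 1):
        z1, z2 = z_nodes[j], z_nodes[j + 1]
        dz = 0.5 * (z2 - z1)
        for i in range(nr - 1):
            r1, r2 = r_nodes[i], r_nodes[i + 1]
            dr = 0.5 * (r2 - r1)
            detj = dr * dz
            # node ids: (i,j), (i+1,j), (i+1,j+1), (i,j+1)
            nid = np.array([j * nr + i, j * nr + i + 1, (j + 1) * nr + i + 1, (j + 1) * nr + i])
            rloc = r_nodes[[i, i + 1, i + 1, i]].astype(float)
            ke = np.zeros((4 * ndpn, 4 * ndpn))
            for N, dNxi, dNeta in shape4:
                rgp = float(N @ rloc)
                B = _b_matrix(harmonic, N, dNxi / dr, dNeta / dz, rgp)
                ke += (B.T @ d_mu @ B) * (rgp * detj)
            N, dNxi, dNeta = shape1
            rgp = float(N @ rloc)
            B = _b_matrix(harmonic, N, dNxi / dr, dNeta / dz, rgp)
            ke += (B.T @ d_lam @ B) * (rgp * detj * 4.0)
            ke *= circ

            dofs = (nid[:, None] * ndpn + np.arange(ndpn)[None, :]).ravel()
            rows.append(np.repeat(dofs, dofs.size))
            cols.append(np.tile(dofs, dofs.size))
            vals.append(ke.ravel())

    n_dof = nr * nz * ndpn
    K = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_dof, n_dof),
    )
    return K.tocsr()


def _solve_patch(
    r_nodes: np.ndarray,
    z_nodes: np.ndarray,
    layer: LayerSpec,
    punch: PunchSpec,
    finite_wall: bool,
) -> float:
    """Stiffness from one mesh: prescribe unit patch motion, return 2U."""
    harmonic = 0 if punch.loading == "normal" else 1
    ndpn = 2 if harmonic == 0 else 3
    nr, nz = r_nodes.size, z_nodes.size
    n_dof = nr * nz * ndpn
    K = assemble_stiffness(r_nodes, z_nodes, layer.E, layer.nu, harmonic)

    def dof(i: int, j: int, c: int) -> int:
        return (j * nr + i) * ndpn + c

    prescribed: dict[int, float] = {}
    # bonded base
    for i in range(nr):
        for c in range(ndpn):
            prescribed[dof(i, 0, c)] = 0.0
    # rigid outer wall when laterally constrained
    if finite_wall:
        for j in range(nz):
            for c in range(ndpn):
                prescribed[dof(nr - 1, j, c)] = 0.0
    # symmetry axis
    slaves: dict[int, int] = {}
    for j in range(nz):
        if harmonic == 0:
            prescribed.setdefault(dof(0, j, 0), 0.0)  # u_r = 0
        else:
            prescribed.setdefault(dof(0, j, 2), 0.0)  # w = 0
            slaves[dof(0, j, 1)] = dof(0, j, 0)  # v = -u for finite x-motion
    # rigid patch on the surface
    on_patch = np.flatnonzero(r_nodes <= punch.a * (1.0 + 1e-9))
    for i in on_patch:
        if harmonic == 0:
            prescribed[dof(i, nz - 1, 1)] = 1.0  # w = 1, shear-free
        else:
            prescribed[dof(i, nz - 1, 0)] = 1.0  # u = 1
            sl = dof(i, nz - 1, 1)
            if sl not in slaves:
                prescribed[sl] = -1.0  # v = -1 (rigid x-translation)

    # master-slave elimination (v = -u on the axis), then partitioned solve
    masters = np.array([d for d in range(n_dof) if d not in slaves])
    red_index = -np.ones(n_dof, dtype=int)
    red_index[masters] = np.arange(masters.size)
    t_rows = list(masters)
    t_cols = list(red_index[masters])
    t_vals = [1.0] * masters.size
    for sl, ma in slaves.items():
        t_rows.append(sl)
        t_cols.append(red_index[ma])
        t_vals.append(-1.0)
    T = sp.coo_matrix((t_vals, (t_rows, t_cols)), shape=(n_dof, masters.size)).tocsr()
    Kr = (T.T @ K @ T).tocsr()

    d_red = np.zeros(masters.size)
    fixed_mask = np.zeros(masters.size, dtype=bool)
    for d, val in prescribed.items():
        if d in slaves:
            continue
        ri = red_index[d]
        fixed_mask[ri] = True
        d_red[ri] = val
    free = np.flatnonzero(~fixed_mask)
    fixed = np.flatnonzero(fixed_mask)
    rhs = -Kr[free][:, fixed] @ d_red[fixed]
    d_red[free] = spla.spsolve(Kr[free][:, free].tocsc(), rhs)

    d_full = T @ d_red
    energy = 0.5 * float(d_full @ (K @ d_full))
    return 2.0 * energy  # k = 2U / delta^2 with delta = 1


def effective_stiffness(
    layer: LayerSpec, punch: PunchSpec, mesh: MeshControls | None = None
) -> StiffnessResult:
    """Apparent stiffness of a rigid patch on a bonded finite-thickness layer.

    Solves axisymmetric linear elasticity on (r, z) in [0, R] x [0, h] with a
    fully bonded base, a traction-free surface outside the rigid patch, and
    either a rigid outer wall (finite ``R_lateral``) or traction-free
    truncation at ``r_max_over_a * a``.  The stiffness is recomputed on a
    nested mesh doubling; drift above ``mesh.rtol_mesh`` raises
    :class:`NumericalError`.
    """
    mesh = mesh or MeshControls()
    finite_wall = math.isfinite(layer.R_lateral)
    if finite_wall and layer.R_lateral <= punch.a:
        raise ConfigError(
            f"R_lateral={layer.R_lateral} must exceed the patch radius a={punch.a}"
        )
    # A laterally unbounded layer is truncated traction-free.  The radius must
    # scale with h as well as a: under a net tangential load a domain with
    # R < h behaves like a bending column and fakes extra compliance.
    r_max = layer.R_lateral if finite_wall else mesh.r_max_over_a * punch.a + 2.0 * layer.h

    r_nodes, z_nodes = _build_mesh(punch.a, layer.h, r_max, mesh)
    k_coarse = _solve_patch(r_nodes, z_nodes, layer, punch, finite_wall)
    r_f, z_f = _refine(r_nodes), _refine(z_nodes)
    k_fine = _solve_patch(r_f, z_f, layer, punch, finite_wall)
    drift = abs(k_fine - k_coarse) / k_fine
    if mesh.check_convergence and drift > mesh.rtol_mesh:
        raise NumericalError(
            f"stiffness not mesh-converged: k changed {drift:.1%} "
            f"({k_coarse:.4g} -> {k_fine:.4g}) on doubling "
            f"({r_nodes.size}x{z_nodes.size} -> {r_f.size}x{z_f.size} nodes)"
        )
    return StiffnessResult(
        k=k_fine,
        k_halfspace=halfspace_stiffness(layer, punch),
        h_over_a=layer.h / punch.a,
        loading=punch.loading,
        mesh_drift=drift,
        n_elements=(r_f.size - 1) * (z_f.size - 1),
    )


def stiffness_curve(
    layer: LayerSpec,
    punch: PunchSpec,
    h_over_a: list[float] | np.ndarray,
    mesh: MeshControls | None = None,
) -> pd.DataFrame:
    """Tabulate k and k/k_halfspace over thickness-to-patch ratios.

    Returns a DataFrame with columns ``h_over_a, k, k_ratio, mesh_level``
    (mesh_level = element count of the converged mesh).
    """
    h_over_a = np.asarray(h_over_a, dtype=float)
    if h_over_a.size == 0 or np.any(h_over_a <= 0):
        raise ConfigError("h/a list must be nonempty and positive")
    rows = []
    for hoa in h_over_a:
        res = effective_stiffness(replace(layer, h=hoa * punch.a), punch, mesh)
        rows.append(
            {"h_over_a": hoa, "k": res.k, "k_ratio": res.ratio, "mesh_level": res.n_elements}
        )
    return pd.DataFrame(rows)


def attenuation_factor(
    layer: LayerSpec, punch: PunchSpec, h: float | None = None, mesh: MeshControls | None = None
) -> float:
    """Displacement attenuation k_halfspace / k(h), in (0, 1].

    For equal traction, a cell on a thin bonded layer produces displacements
    reduced by this factor relative to the half-space; it is independent of E
    (the modulus cancels in the ratio) and tends to 1 as h/a grows.
    """
    if h is not None:
        layer = replace(layer, h=h)
    res = effective_stiffness(layer, punch, mesh)
    return min(1.0, 1.0 / res.ratio)
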