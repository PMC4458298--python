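"""Finite-element forward model for continuous-wave fluorescence diffusion.

Photon transport at the excitation and emission wavelengths is modelled by
the coupled diffusion equations

    div(D_x grad phi_x) - mu_ax phi_x = -q            (excitation)
    div(D_m grad phi_m) - mu_am phi_m = -x * phi_x    (emission)

with D = 1 / (3 (mu_a + mu_s')) and a Robin boundary condition
phi + 2 A_n D dphi/dn = 0, where A_n accounts for the refractive-index
mismatch at the tissue-air interface (Groenhuis approximation; A_n = 1 for
a matched boundary).  The fluorescent yield x = eta * mu_af acts as the
emission source; the weight matrix assembled here maps a nodal yield
vector linearly to boundary photon-density readings.

Discretization: piecewise-linear (P1) Galerkin elements on the structured
triangulations of :mod:`fmtunmix.mesh`.  The laser is modelled as an
isotropic point source placed one transport mean free path (1/mu_s')
inside the boundary, the standard diffusion-theory convention for a
collimated beam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import k0

from .errors import (
    InvalidDetectorError,
    InvalidParameterError,
    MeshQualityError,
    SolverFailureError,
)
from .mesh import Mesh, locate_point

_DEGENERATE_AREA = 1e-12  # mm^2


@dataclass(frozen=True)
class OpticalProperties:
    """Homogeneous optical coefficients at the excitation (x) and emission
    (m) wavelengths, all in mm^-1; refractive index is dimensionless."""

    mu_a_x: float
    mu_s_prime_x: float
    mu_a_m: float
    mu_s_prime_m: float
    refractive_index: float = 1.0

    def __post_init__(self):
        for name in ("mu_a_x", "mu_s_prime_x", "mu_a_m", "mu_s_prime_m",
                     "refractive_index"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")

    def diffusion(self, tag: str) -> float:
        mu_a, mu_s = self._coeffs(tag)
        return 1.0 / (3.0 * (mu_a + mu_s))

    def absorption(self, tag: str) -> float:
        return self._coeffs(tag)[0]

    def _coeffs(self, tag: str):
        if tag == "excitation":
            return self.mu_a_x, self.mu_s_prime_x
        if tag == "emission":
            return self.mu_a_m, self.mu_s_prime_m
        raise InvalidParameterError(f"unknown wavelength tag {tag!r}")

    def boundary_mismatch(self) -> float:
        """Robin coefficient A_n.

        For a matched boundary (n = 1) A_n = 1.  Otherwise the Groenhuis
        polynomial fit of the internal diffuse reflectance r_d is used:
        A_n = (1 + r_d) / (1 - r_d).
        """
        n = self.refractive_index
        if n == 1.0:
            return 1.0
        r_d = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
        return (1.0 + r_d) / (1.0 - r_d)


@dataclass(frozen=True)
class ExcitationSource:
    """Isotropic point source: position in mm, power in arbitrary units."""

    position: tuple
    power: float = 1.0

    def __post_init__(self):
        if self.power <= 0:
            raise InvalidParameterError("source power must be > 0")


@dataclass(frozen=True)
class FieldSolution:
    """Nodal photon density at one wavelength."""

    values: np.ndarray
    wavelength_tag: str


@dataclass
class DiffusionOperator:
    """Assembled sparse system D*stiffness + mu_a*mass + Robin boundary mass.

    Symmetric positive definite; the LU factorization is cached so that
    repeated solves (adjoint assembly, multiple sources) are cheap.
    """

    matrix: sp.csr_matrix
    mesh: Mesh
    props: OpticalProperties
    wavelength_tag: str
    _lu: object = field(default=None, repr=False)

    def solve(self, rhs: np.ndarray, rtol: float = 1e-8) -> np.ndarray:
        if self._lu is None:
            try:
                self._lu = spla.splu(self.matrix.tocsc())
            except RuntimeError as exc:  # singular factorization
                raise SolverFailureError(str(exc)) from exc
        phi = self._lu.solve(rhs)
        if not np.all(np.isfinite(phi)):
            raise SolverFailureError("non-finite solution")
        res = np.linalg.norm(self.matrix @ phi - rhs)
        scale = np.linalg.norm(rhs)
        if scale > 0 and res > rtol * scale:
            raise SolverFailureError(f"relative residual {res / scale:.2e} > {rtol:.0e}")
        return phi


def _p1_matrices(mesh: Mesh):
    """Element-wise P1 stiffness and consistent mass matrices (COO data)."""
    tris = mesh.triangles
    p = mesh.nodes[tris]  # (m, 3, 2)
    x, y = p[..., 0], p[..., 1]
    area = 0.5 * ((x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0])
                  - (x[:, 2] - x[:, 0]) * (y[:, 1] - y[:, 0]))
    if np.any(area < _DEGENERATE_AREA):
        raise MeshQualityError("degenerate triangle (area < 1e-12 mm^2)")
    # gradients of the barycentric basis functions
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    Ke = (b[:, :, None] * b[:, None, :] + c[:, :, None] * c[:, None, :]) \
        / (4.0 * area)[:, None, None]
    Mloc = np.array([[2.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 2.0]]) / 12.0
    Me = area[:, None, None] * Mloc[None]
    rows = np.repeat(tris, 3, axis=1).ravel()
    cols = np.tile(tris, (1, 3)).ravel()
    return rows, cols, Ke.ravel(), Me.ravel()


def mass_matrix(mesh: Mesh) -> sp.csr_matrix:
    """Consistent P1 mass matrix (integral of products of basis functions)."""
    rows, cols, _, me = _p1_matrices(mesh)
    n = mesh.n_nodes
    return sp.coo_matrix((me, (rows, cols)), shape=(n, n)).tocsr()


def stiffness_matrix(mesh: Mesh) -> sp.csr_matrix:
    rows, cols, ke, _ = _p1_matrices(mesh)
    n = mesh.n_nodes
    return sp.coo_matrix((ke, (rows, cols)), shape=(n, n)).tocsr()


def boundary_mass_matrix(mesh: Mesh) -> sp.csr_matrix:
    """Line-integral mass matrix over the boundary edges."""
    e = mesh.boundary_edges
    L = np.linalg.norm(mesh.nodes[e[:, 1]] - mesh.nodes[e[:, 0]], axis=1)
    Mloc = np.array([[2.0, 1.0], [1.0, 2.0]]) / 6.0
    Me = L[:, None, None] * Mloc[None]
    rows = np.repeat(e, 2, axis=1).ravel()
    cols = np.tile(e, (1, 2)).ravel()
    n = mesh.n_nodes
    return sp.coo_matrix((Me.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def assemble_diffusion_operator(mesh: Mesh, props: OpticalProperties,
                                wavelength_tag: str) -> DiffusionOperator:
    """Assemble D*K + mu_a*M + (1/(2 A_n)) * boundary mass.

    The Robin term makes the operator strictly positive definite even for
    vanishing absorption.
    """
    D = props.diffusion(wavelength_tag)
    mu_a = props.absorption(wavelength_tag)
    A_n = props.boundary_mismatch()
    M = (D * stiffness_matrix(mesh)
         + mu_a * mass_matrix(mesh)
         + boundary_mass_matrix(mesh) / (2.0 * A_n))
    return DiffusionOperator(matrix=M.tocsr(), mesh=mesh, props=props,
                             wavelength_tag=wavelength_tag)


def point_load(mesh: Mesh, position, power: float = 1.0) -> np.ndarray:
    """Load vector of an isotropic point source: delta distributed over the
    containing triangle with barycentric weights."""
    tri_id, bary = locate_point(mesh, position[0], position[1])
    rhs = np.zeros(mesh.n_nodes)
    rhs[mesh.triangles[tri_id]] = power * bary
    return rhs


def solve_excitation(operator: DiffusionOperator, source: ExcitationSource,
                     mesh: Mesh) -> FieldSolution:
    """Excitation photon density for one point source."""
    rhs = point_load(mesh, source.position, source.power)
    phi = operator.solve(rhs)
    return FieldSolution(values=phi, wavelength_tag=operator.wavelength_tag)


@dataclass(frozen=True)
class SystemMatrix:
    """Linear map from nodal fluorescent yield to boundary measurements.

    Row (s, d) (source-major order) gives the emission photon density at
    detector node ``detector_node_ids[d]`` under excitation source ``s``
    per unit yield at each node.
    """

    matrix: np.ndarray  # (n_sources * n_detectors, n_nodes)
    detector_node_ids: np.ndarray
    mesh: Mesh
    sources: tuple

    @property
    def n_measurements(self) -> int:
        return self.matrix.shape[0]

    def apply(self, yield_vector: np.ndarray) -> np.ndarray:
        return self.matrix @ yield_vector


def build_weight_matrix(mesh: Mesh, props: OpticalProperties,
                        sources, detector_node_ids) -> SystemMatrix:
    """Assemble the measurement weight matrix by adjoint emission solves.

    For each detector node d the adjoint field g_d = K_m^{-1} e_d is
    computed once (the emission operator is symmetric, so the adjoint
    equals a forward solve); the row for (source s, detector d) is then
    (M g_d) * phi_x,s elementwise, which equals the emission reading at d
    produced by a unit yield at each node.
    """
    detector_node_ids = np.asarray(detector_node_ids, dtype=np.int64)
    if len(sources) == 0 or detector_node_ids.size == 0:
        raise InvalidParameterError("need at least one source and one detector")
    bset = set(mesh.boundary_node_ids.tolist())
    for d in detector_node_ids:
        if int(d) not in bset:
            raise InvalidDetectorError(f"node {int(d)} is not a boundary node")

    op_x = assemble_diffusion_operator(mesh, props, "excitation")
    op_m = assemble_diffusion_operator(mesh, props, "emission")
    M = mass_matrix(mesh)

    phis = [solve_excitation(op_x, s, mesh).values for s in sources]
    adj = np.empty((detector_node_ids.size, mesh.n_nodes))
    for i, d in enumerate(detector_node_ids):
        e = np.zeros(mesh.n_nodes)
        e[int(d)] = 1.0
        adj[i] = M @ op_m.solve(e)

    rows = np.empty((len(sources) * detector_node_ids.size, mesh.n_nodes))
    for s_idx, phi in enumerate(phis):
        rows[s_idx * detector_node_ids.size:(s_idx + 1) * detector_node_ids.size] = \
            adj * phi[None, :]
    return SystemMatrix(matrix=rows, detector_node_ids=detector_node_ids,
                        mesh=mesh, sources=tuple(sources))


def concentration_to_yield(concentration: float, epsilon: float, eta: float) -> float:
    """Fluorescent yield eta * mu_af with mu_af = ln(10) * epsilon * C."""
    if concentration < 0 or epsilon < 0 or eta < 0:
        raise InvalidParameterError("concentration, epsilon and eta must be >= 0")
    return eta * np.log(10.0) * epsilon * concentration


def infinite_medium_green(r, mu_a: float, mu_s_prime: float, power: float = 1.0):
    """Analytic 2-D infinite-medium diffusion Green's function.

    phi(r) = P * K0(mu_eff r) / (2 pi D), mu_eff = sqrt(mu_a / D).
    Used as the independent oracle for forward-model validation.
    """
    D = 1.0 / (3.0 * (mu_a + mu_s_prime))
    mu_eff = np.sqrt(mu_a / D)
    r = np.asarray(r, dtype=float)
    return power * k0(mu_eff * r) / (2.0 * np.pi * D)


def perimeter_sources(width: float, height: float, n: int,
                      props: OpticalProperties, power: float = 1.0):
    """Place ``n`` collimated-laser equivalents evenly around the perimeter,
    each one transport mean free path inside the boundary."""
    off = 1.0 / props.mu_s_prime_x
    if 2 * off >= min(width, height):
        raise InvalidParameterError("domain too small for the source offset")
    peri = 2.0 * (width + height)
    positions = []
    for k in range(n):
        s = (k + 0.5) * peri / n
        if s < width:
            x, y = s, off
        elif s < width + height:
            x, y = width - off, s - width
        elif s < 2 * width + height:
            x, y = 2 * width + height - s, height - off
        else:
            x, y = off, 2 * (width + height) - s
        x = min(max(x, off), width - off)
        y = min(max(y, off), height - off)
        positions.append(ExcitationSource(position=(x, y), power=power))
    return positions


def boundary_detectors(mesh: Mesh, every: int = 1) -> np.ndarray:
    """Subsample the boundary nodes (ordered along the perimeter) as
    detector locations."""
    ids = mesh.boundary_node_ids
    w, h = mesh.extent
    xy = mesh.nodes[ids]
    ang = np.arctan2(xy[:, 1] - h / 2.0, xy[:, 0] - w / 2.0)
    order = np.argsort(ang)
    return ids[order][::every]
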