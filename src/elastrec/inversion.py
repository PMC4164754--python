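"""Regularization-free FEM direct inversion with a modulus boundary condition.

Given a smooth displacement field over a rectangular region of interest
(ROI), the per-element relative Young's modulus is reconstructed with no
regularization term of any kind:

1. ``boundary_forces`` — a one-element-thick ring of elements around the
   ROI is assigned unit modulus; the ring stiffness applied to the known
   ring-node displacements gives the nodal forces the ring exchanges with
   the ROI (the modulus boundary condition replacing force/displacement
   boundary data).
2. ``assemble_D`` — because each element stiffness is linear in its
   modulus, K(E) d = D E for a sensitivity matrix D whose column e is the
   global scatter of K_e(1) d_e; D has shape 2 N_node x N_element with
   N_node > N_element for quadrilateral elements.
3. ``solve_modulus`` — E = argmin ||P (D E - f)||_2, where f carries the
   (negated, by Newton's third law) ring forces at the ROI interface nodes
   and zeros at strictly interior nodes (static equilibrium, no body
   force), and P eliminates the hydrostatic-pressure force modes (below).

Near-incompressibility is central to the numerics. At the working Poisson
ratio (0.495) the volumetric stiffness exceeds the shear stiffness by
lambda/mu ~ 99, so the equilibrium equations weigh the dilatation content
of the displacement data ~100x more than the shear content that actually
encodes the modulus contrast. Displacement data — tracked, spline-fitted,
or interpolated from a finer solution — cannot carry the tissue's true
tiny dilatation (hence pressure) to that accuracy. Two parameter-free
steps make the solve well-posed without regularization:

* the lateral nodal displacements are corrected (minimum-norm) so every
  element preserves area exactly — the discrete form of the motion
  model's incompressibility constraint; the volumetric term of the
  mean-dilatation element then vanishes identically on the data;
* the least squares is solved orthogonally to the force modes of a smooth
  hydrostatic pressure field, discretized as bilinear pressure on the
  2x-coarser element grid (the inf-sup-stable pairing with bilinear
  displacements), because displacement data cannot determine the pressure
  an incompressible medium sustains.

Every step is linear and homogeneous of degree one in the displacements,
so the recovered modulus map is invariant to scaling the displacement
field — the mechanism behind the method's insensitivity to the amount of
applied compression. When the data is an exact solution of the same
discrete operator (forward and inverse meshes coincide), the residual at
the true modulus vector is zero and both projections leave it untouched,
so recovery is exact to solver precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import _GAUSS_PTS, _shape_derivs, QuadMesh, unit_element_stiffness_batch

logger = logging.getLogger(__name__)

__all__ = [
    "ROISpec",
    "ModulusImage",
    "InversionDomain",
    "boundary_forces",
    "assemble_D",
    "incompressibility_projection",
    "solve_modulus",
    "reconstruct",
]

#: default inversion element size (height, width) mm
DEFAULT_ELEMENT_SIZE = (0.48, 0.48)


@dataclass
class ROISpec:
    """Reconstruction region: rectangle (top, left, height, width) in mm,
    plus the uniform quadrilateral element size (default 0.48 x 0.48 mm).
    The one-element boundary ring around the rectangle must also lie inside
    the displacement-field support."""

    top: float
    left: float
    height: float
    width: float
    element_size: tuple[float, float] = DEFAULT_ELEMENT_SIZE

    @property
    def n_elements(self) -> tuple[int, int]:
        eh, ew = self.element_size
        return int(round(self.height / eh)), int(round(self.width / ew))


@dataclass
class ModulusImage:
    """Per-element relative Young's modulus over the ROI mesh.

    ``values`` has shape (n_elem_y, n_elem_x); moduli are dimensionless
    contrasts relative to the unit boundary ring. Values are reported
    as solved — never clamped.
    """

    values: np.ndarray
    roi: ROISpec
    provenance: dict = field(default_factory=dict)

    @property
    def element_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) 1D center coordinates of the ROI element grid, mm."""
        eh, ew = self.roi.element_size
        ny, nx = self.values.shape
        x = self.roi.left + ew * (np.arange(nx) + 0.5)
        y = self.roi.top + eh * (np.arange(ny) + 0.5)
        return x, y


def _mean_dilatation_rows(corners: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-element row vectors b with b @ d_e = element-mean (exx + eyy),
    plus element areas. Shapes (Ne, 8) and (Ne,)."""
    ne = corners.shape[0]
    b = np.zeros((ne, 8))
    area = np.zeros(ne)
    for xi, eta in _GAUSS_PTS:
        dN = _shape_derivs(xi, eta)
        J = np.einsum("ra,eac->erc", dN, corners)
        detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        dNdx = np.linalg.solve(J, np.broadcast_to(dN, (ne, 2, 4)).copy())
        b[:, 0::2] += dNdx[:, 0] * detJ[:, None]
        b[:, 1::2] += dNdx[:, 1] * detJ[:, None]
        area += detJ
    return b / area[:, None], area


class InversionDomain:
    """Mesh bookkeeping for one ROI: the ROI element grid plus its
    one-element unit-modulus boundary ring, with node classifications and
    the cached projection operators used by the solve."""

    def __init__(self, roi: ROISpec):
        eh, ew = roi.element_size
        ny, nx = roi.n_elements
        if ny < 3 or nx < 3:
            raise ValueError("ROI must span at least 3 elements per axis")
        if abs(ny * eh - roi.height) > 1e-6 or abs(nx * ew - roi.width) > 1e-6:
            raise ValueError("element size does not divide the ROI extent")
        self.roi = roi
        # full mesh covers ROI plus the ring: (ny+2) x (nx+2) elements
        self.full_mesh = QuadMesh.regular(
            (roi.left - ew, roi.top - eh),
            (roi.height + 2 * eh, roi.width + 2 * ew),
            (eh, ew),
        )
        ney, nex = ny + 2, nx + 2
        eiy, eix = np.divmod(np.arange(ney * nex), nex)
        self.ring_elements = np.flatnonzero(
            (eiy == 0) | (eiy == ney - 1) | (eix == 0) | (eix == nex - 1)
        )
        self.roi_elements = np.flatnonzero(
            (eiy > 0) & (eiy < ney - 1) & (eix > 0) & (eix < nex - 1)
        )
        # node grid of the full mesh is (ney+1) x (nex+1)
        niy, nix = np.divmod(np.arange((ney + 1) * (nex + 1)), nex + 1)
        in_roi_block = (niy >= 1) & (niy <= ney - 1) & (nix >= 1) & (nix <= nex - 1)
        self.roi_nodes = np.flatnonzero(in_roi_block)
        on_interface = in_roi_block & (
            (niy == 1) | (niy == ney - 1) | (nix == 1) | (nix == nex - 1)
        )
        self.interface_nodes = np.flatnonzero(on_interface)
        self.interior_nodes = np.flatnonzero(in_roi_block & ~on_interface)
        # local numbering of ROI nodes
        self._roi_local = np.full(self.full_mesh.n_nodes, -1, dtype=np.int64)
        self._roi_local[self.roi_nodes] = np.arange(self.roi_nodes.size)
        self.n_roi_nodes = self.roi_nodes.size
        self.n_roi_elements = self.roi_elements.size
        assert self.n_roi_nodes > self.n_roi_elements

    def node_displacements(
        self, displacement: Callable[[np.ndarray, np.ndarray], tuple]
    ) -> np.ndarray:
        """Full-mesh nodal displacement vector (2 N_node,) sampled from a
        ``(x, y) -> (u, v)`` callable (e.g. the spline model)."""
        c = self.full_mesh.node_coords
        u, v = displacement(c[:, 0], c[:, 1])
        d = np.empty(2 * self.full_mesh.n_nodes)
        d[0::2] = np.ravel(u)
        d[1::2] = np.ravel(v)
        return d

    def roi_dofs(self, nodes: np.ndarray) -> np.ndarray:
        """ROI-local dof indices for full-mesh node indices."""
        loc = self._roi_local[nodes]
        return np.column_stack([2 * loc, 2 * loc + 1]).ravel()

    def incompressibility_system(self) -> tuple[sp.csr_matrix, sp.csr_matrix]:
        """(A_u, A_v): sparse maps from nodal u / v values to the
        element-mean dilatations of every element of the full mesh."""
        bbar, _ = _mean_dilatation_rows(self.full_mesh.element_corners)
        conn = self.full_mesh.connectivity
        rows = np.repeat(np.arange(self.full_mesh.n_elements), 4)
        n = self.full_mesh.n_nodes
        Au = sp.csr_matrix(
            (bbar[:, 0::2].ravel(), (rows, conn.ravel())),
            shape=(self.full_mesh.n_elements, n),
        )
        Av = sp.csr_matrix(
            (bbar[:, 1::2].ravel(), (rows, conn.ravel())),
            shape=(self.full_mesh.n_elements, n),
        )
        return Au, Av

    def pressure_force_basis(self) -> sp.csc_matrix:
        """Force modes G of a smooth hydrostatic pressure over the ROI.

        The pressure space is bilinear on the 2x-coarser element grid (the
        stable pairing with bilinear displacements); column k of G is the
        nodal force pattern of pressure basis function q_k acting through
        the element-mean volumetric coupling: G = B^T diag(A_e) Q, where B
        maps ROI-local dofs to element-mean dilatations and Q evaluates
        q_k at element centers.
        """
        corners = self.full_mesh.element_corners[self.roi_elements]
        bbar, area = _mean_dilatation_rows(corners)
        gdofs = self.full_mesh.dof_indices()[self.roi_elements]
        ldofs = self._roi_local[gdofs // 2] * 2 + gdofs % 2
        ne = self.n_roi_elements
        rows = np.repeat(np.arange(ne), 8)
        B_int = sp.csr_matrix(
            ((bbar * area[:, None]).ravel(), (rows, ldofs.ravel())),
            shape=(ne, 2 * self.n_roi_nodes),
        )
        ny, nx = self.roi.n_elements
        eiy, eix = np.divmod(np.arange(ne), nx)
        n_py = ny // 2 + 1
        n_px = nx // 2 + 1
        cy = np.minimum((eiy + 0.5) / 2.0, n_py - 1 - 1e-9)
        cx = np.minimum((eix + 0.5) / 2.0, n_px - 1 - 1e-9)
        iy, ix = cy.astype(np.int64), cx.astype(np.int64)
        ty, tx = cy - iy, cx - ix
        prows = np.repeat(np.arange(ne), 4)
        pcols = np.column_stack(
            [
                iy * n_px + ix,
                iy * n_px + ix + 1,
                (iy + 1) * n_px + ix,
                (iy + 1) * n_px + ix + 1,
            ]
        ).ravel()
        pvals = np.column_stack(
            [(1 - tx) * (1 - ty), tx * (1 - ty), (1 - tx) * ty, tx * ty]
        ).ravel()
        Q = sp.csr_matrix((pvals, (prows, pcols)), shape=(ne, n_py * n_px))
        return (B_int.T @ Q).tocsc()


def _element_force_columns(
    domain: InversionDomain, elements: np.ndarray, d_full: np.ndarray, poisson: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-element nodal force vectors K_e(1) d_e and their global dof
    indices, shapes (n, 8)."""
    Kunit = unit_element_stiffness_batch(domain.full_mesh, poisson)[elements]
    dofs = domain.full_mesh.dof_indices()[elements]
    f_el = np.einsum("eij,ej->ei", Kunit, d_full[dofs])
    return f_el, dofs


def boundary_forces(
    domain: InversionDomain, d_full: np.ndarray, poisson: float = 0.495
) -> np.ndarray:
    """Nodal forces of the unit-modulus boundary ring, f = K_ring d_ring.

    Returns a full-mesh-sized vector (2 N_node,) supported on ring nodes:
    the outer perimeter and the ROI interface. The interface entries are
    the forces the ROI exerts on the ring.
    """
    f_el, dofs = _element_force_columns(domain, domain.ring_elements, d_full, poisson)
    f = np.zeros(2 * domain.full_mesh.n_nodes)
    np.add.at(f, dofs.ravel(), f_el.ravel())
    return f


def assemble_D(
    domain: InversionDomain, d_full: np.ndarray, poisson: float = 0.495
) -> sp.csr_matrix:
    """Modulus-sensitivity matrix D (2 N_node x N_element, ROI numbering).

    Column e is the ROI-local scatter of K_e(1) d_e, so D @ E equals
    K_roi(E) @ d for any element modulus vector E.
    """
    f_el, dofs = _element_force_columns(domain, domain.roi_elements, d_full, poisson)
    local_rows = domain._roi_local[dofs // 2] * 2 + dofs % 2
    cols = np.repeat(np.arange(domain.n_roi_elements), 8)
    return sp.coo_matrix(
        (f_el.ravel(), (local_rows.ravel(), cols)),
        shape=(2 * domain.n_roi_nodes, domain.n_roi_elements),
    ).tocsr()


def incompressibility_projection(
    domain: InversionDomain, d_full: np.ndarray
) -> np.ndarray:
    """Minimum-norm correction of the lateral nodal displacements so that
    every element of the full (ROI + ring) mesh preserves area exactly.

    The discrete counterpart of deriving the lateral field from
    plane-strain incompressibility: the axial data is trusted and left
    untouched; the lateral dofs absorb the (small, ~1e-3 mm) correction.
    """
    Au, Av = domain.incompressibility_system()
    u = d_full[0::2].copy()
    v = d_full[1::2]
    r = -(Au @ u + Av @ v)
    AAt = (Au @ Au.T).tocsc()
    try:
        du = Au.T @ spla.splu(AAt).solve(r)
    except RuntimeError:  # rank-deficient constraint set: fall back to lsqr
        du = spla.lsqr(Au, r, atol=1e-13, btol=1e-13, iter_lim=20000)[0]
    u = u + du
    resid = np.abs(Au @ u + Av @ v).max()
    if resid > 1e-9:
        raise np.linalg.LinAlgError(
            f"incompressibility projection did not converge (residual {resid:g})"
        )
    out = d_full.copy()
    out[0::2] = u
    return out


def solve_modulus(
    D: sp.csr_matrix,
    f_full: np.ndarray,
    pressure_basis: sp.spmatrix | None = None,
    cond_limit: float = 1e12,
) -> tuple[np.ndarray, dict]:
    """Least-squares modulus solve E = argmin ||P (D E - f)||_2.

    ``pressure_basis`` (G) spans the force modes of the smooth hydrostatic
    pressure field that displacement data cannot determine; P is the
    orthogonal projector onto its complement (P = I when G is None). The
    solve itself is an unregularized dense Cholesky of the projected
    normal equations; a rank-deficient system (too-small ROI or degenerate
    displacement field) raises with a condition estimate. Returns
    (E, info) with the residual norm and condition estimate.
    """
    f_full = np.asarray(f_full, float)
    Dd = D.toarray()
    if pressure_basis is not None and pressure_basis.shape[1] > 0:
        G = pressure_basis
        lu_g = spla.splu((G.T @ G).tocsc())
        PD = Dd - G @ lu_g.solve(G.T @ Dd)
        Pf = f_full - G @ lu_g.solve(G.T @ f_full)
    else:
        PD, Pf = Dd, f_full
    A = PD.T @ PD
    rhs = PD.T @ Pf
    from scipy.linalg import cho_factor, cho_solve

    try:
        cf = cho_factor(A)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"modulus normal equations rank-deficient ({exc}); the ROI may "
            "be too small or the displacement field degenerate"
        ) from exc
    # condition estimate: power iteration (largest) / inverse iteration
    rng = np.random.default_rng(0)
    x = rng.standard_normal(A.shape[0])
    for _ in range(12):
        x = A @ x
        x /= np.linalg.norm(x)
    lam_max = float(x @ (A @ x))
    y = rng.standard_normal(A.shape[0])
    for _ in range(12):
        y = cho_solve(cf, y)
        y /= np.linalg.norm(y)
    lam_min = float(y @ (A @ y))
    cond = lam_max / max(lam_min, 1e-300)
    if cond > cond_limit:
        raise np.linalg.LinAlgError(
            f"modulus normal equations numerically rank-deficient "
            f"(condition estimate {cond:.3g}); the ROI may be too small or "
            "the displacement field degenerate"
        )
    E = cho_solve(cf, rhs)
    resid = float(np.linalg.norm(PD @ E - Pf))
    info = {"residual": resid, "condition": cond}
    if np.any(E <= 0):
        logger.warning(
            "solve_modulus: %d non-positive moduli reported as-is",
            int((E <= 0).sum()),
        )
    return E, info


def reconstruct(
    displacement: Callable[[np.ndarray, np.ndarray], tuple],
    roi: ROISpec,
    poisson: float = 0.495,
    incompressible_data: bool = True,
    eliminate_pressure: bool = True,
    provenance: dict | None = None,
) -> ModulusImage:
    """Full direct inversion for one ROI.

    ``displacement`` maps (x, y) arrays in mm to (u, v) in mm — typically
    the fitted B-spline model's analytic evaluation, or an interpolator of
    theoretical FEM displacements. ``incompressible_data`` applies the
    exact element-area-preservation correction to the lateral component
    (disable only for data that is already consistent with the mesh
    operator, e.g. a same-mesh synthetic solution); ``eliminate_pressure``
    projects the solve orthogonally to the smooth pressure force modes.
    """
    domain = InversionDomain(roi)
    d_full = domain.node_displacements(displacement)
    if incompressible_data:
        d_full = incompressibility_projection(domain, d_full)
    f_ring = boundary_forces(domain, d_full, poisson)
    # ROI right-hand side: Newton's third law at the interface, zero inside
    f = np.zeros(2 * domain.n_roi_nodes)
    iface = domain.roi_dofs(domain.interface_nodes)
    ring_iface = np.column_stack(
        [2 * domain.interface_nodes, 2 * domain.interface_nodes + 1]
    ).ravel()
    f[iface] = -f_ring[ring_iface]
    D = assemble_D(domain, d_full, poisson)
    G = domain.pressure_force_basis() if eliminate_pressure else None
    E, info = solve_modulus(D, f, pressure_basis=G)
    ny, nx = roi.n_elements
    prov = {"poisson": poisson, **info}
    if provenance:
        prov.update(provenance)
    return ModulusImage(E.reshape(ny, nx), roi, prov)
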