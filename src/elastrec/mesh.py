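"""Plane-strain linear-elastic FEM core on bilinear quadrilateral meshes.

Shared by the synthetic phantom generator (forward compression solves) and
the direct modulus inversion (boundary-ring forces and the element
sensitivity matrix). Degrees of freedom are interleaved (x, y) per node,
node-major: dof ``2*n`` is the lateral displacement of node ``n`` and
``2*n + 1`` its axial displacement. Elements are mean-dilatation
(B-bar) bilinear quads with 2x2 Gauss integration of the deviatoric part,
accurate at the near-incompressible working Poisson ratio (0.495).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "QuadMesh",
    "PlaneStrainMaterial",
    "BoundaryCondition",
    "element_stiffness",
    "assemble_global",
    "solve_forward",
    "reaction_forces",
]

# 2x2 Gauss points on [-1, 1]^2 and bilinear shape-function data
_G = 1.0 / np.sqrt(3.0)
_GAUSS_PTS = [(-_G, -_G), (_G, -_G), (_G, _G), (-_G, _G)]
# reference corner order: (-1,-1), (1,-1), (1,1), (-1,1)
_XI_C = np.array([-1.0, 1.0, 1.0, -1.0])
_ETA_C = np.array([-1.0, -1.0, 1.0, 1.0])


def _shape_derivs(xi: float, eta: float) -> np.ndarray:
    """d(N_0..N_3)/d(xi, eta), shape (2, 4)."""
    dn_dxi = 0.25 * _XI_C * (1.0 + _ETA_C * eta)
    dn_deta = 0.25 * _ETA_C * (1.0 + _XI_C * xi)
    return np.stack([dn_dxi, dn_deta])


def plane_strain_elasticity(modulus: float, poisson: float) -> np.ndarray:
    """3x3 constitutive matrix C for plane strain (Voigt xx, yy, xy)."""
    e, nu = float(modulus), float(poisson)
    if e <= 0:
        raise ValueError("Young's modulus must be positive")
    if not (0.0 < nu < 0.5):
        raise ValueError("Poisson ratio must lie in (0, 0.5)")
    c = e / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return c * np.array(
        [
            [1.0 - nu, nu, 0.0],
            [nu, 1.0 - nu, 0.0],
            [0.0, 0.0, (1.0 - 2.0 * nu) / 2.0],
        ]
    )


@dataclass
class QuadMesh:
    """Regular-topology quadrilateral mesh.

    node_coords : (N_node, 2) positions in mm, columns (x lateral, y axial).
    connectivity : (N_element, 4) 0-based node indices, ordered
        (x0,y0), (x0+w,y0), (x0+w,y0+h), (x0,y0+h) for regular cells so the
        Jacobian is positive.
    shape : (n_elem_y, n_elem_x) for meshes built on a regular grid, else None.
    """

    node_coords: np.ndarray
    connectivity: np.ndarray
    shape: tuple[int, int] | None = None
    element_size: tuple[float, float] | None = None  # (height, width) mm

    def __post_init__(self) -> None:
        self.node_coords = np.asarray(self.node_coords, dtype=float)
        self.connectivity = np.asarray(self.connectivity, dtype=np.int64)
        if self.connectivity.min(initial=0) < 0 or (
            self.connectivity.size
            and self.connectivity.max() >= self.node_coords.shape[0]
        ):
            raise ValueError("connectivity indices out of range")

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.connectivity.shape[0]

    @property
    def element_corners(self) -> np.ndarray:
        """Corner coordinates per element, shape (N_element, 4, 2)."""
        return self.node_coords[self.connectivity]

    @property
    def element_centers(self) -> np.ndarray:
        return self.element_corners.mean(axis=1)

    def dof_indices(self) -> np.ndarray:
        """Global dof indices per element, shape (N_element, 8)."""
        conn = self.connectivity
        dofs = np.empty((conn.shape[0], 8), dtype=np.int64)
        dofs[:, 0::2] = 2 * conn
        dofs[:, 1::2] = 2 * conn + 1
        return dofs

    @classmethod
    def regular(
        cls,
        origin: tuple[float, float],
        extent: tuple[float, float],
        element_size: tuple[float, float],
    ) -> "QuadMesh":
        """Uniform mesh of a rectangle.

        origin = (x0, y0) mm of the top-left corner; extent = (height,
        width) mm; element_size = (height, width) mm. The element counts
        are ``round(extent / element_size)`` and must reproduce the extent
        to within 1e-6 mm.
        """
        x0, y0 = origin
        h_tot, w_tot = extent
        eh, ew = element_size
        ne_y = int(round(h_tot / eh))
        ne_x = int(round(w_tot / ew))
        if ne_y < 1 or ne_x < 1:
            raise ValueError("extent smaller than one element")
        if abs(ne_y * eh - h_tot) > 1e-6 or abs(ne_x * ew - w_tot) > 1e-6:
            raise ValueError("element size does not divide the extent")
        xs = x0 + ew * np.arange(ne_x + 1)
        ys = y0 + eh * np.arange(ne_y + 1)
        xg, yg = np.meshgrid(xs, ys)  # node (iy, ix) -> index iy*(ne_x+1)+ix
        coords = np.column_stack([xg.ravel(), yg.ravel()])
        iy, ix = np.meshgrid(np.arange(ne_y), np.arange(ne_x), indexing="ij")
        n00 = iy * (ne_x + 1) + ix
        conn = np.column_stack(
            [
                n00.ravel(),
                n00.ravel() + 1,
                n00.ravel() + ne_x + 2,
                n00.ravel() + ne_x + 1,
            ]
        )
        return cls(coords, conn, shape=(ne_y, ne_x), element_size=(eh, ew))

    def node_grid_index(self, iy: np.ndarray, ix: np.ndarray) -> np.ndarray:
        """Node index from grid position for regular meshes."""
        if self.shape is None:
            raise ValueError("mesh is not regular")
        return np.asarray(iy) * (self.shape[1] + 1) + np.asarray(ix)


@dataclass
class PlaneStrainMaterial:
    """Per-element Young's modulus (kPa or dimensionless) and Poisson ratio.

    The near-incompressible default nu = 0.495 matches quasi-static
    elastography practice for soft tissue.
    """

    youngs_modulus: np.ndarray
    poisson_ratio: float = 0.495

    def __post_init__(self) -> None:
        self.youngs_modulus = np.atleast_1d(
            np.asarray(self.youngs_modulus, dtype=float)
        )
        if np.any(self.youngs_modulus <= 0):
            raise ValueError("all element moduli must be positive")
        if not (0.0 < self.poisson_ratio < 0.5):
            raise ValueError("Poisson ratio must lie in (0, 0.5)")


@dataclass
class BoundaryCondition:
    """Prescribed-displacement constraints.

    dof_indices : global dof indices (2*node + axis, axis 0=x, 1=y)
    values : prescribed displacements in mm, same length
    """

    dof_indices: np.ndarray
    values: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        self.dof_indices = np.asarray(self.dof_indices, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.dof_indices.size != self.values.size:
            raise ValueError("dof_indices and values must have equal length")
        if np.unique(self.dof_indices).size != self.dof_indices.size:
            raise ValueError("a degree of freedom is constrained twice")
        if self.dof_indices.size < 3:
            raise ValueError(
                "at least 3 constraints are needed to remove rigid-body modes"
            )


def element_stiffness(
    corner_coords: np.ndarray, modulus: float, poisson: float
) -> np.ndarray:
    """8x8 stiffness of one bilinear quad (plane strain, mean-dilatation
    B-bar element, 2x2 Gauss).

    The volumetric part of the strain-displacement matrix is replaced at
    every quadrature point by its element average, the standard treatment
    that keeps bilinear quads accurate in the near-incompressible regime
    (nu = 0.495) used throughout this method. Rows/columns are ordered
    (node0_x, node0_y, node1_x, ...). The matrix is linear in the modulus:
    K(E) = E * K(1).
    """
    corners = np.asarray(corner_coords, dtype=float)
    if corners.shape != (4, 2):
        raise ValueError("corner_coords must be 4x2")
    if modulus <= 0:
        raise ValueError("Young's modulus must be positive")
    return float(modulus) * _element_stiffness_batch(corners[None], poisson)[0]


def _element_stiffness_batch(corners: np.ndarray, nu: float) -> np.ndarray:
    """Unit-modulus B-bar stiffness for all elements, shape (Ne, 8, 8)."""
    C = plane_strain_elasticity(1.0, nu)
    ne = corners.shape[0]
    dNdx_g = np.empty((4, ne, 2, 4))
    detJ_g = np.empty((4, ne))
    for g, (xi, eta) in enumerate(_GAUSS_PTS):
        dN = _shape_derivs(xi, eta)
        J = np.einsum("ra,eac->erc", dN, corners)  # (Ne, 2, 2)
        detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        if np.any(detJ <= 0):
            bad = int(np.argmax(detJ <= 0))
            raise ValueError(
                f"degenerate element geometry at element {bad}: "
                f"Jacobian determinant {detJ[bad]:g}"
            )
        dNdx_g[g] = np.linalg.solve(J, np.broadcast_to(dN, (ne, 2, 4)).copy())
        detJ_g[g] = detJ
    # element-average volumetric row b_bar with b @ d = eps_xx + eps_yy
    b_g = np.zeros((4, ne, 8))
    b_g[:, :, 0::2] = dNdx_g[:, :, 0]
    b_g[:, :, 1::2] = dNdx_g[:, :, 1]
    b_bar = np.einsum("ge,gei->ei", detJ_g, b_g) / detJ_g.sum(axis=0)[:, None]
    K = np.zeros((ne, 8, 8))
    for g in range(4):
        dNdx = dNdx_g[g]
        B = np.zeros((ne, 3, 8))
        B[:, 0, 0::2] = dNdx[:, 0]
        B[:, 1, 1::2] = dNdx[:, 1]
        B[:, 2, 0::2] = dNdx[:, 1]
        B[:, 2, 1::2] = dNdx[:, 0]
        # distribute the volumetric correction equally to both normal rows
        corr = 0.5 * (b_bar - b_g[g])
        B[:, 0] += corr
        B[:, 1] += corr
        K += np.einsum("eri,rs,esj,e->eij", B, C, B, detJ_g[g], optimize=True)
    return K


def unit_element_stiffness_batch(mesh: QuadMesh, poisson: float) -> np.ndarray:
    """Per-element unit-modulus stiffness matrices, shape (Ne, 8, 8).

    Uniform meshes share one geometry, so a single matrix is computed and
    broadcast.
    """
    corners = mesh.element_corners
    rel = corners - corners[:, :1, :]
    if mesh.n_elements > 1 and np.allclose(rel, rel[:1], atol=1e-12):
        k0 = element_stiffness(corners[0], 1.0, poisson)
        return np.broadcast_to(k0, (mesh.n_elements, 8, 8))
    return _element_stiffness_batch(corners, poisson)


def assemble_global(mesh: QuadMesh, material: PlaneStrainMaterial) -> sp.csr_matrix:
    """Assemble the sparse global stiffness (2 N_node x 2 N_node).

    Symmetric, positive semi-definite with exactly the three 2D rigid-body
    zero-energy modes before constraints are applied.
    """
    E = material.youngs_modulus
    if E.size == 1:
        E = np.full(mesh.n_elements, E[0])
    if E.size != mesh.n_elements:
        raise ValueError(
            f"modulus vector length {E.size} != element count {mesh.n_elements}"
        )
    Kunit = unit_element_stiffness_batch(mesh, material.poisson_ratio)
    Kel = Kunit * E[:, None, None]
    dofs = mesh.dof_indices()
    rows = np.repeat(dofs, 8, axis=1).ravel()
    cols = np.tile(dofs, (1, 8)).ravel()
    n = 2 * mesh.n_nodes
    K = sp.coo_matrix((Kel.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return K


def solve_forward(
    mesh: QuadMesh,
    material: PlaneStrainMaterial,
    bc: BoundaryCondition,
    external_forces: np.ndarray | None = None,
) -> np.ndarray:
    """Solve K d = f under prescribed-displacement constraints.

    Returns the full nodal displacement vector (2 N_node,) in mm with the
    prescribed dofs honored exactly. Raises if the constrained system is
    singular (insufficient constraints).
    """
    K = assemble_global(mesh, material)
    n = K.shape[0]
    if bc.dof_indices.max(initial=-1) >= n:
        raise ValueError("boundary condition references a dof outside the mesh")
    fixed = np.zeros(n, dtype=bool)
    fixed[bc.dof_indices] = True
    free = ~fixed
    d = np.zeros(n)
    d[bc.dof_indices] = bc.values
    f = np.zeros(n) if external_forces is None else np.asarray(external_forces, float)
    rhs = f[free] - K[np.ix_(free, fixed)] @ d[fixed]
    Kff = K[np.ix_(free, free)].tocsc()
    try:
        lu = spla.splu(Kff)
        udiag = np.abs(lu.U.diagonal())
        if udiag.size and udiag.min() < 1e-12 * max(udiag.max(), 1e-300):
            raise np.linalg.LinAlgError(
                "constrained stiffness is singular; boundary conditions do "
                "not remove all rigid-body modes"
            )
    except RuntimeError as exc:  # singular factorization
        raise np.linalg.LinAlgError(
            f"constrained stiffness is singular ({exc}); "
            "boundary conditions may not remove all rigid-body modes"
        ) from exc
    d_free = lu.solve(rhs)
    if not np.all(np.isfinite(d_free)):
        raise np.linalg.LinAlgError(
            "singular constrained system: non-finite solution"
        )
    d[free] = d_free
    return d


def reaction_forces(
    mesh: QuadMesh, material: PlaneStrainMaterial, d: np.ndarray
) -> np.ndarray:
    """Nodal forces K d for a given displacement state (reactions at
    constrained dofs, ~0 at interior equilibrium dofs)."""
    return assemble_global(mesh, material) @ np.asarray(d, float)
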