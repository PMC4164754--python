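"""Plane-strain FEM core: element stiffness, assembly, forward solves."""

import numpy as np
import pytest
import scipy.sparse as sp

from elastrec.mesh import (
    BoundaryCondition,
    PlaneStrainMaterial,
    QuadMesh,
    assemble_global,
    element_stiffness,
    plane_strain_elasticity,
    reaction_forces,
    solve_forward,
)

UNIT_SQUARE = np.array([(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)])


def bbar_stiffness_oracle(corners, modulus, poisson, n_gauss=4):
    """Independent mean-dilatation element stiffness built from first
    principles with dense Gauss quadrature.

    The volumetric part of B is replaced by its element average (computed
    with the same dense rule), the standard treatment for
    near-incompressible bilinear quads.
    """
    corners = np.asarray(corners, float)
    C = plane_strain_elasticity(modulus, poisson)
    g, w = np.polynomial.legendre.leggauss(n_gauss)
    pts = [(xi, eta, wx * we) for xi, wx in zip(g, w) for eta, we in zip(g, w)]
    xi_c = np.array([-1, 1, 1, -1.0])
    eta_c = np.array([-1, -1, 1, 1.0])

    def B_detJ(xi, eta):
        dN = np.stack(
            [0.25 * xi_c * (1 + eta_c * eta), 0.25 * eta_c * (1 + xi_c * xi)]
        )
        J = dN @ corners
        detJ = np.linalg.det(J)
        dNdx = np.linalg.solve(J, dN)
        B = np.zeros((3, 8))
        B[0, 0::2] = dNdx[0]
        B[1, 1::2] = dNdx[1]
        B[2, 0::2] = dNdx[1]
        B[2, 1::2] = dNdx[0]
        return B, detJ

    # element-average volumetric row
    num = np.zeros(8)
    den = 0.0
    for xi, eta, wt in pts:
        B, detJ = B_detJ(xi, eta)
        num += (B[0] + B[1]) * detJ * wt
        den += detJ * wt
    bbar = num / den
    K = np.zeros((8, 8))
    for xi, eta, wt in pts:
        B, detJ = B_detJ(xi, eta)
        corr = 0.5 * (bbar - (B[0] + B[1]))
        Bb = B.copy()
        Bb[0] += corr
        Bb[1] += corr
        K += Bb.T @ C @ Bb * detJ * wt
    return K


DISTORTED = np.array([(0.0, 0.1), (1.2, 0.0), (1.1, 0.9), (-0.1, 1.0)])


@pytest.mark.parametrize("corners", [UNIT_SQUARE, DISTORTED], ids=["square", "distorted"])
@pytest.mark.parametrize("nu", [0.3, 0.495])
def test_element_stiffness_matches_first_principles(corners, nu):
    K = element_stiffness(corners, 1.0, nu)
    K_ref = bbar_stiffness_oracle(corners, 1.0, nu)
    assert np.abs(K - K_ref).max() < 1e-12


def test_element_stiffness_symmetry_and_rigid_modes():
    K = element_stiffness(DISTORTED, 2.5, 0.495)
    assert np.abs(K - K.T).max() < 1e-12
    tx = np.zeros(8)
    tx[0::2] = 1.0  # uniform x translation
    ty = np.zeros(8)
    ty[1::2] = 1.0
    rot = np.empty(8)  # infinitesimal rotation u = -y, v = x
    rot[0::2] = -DISTORTED[:, 1]
    rot[1::2] = DISTORTED[:, 0]
    for mode in (tx, ty, rot):
        assert np.abs(K @ mode).max() < 1e-12


def test_element_stiffness_linear_in_modulus():
    K1 = element_stiffness(UNIT_SQUARE, 1.0, 0.3)
    K2 = element_stiffness(UNIT_SQUARE, 2.0, 0.3)
    assert np.abs(K2 - 2.0 * K1).max() == 0.0


def test_element_stiffness_rejects_degenerate_geometry():
    bowtie = np.array([(0.0, 0.0), (1.0, 1.0), (1.0, 0.0), (0.0, 1.0)])
    with pytest.raises(ValueError, match="[Jj]acobian"):
        element_stiffness(bowtie, 1.0, 0.3)
    with pytest.raises(ValueError):
        element_stiffness(UNIT_SQUARE, -1.0, 0.3)


def test_assembly_matches_dense_scatter_oracle():
    mesh = QuadMesh.regular((0.0, 0.0), (2.0, 2.0), (1.0, 1.0))
    E = np.array([1.0, 2.0, 0.5, 3.0])
    K = assemble_global(mesh, PlaneStrainMaterial(E, 0.4)).toarray()
    K_ref = np.zeros_like(K)
    for e in range(mesh.n_elements):
        Ke = element_stiffness(mesh.element_corners[e], E[e], 0.4)
        dofs = mesh.dof_indices()[e]
        for i in range(8):
            for j in range(8):
                K_ref[dofs[i], dofs[j]] += Ke[i, j]
    assert np.abs(K - K_ref).max() < 1e-12


def test_assembly_single_element_equals_element_matrix():
    mesh = QuadMesh.regular((0.0, 0.0), (1.0, 1.0), (1.0, 1.0))
    K = assemble_global(mesh, PlaneStrainMaterial(np.array([1.7]), 0.3)).toarray()
    Ke = element_stiffness(mesh.element_corners[0], 1.7, 0.3)
    dofs = mesh.dof_indices()[0]  # corner order -> global dof order
    assert np.abs(K[np.ix_(dofs, dofs)] - Ke).max() < 1e-12


def test_global_stiffness_symmetry_nullspace_and_translation():
    mesh = QuadMesh.regular((0.0, 0.0), (3.0, 4.0), (1.0, 1.0))
    K = assemble_global(mesh, PlaneStrainMaterial(np.ones(mesh.n_elements), 0.495))
    assert abs(K - K.T).max() < 1e-12
    t = np.zeros(2 * mesh.n_nodes)
    t[0::2] = 1.0
    assert np.abs(K @ t).max() < 1e-10
    # exactly three zero-energy modes
    w = np.linalg.eigvalsh(K.toarray())
    assert (np.abs(w) < 1e-9 * w.max()).sum() == 3


def test_assembly_rejects_size_mismatch():
    mesh = QuadMesh.regular((0.0, 0.0), (2.0, 2.0), (1.0, 1.0))
    with pytest.raises(ValueError, match="element count"):
        assemble_global(mesh, PlaneStrainMaterial(np.ones(3), 0.3))


def test_patch_test_on_distorted_mesh():
    """Linear boundary displacement reproduces the linear field exactly at
    interior nodes of a distorted-but-valid mesh."""
    mesh = QuadMesh.regular((0.0, 0.0), (3.0, 3.0), (1.0, 1.0))
    coords = mesh.node_coords.copy()
    gen = np.random.default_rng(7)
    interior = [5, 6, 9, 10]  # 4x4 node grid
    coords[interior] += gen.uniform(-0.2, 0.2, (len(interior), 2))
    mesh = QuadMesh(coords, mesh.connectivity, shape=None)
    # linear displacement field u = a x + b y, v = c x + d y
    a, b, c, d = 0.01, -0.004, 0.003, -0.02
    exact = np.empty(2 * mesh.n_nodes)
    exact[0::2] = a * coords[:, 0] + b * coords[:, 1]
    exact[1::2] = c * coords[:, 0] + d * coords[:, 1]
    boundary = [n for n in range(mesh.n_nodes) if n not in interior]
    dofs = np.concatenate([[2 * n, 2 * n + 1] for n in boundary])
    bc = BoundaryCondition(dofs, exact[dofs])
    sol = solve_forward(mesh, PlaneStrainMaterial(np.ones(9), 0.495), bc)
    assert np.abs(sol - exact).max() < 1e-10


def test_forward_homogeneous_compression_closed_form():
    """Slip-compressed homogeneous block: uniform axial strain, lateral
    strain nu/(1-nu) * strain (plane-strain closed form)."""
    from elastrec.phantom import PhantomSpec, simulate_compression

    nu, eps = 0.495, 0.02
    spec = PhantomSpec(extent=(10.0, 10.0), background_modulus=25.0, poisson_ratio=nu)
    field, *_ = simulate_compression(
        spec, eps, element_size=0.5,
        grid=(np.linspace(0, 10, 21), np.linspace(0, 10, 21)),
    )
    assert np.abs(field.axial_strain() + eps).max() < 1e-8
    exx = field.lateral_strain()[5:15, 5:15]
    assert np.abs(exx - nu / (1 - nu) * eps).max() < 1e-8


def test_forward_zero_bc_and_modulus_scaling():
    mesh = QuadMesh.regular((0.0, 0.0), (4.0, 4.0), (1.0, 1.0))
    from elastrec.phantom import compression_bc

    bc = compression_bc(mesh, 0.01)
    E = np.ones(mesh.n_elements)
    d1 = solve_forward(mesh, PlaneStrainMaterial(E, 0.4), bc)
    d5 = solve_forward(mesh, PlaneStrainMaterial(5 * E, 0.4), bc)
    # prescribed-displacement solution independent of the modulus scale
    assert np.abs(d1 - d5).max() < 1e-12
    # reactions scale linearly with the moduli
    f1 = reaction_forces(mesh, PlaneStrainMaterial(E, 0.4), d1)
    f5 = reaction_forces(mesh, PlaneStrainMaterial(5 * E, 0.4), d5)
    assert np.abs(f5 - 5 * f1).max() < 1e-10 * np.abs(f1).max()
    # equilibrium: reactions sum to zero per axis
    assert abs(f1[0::2].sum()) < 1e-9 * np.abs(f1).max()
    assert abs(f1[1::2].sum()) < 1e-9 * np.abs(f1).max()
    # zero prescribed displacement -> zero field
    bc0 = BoundaryCondition(bc.dof_indices, np.zeros_like(bc.values))
    assert np.abs(solve_forward(mesh, PlaneStrainMaterial(E, 0.4), bc0)).max() == 0.0


def test_forward_insufficient_constraints_raises():
    mesh = QuadMesh.regular((0.0, 0.0), (2.0, 2.0), (1.0, 1.0))
    # three x-dofs leave the y-translation mode unconstrained
    bc = BoundaryCondition(np.array([0, 2, 4]), np.zeros(3))
    with pytest.raises(np.linalg.LinAlgError):
        solve_forward(mesh, PlaneStrainMaterial(np.ones(4), 0.3), bc)


def test_boundary_condition_validation():
    with pytest.raises(ValueError, match="twice"):
        BoundaryCondition(np.array([0, 0, 1]), np.zeros(3))
    with pytest.raises(ValueError, match="3 constraints"):
        BoundaryCondition(np.array([0, 1]), np.zeros(2))
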