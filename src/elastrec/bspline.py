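"""Bicubic B-spline (free-form deformation) tissue displacement model.

The axial field V and lateral field U are tensor-product uniform cubic
B-splines over a regular knot grid:

    V(x, y) = sum_{m,n=0..3} B_m(p) B_n(q) a[j+n, i+m]
    U(x, y) = sum_{m,n=0..3} B_m(p) B_n(q) b[j+n, i+m]

with i = floor((x-x0)/h_x), p = (x-x0)/h_x - i (likewise j, q axially) and
the standard uniform cubic basis. The axial control parameters ``a`` are
fitted to tracked axial displacements by linear least squares; the lateral
parameters ``b`` are then derived from plane-strain incompressibility
(eps_xx = -eps_yy) rather than from the noisy tracked lateral estimates.
Strains are analytic spline derivatives, never finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .fields import DisplacementField

__all__ = [
    "cubic_basis",
    "cubic_basis_deriv",
    "BSplineDisplacementModel",
    "fit_axial",
    "derive_lateral",
    "fit_displacement_model",
]

#: default knot spacings (lateral, axial) in mm
DEFAULT_KNOT_SPACING = (4.75, 4.82)


def cubic_basis(t: np.ndarray) -> np.ndarray:
    """Uniform cubic B-spline weights B_0..B_3 at local coordinate t in [0, 1).

    B0 = (1-t)^3/6, B1 = (3t^3-6t^2+4)/6, B2 = (-3t^3+3t^2+3t+1)/6,
    B3 = t^3/6; the four weights sum to 1 (partition of unity).
    Returns shape ``t.shape + (4,)``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0) or np.any(t >= 1.0):
        raise ValueError("local coordinate t must lie in [0, 1)")
    return np.stack(
        [
            (1.0 - t) ** 3 / 6.0,
            (3.0 * t**3 - 6.0 * t**2 + 4.0) / 6.0,
            (-3.0 * t**3 + 3.0 * t**2 + 3.0 * t + 1.0) / 6.0,
            t**3 / 6.0,
        ],
        axis=-1,
    )


def cubic_basis_deriv(t: np.ndarray) -> np.ndarray:
    """dB_m/dt at t in [0, 1); the four derivatives sum to 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0) or np.any(t >= 1.0):
        raise ValueError("local coordinate t must lie in [0, 1)")
    return np.stack(
        [
            -0.5 * (1.0 - t) ** 2,
            1.5 * t**2 - 2.0 * t,
            -1.5 * t**2 + t + 0.5,
            0.5 * t**2,
        ],
        axis=-1,
    )


@dataclass
class BSplineDisplacementModel:
    """Control-parameter grids and knot geometry for the (U, V) fields.

    a, b : (n_cy, n_cx) axial / lateral control parameters (mm); ``b`` may
        be None until derived.
    knot_spacing : (lateral h_x, axial h_y) mm.
    origin : (x0, y0) mm of the support lower corner. The representable
        region is [x0, x0 + (n_cx-3) h_x) x [y0, y0 + (n_cy-3) h_y).
    """

    a: np.ndarray
    b: np.ndarray | None
    knot_spacing: tuple[float, float]
    origin: tuple[float, float]

    @classmethod
    def for_region(
        cls,
        x_range: tuple[float, float],
        y_range: tuple[float, float],
        knot_spacing: tuple[float, float] = DEFAULT_KNOT_SPACING,
    ) -> "BSplineDisplacementModel":
        """Allocate a zeroed control grid whose cubic support covers the
        given rectangle with one knot of margin on each side."""
        h_x, h_y = knot_spacing
        n_cells_x = int(np.ceil((x_range[1] - x_range[0]) / h_x - 1e-9))
        n_cells_y = int(np.ceil((y_range[1] - y_range[0]) / h_y - 1e-9))
        n_cx, n_cy = n_cells_x + 3, n_cells_y + 3
        a = np.zeros((n_cy, n_cx))
        return cls(a, None, (h_x, h_y), (float(x_range[0]), float(y_range[0])))

    @property
    def n_cx(self) -> int:
        return self.a.shape[1]

    @property
    def n_cy(self) -> int:
        return self.a.shape[0]

    def _local(self, x: np.ndarray, y: np.ndarray):
        h_x, h_y = self.knot_spacing
        sx = (np.asarray(x, float) - self.origin[0]) / h_x
        sy = (np.asarray(y, float) - self.origin[1]) / h_y
        tol = 1e-9
        if (
            np.any(sx < -tol)
            or np.any(sx > self.n_cx - 3 + tol)
            or np.any(sy < -tol)
            or np.any(sy > self.n_cy - 3 + tol)
        ):
            raise ValueError("evaluation point outside the knot support")
        i = np.clip(np.floor(sx).astype(np.int64), 0, self.n_cx - 4)
        j = np.clip(np.floor(sy).astype(np.int64), 0, self.n_cy - 4)
        p = np.clip(sx - i, 0.0, 1.0 - 1e-12)
        q = np.clip(sy - j, 0.0, 1.0 - 1e-12)
        return i, j, p, q

    def design_matrix(
        self, x: np.ndarray, y: np.ndarray, dx: int = 0, dy: int = 0
    ) -> sp.csr_matrix:
        """Sparse matrix S with S @ c.ravel() = d^(dx,dy) field at the given
        points, for control grid c of shape (n_cy, n_cx). ``dx``/``dy`` in
        {0, 1} select the analytic first derivative along that axis."""
        x = np.ravel(x)
        y = np.ravel(y)
        i, j, p, q = self._local(x, y)
        h_x, h_y = self.knot_spacing
        wx = (cubic_basis_deriv(p) / h_x) if dx else cubic_basis(p)
        wy = (cubic_basis_deriv(q) / h_y) if dy else cubic_basis(q)
        npts = x.size
        rows = np.repeat(np.arange(npts), 16)
        cols = np.empty((npts, 16), dtype=np.int64)
        data = np.empty((npts, 16))
        for n in range(4):  # axial control offset
            for m in range(4):  # lateral control offset
                k = 4 * n + m
                cols[:, k] = (j + n) * self.n_cx + (i + m)
                data[:, k] = wy[:, n] * wx[:, m]
        return sp.csr_matrix(
            (data.ravel(), (rows, cols.ravel())),
            shape=(npts, self.n_cy * self.n_cx),
        )

    def evaluate(
        self, x: np.ndarray, y: np.ndarray
    ) -> tuple[DisplacementField, dict[str, np.ndarray]]:
        """Evaluate U, V and the analytic strains on a regular grid.

        ``x``, ``y`` are 1D coordinate vectors; returns a DisplacementField
        and a dict with 'exx', 'eyy', 'exy' arrays of shape (len(y), len(x)).
        """
        if self.b is None:
            raise ValueError("lateral parameters not derived yet")
        xg, yg = np.meshgrid(np.ravel(x), np.ravel(y))
        shape = xg.shape
        S = self.design_matrix(xg, yg)
        Sx = self.design_matrix(xg, yg, dx=1)
        Sy = self.design_matrix(xg, yg, dy=1)
        av, bv = self.a.ravel(), self.b.ravel()
        V = (S @ av).reshape(shape)
        U = (S @ bv).reshape(shape)
        eyy = (Sy @ av).reshape(shape)
        exx = (Sx @ bv).reshape(shape)
        exy = 0.5 * ((Sy @ bv) + (Sx @ av)).reshape(shape)
        field = DisplacementField(U, V, np.ravel(x), np.ravel(y))
        return field, {"exx": exx, "eyy": eyy, "exy": exy}

    def displacement_at(
        self, x: np.ndarray, y: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """(u, v) at arbitrary points (used to load the inversion mesh)."""
        if self.b is None:
            raise ValueError("lateral parameters not derived yet")
        S = self.design_matrix(x, y)
        shape = np.shape(x)
        return (S @ self.b.ravel()).reshape(shape), (S @ self.a.ravel()).reshape(shape)


def _check_coverage(model: BSplineDisplacementModel, S: sp.csr_matrix) -> None:
    """Raise if control parameters receive no data support (empty knot
    cells make the normal equations rank-deficient)."""
    weight = np.asarray(abs(S).sum(axis=0)).ravel()
    empty = np.flatnonzero(weight < 1e-12)
    if empty.size:
        cells = [(int(k // model.n_cx), int(k % model.n_cx)) for k in empty[:8]]
        raise ValueError(
            f"{empty.size} control parameters have no supporting samples "
            f"(first empty (row, col) indices: {cells}); enlarge the knot "
            "spacing or the sample coverage"
        )


def _lsq_control_fit(
    model: BSplineDisplacementModel,
    x: np.ndarray,
    y: np.ndarray,
    values: np.ndarray,
    damping: float = 0.0,
) -> np.ndarray:
    """Least-squares fit of one control grid to scattered samples.

    Solved exactly via SVD (the control grid is small); an optional tiny
    Tikhonov term is available for badly covered margins. Rank deficiency
    from empty knot cells is detected and reported explicitly.
    """
    S = model.design_matrix(x, y)
    _check_coverage(model, S)
    if damping > 0.0:
        A = (S.T @ S).toarray()
        rhs = S.T @ np.ravel(values)
        n = A.shape[0]
        A[np.diag_indices(n)] += damping * np.trace(A) / n
        c = np.linalg.solve(A, rhs)
    else:
        c, *_ = np.linalg.lstsq(S.toarray(), np.ravel(values), rcond=None)
    return c.reshape(model.n_cy, model.n_cx)


def fit_axial(
    model: BSplineDisplacementModel,
    tracked: DisplacementField,
    damping: float = 0.0,
) -> BSplineDisplacementModel:
    """Least-squares fit of the axial control parameters ``a`` to tracked
    axial displacements, ignoring NaN-masked samples."""
    xg, yg = np.meshgrid(tracked.x, tracked.y)
    valid = np.isfinite(tracked.v)
    if valid.sum() < 16:
        raise ValueError("too few valid samples to fit the axial spline")
    model.a = _lsq_control_fit(model, xg[valid], yg[valid], tracked.v[valid], damping)
    return model


def _default_grid(model: BSplineDisplacementModel, per_cell: int = 4):
    h_x, h_y = model.knot_spacing
    x0, y0 = model.origin
    x = x0 + np.linspace(0.0, (model.n_cx - 3) * h_x, per_cell * (model.n_cx - 3) + 1)
    y = y0 + np.linspace(0.0, (model.n_cy - 3) * h_y, per_cell * (model.n_cy - 3) + 1)
    return x, y


def derive_lateral(
    model: BSplineDisplacementModel,
    grid: tuple[np.ndarray, np.ndarray] | None = None,
    method: str = "integral",
    gauge_weight: float = 1e-3,
    damping: float = 0.0,
) -> BSplineDisplacementModel:
    """Derive the lateral control parameters ``b`` from plane-strain
    incompressibility (eps_xx = -eps_yy), given fitted axial parameters.

    method="integral" (default): the required lateral strain -eps_yy is
    integrated analytically along x (cumulative trapezoid on a dense grid,
    8 samples per knot cell) into a lateral displacement field, gauged to
    zero mean per grid row, and ``b`` is fitted to it by least squares.
    Integration low-passes the axial fit's residual oscillations, so the
    derived field carries far less spurious strain than direct derivative
    matching; the gauge (an additive function of depth that the constraint
    cannot determine) is irrelevant to the downstream inversion.

    method="derivative": ``b`` minimizes the squared in-plane dilatation
    sum (dU/dx + dV/dy)^2 over the grid directly, with the per-row mean of
    U softly penalized toward zero (weight ``gauge_weight``) to fix the
    same gauge. Kept as the reference formulation; its least-squares
    ringing near sharp strain transitions is amplified by the
    near-incompressible inversion operator, hence not the default.
    """
    if grid is None:
        x, y = _default_grid(model, per_cell=8 if method == "integral" else 4)
    else:
        x, y = np.ravel(grid[0]), np.ravel(grid[1])
    xg, yg = np.meshgrid(x, y)

    if method == "integral":
        from scipy.integrate import cumulative_trapezoid

        Sy = model.design_matrix(xg, yg, dy=1)
        eyy = (Sy @ model.a.ravel()).reshape(xg.shape)
        u = -cumulative_trapezoid(eyy, x, axis=1, initial=0.0)
        u -= u.mean(axis=1, keepdims=True)  # zero-row-mean gauge
        model.b = _lsq_control_fit(model, xg, yg, u, damping)
        return model

    if method != "derivative":
        raise ValueError(f"unknown derive_lateral method {method!r}")
    Sx = model.design_matrix(xg, yg, dx=1)
    Sy = model.design_matrix(xg, yg, dy=1)
    target = -(Sy @ model.a.ravel())  # required eps_xx = -eps_yy
    # per-row zero-mean gauge rows
    S0 = model.design_matrix(xg, yg)
    nrow, ncol = xg.shape
    R = sp.kron(sp.eye(nrow), np.ones((1, ncol)) / ncol) @ S0
    scale = np.sqrt((Sx.multiply(Sx)).sum() / max(1, Sx.shape[0]))
    M = (gauge_weight * scale) * R
    A = (Sx.T @ Sx + M.T @ M).toarray()
    rhs = Sx.T @ target
    n = A.shape[0]
    A[np.diag_indices(n)] += max(damping, 1e-10) * np.trace(A) / n
    model.b = np.linalg.solve(A, rhs).reshape(model.n_cy, model.n_cx)
    return model


def fit_displacement_model(
    tracked: DisplacementField,
    knot_spacing: tuple[float, float] = DEFAULT_KNOT_SPACING,
) -> BSplineDisplacementModel:
    """Fit axial parameters to the tracked field and derive the lateral
    ones from incompressibility (the full displacement-model stage)."""
    valid = np.isfinite(tracked.v)
    if not valid.any():
        raise ValueError("tracked field has no valid samples")
    rows = np.flatnonzero(valid.any(axis=1))
    cols = np.flatnonzero(valid.any(axis=0))
    sl_r = slice(rows[0], rows[-1] + 1)
    sl_c = slice(cols[0], cols[-1] + 1)
    cropped = DisplacementField(
        tracked.u[sl_r, sl_c], tracked.v[sl_r, sl_c],
        tracked.x[sl_c], tracked.y[sl_r],
    )
    model = BSplineDisplacementModel.for_region(
        (cropped.x[0], cropped.x[-1]), (cropped.y[0], cropped.y[-1]), knot_spacing
    )
    fit_axial(model, cropped)
    derive_lateral(model)
    return model
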