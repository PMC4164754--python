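"""Gridded field containers shared across the pipeline.

Coordinate convention (fixed package-wide): ``x`` is lateral (image width,
mm), ``y`` is axial (depth, mm, increasing downward — the compression
direction). Under compression the axial displacement ``v`` is positive
(material moves deeper) and the axial normal strain ``dv/dy`` is negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator


@dataclass
class DisplacementField:
    """Axial/lateral displacement components on a regular 2D grid.

    Parameters
    ----------
    u, v : ndarray, shape (ny, nx)
        Lateral (``u``) and axial (``v``) displacement in mm. Invalid
        samples are NaN.
    x, y : ndarray
        Grid coordinates in mm; ``u[i, j]`` is the displacement at
        ``(x[j], y[i])``.
    """

    u: np.ndarray
    v: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must share a shape")
        if self.u.shape != (self.y.size, self.x.size):
            raise ValueError(
                f"field shape {self.u.shape} inconsistent with axes "
                f"({self.y.size}, {self.x.size})"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean validity mask (True where both components are finite)."""
        return np.isfinite(self.u) & np.isfinite(self.v)

    def sample(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Bilinear interpolation of (u, v) at arbitrary points (mm)."""
        pts = np.column_stack([np.ravel(y), np.ravel(x)])
        ui = RegularGridInterpolator((self.y, self.x), self.u, bounds_error=True)
        vi = RegularGridInterpolator((self.y, self.x), self.v, bounds_error=True)
        shape = np.shape(x)
        return ui(pts).reshape(shape), vi(pts).reshape(shape)

    def axial_strain(self) -> np.ndarray:
        """Numerical axial normal strain dv/dy (negative under compression)."""
        return np.gradient(self.v, self.y, axis=0)

    def lateral_strain(self) -> np.ndarray:
        """Numerical lateral normal strain du/dx."""
        return np.gradient(self.u, self.x, axis=1)


@dataclass
class RFFramePair:
    """Pre/post-deformation radiofrequency echo frames.

    ``pre``/``post`` are real-valued arrays of shape (samples, lines);
    sample ``s`` of line ``l`` maps to depth ``y = s * dy`` and lateral
    position ``x = (l + 0.5) * pitch``.
    """

    pre: np.ndarray
    post: np.ndarray
    dy: float  # axial sample spacing, mm (= c / (2 fs))
    pitch: float  # line spacing, mm
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=float)
        self.post = np.asarray(self.post, dtype=float)
        if self.pre.shape != self.post.shape:
            raise ValueError("pre and post frames must share a shape")

    @property
    def n_samples(self) -> int:
        return self.pre.shape[0]

    @property
    def n_lines(self) -> int:
        return self.pre.shape[1]

    @property
    def sample_depths(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dy

    @property
    def line_positions(self) -> np.ndarray:
        return (np.arange(self.n_lines) + 0.5) * self.pitch
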