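"""Evaluation metrics for reconstructed modulus images.

Both error metrics operate on relative moduli: the reconstruction is
already relative to its unit boundary ring, and the truth is divided by
the background modulus so that background = 1 on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "mean_relative_error",
    "rmse",
    "Rect",
    "Disk",
    "roi_statistics",
]


def _rel(e_hat: np.ndarray, e_true: np.ndarray) -> np.ndarray:
    e_hat = np.asarray(e_hat, float)
    e_true = np.asarray(e_true, float)
    if e_hat.shape != e_true.shape:
        raise ValueError(f"shape mismatch: {e_hat.shape} vs {e_true.shape}")
    if np.any(e_true <= 0):
        raise ValueError("true moduli must be positive")
    return (e_hat - e_true) / e_true


def mean_relative_error(e_hat: np.ndarray, e_true: np.ndarray) -> float:
    """Signed mean relative modulus error in percent:
    100 * mean((E_hat - E_true) / E_true) over all elements."""
    return float(100.0 * _rel(e_hat, e_true).mean())


def rmse(e_hat: np.ndarray, e_true: np.ndarray) -> float:
    """Root-mean-square relative modulus error in percent:
    100 * sqrt(mean(((E_hat - E_true) / E_true)^2))."""
    return float(100.0 * np.sqrt((_rel(e_hat, e_true) ** 2).mean()))


@dataclass
class Rect:
    """Axis-aligned rectangle (top, left, height, width) in mm."""

    top: float
    left: float
    height: float
    width: float

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (
            (x >= self.left)
            & (x <= self.left + self.width)
            & (y >= self.top)
            & (y <= self.top + self.height)
        )


@dataclass
class Disk:
    """Circular region: center (x, y) and radius, mm."""

    center: tuple[float, float]
    radius: float

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        cx, cy = self.center
        return (x - cx) ** 2 + (y - cy) ** 2 <= self.radius**2


def roi_statistics(
    values: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    regions: dict[str, Rect | Disk],
) -> dict[str, tuple[float, float]]:
    """Mean and standard deviation of a gridded field in named regions.

    ``values`` has shape (len(y), len(x)); NaN samples are ignored.
    Raises on a region containing no grid samples.
    """
    xg, yg = np.meshgrid(np.ravel(x), np.ravel(y))
    out: dict[str, tuple[float, float]] = {}
    for name, region in regions.items():
        inside = region.contains(xg, yg) & np.isfinite(values)
        if not np.any(inside):
            raise ValueError(f"region {name!r} contains no samples")
        sel = values[inside]
        out[name] = (float(sel.mean()), float(sel.std()))
    return out
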