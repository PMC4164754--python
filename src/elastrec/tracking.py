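"""Coarse-to-fine speckle tracking on RF frame pairs.

Normalized cross-correlation block matching on the raw RF (integer sample /
line steps) followed by parabolic sub-sample refinement of the correlation
peak in each axis. Axial estimates are sub-sample accurate thanks to the RF
phase; lateral estimates are markedly noisier (coarser pitch, no phase),
which is the property the spline displacement model downstream corrects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import match_template

from .fields import DisplacementField, RFFramePair

__all__ = ["TrackingConfig", "track"]


@dataclass
class TrackingConfig:
    """Two-step block-matching parameters.

    window : (height, width) mm of the correlation kernel; default
        2.2 x 1.8 mm.
    search_axial : (lo, hi) mm of candidate axial displacements for the
        coarse pass. Must cover the expected maximum (applied strain x
        depth); compression moves echoes deeper so the default range is
        one-sided positive.
    search_lateral : (lo, hi) mm of candidate lateral displacements.
    stride_fraction : estimation-grid step as a fraction of the window
        (default 0.25, i.e. 75 % overlap).
    min_correlation : estimates with a peak below this are flagged NaN.
    global_stretch : when True (default), a coarse pass estimates the bulk
        axial strain, the post frame is companded (axially stretched) to
        remove it, and the fine pass tracks only the residual motion.
        Companding suppresses the strain-induced intra-window
        decorrelation bias that otherwise correlates with the local
        stiffness structure.
    search_residual : (lo, hi) mm fine-pass search range after companding.
    """

    window: tuple[float, float] = (2.2, 1.8)
    search_axial: tuple[float, float] = (-0.15, 0.95)
    search_lateral: tuple[float, float] = (-0.3, 0.3)
    stride_fraction: float = 0.25
    min_correlation: float = 0.25
    global_stretch: bool = True
    search_residual: tuple[float, float] = (-0.35, 0.35)

    @classmethod
    def for_strain(cls, applied_strain: float, depth: float = 38.0, **kw):
        """Search range sized to the maximum expected displacement of a
        slip-compressed block (strain x depth plus margin)."""
        vmax = applied_strain * depth
        return cls(search_axial=(-0.15, vmax + 0.3), **kw)


def _parabolic_offset(y_minus: float, y0: float, y_plus: float) -> float:
    """Sub-sample peak offset in [-0.5, 0.5] from three ordinates."""
    denom = y_minus - 2.0 * y0 + y_plus
    if denom >= 0.0:  # flat or non-concave: keep the integer peak
        return 0.0
    return float(np.clip(0.5 * (y_minus - y_plus) / denom, -0.5, 0.5))


def _block_match(
    pre: np.ndarray,
    post: np.ndarray,
    win: tuple[int, int],
    search_s: tuple[int, int],
    search_l: tuple[int, int],
    step: tuple[int, int],
    min_corr: float,
):
    """NCC block matching on integer grids with parabolic refinement.

    Returns (s_centers, l_centers, v_samples, u_lines, corr); displacements
    are in samples / lines, NaN where invalid.
    """
    ns, nl = pre.shape
    win_s, win_l = win
    sa_lo, sa_hi = search_s
    sl_lo, sl_hi = search_l
    half_s, half_l = win_s // 2, win_l // 2

    # window centers for which the search region fits in both frames
    s_min = half_s + max(0, -sa_lo) + 1
    s_max = ns - 1 - half_s - max(0, sa_hi) - 1
    l_min = half_l + max(0, -sl_lo) + 1
    l_max = nl - 1 - half_l - max(0, sl_hi) - 1
    if s_max < s_min or l_max < l_min:
        raise ValueError("search range leaves no valid estimation points")
    s_centers = np.arange(s_min, s_max + 1, step[0])
    l_centers = np.arange(l_min, l_max + 1, step[1])

    v = np.full((s_centers.size, l_centers.size), np.nan)
    u = np.full_like(v, np.nan)
    corr = np.full_like(v, np.nan)
    for i, sc in enumerate(s_centers):
        for j, lc in enumerate(l_centers):
            ker = pre[sc - half_s : sc + half_s + 1, lc - half_l : lc + half_l + 1]
            if not np.any(ker):
                continue
            reg = post[
                sc - half_s + sa_lo - 1 : sc + half_s + sa_hi + 2,
                lc - half_l + sl_lo - 1 : lc + half_l + sl_hi + 2,
            ]
            ncc = match_template(reg, ker)
            pk = np.unravel_index(np.argmax(ncc), ncc.shape)
            peak = ncc[pk]
            corr[i, j] = peak
            if peak < min_corr:
                continue
            ds = pk[0] + sa_lo - 1
            dl = pk[1] + sl_lo - 1
            fs = fl = 0.0  # parabolic refinement, off the search border only
            if 0 < pk[0] < ncc.shape[0] - 1:
                fs = _parabolic_offset(
                    ncc[pk[0] - 1, pk[1]], peak, ncc[pk[0] + 1, pk[1]]
                )
            if 0 < pk[1] < ncc.shape[1] - 1:
                fl = _parabolic_offset(
                    ncc[pk[0], pk[1] - 1], peak, ncc[pk[0], pk[1] + 1]
                )
            v[i, j] = ds + fs
            u[i, j] = dl + fl
    return s_centers, l_centers, v, u, corr


def _window_sizes(frames: RFFramePair, cfg: TrackingConfig) -> tuple[int, int]:
    ns, nl = frames.pre.shape
    win_s = max(5, int(round(cfg.window[0] / frames.dy)) | 1)  # odd
    win_l = max(3, int(round(cfg.window[1] / frames.pitch)) | 1)
    if win_s >= ns or win_l >= nl:
        raise ValueError(
            f"window {win_s}x{win_l} samples does not fit in the {ns}x{nl} frame"
        )
    return win_s, win_l


def estimate_bulk_motion(
    frames: RFFramePair, cfg: TrackingConfig
) -> tuple[float, float]:
    """Coarse-pass estimate of the bulk axial motion v = c + m y (mm):
    sparse integer block matching followed by a least-squares line fit of
    displacement vs depth. For bottom-fixed compression m is minus the
    bulk strain and c the top-surface displacement."""
    win = _window_sizes(frames, cfg)
    sa = (
        int(np.floor(cfg.search_axial[0] / frames.dy)),
        int(np.ceil(cfg.search_axial[1] / frames.dy)),
    )
    sl = (
        int(np.floor(cfg.search_lateral[0] / frames.pitch)),
        int(np.ceil(cfg.search_lateral[1] / frames.pitch)),
    )
    sc, lc, v, _, corr = _block_match(
        frames.pre, frames.post, win, sa, sl, (win[0], 2 * win[1]), 0.35
    )
    ok = np.isfinite(v)
    if ok.sum() < 8:
        return 0.0, 0.0
    y = np.broadcast_to(sc[:, None] * frames.dy, v.shape)[ok]
    m, c = np.polyfit(y, v[ok] * frames.dy, 1)
    return float(c), float(m)


def track(
    frames: RFFramePair, config: TrackingConfig | None = None
) -> tuple[DisplacementField, np.ndarray]:
    """Two-step displacement estimation from pre to post frame.

    Step 1 (optional, on by default): coarse integer block matching
    estimates the bulk axial strain; the post frame is companded axially
    to remove it. Step 2: fine normalized-cross-correlation block matching
    with parabolic sub-sample refinement recovers the residual motion; the
    bulk part is added back analytically.

    Returns ``(field, correlation)`` on a regular estimation grid; both
    components are in mm, positive meaning motion toward larger x / deeper
    y. Points whose correlation peak falls below
    ``config.min_correlation`` (or a degenerate, all-zero window) are NaN.
    """
    cfg = config or TrackingConfig()
    pre, post = frames.pre, frames.post
    win = _window_sizes(frames, cfg)

    c_bulk = m_bulk = 0.0
    if cfg.global_stretch:
        c_bulk, m_bulk = estimate_bulk_motion(frames, cfg)
    if abs(m_bulk) > 1e-5 or abs(c_bulk) > 0.5 * frames.dy:
        from scipy.ndimage import map_coordinates

        # pre content at depth y sits in post near (1+m) y + c; resample the
        # post frame on that map so the fine pass sees only the residual
        ns, nl = post.shape
        s_idx = (1.0 + m_bulk) * np.arange(ns) + c_bulk / frames.dy
        S = np.broadcast_to(s_idx[:, None], (ns, nl))
        L = np.broadcast_to(np.arange(nl)[None, :], (ns, nl))
        post_fine = map_coordinates(post, [S, L], order=3, mode="nearest")
        search_ax = cfg.search_residual
    else:
        c_bulk = m_bulk = 0.0
        post_fine = post
        search_ax = cfg.search_axial

    sa = (
        int(np.floor(search_ax[0] / frames.dy)),
        int(np.ceil(search_ax[1] / frames.dy)),
    )
    sl = (
        int(np.floor(cfg.search_lateral[0] / frames.pitch)),
        int(np.ceil(cfg.search_lateral[1] / frames.pitch)),
    )
    step = (
        max(1, int(round(cfg.stride_fraction * win[0]))),
        max(1, int(round(cfg.stride_fraction * win[1]))),
    )
    s_centers, l_centers, dv, du, corr = _block_match(
        pre, post_fine, win, sa, sl, step, cfg.min_correlation
    )
    y = s_centers * frames.dy
    # undo the companding: material at depth y appears in the companded
    # post at (y + v - c)/(1 + m), so v = residual*(1+m) + c + m*y
    v = dv * frames.dy * (1.0 + m_bulk) + c_bulk + m_bulk * y[:, None]
    u = du * frames.pitch
    field = DisplacementField(u, v, x=(l_centers + 0.5) * frames.pitch, y=y)
    return field, corr
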