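"""Synthetic elastography study generator.

Builds heterogeneous inclusion phantoms, solves the plane-strain forward
compression problem, advects random scatterers with the FEM solution and
synthesizes pre/post radiofrequency (RF) echo frames with a separable
convolution point-spread function (Gaussian-enveloped cosine axially,
Gaussian beam profile laterally) plus additive white noise.

The default phantom and imaging parameters are the study conditions used
throughout the package: a 38 x 38 mm near-incompressible block (nu = 0.495,
background 25 kPa) with two 6.5 mm circular inclusions of 75 kPa (modulus
contrast 3), compressed quasi-statically between perfect-slip plates by
axial strains of 0.5-2.0 %, imaged by a 320-line linear array (6 MHz
center, 50 % -3 dB bandwidth, 32 MHz sampling, 0.12 mm pitch, c = 1540 m/s)
with scatterer density 200 / mm^2 and 30 dB RF SNR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.signal import fftconvolve

from .fields import DisplacementField, RFFramePair
from .mesh import BoundaryCondition, PlaneStrainMaterial, QuadMesh, solve_forward

logger = logging.getLogger(__name__)

__all__ = [
    "Inclusion",
    "PhantomSpec",
    "TransducerSpec",
    "reference_phantom",
    "build_phantom",
    "compression_bc",
    "simulate_compression",
    "make_scatterers",
    "synthesize_rf",
]


@dataclass
class Inclusion:
    """Circular stiff/soft inclusion: center (x, y) mm, diameter mm, modulus kPa."""

    center: tuple[float, float]
    diameter: float
    modulus: float


@dataclass
class PhantomSpec:
    """Rectangular phantom with circular inclusions.

    extent = (height, width) mm; the phantom occupies [0, width] x
    [0, height] in (x, y) with y = 0 at the compressed top surface.
    """

    extent: tuple[float, float] = (38.0, 38.0)
    background_modulus: float = 25.0
    inclusions: list[Inclusion] = field(default_factory=list)
    poisson_ratio: float = 0.495

    def __post_init__(self) -> None:
        if self.background_modulus <= 0:
            raise ValueError("background modulus must be positive")
        h, w = self.extent
        for inc in self.inclusions:
            if inc.modulus <= 0:
                raise ValueError("inclusion modulus must be positive")
            cx, cy = inc.center
            r = inc.diameter / 2.0
            if not (r <= cx <= w - r and r <= cy <= h - r):
                raise ValueError(
                    f"inclusion at {inc.center} (d={inc.diameter} mm) extends "
                    "outside the phantom"
                )

    def modulus_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Pointwise Young's modulus (kPa): inclusion value inside each
        circle, background elsewhere."""
        e = np.full(np.broadcast(x, y).shape, self.background_modulus, dtype=float)
        for inc in self.inclusions:
            cx, cy = inc.center
            inside = (np.asarray(x) - cx) ** 2 + (np.asarray(y) - cy) ** 2 <= (
                inc.diameter / 2.0
            ) ** 2
            e = np.where(inside, inc.modulus, e)
        return e


def reference_phantom() -> PhantomSpec:
    """The two-inclusion study phantom: 38 x 38 mm, 25 kPa background, two
    6.5 mm / 75 kPa inclusions side by side at mid depth (contrast 3)."""
    return PhantomSpec(
        extent=(38.0, 38.0),
        background_modulus=25.0,
        inclusions=[
            Inclusion(center=(12.35, 19.0), diameter=6.5, modulus=75.0),
            Inclusion(center=(25.65, 19.0), diameter=6.5, modulus=75.0),
        ],
        poisson_ratio=0.495,
    )


@dataclass
class TransducerSpec:
    """Linear-array imaging parameters (defaults per the study conditions)."""

    center_frequency: float = 6.0  # MHz
    fractional_bandwidth: float = 0.5  # -3 dB, fraction of center frequency
    sampling_frequency: float = 32.0  # MHz
    pitch: float = 0.12  # mm
    n_lines: int = 320
    sound_speed: float = 1540.0  # m/s
    focal_depth: float = 19.0  # mm
    f_number: float = 0.5

    def __post_init__(self) -> None:
        if self.sampling_frequency <= 2.0 * self.center_frequency:
            raise ValueError("sampling frequency must exceed Nyquist")

    @property
    def axial_sample_spacing(self) -> float:
        """Depth per RF sample, mm: c / (2 fs)."""
        c_mm_per_us = self.sound_speed * 1e-3  # mm per microsecond
        return c_mm_per_us / (2.0 * self.sampling_frequency)

    @property
    def wavelength(self) -> float:
        """Center-frequency wavelength, mm."""
        return self.sound_speed * 1e-3 / self.center_frequency

    @property
    def pulse_sigma_samples(self) -> float:
        """Std of the Gaussian RF pulse envelope in samples, set so the
        -3 dB spectral full width equals the fractional bandwidth."""
        bw = self.fractional_bandwidth * self.center_frequency  # MHz
        sigma_us = np.sqrt(np.log(2.0)) / (np.pi * bw)
        return sigma_us * self.sampling_frequency

    @property
    def beam_sigma(self) -> float:
        """Lateral Gaussian beam std at focus, mm (FWHM = lambda * F#)."""
        fwhm = self.wavelength * self.f_number
        return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def build_phantom(
    spec: PhantomSpec, element_size: float | tuple[float, float]
) -> tuple[QuadMesh, PlaneStrainMaterial]:
    """Mesh the phantom with uniform quads and assign per-element moduli.

    An element takes the inclusion modulus iff its center lies inside an
    inclusion circle, else the background modulus.
    """
    if np.isscalar(element_size):
        element_size = (float(element_size), float(element_size))
    mesh = QuadMesh.regular((0.0, 0.0), spec.extent, element_size)
    centers = mesh.element_centers
    E = spec.modulus_at(centers[:, 0], centers[:, 1])
    return mesh, PlaneStrainMaterial(E, spec.poisson_ratio)


def compression_bc(
    mesh: QuadMesh,
    applied_strain: float,
    contact_fraction: float = 1.0,
) -> BoundaryCondition:
    """Perfect-slip quasi-static compression boundary condition.

    The bottom surface rests on a rigid slip plate (axial displacement 0,
    lateral free); the top surface is pressed down by ``applied_strain *
    height`` (axial prescribed, lateral free). One lateral dof at the
    bottom center is pinned to remove the remaining rigid translation.

    ``contact_fraction < 1`` presses only the central fraction of the top
    surface with a smooth cos^2 indentation profile (a compressor narrower
    than the phantom, e.g. a hand-held transducer), which produces the
    stress decay with depth responsible for the target-hardening artifact
    in strain images; the profile is C1 at the contact edges so the fields
    stay regular.
    """
    coords = mesh.node_coords
    y_top, y_bot = coords[:, 1].min(), coords[:, 1].max()
    x_lo, x_hi = coords[:, 0].min(), coords[:, 0].max()
    height = y_bot - y_top
    delta = applied_strain * height
    tol = 1e-9 * max(height, 1.0)

    top = np.flatnonzero(np.abs(coords[:, 1] - y_top) < tol)
    bottom = np.flatnonzero(np.abs(coords[:, 1] - y_bot) < tol)
    if contact_fraction < 1.0:
        xc = 0.5 * (x_lo + x_hi)
        half = 0.5 * contact_fraction * (x_hi - x_lo)
        rel = (coords[top, 0] - xc) / half
        inside = np.abs(rel) <= 1.0 + 1e-12
        top = top[inside]
        top_vals = delta * np.cos(0.5 * np.pi * np.clip(rel[inside], -1, 1)) ** 2
    else:
        top_vals = np.full(top.size, delta)

    dofs = [2 * top + 1, 2 * bottom + 1]
    vals = [top_vals, np.zeros(bottom.size)]
    # pin lateral translation at the bottom node closest to the centerline
    pin = bottom[np.argmin(np.abs(coords[bottom, 0] - 0.5 * (x_lo + x_hi)))]
    dofs.append(np.array([2 * pin]))
    vals.append(np.array([0.0]))
    return BoundaryCondition(
        np.concatenate(dofs),
        np.concatenate(vals),
        description=f"slip compression, strain {applied_strain:g}, "
        f"contact fraction {contact_fraction:g}",
    )


def nodal_interpolator(mesh: QuadMesh, d: np.ndarray):
    """Bilinear interpolator of a nodal displacement vector over a regular
    mesh; returns ``f(x, y) -> (u, v)``. Exact for per-element bilinear
    fields, i.e. consistent with the FEM shape functions."""
    if mesh.shape is None:
        raise ValueError("nodal interpolation requires a regular mesh")
    ne_y, ne_x = mesh.shape
    coords = mesh.node_coords
    xs = np.unique(np.round(coords[:, 0], 12))
    ys = np.unique(np.round(coords[:, 1], 12))
    u = d[0::2].reshape(ne_y + 1, ne_x + 1)
    v = d[1::2].reshape(ne_y + 1, ne_x + 1)
    ui = RegularGridInterpolator((ys, xs), u, bounds_error=True)
    vi = RegularGridInterpolator((ys, xs), v, bounds_error=True)

    def sample(x, y):
        pts = np.column_stack([np.ravel(y), np.ravel(x)])
        shape = np.shape(x)
        return ui(pts).reshape(shape), vi(pts).reshape(shape)

    return sample


def smoothed_nodal_interpolator(mesh: QuadMesh, d: np.ndarray, sigma_mm: float):
    """Bilinear interpolator of a nodal field after Gaussian anti-alias
    filtering with physical width ``sigma_mm``.

    The standard transfer of a fine-mesh solution onto a coarser mesh:
    content below the coarse grid's resolution is suppressed before
    sampling so it cannot alias into the coarse elements' strains.
    """
    from scipy.ndimage import gaussian_filter

    if mesh.shape is None:
        raise ValueError("anti-aliased interpolation requires a regular mesh")
    ne_y, ne_x = mesh.shape
    eh, ew = mesh.element_size
    sig = (sigma_mm / eh, sigma_mm / ew)  # (axial, lateral) in node-grid units
    u = gaussian_filter(d[0::2].reshape(ne_y + 1, ne_x + 1), sig, mode="nearest")
    v = gaussian_filter(d[1::2].reshape(ne_y + 1, ne_x + 1), sig, mode="nearest")
    ds = np.empty_like(d)
    ds[0::2] = u.ravel()
    ds[1::2] = v.ravel()
    return nodal_interpolator(mesh, ds)


def simulate_compression(
    spec: PhantomSpec,
    applied_strain: float,
    element_size: float | None = None,
    grid: tuple[np.ndarray, np.ndarray] | None = None,
    contact_fraction: float = 1.0,
) -> tuple[DisplacementField, QuadMesh, PlaneStrainMaterial, np.ndarray]:
    """Forward-solve the compressed phantom and sample the theoretical
    displacement field on a regular imaging grid.

    Returns (field, mesh, material, nodal displacement vector). ``grid``
    is an (x, y) coordinate pair; the default is a 0.25 mm grid over the
    phantom. The default element size targets ~0.12 mm (4x finer than the
    0.48 mm inversion elements), rounded to divide the extent.
    """
    if not (0.0 <= applied_strain <= 0.05):
        raise ValueError("applied axial strain must lie in [0, 0.05]")
    if element_size is None:
        h, w = spec.extent
        target = 38.0 / 320.0
        element_size = (
            h / max(1, round(h / target)),
            w / max(1, round(w / target)),
        )
    mesh, material = build_phantom(spec, element_size)
    if applied_strain == 0.0:
        d = np.zeros(2 * mesh.n_nodes)
    else:
        bc = compression_bc(mesh, applied_strain, contact_fraction)
        d = solve_forward(mesh, material, bc)
    if grid is None:
        h, w = spec.extent
        grid = (np.arange(0.0, w + 1e-9, 0.25), np.arange(0.0, h + 1e-9, 0.25))
    x, y = grid
    sample = nodal_interpolator(mesh, d)
    xg, yg = np.meshgrid(x, y)
    u, v = sample(xg, yg)
    return DisplacementField(u, v, x, y), mesh, material, d


def make_scatterers(
    extent: tuple[float, float],
    density: float = 200.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random scatterer positions and standard-normal amplitudes.

    extent = (height, width) mm; density in scatterers / mm^2. The count is
    ``round(density * area)`` (288,800 for the default 38 x 38 mm phantom
    at 200 / mm^2), which exceeds the fully-developed-speckle threshold.
    """
    if density <= 0:
        raise ValueError("scatterer density must be positive")
    rng = np.random.default_rng(seed)
    h, w = extent
    n = int(round(density * h * w))
    pos = np.column_stack([rng.uniform(0.0, w, n), rng.uniform(0.0, h, n)])
    amp = rng.standard_normal(n)
    return pos, amp


# windowed-sinc deposition kernel half-width (samples); wide enough that
# sub-sample scatterer delays keep their phase at 6 MHz / 32 MHz sampling
_DEPOSIT_HALF = 4


def _deposit(
    rf: np.ndarray,
    pos: np.ndarray,
    amp: np.ndarray,
    transducer: TransducerSpec,
) -> int:
    """Scatter amplitudes onto the (sample, line) grid with a lateral
    Gaussian beam weight and an axial windowed-sinc (sub-sample delays).
    Returns the number of scatterers dropped as outside the frame."""
    ns, nl = rf.shape
    dy = transducer.axial_sample_spacing
    pitch = transducer.pitch
    sig_x = transducer.beam_sigma

    s = pos[:, 1] / dy  # fractional axial sample
    l = pos[:, 0] / pitch - 0.5  # fractional line index
    keep = (s >= 0) & (s <= ns - 1) & (pos[:, 0] >= -pitch) & (
        pos[:, 0] <= nl * pitch + pitch
    )
    n_dropped = int((~keep).sum())
    s, l, a = s[keep], l[keep], amp[keep]
    s0 = np.floor(s).astype(np.int64)
    fs_frac = s - s0
    l0 = np.rint(l).astype(np.int64)

    half = _DEPOSIT_HALF
    for dl in range(-2, 3):
        line = l0 + dl
        ok = (line >= 0) & (line < nl)
        if not np.any(ok):
            continue
        xdist = (l[ok] - line[ok]) * pitch
        w_lat = np.exp(-0.5 * (xdist / sig_x) ** 2)
        a_ok = a[ok] * w_lat
        s0_ok, f_ok, line_ok = s0[ok], fs_frac[ok], line[ok]
        for k in range(-half + 1, half + 1):
            t = k - f_ok  # tap offset from true delay, samples
            w_ax = np.sinc(t) * np.cos(np.pi * t / (2 * half - 1)) ** 2
            samp = s0_ok + k
            ok2 = (samp >= 0) & (samp < ns)
            np.add.at(rf, (samp[ok2], line_ok[ok2]), a_ok[ok2] * w_ax[ok2])
    return n_dropped


def _pulse_kernel(transducer: TransducerSpec) -> np.ndarray:
    """Gaussian-enveloped cosine RF pulse sampled at fs, centered."""
    sig = transducer.pulse_sigma_samples
    half = int(np.ceil(4.0 * sig))
    t = np.arange(-half, half + 1)
    f_rel = transducer.center_frequency / transducer.sampling_frequency
    return np.cos(2.0 * np.pi * f_rel * t) * np.exp(-0.5 * (t / sig) ** 2)


def synthesize_rf(
    scatterers: np.ndarray,
    amplitudes: np.ndarray,
    displacement: DisplacementField | None,
    transducer: TransducerSpec = TransducerSpec(),
    depth: float = 38.0,
    snr_db: float | None = 30.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Synthesize one RF frame from point scatterers.

    Each line is the convolution of the beam-weighted scatterer
    reflectivity with a Gaussian-enveloped cosine pulse (center frequency
    and -3 dB bandwidth from ``transducer``). When ``displacement`` is
    given, scatterers are advected by bilinear interpolation of the field
    before insonification; scatterers displaced outside the frame are
    dropped with a logged count. White Gaussian noise is added so that
    signal power / noise power = 10^(snr_db / 10); ``snr_db=None`` yields
    the clean frame.
    """
    pos = np.asarray(scatterers, dtype=float)
    amp = np.asarray(amplitudes, dtype=float)
    if displacement is not None:
        u, v = displacement.sample(pos[:, 0], pos[:, 1])
        if np.any(~np.isfinite(u)) or np.any(~np.isfinite(v)):
            raise ValueError("displacement field does not cover all scatterers")
        pos = pos + np.column_stack([u, v])
    ns = int(round(depth / transducer.axial_sample_spacing))
    rf = np.zeros((ns, transducer.n_lines))
    n_dropped = _deposit(rf, pos, amp, transducer)
    if n_dropped:
        logger.info("synthesize_rf: dropped %d scatterers outside frame", n_dropped)
    kernel = _pulse_kernel(transducer)
    rf = fftconvolve(rf, kernel[:, None], mode="same")
    if snr_db is not None:
        rng = np.random.default_rng(seed)
        p_sig = np.mean(rf**2)
        sigma = np.sqrt(p_sig / 10.0 ** (snr_db / 10.0))
        rf = rf + rng.normal(0.0, sigma, rf.shape)
    return rf


def simulate_frame_pair(
    spec: PhantomSpec,
    displacement: DisplacementField,
    transducer: TransducerSpec = TransducerSpec(),
    snr_db: float | None = 30.0,
    scatterer_density: float = 200.0,
    seed: int | np.random.Generator | None = None,
) -> RFFramePair:
    """Pre/post RF frames of a phantom under a known deformation.

    One scatterer population is drawn, imaged at rest (pre) and after
    advection by ``displacement`` (post); independent noise realizations
    are added to each frame at ``snr_db``.
    """
    rng = np.random.default_rng(seed)
    pos, amp = make_scatterers(spec.extent, scatterer_density, rng)
    depth = spec.extent[0]
    pre = synthesize_rf(pos, amp, None, transducer, depth, snr_db, rng)
    post = synthesize_rf(pos, amp, displacement, transducer, depth, snr_db, rng)
    return RFFramePair(
        pre,
        post,
        dy=transducer.axial_sample_spacing,
        pitch=transducer.pitch,
        meta={"snr_db": snr_db, "density": scatterer_density},
    )
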