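"""HDF5 / CSV / image I/O with config+seed provenance.

Every writer embeds a JSON provenance string in the root attributes so a
saved artifact records how it was produced.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .bspline import BSplineDisplacementModel
from .fields import DisplacementField, RFFramePair
from .inversion import ModulusImage, ROISpec
from .mesh import PlaneStrainMaterial, QuadMesh

__all__ = [
    "save_simulation",
    "load_simulation",
    "save_displacement",
    "load_displacement",
    "save_model",
    "load_model",
    "save_modulus",
    "load_modulus",
    "export_modulus_image",
]


def _write_provenance(root: h5py.File, provenance: dict | None) -> None:
    root.attrs["provenance"] = json.dumps(provenance or {}, default=str)


def _read_provenance(root: h5py.File) -> dict:
    return json.loads(root.attrs.get("provenance", "{}"))


def save_simulation(
    path: str | Path,
    frames: RFFramePair,
    theory: DisplacementField | None = None,
    mesh: QuadMesh | None = None,
    material: PlaneStrainMaterial | None = None,
    provenance: dict | None = None,
) -> None:
    """RF frame pair plus (optionally) the theoretical displacement field
    and the phantom mesh/modulus map."""
    with h5py.File(path, "w") as f:
        g = f.create_group("rf")
        g.create_dataset("pre", data=frames.pre)
        g.create_dataset("post", data=frames.post)
        g.attrs["dy_mm"] = frames.dy
        g.attrs["pitch_mm"] = frames.pitch
        if theory is not None:
            _write_field_group(f.create_group("theory"), theory)
        if mesh is not None:
            g = f.create_group("phantom")
            g.create_dataset("node_coords", data=mesh.node_coords)
            g.create_dataset("connectivity", data=mesh.connectivity)
            if material is not None:
                g.create_dataset("modulus", data=material.youngs_modulus)
                g.attrs["poisson_ratio"] = material.poisson_ratio
        _write_provenance(f, provenance)


def load_simulation(path: str | Path) -> tuple[RFFramePair, DisplacementField | None, dict]:
    with h5py.File(path, "r") as f:
        g = f["rf"]
        frames = RFFramePair(
            g["pre"][()], g["post"][()], float(g.attrs["dy_mm"]), float(g.attrs["pitch_mm"])
        )
        theory = _read_field_group(f["theory"]) if "theory" in f else None
        return frames, theory, _read_provenance(f)


def _write_field_group(g: h5py.Group, field: DisplacementField) -> None:
    g.create_dataset("u", data=field.u)
    g.create_dataset("v", data=field.v)
    g.create_dataset("x", data=field.x)
    g.create_dataset("y", data=field.y)


def _read_field_group(g: h5py.Group) -> DisplacementField:
    return DisplacementField(g["u"][()], g["v"][()], g["x"][()], g["y"][()])


def save_displacement(
    path: str | Path,
    field: DisplacementField,
    correlation: np.ndarray | None = None,
    provenance: dict | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        _write_field_group(f.create_group("displacement"), field)
        if correlation is not None:
            f.create_dataset("correlation", data=correlation)
        _write_provenance(f, provenance)


def load_displacement(path: str | Path) -> tuple[DisplacementField, dict]:
    with h5py.File(path, "r") as f:
        return _read_field_group(f["displacement"]), _read_provenance(f)


def save_model(
    path: str | Path, model: BSplineDisplacementModel, provenance: dict | None = None
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("a", data=model.a)
        if model.b is not None:
            f.create_dataset("b", data=model.b)
        f.attrs["knot_spacing_mm"] = model.knot_spacing
        f.attrs["origin_mm"] = model.origin
        _write_provenance(f, provenance)


def load_model(path: str | Path) -> tuple[BSplineDisplacementModel, dict]:
    with h5py.File(path, "r") as f:
        model = BSplineDisplacementModel(
            a=f["a"][()],
            b=f["b"][()] if "b" in f else None,
            knot_spacing=tuple(f.attrs["knot_spacing_mm"]),
            origin=tuple(f.attrs["origin_mm"]),
        )
        return model, _read_provenance(f)


def save_modulus(path: str | Path, image: ModulusImage) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("modulus", data=image.values)
        f.attrs["roi_mm"] = (image.roi.top, image.roi.left, image.roi.height, image.roi.width)
        f.attrs["element_size_mm"] = image.roi.element_size
        _write_provenance(f, image.provenance)


def load_modulus(path: str | Path) -> ModulusImage:
    with h5py.File(path, "r") as f:
        top, left, height, width = (float(v) for v in f.attrs["roi_mm"])
        eh, ew = (float(v) for v in f.attrs["element_size_mm"])
        return ModulusImage(
            f["modulus"][()],
            ROISpec(top, left, height, width, (eh, ew)),
            _read_provenance(f),
        )


def export_modulus_image(
    image: ModulusImage, path: str | Path, vmax: float = 2.0
) -> None:
    """Render the relative modulus map to PNG/TIFF with a colorbar fixed
    around contrast ``vmax`` (display only — saved values are never
    clipped)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    roi = image.roi
    extent = (roi.left, roi.left + roi.width, roi.top + roi.height, roi.top)
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(image.values, extent=extent, cmap="viridis", vmin=0.0, vmax=vmax)
    ax.set_xlabel("lateral x (mm)")
    ax.set_ylabel("depth y (mm)")
    ax.set_title("relative Young's modulus")
    fig.colorbar(im, ax=ax, label="E / E_ring")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
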