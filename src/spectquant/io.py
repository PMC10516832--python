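"""Volume, sinogram and config I/O.

Volumes go to NIfTI (default, via nibabel) or MetaImage (via SimpleITK when
available), with a JSON truth/provenance sidecar. Sinograms are stored as
``.npy`` arrays (one per energy window) plus a JSON sidecar carrying the
geometry, windows, seed and sensitivity; round-trips are bit-exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .phantoms import (
    EllipticalCylinder,
    GridSpec,
    InsertSpec,
    PhantomRealization,
    PhantomSpec,
    Cylinder,
)
from .projector import AcquisitionGeometry, EnergyWindow, ProjectionSet

__all__ = [
    "save_volume",
    "load_volume",
    "save_projection_set",
    "load_projection_set",
    "save_truth_sidecar",
    "load_phantom_config",
]


def _affine(grid: GridSpec) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def save_volume(
    path: str | Path, data: np.ndarray, grid: GridSpec, fmt: str = "nifti"
) -> Path:
    """Write a 3D volume; format 'nifti' (.nii.gz) or 'metaimage' (.mha)."""
    path = Path(path)
    if fmt == "nifti":
        import nibabel as nib

        if path.suffix not in (".nii", ".gz"):
            path = path.with_suffix(".nii.gz")
        nib.save(nib.Nifti1Image(np.asarray(data, np.float64), _affine(grid)), path)
        return path
    if fmt == "metaimage":
        import SimpleITK as sitk

        if path.suffix != ".mha":
            path = path.with_suffix(".mha")
        img = sitk.GetImageFromArray(np.transpose(np.asarray(data), (2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in grid.spacing))
        img.SetOrigin(tuple(float(o) for o in grid.origin))
        sitk.WriteImage(img, str(path))
        return path
    raise ValueError(f"unknown volume format {fmt!r}")


def load_volume(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    path = Path(path)
    if path.suffix == ".mha":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
        grid = GridSpec(
            shape=tuple(data.shape),
            spacing=tuple(img.GetSpacing()),
            origin=tuple(img.GetOrigin()),
        )
        return np.asarray(data, np.float64), grid
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    aff = img.affine
    grid = GridSpec(
        shape=tuple(data.shape),
        spacing=tuple(float(aff[i, i]) for i in range(3)),
        origin=tuple(float(aff[i, 3]) for i in range(3)),
    )
    return data, grid


def save_truth_sidecar(
    path: str | Path, realization: PhantomRealization, timepoint_h: float | None = None
) -> Path:
    """JSON sidecar: insert names, painted concentrations, analytic volumes."""
    path = Path(path)
    spec = realization.spec
    info = {
        "phantom": spec.name,
        "timepoint_h": timepoint_h,
        "background_kbq_ml": spec.background_kbq_ml,
        "mu_per_mm": spec.mu_per_mm,
        "grid": {
            "shape": list(realization.grid.shape),
            "spacing": list(realization.grid.spacing),
            "origin": list(realization.grid.origin),
        },
        "inserts": [
            {
                "name": i.name,
                "kind": i.kind,
                "center_mm": list(i.center),
                "concentration_kbq_ml": i.concentration_kbq_ml,
                "analytic_volume_ml": i.analytic_volume_ml,
                "mask_volume_ml": realization.mask_volume_ml(i.name),
            }
            for i in spec.inserts
        ],
    }
    path.write_text(json.dumps(info, indent=2))
    return path


def save_projection_set(path_stem: str | Path, proj: ProjectionSet) -> Path:
    """Write one .npy per window plus ``<stem>.json`` metadata sidecar."""
    stem = Path(path_stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    for name, arr in proj.counts.items():
        np.save(stem.with_name(f"{stem.name}_{name}.npy"), arr)
    meta = {
        "windows_present": sorted(proj.counts),
        "geometry": asdict(proj.geometry),
        "windows": {k: asdict(w) for k, w in proj.windows.items()},
        "sensitivity_cps_per_kbq": proj.sensitivity_cps_per_kbq,
        "seed": proj.seed,
    }
    sidecar = stem.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def load_projection_set(path_stem: str | Path) -> ProjectionSet:
    stem = Path(path_stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    counts = {
        name: np.load(stem.with_name(f"{stem.name}_{name}.npy"))
        for name in meta["windows_present"]
    }
    return ProjectionSet(
        counts=counts,
        geometry=AcquisitionGeometry(**meta["geometry"]),
        windows={k: EnergyWindow(**w) for k, w in meta["windows"].items()},
        sensitivity_cps_per_kbq=meta["sensitivity_cps_per_kbq"],
        seed=meta["seed"],
    )


# ---------------------------------------------------------------------------
# Phantom configs
# ---------------------------------------------------------------------------


def load_phantom_config(path: str | Path) -> PhantomSpec:
    """Read a phantom spec from YAML/JSON.

    Schema::

        name: Ph2
        background:
          shape: cylinder | elliptical_cylinder
          diameter_mm: 216        # cylinder
          semi_axis_x_mm: 147     # elliptical_cylinder
          semi_axis_y_mm: 112
          height_mm: 186
          concentration_kbq_ml: 81.07
        mu_per_mm: 0.0152
        inserts:
          - {name: sphere1, kind: sphere, center_mm: [57.2, 0, 0],
             diameter_mm: 37, concentration_kbq_ml: 580}
    """
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    bg = cfg["background"]
    shape = bg.get("shape", "cylinder")
    center = tuple(bg.get("center_mm", (0.0, 0.0, 0.0)))
    if shape == "cylinder":
        background = Cylinder(
            center=center,
            diameter_mm=float(bg["diameter_mm"]),
            height_mm=float(bg["height_mm"]),
        )
    elif shape == "elliptical_cylinder":
        background = EllipticalCylinder(
            center=center,
            semi_axis_x_mm=float(bg["semi_axis_x_mm"]),
            semi_axis_y_mm=float(bg["semi_axis_y_mm"]),
            height_mm=float(bg["height_mm"]),
        )
    else:
        raise ValueError(f"unknown background shape {shape!r}")
    inserts = tuple(
        InsertSpec(
            name=i["name"],
            kind=i["kind"],
            center=tuple(i.get("center_mm", (0.0, 0.0, 0.0))),
            concentration_kbq_ml=float(i["concentration_kbq_ml"]),
            diameter_mm=i.get("diameter_mm"),
            volume_ml=i.get("volume_ml"),
            height_mm=i.get("height_mm"),
        )
        for i in cfg.get("inserts", [])
    )
    return PhantomSpec(
        name=cfg.get("name", path.stem),
        background=background,
        background_kbq_ml=float(bg.get("concentration_kbq_ml", 0.0)),
        inserts=inserts,
        mu_per_mm=float(cfg.get("mu_per_mm", 0.0152)),
    )
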