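"""Voxelized ground-truth phantoms for quantitative SPECT studies.

Builds activity-concentration and attenuation maps for the three phantom
classes used when characterising a camera for Lu-177 quantification:

* ``Ph1`` — a uniform hot water cylinder used for camera calibration,
* ``Ph2`` — a NEMA IEC body phantom with six hot spheres (37–10 mm) in a
  warm background, used for recovery-coefficient analysis,
* ``Ph3`` — a body phantom holding two large hot vials (~130 and ~535 mL)
  in non-radioactive water, emulating organs at risk.

Voxel membership uses a voxel-*center*-inside test with no partial-volume
antialiasing, which deliberately reproduces the small volume discrepancies
that CT-based delineation of small spheres shows in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GridSpec",
    "InsertSpec",
    "PhantomSpec",
    "PhantomRealization",
    "GeometryError",
    "LU177_HALF_LIFE_H",
    "MU_WATER_113KEV_PER_MM",
    "NEMA_SPHERE_DIAMETERS_MM",
    "NEMA_SPHERE_RING_DIAMETER_MM",
    "build_phantom",
    "decay_concentration",
    "concentration_ratio",
    "mask_volume_discrepancy",
    "uniform_cylinder_phantom",
    "nema_iec_phantom",
    "hot_vials_phantom",
]

#: Lu-177 physical half-life (6.647 d) in hours.
LU177_HALF_LIFE_H = 6.647 * 24.0

#: Narrow-beam linear attenuation coefficient of water at 113 keV (1/mm).
MU_WATER_113KEV_PER_MM = 0.0152

#: Inner diameters of the six NEMA IEC image-quality spheres, largest first.
NEMA_SPHERE_DIAMETERS_MM = (37.0, 28.0, 22.0, 17.0, 13.0, 10.0)

#: Diameter of the circle on which the NEMA sphere centers sit.
NEMA_SPHERE_RING_DIAMETER_MM = 114.4


class GeometryError(ValueError):
    """An insert does not fit inside the phantom background."""


@dataclass(frozen=True)
class GridSpec:
    """Voxel grid: axis order (x, y, z) with z cranio-caudal.

    ``spacing`` is mm per axis; voxel (0,0,0) center sits at ``origin`` mm.
    By default the grid is centered on the physical origin.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (2.46, 2.46, 2.5)
    origin: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.shape):
            raise ValueError("grid shape must be >= 1 per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be positive")
        if self.origin is None:
            centered = tuple(
                -(n - 1) / 2.0 * s for n, s in zip(self.shape, self.spacing)
            )
            object.__setattr__(self, "origin", centered)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical mm coordinates of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(
            self.axis_coords(0), self.axis_coords(1), self.axis_coords(2),
            indexing="ij",
        )


# ---------------------------------------------------------------------------
# Shapes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Shape:
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def contains(self, x, y, z):  # pragma: no cover - abstract
        raise NotImplementedError

    def surface_points(self, n: int = 200) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def volume_ml(self) -> float:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass(frozen=True)
class Sphere(_Shape):
    diameter_mm: float = 10.0

    def contains(self, x, y, z):
        r = self.diameter_mm / 2.0
        cx, cy, cz = self.center
        return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r * r

    def surface_points(self, n: int = 200) -> np.ndarray:
        r = self.diameter_mm / 2.0
        # Fibonacci sphere
        i = np.arange(n)
        phi = math.pi * (3.0 - math.sqrt(5.0)) * i
        zu = 1.0 - 2.0 * (i + 0.5) / n
        rho = np.sqrt(1.0 - zu * zu)
        pts = np.stack([rho * np.cos(phi), rho * np.sin(phi), zu], axis=1) * r
        return pts + np.asarray(self.center)

    @property
    def volume_ml(self) -> float:
        return math.pi / 6.0 * self.diameter_mm**3 / 1000.0


@dataclass(frozen=True)
class Cylinder(_Shape):
    """Circular cylinder with axis along z."""

    diameter_mm: float = 50.0
    height_mm: float = 50.0

    def contains(self, x, y, z):
        r = self.diameter_mm / 2.0
        cx, cy, cz = self.center
        inplane = (x - cx) ** 2 + (y - cy) ** 2 <= r * r
        axial = np.abs(z - cz) <= self.height_mm / 2.0
        return inplane & axial

    def surface_points(self, n: int = 200) -> np.ndarray:
        r = self.diameter_mm / 2.0
        h2 = self.height_mm / 2.0
        m = max(n // 4, 8)
        th = np.linspace(0.0, 2.0 * math.pi, m, endpoint=False)
        ring = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
        pts = []
        for z in (-h2, 0.0, h2):
            pts.append(np.column_stack([ring, np.full(m, z)]))
        # cap rims and centers
        pts.append(np.array([[0.0, 0.0, -h2], [0.0, 0.0, h2]]))
        out = np.vstack(pts)
        return out + np.asarray(self.center)

    @property
    def volume_ml(self) -> float:
        return math.pi * (self.diameter_mm / 2.0) ** 2 * self.height_mm / 1000.0


@dataclass(frozen=True)
class EllipticalCylinder(_Shape):
    """Elliptical cylinder (axis along z); surrogate for the NEMA IEC body."""

    semi_axis_x_mm: float = 147.0
    semi_axis_y_mm: float = 112.0
    height_mm: float = 180.0

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        inplane = ((x - cx) / self.semi_axis_x_mm) ** 2 + (
            (y - cy) / self.semi_axis_y_mm
        ) ** 2 <= 1.0
        axial = np.abs(z - cz) <= self.height_mm / 2.0
        return inplane & axial

    @property
    def volume_ml(self) -> float:
        return (
            math.pi * self.semi_axis_x_mm * self.semi_axis_y_mm * self.height_mm
        ) / 1000.0


def _cylinder_for_volume(
    volume_ml: float, diameter_mm: float | None, center
) -> Cylinder:
    if diameter_mm is None:
        # aspect-balanced vial: height = diameter
        diameter_mm = (4.0 * volume_ml * 1000.0 / math.pi) ** (1.0 / 3.0)
    height = volume_ml * 1000.0 / (math.pi * (diameter_mm / 2.0) ** 2)
    return Cylinder(center=tuple(center), diameter_mm=diameter_mm, height_mm=height)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InsertSpec:
    """A radioactive insert: hot sphere, or a vial modeled as a cylinder."""

    name: str
    kind: str  # 'sphere' | 'cylinder' | 'vial'
    center: tuple[float, float, float]
    concentration_kbq_ml: float
    diameter_mm: float | None = None
    volume_ml: float | None = None
    height_mm: float | None = None

    def __post_init__(self) -> None:
        if self.concentration_kbq_ml < 0 or not np.isfinite(self.concentration_kbq_ml):
            raise ValueError(f"insert {self.name}: concentration must be finite, >= 0")
        if self.kind not in ("sphere", "cylinder", "vial"):
            raise ValueError(f"insert {self.name}: unknown kind {self.kind!r}")
        if self.kind == "sphere":
            if self.diameter_mm is None or self.diameter_mm <= 0:
                raise ValueError(f"insert {self.name}: sphere needs diameter > 0")
        else:
            if (self.volume_ml is None or self.volume_ml <= 0) and (
                self.diameter_mm is None or self.height_mm is None
            ):
                raise ValueError(
                    f"insert {self.name}: cylinder needs volume > 0 or diameter+height"
                )

    def shape(self) -> _Shape:
        if self.kind == "sphere":
            return Sphere(center=tuple(self.center), diameter_mm=self.diameter_mm)
        if self.volume_ml is not None:
            return _cylinder_for_volume(self.volume_ml, self.diameter_mm, self.center)
        return Cylinder(
            center=tuple(self.center),
            diameter_mm=self.diameter_mm,
            height_mm=self.height_mm,
        )

    @property
    def analytic_volume_ml(self) -> float:
        return self.shape().volume_ml


@dataclass(frozen=True)
class PhantomSpec:
    """Background geometry plus inserts and fill concentrations."""

    name: str
    background: _Shape
    background_kbq_ml: float
    inserts: tuple[InsertSpec, ...] = ()
    mu_per_mm: float = MU_WATER_113KEV_PER_MM

    def __post_init__(self) -> None:
        if self.background_kbq_ml < 0 or not np.isfinite(self.background_kbq_ml):
            raise ValueError("background concentration must be finite and >= 0")

    def with_concentrations(
        self, background_kbq_ml: float | None = None, scale: float | None = None
    ) -> "PhantomSpec":
        """Return a copy with rescaled or replaced concentrations.

        ``scale`` multiplies background and every insert (radioactive decay);
        ``background_kbq_ml`` replaces the background value only.
        """
        bg = self.background_kbq_ml
        inserts = self.inserts
        if scale is not None:
            bg = bg * scale
            inserts = tuple(
                replace(i, concentration_kbq_ml=i.concentration_kbq_ml * scale)
                for i in inserts
            )
        if background_kbq_ml is not None:
            bg = background_kbq_ml
        return replace(self, background_kbq_ml=bg, inserts=inserts)


@dataclass
class PhantomRealization:
    """Voxelized ground truth for one phantom at one timepoint."""

    spec: PhantomSpec
    grid: GridSpec
    activity: np.ndarray  # kBq/mL
    mu: np.ndarray  # 1/mm
    truth_masks: dict[str, np.ndarray]  # name -> bool mask ('background' included)
    truth_conc: dict[str, float]  # name -> painted kBq/mL

    @property
    def body_mask(self) -> np.ndarray:
        """All voxels inside the phantom body (background + inserts)."""
        return self.mu > 0

    def mask_volume_ml(self, name: str) -> float:
        return float(self.truth_masks[name].sum()) * self.grid.voxel_volume_ml

    def total_activity_kbq(self) -> float:
        return float(self.activity.sum()) * self.grid.voxel_volume_ml


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def build_phantom(spec: PhantomSpec, grid: GridSpec) -> PhantomRealization:
    """Paint a phantom spec onto a voxel grid.

    Each voxel takes the concentration of the innermost shape containing its
    center (inserts override background). Deterministic for identical inputs.

    Raises
    ------
    GeometryError
        If any insert is not fully contained in the background shape.
    """
    X, Y, Z = grid.meshgrid()
    bg_mask = spec.background.contains(X, Y, Z)

    for ins in spec.inserts:
        pts = ins.shape().surface_points()
        inside = spec.background.contains(pts[:, 0], pts[:, 1], pts[:, 2])
        if not np.all(inside):
            raise GeometryError(
                f"insert {ins.name!r} extends outside the phantom background"
            )

    activity = np.zeros(grid.shape, dtype=np.float64)
    activity[bg_mask] = spec.background_kbq_ml
    mu = np.zeros(grid.shape, dtype=np.float64)
    mu[bg_mask] = spec.mu_per_mm

    truth_masks: dict[str, np.ndarray] = {}
    truth_conc: dict[str, float] = {}
    insert_union = np.zeros(grid.shape, dtype=bool)
    for ins in spec.inserts:
        m = ins.shape().contains(X, Y, Z) & bg_mask
        activity[m] = ins.concentration_kbq_ml
        truth_masks[ins.name] = m
        truth_conc[ins.name] = ins.concentration_kbq_ml
        insert_union |= m

    truth_masks["background"] = bg_mask & ~insert_union
    truth_conc["background"] = spec.background_kbq_ml

    return PhantomRealization(
        spec=spec, grid=grid, activity=activity, mu=mu,
        truth_masks=truth_masks, truth_conc=truth_conc,
    )


def decay_concentration(
    c0_kbq_ml: float, t0_h: float, t_h: float, half_life_h: float = LU177_HALF_LIFE_H
) -> float:
    """Physically decay a concentration from ``t0_h`` to ``t_h`` (hours).

    Back-decay (``t < t0``) is refused: the study design only ever moves
    forward along the decay series.
    """
    if half_life_h <= 0:
        raise ValueError("half-life must be positive")
    if t_h < t0_h:
        raise ValueError("t must be >= t0 (no back-decay)")
    return float(c0_kbq_ml) * 2.0 ** (-(t_h - t0_h) / half_life_h)


def concentration_ratio(spec: PhantomSpec) -> float:
    """Insert-to-background concentration ratio (e.g. the NEMA 7:1 fill)."""
    if spec.background_kbq_ml <= 0:
        raise ValueError("undefined ratio: background concentration is zero")
    if not spec.inserts:
        raise ValueError("phantom has no inserts")
    concs = {i.concentration_kbq_ml for i in spec.inserts}
    if len(concs) > 1:
        raise ValueError("inserts carry different concentrations; ratio ambiguous")
    return concs.pop() / spec.background_kbq_ml


def mask_volume_discrepancy(mask_volume_ml: float, actual_volume_ml: float) -> float:
    """Percent difference between a delineated and the actual volume."""
    if actual_volume_ml <= 0:
        raise ValueError("actual volume must be positive")
    return 100.0 * abs(mask_volume_ml - actual_volume_ml) / actual_volume_ml


# ---------------------------------------------------------------------------
# Phantom factories (fill values from the published phantom session)
# ---------------------------------------------------------------------------


def uniform_cylinder_phantom(
    concentration_kbq_ml: float = 122.1,
    diameter_mm: float = 216.0,
    height_mm: float = 186.0,
) -> PhantomSpec:
    """Ph1: uniform hot water cylinder (~6.8 L) for camera calibration."""
    return PhantomSpec(
        name="Ph1",
        background=Cylinder(diameter_mm=diameter_mm, height_mm=height_mm),
        background_kbq_ml=concentration_kbq_ml,
    )


def nema_iec_phantom(
    background_kbq_ml: float = 783.0e3 / 9658.0,
    sphere_kbq_ml: float = 58.0e3 / 100.0,
    sphere_diameters_mm: Sequence[float] = NEMA_SPHERE_DIAMETERS_MM,
    ring_diameter_mm: float = NEMA_SPHERE_RING_DIAMETER_MM,
    body: EllipticalCylinder | None = None,
) -> PhantomSpec:
    """Ph2: NEMA IEC body phantom, six hot spheres in a warm background.

    Default concentrations follow the published fill (783 MBq in a 9658 mL
    background; spheres filled from a 58 MBq / 100 mL stock ⇒ ~7:1).
    Sphere centers sit on a 114.4 mm circle in one transverse plane.
    """
    body = body or EllipticalCylinder()
    r = ring_diameter_mm / 2.0
    inserts = []
    for i, d in enumerate(sphere_diameters_mm):
        ang = 2.0 * math.pi * i / len(sphere_diameters_mm)
        inserts.append(
            InsertSpec(
                name=f"sphere{i + 1}",
                kind="sphere",
                center=(r * math.cos(ang), r * math.sin(ang), 0.0),
                diameter_mm=float(d),
                concentration_kbq_ml=sphere_kbq_ml,
            )
        )
    return PhantomSpec(
        name="Ph2", background=body, background_kbq_ml=background_kbq_ml,
        inserts=tuple(inserts),
    )


def hot_vials_phantom(
    vial1_kbq_ml: float = 129.0e3 / 130.0,
    vial2_kbq_ml: float = 521.0e3 / 535.0,
    vial1_volume_ml: float = 130.0,
    vial2_volume_ml: float = 535.0,
    body: EllipticalCylinder | None = None,
) -> PhantomSpec:
    """Ph3: body phantom with two large hot vials in cold water.

    The vials emulate organs at risk (~130 and ~535 mL); the surrounding
    water is non-radioactive.
    """
    body = body or EllipticalCylinder()
    v1 = InsertSpec(
        name="vial1", kind="vial", center=(-65.0, 0.0, 0.0),
        volume_ml=vial1_volume_ml, concentration_kbq_ml=vial1_kbq_ml,
    )
    v2 = InsertSpec(
        name="vial2", kind="vial", center=(55.0, 0.0, 0.0),
        volume_ml=vial2_volume_ml, concentration_kbq_ml=vial2_kbq_ml,
    )
    return PhantomSpec(
        name="Ph3", background=body, background_kbq_ml=0.0, inserts=(v1, v2)
    )


#: Decay-series acquisition timepoints (hours post injection) per phantom.
ACQUISITION_TIMEPOINTS_H: dict[str, tuple[float, ...]] = {
    "Ph1": (5.1, 27.6, 43.5, 72.4, 187.9, 194.5, 241.4, 338.6),
    "Ph2": (4.0, 25.3, 42.3, 74.4, 186.5, 194.9, 241.0, 338.4),
    "Ph3": (3.5, 18.5, 43.1, 170.5, 218.9),
}
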