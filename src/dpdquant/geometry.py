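"""Grid-aware volume arithmetic.

Everything downstream (marker definitions, phantom rasterization, NIfTI I/O)
is expressed over three primitives defined here:

* :class:`GridGeometry` — voxel grid with physical spacing, origin and an
  orthonormal direction matrix; world coordinates are voxel *centers* in mm.
* :class:`Volume3D` — a scalar image tagged with its unit (SUV, Bq/mL or TBR).
* :class:`StructureSet` — named binary masks sharing one grid, keyed by the
  canonical thoracic anatomy vocabulary.

The geometric operations are deliberately simple and oracle-checkable:
mask resampling is nearest-neighbor in world coordinates, and morphological
expansion (`dilate_mm`) is an exact Euclidean distance-transform threshold in
millimetres, respecting anisotropic spacing.  CT and SPECT are assumed to
share one world frame (hybrid-scanner coregistration); no registration is
performed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from typing import Dict, Iterator, Mapping, Tuple

import numpy as np
from scipy import ndimage

from .errors import (
    GeometryError,
    InvalidDoseError,
    MissingStructureError,
    ParameterError,
    UnitError,
)

__all__ = [
    "Unit",
    "GridGeometry",
    "Volume3D",
    "StructureSet",
    "DoseRecord",
    "CANONICAL_STRUCTURES",
    "CARDIAC_STRUCTURES",
    "VERTEBRAE",
    "suv_scale",
    "resample_mask",
    "dilate_mm",
    "mask_volume_ml",
]

#: Canonical structure vocabulary (all twelve are required for full panel extraction).
CANONICAL_STRUCTURES: Tuple[str, ...] = (
    "MYOCARDIUM",
    "LV",
    "RV",
    "LA",
    "RA",
    "T7",
    "T8",
    "T9",
    "T10",
    "T11",
    "PARASPINAL_RIGHT",
    "IVC",
)

#: Cardiac structures over which the per-structure marker families are computed.
CARDIAC_STRUCTURES: Tuple[str, ...] = ("LV", "RV", "LA", "RA", "MYOCARDIUM")

VERTEBRAE: Tuple[str, ...] = ("T7", "T8", "T9", "T10", "T11")

_IDENTITY = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))


class Unit(str, Enum):
    """Voxel-value unit tag."""

    SUV = "SUV"
    BQ_ML = "BQ_ML"
    TBR = "TBR"


@dataclass(frozen=True)
class GridGeometry:
    """Physical geometry of a 3-D voxel grid.

    Parameters
    ----------
    shape : tuple of int
        Voxel counts per array axis (>= 1 each).
    spacing : tuple of float
        Voxel edge lengths in mm (> 0 each).
    origin : tuple of float, optional
        World position (mm) of the center of voxel (0, 0, 0).
    direction : nested tuple, optional
        3x3 orthonormal matrix mapping index axes to world axes
        (NIfTI direction-cosine semantics). Defaults to identity.
    """

    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: Tuple[Tuple[float, float, float], ...] = _IDENTITY

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(
            self, "direction", tuple(tuple(float(x) for x in row) for row in self.direction)
        )
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise GeometryError(f"shape must be three counts >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be three positive lengths, got {self.spacing}")
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (3, 3):
            raise GeometryError("direction must be a 3x3 matrix")
        if not np.allclose(d.T @ d, np.eye(3), atol=1e-6):
            raise GeometryError("direction matrix must be orthonormal")

    # -- derived quantities -------------------------------------------------

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (product of spacings / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def direction_matrix(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)

    @property
    def affine(self) -> np.ndarray:
        """4x4 index->world affine (world = A @ [i, j, k, 1])."""
        a = np.eye(4)
        a[:3, :3] = self.direction_matrix @ np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a

    @classmethod
    def from_affine(cls, shape, affine) -> "GridGeometry":
        affine = np.asarray(affine, dtype=float)
        m = affine[:3, :3]
        spacing = np.linalg.norm(m, axis=0)
        if np.any(spacing <= 0) or abs(np.linalg.det(m)) < 1e-12:
            raise GeometryError("degenerate affine")
        direction = m / spacing
        return cls(
            shape=tuple(shape),
            spacing=tuple(spacing),
            origin=tuple(affine[:3, 3]),
            direction=tuple(tuple(row) for row in direction),
        )

    # -- coordinate transforms ---------------------------------------------

    def indices_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to world mm coordinates of voxel centers."""
        idx = np.asarray(indices, dtype=float)
        m = self.direction_matrix @ np.diag(self.spacing)
        return idx @ m.T + np.asarray(self.origin)

    def world_to_continuous_index(self, points: np.ndarray) -> np.ndarray:
        """Map (..., 3) world mm points to continuous voxel indices."""
        pts = np.asarray(points, dtype=float) - np.asarray(self.origin)
        m = self.direction_matrix @ np.diag(self.spacing)
        return pts @ np.linalg.inv(m).T

    def voxel_centers_world(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World x/y/z coordinate arrays of every voxel center, each of shape ``self.shape``."""
        grids = np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij")
        idx = np.stack(grids, axis=-1)
        w = self.indices_to_world(idx)
        return w[..., 0], w[..., 1], w[..., 2]

    def world_bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        """Axis-aligned world bounding box of all voxel centers (lo, hi)."""
        corners = np.array(
            [[i, j, k] for i in (0, self.shape[0] - 1)
             for j in (0, self.shape[1] - 1)
             for k in (0, self.shape[2] - 1)],
            dtype=float,
        )
        w = self.indices_to_world(corners)
        return w.min(axis=0), w.max(axis=0)


@dataclass
class Volume3D:
    """A scalar 3-D image with grid geometry and a unit tag."""

    values: np.ndarray
    geometry: GridGeometry
    unit: Unit = Unit.SUV

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.unit = Unit(self.unit)
        if self.values.shape != tuple(self.geometry.shape):
            raise GeometryError(
                f"values shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if self.unit in (Unit.SUV, Unit.TBR) and self.values.min() < -1e-9:
            raise ValueError(f"{self.unit.value} volume contains negative values")

    def with_values(self, values: np.ndarray, unit: Unit | None = None) -> "Volume3D":
        return Volume3D(values=values, geometry=self.geometry, unit=unit or self.unit)


@dataclass
class StructureSet:
    """Named binary masks sharing one grid geometry.

    Keys must come from :data:`CANONICAL_STRUCTURES`; masks are boolean arrays
    of the geometry's shape.
    """

    geometry: GridGeometry
    masks: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: Dict[str, np.ndarray] = {}
        for name, mask in self.masks.items():
            if name not in CANONICAL_STRUCTURES:
                raise MissingStructureError(
                    f"unknown structure name {name!r}; canonical names are {CANONICAL_STRUCTURES}"
                )
            m = np.asarray(mask).astype(bool)
            if m.shape != tuple(self.geometry.shape):
                raise GeometryError(f"mask {name!r} shape {m.shape} != grid {self.geometry.shape}")
            clean[name] = m
        self.masks = clean

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __getitem__(self, name: str) -> np.ndarray:
        return self.require(name)

    def __iter__(self) -> Iterator[str]:
        return iter(self.masks)

    def require(self, name: str) -> np.ndarray:
        if name not in self.masks:
            raise MissingStructureError(f"required structure {name!r} is missing")
        return self.masks[name]

    def missing(self, names=CANONICAL_STRUCTURES) -> Tuple[str, ...]:
        return tuple(n for n in names if n not in self.masks)

    def empty(self, names=None) -> Tuple[str, ...]:
        names = names if names is not None else tuple(self.masks)
        return tuple(n for n in names if n in self.masks and not self.masks[n].any())


@dataclass(frozen=True)
class DoseRecord:
    """Injected-dose metadata needed to convert activity concentration to SUV.

    Attributes
    ----------
    injected_activity_mbq : float
        Administered activity in MBq (decay-corrected to injection time).
    injection_time, acquisition_time : datetime
        Tracer administration and scan start.
    body_weight_kg : float
        Patient weight in kg.
    half_life_hours : float
        Isotope physical half-life; defaults to Tc-99m (6.0067 h).
    """

    injected_activity_mbq: float
    injection_time: datetime
    acquisition_time: datetime
    body_weight_kg: float
    half_life_hours: float = 6.0067

    def __post_init__(self) -> None:
        if self.injected_activity_mbq <= 0:
            raise InvalidDoseError("injected activity must be positive")
        if self.body_weight_kg <= 0:
            raise InvalidDoseError("body weight must be positive")
        if self.half_life_hours <= 0:
            raise InvalidDoseError("half-life must be positive")
        if self.acquisition_time < self.injection_time:
            raise InvalidDoseError("acquisition time precedes injection time")

    @property
    def uptake_hours(self) -> float:
        return (self.acquisition_time - self.injection_time).total_seconds() / 3600.0

    @property
    def decayed_activity_bq(self) -> float:
        """Injected activity (Bq) decayed to acquisition start."""
        factor = 2.0 ** (-self.uptake_hours / self.half_life_hours)
        return self.injected_activity_mbq * 1e6 * factor


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def suv_scale(volume: Volume3D, dose: DoseRecord) -> Volume3D:
    """Convert an activity-concentration volume (Bq/mL) to SUV (body-weight normalized).

    SUV = concentration [Bq/mL] x body weight [g] / decayed activity [Bq],
    with the injected activity decayed to acquisition start.
    """
    if volume.unit is not Unit.BQ_ML:
        raise UnitError(f"suv_scale expects a BQ_ML volume, got {volume.unit.value}")
    scale = dose.body_weight_kg * 1000.0 / dose.decayed_activity_bq
    return Volume3D(values=volume.values * scale, geometry=volume.geometry, unit=Unit.SUV)


def resample_mask(mask: np.ndarray, geometry: GridGeometry, target: GridGeometry) -> np.ndarray:
    """Nearest-neighbor transfer of a binary mask onto another grid.

    A target voxel is set iff the source voxel whose center is nearest to the
    target voxel center (in world mm) is set; target centers falling outside
    the source grid map to background.  Emits a warning (and an empty mask)
    when the two grids have no world overlap.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != tuple(geometry.shape):
        raise GeometryError(f"mask shape {mask.shape} != source grid {geometry.shape}")
    if geometry == target:
        return mask.copy()
    if not mask.any():
        return np.zeros(target.shape, dtype=bool)

    lo_s, hi_s = geometry.world_bounds()
    lo_t, hi_t = target.world_bounds()
    half_s = np.max(np.abs(geometry.direction_matrix) * np.asarray(geometry.spacing), axis=1) / 2
    if np.any(lo_t > hi_s + half_s) or np.any(hi_t < lo_s - half_s):
        warnings.warn("source and target grids have no world overlap; returning empty mask")
        return np.zeros(target.shape, dtype=bool)

    grids = np.meshgrid(*(np.arange(n) for n in target.shape), indexing="ij")
    idx_t = np.stack(grids, axis=-1)
    world = target.indices_to_world(idx_t)
    ci = geometry.world_to_continuous_index(world)
    nearest = np.floor(ci + 0.5).astype(int)  # round half toward +index
    inside = np.all((nearest >= 0) & (nearest < np.asarray(geometry.shape)), axis=-1)
    out = np.zeros(target.shape, dtype=bool)
    n = nearest[inside]
    out[inside] = mask[n[:, 0], n[:, 1], n[:, 2]]
    return out


def dilate_mm(mask: np.ndarray, geometry: GridGeometry, radius_mm: float) -> np.ndarray:
    """Expand a binary mask by a physical radius in mm.

    An output voxel is set iff the Euclidean world distance from its center to
    the nearest set input voxel center is <= ``radius_mm``.  Implemented with
    an exact anisotropic Euclidean distance transform, so the result is a
    superset of the input and monotone in the radius.
    """
    if radius_mm < 0:
        raise ParameterError(f"dilation radius must be >= 0, got {radius_mm}")
    mask = np.asarray(mask).astype(bool)
    if mask.shape != tuple(geometry.shape):
        raise GeometryError(f"mask shape {mask.shape} != grid {geometry.shape}")
    if radius_mm == 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=geometry.spacing)
    # small tolerance so exactly-on-boundary centers survive sqrt round-off
    return dist <= radius_mm * (1 + 1e-12) + 1e-9


def mask_volume_ml(mask: np.ndarray, geometry: GridGeometry) -> float:
    """Physical volume of a binary mask in mL."""
    mask = np.asarray(mask).astype(bool)
    if mask.shape != tuple(geometry.shape):
        raise GeometryError(f"mask shape {mask.shape} != grid {geometry.shape}")
    return int(mask.sum()) * geometry.voxel_volume_ml
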