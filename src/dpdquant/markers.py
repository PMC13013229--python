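"""The 26-marker [99mTc]Tc-DPD SPECT/CT panel.

Four marker families are computed per scan, over the five cardiac structures
(LV, RV, LA, RA, myocardium) plus reference anatomy:

* **SUV metrics** — SUVmax, SUVmean and SUVpeak over each structure's mask
  expanded by 10 mm (spill-out / coregistration margin).  SUVpeak is the mean
  uptake inside a 1 mL sphere placed (over all in-mask voxel centers) to
  maximize the contained uptake.
* **Retention index** — SUVpeak(myocardium) / SUVpeak(T9 vertebra) x
  SUVpeak(right paraspinal muscle restricted axially to the T7-T11 span);
  a composite of cardiac retention against bone and soft-tissue references.
* **Amyloid activity** — SUVmean of the 10-mm-expanded structure region times
  that region's volume (SUV*mL); a total-uptake integral.
* **Amyloid-affected volume** — after target-to-background (TBR)
  normalization by the inferior vena cava mean, the volume (mL) of voxels in
  the 10-mm-expanded region whose TBR is at or above 1 (sub-threshold voxels
  are discarded).

`extract_panel` resamples each CT-grid mask to the SPECT grid, applies the
expansion per family, and returns exactly the 26 named markers together with
a provenance record (mask voxel counts, reference statistics, config hash).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateGeometryError,
    EmptyStructureError,
    GeometryError,
    InvalidReferenceError,
    MissingStructureError,
    ParameterError,
    UnitError,
)
from .geometry import (
    CANONICAL_STRUCTURES,
    CARDIAC_STRUCTURES,
    VERTEBRAE,
    GridGeometry,
    StructureSet,
    Unit,
    Volume3D,
    dilate_mm,
    mask_volume_ml,
    resample_mask,
)

__all__ = [
    "ExtractionConfig",
    "MarkerPanel",
    "MARKER_NAMES",
    "suv_max",
    "suv_mean",
    "suv_peak",
    "sphere_mean_map",
    "sphere_radius_mm",
    "amyloid_activity",
    "tbr_normalize",
    "affected_volume",
    "retention_index",
    "extract_panel",
]

#: Canonical marker vocabulary, in panel order (26 names).
MARKER_NAMES: Tuple[str, ...] = tuple(
    [f"{metric}_{s}" for s in CARDIAC_STRUCTURES for metric in ("SUVmax", "SUVmean", "SUVpeak")]
    + ["RETENTION_INDEX"]
    + [f"AMYLOID_ACTIVITY_{s}" for s in CARDIAC_STRUCTURES]
    + [f"AFFECTED_VOLUME_{s}" for s in CARDIAC_STRUCTURES]
)


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable constants of the marker definitions.

    Defaults mirror the published pipeline: 10 mm mask expansion, 1 mL
    SUVpeak sphere, TBR threshold 1 (inclusive: a voxel counts as affected
    when TBR >= threshold), retention-index masks undilated.
    """

    expansion_mm: float = 10.0
    peak_voi_ml: float = 1.0
    tbr_threshold: float = 1.0
    dilate_for_retention_index: bool = False
    include_combined_chambers: bool = False

    def __post_init__(self) -> None:
        if self.expansion_mm < 0:
            raise ParameterError("expansion_mm must be >= 0")
        if self.peak_voi_ml <= 0:
            raise ParameterError("peak_voi_ml must be > 0")
        if self.tbr_threshold <= 0:
            raise ParameterError("tbr_threshold must be > 0")

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class MarkerPanel:
    """The 26 named marker values for one scan (plus optional extras/provenance)."""

    values: Dict[str, float]
    extras: Dict[str, float] = field(default_factory=dict)
    provenance: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.values) != MARKER_NAMES:
            missing = set(MARKER_NAMES) - set(self.values)
            extra = set(self.values) - set(MARKER_NAMES)
            raise ValueError(
                f"panel must contain exactly the 26 canonical markers in order; "
                f"missing={sorted(missing)} unexpected={sorted(extra)}"
            )
        for k, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"marker {k} is not finite")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_dict(self) -> Dict[str, float]:
        return dict(self.values)


# ---------------------------------------------------------------------------
# elementary SUV statistics
# ---------------------------------------------------------------------------


def _check_mask(suv: Volume3D, mask: np.ndarray, what: str = "structure") -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if mask.shape != suv.values.shape:
        raise GeometryError(f"{what} mask shape {mask.shape} != volume shape {suv.values.shape}")
    if not mask.any():
        raise EmptyStructureError(f"{what} mask is empty")
    return mask


def suv_max(suv: Volume3D, mask: np.ndarray) -> float:
    """Maximum voxel value within the mask."""
    mask = _check_mask(suv, mask)
    return float(suv.values[mask].max())


def suv_mean(suv: Volume3D, mask: np.ndarray) -> float:
    """Arithmetic mean voxel value within the mask."""
    mask = _check_mask(suv, mask)
    vals = suv.values[mask]
    return float(vals.sum() / vals.size)


def sphere_radius_mm(voi_ml: float) -> float:
    """Radius (mm) of a sphere of the given volume in mL (1 mL -> 6.2035 mm)."""
    return (3.0 * voi_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


def _sphere_kernel(spacing, voi_ml: float) -> np.ndarray:
    r = sphere_radius_mm(voi_ml)
    half = [int(np.floor(r / s)) for s in spacing]
    ax = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    dx, dy, dz = np.meshgrid(*ax, indexing="ij")
    kernel = dx**2 + dy**2 + dz**2 <= r**2 * (1 + 1e-12)
    if kernel.sum() <= 1 and np.prod(spacing) / 1000.0 > voi_ml:
        raise DegenerateGeometryError(
            f"voxel spacing {tuple(spacing)} mm too coarse for a {voi_ml} mL VOI sphere"
        )
    return kernel


def sphere_mean_map(suv: Volume3D, voi_ml: float = 1.0) -> np.ndarray:
    """Mean uptake inside a VOI sphere centered at every voxel.

    Sphere membership is voxel-center-within-radius; spheres are clipped at
    the image bounds (the mean is over the in-bounds member voxels only).
    """
    if voi_ml <= 0:
        raise ParameterError("voi_ml must be > 0")
    kernel = _sphere_kernel(suv.geometry.spacing, voi_ml).astype(float)
    sums = ndimage.convolve(suv.values, kernel, mode="constant", cval=0.0)
    counts = ndimage.convolve(np.ones(suv.values.shape), kernel, mode="constant", cval=0.0)
    return sums / counts


def suv_peak(
    suv: Volume3D,
    mask: np.ndarray,
    voi_ml: float = 1.0,
    _mean_map: Optional[np.ndarray] = None,
) -> float:
    """Peak SUV: max over in-mask sphere centers of the sphere-mean uptake.

    The sphere may extend beyond the structure mask (only its *center* is
    constrained to the mask) but is clipped at the image bounds.
    """
    mask = _check_mask(suv, mask)
    mm = sphere_mean_map(suv, voi_ml) if _mean_map is None else _mean_map
    return float(mm[mask].max())


# ---------------------------------------------------------------------------
# composite markers
# ---------------------------------------------------------------------------


def amyloid_activity(
    suv: Volume3D, structure_mask: np.ndarray, cfg: ExtractionConfig = ExtractionConfig()
) -> float:
    """SUVmean of the expanded structure region times its volume (SUV*mL).

    Algebraically the voxelwise SUV sum over the expanded region times the
    voxel volume.
    """
    mask = _check_mask(suv, structure_mask)
    region = dilate_mm(mask, suv.geometry, cfg.expansion_mm)
    return suv_mean(suv, region) * mask_volume_ml(region, suv.geometry)


def tbr_normalize(suv: Volume3D, ivc_mask: np.ndarray) -> Volume3D:
    """Target-to-background normalization: divide voxelwise by the IVC mean."""
    if suv.unit is not Unit.SUV:
        raise UnitError(f"tbr_normalize expects an SUV volume, got {suv.unit.value}")
    ivc_mask = np.asarray(ivc_mask).astype(bool)
    if ivc_mask.shape != suv.values.shape:
        raise GeometryError("IVC mask shape mismatch")
    if not ivc_mask.any():
        raise InvalidReferenceError("IVC mask is empty")
    ref = float(suv.values[ivc_mask].mean())
    if ref <= 0:
        raise InvalidReferenceError(f"IVC mean uptake must be positive, got {ref}")
    return Volume3D(values=suv.values / ref, geometry=suv.geometry, unit=Unit.TBR)


def affected_volume(
    tbr: Volume3D, structure_mask: np.ndarray, cfg: ExtractionConfig = ExtractionConfig()
) -> float:
    """Amyloid-affected volume (mL): expanded-region voxels with TBR >= threshold."""
    if tbr.unit is not Unit.TBR:
        raise UnitError(f"affected_volume expects a TBR volume, got {tbr.unit.value}")
    mask = _check_mask(tbr, structure_mask)
    region = dilate_mm(mask, tbr.geometry, cfg.expansion_mm)
    n = int(np.count_nonzero(tbr.values[region] >= cfg.tbr_threshold))
    return n * tbr.geometry.voxel_volume_ml


def _paraspinal_cropped(structures: StructureSet) -> np.ndarray:
    """Right paraspinal mask restricted axially to the world-z span of T7-T11."""
    para = structures.require("PARASPINAL_RIGHT")
    _, _, zc = structures.geometry.voxel_centers_world()
    zvals = [zc[structures.require(v)] for v in VERTEBRAE]
    z_all = np.concatenate([z for z in zvals if z.size])
    if z_all.size == 0:
        raise EmptyStructureError("all T7-T11 vertebra masks are empty")
    lo, hi = z_all.min(), z_all.max()
    cropped = para & (zc >= lo) & (zc <= hi)
    if not cropped.any():
        raise EmptyStructureError("paraspinal mask is empty after T7-T11 axial crop")
    return cropped


def retention_index(
    suv: Volume3D,
    structures: StructureSet,
    cfg: ExtractionConfig = ExtractionConfig(),
    _mean_map: Optional[np.ndarray] = None,
) -> float:
    """Cardiac retention index.

    SUVpeak(myocardium) / SUVpeak(T9) x SUVpeak(right paraspinal muscle
    cropped to the T7-T11 axial span).  Masks are used undilated unless
    ``cfg.dilate_for_retention_index`` is set.
    """
    if structures.geometry != suv.geometry:
        raise GeometryError("structures must be on the SUV grid for retention_index")
    myo = structures.require("MYOCARDIUM")
    t9 = structures.require("T9")
    para = _paraspinal_cropped(structures)
    if cfg.dilate_for_retention_index:
        myo = dilate_mm(myo, suv.geometry, cfg.expansion_mm)
        t9 = dilate_mm(t9, suv.geometry, cfg.expansion_mm)
        para = dilate_mm(para, suv.geometry, cfg.expansion_mm)
    mm = sphere_mean_map(suv, cfg.peak_voi_ml) if _mean_map is None else _mean_map
    peak_t9 = suv_peak(suv, t9, cfg.peak_voi_ml, _mean_map=mm)
    if peak_t9 == 0:
        raise InvalidReferenceError("SUVpeak of T9 is zero; retention index undefined")
    return (
        suv_peak(suv, myo, cfg.peak_voi_ml, _mean_map=mm)
        / peak_t9
        * suv_peak(suv, para, cfg.peak_voi_ml, _mean_map=mm)
    )


# ---------------------------------------------------------------------------
# full panel
# ---------------------------------------------------------------------------


def extract_panel(
    suv: Volume3D,
    structures: StructureSet,
    cfg: ExtractionConfig = ExtractionConfig(),
) -> MarkerPanel:
    """Compute the full 26-marker panel from one SPECT volume + structure set.

    Masks (typically delineated on the CT grid) are first transferred to the
    SPECT grid by nearest-neighbor resampling, then expanded per marker
    family.  Deterministic for fixed inputs; per-marker provenance (mask
    voxel counts, IVC reference, config hash) is recorded on the returned
    panel.
    """
    if suv.unit is not Unit.SUV:
        raise UnitError(f"extract_panel expects an SUV volume, got {suv.unit.value}")
    missing = structures.missing(CANONICAL_STRUCTURES)
    if missing:
        raise MissingStructureError(f"missing required structures: {', '.join(missing)}")

    # transfer to the SPECT grid
    on_spect: Dict[str, np.ndarray] = {}
    for name in CANONICAL_STRUCTURES:
        m = resample_mask(structures[name], structures.geometry, suv.geometry)
        if not m.any():
            raise EmptyStructureError(f"structure {name!r} is empty on the SPECT grid")
        on_spect[name] = m
    spect_set = StructureSet(geometry=suv.geometry, masks=on_spect)

    mean_map = sphere_mean_map(suv, cfg.peak_voi_ml)
    tbr = tbr_normalize(suv, on_spect["IVC"])
    voxvol = suv.geometry.voxel_volume_ml

    values: Dict[str, float] = {}
    prov: Dict[str, object] = {
        "config_hash": cfg.config_hash,
        "config": dict(cfg.__dict__),
        "ivc_mean_suv": float(suv.values[on_spect["IVC"]].mean()),
        "structures": {},
    }

    dilated: Dict[str, np.ndarray] = {}
    for s in CARDIAC_STRUCTURES:
        dilated[s] = dilate_mm(on_spect[s], suv.geometry, cfg.expansion_mm)
        prov["structures"][s] = {
            "voxels": int(on_spect[s].sum()),
            "voxels_expanded": int(dilated[s].sum()),
            "volume_ml": round(int(on_spect[s].sum()) * voxvol, 6),
            "volume_expanded_ml": round(int(dilated[s].sum()) * voxvol, 6),
        }

    def _family(name: str, region: np.ndarray) -> None:
        values[f"SUVmax_{name}"] = suv_max(suv, region)
        values[f"SUVmean_{name}"] = suv_mean(suv, region)
        values[f"SUVpeak_{name}"] = suv_peak(suv, region, cfg.peak_voi_ml, _mean_map=mean_map)

    try:
        for s in CARDIAC_STRUCTURES:
            _family(s, dilated[s])
        ri = retention_index(suv, spect_set, cfg, _mean_map=mean_map)
        values["RETENTION_INDEX"] = ri
        for s in CARDIAC_STRUCTURES:
            values[f"AMYLOID_ACTIVITY_{s}"] = suv_mean(suv, dilated[s]) * mask_volume_ml(
                dilated[s], suv.geometry
            )
        for s in CARDIAC_STRUCTURES:
            n = int(np.count_nonzero(tbr.values[dilated[s]] >= cfg.tbr_threshold))
            values[f"AFFECTED_VOLUME_{s}"] = n * voxvol
    except Exception as exc:  # attach marker context
        computed = len(values)
        raise type(exc)(f"{exc} (while computing marker #{computed + 1})") from exc

    ordered = {name: values[name] for name in MARKER_NAMES}

    extras: Dict[str, float] = {}
    if cfg.include_combined_chambers:
        ventricles = dilate_mm(
            on_spect["LV"] | on_spect["RV"], suv.geometry, cfg.expansion_mm
        )
        atria = dilate_mm(on_spect["LA"] | on_spect["RA"], suv.geometry, cfg.expansion_mm)
        for label, region in (("VENTRICLES", ventricles), ("ATRIA", atria)):
            extras[f"SUVmax_{label}"] = suv_max(suv, region)
            extras[f"SUVmean_{label}"] = suv_mean(suv, region)
            extras[f"SUVpeak_{label}"] = suv_peak(
                suv, region, cfg.peak_voi_ml, _mean_map=mean_map
            )

    return MarkerPanel(values=ordered, extras=extras, provenance=prov)
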