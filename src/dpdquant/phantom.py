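"""Digital thorax phantom and cohort simulator.

`generate_phantom` rasterizes a parametric thorax — an ellipsoidal-shell
myocardium with four chamber ellipsoids, cylindrical T7-T11 vertebrae, a
right paraspinal box and an inferior-vena-cava cylinder — onto a voxel grid,
paints known per-structure uptake, and optionally degrades the emission image
with a Gaussian point-spread function and noise.  The emitted masks are the
*pre-blur* rasterizations (the "CT truth"), while the SPECT-like image is
blurred/noisy, deliberately reproducing the spill-out situation that the
10 mm mask expansion in the marker definitions addresses.  Analytic ground
truth for every marker is computed from the clean image with direct
element-wise code, independent of the extraction implementations.

`generate_cohort` simulates paired pre/post marker panels (log-normal
baselines matched to the published cohort medians/IQRs, multiplicative
treatment effects) plus clinical covariates and a proportional-hazards
outcome keyed to the sign of the right-ventricular affected-volume change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .cohort import CohortTable
from .errors import PhantomSpecError
from .geometry import (
    CANONICAL_STRUCTURES,
    CARDIAC_STRUCTURES,
    VERTEBRAE,
    GridGeometry,
    StructureSet,
    Unit,
    Volume3D,
    dilate_mm,
)
from .markers import MARKER_NAMES, ExtractionConfig, sphere_radius_mm
from .reference import PUBLISHED_MARKER_TABLE

__all__ = [
    "Ellipsoid",
    "EllipsoidShell",
    "Cylinder",
    "Box",
    "NoiseModel",
    "PhantomSpec",
    "PhantomTruth",
    "default_thorax",
    "generate_phantom",
    "generate_cohort",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# analytic shapes (world mm)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Ellipsoid:
    center: Tuple[float, float, float]
    radii: Tuple[float, float, float]

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        rx, ry, rz = self.radii
        return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0

    def bounds(self):
        c, r = np.asarray(self.center), np.asarray(self.radii)
        return c - r, c + r


@dataclass(frozen=True)
class EllipsoidShell:
    """Between an inner ellipsoid and the concentric ellipsoid inflated by
    ``thickness`` mm on every radius (a myocardial-wall stand-in)."""

    center: Tuple[float, float, float]
    inner_radii: Tuple[float, float, float]
    thickness: float

    @property
    def outer_radii(self) -> Tuple[float, float, float]:
        return tuple(r + self.thickness for r in self.inner_radii)

    def contains(self, x, y, z):
        outer = Ellipsoid(self.center, self.outer_radii)
        inner = Ellipsoid(self.center, self.inner_radii)
        return outer.contains(x, y, z) & ~inner.contains(x, y, z)

    def bounds(self):
        return Ellipsoid(self.center, self.outer_radii).bounds()


@dataclass(frozen=True)
class Cylinder:
    """Axis-aligned circular cylinder (axis = world z)."""

    center: Tuple[float, float, float]
    radius: float
    height: float

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        return ((x - cx) ** 2 + (y - cy) ** 2 <= self.radius**2) & (
            np.abs(z - cz) <= self.height / 2.0
        )

    def bounds(self):
        c = np.asarray(self.center)
        r = np.array([self.radius, self.radius, self.height / 2.0])
        return c - r, c + r


@dataclass(frozen=True)
class Box:
    center: Tuple[float, float, float]
    size: Tuple[float, float, float]

    def contains(self, x, y, z):
        c, s = self.center, self.size
        return (
            (np.abs(x - c[0]) <= s[0] / 2.0)
            & (np.abs(y - c[1]) <= s[1] / 2.0)
            & (np.abs(z - c[2]) <= s[2] / 2.0)
        )

    def bounds(self):
        c, s = np.asarray(self.center), np.asarray(self.size)
        return c - s / 2.0, c + s / 2.0


@dataclass(frozen=True)
class NoiseModel:
    """Emission-noise model: ``none``, ``gaussian`` (additive SD in SUV) or
    ``poisson`` (counts-per-SUV scale; larger = less noise)."""

    kind: str = "none"
    param: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian", "poisson"):
            raise PhantomSpecError(f"unknown noise kind {self.kind!r}")
        if self.kind != "none" and self.param <= 0:
            raise PhantomSpecError(f"{self.kind} noise needs a positive parameter")


# chamber structures allowed to abut/overlap the myocardial shell
_MYO_OVERLAP_OK = {frozenset({"MYOCARDIUM", s}) for s in ("LV", "RV", "LA", "RA")}


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric thorax phantom definition.

    ``grid`` is the SPECT grid; masks are rasterized on ``ct_grid`` (defaults
    to the SPECT grid).  ``shapes``/``uptake`` map canonical structure names
    to analytic shapes and SUV values; ``psf_fwhm_mm`` and ``noise`` degrade
    the emission image only.
    """

    grid: GridGeometry
    shapes: Mapping[str, object]
    uptake: Mapping[str, float]
    background_suv: float = 0.5
    psf_fwhm_mm: float = 8.0
    noise: NoiseModel = NoiseModel()
    seed: int = 0
    ct_grid: Optional[GridGeometry] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "shapes", dict(self.shapes))
        object.__setattr__(self, "uptake", dict(self.uptake))
        if self.psf_fwhm_mm < 0:
            raise PhantomSpecError("psf_fwhm_mm must be >= 0")
        if self.background_suv < 0:
            raise PhantomSpecError("background_suv must be >= 0")
        for name in self.shapes:
            if name not in CANONICAL_STRUCTURES:
                raise PhantomSpecError(f"unknown structure {name!r}")
            if name not in self.uptake:
                raise PhantomSpecError(f"no uptake specified for {name!r}")
        for name, u in self.uptake.items():
            if u < 0:
                raise PhantomSpecError(f"uptake for {name!r} must be >= 0")
        if "IVC" in self.uptake and self.uptake["IVC"] <= 0:
            raise PhantomSpecError("IVC uptake must be > 0 (TBR reference)")
        lo_w, hi_w = self.grid.world_bounds()
        half = np.asarray(self.grid.spacing) / 2.0
        for name, shape in self.shapes.items():
            lo, hi = shape.bounds()
            if np.any(lo < lo_w - half) or np.any(hi > hi_w + half):
                raise PhantomSpecError(f"structure {name!r} extends outside the grid")

    @property
    def mask_grid(self) -> GridGeometry:
        return self.ct_grid if self.ct_grid is not None else self.grid


def default_thorax(
    spacing_mm: float = 3.0,
    myocardium_suv: float = 12.0,
    background_suv: float = 0.5,
    psf_fwhm_mm: float = 8.0,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    ct_spacing_mm: Optional[float] = None,
) -> PhantomSpec:
    """A realistic-scale default thorax (240 x 240 x 288 mm field of view).

    Uptake follows the pattern of a strongly tracer-avid amyloid heart:
    bright myocardial wall, low blood-pool chambers, moderate vertebral bone,
    unit soft tissue (paraspinal) and blood (IVC) references.
    """
    shape = tuple(int(round(extent / spacing_mm)) for extent in (240, 240, 288))
    grid = GridGeometry(shape=shape, spacing=(spacing_mm,) * 3)
    ct_grid = None
    if ct_spacing_mm is not None:
        ct_shape = tuple(int(round(extent / ct_spacing_mm)) for extent in (240, 240, 288))
        ct_grid = GridGeometry(shape=ct_shape, spacing=(ct_spacing_mm,) * 3)

    heart = (95.0, 120.0, 190.0)
    shapes = {
        "LV": Ellipsoid(heart, (26.0, 26.0, 34.0)),
        "MYOCARDIUM": EllipsoidShell(heart, (26.0, 26.0, 34.0), thickness=14.0),
        "RV": Ellipsoid((152.0, 120.0, 190.0), (16.0, 22.0, 28.0)),
        "LA": Ellipsoid((95.0, 120.0, 256.0), (18.0, 18.0, 16.0)),
        "RA": Ellipsoid((152.0, 120.0, 248.0), (15.0, 18.0, 14.0)),
        "T7": Cylinder((120.0, 45.0, 250.0), 13.0, 20.0),
        "T8": Cylinder((120.0, 45.0, 225.0), 13.0, 20.0),
        "T9": Cylinder((120.0, 45.0, 200.0), 13.0, 20.0),
        "T10": Cylinder((120.0, 45.0, 175.0), 13.0, 20.0),
        "T11": Cylinder((120.0, 45.0, 150.0), 13.0, 20.0),
        "PARASPINAL_RIGHT": Box((160.0, 45.0, 200.0), (24.0, 24.0, 116.0)),
        "IVC": Cylinder((60.0, 60.0, 170.0), 9.0, 90.0),
    }
    uptake = {
        "MYOCARDIUM": myocardium_suv,
        "LV": 2.0,
        "RV": 1.8,
        "LA": 1.6,
        "RA": 1.6,
        "T7": 5.0,
        "T8": 5.0,
        "T9": 5.0,
        "T10": 5.0,
        "T11": 5.0,
        "PARASPINAL_RIGHT": 1.0,
        "IVC": 1.0,
    }
    return PhantomSpec(
        grid=grid,
        shapes=shapes,
        uptake=uptake,
        background_suv=background_suv,
        psf_fwhm_mm=psf_fwhm_mm,
        noise=noise,
        seed=seed,
        ct_grid=ct_grid,
    )


# ---------------------------------------------------------------------------
# ground truth (direct computation on the clean image)
# ---------------------------------------------------------------------------


@dataclass
class PhantomTruth:
    """Analytic ground truth for the noiseless, unblurred phantom."""

    uptake: Dict[str, float]
    volume_ml: Dict[str, float]  # undilated, all structures
    dilated_volume_ml: Dict[str, float]  # cardiac structures, 10 mm expanded
    panel: Dict[str, float]  # the 26 markers under the default config
    suv_mean_undilated: Dict[str, float]  # per cardiac structure (= uptake)


def _brute_sphere_peak(values, mask, spacing, voi_ml) -> float:
    """SUVpeak by explicit per-center sphere enumeration (truth path)."""
    r = sphere_radius_mm(voi_ml)
    half = [int(np.floor(r / s)) for s in spacing]
    offs = [
        (i, j, k)
        for i in range(-half[0], half[0] + 1)
        for j in range(-half[1], half[1] + 1)
        for k in range(-half[2], half[2] + 1)
        if (i * spacing[0]) ** 2 + (j * spacing[1]) ** 2 + (k * spacing[2]) ** 2
        <= r**2 * (1 + 1e-12)
    ]
    centers = np.argwhere(mask)
    shape = np.asarray(values.shape)
    best = -np.inf
    offs = np.asarray(offs)
    for c in centers:
        pts = c + offs
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        p = pts[ok]
        m = values[p[:, 0], p[:, 1], p[:, 2]].mean()
        if m > best:
            best = m
    return float(best)


def _truth_from_clean(
    clean: np.ndarray, masks: Dict[str, np.ndarray], spec: PhantomSpec, cfg: ExtractionConfig
) -> PhantomTruth:
    g = spec.grid
    voxvol = g.voxel_volume_ml
    sp = g.spacing

    volume_ml = {n: float(m.sum()) * voxvol for n, m in masks.items()}
    dilated = {s: dilate_mm(masks[s], g, cfg.expansion_mm) for s in CARDIAC_STRUCTURES}
    dilated_volume_ml = {s: float(d.sum()) * voxvol for s, d in dilated.items()}

    ivc_mean = clean[masks["IVC"]].sum() / masks["IVC"].sum()
    tbr = clean / ivc_mean

    panel: Dict[str, float] = {}
    for s in CARDIAC_STRUCTURES:
        region = dilated[s]
        vals = clean[region]
        panel[f"SUVmax_{s}"] = float(vals.max())
        panel[f"SUVmean_{s}"] = float(vals.sum() / vals.size)
        panel[f"SUVpeak_{s}"] = _brute_sphere_peak(clean, region, sp, cfg.peak_voi_ml)

    # retention index on undilated masks, paraspinal cropped to T7-T11 z span
    _, _, zc = g.voxel_centers_world()
    zs = np.concatenate([zc[masks[v]] for v in VERTEBRAE if masks[v].any()])
    para = masks["PARASPINAL_RIGHT"] & (zc >= zs.min()) & (zc <= zs.max())
    peak_myo = _brute_sphere_peak(clean, masks["MYOCARDIUM"], sp, cfg.peak_voi_ml)
    peak_t9 = _brute_sphere_peak(clean, masks["T9"], sp, cfg.peak_voi_ml)
    peak_para = _brute_sphere_peak(clean, para, sp, cfg.peak_voi_ml)
    panel["RETENTION_INDEX"] = peak_myo / peak_t9 * peak_para

    for s in CARDIAC_STRUCTURES:
        panel[f"AMYLOID_ACTIVITY_{s}"] = float(clean[dilated[s]].sum()) * voxvol
    for s in CARDIAC_STRUCTURES:
        n_aff = int(np.count_nonzero(tbr[dilated[s]] >= cfg.tbr_threshold))
        panel[f"AFFECTED_VOLUME_{s}"] = n_aff * voxvol

    panel = {name: panel[name] for name in MARKER_NAMES}
    suv_mean_undilated = {
        s: float(clean[masks[s]].sum() / masks[s].sum()) for s in CARDIAC_STRUCTURES
    }
    return PhantomTruth(
        uptake=dict(spec.uptake),
        volume_ml=volume_ml,
        dilated_volume_ml=dilated_volume_ml,
        panel=panel,
        suv_mean_undilated=suv_mean_undilated,
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _rasterize(spec: PhantomSpec, grid: GridGeometry) -> Dict[str, np.ndarray]:
    x, y, z = grid.voxel_centers_world()
    return {name: np.asarray(shape.contains(x, y, z)) for name, shape in spec.shapes.items()}


def _check_disjoint(masks: Dict[str, np.ndarray]) -> None:
    names = list(masks)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if frozenset({a, b}) in _MYO_OVERLAP_OK:
                continue
            if np.any(masks[a] & masks[b]):
                raise PhantomSpecError(f"structures {a!r} and {b!r} overlap")


def generate_phantom(
    spec: PhantomSpec, cfg: ExtractionConfig = ExtractionConfig()
) -> Tuple[Volume3D, StructureSet, PhantomTruth]:
    """Rasterize, paint, blur and noise one phantom.

    Returns the SPECT-like SUV volume, the pre-blur binary masks (on the CT
    grid) and the analytic ground truth (computed from the clean image under
    ``cfg``).  Identical spec + seed give identical output.
    """
    masks_spect = _rasterize(spec, spec.grid)
    _check_disjoint(masks_spect)
    for name, m in masks_spect.items():
        if not m.any():
            raise PhantomSpecError(f"structure {name!r} rasterizes to an empty mask")

    clean = np.full(spec.grid.shape, float(spec.background_suv))
    # paint the myocardium first so chambers override any modeled overlap
    order = ["MYOCARDIUM"] + [n for n in masks_spect if n != "MYOCARDIUM"]
    for name in order:
        if name in masks_spect:
            clean[masks_spect[name]] = spec.uptake[name]

    truth = _truth_from_clean(clean, masks_spect, spec, cfg)

    img = clean
    if spec.psf_fwhm_mm > 0:
        sigma_vox = [
            spec.psf_fwhm_mm * _FWHM_TO_SIGMA / s for s in spec.grid.spacing
        ]
        img = ndimage.gaussian_filter(img, sigma=sigma_vox, mode="nearest")
    rng = np.random.default_rng(spec.seed)
    if spec.noise.kind == "gaussian":
        img = img + rng.normal(0.0, spec.noise.param, size=img.shape)
    elif spec.noise.kind == "poisson":
        img = rng.poisson(np.clip(img, 0, None) * spec.noise.param) / spec.noise.param
    img = np.clip(img, 0.0, None)

    volume = Volume3D(values=img, geometry=spec.grid, unit=Unit.SUV)

    if spec.ct_grid is not None:
        masks_ct = _rasterize(spec, spec.ct_grid)
        structures = StructureSet(geometry=spec.ct_grid, masks=masks_ct)
    else:
        structures = StructureSet(geometry=spec.grid, masks=masks_spect)
    return volume, structures, truth


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

_TREATMENTS = ("tafamidis", "patisiran", "inotersen")
_TREATMENT_P = (37 / 45, 5 / 45, 3 / 45)


def _lognormal_sigma(q1: float, q3: float) -> float:
    # IQR of a log-normal: log-quartiles are mu +/- 0.67449 sigma
    return (np.log(q3) - np.log(q1)) / (2.0 * 0.6744897501960817)


def generate_cohort(
    n_patients: int,
    effect: Optional[Mapping[str, float]] = None,
    hazard_marker: str = "AFFECTED_VOLUME_RV",
    hazard_ratio: float = 3.19,
    baseline_hazard_per_month: float = 0.016,
    censor_window_months: Tuple[float, float] = (12.0, 72.0),
    post_noise_sd: float = 0.10,
    seed: int = 0,
) -> CohortTable:
    """Simulate a paired pre/post treatment-response cohort.

    Per-marker baselines are log-normal with medians and spreads matched to
    the published cohort table; post-treatment values apply per-marker
    multiplicative effects (default: the published post/pre median ratios)
    with patient-level log-normal noise of SD ``post_noise_sd``.  Event times
    follow an exponential proportional-hazards model whose hazard is
    multiplied by ``hazard_ratio`` for patients whose ``hazard_marker``
    change is >= 0; censoring is uniform over ``censor_window_months``.
    Per-patient random streams are spawned from one root seed, so the cohort
    is reproducible regardless of generation order.
    """
    if n_patients < 2:
        raise PhantomSpecError("n_patients must be >= 2")
    eff = {m: PUBLISHED_MARKER_TABLE[m].post_median / PUBLISHED_MARKER_TABLE[m].pre_median
           for m in MARKER_NAMES}
    if effect is not None:
        for m, v in effect.items():
            if m not in eff:
                raise PhantomSpecError(f"unknown marker {m!r} in effect map")
            if v <= 0:
                raise PhantomSpecError(f"effect multiplier for {m!r} must be > 0")
            eff[m] = float(v)
    if hazard_ratio <= 0 or baseline_hazard_per_month <= 0:
        raise PhantomSpecError("hazard parameters must be > 0")
    if post_noise_sd < 0:
        raise PhantomSpecError("post_noise_sd must be >= 0")

    streams = np.random.SeedSequence(seed).spawn(n_patients)
    rows = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        row: Dict[str, object] = {"patient_id": f"P{i + 1:04d}"}
        row["age"] = float(np.clip(rng.normal(76.8, 9.8), 40, 100))
        row["sex"] = "M" if rng.random() < 0.822 else "F"
        row["treatment"] = _TREATMENTS[rng.choice(3, p=_TREATMENT_P)]

        nyha_pre = int(rng.choice([1, 2, 3, 4], p=np.array([5, 11, 22, 0]) / 38.0))
        d_nyha = int(rng.choice([-2, -1, 0, 1], p=np.array([1, 10, 26, 1]) / 38.0))
        row["nyha_pre"] = nyha_pre
        row["nyha_post"] = int(np.clip(nyha_pre + d_nyha, 1, 4))

        probnp = float(rng.lognormal(7.618, 1.019))
        row["ntprobnp_pre"] = probnp
        row["ntprobnp_post"] = max(0.0, probnp + rng.normal(167.0, 1677.0))
        trop = float(rng.lognormal(3.832, 0.734))
        row["troponin_pre"] = trop
        row["troponin_post"] = max(0.0, trop + rng.normal(3.86, 11.92))
        mwd = float(np.clip(rng.normal(388.7, 131.9), 0, None))
        row["sixmwd_pre"] = mwd
        row["sixmwd_post"] = float(np.clip(mwd + rng.normal(-4.53, 75.16), 0, None))

        for m in MARKER_NAMES:
            ref = PUBLISHED_MARKER_TABLE[m]
            sigma = _lognormal_sigma(ref.pre_q1, ref.pre_q3)
            pre = float(rng.lognormal(np.log(ref.pre_median), sigma))
            noise = float(rng.normal(0.0, post_noise_sd)) if post_noise_sd > 0 else 0.0
            post = pre * eff[m] * float(np.exp(noise))
            row[f"pre_{m}"] = pre
            row[f"post_{m}"] = post

        increased = row[f"post_{hazard_marker}"] - row[f"pre_{hazard_marker}"] >= 0
        rate = baseline_hazard_per_month * (hazard_ratio if increased else 1.0)
        t_event = float(rng.exponential(1.0 / rate))
        t_censor = float(rng.uniform(*censor_window_months))
        row["time_months"] = min(t_event, t_censor)
        row["event"] = int(t_event <= t_censor)
        rows.append(row)

    return CohortTable(pd.DataFrame(rows))
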