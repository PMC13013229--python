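"""NIfTI and table I/O.

Volumes and masks interchange as NIfTI-1 via nibabel; grid geometry (spacing,
origin, orientation) lives in the header affine.  Structure sets load either
from one multi-label volume plus a name->integer label map, or from one
binary NIfTI per structure named ``<STRUCTURE>.nii``/``.nii.gz``.  Marker
panels write as one CSV row per scan (canonical column order, scan id and
config hash first) with a sidecar JSON provenance log.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import PairedTestResult, SurvivalResult
from .errors import GeometryError, MissingStructureError
from .geometry import (
    CANONICAL_STRUCTURES,
    GridGeometry,
    StructureSet,
    Unit,
    Volume3D,
)
from .markers import MARKER_NAMES, MarkerPanel

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "load_structures",
    "write_panel_csv",
    "write_provenance_json",
    "write_change_table_csv",
    "write_survival_table_csv",
    "write_km_curves_csv",
]


def _load_nifti(path) -> tuple[np.ndarray, GridGeometry]:
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise GeometryError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise GeometryError(f"{path}: expected a 3-D image, got shape {data.shape}")
    try:
        geom = GridGeometry.from_affine(data.shape, img.affine)
    except GeometryError as exc:
        raise GeometryError(f"{path}: {exc}") from exc
    return data, geom


def read_volume(path, unit: Unit = Unit.SUV) -> Volume3D:
    """Load a 3-D NIfTI volume; the unit tag comes from the caller/config."""
    data, geom = _load_nifti(path)
    return Volume3D(values=np.asarray(data, dtype=float), geometry=geom, unit=unit)


def write_volume(volume: Volume3D, path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float64), volume.geometry.affine)
    nib.save(img, str(path))


def read_mask(path) -> tuple[np.ndarray, GridGeometry]:
    data, geom = _load_nifti(path)
    return data > 0.5, geom


def write_mask(mask: np.ndarray, geometry: GridGeometry, path) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), geometry.affine)
    nib.save(img, str(path))


def load_structures(
    labels_path=None,
    label_map: Optional[Mapping[str, int]] = None,
    mask_dir=None,
    required: Sequence[str] = CANONICAL_STRUCTURES,
) -> StructureSet:
    """Load a structure set from a multi-label volume or a directory of masks.

    Exactly one of ``labels_path`` (+ ``label_map``) or ``mask_dir`` must be
    given.  Required structures that are missing or empty are reported before
    extraction starts.
    """
    if (labels_path is None) == (mask_dir is None):
        raise ValueError("provide exactly one of labels_path or mask_dir")

    masks: Dict[str, np.ndarray] = {}
    if labels_path is not None:
        if label_map is None:
            raise ValueError("labels_path requires a label_map (name -> integer label)")
        data, geom = _load_nifti(labels_path)
        labels = np.asarray(np.rint(data), dtype=int)
        mapped = set(int(v) for v in label_map.values())
        present = set(int(v) for v in np.unique(labels)) - {0}
        unknown = present - mapped
        if unknown:
            raise MissingStructureError(
                f"labels {sorted(unknown)} present in {labels_path} but absent from the label map"
            )
        for name, lab in label_map.items():
            masks[name] = labels == int(lab)
    else:
        mask_dir = Path(mask_dir)
        geom = None
        for name in CANONICAL_STRUCTURES:
            for suffix in (".nii", ".nii.gz"):
                p = mask_dir / f"{name}{suffix}"
                if p.exists():
                    m, g = read_mask(p)
                    if geom is None:
                        geom = g
                    elif g != geom:
                        raise GeometryError(f"mask {p} is on a different grid than the others")
                    masks[name] = m
                    break
        if geom is None:
            raise MissingStructureError(f"no canonical structure masks found in {mask_dir}")

    ss = StructureSet(geometry=geom, masks=masks)
    missing = ss.missing(required)
    if missing:
        raise MissingStructureError(f"missing required structures: {', '.join(missing)}")
    empty = ss.empty(required)
    if empty:
        raise MissingStructureError(f"empty required structures: {', '.join(empty)}")
    return ss


# ---------------------------------------------------------------------------
# tabular outputs
# ---------------------------------------------------------------------------


def write_panel_csv(panels: Mapping[str, MarkerPanel], path) -> None:
    """One CSV row per scan: scan_id, config_hash, then the 26 marker columns."""
    rows = []
    for scan_id, panel in panels.items():
        row = {"scan_id": scan_id, "config_hash": panel.provenance.get("config_hash", "")}
        row.update(panel.as_dict())
        row.update(panel.extras)
        rows.append(row)
    cols = ["scan_id", "config_hash"] + list(MARKER_NAMES)
    extra_cols = [c for c in rows[0] if c not in cols] if rows else []
    pd.DataFrame(rows).to_csv(path, index=False, columns=cols + extra_cols)


def write_provenance_json(panels: Mapping[str, MarkerPanel], path) -> None:
    payload = {scan_id: panel.provenance for scan_id, panel in panels.items()}
    Path(path).write_text(json.dumps(payload, indent=2, default=str))


def write_change_table_csv(rows: Iterable[PairedTestResult], path) -> None:
    """Published-style marker change table (one row per marker, sorted as given)."""
    recs = []
    for r in rows:
        recs.append(
            {
                "marker": r.marker,
                "p_value_unadjusted": r.p_value,
                "test": r.test_used,
                "pre_median": r.pre_median,
                "pre_q1": r.pre_iqr[0],
                "pre_q3": r.pre_iqr[1],
                "post_median": r.post_median,
                "post_q1": r.post_iqr[0],
                "post_q3": r.post_iqr[1],
                "n_pairs": r.n_pairs,
                "n_dropped": r.n_dropped,
                "error": r.error or "",
            }
        )
    pd.DataFrame(recs).to_csv(path, index=False)


def write_survival_table_csv(results: Iterable[SurvivalResult], path) -> None:
    recs = []
    for r in results:
        recs.append(
            {
                "marker": r.marker,
                "univariate_hr": r.univariate_hr,
                "univariate_ci_low": r.univariate_ci[0],
                "univariate_ci_high": r.univariate_ci[1],
                "logrank_p": r.logrank_p,
                "adjusted_hr": r.adjusted_hr,
                "adjusted_ci_low": r.adjusted_ci[0] if r.adjusted_ci else None,
                "adjusted_ci_high": r.adjusted_ci[1] if r.adjusted_ci else None,
                "adjusted_p": r.adjusted_p,
                "n_used": r.n_used,
                "n_increase": r.n_increase,
                "n_decrease": r.n_decrease,
                "n_events": r.n_events,
                "n_complete_case": r.n_complete_case,
            }
        )
    pd.DataFrame(recs).to_csv(path, index=False)


def write_km_curves_csv(result: SurvivalResult, path) -> None:
    frames = []
    for label, sf in result.km_curves.items():
        f = sf.copy()
        f.insert(0, "stratum", label)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
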