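"""Images, masks and metric tables: the coordinate and labeling conventions.

Conventions used throughout the package:

* arrays are row-major, 0-based; row 0 is the **top** of the image and
  "vertical" means along rows (glands run roughly top to bottom);
* masks are co-registered with the grayscale image — no geometric
  transforms happen anywhere in this package;
* gland label maps are *canonical*: labels form the contiguous set
  ``1..K``, each label is a single 8-connected component, and labels are
  ordered by raster scan of each component's topmost-leftmost pixel so
  repeated runs and platforms agree;
* every gland pixel must lie inside the tarsus mask — a violation is a
  hard :class:`~meibomorph.errors.MaskConsistencyError`, never silently
  clipped, because the density definition presumes glands ⊆ tarsus.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .errors import MaskConsistencyError, ValidationError

#: 8-connectivity structuring element (diagonal pixels join a component).
STRUCTURE_8 = np.ones((3, 3), dtype=bool)

#: Fixed column order of the metrics CSV written by :func:`write_metrics_table`.
METRICS_COLUMNS = [
    "subject_id",
    "eye_role",
    "eyelid",
    "gland_id",
    "height_px",
    "width_px",
    "tortuosity",
    "density",
    "vagueness",
    "interval_months",
    "tbut_s",
    "tmh_mm",
]

EYE_ROLES = ("research", "control")
EYELIDS = ("upper", "lower")


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale raster (the meibography photograph)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError(f"grayscale image must be 2-D and non-empty, got shape {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValidationError(f"grayscale image must be integer-valued, got dtype {px.dtype}")
        if px.min() < 0:
            raise ValidationError("grayscale image has negative intensities")
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class GlandLabelMap:
    """Integer-labeled raster: 0 = background, k ≥ 1 = gland id (canonical)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValidationError("label map must be 2-D")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValidationError("label map must be integer-valued")
        if lab.min() < 0:
            raise ValidationError("label map contains negative labels")
        object.__setattr__(self, "labels", lab.astype(np.int32, copy=False))

    @property
    def n_glands(self) -> int:
        return int(self.labels.max())

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def pixel_count(self) -> int:
        return int(np.count_nonzero(self.labels))


@dataclass(frozen=True)
class TarsusMask:
    """Binary raster delimiting the tarsal plate (region of interest)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValidationError("tarsus mask must be 2-D")
        m = m.astype(bool)
        if not m.any():
            raise ValidationError("tarsus mask is empty")
        object.__setattr__(self, "mask", m)

    @property
    def area_px(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class SubjectMeta:
    """Per-eyelid metadata: eye role in the paired design plus clinical covariates."""

    subject_id: str
    eye_role: str
    eyelid: str
    interval_months: float | None = None
    tbut_s: float | None = None
    tmh_mm: float | None = None

    def __post_init__(self) -> None:
        if self.eye_role not in EYE_ROLES:
            raise ValidationError(f"eye_role must be one of {EYE_ROLES}, got {self.eye_role!r}")
        if self.eyelid not in EYELIDS:
            raise ValidationError(f"eyelid must be one of {EYELIDS}, got {self.eyelid!r}")
        for name in ("interval_months", "tbut_s", "tmh_mm"):
            v = getattr(self, name)
            if v is not None and not np.isnan(v) and v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")


# ---------------------------------------------------------------------------
# raster reading / writing
# ---------------------------------------------------------------------------

def _load_array(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    if path.suffix.lower() not in {".png", ".tif", ".tiff"}:
        raise ValidationError(f"unsupported image format: {path.suffix!r} (PNG or TIFF expected)")
    with Image.open(path) as img:
        return np.asarray(img)


def read_gray_image(path: str | Path) -> GrayImage:
    """Read an 8/16-bit PNG or TIFF as a grayscale image.

    Multi-channel input is accepted only when all color channels are equal
    (a grayscale picture stored as RGB); true color content is rejected.
    """
    arr = _load_array(path)
    if arr.ndim == 3:
        rgb = arr[..., :3]
        if not (np.array_equal(rgb[..., 0], rgb[..., 1]) and np.array_equal(rgb[..., 0], rgb[..., 2])):
            raise ValidationError(f"{path}: true-color image; expected grayscale (equal channels)")
        arr = rgb[..., 0]
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValidationError(f"{path}: unsupported pixel dtype {arr.dtype}")
    return GrayImage(arr)


def write_gray_image(image: GrayImage, path: str | Path) -> None:
    arr = image.pixels
    if arr.max() <= 255:
        Image.fromarray(arr.astype(np.uint8), mode="L").save(path)
    else:
        Image.fromarray(arr.astype(np.int32), mode="I").save(path)


def canonicalize_labels(labels: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Relabel to the contiguous set 1..K in deterministic scan order.

    Components are ordered by their topmost row, ties broken by the leftmost
    column within that row.  Each input label must be a single 8-connected
    component.  Returns the canonical array and the list of original ids in
    their new order (``order[k-1]`` is the original id of canonical label k).
    """
    lab = np.asarray(labels)
    flat = lab.ravel()
    nz = np.flatnonzero(flat)
    if nz.size == 0:
        return np.zeros_like(lab, dtype=np.int32), []
    vals = flat[nz]

    # connectivity: one pass of binary component labeling, then make sure no
    # input label spans two components; labels that share a component with
    # another label get the exact per-label recheck (a bridge through the
    # other label could mask a split)
    comp, _ = ndimage.label(lab > 0, structure=STRUCTURE_8)
    comp_vals = comp.ravel()[nz]
    pairs = np.unique(np.column_stack([vals, comp_vals]), axis=0)
    ids, comps_per_label = np.unique(pairs[:, 0], return_counts=True)
    split = ids[comps_per_label > 1]
    if split.size:
        raise ValidationError(f"label {int(split[0])} is not a single 8-connected component")
    shared_comps, labels_per_comp = np.unique(pairs[:, 1], return_counts=True)
    for cid in shared_comps[labels_per_comp > 1]:
        for gid in pairs[pairs[:, 1] == cid, 0]:
            _, n_comp = ndimage.label(lab == gid, structure=STRUCTURE_8)
            if n_comp != 1:
                raise ValidationError(f"label {int(gid)} is not a single 8-connected component ({n_comp} parts)")

    # raster-scan first occurrence = topmost row, leftmost column in that row
    _, first_idx = np.unique(vals, return_index=True)
    order = [int(g) for g in ids[np.argsort(nz[first_idx])]]
    lut = np.zeros(int(lab.max()) + 1, dtype=np.int32)
    for new, gid in enumerate(order, start=1):
        lut[gid] = new
    return lut[lab], order


def read_label_map(
    path: str | Path,
    binary_ok: bool = True,
    reference_shape: tuple[int, int] | None = None,
) -> GlandLabelMap:
    """Read a gland label map; binary masks are component-labeled if ``binary_ok``."""
    arr = _load_array(path)
    if arr.ndim == 3:
        rgb = arr[..., :3]
        if not (np.array_equal(rgb[..., 0], rgb[..., 1]) and np.array_equal(rgb[..., 0], rgb[..., 2])):
            raise ValidationError(f"{path}: true-color label map")
        arr = rgb[..., 0]
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValidationError(f"{path}: label map must be integer-valued, got {arr.dtype}")
    if arr.min() < 0:
        raise ValidationError(f"{path}: negative label values")
    if reference_shape is not None and tuple(arr.shape) != tuple(reference_shape):
        raise ValidationError(f"{path}: shape {arr.shape} does not match reference {reference_shape}")
    return label_map_from_array(arr, binary_ok=binary_ok)


def label_map_from_array(arr: np.ndarray, binary_ok: bool = True) -> GlandLabelMap:
    """Canonicalize an in-memory integer array into a :class:`GlandLabelMap`."""
    arr = np.asarray(arr)
    if arr.max(initial=0) <= 1 and binary_ok:
        lab, _ = ndimage.label(arr > 0, structure=STRUCTURE_8)
    else:
        lab = arr.astype(np.int64, copy=False)
    canonical, _ = canonicalize_labels(lab)
    return GlandLabelMap(canonical)


def write_label_map(labelmap: GlandLabelMap, path: str | Path) -> None:
    lab = labelmap.labels
    if lab.max() <= 255:
        Image.fromarray(lab.astype(np.uint8), mode="L").save(path)
    else:
        Image.fromarray(lab.astype(np.int32), mode="I").save(path)


def read_tarsus_mask(path: str | Path, reference_shape: tuple[int, int] | None = None) -> TarsusMask:
    arr = _load_array(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    if reference_shape is not None and tuple(arr.shape) != tuple(reference_shape):
        raise ValidationError(f"{path}: shape {arr.shape} does not match reference {reference_shape}")
    return TarsusMask(arr > 0)


def write_tarsus_mask(tarsus: TarsusMask, path: str | Path) -> None:
    Image.fromarray(tarsus.mask.astype(np.uint8) * 255, mode="L").save(path)


def validate_glands_within_tarsus(labelmap: GlandLabelMap, tarsus: TarsusMask) -> None:
    """Every gland pixel must lie inside the tarsus; anything else is an error."""
    if labelmap.shape != tarsus.shape:
        raise ValidationError(f"label map shape {labelmap.shape} != tarsus shape {tarsus.shape}")
    outside = (labelmap.labels > 0) & ~tarsus.mask
    if outside.any():
        n = int(np.count_nonzero(outside))
        raise MaskConsistencyError(f"{n} gland pixel(s) lie outside the tarsus mask")


# ---------------------------------------------------------------------------
# metrics tables
# ---------------------------------------------------------------------------

def write_metrics_table(records: Iterable[dict] | pd.DataFrame, path: str | Path) -> None:
    """Write metric rows to CSV with the fixed schema (lossless to 6 sig. digits)."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(list(records))
    for col in METRICS_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[METRICS_COLUMNS]
    df.to_csv(path, index=False, float_format="%.6g")


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "gland_id": str})
    missing = [c for c in METRICS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: metrics table missing columns {missing}")
    return df
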