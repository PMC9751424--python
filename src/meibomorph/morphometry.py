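"""Per-gland and per-eyelid morphological indices.

The indices, in pixel units on the mask grid:

* **height** — vertical extent of the gland, ``bottom_row − top_row + 1``
  (inclusive, so a single-pixel gland has height 1; the exclusive
  ``bottom − top`` variant is available via ``inclusive=False``);
* **width** — area divided by height, so width × height = area exactly;
* **perimeter** — the number of gland pixels with at least one 4-neighbor
  outside the gland (the image border counts as outside);
* **tortuosity** — ``perimeter / (2 × H_rect) − 1`` where ``H_rect`` is the
  *longer* side of the minimum-area rotated rectangle enclosing the gland.
  A straight vertical gland has perimeter ≈ 2 × length, hence tortuosity
  near 0; lateral meandering raises the perimeter without raising the
  rectangle, so tortuosity grows with distortion;
* **density** — summed gland area divided by tarsus area, in [0, 1].

Geometry uses pixel *centers*: the pixel at (r, c) is the point (r, c), so
an axis-aligned run of ``h`` pixels has rectangle side ``h − 1``. This
center convention is what makes the filled-rectangle closed form
``(2h + 2w − 4) / (2(h − 1)) − 1`` exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import ValidationError
from .io_masks import GlandLabelMap, TarsusMask, validate_glands_within_tarsus

__all__ = [
    "GlandShape",
    "GlandMetrics",
    "EyelidMetrics",
    "gland_shapes",
    "gland_height",
    "gland_width",
    "gland_perimeter",
    "min_external_rect",
    "gland_tortuosity",
    "eyelid_density",
    "summarize_eyelid",
    "combine_eyelids",
    "boundary_pixel_mask",
]


@dataclass(frozen=True)
class GlandShape:
    """Raw geometry of one labeled gland (pixel coordinates and derived shape)."""

    gland_id: int
    rows: np.ndarray
    cols: np.ndarray
    area_px: int
    top_row: int
    bottom_row: int
    perimeter_px: int
    minrect_height_px: float
    minrect_angle_deg: float


@dataclass(frozen=True)
class GlandMetrics:
    gland_id: int
    height_px: int
    width_px: float
    tortuosity: float


@dataclass(frozen=True)
class EyelidMetrics:
    """Eyelid-level aggregate: unweighted means over glands plus density.

    ``total_gland_area_px`` / ``tarsus_area_px`` are carried so that the
    pooled (pixel-weighted) variant of the both-eyelid combination can be
    recomputed without revisiting the masks.
    """

    eyelid: str
    n_glands: int
    mean_height_px: float | None
    mean_width_px: float | None
    mean_tortuosity: float | None
    density: float
    total_gland_area_px: int = 0
    tarsus_area_px: int = 0


def boundary_pixel_mask(labels: np.ndarray) -> np.ndarray:
    """True where a gland pixel has a 4-neighbor outside its own gland."""
    lab = np.asarray(labels)
    padded = np.pad(lab, 1, constant_values=0)
    h, w = lab.shape
    out = np.zeros(lab.shape, dtype=bool)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nb = padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
        out |= nb != lab
    return out & (lab > 0)


def _normalize_angle(deg: float) -> float:
    """Map an axis direction to degrees from vertical in [−90, 90)."""
    deg = math.fmod(deg, 180.0)
    if deg >= 90.0:
        deg -= 180.0
    elif deg < -90.0:
        deg += 180.0
    if deg == -90.0:  # -90 and 90 name the same axis
        deg = -90.0
    return deg


def min_external_rect(rows: np.ndarray, cols: np.ndarray) -> tuple[float, float]:
    """Minimum-area rotated rectangle over the pixel centers of a gland.

    Returns ``(height, angle_deg)`` where height is the **longer** side of
    the rectangle — glands are elongated, and the rectangle measures length
    along the gland axis — and ``angle_deg`` is the long-axis direction
    measured from the vertical image axis, in [−90, 90).

    Rotating calipers over the convex hull: the minimum-area enclosing
    rectangle has a side collinear with a hull edge, so it suffices to test
    each edge direction.  Ties in area are broken by the smallest angle.
    Degenerate sets: a single point returns height 1 (one pixel is one
    pixel tall); collinear points return the extent of the hull segment.
    """
    pts = np.column_stack([np.asarray(rows, dtype=float), np.asarray(cols, dtype=float)])
    if pts.shape[0] == 0:
        raise ValidationError("empty gland has no enclosing rectangle")
    if pts.shape[0] == 1 or (np.ptp(pts, axis=0) == 0).all():
        return 1.0, 0.0

    centered = pts - pts.mean(axis=0)
    try:
        hull = ConvexHull(pts)
        hp = pts[hull.vertices]
    except QhullError:
        # collinear: rectangle degenerates to the hull segment
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        direction = vt[0]
        proj = centered @ direction
        extent = float(proj.max() - proj.min())
        angle = _normalize_angle(math.degrees(math.atan2(direction[1], direction[0])))
        return max(extent, 1.0), angle

    edges = np.roll(hp, -1, axis=0) - hp
    units = edges / np.hypot(edges[:, 0], edges[:, 1])[:, None]
    perp = units[:, ::-1] * np.array([-1.0, 1.0])
    pu = hp @ units.T
    pv = hp @ perp.T
    du = pu.max(axis=0) - pu.min(axis=0)
    dv = pv.max(axis=0) - pv.min(axis=0)
    areas = du * dv
    long_is_u = du >= dv
    long_side = np.where(long_is_u, du, dv)
    axes = np.where(long_is_u[:, None], units, perp)
    angles = np.array(
        [_normalize_angle(math.degrees(math.atan2(a[1], a[0]))) for a in axes]
    )
    candidates = areas <= areas.min() * (1 + 1e-12)
    i = int(np.flatnonzero(candidates)[np.argmin(angles[candidates])])
    return float(long_side[i]), float(angles[i])


def gland_shapes(labelmap: GlandLabelMap) -> list[GlandShape]:
    """Extract the shape record of every gland in a canonical label map."""
    lab = labelmap.labels
    k = labelmap.n_glands
    if k == 0:
        return []
    boundary = boundary_pixel_mask(lab)
    perim_counts = np.bincount(lab[boundary], minlength=k + 1)
    all_rows, all_cols = np.nonzero(lab)
    labs = lab[all_rows, all_cols]
    order = np.argsort(labs, kind="stable")
    counts = np.bincount(labs, minlength=k + 1)[1:]
    splits = np.cumsum(counts)[:-1]
    grouped = list(zip(np.split(all_rows[order], splits), np.split(all_cols[order], splits)))
    shapes: list[GlandShape] = []
    for gid in range(1, k + 1):
        rows, cols = grouped[gid - 1]
        if rows.size == 0:
            raise ValidationError(f"label map not canonical: label {gid} empty")
        height, angle = min_external_rect(rows, cols)
        shapes.append(
            GlandShape(
                gland_id=gid,
                rows=rows,
                cols=cols,
                area_px=int(rows.size),
                top_row=int(rows.min()),
                bottom_row=int(rows.max()),
                perimeter_px=int(perim_counts[gid]),
                minrect_height_px=height,
                minrect_angle_deg=angle,
            )
        )
    return shapes


def gland_height(shape: GlandShape, inclusive: bool = True) -> int:
    """Vertical pixel extent of the gland (top to bottom row)."""
    if shape.area_px < 1:
        raise ValidationError("empty gland has no height")
    extent = shape.bottom_row - shape.top_row
    return extent + 1 if inclusive else extent


def gland_width(shape: GlandShape, inclusive: bool = True) -> float:
    """Area divided by height."""
    h = gland_height(shape, inclusive=inclusive)
    if h == 0:
        raise ValidationError("zero height under the exclusive convention")
    return shape.area_px / h


def gland_perimeter(shape: GlandShape) -> int:
    if shape.area_px < 1:
        raise ValidationError("empty gland has no perimeter")
    return shape.perimeter_px


def gland_tortuosity(shape: GlandShape) -> float:
    """perimeter / (2 × minimum-rectangle height) − 1."""
    if shape.minrect_height_px <= 0:
        raise ValidationError("minimum rectangle height must be positive")
    return shape.perimeter_px / (2.0 * shape.minrect_height_px) - 1.0


def gland_metrics(shape: GlandShape, inclusive: bool = True) -> GlandMetrics:
    return GlandMetrics(
        gland_id=shape.gland_id,
        height_px=gland_height(shape, inclusive=inclusive),
        width_px=gland_width(shape, inclusive=inclusive),
        tortuosity=gland_tortuosity(shape),
    )


def eyelid_density(labelmap: GlandLabelMap, tarsus: TarsusMask) -> float:
    """Summed gland area over tarsus area, in [0, 1]."""
    validate_glands_within_tarsus(labelmap, tarsus)
    return labelmap.pixel_count() / tarsus.area_px


def summarize_eyelid(
    labelmap: GlandLabelMap,
    tarsus: TarsusMask,
    eyelid: str,
    inclusive: bool = True,
) -> EyelidMetrics:
    """Per-gland metrics for all K glands, aggregated with unweighted means."""
    density = eyelid_density(labelmap, tarsus)
    shapes = gland_shapes(labelmap)
    if not shapes:
        return EyelidMetrics(
            eyelid=eyelid,
            n_glands=0,
            mean_height_px=None,
            mean_width_px=None,
            mean_tortuosity=None,
            density=0.0,
            total_gland_area_px=0,
            tarsus_area_px=tarsus.area_px,
        )
    per_gland = [gland_metrics(s, inclusive=inclusive) for s in shapes]
    return EyelidMetrics(
        eyelid=eyelid,
        n_glands=len(per_gland),
        mean_height_px=float(np.mean([m.height_px for m in per_gland])),
        mean_width_px=float(np.mean([m.width_px for m in per_gland])),
        mean_tortuosity=float(np.mean([m.tortuosity for m in per_gland])),
        density=density,
        total_gland_area_px=sum(s.area_px for s in shapes),
        tarsus_area_px=tarsus.area_px,
    )


def _mean_or_none(a: float | None, b: float | None) -> float | None:
    if a is None or b is None:
        return None
    return 0.5 * (a + b)


def combine_eyelids(
    upper: EyelidMetrics | None,
    lower: EyelidMetrics | None,
    pooled: bool = False,
) -> EyelidMetrics | None:
    """Both-eyelid summary.

    Default: the unweighted mean of the two eyelid-level values (density
    included), matching how per-eyelid summaries are usually combined in
    meibography reports.  ``pooled=True`` instead recomputes gland-weighted
    means and a pixel-pooled density from the carried totals.
    Returns None when either eyelid is missing.
    """
    if upper is None or lower is None:
        return None
    n = upper.n_glands + lower.n_glands
    if pooled:
        tarsus = upper.tarsus_area_px + lower.tarsus_area_px
        area = upper.total_gland_area_px + lower.total_gland_area_px

        def _pooled(a: float | None, na: int, b: float | None, nb: int) -> float | None:
            if na == 0 or nb == 0:
                return None
            return (a * na + b * nb) / (na + nb)  # type: ignore[operator]

        return EyelidMetrics(
            eyelid="both",
            n_glands=n,
            mean_height_px=_pooled(upper.mean_height_px, upper.n_glands, lower.mean_height_px, lower.n_glands),
            mean_width_px=_pooled(upper.mean_width_px, upper.n_glands, lower.mean_width_px, lower.n_glands),
            mean_tortuosity=_pooled(upper.mean_tortuosity, upper.n_glands, lower.mean_tortuosity, lower.n_glands),
            density=area / tarsus if tarsus else 0.0,
            total_gland_area_px=area,
            tarsus_area_px=tarsus,
        )
    return EyelidMetrics(
        eyelid="both",
        n_glands=n,
        mean_height_px=_mean_or_none(upper.mean_height_px, lower.mean_height_px),
        mean_width_px=_mean_or_none(upper.mean_width_px, lower.mean_width_px),
        mean_tortuosity=_mean_or_none(upper.mean_tortuosity, lower.mean_tortuosity),
        density=0.5 * (upper.density + lower.density),
        total_gland_area_px=upper.total_gland_area_px + lower.total_gland_area_px,
        tarsus_area_px=upper.tarsus_area_px + lower.tarsus_area_px,
    )
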