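"""Vagueness value: gland-vs-background grayscale contrast within the tarsus.

On infrared meibography the glands appear bright against the tarsal plate;
conjunctival edema scatters the infrared light and washes the contrast out.
The vagueness value quantifies this as a difference of means,

    vagueness = mean gray over gland pixels − mean gray over background pixels,

where *background* is exactly the tarsus minus the glands; pixels outside
the tarsus never enter either mean.  Higher values mean a clearer picture.
The value is signed and not clamped: glands darker than the background give
a negative vagueness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from PIL import Image

from .errors import ValidationError
from .io_masks import GlandLabelMap, GrayImage, TarsusMask, validate_glands_within_tarsus

#: Default heat-map value range (typical vagueness scale on 8-bit meibography).
HEATMAP_RANGE = (0.0, 60.0)
HEATMAP_CMAP = "magma"


@dataclass(frozen=True)
class VaguenessResult:
    mean_gland_gray: float | None
    mean_background_gray: float
    vagueness: float | None
    n_gland_px: int
    n_background_px: int


def vagueness_value(image: GrayImage, labelmap: GlandLabelMap, tarsus: TarsusMask) -> VaguenessResult:
    """Mean gland gray minus mean background gray, both within the tarsus.

    Requires at least one non-gland tarsus pixel (otherwise the background
    mean is undefined).  With no glands at all, the gland mean — and hence
    the vagueness — is reported missing (None).
    """
    if image.shape != labelmap.shape or image.shape != tarsus.shape:
        raise ValidationError("image, label map and tarsus mask must share one shape")
    validate_glands_within_tarsus(labelmap, tarsus)
    gland = labelmap.labels > 0
    background = tarsus.mask & ~gland
    n_gland = int(np.count_nonzero(gland))
    n_bg = int(np.count_nonzero(background))
    if n_bg == 0:
        raise ValidationError("tarsus is entirely gland: background mean undefined")
    px = image.pixels.astype(np.float64)
    mean_bg = float(px[background].mean())
    if n_gland == 0:
        return VaguenessResult(None, mean_bg, None, 0, n_bg)
    mean_gland = float(px[gland].mean())
    return VaguenessResult(mean_gland, mean_bg, mean_gland - mean_bg, n_gland, n_bg)


def vagueness_heatmap(
    values: np.ndarray,
    vmin: float = HEATMAP_RANGE[0],
    vmax: float = HEATMAP_RANGE[1],
    cmap: str = HEATMAP_CMAP,
    cell_px: int = 24,
) -> np.ndarray:
    """Render a grid of vagueness values as an RGB heat map.

    ``values`` is a 2-D array (e.g. subjects × eyelid/group cells); NaN cells
    render mid-gray.  The colormap and value range are fixed arguments, not
    data-driven, so figures are reproducible across cohorts.  Returns a
    (rows·cell_px, cols·cell_px, 3) uint8 array.
    """
    vals = np.atleast_2d(np.asarray(values, dtype=float))
    if vals.size == 0:
        raise ValidationError("no vagueness values to render")
    if vmax <= vmin:
        raise ValidationError("heatmap range must have vmax > vmin")
    norm = np.clip((vals - vmin) / (vmax - vmin), 0.0, 1.0)
    rgba = colormaps[cmap](norm)
    rgb = (rgba[..., :3] * 255).round().astype(np.uint8)
    rgb[np.isnan(vals)] = 128
    return np.kron(rgb, np.ones((cell_px, cell_px, 1), dtype=np.uint8))


def save_heatmap(heatmap_rgb: np.ndarray, path) -> None:
    Image.fromarray(heatmap_rgb, mode="RGB").save(path)
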