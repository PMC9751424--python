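"""Synthetic meibography with exact ground truth.

Real meibography shows meibomian glands as bright, roughly vertical,
sometimes wavy stripes on the tarsal plate of an everted eyelid.  The
generator emulates exactly the features the morphological indices measure:

* a gland is a sinusoid-displaced vertical stripe — the pixel set
  ``{(r, c) : |c − (center + A·sin(2π·P·(r − top)/L))| ≤ w/2}`` for rows
  ``top ≤ r < top + L`` — the simplest family spanning straight, twisted
  and (via an optional fragmentation split) fragmented gland morphologies;
* the tarsus is the image rectangle inset by a margin (true tarsal
  curvature is presentational and irrelevant to the pixel-ratio indices);
* intensities are a flat foreground/background contrast plus clipped
  additive Gaussian noise.

Cohorts follow a paired design: per subject, a *control* eye and a
*research* eye whose gland parameters are the control parameters times
configurable group effect factors with per-subject lognormal jitter.  Every
eyelid ships with its exact label and tarsus masks and a ground-truth
record (per-gland extents, areas, the exact density), so the analysis
pipeline can be validated against pixel-count identities rather than
against another estimator.

All randomness flows from one root seed through named substreams, so the
same seed reproduces a cohort bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .errors import ValidationError
from .io_masks import (
    STRUCTURE_8,
    GlandLabelMap,
    GrayImage,
    SubjectMeta,
    TarsusMask,
    canonicalize_labels,
    write_gray_image,
    write_label_map,
    write_tarsus_mask,
)

__all__ = [
    "GlandSpec",
    "EyelidParams",
    "EffectFactors",
    "CohortConfig",
    "EyelidSample",
    "render_gland",
    "render_eyelid",
    "simulate_cohort",
    "generate_cohort",
]

#: Follow-up interval bins (months), matching the reporting stratification.
INTERVAL_BINS = ((0.0, 3.0), (3.0, 6.0), (6.0, 12.0), (12.0, 24.0))


@dataclass(frozen=True)
class GlandSpec:
    """Parameters of one rendered gland stripe."""

    length_px: int
    half_width_px: float
    amp_px: float
    n_periods: float
    center_col: float
    top_row: int

    def __post_init__(self) -> None:
        if self.length_px < 1:
            raise ValidationError("gland length must be >= 1 px")
        if self.half_width_px < 0.5:
            raise ValidationError("half width must be >= 0.5 px so every row has a pixel")
        if self.amp_px < 0:
            raise ValidationError("amplitude must be non-negative")


@dataclass
class EyelidParams:
    """Distribution of gland parameters for one eyelid (control group)."""

    length_mean: float
    length_sd: float
    half_width_mean: float
    half_width_sd: float
    amp_mean: float
    amp_sd: float
    n_periods_range: tuple[float, float] = (1.0, 2.5)


@dataclass
class EffectFactors:
    """Multiplicative research-vs-control effects on generator parameters."""

    length: float = 1.0
    width: float = 1.0
    amplitude: float = 1.0
    count: float = 1.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValidationError(f"effect factor {f.name} must be > 0")


@dataclass
class CohortConfig:
    """Study-level configuration of the paired synthetic cohort.

    Defaults emulate a typical meibography cohort: 26 subjects, upper-lid
    glands around 150 px tall and lower-lid glands around 90 px on a
    300×640 canvas, stripe widths around 23 px (density ≈ 0.2), a
    foreground/background contrast of 28 gray levels, and follow-up
    intervals spread over four bins between 0 and 24 months.
    """

    n_subjects: int = 26
    glands_per_lid: tuple[int, int] = (10, 14)
    image_shape: tuple[int, int] = (300, 640)
    tarsus_margin_px: int = 10
    g_fg: float = 140.0
    g_bg: float = 112.0
    noise_sd: float = 8.0
    upper: EyelidParams = field(default_factory=lambda: EyelidParams(150.0, 20.0, 11.0, 1.5, 6.0, 2.0))
    lower: EyelidParams = field(default_factory=lambda: EyelidParams(90.0, 15.0, 12.0, 1.5, 5.0, 2.0))
    group_effects: EffectFactors = field(default_factory=EffectFactors)
    jitter_sd: float = 0.06
    interval_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    fragmentation_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.glands_per_lid[0] < 1 or self.glands_per_lid[1] < self.glands_per_lid[0]:
            raise ValidationError("glands_per_lid must be a non-empty integer range")
        if abs(sum(self.interval_probs) - 1.0) > 1e-9:
            raise ValidationError("interval_probs must sum to 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")

    # -- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in ("upper", "lower"):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                if "n_periods_range" in sub:
                    sub["n_periods_range"] = tuple(sub["n_periods_range"])
                d[key] = EyelidParams(**sub)
        if "group_effects" in d and isinstance(d["group_effects"], dict):
            d["group_effects"] = EffectFactors(**d["group_effects"])
        for key in ("glands_per_lid", "image_shape", "interval_probs"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class EyelidSample:
    """One rendered eyelid with its masks, metadata and ground truth."""

    meta: SubjectMeta
    image: GrayImage
    labels: GlandLabelMap
    tarsus: TarsusMask
    ground_truth: dict


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Named substream: deterministic child generator of the root seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=tuple(key)))


# stream indices for _rng keys
_STREAM_PARAMS = 0
_STREAM_JITTER = 1
_STREAM_NOISE = 2
_STREAM_META = 3


def render_gland(spec: GlandSpec, canvas_shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one gland; returns (rows, cols) of its pixel set.

    The vertical extent equals ``length_px`` exactly by construction.  The
    result must be 8-connected; parameter combinations whose lateral slope
    tears consecutive rows apart are rejected.
    """
    n_rows, n_cols = canvas_shape
    top, length = spec.top_row, spec.length_px
    if top < 0 or top + length > n_rows:
        raise ValidationError("gland exceeds canvas vertically")
    r = np.arange(top, top + length)
    center = spec.center_col + spec.amp_px * np.sin(2 * np.pi * spec.n_periods * (r - top) / length)
    lo = np.ceil(center - spec.half_width_px).astype(int)
    hi = np.floor(center + spec.half_width_px).astype(int)
    if (lo > hi).any():
        raise ValidationError("half width too small: a row has no pixels")
    if lo.min() < 0 or hi.max() >= n_cols:
        raise ValidationError("gland exceeds canvas horizontally")
    # 8-connectivity between consecutive rows: intervals must touch diagonally
    if length > 1 and ((lo[1:] > hi[:-1] + 1) | (hi[1:] < lo[:-1] - 1)).any():
        raise ValidationError("gland disconnected: amplitude slope too steep for the width")
    counts = hi - lo + 1
    rows = np.repeat(r, counts)
    cols = np.concatenate([np.arange(a, b + 1) for a, b in zip(lo, hi)])
    return rows, cols


def _tarsus_mask(shape: tuple[int, int], margin: int) -> TarsusMask:
    m = np.zeros(shape, dtype=bool)
    m[margin : shape[0] - margin, margin : shape[1] - margin] = True
    return TarsusMask(m)


def render_eyelid(
    specs: Sequence[GlandSpec],
    image_shape: tuple[int, int],
    tarsus_margin_px: int,
    g_fg: float,
    g_bg: float,
    noise_sd: float,
    rng: np.random.Generator | None = None,
) -> tuple[GrayImage, GlandLabelMap, TarsusMask, dict]:
    """Render glands on a tarsus: image, exact masks and ground truth.

    Glands must be pairwise disjoint with at least a 2-px column gap and lie
    inside the tarsus.  The image is ``g_bg`` on the tarsus, ``g_fg`` on
    glands, 0 outside, plus clipped Gaussian noise of sd ``noise_sd`` (from
    ``rng``; sd 0 or no rng means noiseless).
    """
    tarsus = _tarsus_mask(image_shape, tarsus_margin_px)
    raw = np.zeros(image_shape, dtype=np.int32)
    for i, spec in enumerate(specs, start=1):
        rows, cols = render_gland(spec, image_shape)
        if (raw[rows, cols] != 0).any():
            raise ValidationError("overlapping glands")
        if not tarsus.mask[rows, cols].all():
            raise ValidationError("gland outside tarsus")
        raw[rows, cols] = i
    # enforce the >= 2 px separation: after a 1-px dilation every gland must
    # still be its own connected component
    if len(specs) > 1:
        dilated = ndimage.binary_dilation(raw > 0, structure=STRUCTURE_8)
        _, n_comp = ndimage.label(dilated, structure=STRUCTURE_8)
        if n_comp != len(specs):
            raise ValidationError("glands closer than the 2 px minimum gap")
    canonical, order = canonicalize_labels(raw)
    labels = GlandLabelMap(canonical)

    img = np.zeros(image_shape, dtype=np.float64)
    img[tarsus.mask] = g_bg
    img[canonical > 0] = g_fg
    if rng is not None and noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=image_shape)
    image = GrayImage(np.clip(np.rint(img), 0, 255).astype(np.uint8))

    glands_truth = []
    for new_id, orig in enumerate(order, start=1):
        spec = specs[orig - 1]
        rows, cols = np.nonzero(canonical == new_id)
        glands_truth.append(
            {
                "label": new_id,
                "length_px": int(rows.max() - rows.min() + 1),
                "area_px": int(rows.size),
                "top_row": int(rows.min()),
                "spec": dataclasses.asdict(spec),
            }
        )
    truth = {
        "glands": glands_truth,
        "n_glands": len(specs),
        "total_gland_area_px": int(np.count_nonzero(canonical)),
        "tarsus_area_px": tarsus.area_px,
        "density": float(np.count_nonzero(canonical) / tarsus.area_px),
        "g_fg": g_fg,
        "g_bg": g_bg,
        "noise_sd": noise_sd,
    }
    return image, labels, tarsus, truth


def _draw_control_params(rng: np.random.Generator, cfg: CohortConfig, eyelid: str) -> dict:
    """Per-gland control-eye parameter draws for one eyelid."""
    p = cfg.upper if eyelid == "upper" else cfg.lower
    n = int(rng.integers(cfg.glands_per_lid[0], cfg.glands_per_lid[1] + 1))
    rows, _ = cfg.image_shape
    max_len = rows - 2 * cfg.tarsus_margin_px - 4
    return {
        "n": n,
        "lengths": np.clip(rng.normal(p.length_mean, p.length_sd, n), 10, max_len),
        "half_widths": np.clip(rng.normal(p.half_width_mean, p.half_width_sd, n), 1.0, None),
        "amps": np.clip(rng.normal(p.amp_mean, p.amp_sd, n), 0.0, None),
        "periods": rng.uniform(*p.n_periods_range, n),
        "top_fracs": rng.uniform(0.0, 1.0, n),
        "col_fracs": rng.uniform(-1.0, 1.0, n),
    }


def _scaled_params(params: dict, effects: EffectFactors, jitter: dict, max_len: float) -> dict:
    """Research-eye parameters: control × group effects × per-subject jitter."""
    n = max(1, int(round(params["n"] * effects.count * jitter["count"])))
    idx = np.arange(n) % params["n"]  # reuse control draws beyond the list
    return {
        "n": n,
        "lengths": np.clip(params["lengths"][idx] * effects.length * jitter["length"], 10, max_len),
        "half_widths": np.clip(params["half_widths"][idx] * effects.width * jitter["width"], 1.0, None),
        "amps": params["amps"][idx] * effects.amplitude * jitter["amplitude"],
        "periods": params["periods"][idx],
        "top_fracs": params["top_fracs"][idx],
        "col_fracs": params["col_fracs"][idx],
    }


def _place_specs(params: dict, cfg: CohortConfig, rng_frag: np.random.Generator | None) -> list[GlandSpec]:
    """Deterministic slot placement of glands across the tarsus columns."""
    rows, cols = cfg.image_shape
    margin = cfg.tarsus_margin_px
    n = params["n"]
    usable_lo, usable_hi = margin + 1, cols - margin - 1
    slot_w = (usable_hi - usable_lo) / n
    specs: list[GlandSpec] = []
    for i in range(n):
        length = int(round(params["lengths"][i]))
        hw = float(params["half_widths"][i])
        amp = float(params["amps"][i])
        # amplitude yields to the slot: waviness is clamped so the stripe plus
        # the 2 px gap share always fits its column slot; if even a straight
        # stripe cannot fit, the configuration is infeasible
        amp_max = slot_w / 2 - hw - 1.5
        if amp_max < 0:
            raise ValidationError(
                f"infeasible placement: gland half-width {hw:.1f} px exceeds slot {slot_w:.1f} px"
            )
        periods = float(params["periods"][i])
        # ... and to the connectivity constraint: the per-row lateral step
        # amp*2*pi*P/L must stay within the stripe width (0.9 safety factor)
        if periods > 0:
            amp_max = min(amp_max, 0.9 * 2 * hw * length / (2 * np.pi * periods))
        amp = min(amp, amp_max)
        reach = hw + amp + 1.5
        slack = slot_w / 2 - reach
        center = usable_lo + (i + 0.5) * slot_w + params["col_fracs"][i] * slack
        avail = rows - 2 * margin - 4 - length
        top = margin + 2 + int(round(params["top_fracs"][i] * max(avail, 0)))
        specs.append(
            GlandSpec(
                length_px=length,
                half_width_px=hw,
                amp_px=amp,
                n_periods=periods,
                center_col=float(center),
                top_row=top,
            )
        )
    if rng_frag is not None and cfg.fragmentation_prob > 0:
        specs = _fragment(specs, cfg, rng_frag)
    return specs


def _fragment(specs: list[GlandSpec], cfg: CohortConfig, rng: np.random.Generator) -> list[GlandSpec]:
    """Split some glands into two vertically separated pieces (gap >= 3 rows)."""
    out: list[GlandSpec] = []
    for spec in specs:
        if spec.length_px >= 30 and rng.random() < cfg.fragmentation_prob:
            cut = int(rng.uniform(0.3, 0.7) * spec.length_px)
            gap = 3
            top_len, bot_len = cut, spec.length_px - cut - gap
            if top_len >= 5 and bot_len >= 5:
                out.append(dataclasses.replace(spec, length_px=top_len))
                out.append(
                    dataclasses.replace(
                        spec, length_px=bot_len, top_row=spec.top_row + cut + gap
                    )
                )
                continue
        out.append(spec)
    return out


def _subject_meta(rng: np.random.Generator, cfg: CohortConfig, subject_id: str) -> dict:
    """Interval and clinical covariates for one subject (both eyes)."""
    bin_idx = int(rng.choice(len(INTERVAL_BINS), p=np.asarray(cfg.interval_probs)))
    lo, hi = INTERVAL_BINS[bin_idx]
    interval = float(rng.uniform(lo + 0.05, hi))
    # TBUT (s) and TMH (mm) distributions typical of a paired dry-eye cohort;
    # independent of morphology by design (null clinical correlation).
    return {
        "interval_months": interval,
        "tbut_s": {
            "research": float(max(0.5, rng.normal(5.76, 2.86))),
            "control": float(max(0.5, rng.normal(7.68, 4.92))),
        },
        "tmh_mm": {
            "research": float(max(0.05, rng.normal(0.22, 0.06))),
            "control": float(max(0.05, rng.normal(0.19, 0.05))),
        },
    }


def simulate_cohort(config: CohortConfig) -> Iterator[EyelidSample]:
    """Yield all eyelids (subject × eye role × eyelid) of a paired cohort.

    For each subject and eyelid the control eye's gland parameters are drawn
    from the eyelid distributions; the research eye's parameters are the
    control parameters times the group effect factors times one lognormal
    jitter per parameter family per subject.  With all effects at 1 the two
    eyes are draws from identical distributions (differing only by jitter
    and noise), giving a valid null for type-I-error calibration.
    """
    seed = config.seed
    rows, _ = config.image_shape
    max_len = rows - 2 * config.tarsus_margin_px - 4
    for s in range(config.n_subjects):
        sid = f"S{s + 1:03d}"
        meta_rng = _rng(seed, s, _STREAM_META)
        meta = _subject_meta(meta_rng, config, sid)
        jit_rng = _rng(seed, s, _STREAM_JITTER)
        jitter = {
            name: float(np.exp(jit_rng.normal(0.0, config.jitter_sd)))
            for name in ("length", "width", "amplitude", "count")
        }
        for lid_idx, eyelid in enumerate(("upper", "lower")):
            ctrl_rng = _rng(seed, s, _STREAM_PARAMS, lid_idx)
            control_params = _draw_control_params(ctrl_rng, config, eyelid)
            research_params = _scaled_params(control_params, config.group_effects, jitter, max_len)
            for role_idx, (role, params) in enumerate(
                (("control", control_params), ("research", research_params))
            ):
                frag_rng = (
                    _rng(seed, s, _STREAM_PARAMS, lid_idx, 10 + role_idx)
                    if config.fragmentation_prob > 0
                    else None
                )
                specs = _place_specs(params, config, frag_rng)
                noise_rng = _rng(seed, s, _STREAM_NOISE, lid_idx, role_idx)
                image, labels, tarsus, truth = render_eyelid(
                    specs,
                    config.image_shape,
                    config.tarsus_margin_px,
                    config.g_fg,
                    config.g_bg,
                    config.noise_sd,
                    rng=noise_rng,
                )
                yield EyelidSample(
                    meta=SubjectMeta(
                        subject_id=sid,
                        eye_role=role,
                        eyelid=eyelid,
                        interval_months=meta["interval_months"],
                        tbut_s=meta["tbut_s"][role],
                        tmh_mm=meta["tmh_mm"][role],
                    ),
                    image=image,
                    labels=labels,
                    tarsus=tarsus,
                    ground_truth=truth,
                )


def generate_cohort(config: CohortConfig, out_dir: str | Path) -> Path:
    """Write a cohort directory: images, masks, metadata.csv, ground_truth.json.

    Layout: ``subjects/<id>/<eye_role>_<eyelid>_{image,labels,tarsus}.png``.
    Re-running with the same config (same seed) reproduces every file byte
    for byte.
    """
    out = Path(out_dir)
    (out / "subjects").mkdir(parents=True, exist_ok=True)
    meta_rows = []
    truths: dict[str, dict] = {}
    for sample in simulate_cohort(config):
        m = sample.meta
        sdir = out / "subjects" / m.subject_id
        sdir.mkdir(exist_ok=True)
        stem = f"{m.eye_role}_{m.eyelid}"
        write_gray_image(sample.image, sdir / f"{stem}_image.png")
        write_label_map(sample.labels, sdir / f"{stem}_labels.png")
        write_tarsus_mask(sample.tarsus, sdir / f"{stem}_tarsus.png")
        meta_rows.append(
            {
                "subject_id": m.subject_id,
                "eye_role": m.eye_role,
                "eyelid": m.eyelid,
                "interval_months": m.interval_months,
                "tbut_s": m.tbut_s,
                "tmh_mm": m.tmh_mm,
            }
        )
        truths[f"{m.subject_id}/{stem}"] = sample.ground_truth
    pd.DataFrame(meta_rows).to_csv(out / "metadata.csv", index=False, float_format="%.6g")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truths, fh, indent=1, sort_keys=True)
    config.to_yaml(out / "config.yaml")
    return out
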