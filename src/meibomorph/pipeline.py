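"""End-to-end analysis: masks → metrics table → paired report tables.

The metrics table has one AGGREGATE row per (subject, eye role, eyelid)
carrying the eyelid-level indices (mean gland height/width/tortuosity,
density, vagueness) plus optional per-gland rows.  Report tables mirror the
standard presentation of a paired meibography study:

* a vagueness table (upper / lower / both eyelids),
* a morphology table (four parameters × upper / lower / both),
* a follow-up table (parameters × interval bins),
* a clinical-correlation table (parameters × TBUT / TMH × group),
* a JSON run manifest (seed, config hash, package versions).

"Both eyelids" values are the unweighted mean of the two eyelid-level
values; the pixel-pooled alternative lives behind
:func:`meibomorph.morphometry.combine_eyelids`'s ``pooled`` flag.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import __version__
from .errors import ValidationError
from .io_masks import (
    METRICS_COLUMNS,
    GlandLabelMap,
    GrayImage,
    SubjectMeta,
    TarsusMask,
    read_gray_image,
    read_label_map,
    read_tarsus_mask,
    write_metrics_table,
)
from .morphometry import gland_metrics, gland_shapes, summarize_eyelid
from .stats import (
    INTERVAL_BIN_LABELS,
    ComparisonResult,
    PairedSample,
    compare_paired,
    correlate_with_clinical,
    stratify_by_interval,
)
from .synthetic import EyelidSample, simulate_cohort
from .vagueness import vagueness_value

PARAMETERS = ["height_px", "width_px", "tortuosity", "density", "vagueness"]
EYELID_LEVELS = ["upper", "lower", "both"]


def analyze_eyelid(
    image: GrayImage,
    labelmap: GlandLabelMap,
    tarsus: TarsusMask,
    meta: SubjectMeta,
    include_glands: bool = False,
    inclusive_height: bool = True,
) -> list[dict]:
    """Metric rows (AGGREGATE first, then per-gland) for one eyelid."""
    summary = summarize_eyelid(labelmap, tarsus, meta.eyelid, inclusive=inclusive_height)
    vag = vagueness_value(image, labelmap, tarsus)
    base = {
        "subject_id": meta.subject_id,
        "eye_role": meta.eye_role,
        "eyelid": meta.eyelid,
        "interval_months": meta.interval_months,
        "tbut_s": meta.tbut_s,
        "tmh_mm": meta.tmh_mm,
    }
    rows = [
        {
            **base,
            "gland_id": "AGGREGATE",
            "height_px": summary.mean_height_px,
            "width_px": summary.mean_width_px,
            "tortuosity": summary.mean_tortuosity,
            "density": summary.density,
            "vagueness": vag.vagueness,
        }
    ]
    if include_glands:
        for shape in gland_shapes(labelmap):
            m = gland_metrics(shape, inclusive=inclusive_height)
            rows.append(
                {
                    **base,
                    "gland_id": str(m.gland_id),
                    "height_px": m.height_px,
                    "width_px": m.width_px,
                    "tortuosity": m.tortuosity,
                    "density": np.nan,
                    "vagueness": np.nan,
                }
            )
    return rows


def samples_to_metrics(samples: Iterable[EyelidSample], include_glands: bool = False) -> pd.DataFrame:
    rows: list[dict] = []
    for s in samples:
        rows.extend(analyze_eyelid(s.image, s.labels, s.tarsus, s.meta, include_glands=include_glands))
    df = pd.DataFrame(rows)
    return df[[c for c in METRICS_COLUMNS if c in df.columns]]


def cohort_dir_to_metrics(cohort_dir: str | Path, include_glands: bool = False) -> pd.DataFrame:
    """Read a cohort directory written by the generator and compute metrics."""
    cohort_dir = Path(cohort_dir)
    meta_path = cohort_dir / "metadata.csv"
    if not meta_path.exists():
        raise FileNotFoundError(f"no metadata.csv in {cohort_dir}")
    meta = pd.read_csv(meta_path, dtype={"subject_id": str})
    rows: list[dict] = []
    for rec in meta.to_dict("records"):
        sdir = cohort_dir / "subjects" / rec["subject_id"]
        stem = f"{rec['eye_role']}_{rec['eyelid']}"
        image = read_gray_image(sdir / f"{stem}_image.png")
        labels = read_label_map(sdir / f"{stem}_labels.png", binary_ok=False, reference_shape=image.shape)
        tarsus = read_tarsus_mask(sdir / f"{stem}_tarsus.png", reference_shape=image.shape)
        sm = SubjectMeta(
            subject_id=rec["subject_id"],
            eye_role=rec["eye_role"],
            eyelid=rec["eyelid"],
            interval_months=rec.get("interval_months"),
            tbut_s=rec.get("tbut_s"),
            tmh_mm=rec.get("tmh_mm"),
        )
        rows.extend(analyze_eyelid(image, labels, tarsus, sm, include_glands=include_glands))
    df = pd.DataFrame(rows)
    return df[[c for c in METRICS_COLUMNS if c in df.columns]]


def aggregate_rows(metrics: pd.DataFrame) -> pd.DataFrame:
    if "gland_id" in metrics.columns:
        return metrics[metrics["gland_id"].astype(str) == "AGGREGATE"].copy()
    return metrics.copy()


def with_both_eyelids(metrics: pd.DataFrame) -> pd.DataFrame:
    """Append eyelid="both" rows: unweighted mean of upper and lower values."""
    agg = aggregate_rows(metrics)
    keys = ["subject_id", "eye_role"]
    both_rows = []
    for (sid, role), grp in agg.groupby(keys):
        upper = grp[grp["eyelid"] == "upper"]
        lower = grp[grp["eyelid"] == "lower"]
        if len(upper) != 1 or len(lower) != 1:
            continue  # combined value missing when either eyelid is missing
        u, l = upper.iloc[0], lower.iloc[0]
        row = {
            "subject_id": sid,
            "eye_role": role,
            "eyelid": "both",
            "gland_id": "AGGREGATE",
            "interval_months": u["interval_months"],
            "tbut_s": u["tbut_s"],
            "tmh_mm": u["tmh_mm"],
        }
        for p in PARAMETERS:
            row[p] = 0.5 * (u[p] + l[p])
        both_rows.append(row)
    return pd.concat([agg, pd.DataFrame(both_rows)], ignore_index=True)


def paired_sample(metrics: pd.DataFrame, parameter: str, eyelid: str) -> PairedSample:
    """Per-subject paired vectors of one parameter at one eyelid level."""
    df = metrics[metrics["eyelid"] == eyelid]
    wide = df.pivot_table(index="subject_id", columns="eye_role", values=parameter, aggfunc="mean")
    for col in ("research", "control"):
        if col not in wide:
            wide[col] = np.nan
    return PairedSample(parameter, wide["research"].to_numpy(), wide["control"].to_numpy())


def compare_all(metrics: pd.DataFrame, p_adjust: str | None = None) -> pd.DataFrame:
    """Paired comparisons for every parameter × eyelid level (long table).

    ``p_adjust="bh"`` appends Benjamini–Hochberg adjusted p-values across
    the table; default is unadjusted, matching per-cell reporting.
    """
    full = with_both_eyelids(metrics)
    rows = []
    for eyelid in EYELID_LEVELS:
        for p in PARAMETERS:
            res = compare_paired(paired_sample(full, p, eyelid))
            rows.append(_comparison_row(res, eyelid=eyelid))
    table = pd.DataFrame(rows)
    if p_adjust == "bh":
        from .stats import benjamini_hochberg

        table["p_adjusted"] = benjamini_hochberg(table["p_value"].to_numpy())
    elif p_adjust is not None:
        raise ValidationError(f"unknown p_adjust {p_adjust!r}")
    return table


def _comparison_row(res: ComparisonResult, **extra) -> dict:
    return {
        **extra,
        "parameter": res.parameter_name,
        "n_pairs": res.n_pairs,
        "research": _fmt_summary(res.summary_research, res.summary_kind),
        "control": _fmt_summary(res.summary_control, res.summary_kind),
        "summary_kind": res.summary_kind,
        "test": res.test_used,
        "p_value": res.p_value,
    }


def _fmt_summary(summary: tuple[float, float], kind: str) -> str:
    a, b = summary
    if kind == "mean_sd":
        return f"{a:.6g} ± {b:.6g}"
    return f"{a:.6g} ({b:.6g})"


def interval_table(metrics: pd.DataFrame) -> pd.DataFrame:
    """Parameters × follow-up interval bins, paired comparison per cell."""
    full = with_both_eyelids(metrics)
    both = full[full["eyelid"] == "both"]
    rows = []
    for p in PARAMETERS:
        per_bin = stratify_by_interval(both, p)
        for lab in INTERVAL_BIN_LABELS:
            if lab in per_bin:
                rows.append(_comparison_row(per_bin[lab], interval_bin=lab))
    return pd.DataFrame(rows)


def clinical_correlation_table(metrics: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of each parameter with TBUT and TMH per group."""
    full = with_both_eyelids(metrics)
    both = full[full["eyelid"] == "both"]
    rows = []
    for role in ("research", "control"):
        sub = both[both["eye_role"] == role]
        for p in PARAMETERS:
            for cov in ("tbut_s", "tmh_mm"):
                rho, pval = correlate_with_clinical(sub[p], sub[cov])
                rows.append(
                    {"eye_role": role, "parameter": p, "covariate": cov, "rho": rho, "p_value": pval}
                )
    return pd.DataFrame(rows)


def build_report(metrics: pd.DataFrame, out_dir: str | Path, seed: int | None = None, config_yaml: str | None = None) -> dict[str, Path]:
    """Write the report tables and a run manifest; returns the file map.

    Outputs are deterministic functions of the metrics table (and seed), so
    a fixed-seed pipeline run reproduces every file byte for byte.
    """
    agg = aggregate_rows(metrics)
    if agg.empty:
        raise ValidationError("empty cohort: no aggregate metric rows")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    comparisons = compare_all(metrics)
    vague = comparisons[comparisons["parameter"] == "vagueness"].drop(columns=["parameter"])
    morpho = comparisons[comparisons["parameter"] != "vagueness"]
    files = {
        "vagueness": out / "table_vagueness.csv",
        "parameters": out / "table_parameters.csv",
        "intervals": out / "table_intervals.csv",
        "correlations": out / "table_clinical_correlations.csv",
        "manifest": out / "manifest.json",
    }
    vague.to_csv(files["vagueness"], index=False, float_format="%.6g")
    morpho.to_csv(files["parameters"], index=False, float_format="%.6g")
    interval_table(metrics).to_csv(files["intervals"], index=False, float_format="%.6g")
    clinical_correlation_table(metrics).to_csv(files["correlations"], index=False, float_format="%.6g")
    import numpy as _np
    import pandas as _pd
    import scipy as _sp

    manifest = {
        "meibomorph": __version__,
        "numpy": _np.__version__,
        "scipy": _sp.__version__,
        "pandas": _pd.__version__,
        "seed": seed,
        "n_rows": int(len(agg)),
        "config_sha256": hashlib.sha256(config_yaml.encode()).hexdigest() if config_yaml else None,
    }
    with open(files["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return files


def write_cohort_metrics(samples: Iterable[EyelidSample], path: str | Path, include_glands: bool = False) -> pd.DataFrame:
    df = samples_to_metrics(samples, include_glands=include_glands)
    write_metrics_table(df, path)
    return df
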