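"""Paired research-vs-control statistics with a normality-gated test choice.

The analysis treats each subject's affected (research) eye against the same
subject's contralateral (control) eye.  For each parameter the per-subject
difference vector is tested for normality; normal differences go to the
paired t-test, non-normal ones to the Wilcoxon signed-rank test, and the
summary statistics follow the route (mean ± SD vs median (IQR)).

Normality uses the Kolmogorov–Smirnov statistic against a normal with the
sample's own mean and SD.  Since estimating the parameters from the sample
makes the textbook KS p-value anticonservative, the default p-value is
Lilliefors-corrected via a seeded Monte-Carlo null table (10,000 simulated
samples per sample size, cached per size); the naive KS p is available via
``method="ks"``.

The Wilcoxon signed-rank test drops zero differences, uses the exact null
distribution for up to 25 nonzero differences and the normal approximation
with continuity correction above.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateStatisticsError, ValidationError

__all__ = [
    "PairedSample",
    "NormalityResult",
    "ComparisonResult",
    "normality_check",
    "signed_rank_test",
    "compare_paired",
    "stratify_by_interval",
    "correlate_with_clinical",
    "INTERVAL_BIN_LABELS",
]

ALPHA = 0.05
_LILLIEFORS_SIMS = 10_000
_LILLIEFORS_SEED = 20_220_112  # fixed: the null table is part of the method
_EXACT_WILCOXON_MAX_N = 25

#: Follow-up stratification bins (months): left-open / right-closed.
INTERVAL_BIN_EDGES = [0.0, 3.0, 6.0, 12.0, np.inf]
INTERVAL_BIN_LABELS = ["0-3", "3-6", "6-12", ">12"]


@dataclass(frozen=True)
class PairedSample:
    """Per-subject paired values for one parameter (missing allowed)."""

    parameter_name: str
    research_values: np.ndarray
    control_values: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.research_values, dtype=float)
        c = np.asarray(self.control_values, dtype=float)
        if r.shape != c.shape or r.ndim != 1:
            raise ValidationError("paired vectors must be 1-D and of equal length")
        object.__setattr__(self, "research_values", r)
        object.__setattr__(self, "control_values", c)

    def complete_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Pairwise deletion: keep subjects with both values present."""
        ok = ~(np.isnan(self.research_values) | np.isnan(self.control_values))
        return self.research_values[ok], self.control_values[ok]


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    is_normal: bool
    testable: bool = True


@dataclass(frozen=True)
class ComparisonResult:
    parameter_name: str
    n_pairs: int
    summary_research: tuple[float, float]
    summary_control: tuple[float, float]
    summary_kind: str  # "mean_sd" | "median_iqr"
    test_used: str  # "paired_t" | "wilcoxon_signed_rank"
    p_value: float | None
    degenerate: bool = False
    normality_p: float | None = None


_null_tables: dict[int, np.ndarray] = {}


def _ks_statistic(z_sorted: np.ndarray) -> np.ndarray:
    """Two-sided KS distance of standardized sorted rows against N(0,1)."""
    n = z_sorted.shape[-1]
    u = sps.norm.cdf(z_sorted)
    i = np.arange(1, n + 1)
    d_plus = (i / n - u).max(axis=-1)
    d_minus = (u - (i - 1) / n).max(axis=-1)
    return np.maximum(d_plus, d_minus)


def _lilliefors_table(n: int) -> np.ndarray:
    """Sorted Monte-Carlo null distribution of the estimated-parameter KS stat."""
    table = _null_tables.get(n)
    if table is None:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=_LILLIEFORS_SEED, spawn_key=(n,)))
        x = rng.standard_normal((_LILLIEFORS_SIMS, n))
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
        table = np.sort(_ks_statistic(np.sort(z, axis=1)))
        _null_tables[n] = table
    return table


def normality_check(x: Sequence[float], alpha: float = ALPHA, method: str = "lilliefors") -> NormalityResult:
    """KS normality test with estimated mean/SD; Lilliefors MC p by default."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise DegenerateStatisticsError(f"normality test needs n >= 3, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        return NormalityResult(np.nan, np.nan, is_normal=False, testable=False)
    z = np.sort((x - x.mean()) / sd)
    d = float(_ks_statistic(z))
    if method == "lilliefors":
        table = _lilliefors_table(x.size)
        n_ge = table.size - np.searchsorted(table, d - 1e-12, side="left")
        p = float((1 + n_ge) / (table.size + 1))
    elif method == "ks":
        p = float(sps.kstest(x, "norm", args=(x.mean(), sd)).pvalue)
    else:
        raise ValidationError(f"unknown normality method {method!r}")
    return NormalityResult(d, p, is_normal=p >= alpha, testable=True)


def signed_rank_test(diffs: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value on a difference vector.

    Zero differences are dropped; exact null for <= 25 nonzero differences,
    normal approximation with continuity correction above.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    method = "exact" if d.size <= _EXACT_WILCOXON_MAX_N else "approx"
    res = sps.wilcoxon(d, correction=True, method=method)
    return float(res.pvalue)


def _summaries(r: np.ndarray, c: np.ndarray, normal: bool) -> tuple[tuple[float, float], tuple[float, float], str]:
    if normal:
        sd_r = float(r.std(ddof=1)) if r.size > 1 else float("nan")
        sd_c = float(c.std(ddof=1)) if c.size > 1 else float("nan")
        return (float(r.mean()), sd_r), (float(c.mean()), sd_c), "mean_sd"
    qr = np.percentile(r, [25, 50, 75])
    qc = np.percentile(c, [25, 50, 75])
    return (float(qr[1]), float(qr[2] - qr[0])), (float(qc[1]), float(qc[2] - qc[0])), "median_iqr"


def compare_paired(sample: PairedSample, alpha: float = ALPHA, normality_method: str = "lilliefors") -> ComparisonResult:
    """Paired comparison of research vs control with normality-gated routing."""
    r, c = sample.complete_pairs()
    n = r.size
    if n < 3:
        raise DegenerateStatisticsError(f"{sample.parameter_name}: need >= 3 complete pairs, got {n}")
    d = r - c
    if np.all(d == 0):
        sr, sc, kind = _summaries(r, c, normal=False)
        return ComparisonResult(
            sample.parameter_name, n, sr, sc, kind,
            test_used="wilcoxon_signed_rank", p_value=1.0, degenerate=True,
        )
    norm = (
        normality_check(d, alpha=alpha, method=normality_method)
        if d.std(ddof=1) > 0
        else NormalityResult(np.nan, np.nan, is_normal=False, testable=False)
    )
    if norm.testable and norm.is_normal:
        p = float(sps.ttest_rel(r, c).pvalue)
        sr, sc, kind = _summaries(r, c, normal=True)
        test = "paired_t"
    else:
        p = signed_rank_test(d)
        sr, sc, kind = _summaries(r, c, normal=False)
        test = "wilcoxon_signed_rank"
    return ComparisonResult(
        sample.parameter_name, n, sr, sc, kind, test, p,
        normality_p=None if not norm.testable else norm.p_value,
    )


def assign_interval_bin(interval_months: float) -> str:
    """Bin a follow-up interval (months) into (0,3], (3,6], (6,12], (12,inf)."""
    if interval_months is None or np.isnan(interval_months):
        raise ValidationError("interval is missing")
    if interval_months < 0:
        raise ValidationError(f"negative interval: {interval_months}")
    for (lo, hi), lab in zip(
        [(0.0, 3.0), (3.0, 6.0), (6.0, 12.0), (12.0, np.inf)], INTERVAL_BIN_LABELS
    ):
        if lo < interval_months <= hi:
            return lab
    raise ValidationError(f"interval {interval_months} outside all bins (must be > 0)")


def stratify_by_interval(
    records: pd.DataFrame,
    parameter: str,
    alpha: float = ALPHA,
) -> dict[str, ComparisonResult]:
    """Per-interval-bin paired comparisons of one parameter.

    ``records`` has one row per (subject, eye role) with columns
    ``subject_id``, ``eye_role``, ``interval_months`` and the parameter.
    Bins with fewer than 3 complete pairs are reported descriptively with
    no p-value.
    """
    df = records.copy()
    df["_bin"] = df["interval_months"].map(assign_interval_bin)
    out: dict[str, ComparisonResult] = {}
    for lab in INTERVAL_BIN_LABELS:
        sub = df[df["_bin"] == lab]
        wide = sub.pivot_table(index="subject_id", columns="eye_role", values=parameter, aggfunc="mean")
        if wide.empty or "research" not in wide or "control" not in wide:
            continue
        sample = PairedSample(parameter, wide["research"].to_numpy(), wide["control"].to_numpy())
        r, c = sample.complete_pairs()
        if r.size >= 3:
            out[lab] = compare_paired(sample, alpha=alpha)
        elif r.size >= 1:
            sr, sc, kind = _summaries(r, c, normal=True)
            out[lab] = ComparisonResult(
                parameter, r.size, sr, sc, kind,
                test_used="descriptive", p_value=None,
            )
    return out


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (FDR).  Off by default in all reports —
    the mirrored reporting style presents unadjusted per-cell p-values."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def correlate_with_clinical(
    values: Sequence[float],
    covariate: Sequence[float],
    method: str = "spearman",
) -> tuple[float, float]:
    """Rank correlation of a morphology parameter with a clinical covariate.

    Spearman by default (several parameters are summarized as median (IQR),
    i.e. non-normal); Pearson via ``method="pearson"``.  Pairwise deletion.
    """
    v = np.asarray(values, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if v.shape != c.shape:
        raise ValidationError("value and covariate vectors must align")
    ok = ~(np.isnan(v) | np.isnan(c))
    v, c = v[ok], c[ok]
    if v.size < 3:
        raise DegenerateStatisticsError(f"correlation needs >= 3 complete pairs, got {v.size}")
    if np.ptp(c) == 0:
        raise DegenerateStatisticsError("constant covariate")
    if method == "spearman":
        res = sps.spearmanr(v, c)
    elif method == "pearson":
        res = sps.pearsonr(v, c)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return float(res.statistic), float(res.pvalue)
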