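"""Validation studies and brute-force reference implementations.

This module holds the package's self-checks, kept deliberately independent
of the production code paths they validate:

* closed-form morphometry on filled rectangles;
* a brute-force 4-neighbor perimeter count (python loop over pixels);
* an exhaustive-angle minimum-rectangle search (0.5° grid);
* a full 2^n sign-assignment enumeration of the Wilcoxon signed-rank null;
* replicate studies on the synthetic cohort: type-I error under null group
  effects and sign-recovery / power under injected effects.

The replicate studies run on a scaled-down cohort configuration (small
canvas, short glands) so that hundreds of replicates at n = 26 subjects
finish in minutes; the statistical structure (paired design, jitter,
normality-gated tests) is identical to the full-scale defaults.
"""

from __future__ import annotations

import dataclasses
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .morphometry import gland_shapes
from .pipeline import PARAMETERS, paired_sample, samples_to_metrics, with_both_eyelids
from .stats import compare_paired
from .synthetic import CohortConfig, EffectFactors, EyelidParams, simulate_cohort

__all__ = [
    "rectangle_formula_errors",
    "perimeter_bruteforce",
    "minrect_exhaustive",
    "random_blob",
    "signed_rank_exact_enumeration",
    "calibration_config",
    "replicate_comparisons",
    "type1_error_rates",
    "effect_recovery_rates",
]


# ---------------------------------------------------------------------------
# analytic / brute-force oracles
# ---------------------------------------------------------------------------

def rectangle_formula_errors(heights=(20, 50, 100), widths=(2, 5, 10)) -> dict[str, float]:
    """Max abs deviation of pipeline metrics from rectangle closed forms.

    For a filled h×w rectangle: height h, width w, perimeter 2h+2w−4,
    minimum-rectangle height h−1 (pixel centers), tortuosity
    (2h+2w−4)/(2(h−1)) − 1.
    """
    from .io_masks import label_map_from_array
    from .morphometry import gland_height, gland_tortuosity, gland_width

    errs = {"height": 0.0, "width": 0.0, "perimeter": 0.0, "tortuosity": 0.0}
    for h, w in product(heights, widths):
        arr = np.zeros((h + 4, w + 4), dtype=np.uint8)
        arr[2 : 2 + h, 2 : 2 + w] = 1
        shape = gland_shapes(label_map_from_array(arr))[0]
        errs["height"] = max(errs["height"], abs(gland_height(shape) - h))
        errs["width"] = max(errs["width"], abs(gland_width(shape) - w))
        errs["perimeter"] = max(errs["perimeter"], abs(shape.perimeter_px - (2 * h + 2 * w - 4)))
        expected_t = (2 * h + 2 * w - 4) / (2 * (h - 1)) - 1
        errs["tortuosity"] = max(errs["tortuosity"], abs(gland_tortuosity(shape) - expected_t))
    return errs


def perimeter_bruteforce(mask: np.ndarray) -> int:
    """Count pixels of a binary blob with a 4-neighbor outside it (slow loop)."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    count = 0
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if rr < 0 or rr >= h or cc < 0 or cc >= w or not mask[rr, cc]:
                    count += 1
                    break
    return count


def minrect_exhaustive(rows: np.ndarray, cols: np.ndarray, step_deg: float = 0.5) -> tuple[float, float]:
    """Minimum enclosing-box search over a fixed angle grid.

    Returns (long side, box area) of the best box over angles
    0° .. 180°−step in ``step_deg`` increments, on pixel centers.
    """
    pts = np.unique(np.column_stack([np.asarray(rows, float), np.asarray(cols, float)]), axis=0)
    if len(pts) == 1:
        return 1.0, 0.0
    angles = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    ca, sa = np.cos(angles), np.sin(angles)
    x = pts[:, 0][:, None] * ca + pts[:, 1][:, None] * sa
    y = -pts[:, 0][:, None] * sa + pts[:, 1][:, None] * ca
    du = x.max(axis=0) - x.min(axis=0)
    dv = y.max(axis=0) - y.min(axis=0)
    areas = du * dv
    i = int(np.argmin(areas))
    return float(max(du[i], dv[i])), float(areas[i])


def random_blob(rng: np.random.Generator, n_px: int, canvas: int = 48) -> np.ndarray:
    """Grow a random 4-connected blob of ``n_px`` pixels on a square canvas."""
    mask = np.zeros((canvas, canvas), dtype=bool)
    r = c = canvas // 2
    mask[r, c] = True
    frontier = [(r, c)]
    while mask.sum() < n_px and frontier:
        idx = int(rng.integers(len(frontier)))
        r, c = frontier[idx]
        moves = [(r + dr, c + dc) for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))]
        moves = [(rr, cc) for rr, cc in moves if 0 <= rr < canvas and 0 <= cc < canvas and not mask[rr, cc]]
        if not moves:
            frontier.pop(idx)
            continue
        rr, cc = moves[int(rng.integers(len(moves)))]
        mask[rr, cc] = True
        frontier.append((rr, cc))
    return mask


def signed_rank_exact_enumeration(diffs: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p by enumerating all 2^n sign vectors.

    Drops zero differences, ranks |d|, and counts sign assignments whose
    positive-rank sum is at least as extreme (in either tail) as observed.
    The null distribution is symmetric, so the two-tail count equals the
    usual doubled one-tail probability.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    if n > 20:
        raise ValueError("enumeration oracle limited to n <= 20")
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    lo, hi = min(w_obs, total - w_obs), max(w_obs, total - w_obs)
    count = 0
    for bits in range(2**n):
        w = sum(ranks[i] for i in range(n) if bits >> i & 1)
        if w <= lo + 1e-9 or w >= hi - 1e-9:
            count += 1
    return min(1.0, count / 2**n)


# ---------------------------------------------------------------------------
# replicate studies on the synthetic cohort
# ---------------------------------------------------------------------------

def calibration_config(seed: int = 0, n_subjects: int = 26) -> CohortConfig:
    """Scaled-down cohort used for replicate studies (small canvas, short glands)."""
    return CohortConfig(
        n_subjects=n_subjects,
        glands_per_lid=(7, 9),
        image_shape=(150, 260),
        tarsus_margin_px=8,
        g_fg=140.0,
        g_bg=112.0,
        noise_sd=6.0,
        upper=EyelidParams(60.0, 8.0, 4.0, 0.8, 3.0, 1.0),
        lower=EyelidParams(42.0, 6.0, 4.0, 0.8, 2.5, 1.0),
        jitter_sd=0.06,
        seed=seed,
    )


def cohort_paired_frame(config: CohortConfig) -> pd.DataFrame:
    """One cohort → per-subject both-eyelid values of every parameter."""
    metrics = samples_to_metrics(simulate_cohort(config))
    return with_both_eyelids(metrics)


def replicate_comparisons(
    base_config: CohortConfig,
    effects: EffectFactors,
    n_replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Run seeded replicates; one row per (replicate, parameter).

    Each replicate regenerates a full paired cohort with a distinct derived
    seed, computes both-eyelid per-subject values, and runs the paired
    comparison.  Columns: replicate, parameter, p_value, mean_diff, test.
    """
    rows = []
    for rep in range(n_replicates):
        cfg = dataclasses.replace(
            base_config,
            group_effects=effects,
            seed=(seed * 100_003 + rep) % (2**31),
        )
        frame = cohort_paired_frame(cfg)
        for p in PARAMETERS:
            sample = paired_sample(frame, p, "both")
            res = compare_paired(sample)
            r, c = sample.complete_pairs()
            rows.append(
                {
                    "replicate": rep,
                    "parameter": p,
                    "p_value": res.p_value,
                    "mean_diff": float((r - c).mean()),
                    "test": res.test_used,
                    "n_pairs": res.n_pairs,
                }
            )
    return pd.DataFrame(rows)


def type1_error_rates(results: pd.DataFrame, alpha: float = 0.05) -> dict[str, float]:
    """Fraction of null replicates with p < alpha, per parameter."""
    return {
        p: float((grp["p_value"] < alpha).mean())
        for p, grp in results.groupby("parameter")
    }


def effect_recovery_rates(results: pd.DataFrame, expected_sign: int = -1, alpha: float = 0.05) -> pd.DataFrame:
    """Per parameter: fraction of replicates recovering the injected sign, and power."""
    rows = []
    for p, grp in results.groupby("parameter"):
        rows.append(
            {
                "parameter": p,
                "sign_recovery": float((np.sign(grp["mean_diff"]) == expected_sign).mean()),
                "power": float((grp["p_value"] < alpha).mean()),
            }
        )
    return pd.DataFrame(rows)
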