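"""Gut-level summaries and the cohort statistics of the study design.

Covers: per-gut counts and proportions (total, GFP+, small, large, pH3+,
Pros+), mitotic index and fold change between feeding conditions,
Kaplan-Meier LT50 with log-rank contrasts, colony counting and log10 CFU
per gut, relative expression by the 2^-ddCt method with two reference
genes, the OD600-to-density conversion, and the classical two-group /
k-group tests used for figure-legend comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "FoldChange",
    "ColonyCount",
    "CfuResult",
    "summarize_gut",
    "mitotic_index",
    "fold_change",
    "km_lt50",
    "logrank",
    "count_colonies",
    "cfu_log10",
    "ddct",
    "od_to_density",
    "compare_groups",
]

#: Single calibration point of the infection model: OD600 = 3 corresponds
#: to 5e9 bacteria per ml.
OD600_CALIBRATION = (3.0, 5e9)


@dataclass(frozen=True)
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    group_summaries: pd.DataFrame

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class FoldChange:
    fold: float
    ci_low: float
    ci_high: float
    n_boot: int


@dataclass(frozen=True)
class ColonyCount:
    count: int
    areas_px: np.ndarray
    area_outliers: np.ndarray  # indices of suspiciously large components


@dataclass(frozen=True)
class CfuResult:
    cfu_per_gut: float
    log10_cfu: float
    below_detection: bool
    detection_limit_log10: float


# ---------------------------------------------------------------------------
# gut summaries
# ---------------------------------------------------------------------------


def summarize_gut(calls: pd.DataFrame, gut_id: str = "gut") -> pd.Series:
    """Counts and proportions for one gut from a per-cell call table.

    Requires a ``size_class`` column; marker columns (gfp/ph3/pros) are
    summarised when present.  Proportions are exact counts over total.
    """
    if len(calls) == 0:
        raise ValueError("empty call table")
    total = len(calls)
    out: dict[str, object] = {"gut_id": gut_id, "total_cells": total}
    n_small = int((calls["size_class"] == "small").sum())
    out["n_small"] = n_small
    out["n_large"] = total - n_small
    for marker in ("gfp", "ph3", "pros"):
        if marker in calls.columns:
            out[f"n_{marker}"] = int(calls[marker].sum())
    if "gfp" in calls.columns and "pros" in calls.columns:
        out["n_gfp_and_pros"] = int(((calls["gfp"] == 1) & (calls["pros"] == 1)).sum())
    out["prop_small"] = out["n_small"] / total
    out["prop_large"] = out["n_large"] / total
    for marker in ("gfp", "ph3", "pros"):
        if f"n_{marker}" in out:
            out[f"prop_{marker}"] = out[f"n_{marker}"] / total
    if "n_gfp_and_pros" in out and out.get("n_pros", 0):
        out["ratio_gfp_pros_over_pros"] = out["n_gfp_and_pros"] / out["n_pros"]
    return pd.Series(out)


def mitotic_index(
    counts: pd.DataFrame, group_col: str = "group", count_col: str = "count"
) -> pd.DataFrame:
    """Per-group mean +/- dispersion of whole-gut pH3+ totals."""
    if len(counts) == 0:
        raise ValueError("no guts supplied")
    grouped = counts.groupby(group_col)[count_col]
    out = grouped.agg(n="count", mean="mean", sd="std", median="median")
    out["sd"] = out["sd"].fillna(0.0)
    return out


def fold_change(
    treated: np.ndarray,
    control: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    ci: float = 0.95,
) -> FoldChange:
    """Ratio of group means, with a seeded bootstrap percentile CI."""
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if control.mean() <= 0:
        raise ValueError("control mean must be positive")
    fold = treated.mean() / control.mean()
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        t = rng.choice(treated, size=len(treated))
        c = rng.choice(control, size=len(control))
        boot[b] = t.mean() / c.mean() if c.mean() > 0 else np.nan
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.nanquantile(boot, [alpha, 1.0 - alpha])
    return FoldChange(fold=float(fold), ci_low=float(lo), ci_high=float(hi), n_boot=n_boot)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def _km_steps(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Event-time step points (t_i, S(t_i)) of the product-limit curve."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_.iloc[:, 0]
    t = sf.index.to_numpy(dtype=float)
    s = sf.to_numpy(dtype=float)
    drops = np.flatnonzero(np.diff(s) < 0) + 1
    return t[drops], s[drops]


def km_lt50(
    cohort: pd.DataFrame,
    group_col: str = "group",
    time_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Kaplan-Meier LT50 per group.

    LT50 is the first time at which the product-limit survival drops to
    0.5 or below, linearly interpolated between the bracketing event
    times; a group whose curve never reaches 0.5 (e.g. heavy censoring)
    gets ``defined=False`` and NaN rather than an error.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rows = []
    for group, sub in cohort.groupby(group_col, sort=True):
        times = sub[time_col].to_numpy(dtype=float)
        events = sub[event_col].to_numpy(dtype=int)
        if (times <= 0).any():
            raise ValueError("survival times must be positive")
        if events.sum() == 0:
            rows.append({"group": group, "lt50": np.nan, "defined": False,
                         "n": len(sub), "events": 0})
            continue
        step_t, step_s = _km_steps(times, events)
        below = step_s <= 0.5
        if not below.any():
            rows.append({"group": group, "lt50": np.nan, "defined": False,
                         "n": len(sub), "events": int(events.sum())})
            continue
        k = int(np.argmax(below))
        if k == 0:
            lt50 = float(step_t[0])
        else:
            s_prev, s_k = step_s[k - 1], step_s[k]
            lt50 = float(
                step_t[k - 1]
                + (s_prev - 0.5) / (s_prev - s_k) * (step_t[k] - step_t[k - 1])
            )
        rows.append({"group": group, "lt50": lt50, "defined": True,
                     "n": len(sub), "events": int(events.sum())})
    return pd.DataFrame(rows).set_index("group")


def logrank(
    cohort: pd.DataFrame,
    group_a: str,
    group_b: str,
    group_col: str = "group",
    time_col: str = "time",
    event_col: str = "event",
) -> GroupComparison:
    """Two-group log-rank test (chi-square reference distribution)."""
    from lifelines.statistics import logrank_test

    sub_a = cohort[cohort[group_col] == group_a]
    sub_b = cohort[cohort[group_col] == group_b]
    if len(sub_a) == 0 or len(sub_b) == 0:
        raise ValueError("both groups must be non-empty")
    if sub_a[event_col].sum() == 0 or sub_b[event_col].sum() == 0:
        raise ValueError("both groups must contain at least one event")
    res = logrank_test(
        sub_a[time_col], sub_b[time_col],
        event_observed_A=sub_a[event_col], event_observed_B=sub_b[event_col],
    )
    summaries = pd.DataFrame(
        {
            "n": [len(sub_a), len(sub_b)],
            "events": [int(sub_a[event_col].sum()), int(sub_b[event_col].sum())],
            "median_time": [float(sub_a[time_col].median()), float(sub_b[time_col].median())],
        },
        index=[group_a, group_b],
    )
    return GroupComparison(
        test_name="logrank",
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        group_summaries=summaries,
    )


# ---------------------------------------------------------------------------
# colony counting and CFU
# ---------------------------------------------------------------------------


def count_colonies(
    image: np.ndarray,
    threshold_method: str | float = "otsu",
    min_area_px: int = 5,
) -> ColonyCount:
    """Particle-count colonies on a plate photograph.

    Global threshold (Otsu by default, or an absolute value) -> mask of
    above-background pixels -> connected components -> drop components
    below ``min_area_px``.  Touching colonies merge into one component —
    the count stays conservative and the merged blob is reported as an
    area outlier (area > 1.8x the median colony area).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("plate image must be 2D")
    if threshold_method == "otsu":
        from skimage.filters import threshold_otsu

        if np.ptp(image) == 0:
            return ColonyCount(0, np.zeros(0), np.zeros(0, int))
        thr = threshold_otsu(image)
    else:
        thr = float(threshold_method)
    mask = image > thr
    labels, n = ndi.label(mask)
    if n == 0:
        return ColonyCount(0, np.zeros(0), np.zeros(0, int))
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = areas >= min_area_px
    areas = areas[keep]
    if len(areas) == 0:
        return ColonyCount(0, np.zeros(0), np.zeros(0, int))
    outliers = np.flatnonzero(areas > 1.8 * np.median(areas))
    return ColonyCount(count=int(len(areas)), areas_px=areas, area_outliers=outliers)


def cfu_log10(
    plate_counts: np.ndarray,
    dilution_factor: float = 100.0,
    plated_volume_ul: float = 200.0,
    homogenate_volume_ul: float = 1000.0,
    n_guts: int = 5,
) -> CfuResult:
    """log10 colony-forming units per gut from technical-replicate plates.

    Technical replicates are averaged before scaling:
    ``CFU/gut = mean(count) * dilution / (plated/homogenate volume) / n_guts``.
    Zero colonies across all plates is reported as below the detection
    limit (the CFU a single colony would imply), never as -inf.
    """
    counts = np.asarray(plate_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("plate counts must be >= 0")
    if dilution_factor <= 0 or plated_volume_ul <= 0 or homogenate_volume_ul <= 0:
        raise ValueError("dilution and volumes must be positive")
    if n_guts <= 0:
        raise ValueError("n_guts must be positive")
    plated_fraction = plated_volume_ul / homogenate_volume_ul
    scale = dilution_factor / plated_fraction / n_guts
    detection_limit = 1.0 * scale
    mean_count = counts.mean()
    cfu = mean_count * scale
    if cfu <= 0:
        return CfuResult(
            cfu_per_gut=0.0,
            log10_cfu=np.nan,
            below_detection=True,
            detection_limit_log10=float(np.log10(detection_limit)),
        )
    return CfuResult(
        cfu_per_gut=float(cfu),
        log10_cfu=float(np.log10(cfu)),
        below_detection=False,
        detection_limit_log10=float(np.log10(detection_limit)),
    )


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def ddct(
    ct_table: pd.DataFrame,
    target: str,
    reference_genes: tuple[str, str] = ("RpL32", "Gapdh1"),
    calibrator_condition: str | None = None,
) -> pd.DataFrame:
    """Relative expression per condition by the 2^-ddCt method.

    Per condition, each target replicate is normalized against the mean of
    the two reference genes' Cts over that condition's replicates
    (arithmetic mean in Ct space = geometric mean of linear quantities);
    ddCt is taken against the calibrator condition (default: first
    condition in the table), whose expression is 1 by construction.
    """
    if len(reference_genes) < 2:
        raise ValueError("two reference genes are required")
    conditions = list(pd.unique(ct_table["condition"]))
    if calibrator_condition is None:
        calibrator_condition = conditions[0]
    if calibrator_condition not in conditions:
        raise ValueError(f"calibrator condition {calibrator_condition!r} not in table")
    delta_ct = {}
    for cond in conditions:
        sub = ct_table[ct_table["condition"] == cond]
        for gene in (target, *reference_genes):
            if not (sub["gene"] == gene).any():
                raise ValueError(f"gene {gene!r} missing in condition {cond!r}")
        ref_mean = sub[sub["gene"].isin(reference_genes)]["ct"].mean()
        target_cts = sub[sub["gene"] == target]["ct"].to_numpy()
        delta_ct[cond] = float(np.mean(target_cts - ref_mean))
    cal = delta_ct[calibrator_condition]
    rows = [
        {
            "condition": cond,
            "delta_ct": delta_ct[cond],
            "ddct": delta_ct[cond] - cal,
            "rel_expr": 2.0 ** -(delta_ct[cond] - cal),
        }
        for cond in conditions
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# utilities and classical tests
# ---------------------------------------------------------------------------


def od_to_density(od600: float | np.ndarray) -> float | np.ndarray:
    """Bacteria per ml from OD600 via the linear single-point calibration."""
    od = np.asarray(od600, dtype=float)
    if (od < 0).any():
        raise ValueError("OD600 must be >= 0")
    density = od * (OD600_CALIBRATION[1] / OD600_CALIBRATION[0])
    return float(density) if np.isscalar(od600) else density


def _group_summaries(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "n": {k: len(v) for k, v in groups.items()},
            "mean": {k: float(np.mean(v)) for k, v in groups.items()},
            "sd": {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for k, v in groups.items()},
        }
    )


def compare_groups(
    values_by_group: dict[str, np.ndarray], test_name: str
) -> GroupComparison:
    """Classical figure-legend tests, two-sided.

    ``t_unpaired``: unpaired Student's t (equal variances);
    ``mann_whitney``: Mann-Whitney U, exact for small untied samples;
    ``anova_oneway``: one-way ANOVA across two or more groups.
    """
    groups = {str(k): np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    vals = list(groups.values())
    if test_name == "t_unpaired":
        if len(groups) != 2:
            raise ValueError("t-test takes exactly two groups")
        if any(len(v) < 2 for v in vals):
            raise ValueError("t-test needs >= 2 values per group")
        stat, p = sps.ttest_ind(vals[0], vals[1], equal_var=True)
    elif test_name == "mann_whitney":
        if len(groups) != 2:
            raise ValueError("Mann-Whitney takes exactly two groups")
        stat, p = sps.mannwhitneyu(vals[0], vals[1], alternative="two-sided", method="auto")
    elif test_name == "anova_oneway":
        if any(len(v) < 2 for v in vals):
            raise ValueError("ANOVA needs >= 2 values per group")
        stat, p = sps.f_oneway(*vals)
    else:
        raise ValueError(f"unknown test {test_name!r}")
    return GroupComparison(
        test_name=test_name,
        statistic=float(stat),
        p_value=float(min(p, 1.0)),
        group_summaries=_group_summaries(groups),
    )
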