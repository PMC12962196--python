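"""ROI aggregation and group statistics.

Turns metric maps into a long-format region table and computes the
study-level statistics: exact Wilcoxon rank-sum comparisons of the lesion
and contralateral sides against pre-lesion values (8 injured segments per
group), percent changes, and the metric-by-metric correlation matrix over
the pooled ROI entries.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .phantom import METRIC_NAMES, RoiLabelScheme

EXACT_MAX_N = 20  # full enumeration of C(n+m, n) up to this combined size

_COMBO_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _combo_matrix(n_total: int, n: int) -> np.ndarray:
    key = (n_total, n)
    if key not in _COMBO_CACHE:
        _COMBO_CACHE[key] = np.array(list(combinations(range(n_total), n)))
    return _COMBO_CACHE[key]


# ---------------------------------------------------------------------------
# ROI extraction
# ---------------------------------------------------------------------------

def extract_roi_means(metric_maps: dict[str, np.ndarray], labels: np.ndarray,
                      scheme: RoiLabelScheme) -> pd.DataFrame:
    """Mean metric value per side-resolved ROI.

    NaN voxels (masked or non-converged fits) are excluded; the returned
    table reports how many voxels entered each mean and how many were
    missing.  An ROI with no usable voxels gets value NA and missing=True.
    """
    labels = np.asarray(labels)
    rows = []
    for code, (name, side) in scheme.labels.items():
        vox = labels == code
        n_total = int(vox.sum())
        for metric, m in metric_maps.items():
            vals = np.asarray(m)[vox]
            good = np.isfinite(vals)
            rows.append({
                "roi": name, "side": side, "metric": metric,
                "value": float(vals[good].mean()) if good.any() else np.nan,
                "n_voxels": int(good.sum()),
                "n_missing": n_total - int(good.sum()),
                "missing": not good.any(),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exact Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def _ranksum_stat(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    return float(ranks[: x.size].sum()), ranks


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon rank-sum test; returns (rank-sum statistic of x, p-value).

    For combined sample size n+m <= 20 the null distribution is obtained
    exactly by enumerating all C(n+m, n) assignments of the pooled
    mid-ranks (ties therefore handled by tie-respecting permutation);
    larger samples use the normal approximation with tie correction and
    continuity correction.  Two-sided p = min(1, 2 * min(tail probs)).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n, m = x.size, y.size
    t_obs, ranks = _ranksum_stat(x, y)

    if n + m <= EXACT_MAX_N:
        combos = _combo_matrix(n + m, n)
        t_all = ranks[combos].sum(axis=1)
        eps = 1e-9
        p_low = np.mean(t_all <= t_obs + eps)
        p_high = np.mean(t_all >= t_obs - eps)
    else:
        mu = n * (n + m + 1) / 2.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = (counts ** 3 - counts).sum() / ((n + m) * (n + m - 1))
        var = n * m / 12.0 * ((n + m + 1) - tie_term)
        sd = np.sqrt(var)
        p_low = sps.norm.cdf((t_obs - mu + 0.5) / sd)
        p_high = sps.norm.sf((t_obs - mu - 0.5) / sd)

    if alternative == "less":
        p = p_low
    elif alternative == "greater":
        p = p_high
    else:
        p = min(1.0, 2.0 * min(p_low, p_high))
    return t_obs, float(p)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def percent_change(lesion_values, pre_values) -> float:
    """100 * (mean(lesion) - mean(pre)) / mean(pre); decrease is negative."""
    lesion = np.asarray(lesion_values, dtype=float)
    pre = np.asarray(pre_values, dtype=float)
    pre_mean = pre.mean()
    if pre_mean == 0:
        raise ValueError("percent change undefined: pre-lesion mean is zero")
    return float(100.0 * (lesion.mean() - pre_mean) / pre_mean)


# ---------------------------------------------------------------------------
# region table and group statistics
# ---------------------------------------------------------------------------

REGION_TABLE_COLUMNS = ("subject", "segment", "condition", "group", "side",
                        "roi", "metric", "value")


def assign_groups(table: pd.DataFrame, lesion_side: str) -> pd.DataFrame:
    """Add the analysis group column: pre / lesion / contralateral."""
    out = table.copy()
    group = np.where(out["condition"] == "pre", "pre",
                     np.where(out["side"] == lesion_side, "lesion", "contralateral"))
    out["group"] = group
    return out


def group_comparisons(region_table: pd.DataFrame, lesion_side: str,
                      pre_matching: str = "matched") -> pd.DataFrame:
    """Per (roi, metric): Wilcoxon vs pre-lesion, percent change, stars.

    The lesion and contralateral groups each hold one value per injured
    segment (subjects x segments).  ``pre_matching='matched'`` compares
    each post-lesion side against the same side pre-lesion;
    ``'averaged'`` compares against the side-averaged pre-lesion value.
    """
    if pre_matching not in ("matched", "averaged"):
        raise ValueError(f"unknown pre_matching {pre_matching!r}")
    contra_side = "right" if lesion_side == "left" else "left"
    rows = []
    for (roi, metric), sub in region_table.groupby(["roi", "metric"], sort=False):
        pre = sub[sub["condition"] == "pre"]
        post = sub[sub["condition"] == "post"]
        lesion = post.loc[post["side"] == lesion_side, "value"].to_numpy()
        contra = post.loc[post["side"] == contra_side, "value"].to_numpy()
        if pre_matching == "matched":
            pre_for_lesion = pre.loc[pre["side"] == lesion_side, "value"].to_numpy()
            pre_for_contra = pre.loc[pre["side"] == contra_side, "value"].to_numpy()
        else:
            avg = pre.groupby(["subject", "segment"])["value"].mean().to_numpy()
            pre_for_lesion = pre_for_contra = avg
        _, p_lesion = wilcoxon_rank_sum(lesion, pre_for_lesion)
        _, p_contra = wilcoxon_rank_sum(contra, pre_for_contra)
        rows.append({
            "roi": roi, "metric": metric,
            "n_segments": lesion.size,
            "mean_pre": pre_for_lesion.mean(),
            "mean_lesion": lesion.mean(),
            "mean_contralateral": contra.mean(),
            "median_pre": float(np.median(pre_for_lesion)),
            "median_lesion": float(np.median(lesion)),
            "median_contralateral": float(np.median(contra)),
            "percent_change_lesion": percent_change(lesion, pre_for_lesion),
            "percent_change_contralateral": percent_change(contra, pre_for_contra),
            "p_lesion_vs_pre": p_lesion,
            "p_contralateral_vs_pre": p_contra,
            "stars_lesion": significance_stars(p_lesion),
            "stars_contralateral": significance_stars(p_contra),
        })
    return pd.DataFrame(rows)


def correlation_entries(region_table: pd.DataFrame, lesion_side: str) -> pd.DataFrame:
    """Pooled entries for the correlation analysis.

    Each (subject, segment, roi) contributes three groups: the
    side-averaged pre-lesion value plus the post-lesion contralateral and
    lesion sides — 7 ROIs x segments x subjects x 3 groups entries per
    metric (168 under the default design).
    """
    table = assign_groups(region_table, lesion_side)
    pre = (table[table["group"] == "pre"]
           .groupby(["subject", "segment", "roi", "metric"], as_index=False)["value"]
           .mean())
    pre["group"] = "pre"
    post = table.loc[table["group"] != "pre",
                     ["subject", "segment", "roi", "metric", "value", "group"]]
    return pd.concat([pre, post], ignore_index=True)


def correlation_matrix(entries: pd.DataFrame, method: str = "pearson",
                       alpha: float = 0.05):
    """Metric-by-metric correlation over the pooled entries.

    Returns ``(r, p, not_significant, n)`` where ``r`` and ``p`` are
    DataFrames indexed by metric, ``not_significant`` masks pairs with
    p > alpha, and ``n`` is the entry count per metric.  Raises if the
    metrics do not share identical entry keys.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    wide = entries.pivot_table(index=["subject", "segment", "roi", "group"],
                               columns="metric", values="value")
    metrics = [m for m in METRIC_NAMES if m in wide.columns]
    wide = wide[metrics]
    if wide.isna().any().any():
        raise ValueError("metrics do not share identical entry keys")
    n = len(wide)
    k = len(metrics)
    r = np.eye(k)
    p = np.zeros((k, k))
    test = sps.pearsonr if method == "pearson" else sps.spearmanr
    for i in range(k):
        for j in range(i + 1, k):
            res = test(wide.iloc[:, i], wide.iloc[:, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    r_df = pd.DataFrame(r, index=metrics, columns=metrics)
    p_df = pd.DataFrame(p, index=metrics, columns=metrics)
    return r_df, p_df, (p_df > alpha) & ~np.eye(k, dtype=bool), n


def region_table_from_truth(cohort_params: dict, lesion_side: str) -> pd.DataFrame:
    """Region table built from ground-truth parameters (no image fitting).

    Maps each (subject, segment, condition, ROI, side) parameter set
    through the metric definitions.  Used for round-trip checks and for
    type-I-error calibration, where simulating and fitting images for
    hundreds of cohorts would add nothing to the statistic under test.
    """
    from .phantom import true_metrics
    rows = []
    for (subject, segment, condition), table in cohort_params.items():
        for (roi, side), params in table.items():
            for metric, value in true_metrics(params).items():
                rows.append({"subject": subject, "segment": segment,
                             "condition": condition, "side": side,
                             "roi": roi, "metric": metric, "value": value})
    return pd.DataFrame(rows)


def type_one_error_rate(n_cohorts: int = 200, seed: int = 0,
                        between_subject_cv: float = 0.05,
                        alpha: float = 0.05) -> tuple[float, int]:
    """Null-cohort rejection fraction of the lesion-vs-pre Wilcoxon tests.

    Simulates ``n_cohorts`` cohorts with all lesion factors at 1 (the
    null), runs the lesion-vs-pre comparison for every (roi, metric) pair
    at the ground-truth level, and returns ``(fraction of p < alpha,
    total number of tests)``.
    """
    from .phantom import (CohortDesign, LesionEffectTable, METRIC_NAMES,
                          sample_cohort_parameters, true_metrics)
    rng = np.random.default_rng(seed)
    design = CohortDesign(seed=seed)
    n_reject = 0
    n_tests = 0
    for _ in range(n_cohorts):
        cohort = sample_cohort_parameters(
            design, between_subject_cv=between_subject_cv,
            effects=LesionEffectTable.null(), rng=rng, shared_base=False)
        lesion_vals: dict[tuple[str, str], list] = {}
        pre_vals: dict[tuple[str, str], list] = {}
        for (subject, segment, condition), table in cohort.items():
            for (roi, side), params in table.items():
                if side != design.lesion_side:
                    continue
                target = lesion_vals if condition == "post" else pre_vals
                for metric, value in true_metrics(params).items():
                    target.setdefault((roi, metric), []).append(value)
        for key, lesion in lesion_vals.items():
            _, p = wilcoxon_rank_sum(lesion, pre_vals[key])
            n_reject += p < alpha
            n_tests += 1
    return n_reject / n_tests, n_tests


@dataclass
class StatsReport:
    """Bundle of the study-level statistical outputs."""

    region_table: pd.DataFrame
    comparisons: pd.DataFrame
    correlation_r: pd.DataFrame
    correlation_p: pd.DataFrame
    correlation_ns_mask: pd.DataFrame
    n_entries: int

    def write(self, out_dir) -> None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        kw = {"sep": "\t", "na_rep": "NA"}
        self.region_table.to_csv(out / "region_table.tsv", index=False, **kw)
        self.comparisons.to_csv(out / "stats_report.tsv", index=False, **kw)
        self.correlation_r.to_csv(out / "correlation_matrix.tsv", **kw)
        self.correlation_p.to_csv(out / "correlation_pvalues.tsv", **kw)


def compute_stats(region_table: pd.DataFrame, lesion_side: str,
                  pre_matching: str = "matched",
                  correlation_method: str = "pearson",
                  alpha: float = 0.05,
                  benjamini_hochberg: bool = False) -> StatsReport:
    """Group comparisons plus correlation matrix for one region table.

    ``benjamini_hochberg=True`` adds FDR-adjusted p/star columns for the
    group comparisons (raw p at fixed levels is the default reporting
    convention, so the option is off unless asked for).
    """
    comparisons = group_comparisons(region_table, lesion_side, pre_matching)
    if benjamini_hochberg:
        for col in ("p_lesion_vs_pre", "p_contralateral_vs_pre"):
            adj = sps.false_discovery_control(comparisons[col].to_numpy(),
                                              method="bh")
            comparisons[col + "_bh"] = adj
            comparisons[col.replace("p_", "stars_") + "_bh"] = [
                significance_stars(p) for p in adj]
    entries = correlation_entries(region_table, lesion_side)
    r, p, ns, n = correlation_matrix(entries, method=correlation_method,
                                     alpha=alpha)
    return StatsReport(region_table=region_table, comparisons=comparisons,
                       correlation_r=r, correlation_p=p, correlation_ns_mask=ns,
                       n_entries=n)
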