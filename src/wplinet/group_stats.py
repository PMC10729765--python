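"""Two-group comparison of connectivity and network properties.

Edgewise Welch t-tests with Benjamini-Hochberg FDR control across the
N(N-1)/2 unique edges of one band, Wilcoxon-Mann-Whitney rank-sum tests on
the four network metrics, and the presentational top-fraction selection of
differential edges.

Directions are reported for group A relative to group B ("increase" means
mean_a > mean_b). Edgewise observations may be subject-level (one mean wPLI
per subject per edge; the default, one observation per independent unit) or
epoch-level (pooled epoch values).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05


def edge_index_pairs(n_channels: int) -> list[tuple[int, int]]:
    """Unordered channel pairs (i < j) in row-major upper-triangle order."""
    return [(i, j) for i in range(n_channels) for j in range(i + 1, n_channels)]


def upper_triangle(matrices: np.ndarray) -> np.ndarray:
    """Extract the strict upper triangle of a stack of square matrices as
    (n_matrices, n_edges)."""
    matrices = np.asarray(matrices)
    n = matrices.shape[-1]
    iu = np.triu_indices(n, k=1)
    return matrices[..., iu[0], iu[1]]


def fdr_correct(p_values: np.ndarray, q: float = ALPHA) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (adjusted p, reject flags)."""
    p_values = np.asarray(p_values, dtype=np.float64)
    if p_values.size == 0:
        raise ValueError("no p-values to correct")
    if p_values.min() < 0 or p_values.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p_values, alpha=q, method="fdr_bh")
    return p_adj, reject


def edgewise_ttest(
    values_a: np.ndarray,
    values_b: np.ndarray,
    channel_names: list[str],
    q: float = ALPHA,
) -> pd.DataFrame:
    """Welch two-sample t-test per edge with BH-FDR across edges.

    ``values_a``/``values_b``: observations x edges arrays (upper-triangle
    edge order). Returns one row per unordered channel pair with columns
    node_i, node_j, mean_a, mean_b, t, p_raw, p_adj, significant, direction,
    degenerate. Edges with zero variance in both groups and equal means are
    flagged degenerate and reported as t=0, p=1.
    """
    a = np.atleast_2d(np.asarray(values_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(values_b, dtype=np.float64))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups have different edge sets")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 observations per group")
    n_edges = a.shape[1]
    pairs = edge_index_pairs(len(channel_names))
    if len(pairs) != n_edges:
        raise ValueError(
            f"{n_edges} edges but {len(channel_names)} channels imply {len(pairs)}"
        )
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # zero-variance edges are caught and flagged below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    p_adj, reject = fdr_correct(p, q=q)
    mean_a = a.mean(axis=0)
    mean_b = b.mean(axis=0)
    return pd.DataFrame(
        {
            "node_i": [channel_names[i] for i, _ in pairs],
            "node_j": [channel_names[j] for _, j in pairs],
            "mean_a": mean_a,
            "mean_b": mean_b,
            "t": t,
            "p_raw": p,
            "p_adj": p_adj,
            "significant": reject,
            "direction": np.where(mean_a > mean_b, "increase", "decrease"),
            "degenerate": degenerate,
        }
    )


def top_fraction_edges(edge_stats: pd.DataFrame, fraction: float = 0.10) -> pd.DataFrame:
    """Keep at most ceil(fraction * n_edges) FDR-significant edges, ranked by
    adjusted p ascending with ties broken by |t| descending. If fewer edges
    are significant, all of them are kept."""
    sig = edge_stats[edge_stats["significant"]].copy()
    cap = math.ceil(fraction * len(edge_stats))
    sig["_abs_t"] = sig["t"].abs()
    sig = sig.sort_values(["p_adj", "_abs_t"], ascending=[True, False])
    return sig.drop(columns="_abs_t").head(cap).reset_index(drop=True)


@dataclass
class RankSumResult:
    statistic: float  # Mann-Whitney U of group A
    p: float
    median_a: float
    median_b: float
    direction: str  # group A relative to group B
    degenerate: bool = False
    method: str = "exact"


def metric_ranksum(values_a: np.ndarray, values_b: np.ndarray) -> RankSumResult:
    """Wilcoxon-Mann-Whitney two-sided test on one network metric.

    Exact null distribution when both groups have <= 8 observations and there
    are no ties; mid-rank normal approximation with tie correction otherwise.
    All-identical samples are degenerate and reported with p = 1.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 1 or b.size < 1:
        raise ValueError("need at least one observation per group")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    direction = "increase" if med_a > med_b else "decrease"
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return RankSumResult(
            statistic=a.size * b.size / 2.0,
            p=1.0,
            median_a=med_a,
            median_b=med_b,
            direction="none",
            degenerate=True,
            method="degenerate",
        )
    has_ties = np.unique(pooled).size < pooled.size
    if max(a.size, b.size) <= 8 and not has_ties:
        method = "exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "asymptotic"
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return RankSumResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        median_a=med_a,
        median_b=med_b,
        direction=direction,
        method=method,
    )


def metric_stats_table(
    metrics_a: pd.DataFrame, metrics_b: pd.DataFrame, bands: list[str]
) -> pd.DataFrame:
    """Rank-sum tests for every (band, metric) cell.

    ``metrics_a``/``metrics_b``: per-subject tables with columns
    band, D, CC, CPL, GE (one row per subject per band).
    """
    rows = []
    for band in bands:
        sub_a = metrics_a[metrics_a["band"] == band]
        sub_b = metrics_b[metrics_b["band"] == band]
        for metric in ("D", "CC", "CPL", "GE"):
            r = metric_ranksum(sub_a[metric].to_numpy(), sub_b[metric].to_numpy())
            rows.append(
                {
                    "band": band,
                    "metric": metric,
                    "statistic": r.statistic,
                    "p": r.p,
                    "median_a": r.median_a,
                    "median_b": r.median_b,
                    "direction": r.direction,
                    "significant": r.p <= ALPHA and not r.degenerate,
                    "method": r.method,
                }
            )
    return pd.DataFrame(rows)


def band_direction_summary(edge_stats: pd.DataFrame) -> dict:
    """Per-band verdict on connectivity change in group A vs group B.

    "ns" when no edge survives FDR; otherwise the direction shared by the
    majority of significant edges ("mixed" on an exact tie).
    """
    sig = edge_stats[edge_stats["significant"]]
    n_inc = int((sig["direction"] == "increase").sum())
    n_dec = int((sig["direction"] == "decrease").sum())
    if n_inc + n_dec == 0:
        verdict = "ns"
    elif n_inc > n_dec:
        verdict = "increase"
    elif n_dec > n_inc:
        verdict = "decrease"
    else:
        verdict = "mixed"
    return {
        "n_significant": n_inc + n_dec,
        "n_increase": n_inc,
        "n_decrease": n_dec,
        "verdict": verdict,
    }
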