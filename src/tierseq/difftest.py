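"""Per-position differential enrichment test for 5'-end count tables.

A deliberately documented simplification of the DESeq2 machinery: median-of-
ratios size factors, method-of-moments dispersions with an a0 + a1/mu trend
and fixed-weight shrinkage, a negative-binomial delta-method Wald test on the
log2 ratio of condition means, and Benjamini-Hochberg adjustment across all
tested positions jointly.  Exact numerical parity with DESeq2 is a non-goal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import PositionTable

DISPERSION_FLOOR = 1e-8
TREND_WEIGHT = 0.5
PSEUDOCOUNT = 0.5

RESULT_COLUMNS = ["base_mean", "log2fc", "se", "p_value", "padj"]


def estimate_size_factors(table: PositionTable) -> pd.Series:
    """Median-of-ratios library size factors.

    The reference is the per-row geometric mean across libraries; each
    library's factor is the median ratio to that reference over rows whose
    geometric mean is positive (i.e. rows observed in every library).
    """
    counts = table.counts.to_numpy(dtype=float)
    if counts.size == 0:
        raise ValueError("empty position table")
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts)
    geomean = np.exp(log_counts.mean(axis=1))
    reference = geomean > 0
    if not reference.any():
        raise ValueError(
            "no position with positive counts in every library; cannot form "
            "the median-of-ratios reference set (relax the filter or pool "
            "more positions)"
        )
    ratios = counts[reference] / geomean[reference, None]
    factors = np.median(ratios, axis=0)
    if not np.all(factors > 0):
        raise ValueError("non-positive size factor estimated")
    return pd.Series(factors, index=table.counts.columns, name="size_factor")


@dataclass
class DispersionModel:
    """Raw, trend and shrunk per-position NB dispersions."""

    raw: np.ndarray
    trend_coef: tuple[float, float]  # alpha(mu) = a0 + a1 / mu
    shrunk: np.ndarray

    def trend(self, mean: np.ndarray) -> np.ndarray:
        a0, a1 = self.trend_coef
        with np.errstate(divide="ignore", invalid="ignore"):
            values = a0 + a1 / mean
        return np.clip(np.where(mean > 0, values, 0.0), 0.0, None)


def estimate_dispersions(
    table: PositionTable,
    size_factors: pd.Series,
    trend_weight: float = TREND_WEIGHT,
) -> DispersionModel:
    """Method-of-moments dispersions pooled within condition, trend-shrunk.

    raw alpha_i = max(0, (v_i - m_i) / m_i^2) where m_i is the mean of
    normalized counts across all libraries and v_i the within-condition
    pooled variance.  A trend a0 + a1/mu is least-squares fitted on positions
    with positive mean and positive raw dispersion, and the shrunk value is
    w * trend(m_i) + (1 - w) * alpha_i, floored at 1e-8.
    """
    for condition in ("wild_type", "mutant"):
        if len(table.libraries_for(condition)) < 2:
            raise ValueError(
                f"condition {condition!r} has fewer than 2 replicates; "
                "dispersion estimation requires at least 2 per condition"
            )
    norm = table.counts.to_numpy(dtype=float) / size_factors.to_numpy()[None, :]
    mean = norm.mean(axis=1)

    ss = np.zeros(len(norm))
    df = 0
    for condition in ("wild_type", "mutant"):
        cols = [table.counts.columns.get_loc(c) for c in table.libraries_for(condition)]
        sub = norm[:, cols]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += len(cols) - 1
    pooled_var = ss / df

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (pooled_var - mean) / mean**2
    raw = np.where(mean > 0, np.clip(raw, 0.0, None), 0.0)

    fit_mask = (mean > 0) & (raw > 0)
    if fit_mask.sum() >= 2:
        design = np.column_stack(
            [np.ones(fit_mask.sum()), 1.0 / mean[fit_mask]]
        )
        coef, *_ = np.linalg.lstsq(design, raw[fit_mask], rcond=None)
        trend_coef = (float(coef[0]), float(coef[1]))
    else:
        trend_coef = (float(raw[fit_mask].mean()) if fit_mask.any() else 0.0, 0.0)

    model = DispersionModel(raw=raw, trend_coef=trend_coef, shrunk=raw)
    shrunk = trend_weight * model.trend(mean) + (1.0 - trend_weight) * raw
    model.shrunk = np.maximum(shrunk, DISPERSION_FLOOR)
    return model


def _group_stats(
    counts: np.ndarray,
    size_factors: np.ndarray,
    wt_cols: np.ndarray,
    mut_cols: np.ndarray,
    alpha: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Wald statistics for a (positions x libraries) matrix."""
    norm = counts / size_factors[None, :]
    wt_mean = norm[:, wt_cols].mean(axis=1)
    mut_mean = norm[:, mut_cols].mean(axis=1)

    # pseudocount only when one of the means is zero, to keep ratios finite
    needs_c = (wt_mean == 0) | (mut_mean == 0)
    c = np.where(needs_c, PSEUDOCOUNT, 0.0)
    wt_adj = wt_mean + c
    mut_adj = mut_mean + c
    log2fc = np.log2(wt_adj / mut_adj)

    ln2 = np.log(2.0)
    se_sq = np.zeros(len(counts))
    for cols, mu in ((wt_cols, wt_adj), (mut_cols, mut_adj)):
        s = size_factors[cols]
        var_mean = (mu[:, None] / s[None, :] + alpha[:, None] * mu[:, None] ** 2).sum(
            axis=1
        ) / len(cols) ** 2
        se_sq += var_mean / (mu * ln2) ** 2
    se = np.sqrt(se_sq)

    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(log2fc == 0.0, 1.0, np.minimum(p, 1.0))
    return log2fc, se, p, norm.mean(axis=1)


def wald_test(
    row_counts: np.ndarray,
    conditions: list[str],
    size_factors: np.ndarray,
    alpha: float,
) -> tuple[float, float, float]:
    """Wald test for a single position; returns (log2fc, se, p_value)."""
    if not np.isfinite(alpha) or alpha < 0:
        raise ValueError(f"invalid dispersion {alpha!r}")
    conditions = list(conditions)
    wt_cols = np.array([i for i, c in enumerate(conditions) if c == "wild_type"])
    mut_cols = np.array([i for i, c in enumerate(conditions) if c == "mutant"])
    if len(wt_cols) < 2 or len(mut_cols) < 2:
        raise ValueError("each condition needs at least 2 libraries")
    counts = np.asarray(row_counts, dtype=float)[None, :]
    log2fc, se, p, _ = _group_stats(
        counts, np.asarray(size_factors, dtype=float), wt_cols, mut_cols,
        np.array([alpha]),
    )
    return float(log2fc[0]), float(se[0]), float(p[0])


def adjust_bh(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def run_difftest(
    table: PositionTable,
    size_factors: pd.Series | None = None,
    dispersions: DispersionModel | None = None,
) -> pd.DataFrame:
    """Full per-position test: normalization, dispersion, Wald, BH.

    Returns a frame indexed like the table with columns base_mean, log2fc,
    se, p_value, padj (log2fc oriented wild_type over mutant).
    """
    if size_factors is None:
        size_factors = estimate_size_factors(table)
    if dispersions is None:
        dispersions = estimate_dispersions(table, size_factors)
    columns = list(table.counts.columns)
    wt_cols = np.array(
        [columns.index(c) for c in table.libraries_for("wild_type")]
    )
    mut_cols = np.array([columns.index(c) for c in table.libraries_for("mutant")])
    if len(wt_cols) < 2 or len(mut_cols) < 2:
        raise ValueError("each condition needs at least 2 libraries")
    counts = table.counts.to_numpy(dtype=float)
    log2fc, se, p, base_mean = _group_stats(
        counts,
        size_factors.to_numpy(dtype=float),
        wt_cols,
        mut_cols,
        dispersions.shrunk,
    )
    padj = adjust_bh(p)
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "p_value": p,
            "padj": padj,
        },
        index=table.counts.index,
    )


def ma_table(results: pd.DataFrame, lfc_min: float = 1.0, alpha: float = 0.05) -> pd.DataFrame:
    """Attach MA-plot significance classes (wt_enriched / mut_enriched / ns)."""
    out = results.copy()
    significant = out["padj"] < alpha
    klass = np.full(len(out), "ns", dtype=object)
    klass[significant & (out["log2fc"] >= lfc_min)] = "wt_enriched"
    klass[significant & (out["log2fc"] <= -lfc_min)] = "mut_enriched"
    out["class"] = klass
    return out


def write_results(results: pd.DataFrame, path) -> None:
    results.reset_index().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index(["replicon", "strand", "position"])
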