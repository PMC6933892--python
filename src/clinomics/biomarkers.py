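"""Differential feature discovery between sample groups.

Per-feature two-group or k-group tests with Benjamini–Hochberg correction,
fold-change filtering, up/down splitting, and correlation-to-anchor ranking.

Fold changes: when the matrix's ``value_scale`` declares a log scale (the
string contains "log"), values are already logged and log2FC is the
difference of group means; for positive linear-scale data it is
log2(mean_A / mean_B); otherwise the plain difference of means is reported
with ``lfc_scale = "difference"``.
"""

from __future__ import annotations

import warnings
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import ClinicalTable, OmicMatrix, Partition

__all__ = [
    "adjust_bh",
    "differential_test",
    "filter_de",
    "split_up_down",
    "rank_by_correlation",
]


def adjust_bh(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_arrays(m: OmicMatrix, groups: Partition | str,
                  clinical: ClinicalTable | None) -> tuple[np.ndarray, list]:
    """Per-sample group codes aligned to the matrix columns (NaN-free)."""
    if isinstance(groups, Partition):
        if groups.axis != "samples":
            raise ValueError("groups partition must be over samples")
        labels = groups.labels_for(m.sample_ids)
        levels = sorted(set(labels.tolist()))
        codes = np.array([levels.index(v) for v in labels])
        return codes, levels
    if clinical is None:
        raise ValueError("grouping by a clinical label requires the clinical table")
    series = clinical.get(groups).reindex(pd.Index(m.sample_ids))
    obs = series.dropna().astype(str)
    levels = list(dict.fromkeys(obs.tolist()))
    codes = np.full(m.n_samples, -1)
    for j, s in enumerate(m.sample_ids):
        v = series[s]
        if pd.notna(v):
            codes[j] = levels.index(str(v))
    return codes, levels


def differential_test(m: OmicMatrix, groups: Partition | str,
                      test: Literal["t", "ranksum", "kruskal", "anova"] = "t",
                      reference_group=None,
                      clinical: ClinicalTable | None = None,
                      equal_var: bool = False) -> pd.DataFrame:
    """Per-feature differential test between sample groups.

    ``t`` (Welch by default) and ``ranksum`` need exactly two groups;
    ``kruskal``/``anova`` accept two or more. Returns one row per feature
    with statistic, p, BH q, log2 fold change and direction relative to the
    reference (second) group. ``reference_group`` names the baseline group;
    the other group is the "A" side whose higher expression means "up".
    """
    codes, levels = _group_arrays(m, groups, clinical)
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if test in ("t", "ranksum") and k != 2:
        raise ValueError(f"test {test!r} requires exactly 2 groups, got {k}")
    sizes = [int((codes == g).sum()) for g in range(k)]
    if test in ("t", "anova") and min(sizes) < 2:
        raise ValueError("variance-based tests need >= 2 samples per group")
    if min(sizes) < 1:
        raise ValueError("every group needs >= 1 sample")

    two_group = k == 2
    ref_idx = 1
    if two_group and reference_group is not None:
        if reference_group not in levels:
            raise KeyError(f"reference group {reference_group!r} not among {levels}")
        ref_idx = levels.index(reference_group)
    a_idx = 1 - ref_idx if two_group else None

    log_scale = "log" in (m.value_scale or "").lower()
    dense = not np.isnan(m.values[:, codes >= 0]).any()
    if dense and test in ("t", "ranksum", "anova"):
        return _differential_dense(m, codes, levels, test, ref_idx, a_idx,
                                   log_scale, equal_var)
    rows = []
    for i, fid in enumerate(m.feature_ids):
        vals = m.values[i]
        per_group = [vals[(codes == g) & ~np.isnan(vals)] for g in range(k)]
        if any(len(v) == 0 for v in per_group):
            rows.append((fid, np.nan, 1.0, np.nan, "flat", "insufficient", *[np.nan] * k))
            continue
        means = [float(v.mean()) for v in per_group]
        flat = all(np.ptp(v) == 0 for v in per_group) and len(set(means)) == 1
        if flat:
            rows.append((fid, 0.0, 1.0, 0.0, "flat", "zero_variance", *means))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if test == "t":
                stat, p = stats.ttest_ind(per_group[0], per_group[1], equal_var=equal_var)
            elif test == "ranksum":
                stat, p = stats.mannwhitneyu(per_group[0], per_group[1],
                                             alternative="two-sided")
            elif test == "kruskal":
                try:
                    stat, p = stats.kruskal(*per_group)
                except ValueError:  # all values identical
                    stat, p = 0.0, 1.0
            elif test == "anova":
                stat, p = stats.f_oneway(*per_group)
            else:
                raise ValueError(f"unknown test {test!r}")
        if not np.isfinite(p):
            stat, p = 0.0, 1.0
        if two_group:
            mean_a, mean_b = means[a_idx], means[ref_idx]
            if log_scale:
                lfc = mean_a - mean_b
            elif mean_a > 0 and mean_b > 0:
                lfc = float(np.log2(mean_a / mean_b))
            else:
                lfc = mean_a - mean_b
            direction = "up" if lfc > 0 else ("down" if lfc < 0 else "flat")
        else:
            lfc, direction = np.nan, ""
        rows.append((fid, float(stat), float(p), lfc, direction, "", *means))
    mean_cols = [f"mean_{levels[g]}" for g in range(k)]
    df = pd.DataFrame(rows, columns=["feature", "statistic", "p", "log2fc",
                                     "direction", "flag", *mean_cols])
    df["q"] = adjust_bh(df["p"].fillna(1.0).to_numpy())
    df.attrs["test"] = test
    df.attrs["reference_group"] = levels[ref_idx] if two_group else None
    df.attrs["groups"] = levels
    df.attrs["lfc_scale"] = ("log_difference" if log_scale else "ratio_or_difference")
    return df


def _differential_dense(m: OmicMatrix, codes: np.ndarray, levels: list,
                        test: str, ref_idx: int, a_idx: int | None,
                        log_scale: bool, equal_var: bool) -> pd.DataFrame:
    """All-features-at-once path for complete (NaN-free) matrices."""
    k = len(levels)
    groups = [m.values[:, codes == g] for g in range(k)]
    means = np.stack([g.mean(axis=1) for g in groups], axis=1)
    flat = np.all([np.ptp(g, axis=1) == 0 for g in groups], axis=0) & \
        (np.ptp(means, axis=1) == 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if test == "t":
            stat, p = stats.ttest_ind(groups[0], groups[1], axis=1, equal_var=equal_var)
        elif test == "ranksum":
            stat, p = stats.mannwhitneyu(groups[0], groups[1], axis=1,
                                         alternative="two-sided")
        else:
            stat, p = stats.f_oneway(*groups, axis=1)
    stat = np.asarray(stat, dtype=float)
    p = np.asarray(p, dtype=float)
    bad = ~np.isfinite(p)
    stat = np.where(bad, 0.0, stat)
    p = np.where(bad | flat, 1.0, p)
    if k == 2:
        mean_a, mean_b = means[:, a_idx], means[:, ref_idx]
        if log_scale:
            lfc = mean_a - mean_b
        else:
            pos = (mean_a > 0) & (mean_b > 0)
            with np.errstate(divide="ignore", invalid="ignore"):
                lfc = np.where(pos, np.log2(np.where(pos, mean_a, 1.0) /
                                            np.where(pos, mean_b, 1.0)),
                               mean_a - mean_b)
        direction = np.where(lfc > 0, "up", np.where(lfc < 0, "down", "flat"))
    else:
        lfc = np.full(m.n_features, np.nan)
        direction = np.array([""] * m.n_features)
    df = pd.DataFrame({"feature": m.feature_ids, "statistic": stat, "p": p,
                       "log2fc": lfc, "direction": direction,
                       "flag": np.where(flat, "zero_variance", "")})
    for g in range(k):
        df[f"mean_{levels[g]}"] = means[:, g]
    df["q"] = adjust_bh(df["p"].to_numpy())
    df.attrs["test"] = test
    df.attrs["reference_group"] = levels[ref_idx] if k == 2 else None
    df.attrs["groups"] = levels
    df.attrs["lfc_scale"] = "log_difference" if log_scale else "ratio_or_difference"
    return df


def filter_de(table: pd.DataFrame, q_max: float = 0.05,
              min_abs_log2fc: float = 0.0) -> pd.DataFrame:
    """Keep rows with q <= q_max and |log2FC| >= min_abs_log2fc."""
    if q_max < 0 or min_abs_log2fc < 0:
        raise ValueError("thresholds must be >= 0")
    keep = (table["q"] <= q_max) & (table["log2fc"].abs() >= min_abs_log2fc)
    out = table[keep.fillna(False)].copy()
    out.attrs.update(table.attrs)
    return out


def split_up_down(table: pd.DataFrame) -> tuple[list[str], list[str]]:
    """(up-regulated, down-regulated) feature lists of a two-group DE table."""
    if table.attrs.get("reference_group") is None and len(table):
        raise ValueError("up/down split needs a two-group table with a reference group")
    up = table.loc[table["log2fc"] > 0, "feature"].tolist()
    down = table.loc[table["log2fc"] < 0, "feature"].tolist()
    return up, down


def rank_by_correlation(m: OmicMatrix, anchor_feature: str,
                        method: Literal["pearson", "spearman"] = "pearson",
                        min_samples: int = 3) -> pd.DataFrame:
    """Rank all features by correlation to an anchor feature.

    Correlations use pairwise-complete samples; features sharing fewer than
    ``min_samples`` observed samples with the anchor get r = NaN, p = 1.
    Sorted by |r| descending with the anchor first.
    """
    a = m.values[m.feature_index(anchor_feature)]
    if np.ptp(a[~np.isnan(a)]) == 0:
        raise ValueError(f"anchor feature {anchor_feature!r} is constant")
    rows = []
    for i, fid in enumerate(m.feature_ids):
        y = m.values[i]
        ok = ~np.isnan(a) & ~np.isnan(y)
        if ok.sum() < min_samples or np.ptp(y[ok]) == 0:
            rows.append((fid, np.nan, 1.0))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if method == "spearman":
                r, p = stats.spearmanr(a[ok], y[ok])
            elif method == "pearson":
                r, p = stats.pearsonr(a[ok], y[ok])
            else:
                raise ValueError(f"unknown method {method!r}")
        if not np.isfinite(p):
            p = 1.0
        rows.append((fid, float(r), float(p)))
    df = pd.DataFrame(rows, columns=["feature", "r", "p"])
    df["q"] = adjust_bh(df["p"].to_numpy())
    df["is_anchor"] = df["feature"] == anchor_feature
    df = df.sort_values(["is_anchor", "r"], key=lambda s: s.abs() if s.name == "r" else s,
                        ascending=[False, False], kind="stable")
    return df.drop(columns="is_anchor").reset_index(drop=True)
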