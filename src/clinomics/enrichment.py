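"""Enrichment of clinical labels on sample clusters, and gene-set enrichment
on feature clusters.

Test choice by label type (all distribution-free):

* categorical — per (cluster, category) hypergeometric upper-tail on the
  overlap; the label-level summary p is the smallest cell p Bonferroni-scaled
  by the number of categories.
* numeric — Kruskal–Wallis across clusters (label level) plus one-vs-rest
  Wilcoxon rank-sum per cluster.
* ordinal — as numeric, on the declared level ranks.
* survival — k-group log-rank (label level) plus one-vs-rest log-rank per
  cluster.

Benjamini–Hochberg correction is applied to the label-level p-values within
each label-type stratum, never across types; per-cell raw p-values are
reported uncorrected for transparency.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .biomarkers import adjust_bh
from .data_io import ClinicalTable, GeneSetCollection, Partition

__all__ = [
    "multi_label_enrichment",
    "single_label_enrichment",
    "gene_set_enrichment",
    "hypergeom_upper_tail",
]

_REPORT_COLS = ["label", "label_type", "cluster", "test", "statistic", "p", "q", "summary"]


def hypergeom_upper_tail(overlap: int, population: int, successes: int,
                         draws: int) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(population, successes, draws)."""
    if not (0 <= successes <= population and 0 <= draws <= population):
        raise ValueError("invalid hypergeometric parameters")
    return float(stats.hypergeom.sf(overlap - 1, population, successes, draws))


def _ranksum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum; exact for small tie-free samples."""
    exact_ok = max(len(x), len(y)) <= 25 and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact" if exact_ok else "asymptotic")
    return float(stat), float(p)


def _label_rows(part: Partition, clinical: ClinicalTable, label: str,
                sample_order: Sequence[str]) -> list[dict]:
    """Enrichment rows for one label: per-cluster cells plus one label-level row."""
    from .survival import logrank_test  # local import to avoid a cycle

    kind = clinical.kind(label)
    clusters = list(range(1, part.k + 1))
    labels_arr = part.labels_for(sample_order)
    rows: list[dict] = []

    def row(cluster, test, statistic, p, summary) -> dict:
        return {"label": label, "label_type": kind, "cluster": cluster,
                "test": test, "statistic": statistic, "p": p, "q": np.nan,
                "summary": summary}

    if kind == "categorical":
        series = clinical.get(label).reindex(pd.Index(sample_order))
        obs = series.notna().to_numpy()
        vals = series.astype(object).where(series.notna(), None).to_numpy()
        cats = list(dict.fromkeys(v for v in vals if v is not None))
        N = int(obs.sum())
        if len(cats) < 2 or N < 2:
            return [row("all", "hypergeometric", np.nan, np.nan,
                        "skipped: fewer than 2 observed categories")]
        best = np.inf
        for c in clusters:
            in_c = (labels_arr == c) & obs
            n_draws = int(in_c.sum())
            if n_draws == 0:
                rows.append(row(c, "hypergeometric", np.nan, np.nan,
                                "not computable: cluster has no labeled samples"))
                continue
            for cat in cats:
                is_cat = np.array([v == cat for v in vals]) & obs
                K = int(is_cat.sum())
                x = int((in_c & is_cat).sum())
                p = hypergeom_upper_tail(x, N, K, n_draws)
                best = min(best, p)
                rows.append(row(c, "hypergeometric", float(x), p,
                                f"category={cat}: {x}/{n_draws} in cluster vs {K}/{N} overall"))
        label_p = min(1.0, best * len(cats)) if np.isfinite(best) else np.nan
        rows.append(row("all", "hypergeometric_min_bonferroni", np.nan, label_p,
                        f"min cell p x {len(cats)} categories"))
        return rows

    if kind in ("numeric", "ordinal"):
        series = (clinical.get(label) if kind == "numeric"
                  else clinical.ordinal_ranks(label))
        v = series.reindex(pd.Index(sample_order)).to_numpy(dtype=float)
        obs = ~np.isnan(v)
        if len(np.unique(v[obs])) < 2:
            return [row("all", "kruskal_wallis", np.nan, np.nan,
                        "skipped: fewer than 2 observed values")]
        groups = [v[(labels_arr == c) & obs] for c in clusters]
        nonempty = [g for g in groups if len(g) > 0]
        test_name = "kruskal_wallis" if kind == "numeric" else "kruskal_wallis_on_ranks"
        if len(nonempty) >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    stat, p = stats.kruskal(*nonempty)
                except ValueError:
                    stat, p = 0.0, 1.0
            rows.append(row("all", test_name, float(stat), float(p),
                            "k-group comparison across clusters"))
        for c, g in zip(clusters, groups):
            rest = v[(labels_arr != c) & obs]
            if len(g) == 0:
                rows.append(row(c, "ranksum_one_vs_rest", np.nan, np.nan,
                                "not computable: cluster has no labeled samples"))
                continue
            if len(rest) == 0:
                rows.append(row(c, "ranksum_one_vs_rest", np.nan, np.nan,
                                "not computable: no labeled samples outside cluster"))
                continue
            stat, p = _ranksum(g, rest)
            rows.append(row(c, "ranksum_one_vs_rest", stat, p,
                            f"cluster median={np.median(g):.4g} vs rest median={np.median(rest):.4g}"))
        return rows

    if kind == "survival":
        tser, eser = clinical.get_survival(label)
        t = tser.reindex(pd.Index(sample_order)).to_numpy(dtype=float)
        e = eser.reindex(pd.Index(sample_order)).to_numpy(dtype=float)
        obs = ~np.isnan(t) & ~np.isnan(e)
        if obs.sum() < 2 or e[obs].sum() < 1:
            return [row("all", "logrank", np.nan, np.nan,
                        "skipped: fewer than 2 observed survival entries or no events")]
        g_obs = labels_arr[obs]
        present = [c for c in clusters if np.any(g_obs == c)]
        if len(present) >= 2:
            keep = np.isin(g_obs, present)
            stat, df, p = logrank_test(t[obs][keep], e[obs][keep], g_obs[keep])
            rows.append(row("all", "logrank_k_group", float(stat), float(p),
                            f"df={df}"))
        for c in clusters:
            if c not in present or len(present) < 2:
                rows.append(row(c, "logrank_one_vs_rest", np.nan, np.nan,
                                "not computable: cluster has no observed survival"))
                continue
            stat, df, p = logrank_test(t[obs], e[obs], g_obs,
                                       mode="one_vs_rest", focus_group=c)
            rows.append(row(c, "logrank_one_vs_rest", float(stat), float(p),
                            "cluster vs rest"))
        return rows

    raise AssertionError(f"unhandled label kind {kind!r}")


def _apply_stratified_bh(report: pd.DataFrame) -> pd.DataFrame:
    """BH within each label type, over the label-level ("all") rows only."""
    report = report.copy()
    for kind in report["label_type"].unique():
        mask = (report["label_type"] == kind) & (report["cluster"] == "all") & report["p"].notna()
        if mask.sum() > 0:
            report.loc[mask, "q"] = adjust_bh(report.loc[mask, "p"].to_numpy())
    return report


def multi_label_enrichment(part: Partition, clinical: ClinicalTable) -> pd.DataFrame:
    """Test every clinical label for enrichment on the sample clusters.

    Returns a report with per-cluster test rows and one label-level summary
    row (cluster = "all") per label; q-values are BH within each label-type
    stratum over the label-level rows.
    """
    if part.axis != "samples":
        raise ValueError("enrichment requires a sample partition")
    if part.k < 2:
        raise ValueError("enrichment requires >= 2 clusters")
    sample_order = [s for s in clinical.sample_ids if s in part.assignments]
    if not sample_order:
        raise ValueError("partition covers no samples of the clinical table")
    rows: list[dict] = []
    for label in clinical.label_names:
        rows.extend(_label_rows(part, clinical, label, sample_order))
    report = pd.DataFrame(rows, columns=_REPORT_COLS)
    return _apply_stratified_bh(report)


def single_label_enrichment(part: Partition, clinical: ClinicalTable,
                            label: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Enrichment of one label, plus its per-cluster value distribution.

    The second return value is a cluster × category count table for
    categorical/ordinal labels, or per-cluster summary statistics (n, mean,
    median, sd) for numeric/survival labels (survival summarizes times).
    """
    if label not in clinical.label_names:
        raise KeyError(f"unknown clinical label {label!r}")
    sample_order = [s for s in clinical.sample_ids if s in part.assignments]
    rows = _label_rows(part, clinical, label, sample_order)
    report = _apply_stratified_bh(pd.DataFrame(rows, columns=_REPORT_COLS))

    kind = clinical.kind(label)
    labels_arr = part.labels_for(sample_order)
    clusters = list(range(1, part.k + 1))
    if kind in ("categorical", "ordinal"):
        series = clinical.get(label).reindex(pd.Index(sample_order))
        cats = list(dict.fromkeys(series.dropna().astype(str)))
        counts = pd.DataFrame(0, index=pd.Index(clusters, name="cluster"), columns=cats)
        for c in clusters:
            sub = series[(labels_arr == c) & series.notna().to_numpy()].astype(str)
            for cat, n in sub.value_counts().items():
                counts.loc[c, cat] = int(n)
        dist = counts
    else:
        if kind == "survival":
            tser, _ = clinical.get_survival(label)
            v = tser.reindex(pd.Index(sample_order)).to_numpy(dtype=float)
        else:
            v = clinical.get(label).reindex(pd.Index(sample_order)).to_numpy(dtype=float)
        stats_rows = []
        for c in clusters:
            g = v[(labels_arr == c) & ~np.isnan(v)]
            stats_rows.append({"cluster": c, "n": len(g),
                               "mean": float(np.mean(g)) if len(g) else np.nan,
                               "median": float(np.median(g)) if len(g) else np.nan,
                               "sd": float(np.std(g, ddof=1)) if len(g) > 1 else np.nan})
        dist = pd.DataFrame(stats_rows).set_index("cluster")
    return report, dist


def gene_set_enrichment(feature_part: Partition, sets: GeneSetCollection,
                        background: Sequence[str], top_n: int = 5) -> pd.DataFrame:
    """Hypergeometric gene-set enrichment per feature cluster.

    Sets are intersected with the background; p is the upper-tail probability
    of the observed overlap; BH is applied across sets within each cluster;
    the top ``top_n`` sets per cluster (by q, then p) are returned.
    """
    if feature_part.axis != "features":
        raise ValueError("gene-set enrichment requires a feature partition")
    bg = list(dict.fromkeys(str(b) for b in background))
    bg_set = set(bg)
    uncovered = [f for f in feature_part.ids if f not in bg_set]
    if uncovered:
        raise ValueError(f"background must contain all clustered features; missing {uncovered[:5]}")
    N = len(bg)
    trimmed = {name: [m for m in sets.members(name) if m in bg_set]
               for name in sets.names}
    trimmed = {name: mem for name, mem in trimmed.items() if mem}
    out = []
    for c in range(1, feature_part.k + 1):
        members = set(feature_part.members(c))
        n_draws = len(members)
        cluster_rows = []
        for name, mem in trimmed.items():
            K = len(mem)
            x = len(members.intersection(mem))
            p = hypergeom_upper_tail(x, N, K, n_draws)
            cluster_rows.append({"cluster": c, "set": name, "overlap": x,
                                 "set_size": K, "cluster_size": n_draws,
                                 "background": N, "p": p})
        if not cluster_rows:
            continue
        sub = pd.DataFrame(cluster_rows)
        sub["q"] = adjust_bh(sub["p"].to_numpy())
        sub = sub.sort_values(["q", "p", "set"], kind="stable").head(top_n)
        out.append(sub)
    if not out:
        return pd.DataFrame(columns=["cluster", "set", "overlap", "set_size",
                                     "cluster_size", "background", "p", "q"])
    return pd.concat(out, ignore_index=True)
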