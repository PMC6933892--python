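"""Matrix cleaning: clipping, row z-scoring, feature/sample filtering, sorting, PCA.

All operations return new :class:`~clinomics.data_io.OmicMatrix` objects and
append to a :class:`PreprocessLog`. Variance and z-scores use the unbiased
estimator (ddof=1) throughout, computed over non-missing entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .data_io import ClinicalTable, OmicMatrix

__all__ = [
    "PreprocessLog",
    "clip_values",
    "row_normalize",
    "filter_features",
    "filter_samples_by_label",
    "sort_samples",
    "pca_scores",
]


@dataclass
class PreprocessLog:
    """Append-only record of preprocessing steps and dimension changes."""

    steps: list[dict] = field(default_factory=list)

    def record(self, op: str, params: dict, before: tuple[int, int],
               after: tuple[int, int]) -> None:
        self.steps.append({"op": op, "params": params,
                           "before": {"features": before[0], "samples": before[1]},
                           "after": {"features": after[0], "samples": after[1]}})

    def __str__(self) -> str:
        lines = []
        for s in self.steps:
            p = ", ".join(f"{k}={v}" for k, v in s["params"].items())
            lines.append(
                f"{s['op']}({p}): {s['before']['features']}x{s['before']['samples']}"
                f" -> {s['after']['features']}x{s['after']['samples']}")
        return "\n".join(lines)


def _logged(log: PreprocessLog | None, op: str, params: dict,
            before: OmicMatrix, after: OmicMatrix) -> OmicMatrix:
    if log is not None:
        log.record(op, params, (before.n_features, before.n_samples),
                   (after.n_features, after.n_samples))
    return after


def clip_values(m: OmicMatrix, floor: float | None = None, ceil: float | None = None,
                log: PreprocessLog | None = None) -> OmicMatrix:
    """Floor/ceil the matrix values; the missing mask is unchanged."""
    if floor is None and ceil is None:
        raise ValueError("clip_values requires at least one of floor/ceil")
    if floor is not None and ceil is not None and floor > ceil:
        raise ValueError(f"floor {floor} exceeds ceil {ceil}")
    out = m.copy()
    with np.errstate(invalid="ignore"):
        out.values = np.clip(out.values, floor, ceil)
    return _logged(log, "clip_values", {"floor": floor, "ceil": ceil}, m, out)


def row_normalize(m: OmicMatrix, log: PreprocessLog | None = None) -> OmicMatrix:
    """Z-score each feature row to mean 0, sd 1 (ddof=1) over non-missing entries.

    Rows with zero variance (or a single observed value) become all-zero,
    with a warning.
    """
    out = m.copy()
    vals = out.values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(vals, axis=1, keepdims=True)
        sd = np.nanstd(vals, axis=1, ddof=1, keepdims=True)
    flat = ~np.isfinite(sd) | (sd == 0)
    if np.any(flat):
        warnings.warn(f"{int(flat.sum())} constant row(s) set to zero by row_normalize")
    safe_sd = np.where(flat, 1.0, sd)
    safe_mean = np.where(np.isfinite(mean), mean, 0.0)
    out.values = np.where(flat, np.where(np.isnan(vals), np.nan, 0.0),
                          (vals - safe_mean) / safe_sd)
    return _logged(log, "row_normalize", {}, m, out)


FilterMode = Literal["top_variance", "id_list_keep", "id_list_drop", "mean_range"]


def filter_features(m: OmicMatrix, mode: FilterMode, *,
                    n: int | None = None,
                    ids: Sequence[str] | None = None,
                    lo: float | None = None, hi: float | None = None,
                    log: PreprocessLog | None = None) -> OmicMatrix:
    """Keep/drop feature rows; surviving rows keep their original order and values.

    Modes: ``top_variance`` keeps the ``n`` rows of largest variance (ddof=1,
    missing-aware); ``id_list_keep``/``id_list_drop`` match ids exactly;
    ``mean_range`` keeps rows with mean in [lo, hi].
    """
    if mode == "top_variance":
        if n is None or n < 1:
            raise ValueError("top_variance requires n >= 1")
        if n >= m.n_features:
            if n > m.n_features:
                warnings.warn(f"top_variance n={n} exceeds {m.n_features} features; keeping all")
            keep_idx = list(range(m.n_features))
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                var = np.nanvar(m.values, axis=1, ddof=1)
            var = np.where(np.isfinite(var), var, -np.inf)
            top = set(np.argsort(-var, kind="stable")[:n])
            keep_idx = [i for i in range(m.n_features) if i in top]
        params: dict = {"mode": mode, "n": n}
    elif mode in ("id_list_keep", "id_list_drop"):
        if ids is None:
            raise ValueError(f"{mode} requires an id list")
        idset = {str(i) for i in ids}
        hits = [i for i, f in enumerate(m.feature_ids) if f in idset]
        if mode == "id_list_keep":
            if not hits:
                raise ValueError("id_list_keep matched no features (would yield empty matrix)")
            keep_idx = hits
        else:
            if not hits:
                warnings.warn("id_list_drop matched no features; matrix unchanged")
            drop = set(hits)
            keep_idx = [i for i in range(m.n_features) if i not in drop]
        params = {"mode": mode, "n_ids": len(idset)}
    elif mode == "mean_range":
        if lo is None or hi is None or lo > hi:
            raise ValueError("mean_range requires lo <= hi")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(m.values, axis=1)
        keep_idx = [i for i in range(m.n_features)
                    if np.isfinite(means[i]) and lo <= means[i] <= hi]
        params = {"mode": mode, "lo": lo, "hi": hi}
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    out = m.subset(features=[m.feature_ids[i] for i in keep_idx])
    return _logged(log, "filter_features", params, m, out)


def filter_samples_by_label(m: OmicMatrix, clinical: ClinicalTable, label: str,
                            keep_values: Sequence | tuple[float, float] | None = None,
                            interval: tuple[float, float] | None = None,
                            log: PreprocessLog | None = None) -> OmicMatrix:
    """Retain the samples whose clinical label matches the selector.

    For categorical/ordinal labels pass ``keep_values`` (a set of tokens);
    for numeric labels pass ``interval=(lo, hi)`` (inclusive; use ±inf for
    open ends). Samples with a missing label are dropped with a warning.
    """
    kind = clinical.kind(label)
    if kind == "survival":
        raise TypeError("cannot filter samples on a survival label; filter on time/event separately")
    series = clinical.get(label).reindex(pd.Index(m.sample_ids))
    n_missing = int(series.isna().sum())
    if n_missing:
        warnings.warn(f"{n_missing} sample(s) with missing label {label!r} dropped")
    if kind == "numeric":
        if interval is None:
            raise ValueError("numeric label filtering requires interval=(lo, hi)")
        lo, hi = interval
        keep = [s for s in m.sample_ids
                if pd.notna(series[s]) and lo <= float(series[s]) <= hi]
    else:
        if keep_values is None:
            raise ValueError("categorical/ordinal label filtering requires keep_values")
        allowed = {str(v) for v in keep_values}
        keep = [s for s in m.sample_ids
                if pd.notna(series[s]) and str(series[s]) in allowed]
    if not keep:
        raise ValueError(f"filter on label {label!r} excluded every sample")
    out = m.subset(samples=keep)
    return _logged(log, "filter_samples_by_label", {"label": label}, m, out)


def sort_samples(m: OmicMatrix, by: str, clinical: ClinicalTable | None = None,
                 direction: Literal["ascending", "descending"] = "ascending",
                 log: PreprocessLog | None = None) -> OmicMatrix:
    """Stable sort of sample columns by a clinical label or by mean expression.

    Categorical labels sort in declared (ordinal) or first-appearance order;
    survival labels sort by the time component; ties keep the prior order.
    Missing labels sort last.
    """
    if by == "mean_expression":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            key = np.nanmean(m.values, axis=0)
        key = np.where(np.isfinite(key), key, np.inf)
    else:
        if clinical is None:
            raise ValueError("sorting by a clinical label requires the clinical table")
        kind = clinical.kind(by)
        if kind == "survival":
            t, _ = clinical.get_survival(by)
            series = t.reindex(pd.Index(m.sample_ids))
            key = series.to_numpy(dtype=float)
        elif kind == "numeric":
            key = clinical.get(by).reindex(pd.Index(m.sample_ids)).to_numpy(dtype=float)
        elif kind == "ordinal":
            key = clinical.ordinal_ranks(by).reindex(pd.Index(m.sample_ids)).to_numpy(dtype=float)
        else:
            series = clinical.get(by).reindex(pd.Index(m.sample_ids))
            order: dict[str, int] = {}
            key = np.empty(m.n_samples)
            for j, s in enumerate(m.sample_ids):
                v = series[s]
                if pd.isna(v):
                    key[j] = np.nan
                else:
                    v = str(v)
                    order.setdefault(v, len(order))
                    key[j] = order[v]
        key = np.where(np.isnan(key), np.inf, key)
    if direction == "descending":
        finite = np.isfinite(key)
        key = np.where(finite, -key, key)  # missing still sorts last
    idx = np.argsort(key, kind="stable")
    out = m.subset(samples=[m.sample_ids[j] for j in idx])
    return _logged(log, "sort_samples", {"by": by, "direction": direction}, m, out)


def pca_scores(m: OmicMatrix, n_components: int) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA sample scores and explained-variance fractions.

    Missing values are imputed to the feature (row) mean before centering.
    Returns (scores DataFrame of shape n_samples × n_components, fractions).
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(m.n_features, m.n_samples):
        raise ValueError("n_components exceeds matrix rank bound")
    vals = m.values.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_mean = np.nanmean(vals, axis=1, keepdims=True)
    row_mean = np.where(np.isfinite(row_mean), row_mean, 0.0)
    nanmask = np.isnan(vals)
    if nanmask.any():
        vals[nanmask] = np.broadcast_to(row_mean, vals.shape)[nanmask]
    X = vals.T  # samples x features
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    frame = pd.DataFrame(scores, index=m.sample_ids,
                         columns=[f"PC{i + 1}" for i in range(n_components)])
    return frame, pca.explained_variance_ratio_.copy()
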