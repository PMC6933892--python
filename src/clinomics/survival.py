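"""Survival analysis: Kaplan–Meier estimation, log-rank tests, univariate Cox
proportional-hazards ranking, and expression-derived sample labels.

Conventions
-----------
* Censorings at an event time are counted at risk for the events at that
  time (the usual product-limit convention).
* The log-rank test is the Mantel–Haenszel chi-square with the
  hypergeometric variance, df = k-1 for the k-group test and df = 1 for the
  one-vs-rest mode.
* Cox fits maximize the partial likelihood by Newton–Raphson with Efron's
  tie correction, converging when |Δβ| < 1e-8 (at most 50 iterations).
  Zero-variance covariates are flagged degenerate (β = 0, HR = 1, p = 1);
  monotone likelihoods (perfect separation) are flagged non-converged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .biomarkers import adjust_bh
from .data_io import ClinicalTable, LabelSpec, OmicMatrix

__all__ = [
    "KMEstimate",
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "cox_univariate",
    "rank_features_by_survival",
    "label_from_expression",
]


@dataclass
class KMEstimate:
    """Product-limit survival estimate at the distinct event times."""

    event_times: np.ndarray     # distinct times with >= 1 event, ascending
    at_risk: np.ndarray         # n_i at each event time
    events: np.ndarray          # d_i at each event time
    survival: np.ndarray        # S(t_i)
    censor_times: np.ndarray    # times of censored observations

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); S = 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def median_time(self) -> float:
        """Smallest event time with S(t) <= 0.5 (NaN if never reached)."""
        below = np.where(self.survival <= 0.5)[0]
        return float(self.event_times[below[0]]) if len(below) else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.event_times, "at_risk": self.at_risk,
                             "events": self.events, "survival": self.survival})


def _as_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if np.any(np.isnan(t)) or np.any(np.isnan(e)):
        raise ValueError("times/events contain missing values; drop them first")
    if np.any(t < 0):
        raise ValueError("negative survival times")
    if not np.all(np.isin(e, (0.0, 1.0))):
        raise ValueError("event flags must be 0/1")
    return t, e.astype(int)


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMEstimate:
    """Kaplan–Meier product-limit estimator."""
    t, e = _as_surv(times, events)
    if e.sum() == 0:
        warnings.warn("no events observed; survival estimate is identically 1")
        return KMEstimate(np.empty(0), np.empty(0, int), np.empty(0, int),
                          np.empty(0), np.sort(t))
    ev_times = np.unique(t[e == 1])
    n_i = np.array([(t >= ti).sum() for ti in ev_times])
    d_i = np.array([((t == ti) & (e == 1)).sum() for ti in ev_times])
    surv = np.cumprod(1.0 - d_i / n_i)
    return KMEstimate(ev_times, n_i, d_i, surv, np.sort(t[e == 0]))


def logrank_test(times: Sequence[float], events: Sequence[int],
                 group: Sequence, mode: Literal["k_group", "one_vs_rest"] = "k_group",
                 focus_group=None) -> tuple[float, int, float]:
    """Mantel–Haenszel log-rank test across k groups.

    Returns (chi-square statistic, degrees of freedom, p-value). In
    ``one_vs_rest`` mode all groups other than ``focus_group`` are collapsed.
    """
    t, e = _as_surv(times, events)
    g = np.asarray(group)
    if g.shape != t.shape:
        raise ValueError("group assignment length mismatch")
    if mode == "one_vs_rest":
        if focus_group is None:
            raise ValueError("one_vs_rest requires focus_group")
        g = np.where(g == focus_group, 0, 1)
    levels, g_idx = np.unique(g, return_inverse=True)
    k = len(levels)
    if k < 2:
        raise ValueError("log-rank test needs >= 2 non-empty groups")
    ev_times = np.unique(t[e == 1])
    if len(ev_times) == 0:
        return 0.0, k - 1, 1.0
    OmE = np.zeros(k)
    V = np.zeros((k, k))
    for ti in ev_times:
        at_risk = t >= ti
        n_j = at_risk.sum()
        d_j = int(((t == ti) & (e == 1)).sum())
        n_gj = np.bincount(g_idx[at_risk], minlength=k).astype(float)
        d_gj = np.bincount(g_idx[(t == ti) & (e == 1)], minlength=k).astype(float)
        E = d_j * n_gj / n_j
        OmE += d_gj - E
        if n_j > 1:
            frac = n_gj / n_j
            c = d_j * (n_j - d_j) / (n_j - 1)
            V += c * (np.diag(frac) - np.outer(frac, frac))
    z = OmE[:-1]
    Vsub = V[:-1, :-1]
    try:
        stat = float(z @ np.linalg.solve(Vsub, z))
    except np.linalg.LinAlgError:
        stat = float(z @ np.linalg.pinv(Vsub) @ z)
    stat = max(stat, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


@dataclass
class CoxFit:
    """Univariate Cox proportional-hazards fit."""

    beta: float
    hazard_ratio: float
    se: float
    z: float
    p: float
    converged: bool
    degenerate: bool
    n: int
    n_events: int
    drift_sign: int = 0  # sign of β drift when the likelihood is monotone


def _efron_derivs(beta: float, x: np.ndarray, t: np.ndarray,
                  e: np.ndarray) -> tuple[float, float, float]:
    """(log-lik, score, information) of the Efron partial likelihood."""
    order = np.argsort(-t, kind="stable")  # descending time
    xs, ts, es = x[order], t[order], e[order]
    r = np.exp(beta * xs)
    S0 = np.cumsum(r)
    S1 = np.cumsum(xs * r)
    S2 = np.cumsum(xs * xs * r)
    if len(np.unique(ts)) == len(ts):  # no ties: fully vectorized
        ev = es == 1
        phi0, phi1, phi2 = S0[ev], S1[ev], S2[ev]
        ll = float((beta * xs[ev] - np.log(phi0)).sum())
        U = float((xs[ev] - phi1 / phi0).sum())
        I = float((phi2 / phi0 - (phi1 / phi0) ** 2).sum())
        return ll, U, I
    ll = U = I = 0.0
    i = 0
    n = len(xs)
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        # risk set = everything with time >= ts[i] = indices [0, j)
        tied = slice(i, j)
        ev = es[tied] == 1
        d = int(ev.sum())
        if d > 0:
            xd = xs[tied][ev]
            rd = r[tied][ev]
            s0d, s1d, s2d = rd.sum(), (xd * rd).sum(), (xd * xd * rd).sum()
            ll += beta * xd.sum()
            for l in range(d):
                f = l / d
                phi0 = S0[j - 1] - f * s0d
                phi1 = S1[j - 1] - f * s1d
                phi2 = S2[j - 1] - f * s2d
                ll -= np.log(phi0)
                U -= phi1 / phi0
                I += phi2 / phi0 - (phi1 / phi0) ** 2
            U += xd.sum()
        i = j
    return ll, U, I


def cox_univariate(times: Sequence[float], events: Sequence[int],
                   covariate: Sequence[float], max_iter: int = 50,
                   tol: float = 1e-8) -> CoxFit:
    """Fit a one-covariate Cox model by Newton–Raphson (Efron ties)."""
    t, e = _as_surv(times, events)
    x = np.asarray(covariate, dtype=float)
    if x.shape != t.shape:
        raise ValueError("covariate length mismatch")
    if np.any(~np.isfinite(x)):
        raise ValueError("covariate contains non-finite values")
    n, n_events = len(t), int(e.sum())
    if n_events < 1:
        raise ValueError("Cox fit requires at least one event")
    if np.ptp(x) == 0:
        return CoxFit(0.0, 1.0, float("nan"), 0.0, 1.0, True, True, n, n_events)
    # center & scale for numerical stability; rescale back afterwards
    mu, sd = x.mean(), x.std()
    xz = (x - mu) / sd
    beta = 0.0
    converged = False
    drift = 0
    for _ in range(max_iter):
        _, U, I = _efron_derivs(beta, xz, t, e)
        if I <= 0 or not np.isfinite(I):
            break
        step = U / I
        beta_new = beta + step
        if abs(beta_new) > 50:  # monotone partial likelihood
            drift = int(np.sign(beta_new))
            beta = beta_new
            break
        if abs(beta_new - beta) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    _, U, I = _efron_derivs(beta, xz, t, e)
    se_z = 1.0 / np.sqrt(I) if I > 0 else float("nan")
    b = beta / sd
    se = se_z / sd
    zval = b / se if se > 0 else float("nan")
    p = float(2 * stats.norm.sf(abs(zval))) if np.isfinite(zval) else float("nan")
    return CoxFit(float(b), float(np.exp(b)), float(se), float(zval), p,
                  converged, False, n, n_events, drift_sign=drift)


def cox_score_statistic(times, events, covariate) -> float:
    """Score chi-square at β = 0 (equals the log-rank statistic for a binary
    covariate without ties)."""
    t, e = _as_surv(times, events)
    x = np.asarray(covariate, dtype=float)
    _, U, I = _efron_derivs(0.0, x, t, e)
    return float(U * U / I)


def rank_features_by_survival(m: OmicMatrix, clinical: ClinicalTable,
                              survival_label: str) -> pd.DataFrame:
    """Univariate Cox fit per feature; BH-corrected and sorted by p.

    Degenerate features (constant expression, or too few usable samples) sink
    to the bottom with p = q = 1.
    """
    tser, eser = clinical.get_survival(survival_label)
    idx = pd.Index(m.sample_ids)
    t_all = tser.reindex(idx).to_numpy(dtype=float)
    e_all = eser.reindex(idx).to_numpy(dtype=float)
    usable = ~np.isnan(t_all) & ~np.isnan(e_all)
    rows = []
    for i, fid in enumerate(m.feature_ids):
        x = m.values[i]
        ok = usable & ~np.isnan(x)
        if ok.sum() < 3 or e_all[ok].sum() < 1 or np.ptp(x[ok]) == 0:
            rows.append((fid, 0.0, 1.0, np.nan, 1.0, True))
            continue
        fit = cox_univariate(t_all[ok], e_all[ok], x[ok])
        p = fit.p if np.isfinite(fit.p) else 1.0
        rows.append((fid, fit.beta, fit.hazard_ratio, fit.z, p, fit.degenerate))
    df = pd.DataFrame(rows, columns=["feature", "beta", "HR", "z", "p", "degenerate"])
    df["q"] = adjust_bh(df["p"].to_numpy())
    df = df.sort_values(["degenerate", "p"], kind="stable").reset_index(drop=True)
    return df


def label_from_expression(m: OmicMatrix, feature: str, clinical: ClinicalTable,
                          rule: Literal["median", "threshold", "quantile"] = "median",
                          threshold: float | None = None,
                          q_lo: float | None = None, q_hi: float | None = None,
                          names: tuple[str, str] = ("Low", "High"),
                          label_name: str | None = None) -> str:
    """Add a two-category clinical label derived from one feature's values.

    ``median``: at-or-below the median -> Low, above -> High. ``threshold``:
    split at an explicit value (<= threshold -> Low). ``quantile``: Low below
    the q_lo quantile, High above q_hi, strictly-between samples missing.
    Returns the new label's name.
    """
    row = m.values[m.feature_index(feature)]
    x = pd.Series(row, index=pd.Index(m.sample_ids))
    obs = x.dropna()
    if len(obs) == 0:
        raise ValueError(f"feature {feature!r} has no observed values")
    low_name, high_name = names
    if rule == "median":
        cut = float(obs.median())
        cat = x.map(lambda v: np.nan if pd.isna(v) else (low_name if v <= cut else high_name))
    elif rule == "threshold":
        if threshold is None:
            raise ValueError("threshold rule requires threshold=")
        cat = x.map(lambda v: np.nan if pd.isna(v) else (low_name if v <= threshold else high_name))
    elif rule == "quantile":
        if q_lo is None or q_hi is None or not 0 <= q_lo <= q_hi <= 1:
            raise ValueError("quantile rule requires 0 <= q_lo <= q_hi <= 1")
        lo_cut, hi_cut = float(obs.quantile(q_lo)), float(obs.quantile(q_hi))
        def assign(v):
            if pd.isna(v):
                return np.nan
            if v <= lo_cut:
                return low_name
            if v >= hi_cut:
                return high_name
            return np.nan
        cat = x.map(assign)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    counts = cat.value_counts()
    if counts.get(low_name, 0) == 0 or counts.get(high_name, 0) == 0:
        raise ValueError(f"degenerate split: all samples fall on one side for {feature!r}")
    name = label_name or f"{feature}_{rule}"
    clinical.add_label(name, cat, LabelSpec(name, "categorical"))
    return name
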