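"""Ground-truth synthetic cohorts for exercising the whole pipeline.

The generator emulates a clinically-annotated tumor cohort with ``k``
planted molecular subtypes:

* **expression** — unit-variance Gaussian noise; each subtype shifts its own
  random 10% feature subset by ``effect_size`` standard deviations.
* **methylation** — a logistic squash of a latent value correlated with the
  expression of the same feature id, sign-flipped for a planted
  anti-correlated subset (values bounded in (0,1), as beta-values are).
* **cnv** — integer-centred Gaussian mixture around a diploid baseline,
  with subtype-specific integer gains/losses on that subtype's subset.
* **survival** — exponential event times with subtype-dependent hazards and
  independent exponential censoring calibrated to the requested censoring
  fraction.
* **labels** — a subtype label flipped with probability ``label_noise``,
  plus one nuisance label independent of subtype.

A GMT-style gene-set collection with one set per subtype's shifted features
backs gene-set enrichment tests. Identical parameters and seed give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import (ClinicalTable, DatasetCollection, GeneSetCollection,
                      LabelSpec, OmicMatrix)

__all__ = ["GroundTruth", "make_dataset", "make_survival_cohort"]

_DEFAULT_FEATURES = {"expression": 1000, "methylation": 400, "cnv": 300}
#: Baseline hazard: mean survival of 1000 time units for the reference subtype.
_BASELINE_RATE = 1e-3


@dataclass
class GroundTruth:
    """The planted structure behind a synthetic collection."""

    subtype: dict[str, int]                       # sample -> subtype 1..k
    shifted_features: dict[int, list[str]]        # subtype -> shifted expression features
    hazard_ratios: list[float]
    anti_correlated_features: list[str]
    gene_sets: GeneSetCollection
    effect_size: float
    label_noise: float
    params: dict = field(default_factory=dict)


def _censored(rng: np.random.Generator, rate: np.ndarray,
              censor_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with exponential censoring at the given fraction."""
    t_event = rng.exponential(1.0 / rate)
    if censor_rate <= 0:
        return t_event, np.ones(len(t_event), dtype=int)
    c_rate = rate * censor_rate / (1.0 - censor_rate)
    t_cens = rng.exponential(1.0 / c_rate)
    obs = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return obs, event


def make_dataset(n_samples: int = 300,
                 n_features: Mapping[str, int] | None = None,
                 k_subtypes: int = 4,
                 proportions: Sequence[float] | None = None,
                 effect_size: float = 2.0,
                 omics: Sequence[str] = ("expression", "methylation", "cnv"),
                 censor_rate: float = 0.3,
                 hazard_ratios: Sequence[float] | None = None,
                 label_noise: float = 0.1,
                 seed: int = 0) -> tuple[DatasetCollection, GroundTruth]:
    """Simulate a multi-omic cohort with planted subtypes.

    Returns the collection (omics + clinical table with subtype, nuisance,
    age and overall-survival labels) and the ground truth behind it.
    """
    rng = np.random.default_rng(seed)
    if n_features is None:
        n_features = {o: _DEFAULT_FEATURES[o] for o in omics}
    unknown = set(omics) - {"expression", "methylation", "cnv"}
    if unknown:
        raise ValueError(f"unknown omics {sorted(unknown)}")
    if "expression" not in omics:
        raise ValueError("the generator requires the expression omic (others derive from it)")
    if proportions is None:
        proportions = [1.0 / k_subtypes] * k_subtypes
    proportions = np.asarray(proportions, dtype=float)
    if len(proportions) != k_subtypes or abs(proportions.sum() - 1.0) > 1e-8:
        raise ValueError("proportions must have length k and sum to 1")
    if hazard_ratios is None:
        hazard_ratios = np.geomspace(1.0, 3.0, k_subtypes)
    hazard_ratios = np.asarray(hazard_ratios, dtype=float)
    if len(hazard_ratios) != k_subtypes or np.any(hazard_ratios <= 0):
        raise ValueError("hazard_ratios must be positive, one per subtype")

    sample_ids = [f"s{i + 1:04d}" for i in range(n_samples)]
    # planted subtype per sample (guarantee every subtype non-empty)
    subtype = rng.choice(np.arange(1, k_subtypes + 1), size=n_samples, p=proportions)
    for c in range(1, k_subtypes + 1):
        if not np.any(subtype == c):
            subtype[rng.integers(n_samples)] = c

    n_expr = int(n_features["expression"])
    expr_ids = [f"g{i + 1:05d}" for i in range(n_expr)]
    expr = rng.standard_normal((n_expr, n_samples))
    n_shift = max(1, int(round(0.10 * n_expr)))
    shifted: dict[int, list[str]] = {}
    for c in range(1, k_subtypes + 1):
        idx = rng.choice(n_expr, size=n_shift, replace=False)
        expr[np.ix_(idx, np.where(subtype == c)[0])] += effect_size
        shifted[c] = [expr_ids[i] for i in sorted(idx)]
    omic_mats: dict[str, OmicMatrix] = {
        "expression": OmicMatrix("expression", expr_ids, sample_ids, expr,
                                 value_scale="log2(norm_count+1)-like (z units)")}

    if "methylation" in omics:
        n_meth = int(n_features.get("methylation", _DEFAULT_FEATURES["methylation"]))
        if n_meth > n_expr:
            raise ValueError("methylation features must be a subset of expression ids")
        meth_idx = np.sort(rng.choice(n_expr, size=n_meth, replace=False))
        n_anti = max(1, n_meth // 5)
        anti_pos = rng.choice(n_meth, size=n_anti, replace=False)
        sign = np.ones(n_meth)
        sign[anti_pos] = -1.0
        latent = (sign[:, None] * expr[meth_idx]
                  + 0.3 * rng.standard_normal((n_meth, n_samples)))
        meth = 1.0 / (1.0 + np.exp(-latent))
        meth_ids = [expr_ids[i] for i in meth_idx]
        anti_ids = [meth_ids[i] for i in sorted(anti_pos)]
        omic_mats["methylation"] = OmicMatrix("methylation", meth_ids, sample_ids,
                                              meth, value_scale="beta-value-like (0,1)")
    else:
        anti_ids = []

    if "cnv" in omics:
        n_cnv = int(n_features.get("cnv", _DEFAULT_FEATURES["cnv"]))
        cnv_ids = [f"cnv{i + 1:05d}" for i in range(n_cnv)]
        cnv = np.full((n_cnv, n_samples), 2.0)
        for c in range(1, k_subtypes + 1):
            idx = rng.choice(n_cnv, size=max(1, n_cnv // 10), replace=False)
            gains = rng.choice([-1.0, 1.0], size=len(idx))
            cnv[np.ix_(idx, np.where(subtype == c)[0])] += gains[:, None]
        cnv += 0.3 * rng.standard_normal((n_cnv, n_samples))
        omic_mats["cnv"] = OmicMatrix("cnv", cnv_ids, sample_ids, cnv,
                                      value_scale="copy-number-like")

    # survival with subtype-dependent hazards
    rates = _BASELINE_RATE * hazard_ratios[subtype - 1]
    times, events = _censored(rng, rates, censor_rate)

    # clinical labels
    noisy = subtype.copy()
    flip = rng.random(n_samples) < label_noise
    if k_subtypes > 1:
        offsets = rng.integers(1, k_subtypes, size=n_samples)
        noisy[flip] = ((subtype[flip] - 1 + offsets[flip]) % k_subtypes) + 1
    subtype_names = np.array([f"subtype{c}" for c in noisy])
    nuisance = rng.choice(["siteA", "siteB", "siteC"], size=n_samples)
    age = np.round(rng.normal(60, 10, size=n_samples), 1)

    clinical = ClinicalTable(sample_ids)
    clinical.add_label("subtype", pd.Series(subtype_names, index=sample_ids),
                       LabelSpec("subtype", "categorical"))
    clinical.add_label("site", pd.Series(nuisance, index=sample_ids),
                       LabelSpec("site", "categorical"))
    clinical.add_label("age", pd.Series(age, index=sample_ids),
                       LabelSpec("age", "numeric"))
    clinical.add_label("OS", pd.DataFrame({"time": times, "event": events},
                                          index=sample_ids),
                       LabelSpec("OS", "survival"))

    gene_sets = GeneSetCollection(sets={
        f"subtype{c}_signature": (f"features shifted in subtype {c}", shifted[c])
        for c in range(1, k_subtypes + 1)})

    coll = DatasetCollection(omics=omic_mats, clinical=clinical)
    truth = GroundTruth(
        subtype={s: int(c) for s, c in zip(sample_ids, subtype)},
        shifted_features=shifted,
        hazard_ratios=[float(h) for h in hazard_ratios],
        anti_correlated_features=anti_ids,
        gene_sets=gene_sets,
        effect_size=effect_size,
        label_noise=label_noise,
        params={"n_samples": n_samples, "k_subtypes": k_subtypes,
                "censor_rate": censor_rate, "seed": seed,
                "omics": list(omics)},
    )
    return coll, truth


def make_survival_cohort(n: int = 500, beta: float = float(np.log(2)),
                         covariate_type: str = "binary",
                         censor_rate: float = 0.3,
                         seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exponential survival with log-hazard = beta * covariate.

    ``covariate_type``: "binary" (balanced 0/1) or "normal" (standard
    Gaussian). Returns (times, events, covariate).
    """
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    if covariate_type == "binary":
        x = (rng.random(n) < 0.5).astype(float)
    elif covariate_type == "normal":
        x = rng.standard_normal(n)
    else:
        raise ValueError(f"unknown covariate_type {covariate_type!r}")
    rate = _BASELINE_RATE * np.exp(beta * x)
    times, events = _censored(rng, rate, censor_rate)
    return times, events, x
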