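"""Integrative multi-omic analysis.

Implements the three multi-omic sample-clustering routes over a
:class:`~clinomics.data_io.DatasetCollection`:

* **Similarity network fusion (SNF)** — per-omic scaled-exponential affinity
  graphs with a local kernel width, iteratively cross-diffused through each
  view's K-nearest-neighbour graph and averaged into one fused network,
  which is then cut by spectral clustering.
* **Neighbourhood-based integration (NEMO-style)** — per-omic relative
  similarity restricted to each sample's K nearest neighbours, symmetrized
  and averaged across omics, with optional automatic choice of the cluster
  number by the largest Laplacian eigengap.
* **Consensus clustering** — subsampled k-means on the concatenation of
  row-normalized omics; cluster number chosen by minimizing the proportion
  of ambiguous clustering (PAC).

Plus inter-omic feature correlation (e.g. expression vs methylation
anti-correlation) with BH correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .data_io import ClinicalTable, DatasetCollection, OmicMatrix, Partition
from .biomarkers import adjust_bh
from .preprocess import row_normalize

__all__ = [
    "SimilarityMatrix",
    "ConsensusResult",
    "build_collection",
    "snf_cluster",
    "nemo_cluster",
    "consensus_cluster",
    "interomic_correlation",
    "spectral_partition",
]


@dataclass
class SimilarityMatrix:
    """A symmetric nonnegative sample-similarity matrix."""

    sample_ids: list[str]
    matrix: np.ndarray
    kind: str = "full"

    def __post_init__(self) -> None:
        A = np.asarray(self.matrix, dtype=float)
        if A.shape != (len(self.sample_ids),) * 2:
            raise ValueError("similarity matrix shape mismatch")
        if not np.allclose(A, A.T, atol=1e-9):
            raise ValueError("similarity matrix not symmetric")
        if np.any(A < -1e-12):
            raise ValueError("similarity matrix has negative entries")
        self.matrix = A

    def row_normalized(self) -> np.ndarray:
        rs = self.matrix.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        return self.matrix / rs


@dataclass
class ConsensusResult:
    """Consensus matrices and PAC scores per candidate k."""

    sample_ids: list[str]
    consensus: dict[int, np.ndarray]
    pac: dict[int, float]
    selected_k: int
    partition: Partition


def build_collection(omics: Sequence[OmicMatrix], clinical: ClinicalTable,
                     sample_policy: Literal["intersect", "union"] = "intersect",
                     ) -> DatasetCollection:
    """Assemble named omics and a clinical table into a collection.

    ``intersect`` restricts every omic to the common sample set (required by
    SNF/consensus); ``union`` keeps per-omic coverage. Samples absent from
    the clinical table are dropped with a warning.
    """
    if not omics:
        raise ValueError("need at least one omic")
    names = [om.omic_name for om in omics]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate omic names: {names}")
    clin_ids = set(clinical.sample_ids)
    trimmed: list[OmicMatrix] = []
    for om in omics:
        extra = [s for s in om.sample_ids if s not in clin_ids]
        if extra:
            warnings.warn(f"omic {om.omic_name!r}: {len(extra)} sample(s) absent "
                          "from the clinical table dropped")
            om = om.subset(samples=[s for s in om.sample_ids if s in clin_ids])
        trimmed.append(om)
    if sample_policy == "intersect":
        shared = set(trimmed[0].sample_ids)
        for om in trimmed[1:]:
            shared &= set(om.sample_ids)
        if not shared:
            raise ValueError("empty sample intersection across omics")
        order = [s for s in trimmed[0].sample_ids if s in shared]
        trimmed = [om.subset(samples=order) for om in trimmed]
    elif sample_policy != "union":
        raise ValueError(f"unknown sample_policy {sample_policy!r}")
    return DatasetCollection(omics={om.omic_name: om for om in trimmed},
                             clinical=clinical)


# ---------------------------------------------------------------------------
# Affinity construction (shared by SNF and NEMO)
# ---------------------------------------------------------------------------

def _sample_distances(m: OmicMatrix) -> np.ndarray:
    """Euclidean distances between samples on row-normalized features."""
    norm = row_normalize(m)
    X = norm.values.T
    if np.isnan(X).any():
        raise ValueError(f"omic {m.omic_name!r} has missing values; impute/filter first")
    return squareform(pdist(X, metric="euclidean"))


def _affinity(D: np.ndarray, K: int, mu: float) -> np.ndarray:
    """Gaussian kernel with a locally adaptive bandwidth.

    eps_ij = (mean distance of i to its K-NN + same for j + d_ij) / 3 sets
    the local scale; the affinity is exp(-d_ij^2 / (2 (mu * eps_ij)^2)),
    i.e. an (unnormalized) Gaussian density in d with sd mu * eps_ij, which
    keeps the kernel scale-free in the raw distance units.
    """
    n = D.shape[0]
    K = min(K, n - 1)
    # mean distance to K nearest neighbours, self excluded
    Dsort = np.sort(D, axis=1)[:, 1:K + 1]
    t = Dsort.mean(axis=1)
    eps = (t[:, None] + t[None, :] + D) / 3.0
    eps = np.maximum(eps, np.finfo(float).eps)
    with np.errstate(under="ignore"):
        W = np.exp(-(D ** 2) / (2.0 * (mu * eps) ** 2))
    return (W + W.T) / 2.0


def _knn_mask(W: np.ndarray, K: int) -> np.ndarray:
    """Boolean mask of each row's K nearest neighbours (self excluded)."""
    n = W.shape[0]
    K = min(K, n - 1)
    mask = np.zeros_like(W, dtype=bool)
    for i in range(n):
        order = np.argsort(-W[i])
        picked = [j for j in order if j != i][:K]
        mask[i, picked] = True
    return mask


def _full_kernel(W: np.ndarray) -> np.ndarray:
    """Row-stochastic full kernel with self-weight 1/2."""
    n = W.shape[0]
    off = W * (1 - np.eye(n))
    rs = off.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    P = off / (2.0 * rs)
    np.fill_diagonal(P, 0.5)
    return P


def _sparse_kernel(W: np.ndarray, K: int) -> np.ndarray:
    """Row-stochastic restriction of W to each row's K nearest neighbours."""
    S = np.where(_knn_mask(W, K), W, 0.0)
    rs = S.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    return S / rs


def _default_K(n: int, K: int | None) -> int:
    if K is not None:
        return min(K, n - 1)
    return min(20, max(1, int(np.ceil(n / 10))), n - 1)


def snf_fuse(coll: DatasetCollection, K: int | None = None, mu: float = 0.5,
             T: int = 20) -> SimilarityMatrix:
    """Cross-diffuse the per-omic affinity networks into one fused network."""
    omics = list(coll.omics.values())
    if len(omics) < 2:
        raise ValueError("SNF requires >= 2 omics")
    ids = omics[0].sample_ids
    for om in omics[1:]:
        if om.sample_ids != ids:
            raise ValueError("omics must share an identical sample set/order; "
                             "use build_collection(..., sample_policy='intersect')")
    n = len(ids)
    K = _default_K(n, K)
    Ws = [_affinity(_sample_distances(om), K, mu) for om in omics]
    Ps = [_full_kernel(W) for W in Ws]
    Ss = [_sparse_kernel(W, K) for W in Ws]
    m = len(Ps)
    eye = np.eye(n)
    for _ in range(T):
        new = []
        for v in range(m):
            others = sum(Ps[u] for u in range(m) if u != v) / max(m - 1, 1)
            Pv = Ss[v] @ others @ Ss[v].T
            # identity regularization keeps self-similarity dominant and
            # stops the diffusion from flattening to a uniform matrix
            new.append((Pv + Pv.T) / 2.0 + eye)
        Ps = new
    fused = sum(Ps) / m
    rs = fused.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    fused = fused / rs
    fused = (fused + fused.T) / 2.0
    return SimilarityMatrix(sample_ids=list(ids), matrix=fused, kind=f"fused(K={K})")


def spectral_partition(sim: SimilarityMatrix, k: int, seed: int = 0,
                       provenance: str = "spectral") -> Partition:
    """Normalized-Laplacian spectral clustering of a similarity matrix."""
    W = sim.matrix.copy()
    np.fill_diagonal(W, 0.0)
    d = W.sum(axis=1)
    d[d == 0] = 1.0
    Dm12 = 1.0 / np.sqrt(d)
    L = np.eye(len(d)) - (Dm12[:, None] * W * Dm12[None, :])
    L = (L + L.T) / 2.0
    vals, vecs = np.linalg.eigh(L)
    U = vecs[:, :k]
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    U = U / norms
    km = KMeans(n_clusters=k, n_init=20, random_state=seed % (2**31 - 1))
    labels = km.fit_predict(U)
    return Partition.from_labels("samples", sim.sample_ids, labels, provenance=provenance)


def snf_cluster(coll: DatasetCollection, k: int, K: int | None = None,
                mu: float = 0.5, T: int = 20,
                seed: int = 0) -> tuple[Partition, SimilarityMatrix]:
    """Similarity-network-fusion clustering into k subtypes."""
    fused = snf_fuse(coll, K=K, mu=mu, T=T)
    part = spectral_partition(fused, k, seed=seed,
                              provenance=f"snf(k={k}, K={K}, mu={mu}, T={T}, seed={seed})")
    return part, fused


def _eigengap_k(W: np.ndarray, k_max: int = 10) -> int:
    """k with the largest gap between consecutive normalized-Laplacian eigenvalues."""
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    d = W.sum(axis=1)
    d[d == 0] = 1.0
    Dm12 = 1.0 / np.sqrt(d)
    L = np.eye(len(d)) - (Dm12[:, None] * W * Dm12[None, :])
    vals = np.linalg.eigvalsh((L + L.T) / 2.0)
    hi = min(k_max, len(vals) - 1)
    gaps = {k: vals[k] - vals[k - 1] for k in range(2, hi + 1)}
    return max(gaps, key=gaps.get)


def nemo_cluster(coll: DatasetCollection, K: int | None = None,
                 k: int | Literal["auto"] = "auto",
                 seed: int = 0) -> Partition:
    """Neighbourhood-based multi-omic clustering (relative-similarity average)."""
    omics = list(coll.omics.values())
    if len(omics) < 2:
        raise ValueError("NEMO-style clustering requires >= 2 omics")
    ids = omics[0].sample_ids
    for om in omics[1:]:
        if om.sample_ids != ids:
            raise ValueError("omics must share an identical sample set/order; "
                             "use build_collection(..., sample_policy='intersect')")
    n = len(ids)
    K = _default_K(n, K)
    Rs = []
    for om in omics:
        W = _affinity(_sample_distances(om), K, _NEMO_MU)
        mask = _knn_mask(W, K)
        denom = np.where(mask, W, 0.0).sum(axis=1, keepdims=True)
        denom[denom == 0] = 1.0
        R = np.where(mask, W, 0.0) / denom
        Rs.append((R + R.T) / 2.0)
    avg = sum(Rs) / len(Rs)
    kk = _eigengap_k(avg) if k == "auto" else int(k)
    sim = SimilarityMatrix(sample_ids=list(ids), matrix=avg, kind=f"nemo(K={K})")
    return spectral_partition(sim, kk, seed=seed,
                              provenance=f"nemo(k={kk}, K={K}, seed={seed})")


_NEMO_MU = 0.5


def consensus_cluster(data: DatasetCollection | OmicMatrix,
                      k_range: Sequence[int] = (2, 3, 4, 5),
                      n_resamples: int = 100, sample_fraction: float = 0.8,
                      seed: int = 0) -> ConsensusResult:
    """Subsampled-k-means consensus clustering with PAC-based k selection.

    Multi-omic input is handled by concatenating the row-normalized feature
    matrices of all omics over the shared samples. The consensus entry (i,j)
    is the fraction of resamples containing both samples in which they
    co-clustered; PAC is the fraction of off-diagonal entries in (0.1, 0.9).
    """
    if isinstance(data, OmicMatrix):
        blocks = [row_normalize(data)]
        ids = list(data.sample_ids)
    else:
        omics = list(data.omics.values())
        ids = omics[0].sample_ids
        for om in omics[1:]:
            if om.sample_ids != ids:
                raise ValueError("consensus clustering needs a shared sample set; "
                                 "use build_collection(..., sample_policy='intersect')")
        blocks = [row_normalize(om) for om in omics]
        ids = list(ids)
    X = np.vstack([b.values for b in blocks]).T  # samples x features
    if np.isnan(X).any():
        raise ValueError("missing values present; impute/filter first")
    n = X.shape[0]
    k_range = [int(k) for k in k_range]
    if not k_range:
        raise ValueError("k_range is empty")
    if max(k_range) > n // 2:
        raise ValueError("k_range must lie within [2, n/2]")
    if not 0.5 < sample_fraction <= 1:
        raise ValueError("sample_fraction must lie in (0.5, 1]")
    m_sub = max(2, int(round(sample_fraction * n)))
    rng = np.random.default_rng(seed)
    consensus: dict[int, np.ndarray] = {}
    pac: dict[int, float] = {}
    # one shared subsample sequence across k, for comparability
    subsamples = [rng.choice(n, size=m_sub, replace=False) for _ in range(n_resamples)]
    for k in k_range:
        co = np.zeros((n, n))
        both = np.zeros((n, n))
        for r, idx in enumerate(subsamples):
            km = KMeans(n_clusters=k, n_init=5,
                        random_state=int(rng.integers(2**31 - 1)))
            labels = km.fit_predict(X[idx])
            both[np.ix_(idx, idx)] += 1.0
            for c in range(k):
                members = idx[labels == c]
                co[np.ix_(members, members)] += 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.where(both > 0, co / np.maximum(both, 1), 0.0)
        np.fill_diagonal(C, 1.0)
        C = (C + C.T) / 2.0
        consensus[k] = C
        tri = C[np.triu_indices(n, 1)]
        pac[k] = float(np.mean((tri > 0.1) & (tri < 0.9)))
    selected = min(k_range, key=lambda k: (pac[k], k))
    Z = hierarchy.linkage(squareform(1.0 - consensus[selected], checks=False),
                          method="average")
    labels = hierarchy.fcluster(Z, t=selected, criterion="maxclust")
    part = Partition.from_labels(
        "samples", ids, labels,
        provenance=f"consensus(k={selected}, resamples={n_resamples}, "
                   f"fraction={sample_fraction}, seed={seed})")
    return ConsensusResult(sample_ids=ids, consensus=consensus, pac=pac,
                           selected_k=selected, partition=part)


# ---------------------------------------------------------------------------
# Inter-omic correlation
# ---------------------------------------------------------------------------

def _pair_corr(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
        return np.nan, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if method == "spearman":
            r, p = stats.spearmanr(x[ok], y[ok])
        else:
            r, p = stats.pearsonr(x[ok], y[ok])
    if not np.isfinite(p):
        p = 1.0
    return float(r), float(p)


def interomic_correlation(coll: DatasetCollection, omic_a: str, omic_b: str,
                          pairing: Literal["shared_feature_ids", "all_pairs_topN"] = "shared_feature_ids",
                          method: Literal["spearman", "pearson"] = "spearman",
                          top_n: int = 100,
                          sort_by_abs: bool = False) -> pd.DataFrame:
    """Correlate features between two omics over their shared samples.

    ``shared_feature_ids`` pairs features with identical ids (e.g. a gene's
    expression vs its methylation); ``all_pairs_topN`` scans every cross-omic
    pair and keeps the ``top_n`` by |r|. Default ordering puts the strongest
    anti-correlations first; ``sort_by_abs`` sorts by |r| descending instead.
    """
    A, B = coll.omics[omic_a], coll.omics[omic_b]
    shared = [s for s in A.sample_ids if s in set(B.sample_ids)]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples between the two omics")
    A = A.subset(samples=shared)
    B = B.subset(samples=shared)
    rows = []
    if pairing == "shared_feature_ids":
        common = [f for f in A.feature_ids if f in set(B.feature_ids)]
        if not common:
            raise ValueError("no shared feature ids between the two omics")
        for f in common:
            r, p = _pair_corr(A.values[A.feature_index(f)],
                              B.values[B.feature_index(f)], method)
            rows.append((f, f, r, p))
    elif pairing == "all_pairs_topN":
        for fa in A.feature_ids:
            xa = A.values[A.feature_index(fa)]
            for fb in B.feature_ids:
                r, p = _pair_corr(xa, B.values[B.feature_index(fb)], method)
                rows.append((fa, fb, r, p))
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    df = pd.DataFrame(rows, columns=["feature_a", "feature_b", "r", "p"])
    df["q"] = adjust_bh(df["p"].to_numpy())
    if pairing == "all_pairs_topN":
        df = df.sort_values("r", key=lambda s: s.abs(), ascending=False,
                            kind="stable").head(top_n)
    if sort_by_abs:
        df = df.sort_values("r", key=lambda s: s.abs(), ascending=False, kind="stable")
    else:
        df = df.sort_values("r", ascending=True, kind="stable")
    return df.reset_index(drop=True)
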