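"""Gene-subset evaluation by embedding + k-means + V-measure with a resampling null.

A gene subset is judged by how well the samples, restricted to those genes,
separate into their classes: embed to 2-D (UMAP by default, PCA as a fast
deterministic alternative), run k-means with k = number of classes, and
score the clustering against the labels with the V-measure.  Because
k-means is initialization-sensitive the score is a distribution over
random initializations, and the significance of an evaluated subset is
assessed against a null of same-size random gene subsets, each re-embedded
and scored under the identical protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "VMeasureResult",
    "NullTestResult",
    "embed",
    "v_measure",
    "kmeans_vmeasure_distribution",
    "null_subset_test",
]


@dataclass
class VMeasureResult:
    homogeneity: float
    completeness: float
    v: float
    contingency: np.ndarray  # class x cluster counts


@dataclass
class NullTestResult:
    null_means: np.ndarray
    statistic: float
    p_value: float
    subset_size: int


def embed(
    X: np.ndarray,
    seed: int = 0,
    method: str = "umap",
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> np.ndarray:
    """2-D embedding of samples x features, deterministic given the seed."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must be 2-D with at least one feature")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to embed")
    if method == "pca":
        return PCA(n_components=min(2, X.shape[1]), random_state=seed).fit_transform(X)
    if method == "umap":
        import umap  # deferred: pulls in numba JIT

        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=min(n_neighbors, X.shape[0] - 1),
            min_dist=min_dist,
            random_state=seed,
        )
        return np.asarray(reducer.fit_transform(X))
    raise ValueError(f"unknown embedding method {method!r}")


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def v_measure(labels: np.ndarray, clusters: np.ndarray) -> VMeasureResult:
    """Homogeneity, completeness and their harmonic mean from the contingency table.

    h = 1 - H(C|K)/H(C) (defined as 1 when H(C) = 0), c = 1 - H(K|C)/H(K)
    (1 when H(K) = 0), V = 2hc/(h+c) with V = 0 when h + c = 0.
    """
    labels = np.asarray(labels)
    clusters = np.asarray(clusters)
    if len(labels) != len(clusters) or len(labels) == 0:
        raise ValueError("labels and clusters must be equal-length and non-empty")
    class_ids = {c: i for i, c in enumerate(sorted(set(labels.tolist())))}
    cluster_ids = {k: i for i, k in enumerate(sorted(set(clusters.tolist())))}
    cont = np.zeros((len(class_ids), len(cluster_ids)))
    for l, k in zip(labels, clusters):
        cont[class_ids[l], cluster_ids[k]] += 1

    n = cont.sum()
    h_c = _entropy(cont.sum(axis=1))
    h_k = _entropy(cont.sum(axis=0))
    # H(C|K): entropy of classes within each cluster, cluster-weighted.
    h_c_given_k = sum(
        (cont[:, j].sum() / n) * _entropy(cont[:, j]) for j in range(cont.shape[1])
    )
    h_k_given_c = sum(
        (cont[i].sum() / n) * _entropy(cont[i]) for i in range(cont.shape[0])
    )
    h = 1.0 if h_c == 0 else 1.0 - h_c_given_k / h_c
    c = 1.0 if h_k == 0 else 1.0 - h_k_given_c / h_k
    v = 0.0 if h + c == 0 else 2 * h * c / (h + c)
    return VMeasureResult(homogeneity=h, completeness=c, v=v, contingency=cont)


def kmeans_vmeasure_distribution(
    embedding: np.ndarray,
    labels: np.ndarray,
    k: int | None = None,
    iterations: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """V-measures over independent k-means initializations of one embedding.

    ``k`` defaults to the number of classes, which anchors homogeneity and
    completeness to a comparable scale across gene subsets.
    """
    labels = np.asarray(labels)
    if k is None:
        k = len(set(labels.tolist()))
    if k > embedding.shape[0]:
        raise ValueError(f"k={k} exceeds the number of samples {embedding.shape[0]}")
    rng = np.random.default_rng(seed)
    out = np.empty(iterations)
    for i in range(iterations):
        km = KMeans(n_clusters=k, n_init=1, random_state=int(rng.integers(0, 2**31)))
        assign = km.fit_predict(embedding)
        out[i] = v_measure(labels, assign).v
    return out


def null_subset_test(
    X: np.ndarray,
    labels: np.ndarray,
    evaluated_genes: np.ndarray,
    n_subsets: int = 100,
    inits_per_subset: int = 100,
    seed: int = 0,
    method: str = "umap",
) -> NullTestResult:
    """Is the evaluated gene subset's clustering better than random subsets?

    ``evaluated_genes`` is a boolean mask or integer index into the feature
    axis of ``X`` (samples x genes).  Each of ``n_subsets`` random subsets
    of the same size is re-embedded and scored by its mean V-measure over
    ``inits_per_subset`` k-means initializations; the evaluated subset is
    scored under the identical protocol and its mean is tested against the
    null means with an upper-tail one-sample t-test.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    evaluated_genes = np.asarray(evaluated_genes)
    if evaluated_genes.dtype == bool:
        eval_idx = np.flatnonzero(evaluated_genes)
    else:
        eval_idx = evaluated_genes.astype(int)
    subset_size = len(eval_idx)
    if subset_size == 0 or subset_size > X.shape[1]:
        raise ValueError(f"evaluated subset size {subset_size} out of range")

    ss = np.random.SeedSequence(seed)
    eval_seed, null_seed = ss.spawn(2)
    rng = np.random.default_rng(null_seed)

    def mean_v(idx: np.ndarray, embed_seed: int, km_seed: int) -> float:
        emb = embed(X[:, idx], seed=embed_seed, method=method)
        return float(
            kmeans_vmeasure_distribution(
                emb, labels, iterations=inits_per_subset, seed=km_seed
            ).mean()
        )

    stat = mean_v(eval_idx, int(eval_seed.generate_state(1)[0]) % (2**31), seed)
    null_means = np.empty(n_subsets)
    for i in range(n_subsets):
        idx = rng.choice(X.shape[1], size=subset_size, replace=False)
        null_means[i] = mean_v(idx, int(rng.integers(0, 2**31)), int(rng.integers(0, 2**31)))
        logger.debug("null subset %d mean V = %.4f", i, null_means[i])

    # Upper tail: small p when the statistic exceeds the null means.
    p = float(stats.ttest_1samp(null_means, stat, alternative="less").pvalue)
    return NullTestResult(
        null_means=null_means, statistic=stat, p_value=p, subset_size=subset_size
    )
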