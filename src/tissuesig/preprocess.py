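"""Expression filtering, TPM, TMM normalization, transform and image encoding.

The normalization pipeline mirrors standard bulk RNA-seq practice: genes are
kept when they are expressed (count and TPM criteria intersected), between-
sample scaling uses the weighted trimmed mean of M-values (TMM), and the
normalized values are passed through ``log2(x + 0.001) + 10`` before being
laid out row-major into the smallest square image that holds them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .simulate import CountMatrix

__all__ = [
    "TMMFactors",
    "LabeledDataset",
    "compute_tpm",
    "filter_genes",
    "tmm_factors",
    "transform_expression",
    "normalized_expression",
    "pad_and_reshape",
    "unflatten_gene_order",
    "split_train_test",
    "build_dataset",
    "PAD_VALUE",
]


@dataclass
class TMMFactors:
    """Per-sample TMM normalization factors (geometric mean re-centered to 1)."""

    factors: np.ndarray
    reference_sample: str
    library_sizes: np.ndarray

    @property
    def effective_library_sizes(self) -> np.ndarray:
        return self.library_sizes * self.factors


@dataclass
class LabeledDataset:
    """Square-image encodings of transformed expression plus labels and split.

    ``gene_order`` maps each flattened image position to a gene id; padding
    positions hold ``None``.  ``images`` has shape (n_samples, side, side).
    """

    images: np.ndarray
    labels: np.ndarray
    split: np.ndarray  # "train" | "test" per sample
    gene_order: list[str | None]
    class_names: list[str]
    sample_ids: np.ndarray

    @property
    def side(self) -> int:
        return self.images.shape[1]

    @property
    def n_genes(self) -> int:
        return sum(g is not None for g in self.gene_order)

    def vectors(self) -> np.ndarray:
        """(n_samples, n_genes) transformed expression, padding stripped."""
        flat = self.images.reshape(self.images.shape[0], -1)
        return flat[:, : self.n_genes]

    def subset(self, mask: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            images=self.images[mask],
            labels=self.labels[mask],
            split=self.split[mask],
            gene_order=self.gene_order,
            class_names=self.class_names,
            sample_ids=self.sample_ids[mask],
        )


def compute_tpm(counts: CountMatrix) -> np.ndarray:
    """Transcripts-per-million: length-normalized counts scaled to 1e6 per sample."""
    lengths = np.asarray(counts.gene_lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive for TPM")
    rate = counts.counts / lengths[:, None]
    denom = rate.sum(axis=0)
    denom[denom == 0] = np.nan
    return rate / denom[None, :] * 1e6


def filter_genes(
    counts: CountMatrix,
    tpm: np.ndarray,
    min_count: float = 6,
    min_tpm: float = 0.1,
    min_samples: int | None = None,
) -> np.ndarray:
    """Boolean keep-mask: count >= min_count in > min_samples samples AND
    TPM > min_tpm in > min_samples samples.

    When ``min_samples`` is None it defaults to ``ceil(0.8 * smallest class
    size)`` — the fraction-of-smallest-class rationale behind the canonical
    80-sample threshold, which keeps the rule meaningful at synthetic scale.
    """
    if min_samples is None:
        _, class_sizes = np.unique(counts.labels, return_counts=True)
        min_samples = math.ceil(0.8 * class_sizes.min())
    if min_samples >= counts.n_samples:
        raise ValueError(
            f"min_samples={min_samples} must be below n_samples={counts.n_samples}"
        )
    if tpm.shape != counts.counts.shape:
        raise ValueError("tpm and counts must share shape")
    count_pass = (counts.counts >= min_count).sum(axis=1) > min_samples
    tpm_pass = (np.nan_to_num(tpm) > min_tpm).sum(axis=1) > min_samples
    return count_pass & tpm_pass


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """log2 TMM factor of one sample against the reference (edgeR-style)."""
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 0.0
    o = obs[keep] / lib_obs
    r = ref[keep] / lib_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # Precision weights: inverse asymptotic variance of M (binomial delta method).
    w = (lib_obs - obs[keep]) / (lib_obs * obs[keep]) + (lib_ref - ref[keep]) / (
        lib_ref * ref[keep]
    )
    n = len(m)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = m.argsort().argsort() + 1
    rank_a = a.argsort().argsort() + 1
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 0.0
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return 0.0 if not np.isfinite(f) else float(f)


def tmm_factors(
    counts: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference_pool: np.ndarray | None = None,
) -> TMMFactors:
    """Weighted trimmed mean of M-values normalization factors.

    The reference is the sample whose 75th count percentile (scaled by
    library size) is closest to the mean across samples; ``reference_pool``
    (a boolean sample mask) can restrict which samples may serve as the
    reference, e.g. to keep held-out samples from influencing the factors
    applied to training data.  Genes zero in either member of a pair are
    excluded from that pair's trimmed mean, the M-values are double-trimmed
    (``trim_m`` on M, ``trim_a`` on A) and averaged with precision weights;
    factors are re-centered to geometric mean 1.
    """
    if counts.n_samples < 2:
        raise ValueError("TMM requires at least 2 samples")
    lib = counts.counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        bad = [str(s) for s, l in zip(counts.sample_ids, lib) if l == 0]
        raise ValueError(f"samples with zero library size: {bad}")
    uq = np.array(
        [np.quantile(counts.counts[:, k], 0.75) / lib[k] for k in range(counts.n_samples)]
    )
    if reference_pool is None:
        pool = np.arange(counts.n_samples)
    else:
        pool = np.flatnonzero(np.asarray(reference_pool))
        if len(pool) == 0:
            raise ValueError("reference_pool excludes every sample")
    ref_idx = int(pool[np.argmin(np.abs(uq[pool] - uq[pool].mean()))])
    log_f = np.array(
        [
            _tmm_pair(
                counts.counts[:, k].astype(float),
                counts.counts[:, ref_idx].astype(float),
                lib[k],
                lib[ref_idx],
                trim_m,
                trim_a,
            )
            for k in range(counts.n_samples)
        ]
    )
    factors = 2.0 ** log_f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return TMMFactors(
        factors=factors,
        reference_sample=str(counts.sample_ids[ref_idx]),
        library_sizes=lib,
    )


def transform_expression(x):
    """``log2(x + 0.001) + 10`` — compresses outliers, keeps zeros finite."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("expression values must be non-negative")
    return np.log2(x + 0.001) + 10.0


PAD_VALUE = float(transform_expression(0.0))  # transform of zero expression


def normalized_expression(counts: CountMatrix, tmm: TMMFactors) -> np.ndarray:
    """TMM-normalized expression: counts scaled by effective library size, per million."""
    eff = tmm.effective_library_sizes
    return counts.counts / eff[None, :] * 1e6


def pad_and_reshape(vector: np.ndarray) -> tuple[np.ndarray, int]:
    """Lay a length-n vector row-major into a ceil(sqrt(n))-sided square.

    Trailing positions are filled with ``PAD_VALUE`` (the transform of zero
    expression) so padding is indistinguishable from unexpressed genes.
    Returns (matrix, n_pad).
    """
    vector = np.asarray(vector, dtype=float).ravel()
    n = vector.size
    if n < 1:
        raise ValueError("vector must be non-empty")
    side = math.isqrt(n)
    if side * side < n:
        side += 1
    n_pad = side * side - n
    padded = np.concatenate([vector, np.full(n_pad, PAD_VALUE)])
    return padded.reshape(side, side), n_pad


def unflatten_gene_order(gene_ids: np.ndarray, side: int) -> list[str | None]:
    order: list[str | None] = [str(g) for g in gene_ids]
    order.extend([None] * (side * side - len(order)))
    return order


def split_train_test(
    labels: np.ndarray, per_class_test_n: int = 50, seed: int = 0
) -> np.ndarray:
    """Assign ``per_class_test_n`` samples of every class to the test split.

    Sampling is without replacement and deterministic given the seed.  A
    class whose size does not exceed ``per_class_test_n`` would be left with
    no training samples and raises.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    split = np.array(["train"] * len(labels), dtype=object)
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        if len(idx) <= per_class_test_n:
            raise ValueError(
                f"class {cls!r} has {len(idx)} samples; needs > {per_class_test_n} "
                "to keep a non-empty training set"
            )
        test_idx = rng.choice(idx, size=per_class_test_n, replace=False)
        split[test_idx] = "test"
    return split


def build_dataset(
    counts: CountMatrix,
    tmm: TMMFactors,
    split: np.ndarray,
    gene_mask: np.ndarray | None = None,
) -> LabeledDataset:
    """Full encoding: TMM-normalize, transform, pad to square images."""
    cm = counts if gene_mask is None else counts.subset_genes(gene_mask)
    expr = transform_expression(normalized_expression(cm, tmm))  # (genes, samples)
    n_genes = expr.shape[0]
    first, n_pad = pad_and_reshape(expr[:, 0])
    side = first.shape[0]
    images = np.empty((expr.shape[1], side, side), dtype=np.float32)
    for s in range(expr.shape[1]):
        images[s], _ = pad_and_reshape(expr[:, s])
    class_names = sorted(set(cm.labels.tolist()))
    return LabeledDataset(
        images=images,
        labels=np.asarray(cm.labels, dtype=object),
        split=np.asarray(split, dtype=object),
        gene_order=unflatten_gene_order(cm.gene_ids, side),
        class_names=class_names,
        sample_ids=np.asarray(cm.sample_ids, dtype=object),
    )
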