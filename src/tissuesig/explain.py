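"""Shapley-style expected-gradients attribution and explainable-gene selection.

``expected_gradients`` approximates Shapley values for a differentiable
model by Monte-Carlo integration: draw a baseline ``b`` from a background
set and an interpolation coefficient ``u ~ U(0,1)``, evaluate the model
gradient at ``b + u (x - b)``, and average ``grad * (x - b)``.  Summed over
features this converges to ``f(x) - E[f(b)]`` (the additivity property).

Downstream, attributions for correctly-predicted samples are reduced to a
per-class median per gene, genes are ranked per class, and the
uniqueness/exclusivity structure of the expanding top-n lists determines
the selected gene set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._nn import Sequential, softmax
from .preprocess import LabeledDataset

logger = logging.getLogger(__name__)

__all__ = [
    "AttributionTensor",
    "RankedGeneTable",
    "expected_gradients",
    "attribute_dataset",
    "filter_attributions",
    "median_rank_genes",
    "uniqueness_curve",
    "select_top_genes",
    "depth_at_unique_fraction",
    "cohort_overlap",
]


@dataclass
class AttributionTensor:
    """Signed attributions phi[sample, class, gene] with provenance."""

    values: np.ndarray
    sample_ids: np.ndarray
    class_names: list[str]
    gene_ids: np.ndarray
    background_size: int
    nsamples: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attributions must be finite")


@dataclass
class RankedGeneTable:
    """Per class, genes ordered by descending median attribution.

    ``genes[c]`` and ``medians[c]`` are aligned arrays for class ``c``; rank
    1 is the largest median.  Ties are broken by ascending gene id so the
    ordering is deterministic.
    """

    class_names: list[str]
    genes: dict[str, np.ndarray]
    medians: dict[str, np.ndarray]

    @property
    def n_genes(self) -> int:
        return len(next(iter(self.genes.values())))

    def top(self, class_name: str, depth: int) -> list[str]:
        return [str(g) for g in self.genes[class_name][:depth]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in self.class_names:
            for rank, (g, m) in enumerate(zip(self.genes[cls], self.medians[cls]), start=1):
                rows.append((cls, rank, g, m))
        return pd.DataFrame(rows, columns=["class", "rank", "gene", "median_shap"])


def _interp_points(x, b, u):
    # x: feature shape S, b: (n, *S), u: (n,)
    extra = (1,) * x.ndim
    return b + u.reshape(-1, *extra) * (x[None] - b)


def expected_gradients(
    model: Sequential,
    x: np.ndarray,
    background: np.ndarray,
    nsamples: int = 50,
    seed: int = 0,
    output: str = "proba",
) -> np.ndarray:
    """Attributions for one input ``x`` of arbitrary feature shape.

    Returns an array of shape (n_classes, *x.shape).  ``output`` selects
    whether the explained quantity is the softmax probability (default,
    matching a model explained as built) or the raw logit.

    Interpolation coefficients are stratified over [0, 1) (jittered grid),
    which keeps the estimator unbiased while markedly reducing the variance
    of the completeness sum at small ``nsamples``.
    """
    if len(background) == 0:
        raise ValueError("background set must be non-empty")
    if nsamples < 1:
        raise ValueError("nsamples must be >= 1")
    if output not in ("proba", "logits"):
        raise ValueError("output must be 'proba' or 'logits'")
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=np.float32)
    # Jointly stratified (baseline, u) pairs: u is a jittered grid kept in
    # order, baselines cycle through an independent shuffle of the pool per
    # grid block.  Every baseline is represented nearly equally AND sees
    # u values spread across [0,1), which removes both the baseline-sampling
    # and most of the path-sampling variance of the completeness sum.
    reps = int(np.ceil(nsamples / len(background)))
    perm = rng.permutation(len(background))
    # Alternate blocks mirror the permutation, so each baseline's u values
    # pair antithetically (u near t with u near 1-t).
    b_idx = np.concatenate(
        [perm if r % 2 == 0 else perm[::-1] for r in range(reps)]
    )[:nsamples]
    b = np.asarray(background, dtype=np.float32)[b_idx]
    u = ((np.arange(nsamples) + rng.random(nsamples)) / nsamples).astype(np.float32)
    points = _interp_points(x, b, u)

    logits = model.forward(points, train=False)
    n_classes = logits.shape[1]
    probs = softmax(logits)
    diff = (x[None] - b).astype(np.float32)

    phi = np.empty((n_classes,) + x.shape, dtype=np.float64)
    for c in range(n_classes):
        if output == "proba":
            seed_vec = (-probs[:, c : c + 1]) * probs
            seed_vec[:, c] += probs[:, c]
        else:
            seed_vec = np.zeros_like(logits)
            seed_vec[:, c] = 1.0
        model.zero_grad()
        grads = model.backward(seed_vec.astype(np.float32))
        phi[c] = (grads.astype(np.float64) * diff).mean(axis=0)
    return phi


def attribute_dataset(
    model: Sequential,
    dataset: LabeledDataset,
    background_images: np.ndarray,
    nsamples: int = 50,
    background_size: int = 100,
    seed: int = 0,
    output: str = "proba",
    which: str = "test",
) -> AttributionTensor:
    """Expected-gradients attributions for every sample of a dataset split.

    The background is a seeded subsample of the supplied (training) images;
    pad pixels receive gradients like any other but are dropped when the
    per-pixel attributions are mapped back to genes through ``gene_order``.
    """
    rng = np.random.default_rng(seed)
    part = dataset.subset(dataset.split == which) if which in ("train", "test") else dataset
    bg = background_images
    if len(bg) > background_size:
        bg = bg[rng.choice(len(bg), size=background_size, replace=False)]
    bg4 = bg[:, None, :, :] if bg.ndim == 3 else bg

    gene_pos = [i for i, g in enumerate(dataset.gene_order) if g is not None]
    gene_ids = np.array(
        [g for g in dataset.gene_order if g is not None], dtype=object
    )
    n = len(part.labels)
    n_classes = len(dataset.class_names)
    values = np.empty((n, n_classes, len(gene_pos)))
    child_seeds = np.random.SeedSequence(seed).spawn(n)
    for i in range(n):
        img = part.images[i][None, :, :]
        phi = expected_gradients(
            model,
            img,
            bg4,
            nsamples=nsamples,
            seed=int(child_seeds[i].generate_state(1)[0]),
            output=output,
        )
        flat = phi.reshape(n_classes, -1)
        values[i] = flat[:, gene_pos]
    return AttributionTensor(
        values=values,
        sample_ids=part.sample_ids,
        class_names=list(dataset.class_names),
        gene_ids=gene_ids,
        background_size=len(bg),
        nsamples=nsamples,
    )


def filter_attributions(
    phi: AttributionTensor, predictions: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Keep correctly-predicted samples and their true-class slice only.

    Returns (gene x kept-sample matrix, kept-sample mask).  Classes left
    with no correct prediction are warned about — they silently vanish from
    any per-class downstream summary.
    """
    predictions = np.asarray(predictions, dtype=object)
    labels = np.asarray(labels, dtype=object)
    if len(predictions) != phi.values.shape[0] or len(labels) != phi.values.shape[0]:
        raise ValueError("predictions/labels must align with the sample axis")
    correct = predictions == labels
    if not correct.any():
        raise ValueError("no correctly predicted samples; nothing to attribute")
    lut = {name: i for i, name in enumerate(phi.class_names)}
    kept = np.flatnonzero(correct)
    out = np.empty((len(phi.gene_ids), len(kept)))
    for j, s in enumerate(kept):
        out[:, j] = phi.values[s, lut[labels[s]], :]
    lost = sorted(set(labels.tolist()) - set(labels[correct].tolist()))
    if lost:
        warnings.warn(f"classes with zero correct predictions: {lost}", stacklevel=2)
    return out, correct


def median_rank_genes(
    filtered: np.ndarray, labels: np.ndarray, gene_ids: np.ndarray
) -> RankedGeneTable:
    """Per class: median attribution per gene, ranked largest-first.

    ``filtered`` is the gene x sample matrix from ``filter_attributions``;
    ``labels`` are the kept samples' true classes.
    """
    labels = np.asarray(labels, dtype=object)
    if filtered.shape[1] != len(labels):
        raise ValueError("labels must align with the kept-sample axis")
    gene_ids = np.asarray(gene_ids, dtype=object)
    classes = sorted(set(labels.tolist()))
    genes: dict[str, np.ndarray] = {}
    medians: dict[str, np.ndarray] = {}
    for cls in classes:
        med = np.median(filtered[:, labels == cls], axis=1)
        # Descending median, ties broken by ascending gene id (lexsort keys
        # are applied last-key-primary).
        order = np.lexsort((gene_ids.astype(str), -med))
        genes[cls] = gene_ids[order]
        medians[cls] = med[order]
    return RankedGeneTable(class_names=classes, genes=genes, medians=medians)


def uniqueness_curve(table: RankedGeneTable, depths: list[int]) -> pd.DataFrame:
    """Slot / unique / exclusive accounting of top-n lists across classes.

    For each depth d: ``slots = n_classes * d``; ``unique`` counts distinct
    genes across all lists (a gene in several lists counts once);
    ``exclusive`` counts genes present in exactly one class's list.
    """
    rows = []
    for depth in depths:
        if depth < 1:
            raise ValueError("depths must be >= 1")
        if depth > table.n_genes:
            raise ValueError(f"depth {depth} exceeds gene count {table.n_genes}")
        tops = {cls: table.top(cls, depth) for cls in table.class_names}
        slots = depth * len(table.class_names)
        seen: dict[str, int] = {}
        for genes in tops.values():
            for g in genes:
                seen[g] = seen.get(g, 0) + 1
        unique = len(seen)
        exclusive = sum(1 for v in seen.values() if v == 1)
        rows.append(
            (depth, slots, unique, unique / slots, exclusive, exclusive / slots)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "depth",
            "slots",
            "unique",
            "unique_fraction",
            "exclusive",
            "exclusive_fraction",
        ],
    )


def select_top_genes(
    table: RankedGeneTable, depth: int
) -> tuple[dict[str, list[str]], set[str]]:
    """Per-class top-``depth`` lists and their deduplicated union."""
    if depth < 1 or depth > table.n_genes:
        raise ValueError(f"depth {depth} out of range")
    per_class = {cls: table.top(cls, depth) for cls in table.class_names}
    union = set(g for genes in per_class.values() for g in genes)
    return per_class, union


def depth_at_unique_fraction(
    table: RankedGeneTable, target: float = 0.5, max_depth: int | None = None
) -> int | None:
    """Smallest depth whose cross-class unique fraction first drops to ``target``.

    Returns None when no depth up to ``max_depth`` (default: all genes)
    reaches the target — reported as unreachable rather than raising.
    """
    limit = table.n_genes if max_depth is None else min(max_depth, table.n_genes)
    for depth in range(1, limit + 1):
        frac = uniqueness_curve(table, [depth])["unique_fraction"].iloc[0]
        if frac <= target:
            return depth
    return None


def cohort_overlap(
    table_a: RankedGeneTable, table_b: RankedGeneTable, depth: int
) -> tuple[dict[str, int], float]:
    """|top-depth(A) ∩ top-depth(B)| per shared class, plus the median.

    The class sets must match; classes of B are allowed to be a subset of A
    (an independent cohort may cover fewer classes), but names present in B
    and absent from A are an error.
    """
    extra = sorted(set(table_b.class_names) - set(table_a.class_names))
    if extra:
        raise ValueError(f"classes absent from the reference table: {extra}")
    overlaps = {
        cls: len(set(table_a.top(cls, depth)) & set(table_b.top(cls, depth)))
        for cls in table_b.class_names
    }
    return overlaps, float(np.median(list(overlaps.values())))
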