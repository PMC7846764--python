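"""Synthetic multi-class RNA-seq count cohorts with planted class signatures.

Generates negative-binomial gene x sample count matrices in which a known
subset of genes carries class-specific expression shifts (the "signatures").
The ground truth is returned alongside the counts so that every downstream
stage — filtering, normalization, classification, attribution, differential
expression, cluster evaluation — can be scored against what was planted.

The generative model is deliberately simple but faithful to bulk RNA-seq:

* per-gene baseline means are log-normal across genes,
* counts are NB with variance ``mu + alpha * mu**2``,
* each sample carries a log-normal library-size factor,
* a signature gene's mean is multiplied by ``2**lfc`` in its owning
  class(es); lfc may be negative (down-regulated markers).

"Sibling" class pairs share a configurable set of signature genes, which
makes them mutually confusable for a classifier in the same way closely
related tissue subtypes are.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SignatureTruth",
    "CountMatrix",
    "simulate_cohort",
    "simulate_independent_cohort",
    "default_config",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated cohort.

    ``n_exclusive_per_class`` genes are planted per class and owned by that
    class alone; ``n_shared_signatures`` genes are each owned by a pair of
    classes (sibling pairs first, then arbitrary pairs).  ``subtle_fraction``
    of the planted genes draw their |log2 fold change| from
    ``subtle_lfc_range`` instead of ``strong_lfc_range``; ``down_fraction``
    get a negative sign.
    """

    n_classes: int = 8
    samples_per_class: tuple[int, ...] = (60, 72, 85, 98, 110, 123, 136, 150)
    n_genes: int = 1200
    n_exclusive_per_class: int = 8
    n_shared_signatures: int = 8
    strong_lfc_range: tuple[float, float] = (4.0, 8.0)
    subtle_lfc_range: tuple[float, float] = (1.0, 3.0)
    subtle_fraction: float = 0.125
    down_fraction: float = 0.1
    dispersion: float = 0.05
    libsize_sigma: float = 0.2
    sibling_pairs: tuple[tuple[int, int], ...] = ((0, 1), (2, 3))
    gene_length_range: tuple[int, int] = (300, 10_000)
    cohort_shift_sigma: float = 0.0
    baseline_log2_mean: float = 5.0
    baseline_log2_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if len(self.samples_per_class) != self.n_classes:
            raise ValueError(
                f"samples_per_class has {len(self.samples_per_class)} entries "
                f"for {self.n_classes} classes"
            )
        if any(n <= 0 for n in self.samples_per_class):
            raise ValueError("samples_per_class entries must be positive")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        n_planted = self.n_exclusive_per_class * self.n_classes + self.n_shared_signatures
        if n_planted > self.n_genes:
            raise ValueError(
                f"{n_planted} planted signature genes exceed n_genes={self.n_genes}"
            )
        for name in ("strong_lfc_range", "subtle_lfc_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be positive and ordered, got ({lo}, {hi})")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for a, b in self.sibling_pairs:
            if not (0 <= a < self.n_classes and 0 <= b < self.n_classes and a != b):
                raise ValueError(f"invalid sibling pair ({a}, {b})")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError("gene_length_range must be positive and ordered")


@dataclass
class SignatureTruth:
    """Ground truth of the planted signatures plus the generator parameters.

    ``owners`` holds, per gene, the tuple of owning class indices (empty for
    null genes).  ``lfc`` is the signed planted log2 fold change (0 for null
    genes).  ``tier`` is ``"strong"``, ``"subtle"`` or ``"null"``.  The
    baseline means, dispersion and gene lengths are carried so that
    independent cohorts can be drawn from the same model.
    """

    gene_ids: np.ndarray
    gene_lengths: np.ndarray
    baseline_mean: np.ndarray
    dispersion: float
    class_names: list[str]
    owners: list[tuple[int, ...]]
    lfc: np.ndarray
    exclusive: np.ndarray
    tier: np.ndarray

    def expected_onevsrest_lfc(self, class_sizes: dict[str, int]) -> np.ndarray:
        """Realized one-vs-rest log2 contrast per (class, gene) under the model.

        A gene planted only in class c still carries a non-zero contrast for
        every other class, because the rest-group mean is inflated (or
        depressed) by the owning class; this is the ground truth against
        which one-vs-rest differential expression should be scored.
        Baseline means cancel, so the matrix depends only on owners, lfc
        and the class sizes.
        """
        sizes = np.array([class_sizes[c] for c in self.class_names], dtype=float)
        n_classes = len(self.class_names)
        n_genes = len(self.gene_ids)
        rel = np.ones((n_classes, n_genes))  # per-class relative mean
        for g, own in enumerate(self.owners):
            for c in own:
                rel[c, g] = 2.0 ** self.lfc[g]
        out = np.empty((n_classes, n_genes))
        total = sizes.sum()
        for c in range(n_classes):
            rest = (sizes[:, None] * rel).sum(axis=0) - sizes[c] * rel[c]
            rest /= total - sizes[c]
            out[c] = np.log2(rel[c] / rest)
        return out

    def signature_genes(self, class_idx: int) -> list[str]:
        """Gene ids planted for ``class_idx`` (exclusive and shared)."""
        return [
            str(g)
            for g, own in zip(self.gene_ids, self.owners)
            if class_idx in own
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "owners": [";".join(map(str, o)) for o in self.owners],
                "lfc": self.lfc,
                "exclusive": self.exclusive,
                "tier": self.tier,
                "baseline_mean": self.baseline_mean,
                "gene_length": self.gene_lengths,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class CountMatrix:
    """Integer gene x sample read counts with per-sample class labels."""

    counts: np.ndarray  # (n_genes, n_samples) non-negative ints
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    gene_lengths: np.ndarray
    labels: np.ndarray  # class name per sample

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.gene_lengths = np.asarray(self.gene_lengths)
        self.labels = np.asarray(self.labels, dtype=object)
        g, s = self.counts.shape
        if len(self.gene_ids) != g:
            raise ValueError("gene_ids length does not match count rows")
        if len(self.sample_ids) != s or len(self.labels) != s:
            raise ValueError("sample_ids/labels length does not match count columns")
        if len(self.gene_lengths) != g:
            raise ValueError("gene_lengths length does not match count rows")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != s:
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.counts.astype(float))):
            raise ValueError("counts must be finite")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be positive")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts[mask],
            gene_ids=self.gene_ids[mask],
            sample_ids=self.sample_ids,
            gene_lengths=self.gene_lengths[mask],
            labels=self.labels,
        )

    def write_tsv(self, path: str | Path) -> None:
        """Counts as TSV: genes as rows, first column ``gene_id``."""
        df = pd.DataFrame(self.counts, index=pd.Index(self.gene_ids, name="gene_id"),
                          columns=list(self.sample_ids))
        df.to_csv(path, sep="\t")

    def write_labels_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"sample_id": self.sample_ids, "class": self.labels}).to_csv(
            path, sep="\t", index=False
        )

    def write_gct(self, path: str | Path) -> None:
        """GCT 1.2: ``#1.2`` header, dims line, Name/Description columns."""
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{self.n_genes}\t{self.n_samples}\n")
            fh.write("Name\tDescription\t" + "\t".join(map(str, self.sample_ids)) + "\n")
            for i in range(self.n_genes):
                row = "\t".join(str(int(v)) for v in self.counts[i])
                fh.write(f"{self.gene_ids[i]}\t{self.gene_ids[i]}\t{row}\n")


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default desk-scale cohort used throughout the test-suite."""
    return replace(SimulationConfig(seed=seed), **overrides)


def _derive_rngs(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    # One child stream per stochastic sub-step, all derived from the single
    # config seed via SeedSequence.spawn — adding a step never perturbs others.
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _plant_signatures(config: SimulationConfig, rng: np.random.Generator) -> SignatureTruth:
    n_genes = config.n_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(n_genes)], dtype=object)
    gene_lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, size=n_genes
    )
    baseline = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sigma, n_genes)

    owners: list[tuple[int, ...]] = [() for _ in range(n_genes)]
    lfc = np.zeros(n_genes)
    tier = np.array(["null"] * n_genes, dtype=object)

    n_excl = config.n_exclusive_per_class * config.n_classes
    n_planted = n_excl + config.n_shared_signatures
    planted_idx = rng.choice(n_genes, size=n_planted, replace=False)
    excl_idx = planted_idx[:n_excl]
    shared_idx = planted_idx[n_excl:]

    # Owner pairs for shared genes: sibling pairs first (round-robin), then
    # arbitrary distinct pairs if there are more shared genes than siblings.
    pairs: list[tuple[int, int]] = list(config.sibling_pairs)
    if not pairs:
        pairs = [(0, 1 % config.n_classes)]
    shared_owner = [pairs[i % len(pairs)] for i in range(len(shared_idx))]

    def draw_lfc(is_subtle: bool, is_down: bool) -> float:
        lo, hi = config.subtle_lfc_range if is_subtle else config.strong_lfc_range
        mag = rng.uniform(lo, hi)
        return -mag if is_down else mag

    for j, g in enumerate(excl_idx):
        cls = j // config.n_exclusive_per_class
        owners[g] = (cls,)
        is_subtle = rng.random() < config.subtle_fraction
        is_down = rng.random() < config.down_fraction
        lfc[g] = draw_lfc(is_subtle, is_down)
        tier[g] = "subtle" if is_subtle else "strong"

    for g, pair in zip(shared_idx, shared_owner):
        owners[g] = tuple(sorted(pair))
        is_subtle = rng.random() < config.subtle_fraction
        is_down = rng.random() < config.down_fraction
        lfc[g] = draw_lfc(is_subtle, is_down)
        tier[g] = "subtle" if is_subtle else "strong"

    exclusive = np.array([len(o) == 1 for o in owners])
    class_names = [f"class_{c:02d}" for c in range(config.n_classes)]
    return SignatureTruth(
        gene_ids=gene_ids,
        gene_lengths=gene_lengths,
        baseline_mean=baseline,
        dispersion=config.dispersion,
        class_names=class_names,
        owners=owners,
        lfc=lfc,
        exclusive=exclusive,
        tier=tier,
    )


def _draw_counts(
    truth: SignatureTruth,
    class_idx_per_sample: np.ndarray,
    lib_factors: np.ndarray,
    rng: np.random.Generator,
    gene_shift: np.ndarray | None = None,
) -> np.ndarray:
    n_genes = len(truth.gene_ids)
    n_samples = len(class_idx_per_sample)
    log2fc = np.zeros((n_genes, n_samples))
    for g, own in enumerate(truth.owners):
        if not own:
            continue
        member = np.isin(class_idx_per_sample, own)
        log2fc[g, member] = truth.lfc[g]
    mu = truth.baseline_mean[:, None] * (2.0 ** log2fc) * lib_factors[None, :]
    if gene_shift is not None:
        mu = mu * gene_shift[:, None]
    alpha = truth.dispersion
    if alpha <= 0:
        return rng.poisson(mu).astype(np.int64)
    # NB(mean mu, var mu + alpha mu^2): size r = 1/alpha, p = r / (r + mu)
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p).astype(np.int64)


def simulate_cohort(config: SimulationConfig) -> tuple[CountMatrix, SignatureTruth]:
    """Draw a labeled count cohort and the signature truth that generated it.

    Deterministic: the same config (including seed) yields bit-identical
    output.
    """
    rngs = _derive_rngs(config.seed, ["plant", "libsize", "counts"])
    truth = _plant_signatures(config, rngs["plant"])

    class_idx = np.concatenate(
        [np.full(n, c, dtype=np.int64) for c, n in enumerate(config.samples_per_class)]
    )
    n_samples = len(class_idx)
    lib_factors = np.exp(rngs["libsize"].normal(0.0, config.libsize_sigma, n_samples))
    counts = _draw_counts(truth, class_idx, lib_factors, rngs["counts"])

    sample_ids = np.array([f"S{i:05d}" for i in range(n_samples)], dtype=object)
    labels = np.array([truth.class_names[c] for c in class_idx], dtype=object)
    cm = CountMatrix(
        counts=counts,
        gene_ids=truth.gene_ids,
        sample_ids=sample_ids,
        gene_lengths=truth.gene_lengths,
        labels=labels,
    )
    return cm, truth


def simulate_independent_cohort(
    truth: SignatureTruth,
    config: SimulationConfig,
    samples_per_class: dict[str, int] | None = None,
    seed: int | None = None,
) -> CountMatrix:
    """Draw a fresh cohort from an existing signature model.

    Emulates an independently collected validation dataset: new samples, new
    library-size factors and (if ``config.cohort_shift_sigma > 0``) a small
    log-normal per-gene mean shift shared by every sample of the new cohort.
    ``samples_per_class`` may request a subset of the classes in ``truth``.
    """
    if samples_per_class is None:
        samples_per_class = {
            name: n for name, n in zip(truth.class_names, config.samples_per_class)
        }
    unknown = sorted(set(samples_per_class) - set(truth.class_names))
    if unknown:
        raise ValueError(f"classes absent from truth: {unknown}")

    if seed is None:
        seed = config.seed + 1
    rngs = _derive_rngs(seed, ["libsize", "counts", "shift"])

    name_to_idx = {n: i for i, n in enumerate(truth.class_names)}
    class_idx = np.concatenate(
        [
            np.full(n, name_to_idx[name], dtype=np.int64)
            for name, n in samples_per_class.items()
        ]
    )
    n_samples = len(class_idx)
    lib_factors = np.exp(rngs["libsize"].normal(0.0, config.libsize_sigma, n_samples))
    gene_shift = None
    if config.cohort_shift_sigma > 0:
        gene_shift = np.exp(
            rngs["shift"].normal(0.0, config.cohort_shift_sigma, len(truth.gene_ids))
        )
    counts = _draw_counts(truth, class_idx, lib_factors, rngs["counts"], gene_shift)
    sample_ids = np.array([f"V{i:05d}" for i in range(n_samples)], dtype=object)
    labels = np.array([truth.class_names[c] for c in class_idx], dtype=object)
    return CountMatrix(
        counts=counts,
        gene_ids=truth.gene_ids,
        sample_ids=sample_ids,
        gene_lengths=truth.gene_lengths,
        labels=labels,
    )
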