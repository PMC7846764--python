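"""One-vs-rest negative-binomial differential expression with BH control.

The test is the classic conditional NB exact test: counts are adjusted to a
common effective library size (library size x TMM factor), summed within
each group, and the two-sided p-value is the conditional probability — given
the grand total — of all outcomes at most as likely as the observed split.
Group sums of i.i.d. NB(mu, alpha) samples are NB with mean ``n * mu`` and
size ``n / alpha``, which makes the conditional distribution a product of
two NB pmfs and (being log-concave) unimodal; the summation is restricted
to windows around the conditional mode and the observed value, outside of
which the mass is far below double precision.

Dispersion is a pooled method-of-moments estimate (common across genes);
exact numerical parity with any particular external DE package is a
non-goal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .preprocess import TMMFactors
from .simulate import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DETable",
    "estimate_common_dispersion",
    "nb_exact_test",
    "bh_adjust",
    "de_one_vs_rest",
]


@dataclass
class DETable:
    """Long-format per-(class, gene) results with significance flags."""

    table: pd.DataFrame  # columns: class, gene, logFC, pvalue, fdr, significant, direction
    lfc_cut: float
    fdr_cut: float

    def for_class(self, class_name: str) -> pd.DataFrame:
        return self.table[self.table["class"] == class_name].reset_index(drop=True)

    def significant_genes(self, class_name: str) -> set[str]:
        sub = self.for_class(class_name)
        return set(sub.loc[sub["significant"], "gene"])

    def collapsed_significant(self) -> set[str]:
        return set(self.table.loc[self.table["significant"], "gene"])

    def per_class_counts(self) -> pd.DataFrame:
        sig = self.table[self.table["significant"]]
        counts = sig.groupby("class").agg(
            n_significant=("gene", "size"),
            n_up=("direction", lambda d: int((d == "up").sum())),
            n_down=("direction", lambda d: int((d == "down").sum())),
        )
        # Exclusive = significant in exactly one class.
        gene_multiplicity = sig.groupby("gene")["class"].nunique()
        exclusive_genes = set(gene_multiplicity[gene_multiplicity == 1].index)
        counts["n_exclusive"] = [
            int(sum(g in exclusive_genes for g in sig.loc[sig["class"] == c, "gene"]))
            for c in counts.index
        ]
        return counts.reset_index()

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def estimate_common_dispersion(counts: np.ndarray, groups: np.ndarray,
                               lib_sizes: np.ndarray | None = None) -> float:
    """Pooled method-of-moments NB dispersion, floored at 1e-6.

    Counts are first rescaled to the mean library size so that library-size
    variation does not inflate the apparent biological variance; per gene
    and group, ``alpha_g = (var - mean) / mean**2``, pooled as the median
    over sufficiently expressed genes.
    """
    counts = np.asarray(counts, dtype=float)
    groups = np.asarray(groups)
    if counts.sum() == 0:
        raise ValueError("all-zero count matrix")
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    scaled = counts * (lib_sizes.mean() / lib_sizes)[None, :]

    est_num = np.zeros(counts.shape[0])
    est_den = np.zeros(counts.shape[0])
    for g in sorted(set(groups.tolist())):
        sub = scaled[:, groups == g]
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        w = sub.shape[1] - 1
        with np.errstate(invalid="ignore", divide="ignore"):
            a = np.where(m > 0, (v - m) / np.maximum(m, 1e-12) ** 2, np.nan)
        ok = np.isfinite(a) & (m >= 1)
        est_num[ok] += w * a[ok]
        est_den[ok] += w
    per_gene = est_num[est_den > 0] / est_den[est_den > 0]
    if len(per_gene) == 0:
        raise ValueError("no usable genes for dispersion estimation")
    return float(max(np.median(per_gene), 1e-6))


def _log_nb_pmf(a: np.ndarray, mean: float, size: float) -> np.ndarray:
    """log pmf of NB with given mean and size r (Poisson limit for huge r)."""
    a = np.asarray(a, dtype=float)
    if size > 1e12 or not np.isfinite(size):
        return a * np.log(mean) - mean - gammaln(a + 1) if mean > 0 else np.where(a == 0, 0.0, -np.inf)
    logp = np.log(size / (size + mean))
    log1mp = np.log(mean / (size + mean)) if mean > 0 else -np.inf
    return gammaln(a + size) - gammaln(size) - gammaln(a + 1) + size * logp + a * log1mp


def _exact_p_one_gene(a_obs: float, t: float, n1: int, n2: int, alpha: float) -> float:
    """Two-sided conditional exact p for one gene's group-sum split."""
    t = float(round(t))
    a_obs = float(np.clip(round(a_obs), 0, t))
    if t <= 0:
        return 1.0
    mu = t / (n1 + n2)  # per-sample null mean
    mu1, mu2 = n1 * mu, n2 * mu
    size1 = n1 / alpha if alpha > 0 else np.inf
    size2 = n2 / alpha if alpha > 0 else np.inf
    var1 = mu1 * (1 + alpha * mu)
    var2 = mu2 * (1 + alpha * mu)
    # Gaussian approximation of the conditional mode / spread.
    mode = mu1 + var1 / (var1 + var2) * (t - mu1 - mu2)
    sd = max(np.sqrt(var1 * var2 / (var1 + var2)), 2.0)
    half = int(np.ceil(12 * sd))
    lo1, hi1 = max(0, int(mode) - half), min(int(t), int(mode) + half)
    lo2, hi2 = max(0, int(a_obs) - half), min(int(t), int(a_obs) + half)
    support = np.unique(np.concatenate([np.arange(lo1, hi1 + 1), np.arange(lo2, hi2 + 1)]))
    logf = _log_nb_pmf(support, mu1, size1) + _log_nb_pmf(t - support, mu2, size2)
    log_obs = (_log_nb_pmf(np.array([a_obs]), mu1, size1)
               + _log_nb_pmf(np.array([t - a_obs]), mu2, size2))[0]
    thr = log_obs + 1e-9 * abs(log_obs)
    denom = logsumexp(logf)
    keep = logf <= thr
    if not keep.any():
        return 1.0
    num = logsumexp(logf[keep])
    return float(min(1.0, np.exp(num - denom)))


def nb_exact_test(
    group_counts: np.ndarray,
    rest_counts: np.ndarray,
    dispersion: float,
    eff_lib_group: np.ndarray,
    eff_lib_rest: np.ndarray,
) -> np.ndarray:
    """Per-gene two-sided p for group vs rest (rows = genes).

    Counts are linearly adjusted to the geometric-mean effective library
    size before summing within groups.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    group_counts = np.atleast_2d(np.asarray(group_counts, dtype=float))
    rest_counts = np.atleast_2d(np.asarray(rest_counts, dtype=float))
    n1, n2 = group_counts.shape[1], rest_counts.shape[1]
    all_lib = np.concatenate([eff_lib_group, eff_lib_rest]).astype(float)
    common = np.exp(np.mean(np.log(all_lib)))
    adj1 = group_counts * (common / np.asarray(eff_lib_group, dtype=float))[None, :]
    adj2 = rest_counts * (common / np.asarray(eff_lib_rest, dtype=float))[None, :]
    sums1 = adj1.sum(axis=1)
    sums2 = adj2.sum(axis=1)
    p = np.empty(group_counts.shape[0])
    for g in range(group_counts.shape[0]):
        p[g] = _exact_p_one_gene(sums1[g], sums1[g] + sums2[g], n1, n2, dispersion)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def de_one_vs_rest(
    counts: CountMatrix,
    tmm: TMMFactors,
    lfc_cut: float = 4.0,
    fdr_cut: float = 0.01,
    dispersion: float | None = None,
) -> DETable:
    """Exact-test DE of every class against all remaining samples.

    logFC is the log2 ratio of mean library-size-adjusted counts with a
    prior count of 0.5 on each side; BH adjustment is applied within each
    class; a gene is significant when ``|logFC| > lfc_cut`` and
    ``FDR < fdr_cut``.
    """
    labels = counts.labels
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("de_one_vs_rest requires >= 2 classes")
    eff = tmm.effective_library_sizes
    if dispersion is None:
        dispersion = estimate_common_dispersion(counts.counts, labels, eff)
        logger.info("common dispersion estimate: %.4g", dispersion)

    common = np.exp(np.mean(np.log(eff)))
    adj = counts.counts * (common / eff)[None, :]

    rows = []
    for cls in classes:
        in_group = labels == cls
        if in_group.sum() < 2:
            warnings.warn(f"class {cls!r} has < 2 samples; skipped", stacklevel=2)
            continue
        m1 = adj[:, in_group].mean(axis=1)
        m2 = adj[:, ~in_group].mean(axis=1)
        logfc = np.log2((m1 + 0.5) / (m2 + 0.5))
        pvals = nb_exact_test(
            counts.counts[:, in_group],
            counts.counts[:, ~in_group],
            dispersion,
            eff[in_group],
            eff[~in_group],
        )
        fdr = bh_adjust(pvals)
        significant = (np.abs(logfc) > lfc_cut) & (fdr < fdr_cut)
        direction = np.where(
            significant, np.where(logfc > 0, "up", "down"), "ns"
        )
        for g in range(counts.n_genes):
            rows.append(
                (cls, counts.gene_ids[g], logfc[g], pvals[g], fdr[g],
                 bool(significant[g]), direction[g])
            )
    table = pd.DataFrame(
        rows, columns=["class", "gene", "logFC", "pvalue", "fdr", "significant", "direction"]
    )
    return DETable(table=table, lfc_cut=lfc_cut, fdr_cut=fdr_cut)
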