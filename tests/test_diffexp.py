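"""Tests for dispersion estimation, the NB exact test and BH adjustment."""

import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import kstest

from tissuesig.diffexp import (
    bh_adjust,
    de_one_vs_rest,
    estimate_common_dispersion,
    nb_exact_test,
)
from tissuesig.preprocess import tmm_factors
from tissuesig.simulate import CountMatrix


def _cm(counts, labels):
    counts = np.asarray(counts)
    g, s = counts.shape
    return CountMatrix(
        counts=counts,
        gene_ids=np.array([f"g{i}" for i in range(g)], dtype=object),
        sample_ids=np.array([f"s{i}" for i in range(s)], dtype=object),
        gene_lengths=np.full(g, 1000),
        labels=np.asarray(labels, dtype=object),
    )


class TestDispersion:
    def test_poisson_counts_near_zero(self):
        rng = np.random.default_rng(0)
        mu = rng.uniform(20, 200, 300)
        counts = rng.poisson(mu[:, None], (300, 60))
        groups = np.array(["a"] * 30 + ["b"] * 30)
        est = estimate_common_dispersion(counts, groups, np.full(60, 1.0))
        assert est < 0.01

    def test_nb_alpha_point_two_recovered(self):
        rng = np.random.default_rng(1)
        alpha = 0.2
        mu = rng.uniform(30, 300, 200)
        r = 1 / alpha
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p[:, None], (200, 40))
        groups = np.array(["a"] * 20 + ["b"] * 20)
        est = estimate_common_dispersion(counts, groups, np.full(40, 1.0))
        assert est == pytest.approx(alpha, rel=0.25)

    def test_duplicated_samples_near_zero(self):
        rng = np.random.default_rng(2)
        col = rng.integers(10, 100, 100)
        counts = np.tile(col[:, None], (1, 10))
        groups = np.array(["a"] * 5 + ["b"] * 5)
        est = estimate_common_dispersion(counts, groups, np.full(10, 1.0))
        assert est <= 1e-4

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            estimate_common_dispersion(np.zeros((5, 4)), np.array(["a", "a", "b", "b"]))


def _conditional_exact_oracle(a_obs, t, n1, n2):
    """Small-count Poisson-limit oracle: conditional on the total, the group
    sum is Binomial(t, n1/(n1+n2)); two-sided p sums outcomes no more likely
    than the observed one.  Pure enumeration, independent of the package."""
    from scipy.stats import binom

    q = n1 / (n1 + n2)
    support = np.arange(0, t + 1)
    pmf = binom.pmf(support, t, q)
    return pmf[pmf <= pmf[int(a_obs)] * (1 + 1e-9)].sum()


class TestExactTest:
    def test_identical_groups_p_near_one(self):
        rng = np.random.default_rng(3)
        base = rng.integers(50, 150, (20, 8))
        p = nb_exact_test(base, base.copy(), 0.05, np.full(8, 1e4), np.full(8, 1e4))
        assert (p > 0.5).all()

    def test_poisson_limit_matches_binomial_oracle(self):
        # dispersion -> 0, equal library sizes: the conditional distribution
        # is exactly binomial; enumerate it for small totals.
        rng = np.random.default_rng(4)
        n1, n2 = 3, 5
        for _ in range(20):
            g1 = rng.integers(0, 12, n1)
            g2 = rng.integers(0, 12, n2)
            t = g1.sum() + g2.sum()
            if t == 0:
                continue
            p_pkg = nb_exact_test(
                g1[None, :], g2[None, :], 0.0, np.full(n1, 1e4), np.full(n2, 1e4)
            )[0]
            p_oracle = _conditional_exact_oracle(g1.sum(), t, n1, n2)
            assert p_pkg == pytest.approx(p_oracle, rel=1e-6, abs=1e-12)

    def test_planted_32_fold_gene_tiny_p(self):
        rng = np.random.default_rng(5)
        mu = 100.0
        r = 1 / 0.1
        g1 = rng.negative_binomial(r, r / (r + mu * 32), 20)
        g2 = rng.negative_binomial(r, r / (r + mu), 40)
        p = nb_exact_test(
            g1[None, :], g2[None, :], 0.1, np.full(20, 1e5), np.full(40, 1e5)
        )[0]
        assert p < 1e-6

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(6)
        g1 = rng.integers(10, 80, (15, 6))
        g2 = rng.integers(10, 80, (15, 10))
        l1, l2 = np.full(6, 2e4), np.full(10, 2e4)
        p12 = nb_exact_test(g1, g2, 0.08, l1, l2)
        p21 = nb_exact_test(g2, g1, 0.08, l2, l1)
        assert np.allclose(p12, p21, rtol=1e-6)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test(np.ones((1, 2)), np.ones((1, 2)), -0.1,
                          np.ones(2), np.ones(2))

    def test_null_p_roughly_uniform(self):
        # KS at coarse tolerance on NB null data (discreteness makes exact
        # uniformity unattainable, so alpha is generous).
        rng = np.random.default_rng(7)
        alpha = 0.05
        mu = rng.uniform(50, 500, 400)
        r = 1 / alpha
        counts = rng.negative_binomial(r, (r / (r + mu))[:, None], (400, 30))
        p = nb_exact_test(
            counts[:, :15], counts[:, 15:], alpha,
            np.full(15, 1.0), np.full(15, 1.0),
        )
        stat = kstest(p, "uniform")
        assert stat.statistic < 0.12


class TestBH:
    def test_hand_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(bh_adjust(p), 0.04)

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        p = rng.uniform(size=200)
        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)

    def test_order_preserved(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_fdr_at_least_p(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(size=100)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))


class TestOneVsRest:
    def test_strong_signatures_significant_with_direction(
        self, de_result, trained_pipeline
    ):
        truth = trained_pipeline["truth"]
        filtered = trained_pipeline["filtered"]
        kept = set(map(str, filtered.gene_ids))
        # Exclusive genes only: a sibling-shared gene's one-vs-rest contrast
        # is diluted by the co-owning class in the rest group, so its
        # realized logFC sits below the planted |lfc| by construction.
        hits = total = 0
        for g, gid in enumerate(truth.gene_ids):
            if truth.tier[g] != "strong" or abs(truth.lfc[g]) <= 4 or str(gid) not in kept:
                continue
            if not truth.exclusive[g]:
                continue
            cls = truth.class_names[truth.owners[g][0]]
            sub = de_result.for_class(cls)
            row = sub[sub["gene"] == gid]
            total += 1
            want = "up" if truth.lfc[g] > 0 else "down"
            if len(row) and bool(row["significant"].iloc[0]) and row["direction"].iloc[0] == want:
                hits += 1
        assert total >= 20
        assert hits / total >= 0.9

    def test_subtle_signatures_pass_fdr_fail_lfc(self, de_result, trained_pipeline):
        # The "attribution-only" regime: genes with planted |lfc| in 1..3
        # clear the FDR filter but not the fold-change filter.
        truth = trained_pipeline["truth"]
        kept = set(map(str, trained_pipeline["filtered"].gene_ids))
        pass_fdr = fail_lfc = total = 0
        for g, gid in enumerate(truth.gene_ids):
            if truth.tier[g] != "subtle" or str(gid) not in kept:
                continue
            cls = truth.class_names[truth.owners[g][0]]
            sub = de_result.for_class(cls)
            row = sub[sub["gene"] == gid]
            if not len(row):
                continue
            total += 1
            if row["fdr"].iloc[0] < de_result.fdr_cut:
                pass_fdr += 1
                if abs(row["logFC"].iloc[0]) <= de_result.lfc_cut:
                    fail_lfc += 1
        assert total >= 5
        assert pass_fdr / total >= 0.8
        assert fail_lfc >= 1

    def test_false_discovery_proportion(self, de_result, trained_pipeline):
        # Truth = the realized one-vs-rest contrast of the generative model
        # (a strongly up-regulated gene is genuinely down in every other
        # class's comparison); calls in the ambiguity band around the cutoff
        # are excluded.
        truth = trained_pipeline["truth"]
        filtered = trained_pipeline["filtered"]
        class_sizes = {c: int((filtered.labels == c).sum()) for c in truth.class_names}
        contrast = truth.expected_onevsrest_lfc(class_sizes)
        gene_pos = {str(g): i for i, g in enumerate(truth.gene_ids)}
        false = total_sig = 0
        for ci, cls in enumerate(truth.class_names):
            for gid in de_result.significant_genes(cls):
                t_lfc = abs(contrast[ci, gene_pos[gid]])
                if 3.7 < t_lfc < 4.3:
                    continue
                total_sig += 1
                if t_lfc <= 3.7:
                    false += 1
        assert total_sig > 0
        assert false / total_sig <= 0.05

    def test_expected_onevsrest_contrast_oracle(self, trained_pipeline):
        # Sanity: for an exclusive gene, the realized contrast in the owning
        # class nearly equals the planted lfc, and the off-class contrast
        # has the opposite sign (rest-mean dilution).
        truth = trained_pipeline["truth"]
        filtered = trained_pipeline["filtered"]
        class_sizes = {c: int((filtered.labels == c).sum()) for c in truth.class_names}
        contrast = truth.expected_onevsrest_lfc(class_sizes)
        checked = 0
        for g in range(len(truth.gene_ids)):
            if not truth.exclusive[g] or truth.tier[g] != "strong":
                continue
            ci = truth.owners[g][0]
            assert contrast[ci, g] == pytest.approx(truth.lfc[g], abs=0.6)
            other = (ci + 1) % len(truth.class_names)
            assert np.sign(contrast[other, g]) == -np.sign(truth.lfc[g])
            checked += 1
        assert checked >= 20

    def test_permuted_labels_controls_discoveries(self, trained_pipeline):
        filtered = trained_pipeline["filtered"]
        tmm = trained_pipeline["tmm"]
        rng = np.random.default_rng(0)
        shuffled = CountMatrix(
            counts=filtered.counts,
            gene_ids=filtered.gene_ids,
            sample_ids=filtered.sample_ids,
            gene_lengths=filtered.gene_lengths,
            labels=rng.permutation(filtered.labels),
        )
        de = de_one_vs_rest(shuffled, tmm)
        n_classes = len(set(shuffled.labels.tolist()))
        n_sig = int(de.table["significant"].sum())
        assert n_sig <= de.fdr_cut * filtered.n_genes * n_classes + 2

    def test_single_class_rejected(self):
        cm = _cm(np.ones((3, 4), dtype=int), ["a"] * 4)
        with pytest.raises(ValueError):
            de_one_vs_rest(cm, tmm_factors(cm))

    def test_tiny_class_skipped_with_warning(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(10, 100, (10, 7))
        cm = _cm(counts, ["a"] * 3 + ["b"] * 3 + ["c"])
        with pytest.warns(UserWarning, match="'c'"):
            de = de_one_vs_rest(cm, tmm_factors(cm), dispersion=0.1)
        assert set(de.table["class"]) == {"a", "b"}
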