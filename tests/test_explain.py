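"""Tests for expected gradients and the ranked-gene analysis.

The attribution oracles are independent of the implementation path: a
closed form for linear models, and a dense-grid Riemann sum (integrated
gradients) for a single-baseline nonlinear model.
"""

import numpy as np
import pytest

from tissuesig._nn import Linear, Sequential, softmax
from tissuesig.explain import (
    AttributionTensor,
    RankedGeneTable,
    cohort_overlap,
    depth_at_unique_fraction,
    expected_gradients,
    filter_attributions,
    median_rank_genes,
    select_top_genes,
    uniqueness_curve,
)


def _linear_model(W, b=None):
    rng = np.random.default_rng(0)
    layer = Linear(W.shape[1], W.shape[0], rng)
    layer.W[...] = W.astype(np.float32)
    layer.b[...] = 0 if b is None else b.astype(np.float32)
    return Sequential([layer])


class TestExpectedGradients:
    def test_constant_model_zero_attribution(self):
        model = _linear_model(np.zeros((3, 5)), np.array([1.0, 2.0, 3.0]))
        x = np.random.default_rng(0).normal(size=5)
        bg = np.random.default_rng(1).normal(size=(20, 5))
        phi = expected_gradients(model, x, bg, nsamples=50, seed=0)
        assert np.allclose(phi, 0.0, atol=1e-7)

    def test_linear_closed_form(self):
        # For f(x) = Wx explained on logits, phi_j -> w_j (x_j - mean(b_j)).
        rng = np.random.default_rng(2)
        W = rng.normal(size=(2, 6))
        model = _linear_model(W)
        x = rng.normal(size=6)
        bg = rng.normal(size=(40, 6))
        phi = expected_gradients(model, x, bg, nsamples=2000, seed=3, output="logits")
        expected = W * (x - bg.mean(axis=0))[None, :]
        assert np.allclose(phi, expected, rtol=0.05, atol=0.02)

    def test_single_baseline_matches_integrated_gradients_oracle(self):
        # Nonlinear model, single baseline: expected gradients reduces to
        # integrated gradients, evaluated here as a dense Riemann sum.
        rng = np.random.default_rng(4)
        model = Sequential([Linear(4, 8, rng)])
        # add a ReLU-like nonlinearity via a second layer on positive parts
        from tissuesig._nn import ReLU

        model = Sequential([Linear(4, 8, rng), ReLU(), Linear(8, 3, rng)])
        x = rng.normal(size=4).astype(np.float32)
        b = rng.normal(size=4).astype(np.float32)
        phi = expected_gradients(
            model, x, b[None], nsamples=4000, seed=5, output="logits"
        )
        # Oracle: Riemann sum over a dense u-grid with the same baseline.
        grid = (np.arange(4000) + 0.5) / 4000
        pts = b[None] + grid[:, None] * (x - b)[None]
        riemann = np.zeros((3, 4))
        for c in range(3):
            seed_vec = np.zeros((len(pts), 3), dtype=np.float32)
            seed_vec[:, c] = 1.0
            model.forward(pts.astype(np.float32))
            model.zero_grad()
            g = model.backward(seed_vec)
            riemann[c] = g.mean(axis=0) * (x - b)
        scale = np.abs(riemann).max()
        assert np.all(np.abs(phi - riemann) <= 0.01 * scale + 1e-6)

    def test_completeness_linear_softmax(self):
        # Sum of attributions equals f(x) - E[f(b)] for the explained output.
        rng = np.random.default_rng(6)
        W = rng.normal(size=(3, 5)) * 0.5
        model = _linear_model(W)
        x = rng.normal(size=5)
        bg = rng.normal(size=(30, 5))
        phi = expected_gradients(model, x, bg, nsamples=3000, seed=7, output="proba")
        p_x = softmax(model.forward(x[None].astype(np.float32)))[0]
        p_b = softmax(model.forward(bg.astype(np.float32))).mean(axis=0)
        for c in range(3):
            assert phi[c].sum() == pytest.approx(p_x[c] - p_b[c], abs=0.02)

    def test_empty_background_rejected(self):
        model = _linear_model(np.ones((2, 3)))
        with pytest.raises(ValueError, match="background"):
            expected_gradients(model, np.zeros(3), np.empty((0, 3)), nsamples=5)

    def test_deterministic_given_seed(self):
        model = _linear_model(np.random.default_rng(0).normal(size=(2, 4)))
        x = np.ones(4)
        bg = np.random.default_rng(1).normal(size=(10, 4))
        a = expected_gradients(model, x, bg, nsamples=20, seed=42)
        b = expected_gradients(model, x, bg, nsamples=20, seed=42)
        assert np.array_equal(a, b)


def _phi(values, classes, genes):
    n, c, g = values.shape
    return AttributionTensor(
        values=values,
        sample_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
        class_names=classes,
        gene_ids=np.array(genes, dtype=object),
        background_size=1,
        nsamples=1,
    )


class TestFilterAttributions:
    def test_all_correct_one_value_per_gene_per_sample(self):
        values = np.arange(2 * 2 * 3, dtype=float).reshape(2, 2, 3)
        phi = _phi(values, ["a", "b"], ["g0", "g1", "g2"])
        labels = np.array(["a", "b"], dtype=object)
        out, kept = filter_attributions(phi, labels, labels)
        assert out.shape == (3, 2)
        assert np.array_equal(out[:, 0], values[0, 0])
        assert np.array_equal(out[:, 1], values[1, 1])

    def test_misclassified_sample_dropped(self):
        values = np.ones((3, 2, 2))
        phi = _phi(values, ["a", "b"], ["g0", "g1"])
        labels = np.array(["a", "a", "b"], dtype=object)
        preds = np.array(["a", "b", "b"], dtype=object)
        out, kept = filter_attributions(phi, preds, labels)
        assert out.shape == (2, 2)
        assert kept.tolist() == [True, False, True]

    def test_no_correct_samples_raises(self):
        phi = _phi(np.ones((2, 2, 2)), ["a", "b"], ["g0", "g1"])
        labels = np.array(["a", "a"], dtype=object)
        preds = np.array(["b", "b"], dtype=object)
        with pytest.raises(ValueError, match="no correctly predicted"):
            filter_attributions(phi, preds, labels)

    def test_class_without_correct_predictions_warns(self):
        phi = _phi(np.ones((3, 2, 2)), ["a", "b"], ["g0", "g1"])
        labels = np.array(["a", "b", "b"], dtype=object)
        preds = np.array(["a", "a", "a"], dtype=object)
        with pytest.warns(UserWarning, match="zero correct"):
            filter_attributions(phi, preds, labels)


class TestMedianRank:
    def test_single_sample_median_is_value(self):
        filtered = np.array([[3.0], [1.0]])
        t = median_rank_genes(filtered, np.array(["a"], dtype=object), ["g0", "g1"])
        assert t.top("a", 2) == ["g0", "g1"]
        assert t.medians["a"].tolist() == [3.0, 1.0]

    def test_tie_broken_by_gene_id(self):
        # gene values {1,3} and {2,2}: both medians 2 -> order by gene id.
        filtered = np.array([[1.0, 3.0], [2.0, 2.0]])
        labels = np.array(["a", "a"], dtype=object)
        t = median_rank_genes(filtered, labels, ["gB", "gA"])
        assert t.top("a", 2) == ["gA", "gB"]

    def test_sample_permutation_invariant(self):
        rng = np.random.default_rng(0)
        filtered = rng.normal(size=(5, 8))
        labels = np.array(["a"] * 4 + ["b"] * 4, dtype=object)
        t1 = median_rank_genes(filtered, labels, [f"g{i}" for i in range(5)])
        perm = rng.permutation(8)
        t2 = median_rank_genes(filtered[:, perm], labels[perm], [f"g{i}" for i in range(5)])
        for cls in "ab":
            assert t1.top(cls, 5) == t2.top(cls, 5)

    def test_medians_non_increasing(self):
        rng = np.random.default_rng(1)
        filtered = rng.normal(size=(20, 6))
        labels = np.array(["a"] * 3 + ["b"] * 3, dtype=object)
        t = median_rank_genes(filtered, labels, [f"g{i}" for i in range(20)])
        for cls in "ab":
            med = t.medians[cls]
            assert (np.diff(med) <= 1e-12).all()


def _table(lists: dict[str, list[str]]) -> RankedGeneTable:
    n = len(next(iter(lists.values())))
    return RankedGeneTable(
        class_names=sorted(lists),
        genes={c: np.array(g, dtype=object) for c, g in lists.items()},
        medians={c: np.arange(n, 0, -1, dtype=float) for c in lists},
    )


class TestUniquenessCurve:
    def test_forty_seven_by_103_slots(self):
        genes = [f"g{i}" for i in range(150)]
        t = _table({f"c{k}": genes for k in range(47)})
        curve = uniqueness_curve(t, [103])
        assert int(curve["slots"].iloc[0]) == 4841

    def test_all_distinct_depth_one(self):
        t = _table({"a": ["g1", "g2"], "b": ["g3", "g4"]})
        curve = uniqueness_curve(t, [1])
        assert curve["unique_fraction"].iloc[0] == 1.0
        assert curve["exclusive_fraction"].iloc[0] == 1.0

    def test_shared_gene_enumeration(self):
        # 2 classes depth 2 sharing one gene: 4 slots, 3 unique, 2 exclusive.
        t = _table({"a": ["g1", "gS"], "b": ["gS", "g2"]})
        curve = uniqueness_curve(t, [2])
        row = curve.iloc[0]
        assert (row["slots"], row["unique"], row["exclusive"]) == (4, 3, 2)

    def test_depth_beyond_genes_rejected(self):
        t = _table({"a": ["g1"], "b": ["g2"]})
        with pytest.raises(ValueError, match="depth"):
            uniqueness_curve(t, [2])

    def test_unique_fraction_non_increasing_on_nested_fixture(self):
        # Construct nested lists whose overlap grows with depth.
        t = _table({
            "a": ["a1", "s1", "s2", "s3"],
            "b": ["b1", "s1", "s2", "s3"],
            "c": ["c1", "s1", "s2", "s3"],
        })
        curve = uniqueness_curve(t, [1, 2, 3, 4])
        fracs = curve["unique_fraction"].tolist()
        assert all(x >= y for x, y in zip(fracs, fracs[1:]))


class TestSelectTopGenes:
    def test_union_bound_depth_one(self):
        t = _table({"a": ["g1"], "b": ["g1"]})
        _, union = select_top_genes(t, 1)
        assert len(union) <= 2

    def test_union_contains_exclusives(self):
        t = _table({"a": ["g1", "gS"], "b": ["gS", "g2"]})
        per_class, union = select_top_genes(t, 2)
        assert {"g1", "g2"} <= union

    def test_depth_rule_constructed_fixture(self):
        # Unique fraction: depth1 -> 2/2=1, depth2 -> 3/4=0.75, depth3 -> 3/6=0.5.
        t = _table({"a": ["g1", "s1", "s2"], "b": ["s2", "s1", "g1"]})
        assert depth_at_unique_fraction(t, 0.5) == 3

    def test_depth_rule_unreachable(self):
        t = _table({"a": ["g1", "g2"], "b": ["g3", "g4"]})
        assert depth_at_unique_fraction(t, 0.4) is None


class TestCohortOverlap:
    def test_identical_tables(self):
        t = _table({"a": ["g1", "g2"], "b": ["g3", "g4"]})
        overlaps, med = cohort_overlap(t, t, 2)
        assert overlaps == {"a": 2, "b": 2}
        assert med == 2

    def test_disjoint_tables(self):
        t1 = _table({"a": ["g1", "g2"]})
        t2 = _table({"a": ["g3", "g4"]})
        overlaps, med = cohort_overlap(t1, t2, 2)
        assert overlaps == {"a": 0}

    def test_unmatched_classes_listed(self):
        t1 = _table({"a": ["g1"]})
        t2 = _table({"zz": ["g1"]})
        with pytest.raises(ValueError, match="zz"):
            cohort_overlap(t1, t2, 1)

    def test_two_cohorts_beat_hypergeometric_chance(self, trained_pipeline):
        # An independent cohort from the same truth should agree with the
        # original far better than random draws of the same list size.
        from scipy.stats import hypergeom

        from tissuesig import classifier as clf
        from tissuesig import explain as ex
        from tissuesig import preprocess as pp
        from tissuesig.simulate import default_config, simulate_independent_cohort

        truth = trained_pipeline["truth"]
        cfg = default_config(seed=1)
        vc = simulate_independent_cohort(
            truth, cfg, {c: 12 for c in truth.class_names}, seed=99
        )
        model = trained_pipeline["model"]
        dataset = trained_pipeline["dataset"]
        filtered = trained_pipeline["filtered"]
        tmm2 = pp.tmm_factors(vc.subset_genes(
            np.isin(vc.gene_ids, filtered.gene_ids)))
        vc_f = vc.subset_genes(np.isin(vc.gene_ids, filtered.gene_ids))
        split2 = np.array(["test"] * vc_f.n_samples, dtype=object)
        ds2 = pp.build_dataset(vc_f, tmm2, split2)
        phi2 = ex.attribute_dataset(
            model, ds2, trained_pipeline["train_ds"].images,
            nsamples=20, seed=123,
        )
        pred2 = clf.predict(model, ds2.images, dataset.class_names)
        filt2, correct2 = ex.filter_attributions(phi2, pred2, ds2.labels)
        ranked2 = ex.median_rank_genes(filt2, ds2.labels[correct2], phi2.gene_ids)
        depth = 10
        overlaps, med = cohort_overlap(trained_pipeline["ranked"], ranked2, depth)
        n_genes = len(phi2.gene_ids)
        chance = hypergeom.mean(n_genes, depth, depth)  # ~ depth^2 / n_genes
        assert med > 5 * chance
        assert med >= 3


# Completeness and signature-recovery assertions on the trained model live
# in tests/test_acceptance.py (criteria 2 and 4).
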