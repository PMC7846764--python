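"""Shared fixtures.

The trained-pipeline fixture is expensive (a few minutes of CPU) and is
therefore session-scoped and shared between the classifier, attribution and
acceptance tests; everything else uses small, fast cohorts generated on the
fly.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from tissuesig import balance as bal
from tissuesig import classifier as clf
from tissuesig import explain as ex
from tissuesig import preprocess as pp
from tissuesig.simulate import SimulationConfig, default_config, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return replace(
        default_config(seed=42),
        n_classes=4,
        samples_per_class=(30, 35, 40, 45),
        n_genes=300,
        n_exclusive_per_class=4,
        n_shared_signatures=4,
        sibling_pairs=((0, 1),),
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(default_config(seed=1))


@pytest.fixture(scope="session")
def de_result(trained_pipeline):
    """One-vs-rest DE on the default cohort (shared; ~half a minute)."""
    from tissuesig.diffexp import de_one_vs_rest

    return de_one_vs_rest(trained_pipeline["filtered"], trained_pipeline["tmm"])


@pytest.fixture(scope="session")
def trained_pipeline(default_cohort):
    """Full preprocess -> SMOTE -> train -> attribute state on the default cohort.

    Returned as a dict so individual tests can pick the pieces they need
    without re-running the expensive stages.
    """
    cm, truth = default_cohort
    tpm = pp.compute_tpm(cm)
    mask = pp.filter_genes(cm, tpm)
    filtered = cm.subset_genes(mask)
    split = pp.split_train_test(filtered.labels, per_class_test_n=15, seed=3)
    tmm = pp.tmm_factors(filtered, reference_pool=split == "train")
    dataset = pp.build_dataset(filtered, tmm, split)
    train_ds = dataset.subset(dataset.split == "train")
    Xb, yb = bal.smote_balance(
        train_ds.vectors(), train_ds.labels, bal.SmoteConfig(seed=5)
    )
    images_b = np.stack([pp.pad_and_reshape(v)[0] for v in Xb]).astype(np.float32)
    spec = clf.CNNSpec(
        side=dataset.side,
        n_classes=len(dataset.class_names),
        conv_channels=(8, 16, 32, 32),
        fc_hidden=64,
    )
    model = clf.build_model(spec, seed=7)
    history = clf.train(
        model, images_b, yb, dataset.class_names,
        clf.TrainConfig(epochs=20, input_dropout=0.5, seed=7),
    )
    metrics = clf.evaluate(model, dataset)

    test_ds = dataset.subset(dataset.split == "test")
    # Ranking uses logit attributions (see pipeline.RunConfig.explain_output).
    phi = ex.attribute_dataset(
        model, dataset, train_ds.images, nsamples=40, background_size=100,
        seed=11, output="logits",
    )
    predictions = clf.predict(model, test_ds.images, dataset.class_names)
    filtered_phi, correct = ex.filter_attributions(phi, predictions, test_ds.labels)
    ranked = ex.median_rank_genes(filtered_phi, test_ds.labels[correct], phi.gene_ids)
    return {
        "counts": cm,
        "truth": truth,
        "filtered": filtered,
        "tmm": tmm,
        "dataset": dataset,
        "train_ds": train_ds,
        "test_ds": test_ds,
        "model": model,
        "spec": spec,
        "history": history,
        "metrics": metrics,
        "phi": phi,
        "predictions": predictions,
        "filtered_phi": filtered_phi,
        "correct": correct,
        "ranked": ranked,
        "balanced_X": Xb,
        "balanced_y": yb,
    }
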