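"""End-to-end orchestration: simulate -> preprocess -> balance -> train ->
evaluate -> explain -> diffexp -> compare -> cluster_eval.

Both analysis branches (attribution via the classifier, and one-vs-rest
differential expression) run on the same normalized data and are compared
at the end; every stage writes its artifacts under the run directory so a
run can be inspected or resumed stage by stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import balance as balance_mod
from . import classifier as clf
from . import cluster_eval, compare, diffexp, explain, preprocess
from .simulate import CountMatrix, SignatureTruth, SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_all"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a full run needs; round-trips through JSON."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    per_class_test_n: int = 15
    balance: str = "smote"  # none | smote | ros | rus
    conv_channels: tuple[int, int, int, int] = (8, 16, 32, 32)
    fc_hidden: int = 64
    epochs: int = 25
    batch_size: int = 64
    lr: float = 1e-3
    input_dropout: float = 0.5
    explain_nsamples: int = 40
    # Gene ranking explains the logit: empirically, probability-space
    # attributions divert credit onto other classes' markers through the
    # softmax normalization (their absence raises this class's probability),
    # which buries a class's own subtler markers in the ranking.
    explain_output: str = "logits"
    background_size: int = 100
    explain_depth: int | str = "auto"
    fallback_depth: int = 10
    lfc_cut: float = 4.0
    fdr_cut: float = 0.01
    cluster_subsets: int = 20
    cluster_inits: int = 20
    embed_method: str = "umap"
    seed: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        sim = d.pop("simulation")
        for key in ("samples_per_class", "strong_lfc_range", "subtle_lfc_range",
                    "gene_length_range"):
            sim[key] = tuple(sim[key])
        sim["sibling_pairs"] = tuple(tuple(p) for p in sim["sibling_pairs"])
        d["conv_channels"] = tuple(d["conv_channels"])
        return cls(simulation=SimulationConfig(**sim), **d)


@dataclass
class RunReport:
    summary: dict
    out_dir: Path

    def write(self) -> None:
        (self.out_dir / "summary.json").write_text(json.dumps(self.summary, indent=2))


def _stage_seeds(seed: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0]) % (2**31) for n, c in zip(names, children)}


class _Stage:
    """Context manager logging stage timing and naming failures."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        logger.info("stage %s: start", self.name)
        self.t0 = time.monotonic()
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.monotonic() - self.t0
        if exc is not None:
            logger.error("stage %s: FAILED after %.1fs: %s", self.name, dt, exc)
            raise RuntimeError(f"stage {self.name!r} failed: {exc}") from exc
        logger.info("stage %s: done in %.1fs", self.name, dt)


def run_all(
    config: RunConfig,
    out_dir: str | Path,
    counts: CountMatrix | None = None,
    truth: SignatureTruth | None = None,
) -> RunReport:
    """Execute the full pipeline; idempotent given the config seed.

    When ``counts`` is provided the simulation stage is skipped and the
    matrix (with its labels) is used directly; ``truth`` is then optional
    and only used for reporting.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(config.to_json())
    seeds = _stage_seeds(
        config.seed,
        ["simulate", "split", "balance", "train", "explain", "cluster"],
    )
    summary: dict = {"seed": config.seed}

    with _Stage("simulate"):
        if counts is None:
            sim_cfg = dataclasses.replace(config.simulation, seed=seeds["simulate"])
            counts, truth = simulate_cohort(sim_cfg)
            counts.write_tsv(out_dir / "counts.tsv")
            counts.write_labels_tsv(out_dir / "labels.tsv")
            truth.write_csv(out_dir / "truth.csv")
        summary["n_samples"] = counts.n_samples
        summary["n_genes_input"] = counts.n_genes

    with _Stage("preprocess"):
        tpm = preprocess.compute_tpm(counts)
        mask = preprocess.filter_genes(counts, tpm)
        filtered = counts.subset_genes(mask)
        split = preprocess.split_train_test(
            filtered.labels, per_class_test_n=config.per_class_test_n, seed=seeds["split"]
        )
        # Reference pool restricted to training samples: test data must not
        # influence the factors used when balancing the training set.
        tmm = preprocess.tmm_factors(filtered, reference_pool=split == "train")
        dataset = preprocess.build_dataset(filtered, tmm, split)
        np.savetxt(out_dir / "tmm_factors.tsv", tmm.factors, fmt="%.6f")
        with open(out_dir / "split.tsv", "w") as fh:
            fh.write("sample_id\tsplit\n")
            for s, sp in zip(filtered.sample_ids, split):
                fh.write(f"{s}\t{sp}\n")
        with open(out_dir / "gene_order.csv", "w") as fh:
            fh.write("position,gene_id\n")
            for i, g in enumerate(dataset.gene_order):
                fh.write(f"{i},{'' if g is None else g}\n")
        summary["n_genes_filtered"] = filtered.n_genes
        summary["image_side"] = dataset.side

    with _Stage("balance"):
        train_ds = dataset.subset(dataset.split == "train")
        X = train_ds.vectors()
        y = train_ds.labels
        if config.balance == "smote":
            Xb, yb = balance_mod.smote_balance(
                X, y, balance_mod.SmoteConfig(seed=seeds["balance"])
            )
        elif config.balance == "ros":
            Xb, yb = balance_mod.random_oversample(X, y, seed=seeds["balance"])
        elif config.balance == "rus":
            Xb, yb = balance_mod.random_undersample(X, y, seed=seeds["balance"])
        elif config.balance == "none":
            Xb, yb = X, y
        else:
            raise ValueError(f"unknown balance mode {config.balance!r}")
        images_b = np.stack([preprocess.pad_and_reshape(v)[0] for v in Xb]).astype(
            np.float32
        )
        summary["balance"] = config.balance
        summary["n_train_after_balance"] = len(yb)

    with _Stage("train"):
        spec = clf.CNNSpec(
            side=dataset.side,
            n_classes=len(dataset.class_names),
            conv_channels=config.conv_channels,
            fc_hidden=config.fc_hidden,
        )
        model = clf.build_model(spec, seed=seeds["train"])
        history = clf.train(
            model, images_b, yb, dataset.class_names,
            clf.TrainConfig(
                epochs=config.epochs, batch_size=config.batch_size,
                lr=config.lr, input_dropout=config.input_dropout,
                seed=seeds["train"],
            ),
        )
        clf.save_model(model, spec, out_dir / "model")
        (out_dir / "history.json").write_text(json.dumps(history))

    with _Stage("evaluate"):
        metrics = clf.evaluate(model, dataset)
        (out_dir / "metrics.json").write_text(json.dumps(metrics.to_dict(), indent=2))
        np.savetxt(out_dir / "confusion.csv", metrics.confusion, fmt="%d", delimiter=",")
        summary["macro_f1"] = metrics.macro_f1

    with _Stage("explain"):
        test_ds = dataset.subset(dataset.split == "test")
        phi = explain.attribute_dataset(
            model, dataset, train_ds.images,
            nsamples=config.explain_nsamples,
            background_size=config.background_size,
            seed=seeds["explain"],
            output=config.explain_output,
        )
        predictions = clf.predict(model, test_ds.images, dataset.class_names)
        filtered_phi, correct = explain.filter_attributions(
            phi, predictions, test_ds.labels
        )
        ranked = explain.median_rank_genes(
            filtered_phi, test_ds.labels[correct], phi.gene_ids
        )
        ranked.to_frame().to_csv(out_dir / "ranked_genes.csv", index=False)
        if config.explain_depth == "auto":
            depth = explain.depth_at_unique_fraction(ranked, 0.5, max_depth=50)
            if depth is None:
                depth = config.fallback_depth
        else:
            depth = int(config.explain_depth)
        per_class, selected = explain.select_top_genes(ranked, depth)
        curve = explain.uniqueness_curve(ranked, list(range(1, min(50, ranked.n_genes) + 1)))
        curve.to_csv(out_dir / "uniqueness_curve.csv", index=False)
        summary["selected_depth"] = depth
        summary["n_selected_genes"] = len(selected)

    with _Stage("diffexp"):
        de = diffexp.de_one_vs_rest(
            filtered, tmm, lfc_cut=config.lfc_cut, fdr_cut=config.fdr_cut
        )
        de.write_csv(out_dir / "de_results.csv")
        de.per_class_counts().to_csv(out_dir / "de_class_counts.csv", index=False)
        summary["n_de_genes"] = len(de.collapsed_significant())

    with _Stage("compare"):
        report = compare.build_overlap_report(ranked, de, depth)
        (out_dir / "overlap.json").write_text(json.dumps(report.to_dict(), indent=2))
        report.per_class.to_csv(out_dir / "overlap_per_class.csv", index=False)
        summary["overlap_percent_of_shap"] = report.collapsed_percent

    with _Stage("cluster_eval"):
        test_X = test_ds.vectors()
        gene_idx = np.array(
            [i for i, g in enumerate(phi.gene_ids) if g in selected], dtype=int
        )
        null_res = cluster_eval.null_subset_test(
            test_X, test_ds.labels, gene_idx,
            n_subsets=config.cluster_subsets,
            inits_per_subset=config.cluster_inits,
            seed=seeds["cluster"],
            method=config.embed_method,
        )
        (out_dir / "cluster.json").write_text(
            json.dumps(
                {
                    "statistic": null_res.statistic,
                    "p_value": null_res.p_value,
                    "null_means": null_res.null_means.tolist(),
                    "subset_size": null_res.subset_size,
                },
                indent=2,
            )
        )
        summary["cluster_mean_v"] = null_res.statistic
        summary["cluster_p"] = null_res.p_value

    if truth is not None:
        recovered = {
            cls: sorted(set(per_class[cls]) & set(truth.signature_genes(i)))
            for i, cls in enumerate(truth.class_names)
            if cls in per_class
        }
        summary["planted_recovered_per_class"] = {
            c: len(v) for c, v in recovered.items()
        }

    report_obj = RunReport(summary=summary, out_dir=out_dir)
    report_obj.write()
    return report_obj
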