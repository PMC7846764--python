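"""Set accounting between attribution-selected genes and DE-significant genes.

Two conventions are used, matching the two ways such comparisons are
usually reported: *collapsed* sets deduplicate genes across classes (a gene
counts once no matter how many classes list it), while *slot-level*
accounting counts every (class, gene) entry separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .diffexp import DETable
from .explain import RankedGeneTable, select_top_genes

__all__ = ["OverlapReport", "overlap_collapsed", "slot_accounting",
           "annotate_direction", "build_overlap_report"]


@dataclass
class OverlapReport:
    collapsed_shap: int
    collapsed_de: int
    collapsed_common: int
    collapsed_percent: float  # of the attribution-selected set
    shap_slots: int
    de_slots: int
    common_slots: int
    shap_only_slots: int
    de_only_slots: int
    per_class: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {
            "collapsed": {
                "shap": self.collapsed_shap,
                "de": self.collapsed_de,
                "common": self.collapsed_common,
                "percent_of_shap": self.collapsed_percent,
            },
            "slots": {
                "shap": self.shap_slots,
                "de": self.de_slots,
                "common": self.common_slots,
                "shap_only": self.shap_only_slots,
                "de_only": self.de_only_slots,
            },
        }


def overlap_collapsed(shap_genes: set[str], de_genes: set[str]) -> dict:
    """Intersection/difference sizes; the percentage is of the SHAP set."""
    if not shap_genes or not de_genes:
        raise ValueError("both gene sets must be non-empty")
    common = shap_genes & de_genes
    return {
        "common": len(common),
        "shap_only": len(shap_genes - de_genes),
        "de_only": len(de_genes - shap_genes),
        "percent_of_shap": 100.0 * len(common) / len(shap_genes),
    }


def slot_accounting(n_shap_slots: int, n_de_slots: int, n_common: int) -> tuple[int, int]:
    """(shap_only, de_only) from printed slot totals; errors on impossible input."""
    if n_common > min(n_shap_slots, n_de_slots):
        raise ValueError("common slots exceed one of the totals")
    shap_only = n_shap_slots - n_common
    de_only = n_de_slots - n_common
    if shap_only < 0 or de_only < 0:
        raise ValueError("negative slot count; inputs are inconsistent")
    return shap_only, de_only


def annotate_direction(
    per_class_genes: dict[str, list[str]], de: DETable
) -> pd.DataFrame:
    """Label each (class, gene) entry up/down/ns from its class's DE result.

    Genes missing from the DE universe are labelled ``unknown`` with a
    warning — this happens when the attribution ran on a different gene
    filter than the DE analysis.
    """
    rows = []
    missing: set[str] = set()
    for cls, genes in per_class_genes.items():
        sub = de.for_class(cls)
        lut = dict(zip(sub["gene"], sub["direction"]))
        for g in genes:
            if g in lut:
                rows.append((cls, g, lut[g]))
            else:
                missing.add(g)
                rows.append((cls, g, "unknown"))
    if missing:
        warnings.warn(
            f"{len(missing)} genes absent from the DE table; labelled unknown",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=["class", "gene", "direction"])


def build_overlap_report(
    ranked: RankedGeneTable, de: DETable, depth: int
) -> OverlapReport:
    """Full collapsed + per-class + slot-level comparison at one depth."""
    per_class, shap_union = select_top_genes(ranked, depth)
    de_union = de.collapsed_significant()
    collapsed = overlap_collapsed(shap_union, de_union)

    shap_slots = de_slots = common_slots = 0
    per_rows = []
    for cls in ranked.class_names:
        top = set(per_class[cls])
        sig = de.significant_genes(cls)
        inter = top & sig
        directions = annotate_direction({cls: sorted(inter)}, de)
        n_up = int((directions["direction"] == "up").sum())
        n_down = int((directions["direction"] == "down").sum())
        shap_slots += len(top)
        de_slots += len(sig)
        common_slots += len(inter)
        per_rows.append(
            (cls, len(top), len(sig), len(inter),
             100.0 * len(inter) / len(top) if top else 0.0, n_up, n_down)
        )
    shap_only, de_only = slot_accounting(shap_slots, de_slots, common_slots)
    return OverlapReport(
        collapsed_shap=len(shap_union),
        collapsed_de=len(de_union),
        collapsed_common=collapsed["common"],
        collapsed_percent=collapsed["percent_of_shap"],
        shap_slots=shap_slots,
        de_slots=de_slots,
        common_slots=common_slots,
        shap_only_slots=shap_only,
        de_only_slots=de_only,
        per_class=pd.DataFrame(
            per_rows,
            columns=["class", "shap_n", "de_n", "common", "percent_of_shap",
                     "common_up", "common_down"],
        ),
    )
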