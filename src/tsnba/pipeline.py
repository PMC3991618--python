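"""End-to-end orchestration of the three-step analysis for one contrast.

Step 1 ranks network genes by received interaction activity; step 2 tunes
a co-expression threshold over the top-K genes to a target signature size;
step 3 infers TF→target interactions among the top-K by CLR and screens
for key regulators.  ``run_conditions`` loops over several contrasts and
unions the per-condition regulator sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tsnba.activity import WeightParams, build_activity_matrix, rank_genes
from tsnba.coexpression import SignatureResult, pearson_matrix, tune_threshold
from tsnba.io import (
    Contrast,
    GeneNetwork,
    GeneSet,
    RankedGeneList,
    log2_fold_change,
    restrict_to_network,
)
from tsnba.regulators import (
    RegulatorScreenCriteria,
    RegulatoryInteraction,
    clr_z,
    gaussian_mi,
    screen_regulators,
    union_regulators,
)

__all__ = ["ConditionResult", "run_condition", "run_conditions"]


@dataclass
class ConditionResult:
    """Everything the three steps produce for a single contrast."""

    contrast: str
    fold_change: pd.Series
    ranking: RankedGeneList
    signature: SignatureResult | None
    interactions: list[RegulatoryInteraction] | None
    regulator_report: pd.DataFrame | None
    regulators: GeneSet | None


def run_condition(
    net: GeneNetwork,
    expr: pd.DataFrame,
    contrast: Contrast,
    *,
    top_k: int = 300,
    target_size: int = 50,
    weight_params: WeightParams = WeightParams(),
    tf_genes: GeneSet | None = None,
    benchmark: GeneSet | None = None,
    criteria: RegulatorScreenCriteria = RegulatorScreenCriteria(),
    absolute_corr: bool = False,
) -> ConditionResult:
    """Run steps 1–3 for one contrast.

    Step 3 requires both ``tf_genes`` and ``benchmark``; without them only
    ranking and signature are computed.
    """
    expr_net = restrict_to_network(expr, net)
    f = log2_fold_change(expr_net, contrast.control, contrast.treated)
    activity = build_activity_matrix(net, f, weight_params)
    ranking = rank_genes(activity)

    k = min(top_k, len(ranking))
    corr = pearson_matrix(expr_net, ranking.top(k))
    signature = tune_threshold(corr, target_size=target_size, absolute=absolute_corr)

    interactions = report = regulators = None
    if tf_genes is not None and benchmark is not None:
        mi = gaussian_mi(corr)
        if len(set(tf_genes.members) & set(mi.genes)) >= 2:
            interactions = clr_z(mi, tf_genes)
            report, regulators = screen_regulators(interactions, benchmark, criteria)
        else:
            interactions, regulators = [], GeneSet("key_regulators", [])
            report = pd.DataFrame(
                columns=["tf", "n_targets", "n_benchmark", "benchmark_fraction", "retained"]
            )
    return ConditionResult(
        contrast.name, f, ranking, signature, interactions, report, regulators
    )


def run_conditions(
    net: GeneNetwork,
    expr: pd.DataFrame,
    contrasts: dict[str, Contrast],
    **kwargs,
) -> tuple[dict[str, ConditionResult], GeneSet | None, pd.DataFrame | None]:
    """Run every contrast and union the per-condition regulator sets."""
    results = {
        name: run_condition(net, expr, c, **kwargs) for name, c in contrasts.items()
    }
    per_cond = {
        name: r.regulators for name, r in results.items() if r.regulators is not None
    }
    if per_cond:
        union, provenance = union_regulators(per_cond)
        return results, union, provenance
    return results, None, None
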