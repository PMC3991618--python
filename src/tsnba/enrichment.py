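"""Enrichment evaluation against a benchmark pathology gene set.

The enrichment ratio of a selection is the fraction of its genes that
belong to the benchmark set; significance is the exact upper-tail
hypergeometric probability P(X ≥ hits) of drawing that many benchmark
genes from the network universe.  The benchmark is always pre-intersected
with the population (the restricted network's genes), and p-values are
reported raw (no multiple-testing correction).  Enrichment curves walk a
K grid starting at 50 in steps of 50; the paired-comparison harness is a
standard paired t-test on per-dataset ratio differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from tsnba.io import GeneNetwork, GeneSet, RankedGeneList

__all__ = [
    "EnrichmentResult",
    "enrichment_ratio",
    "hypergeom_pvalue",
    "enrichment_curve",
    "paired_compare",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Overlap of a gene selection with the benchmark, plus significance."""

    selected_size: int
    hits: int
    population: int
    population_hits: int
    pvalue: float

    @property
    def ratio(self) -> float:
        return self.hits / self.selected_size

    @property
    def percent(self) -> float:
        """Ratio as a percentage, one decimal, round half up (e.g. 19.2)."""
        pct = Decimal(100 * self.hits) / Decimal(self.selected_size)
        return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def hypergeom_pvalue(
    hits: int, selected_size: int, population_hits: int, population: int
) -> float:
    """Exact upper-tail P(X ≥ hits) for the hypergeometric draw.

    ``selected_size`` genes drawn without replacement from a population of
    ``population`` genes containing ``population_hits`` benchmark genes.
    """
    if not (
        0 <= hits <= selected_size <= population
        and 0 <= population_hits <= population
        and hits <= population_hits
    ):
        raise ValueError(
            f"inconsistent hypergeometric arguments: hits={hits}, "
            f"n={selected_size}, K={population_hits}, N={population}"
        )
    return float(stats.hypergeom.sf(hits - 1, population, population_hits, selected_size))


def enrichment_ratio(
    selection: GeneSet | list[str],
    benchmark: GeneSet,
    population: GeneNetwork | int,
    population_hits: int | None = None,
) -> EnrichmentResult:
    """Fraction of the selection inside the benchmark, with hypergeometric p.

    ``population`` is normally the (restricted) network, in which case the
    benchmark is first intersected with its genes; sizes may be passed
    directly for worked examples on published counts.
    """
    members = set(selection.members if isinstance(selection, GeneSet) else selection)
    if not members:
        raise ValueError("empty selection")
    if isinstance(population, GeneNetwork):
        universe = population.nodes
        if not members <= universe:
            raise ValueError("selection contains genes outside the population network")
        bench = set(benchmark.members) & universe
        n_pop, n_pop_hits = len(universe), len(bench)
        hits = len(members & bench)
    else:
        n_pop = int(population)
        if population_hits is None:
            raise ValueError("population_hits required when population is a size")
        n_pop_hits = int(population_hits)
        hits = len(members & set(benchmark.members))
    p = hypergeom_pvalue(hits, len(members), n_pop_hits, n_pop)
    return EnrichmentResult(len(members), hits, n_pop, n_pop_hits, p)


def enrichment_curve(
    ranked: RankedGeneList,
    benchmark: GeneSet,
    population: GeneNetwork,
    k_start: int = 50,
    k_step: int = 50,
    k_max: int | None = None,
) -> pd.DataFrame:
    """Enrichment of the top-K prefix for K = k_start, k_start+k_step, … ≤ k_max."""
    k_max = len(ranked) if k_max is None else k_max
    if k_max > len(ranked):
        raise ValueError("k_max exceeds ranked list length")
    rows = []
    for k in range(k_start, k_max + 1, k_step):
        res = enrichment_ratio(ranked.top(k), benchmark, population)
        rows.append((k, res.hits, res.ratio, res.percent, res.pvalue))
    return pd.DataFrame(rows, columns=["k", "hits", "ratio", "percent", "pvalue"])


@dataclass(frozen=True)
class PairedComparison:
    t: float | None
    pvalue: float | None
    mean_difference: float
    degenerate: bool


def paired_compare(ratios_a: list[float], ratios_b: list[float]) -> PairedComparison:
    """Paired t-test on per-dataset enrichment-ratio differences (a − b).

    Zero-variance differences are flagged degenerate and no p is emitted.
    """
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need equal-length paired vectors of length >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return PairedComparison(None, None, float(d.mean()), True)
    t, p = stats.ttest_rel(a, b)
    return PairedComparison(float(t), float(p), float(d.mean()), False)
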