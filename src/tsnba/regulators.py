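"""Step 3 — CLR regulatory inference and key-regulator screening.

Mutual information between genes is obtained from the Pearson matrix of
the top-K genes under the Gaussian closed form MI = −½·ln(1 − ρ²).  Each
TF→target pair's MI is then compared against the background MI
distribution of both the TF and the target (context likelihood of
relatedness): z_t = max(0, (MI − μ_t)/σ_t) over the TF's non-self
partners, z_g analogously over the target's, combined as
z = sqrt(z_t² + z_g²) and sorted descending.

A TF is called a *key regulator* when, among its interactions with
z ≥ 3, it has strictly more than 3 targets in the benchmark pathology
set and those benchmark targets make up strictly more than 60% of all
its surviving targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from tsnba.coexpression import CorrelationMatrix
from tsnba.io import GeneSet

logger = logging.getLogger("tsnba")

__all__ = [
    "MIMatrix",
    "RegulatoryInteraction",
    "RegulatorScreenCriteria",
    "gaussian_mi",
    "clr_z",
    "screen_regulators",
    "union_regulators",
]

_RHO_CLAMP = 1.0 - 1e-12


@dataclass
class MIMatrix:
    """Symmetric nonnegative mutual-information matrix (zero diagonal)."""

    genes: list[str]
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class RegulatoryInteraction:
    """One putative TF→target interaction with its background-corrected score."""

    tf: str
    target: str
    mi: float
    z: float


@dataclass(frozen=True)
class RegulatorScreenCriteria:
    """Thresholds of the three key-regulator screening criteria.

    Interactions need z ≥ ``z_min``; a TF needs strictly more than
    ``min_benchmark_targets`` benchmark targets and a benchmark fraction
    strictly greater than ``min_benchmark_fraction``.
    """

    z_min: float = 3.0
    min_benchmark_targets: int = 3
    min_benchmark_fraction: float = 0.6

    def __post_init__(self) -> None:
        if self.z_min <= 0 or self.min_benchmark_targets <= 0:
            raise ValueError("thresholds must be positive")
        if not (0.0 < self.min_benchmark_fraction < 1.0):
            raise ValueError("min_benchmark_fraction must lie in (0, 1)")


def gaussian_mi(corr: CorrelationMatrix) -> MIMatrix:
    """MI(i,j) = −½·ln(1 − ρ(i,j)²), diagonal set to 0.

    |ρ| is clamped just below 1 so duplicated profiles stay finite.
    """
    rho = np.clip(corr.values, -_RHO_CLAMP, _RHO_CLAMP)
    mi = -0.5 * np.log1p(-(rho**2))
    np.fill_diagonal(mi, 0.0)
    return MIMatrix(list(corr.genes), mi)


def clr_z(mi: MIMatrix, tf_genes: GeneSet) -> list[RegulatoryInteraction]:
    """Background-corrected z for every TF→gene pair, sorted by decreasing z.

    Background statistics are the plain mean/sd of each gene's MI values
    over all non-self partners; negative deviations are rectified to 0.
    A gene whose MI values are all equal (σ = 0) contributes component 0.
    """
    n = len(mi)
    tfs = sorted(set(tf_genes.members) & set(mi.genes))
    if len(tfs) < 2 or n < 3:
        raise ValueError("need at least 2 TFs and 3 genes for background statistics")
    vals = mi.values
    mask = ~np.eye(n, dtype=bool)
    # per-row background over the n-1 non-self partners
    mu = np.where(mask, vals, np.nan)
    row_mean = np.nanmean(mu, axis=1)
    row_sd = np.nanstd(mu, axis=1, ddof=1)
    zero_sd = row_sd == 0
    if zero_sd.any():
        logger.info("clr_z: %d genes have zero MI dispersion (component set to 0)",
                    int(zero_sd.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        z_rows = (vals - row_mean[:, None]) / row_sd[:, None]
    z_rows[zero_sd, :] = 0.0
    z_rows = np.maximum(z_rows, 0.0)

    index = {g: i for i, g in enumerate(mi.genes)}
    out = []
    for tf in tfs:
        t = index[tf]
        for g, gene in enumerate(mi.genes):
            if g == t:
                continue
            z = float(np.hypot(z_rows[t, g], z_rows[g, t]))
            out.append(RegulatoryInteraction(tf, gene, float(vals[t, g]), z))
    out.sort(key=lambda r: (-r.z, r.tf, r.target))
    return out


def screen_regulators(
    interactions: list[RegulatoryInteraction],
    benchmark: GeneSet,
    criteria: RegulatorScreenCriteria = RegulatorScreenCriteria(),
) -> tuple[pd.DataFrame, GeneSet]:
    """Apply the three screening criteria; return a per-TF report and the kept TFs.

    Report columns: tf, n_targets, n_benchmark, benchmark_fraction, retained —
    computed over interactions surviving the z cut.
    """
    surviving: dict[str, set[str]] = {}
    for it in interactions:
        if it.z >= criteria.z_min:
            surviving.setdefault(it.tf, set()).add(it.target)
    rows = []
    kept = []
    for tf in sorted(surviving):
        targets = surviving[tf]
        n_bench = len(targets & set(benchmark.members))
        frac = n_bench / len(targets)
        retained = (
            n_bench > criteria.min_benchmark_targets
            and frac > criteria.min_benchmark_fraction
        )
        if retained:
            kept.append(tf)
        rows.append((tf, len(targets), n_bench, frac, retained))
    report = pd.DataFrame(
        rows, columns=["tf", "n_targets", "n_benchmark", "benchmark_fraction", "retained"]
    )
    return report, GeneSet("key_regulators", kept)


def union_regulators(per_condition: dict[str, GeneSet]) -> tuple[GeneSet, pd.DataFrame]:
    """Union of per-condition regulator sets, with per-TF provenance.

    Returns the union set and a table (tf, conditions) listing which
    conditions nominated each TF.
    """
    if not per_condition:
        raise ValueError("need at least one per-condition regulator set")
    nominations: dict[str, list[str]] = {}
    for cond, gs in per_condition.items():
        for tf in gs.members:
            nominations.setdefault(tf, []).append(cond)
    table = pd.DataFrame(
        [(tf, ";".join(sorted(conds))) for tf, conds in sorted(nominations.items())],
        columns=["tf", "conditions"],
    )
    return GeneSet("regulators_union", nominations.keys()), table
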