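"""Step 2 — co-expression filtering of the top-ranked genes.

The top-K genes from step 1 are screened by pairwise Pearson correlation
computed over all samples of the dataset (all conditions pooled).  Gene
pairs whose coefficient reaches a threshold τ form a co-expression
network; every gene incident to at least one retained edge belongs to the
molecular signature.  The threshold is either given, or tuned on the grid
0.600, 0.605, …, 0.945 to the *largest* τ whose signature still contains
at least ``target_size`` genes (about 50, but no fewer).

The comparison is against the signed coefficient by default — strongly
anti-correlated pairs are excluded — with an ``absolute`` switch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tsnba.io import GeneSet

logger = logging.getLogger("tsnba")

__all__ = [
    "CorrelationMatrix",
    "SignatureResult",
    "default_threshold_grid",
    "pearson_matrix",
    "signature_at_threshold",
    "tune_threshold",
]


def default_threshold_grid() -> np.ndarray:
    """Correlation thresholds 0.6 … 0.945 in increments of 0.005."""
    return np.round(np.arange(0.600, 0.945 + 1e-9, 0.005), 3)


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson matrix over a gene subset (unit diagonal)."""

    genes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.genes), len(self.genes)):
            raise ValueError("matrix shape does not match gene list")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.abs(v).max(initial=0.0) > 1 + 1e-12:
            raise ValueError("correlation values must lie in [-1, 1]")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class SignatureResult:
    """A thresholded co-expression network and its signature gene set."""

    threshold: float
    edges: set[frozenset[str]]
    signature: GeneSet
    size: int = field(init=False)
    target_met: bool = True

    def __post_init__(self) -> None:
        self.size = len(self.signature)

    def edge_frame(self) -> pd.DataFrame:
        rows = sorted(tuple(sorted(e)) for e in self.edges)
        return pd.DataFrame(rows, columns=["gene_a", "gene_b"])


def pearson_matrix(expr: pd.DataFrame, genes: list[str] | None = None) -> CorrelationMatrix:
    """Pairwise Pearson correlation of expression rows.

    ``genes`` (e.g. the step-1 top-K, in rank order) selects and orders the
    rows; constant rows are dropped with a warning since their coefficient
    is undefined.  Requires ≥3 samples.
    """
    if genes is not None:
        missing = [g for g in genes if g not in expr.index]
        if missing:
            raise KeyError(f"genes absent from expression matrix: {missing[:5]}")
        expr = expr.loc[genes]
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    keep = sd > 0
    n_const = int((~keep).sum())
    if n_const:
        logger.warning("pearson_matrix: dropping %d constant gene rows", n_const)
        x = x[keep]
        expr = expr.loc[keep]
    if x.shape[0] == 0:
        raise ValueError("all gene rows are constant")
    corr = np.corrcoef(x)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(list(expr.index), corr)


def _retained_mask(corr: CorrelationMatrix, tau: float, absolute: bool) -> np.ndarray:
    v = np.abs(corr.values) if absolute else corr.values
    mask = v >= tau
    np.fill_diagonal(mask, False)
    return mask


def signature_at_threshold(
    corr: CorrelationMatrix, tau: float, absolute: bool = False
) -> SignatureResult:
    """Retain gene pairs with coefficient ≥ τ; signature = edge-incident genes."""
    if not (0.0 < tau < 1.0):
        raise ValueError("tau must lie in (0, 1)")
    mask = _retained_mask(corr, tau, absolute)
    ii, jj = np.nonzero(np.triu(mask, k=1))
    edges = {frozenset((corr.genes[i], corr.genes[j])) for i, j in zip(ii, jj)}
    members = sorted({g for e in edges for g in e})
    return SignatureResult(float(tau), edges, GeneSet(f"signature_tau{tau:g}", members))


def tune_threshold(
    corr: CorrelationMatrix,
    target_size: int = 50,
    grid: np.ndarray | None = None,
    absolute: bool = False,
) -> SignatureResult:
    """Pick the largest grid threshold whose signature size ≥ ``target_size``.

    If even the lowest threshold falls short, that lowest-threshold result
    is returned with ``target_met=False`` and a warning.
    """
    if len(corr) == 0:
        raise ValueError("empty correlation matrix")
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    grid = default_threshold_grid() if grid is None else np.sort(np.asarray(grid))
    for tau in grid[::-1]:
        mask = _retained_mask(corr, float(tau), absolute)
        size = int(mask.any(axis=1).sum())
        if size >= target_size:
            return signature_at_threshold(corr, float(tau), absolute)
    logger.warning(
        "tune_threshold: no grid threshold reaches %d signature genes; "
        "returning lowest threshold %.3f",
        target_size,
        grid[0],
    )
    result = signature_at_threshold(corr, float(grid[0]), absolute)
    result.target_met = False
    return result
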