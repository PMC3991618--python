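"""Step 1 — interaction-activity weighting and gene ranking.

Each PPI edge {i, t} is assigned an *activity* computed from the log2 fold
changes of its two endpoints.  The weighting function is a sum of two
bivariate logistic terms

    w(f_i, f_t) = C·s(K f_i) · C·s(K f_t)  +  C·s(−K f_i) · C·s(−K f_t)  −  T

with s(x) = 1/(1+e^(−x)) the standard logistic.  The first term is large
only when both genes are up-regulated together (co-activation), the second
only when both are down-regulated (co-suppression); C and K set the scale
and steepness, and the shift T (0.5 by default, with C = 1) makes the
weight exactly zero when neither gene responds.  An edge with one silent
endpoint therefore contributes ~nothing, which is the point: activity flows
only through interactions whose both partners respond to the perturbation.

The activities replace the 1-entries of the adjacency matrix; a gene's
score P_i is the total activity it receives from its interaction partners
(the row sum), and genes are ranked by descending P_i.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from tsnba.io import GeneNetwork, RankedGeneList

logger = logging.getLogger("tsnba")

__all__ = [
    "WeightParams",
    "edge_weight",
    "InteractionActivityMatrix",
    "build_activity_matrix",
    "rank_genes",
]


@dataclass(frozen=True)
class WeightParams:
    """Shape (C, K) and shift (T) parameters of the edge-weighting function."""

    C: float = 1.0
    K: float = 5.0
    T: float = 0.5

    def __post_init__(self) -> None:
        if not (self.C > 0 and self.K > 0):
            raise ValueError("C and K must be positive")
        if not (0.0 <= self.T <= 1.0):
            raise ValueError("T must lie in [0, 1]")


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    # equivalent to 1/(1+exp(-x)) but overflow-safe for large |x|
    return np.piecewise(
        np.asarray(x, dtype=float),
        [np.asarray(x) >= 0],
        [lambda v: 1.0 / (1.0 + np.exp(-v)), lambda v: np.exp(v) / (1.0 + np.exp(v))],
    )


def edge_weight(
    f_i: float | np.ndarray,
    f_j: float | np.ndarray,
    params: WeightParams = WeightParams(),
) -> float | np.ndarray:
    """Activity of an interaction from its endpoints' log2 fold changes.

    Symmetric in (f_i, f_j); exactly zero at (0, 0) with the defaults
    C = 1, K = 5, T = 0.5.  Accepts scalars or broadcastable arrays.
    """
    f_i = np.asarray(f_i, dtype=float)
    f_j = np.asarray(f_j, dtype=float)
    if not (np.isfinite(f_i).all() and np.isfinite(f_j).all()):
        raise ValueError("fold changes must be finite")
    C, K, T = params.C, params.K, params.T
    up = (C * _logistic(K * f_i)) * (C * _logistic(K * f_j))
    down = (C * _logistic(-K * f_i)) * (C * _logistic(-K * f_j))
    out = up + down - T
    return float(out) if out.ndim == 0 else out


@dataclass
class InteractionActivityMatrix:
    """Symmetric sparse matrix of edge activities over the network genes.

    Sparsity pattern equals the network adjacency (zero diagonal); entries
    are edge_weight values.  ``genes`` fixes the row/column order and
    ``degrees`` carries the network degrees for deterministic tie-breaking.
    """

    genes: list[str]
    matrix: sp.csr_matrix
    degrees: np.ndarray
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {g: i for i, g in enumerate(self.genes)}

    def activity(self, i: str, j: str) -> float:
        return float(self.matrix[self.index[i], self.index[j]])

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def total_edge_activity(self) -> float:
        return float(self.matrix.sum()) / 2.0


def build_activity_matrix(
    net: GeneNetwork,
    contrast: pd.Series,
    params: WeightParams = WeightParams(),
) -> InteractionActivityMatrix:
    """Replace the adjacency 1-entries with edge activities.

    Network genes missing from the contrast are treated as unresponsive
    (f = 0) and counted in a log message.
    """
    genes = net.node_list
    if not genes:
        raise ValueError("empty network")
    f = contrast.reindex(genes)
    n_missing = int(f.isna().sum())
    if n_missing:
        logger.info(
            "build_activity_matrix: %d network genes lack a fold change; using f=0",
            n_missing,
        )
        f = f.fillna(0.0)
    fv = f.to_numpy(dtype=float)
    idx = {g: i for i, g in enumerate(genes)}
    edges = np.array(
        [(idx[a], idx[b]) for a, b in net.graph.edges], dtype=np.int64
    ).reshape(-1, 2)
    n = len(genes)
    if len(edges):
        w = np.asarray(edge_weight(fv[edges[:, 0]], fv[edges[:, 1]], params))
        rows = np.concatenate([edges[:, 0], edges[:, 1]])
        cols = np.concatenate([edges[:, 1], edges[:, 0]])
        data = np.concatenate([w, w])
        mat = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    else:
        mat = sp.csr_matrix((n, n))
    return InteractionActivityMatrix(genes, mat, net.degrees(genes))


def rank_genes(activity: InteractionActivityMatrix) -> RankedGeneList:
    """Rank genes by total received activity P_i = Σ_t A(i, t), descending.

    The node's own fold change enters only through its edges; there is no
    self term.  Ties: higher degree first, then lexicographic gene id.
    """
    p = activity.row_sums()
    order = sorted(
        range(len(activity.genes)),
        key=lambda i: (-p[i], -activity.degrees[i], activity.genes[i]),
    )
    return RankedGeneList(
        [activity.genes[i] for i in order],
        [float(p[i]) for i in order],
        method="tsnba_step1",
    )
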