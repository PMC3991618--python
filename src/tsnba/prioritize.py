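"""Competitor prioritization methods.

Five baselines that rank the same gene universe and emit the same
:class:`~tsnba.io.RankedGeneList` contract as step 1, so the evaluation
harness is method-agnostic:

* fold change — descending |log2 FC|;
* degree — descending PPI degree;
* neighborhood scoring — ½(|f_i| + mean |f| over direct neighbors),
  zero for genes that are neither differentially expressed nor adjacent
  to a differentially expressed gene;
* interconnectivity — connectivity of each gene to all differentially
  expressed genes, via direct edges and shared neighbors normalized by
  the geometric mean of the two degrees;
* network propagation — diffusion of a binary DEG prior over the
  degree-normalized adjacency, F ← α·Â·F + (1−α)·F⁰, iterated until the
  L1 change drops below 1e−6 (α = 0.1 by default).

Differential expression is an absolute *linear* fold-change cutoff c,
applied as |log2 FC| ≥ log2(c).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from tsnba.io import GeneNetwork, GeneSet, RankedGeneList

logger = logging.getLogger("tsnba")

__all__ = [
    "DEGSet",
    "deg_set",
    "fold_change_rank",
    "degree_rank",
    "neighborhood_score",
    "interconnectivity_rank",
    "network_propagation",
]


@dataclass(frozen=True)
class DEGSet:
    """Differentially expressed genes at a linear fold-change cutoff."""

    genes: frozenset[str]
    cutoff: float

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def deg_set(contrast: pd.Series, cutoff: float) -> DEGSet:
    """Genes with |log2 FC| ≥ log2(cutoff), cutoff on the linear scale (> 1)."""
    if cutoff <= 1:
        raise ValueError("linear fold-change cutoff must exceed 1")
    thr = np.log2(cutoff)
    members = contrast.index[contrast.abs() >= thr]
    return DEGSet(frozenset(members), float(cutoff))


def fold_change_rank(
    contrast: pd.Series, net: GeneNetwork | None = None
) -> RankedGeneList:
    """Rank genes by descending absolute log2 fold change."""
    scores = {g: abs(float(v)) for g, v in contrast.items()}
    return RankedGeneList.from_scores(scores, "fold_change", network=net)


def degree_rank(net: GeneNetwork) -> RankedGeneList:
    """Rank genes by descending PPI degree (hub genes first)."""
    scores = {g: float(net.degree(g)) for g in net.node_list}
    return RankedGeneList.from_scores(scores, "degree", network=net)


def neighborhood_score(
    net: GeneNetwork, contrast: pd.Series, deg: DEGSet
) -> RankedGeneList:
    """Score(i) = ½(|f_i| + mean over N(i) of |f_j|).

    Genes that are not differentially expressed and have no differentially
    expressed neighbor score 0; an empty neighborhood contributes 0 to the
    average term.
    """
    absf = contrast.abs()
    scores = {}
    for g in net.node_list:
        nbrs = net.neighbors(g)
        if g not in deg and not (nbrs & deg.genes):
            scores[g] = 0.0
            continue
        own = float(absf.get(g, 0.0))
        nb_vals = [float(absf.get(j, 0.0)) for j in nbrs]
        nb_mean = float(np.mean(nb_vals)) if nb_vals else 0.0
        scores[g] = 0.5 * (own + nb_mean)
    return RankedGeneList.from_scores(scores, "neighborhood", network=net)


def interconnectivity_rank(net: GeneNetwork, deg: DEGSet) -> RankedGeneList:
    """Sum over DEGs d of (e(i,d) + |N(i) ∩ N(d)|) / sqrt(degree(i)·degree(d)).

    Degree-0 genes (and degree-0 DEGs) contribute/score 0.
    """
    genes = net.node_list
    degs_in_net = sorted(deg.genes & set(genes))
    neighbor_sets = {d: net.neighbors(d) for d in degs_in_net}
    scores = {}
    for g in genes:
        kg = net.degree(g)
        if kg == 0:
            scores[g] = 0.0
            continue
        ng = net.neighbors(g)
        total = 0.0
        for d in degs_in_net:
            if d == g:
                continue
            kd = net.degree(d)
            if kd == 0:
                continue
            icn = (net.e(g, d) + len(ng & neighbor_sets[d])) / np.sqrt(kg * kd)
            total += icn
        scores[g] = float(total)
    return RankedGeneList.from_scores(scores, "interconnectivity", network=net)


def _normalized_adjacency(net: GeneNetwork, genes: list[str]) -> sp.csr_matrix:
    """Â(i,j) = e(i,j) / sqrt(degree(i)·degree(j)); zero rows for isolated genes."""
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    deg = net.degrees(genes).astype(float)
    inv_sqrt = np.zeros(n)
    nz = deg > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(deg[nz])
    edges = np.array([(idx[a], idx[b]) for a, b in net.graph.edges], dtype=np.int64)
    edges = edges.reshape(-1, 2)
    if len(edges) == 0:
        return sp.csr_matrix((n, n))
    w = inv_sqrt[edges[:, 0]] * inv_sqrt[edges[:, 1]]
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    return sp.csr_matrix((np.concatenate([w, w]), (rows, cols)), shape=(n, n))


def network_propagation(
    net: GeneNetwork,
    deg: DEGSet,
    alpha: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> RankedGeneList:
    """Diffuse a binary DEG prior until the L1 change falls below ``tol``.

    F⁰ is 1 on DEGs, 0 elsewhere; F ← α·Â·F + (1−α)·F⁰ with Â the
    degree-normalized adjacency.  Converges for any α < 1 (spectral radius
    of Â is ≤ 1); exceeding ``max_iter`` raises.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    genes = net.node_list
    a_norm = _normalized_adjacency(net, genes)
    f0 = np.array([1.0 if g in deg else 0.0 for g in genes])
    f = f0.copy()
    for _ in range(max_iter):
        f_new = alpha * (a_norm @ f) + (1.0 - alpha) * f0
        if np.abs(f_new - f).sum() < tol:
            f = f_new
            break
        f = f_new
    else:
        raise RuntimeError(f"network propagation did not converge in {max_iter} iterations")
    scores = {g: float(v) for g, v in zip(genes, f)}
    return RankedGeneList.from_scores(scores, "propagation", network=net)
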