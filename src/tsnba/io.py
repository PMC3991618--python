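"""Core domain types and file readers/writers.

Everything downstream of this module speaks in terms of four objects: a
:class:`GeneNetwork` (an undirected, self-loop-free protein–protein
interaction graph), an expression matrix (a genes × samples
:class:`pandas.DataFrame` of strictly positive, linear-scale intensities),
a contrast vector (a :class:`pandas.Series` of per-gene log2 fold changes),
and a :class:`GeneSet`.  Gene identifiers are opaque, case-sensitive
strings.

File formats are deliberately plain: tab-separated edge lists (SIF with an
ignored middle column is accepted), TSV expression tables with a sample
header and a gene-id first column, GMT or one-gene-per-line gene sets, and
a YAML mapping of contrast name → ``{control: [...], treated: [...]}``.
"""

from __future__ import annotations

import json
import logging
import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("tsnba")

__all__ = [
    "GeneNetwork",
    "GeneSet",
    "RankedGeneList",
    "read_network",
    "write_network",
    "read_expression",
    "write_expression",
    "read_gene_set",
    "read_contrasts",
    "log2_fold_change",
    "restrict_to_network",
]


class GeneNetwork:
    """Undirected gene graph with no self-loops.

    Thin wrapper around :class:`networkx.Graph` that enforces the
    invariants every algorithm here relies on: edges are unordered pairs of
    distinct genes, duplicates are collapsed, and every edge endpoint is a
    node.  ``node_list`` gives a deterministic (sorted) gene ordering used
    whenever a matrix is indexed by genes.
    """

    def __init__(self, graph: nx.Graph | None = None):
        g = nx.Graph() if graph is None else nx.Graph(graph)
        g.remove_edges_from(nx.selfloop_edges(g))
        self.graph = g

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()
    ) -> "GeneNetwork":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from((a, b) for a, b in edges if a != b)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def node_list(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b in self.graph.edges}

    def degree(self, gene: str) -> int:
        return int(self.graph.degree[gene])

    def degrees(self, genes: Sequence[str] | None = None) -> np.ndarray:
        genes = self.node_list if genes is None else genes
        return np.array([self.graph.degree[g] if g in self.graph else 0 for g in genes])

    def neighbors(self, gene: str) -> set[str]:
        return set(self.graph.neighbors(gene))

    def has_edge(self, i: str, j: str) -> bool:
        return self.graph.has_edge(i, j)

    def e(self, i: str, j: str) -> int:
        """Adjacency indicator: 1 iff {i, j} is an edge."""
        return int(i != j and self.graph.has_edge(i, j))

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def subgraph(self, genes: Iterable[str]) -> "GeneNetwork":
        return GeneNetwork(self.graph.subgraph(genes).copy())

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return (
            f"GeneNetwork({self.number_of_nodes()} genes, "
            f"{self.number_of_edges()} interactions)"
        )


@dataclass(frozen=True)
class GeneSet:
    """Named set of gene identifiers."""

    name: str
    members: frozenset[str]

    def __init__(self, name: str, members: Iterable[str]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "members", frozenset(members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __iter__(self):
        return iter(sorted(self.members))

    def intersect(self, genes: Iterable[str], name: str | None = None) -> "GeneSet":
        return GeneSet(name or self.name, self.members & set(genes))


@dataclass
class RankedGeneList:
    """Genes ordered by a method-specific score, descending.

    Ties are broken deterministically: higher network degree first, then
    lexicographic gene id (degrees default to 0 when no network is given).
    """

    genes: list[str]
    scores: list[float]
    method: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate genes")
        if any(
            self.scores[i] < self.scores[i + 1] for i in range(len(self.scores) - 1)
        ):
            raise ValueError("scores must be non-increasing")

    @classmethod
    def from_scores(
        cls,
        scores: dict[str, float],
        method: str,
        network: "GeneNetwork | None" = None,
    ) -> "RankedGeneList":
        def key(gene: str):
            deg = network.degree(gene) if network is not None and gene in network else 0
            return (-scores[gene], -deg, gene)

        order = sorted(scores, key=key)
        return cls(order, [float(scores[g]) for g in order], method)

    def top(self, k: int) -> list[str]:
        return self.genes[:k]

    def top_set(self, k: int, name: str | None = None) -> GeneSet:
        return GeneSet(name or f"{self.method}_top{k}", self.genes[:k])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.genes) + 1),
                "gene": self.genes,
                "score": self.scores,
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_network(path: str | Path) -> GeneNetwork:
    """Read a 2-column TSV/whitespace edge list (or 3-column SIF).

    Self-pairs are dropped and duplicate edges collapsed; counts of dropped
    records are logged to standard error.  Lines starting with ``#`` are
    comments.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    n_self = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 2 columns, got {len(parts)}"
                )
            if len(parts) >= 3:
                a, b = parts[0], parts[2]  # SIF: source, interaction, target
            else:
                a, b = parts[0], parts[1]
            if a == b:
                n_self += 1
                continue
            edges.append((a, b))
    net = GeneNetwork.from_edges(edges)
    n_dup = len(edges) - net.number_of_edges()
    if n_self or n_dup:
        logger.info(
            "read_network(%s): dropped %d self-pairs, collapsed %d duplicate edges",
            path.name,
            n_self,
            n_dup,
        )
    return net


def write_network(net: GeneNetwork, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{a}\t{b}\n")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a TSV expression table (header = sample ids, first column = gene id).

    Duplicate gene rows are collapsed by averaging, mirroring probe-level
    summarisation by the mean over probes mapped to the same gene.  Rows
    with missing values are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression value in {path}: {exc}") from exc
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"missing values in expression rows: {bad[:5]}")
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.info("read_expression: averaging %d duplicate gene rows", n_dup)
        df = df.groupby(level=0, sort=False).mean()
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a gene set from a GMT line file or a one-gene-per-line list.

    For GMT input (any line with ≥3 tab-separated fields) the first line's
    set is returned unless ``name`` selects another.
    """
    path = Path(path)
    lines = [
        ln.rstrip("\n") for ln in path.open() if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ValueError(f"{path}: empty gene set file")
    is_gmt = any("\t" in ln and len(ln.split("\t")) >= 3 for ln in lines)
    if is_gmt:
        sets = {}
        for ln in lines:
            parts = ln.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed GMT line: {ln[:60]!r}")
            members = [g for g in parts[2:] if g]
            if not members:
                raise ValueError(f"{path}: GMT set {parts[0]!r} has no members")
            sets[parts[0]] = GeneSet(parts[0], members)
        if name is not None and name in sets:
            return sets[name]
        first = next(iter(sets.values()))
        return GeneSet(name, first.members) if name else first
    members = [ln.split()[0] for ln in lines]
    return GeneSet(name or path.stem, members)


@dataclass
class Contrast:
    """One treated-vs-control comparison."""

    name: str
    control: list[str]
    treated: list[str]


def read_contrasts(path: str | Path) -> dict[str, Contrast]:
    """Read a YAML mapping: contrast name → {control: [...], treated: [...]}."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise ValueError(f"{path}: expected a non-empty mapping of contrasts")
    out = {}
    for cname, spec in raw.items():
        if not isinstance(spec, dict) or "control" not in spec or "treated" not in spec:
            raise ValueError(f"{path}: contrast {cname!r} needs control and treated lists")
        out[cname] = Contrast(
            cname, [str(s) for s in spec["control"]], [str(s) for s in spec["treated"]]
        )
    return out


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


def log2_fold_change(
    expr: pd.DataFrame,
    control: Sequence[str],
    treated: Sequence[str],
) -> pd.Series:
    """Per-gene log2 fold change of group means on the linear intensity scale.

    f_g = log2(mean(treated_g) / mean(control_g)).  Both groups must be
    non-empty and every group mean strictly positive.
    """
    if len(control) == 0 or len(treated) == 0:
        raise ValueError("both sample groups must be non-empty")
    missing = [s for s in (*control, *treated) if s not in expr.columns]
    if missing:
        raise KeyError(f"samples not in expression matrix: {missing}")
    mean_c = expr[list(control)].mean(axis=1)
    mean_t = expr[list(treated)].mean(axis=1)
    bad = expr.index[(mean_c <= 0) | (mean_t <= 0)]
    if len(bad):
        raise ValueError(
            f"non-positive mean intensity for genes {bad.tolist()[:5]}; "
            "expression must be strictly positive on the linear scale"
        )
    f = np.log2(mean_t / mean_c)
    f.name = "log2_fc"
    if not np.isfinite(f).all():
        raise ValueError("non-finite fold change encountered")
    return f


def restrict_to_network(expr: pd.DataFrame, net: GeneNetwork) -> pd.DataFrame:
    """Keep only expression rows for genes present in the network (order kept)."""
    keep = expr.index[expr.index.isin(net.nodes)]
    if len(keep) == 0:
        raise ValueError("no expression gene is present in the network")
    return expr.loc[keep]


def write_run_metadata(path: str | Path, **params) -> None:
    """Write run parameters (plus package version) as JSON."""
    from tsnba import __version__

    meta = {"tsnba_version": __version__, **params}
    with Path(path).open("w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
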