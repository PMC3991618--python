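"""Seeded synthetic benchmark: networks, planted pathology, TFs, expression.

The generator emulates the input constellation the pipeline was designed
for — a scale-free PPI network, a benchmark pathology gene set, a TF list,
and condition-contrast microarray-style expression — with known ground
truth so every stage is testable without external databases.

Model sketch (log2 scale, exported linear as 2^x):

* network: preferential attachment seeded with a complete graph on
  m+1 nodes, so edge count = C(m+1, 2) + (n − m − 1)·m;
* pathology genes: a connected breadth-first neighborhood (interacting
  signature components), partitioned into co-expression modules; a
  ``scattered`` switch plants them uniformly instead (ablation/null);
* decoy responders: scattered genes that respond to treatment just as
  strongly but sit outside the benchmark and outside any module — they
  emulate the fact that a perturbation changes many genes the benchmark
  does not annotate, which is what defeats pure fold-change ranking;
* expression: x = baseline + a_g·loading·z_module + delta·(treated and
  responsive) + N(0, noise_sd), with per-sample module factors z centered
  within each condition group (and rescaled to unit variance) so planted
  co-expression never leaks into group-mean fold changes;
* TFs: one *active* TF per module — its highest-degree member, which
  carries the module factor at full strength (the factor models the TF's
  regulatory activity and the module is its regulon); its planted targets
  are the other members, loading the factor at a_g =
  tf_target_coupling·U(0.625, 1.25) (clamped to 1), so coupling strength
  is heterogeneous.  Background TFs are placed uniformly with no targets.

All stochastic operations take an explicit seed; a fixed seed gives
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from tsnba.io import Contrast, GeneNetwork, GeneSet, write_expression, write_network

logger = logging.getLogger("tsnba")

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "signal_preset",
    "null_preset",
    "genome_scale_preset",
    "generate_network",
    "plant_truth",
    "simulate_expression",
    "make_fixture",
]


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings; defaults define the standard signal conditions.

    ``effect_size`` is the treated-vs-control shift of responsive genes in
    log2 units; ``within_module_correlation`` the target Pearson
    correlation of module co-members; ``tf_target_coupling`` the loading
    of planted targets on their TF's latent factor; ``noise_sd`` the
    per-gene Gaussian noise (log2 units).  ``n_decoys`` scattered
    responders outside the benchmark model unannotated perturbation
    response.
    """

    n_genes: int = 2000
    edges_per_node: int = 4
    n_pathology: int = 200
    n_modules: int = 4
    n_tfs: int = 20
    n_decoys: int = 200
    n_samples_control: int = 10
    n_samples_treated: int = 10
    effect_size: float = 2.0
    within_module_correlation: float = 0.8
    tf_target_coupling: float = 0.8
    noise_sd: float = 1.0
    scattered: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_genes,
            self.edges_per_node,
            self.n_pathology,
            self.n_modules,
            self.n_tfs,
            self.n_samples_control,
            self.n_samples_treated,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be >= 0")
        if not (0.0 <= self.within_module_correlation < 1.0):
            raise ValueError("within_module_correlation must lie in [0, 1)")
        if self.n_genes <= self.edges_per_node:
            raise ValueError("n_genes must exceed edges_per_node")
        if self.n_pathology > self.n_genes:
            raise ValueError("n_pathology cannot exceed n_genes")
        if self.n_pathology < self.n_modules:
            raise ValueError("cannot split pathology genes into that many modules")


def signal_preset(seed: int = 0, **overrides) -> SimulationParams:
    """Standard planted-signature conditions (2000 genes, 10% pathology)."""
    return SimulationParams(seed=seed, **overrides)


def null_preset(seed: int = 0, **overrides) -> SimulationParams:
    """No planted structure: zero effect size, zero module co-expression,
    and uniform (scattered) placement — a pure-noise negative control."""
    overrides.setdefault("effect_size", 0.0)
    overrides.setdefault("within_module_correlation", 0.0)
    overrides.setdefault("scattered", True)
    return SimulationParams(seed=seed, **overrides)


def genome_scale_preset(seed: int = 0, **overrides) -> SimulationParams:
    """Curated-human-interactome scale: 7633 genes, ~31k edges, 1462 pathology."""
    overrides.setdefault("n_genes", 7633)
    overrides.setdefault("n_pathology", 1462)
    overrides.setdefault("n_decoys", 800)
    overrides.setdefault("n_modules", 28)
    overrides.setdefault("n_tfs", 100)
    return SimulationParams(seed=seed, **overrides)


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic study."""

    network: GeneNetwork
    pathology_genes: GeneSet
    decoy_genes: GeneSet
    tf_genes: GeneSet
    active_tfs: GeneSet
    regulatory_edges: set[tuple[str, str]]
    module_assignments: dict[str, int]
    params: SimulationParams

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pathology_genes": sorted(self.pathology_genes.members),
            "decoy_genes": sorted(self.decoy_genes.members),
            "tf_genes": sorted(self.tf_genes.members),
            "active_tfs": sorted(self.active_tfs.members),
            "regulatory_edges": sorted(map(list, self.regulatory_edges)),
            "module_assignments": self.module_assignments,
            "params": dataclasses.asdict(self.params),
        }
        with Path(path).open("w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path, network: GeneNetwork) -> "SyntheticTruth":
        with Path(path).open() as fh:
            d = json.load(fh)
        return cls(
            network=network,
            pathology_genes=GeneSet("pathology", d["pathology_genes"]),
            decoy_genes=GeneSet("decoys", d["decoy_genes"]),
            tf_genes=GeneSet("tfs", d["tf_genes"]),
            active_tfs=GeneSet("active_tfs", d["active_tfs"]),
            regulatory_edges={tuple(e) for e in d["regulatory_edges"]},
            module_assignments={g: int(m) for g, m in d["module_assignments"].items()},
            params=SimulationParams(**d["params"]),
        )


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_network(params: SimulationParams, seed: int | None = None) -> GeneNetwork:
    """Connected preferential-attachment graph with hub-heavy degrees.

    Growth starts from a complete graph on m+1 nodes and every later node
    attaches m edges preferentially, hence exactly
    C(m+1, 2) + (n − m − 1)·m edges and a connected, self-loop-free graph.
    Deterministic for a fixed seed.
    """
    n, m = params.n_genes, params.edges_per_node
    rng = np.random.default_rng(params.seed if seed is None else seed)
    g = nx.complete_graph(m + 1)
    # repeated-endpoint list implements linear preferential attachment
    repeated: list[int] = [v for e in g.edges for v in e]
    for new in range(m + 1, n):
        targets: set[int] = set()
        while len(targets) < m:
            targets.add(repeated[rng.integers(len(repeated))])
        for t in targets:
            g.add_edge(new, t)
            repeated.extend((new, t))
    ids = _gene_ids(n)
    g = nx.relabel_nodes(g, {i: ids[i] for i in range(n)})
    return GeneNetwork(g)


def _bfs_neighborhood(
    net: GeneNetwork, start: str, size: int, rng: np.random.Generator
) -> list[str]:
    """Breadth-first gene neighborhood of the requested size (shuffled levels)."""
    seen = {start}
    order = [start]
    queue = deque([start])
    while queue and len(order) < size:
        node = queue.popleft()
        nbrs = sorted(net.neighbors(node) - seen)
        rng.shuffle(nbrs)
        for nb in nbrs:
            if len(order) >= size:
                break
            seen.add(nb)
            order.append(nb)
            queue.append(nb)
    return order


def plant_truth(
    net: GeneNetwork, params: SimulationParams, seed: int | None = None
) -> SyntheticTruth:
    """Choose pathology genes, modules, decoys, and TFs with planted targets."""
    rng = np.random.default_rng((params.seed if seed is None else seed) + 1)
    genes = net.node_list
    if params.scattered:
        pathology = sorted(rng.choice(genes, size=params.n_pathology, replace=False))
    else:
        start = genes[int(rng.integers(len(genes)))]
        pathology = _bfs_neighborhood(net, start, params.n_pathology, rng)
        if len(pathology) < params.n_pathology:  # tiny component: top up uniformly
            rest = sorted(set(genes) - set(pathology))
            extra = rng.choice(rest, size=params.n_pathology - len(pathology), replace=False)
            pathology = pathology + sorted(extra)
    # contiguous chunks of the (BFS or sampled) order become modules
    bounds = np.linspace(0, len(pathology), params.n_modules + 1).astype(int)
    modules = {}
    for m in range(params.n_modules):
        for g in pathology[bounds[m] : bounds[m + 1]]:
            modules[g] = m

    remaining = sorted(set(genes) - set(pathology))
    n_decoys = min(params.n_decoys, len(remaining))
    decoys = sorted(rng.choice(remaining, size=n_decoys, replace=False)) if n_decoys else []

    # one active TF per module: its highest-degree member (master regulators
    # tend to be hubs); planted targets are the remaining module members
    n_active = min(params.n_modules, params.n_tfs)
    active_tfs = []
    regulatory_edges: set[tuple[str, str]] = set()
    for m in range(n_active):
        members = pathology[bounds[m] : bounds[m + 1]]
        tf = max(sorted(members), key=net.degree)
        active_tfs.append(tf)
        regulatory_edges.update((tf, t) for t in members if t != tf)
    background_pool = sorted(set(remaining) - set(decoys))
    n_background = params.n_tfs - n_active
    background_tfs = (
        sorted(rng.choice(background_pool, size=n_background, replace=False))
        if n_background
        else []
    )
    return SyntheticTruth(
        network=net,
        pathology_genes=GeneSet("pathology", pathology),
        decoy_genes=GeneSet("decoys", decoys),
        tf_genes=GeneSet("tfs", list(active_tfs) + list(background_tfs)),
        active_tfs=GeneSet("active_tfs", active_tfs),
        regulatory_edges=regulatory_edges,
        module_assignments=modules,
        params=params,
    )


def _group_centered_factors(
    rng: np.random.Generator, n_factors: int, group_sizes: list[int]
) -> np.ndarray:
    """Per-sample latent factors, zero-mean and unit-variance within each group.

    Centering guarantees the factors contribute exactly nothing to
    group-mean contrasts; groups of size 1 get factor 0.
    """
    cols = []
    for size in group_sizes:
        z = rng.standard_normal((n_factors, size))
        if size > 1:
            z = z - z.mean(axis=1, keepdims=True)
            sd = z.std(axis=1, keepdims=True, ddof=0)
            sd[sd == 0] = 1.0
            z = z / sd
        else:
            z = np.zeros((n_factors, size))
        cols.append(z)
    return np.concatenate(cols, axis=1)


def simulate_expression(
    truth: SyntheticTruth, seed: int | None = None
) -> tuple[pd.DataFrame, Contrast]:
    """Linear-scale expression matrix plus the treated-vs-control contrast.

    Simulated in log2 space and exported as 2^x so the fold-change pipeline
    runs end-to-end exactly as on linear-intensity microarray data.
    """
    p = truth.params
    rng = np.random.default_rng((p.seed if seed is None else seed) + 2)
    genes = truth.network.node_list
    n = len(genes)
    n_c, n_t = p.n_samples_control, p.n_samples_treated
    samples = [f"ctrl_{i+1}" for i in range(n_c)] + [f"trt_{i+1}" for i in range(n_t)]
    treated_mask = np.array([False] * n_c + [True] * n_t)

    rho = p.within_module_correlation
    loading = p.noise_sd * np.sqrt(rho / (1.0 - rho))

    baseline = rng.uniform(6.0, 12.0, size=n)
    x = baseline[:, None] + rng.normal(0.0, p.noise_sd, size=(n, n_c + n_t))

    z_mod = _group_centered_factors(rng, p.n_modules, [n_c, n_t])
    active = set(truth.active_tfs.members)
    gene_idx = {g: i for i, g in enumerate(genes)}
    # active TFs carry their module's factor at full strength (it models
    # their regulatory activity); targets load it at a heterogeneous,
    # coupling-scaled strength
    for g in sorted(truth.module_assignments):
        m = truth.module_assignments[g]
        if g in active:
            a = 1.0
        else:
            a = min(1.0, p.tf_target_coupling * rng.uniform(0.625, 1.25))
        x[gene_idx[g]] += a * loading * z_mod[m]

    responsive = set(truth.pathology_genes.members) | set(truth.decoy_genes.members)
    if p.effect_size != 0.0:
        rows = [gene_idx[g] for g in responsive]
        x[np.ix_(rows, np.where(treated_mask)[0])] += p.effect_size

    expr = pd.DataFrame(np.exp2(x), index=genes, columns=samples)
    contrast = Contrast("treated_vs_control", samples[:n_c], samples[n_c:])
    return expr, contrast


def make_fixture(params: SimulationParams, outdir: str | Path) -> dict[str, Path]:
    """Generate one study and write all pipeline inputs to ``outdir``.

    Files: network.tsv, expression.tsv, benchmark.gmt (pathology genes),
    tfs.txt, contrasts.yaml, truth.json, params.json.  The full CLI runs on
    these unmodified.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net = generate_network(params)
    truth = plant_truth(net, params)
    expr, contrast = simulate_expression(truth)

    paths = {name: outdir / fname for name, fname in [
        ("network", "network.tsv"),
        ("expression", "expression.tsv"),
        ("benchmark", "benchmark.gmt"),
        ("tfs", "tfs.txt"),
        ("contrasts", "contrasts.yaml"),
        ("truth", "truth.json"),
        ("params", "params.json"),
    ]}
    write_network(net, paths["network"])
    write_expression(expr, paths["expression"])
    with paths["benchmark"].open("w") as fh:
        fh.write("pathology\tsynthetic benchmark gene set\t")
        fh.write("\t".join(sorted(truth.pathology_genes.members)))
        fh.write("\n")
    with paths["tfs"].open("w") as fh:
        fh.writelines(f"{g}\n" for g in sorted(truth.tf_genes.members))
    with paths["contrasts"].open("w") as fh:
        yaml.safe_dump(
            {contrast.name: {"control": contrast.control, "treated": contrast.treated}},
            fh,
        )
    truth.to_json(paths["truth"])
    with paths["params"].open("w") as fh:
        json.dump(dataclasses.asdict(params), fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("make_fixture: wrote %d files to %s", len(paths), outdir)
    return paths
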