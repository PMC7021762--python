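"""Seeded generators for networks and mutation cohorts.

The cohort generator emulates the statistical structure of somatic-mutation
panels in tumor cohorts: a binary genes-by-samples matrix whose marginal
frequencies are long-tailed — a couple of highly recurrent "driver-like"
genes (tens of percent of samples) plus a power-law tail of rarely mutated
genes — so that most mutation configurations involve at least one driver.
An optional planted effect co-mutates the top driver with a randomly chosen
degree-1 (marginal) gene of the network in a fraction of samples, providing
a known-positive signal for the marginal-mutation enrichment analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import Network

__all__ = [
    "CohortSpec",
    "MutationMatrix",
    "make_complete_network",
    "make_random_network",
    "mutation_frequencies",
    "make_mutation_cohort",
    "make_ppi_like_network",
    "make_gene_sets",
]


@dataclass(frozen=True)
class MutationMatrix:
    """Binary genes-by-samples mutation matrix.

    ``a.loc[g, s] = 1`` iff sample ``s`` carries at least one mutation in
    gene ``g``.
    """

    a: pd.DataFrame  # index: gene labels; columns: sample labels; values 0/1

    def __post_init__(self) -> None:
        vals = self.a.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mutation matrix entries must be 0/1")
        if self.a.index.duplicated().any():
            raise ValueError("duplicate gene labels")
        if self.a.columns.duplicated().any():
            raise ValueError("duplicate sample labels")

    @property
    def gene_labels(self) -> list[str]:
        return [str(g) for g in self.a.index]

    @property
    def sample_labels(self) -> list[str]:
        return [str(s) for s in self.a.columns]

    @property
    def n_samples(self) -> int:
        return self.a.shape[1]

    def mutated_genes(self, sample: str) -> set[str]:
        col = self.a[sample]
        return {str(g) for g in col.index[col == 1]}


def make_complete_network(M: int = 20, prefix: str = "n") -> Network:
    """Complete graph ``K_M`` with labeled nodes (``M >= 2``)."""
    if M < 2:
        raise ValueError("a complete network needs M >= 2")
    a = np.ones((M, M)) - np.eye(M)
    return Network(tuple(f"{prefix}{i}" for i in range(M)), a)


def make_random_network(
    kind: str,
    n_nodes: int,
    seed: int,
    p: float = 0.3,
    m_attach: int = 2,
    prefix: str = "g",
    max_retries: int = 50,
) -> Network:
    """Connected random network, reproducible per seed.

    ``kind="erdos_renyi"`` draws G(n, p) and retries with incremented seed
    until connected (up to ``max_retries``); ``kind="preferential_attachment"``
    grows a Barabasi-Albert graph with ``m_attach`` edges per new node
    (connected by construction; ``m_attach=1`` yields a tree).
    """
    if kind == "erdos_renyi":
        for attempt in range(max_retries):
            g = nx.erdos_renyi_graph(n_nodes, p, seed=seed + attempt)
            if nx.is_connected(g):
                break
        else:
            raise ValueError(
                f"no connected G({n_nodes}, {p}) draw in {max_retries} attempts"
            )
    elif kind == "preferential_attachment":
        g = nx.barabasi_albert_graph(n_nodes, m_attach, seed=seed)
    else:
        raise ValueError(f"unknown network kind: {kind!r}")
    mapping = {i: f"{prefix}{i}" for i in g.nodes}
    return Network.from_networkx(nx.relabel_nodes(g, mapping))


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic mutation cohort.

    ``driver_freqs`` are the per-sample mutation probabilities of the two
    most recurrent genes (defaults mirror the frequencies of the two dominant
    breast-cancer drivers, ~35% and ~25%); the remaining genes follow a
    ``rank^-tail_exponent`` power law rescaled to ``tail_mean`` (2% — a
    typical background somatic rate per gene).  With ``planted_effect`` a
    fraction ``planted_fraction`` of samples additionally carries the top
    driver together with one randomly chosen degree-1 gene of the network —
    the co-occurrence pattern the frailness analysis should flag.
    """

    n_genes: int
    n_samples: int
    seed: int = 0
    driver_freqs: tuple[float, ...] = (0.35, 0.25)
    tail_exponent: float = 1.5
    tail_mean: float = 0.02
    planted_effect: bool = False
    planted_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.n_genes < len(self.driver_freqs):
            raise ValueError("n_genes smaller than the number of driver genes")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction must be in [0, 1]")


def mutation_frequencies(spec: CohortSpec) -> np.ndarray:
    """Per-gene marginal mutation probabilities (drivers first, then the tail)."""
    n_tail = spec.n_genes - len(spec.driver_freqs)
    freqs = list(spec.driver_freqs)
    if n_tail > 0:
        tail = np.arange(1, n_tail + 1, dtype=float) ** (-spec.tail_exponent)
        if spec.tail_mean > 0:
            tail *= spec.tail_mean / tail.mean()
        else:
            tail[:] = 0.0
        freqs.extend(np.clip(tail, 0.0, 0.999))
    return np.asarray(freqs[: spec.n_genes])


def make_mutation_cohort(spec: CohortSpec, network: Network) -> MutationMatrix:
    """Sample a binary mutation matrix over the network's nodes.

    Genes are the network's nodes in label order; gene ``i`` is mutated in
    each sample independently with probability ``freqs[i]``.  The planted
    effect overwrites a seeded subset of samples with driver + marginal-gene
    co-mutations.  Reproducible given ``spec.seed``.
    """
    if spec.n_genes != network.M:
        raise ValueError(
            f"spec.n_genes={spec.n_genes} does not match network size {network.M}"
        )
    rng = np.random.default_rng(spec.seed)
    freqs = mutation_frequencies(spec)
    genes = list(network.labels)
    samples = [f"s{j:04d}" for j in range(spec.n_samples)]
    a = (rng.random((spec.n_genes, spec.n_samples)) < freqs[:, None]).astype(np.int8)

    if spec.planted_effect:
        degrees = network.degrees()
        marginal = np.flatnonzero(degrees == 1)
        if marginal.size == 0:
            raise ValueError("planted effect requires degree-1 nodes in the network")
        driver_row = 0  # top driver is the first gene
        n_plant = int(round(spec.planted_fraction * spec.n_samples))
        planted = rng.choice(spec.n_samples, size=n_plant, replace=False)
        for j in planted:
            a[driver_row, j] = 1
            a[rng.choice(marginal), j] = 1
    return MutationMatrix(pd.DataFrame(a, index=genes, columns=samples))


def make_ppi_like_network(
    n_core: int,
    n_leaves: int,
    seed: int,
    m_attach: int = 2,
    prefix: str = "g",
) -> Network:
    """Scale-free core with a controlled minority of degree-1 genes.

    A Barabasi-Albert core (minimum degree ``m_attach``) plus ``n_leaves``
    extra genes attached by a single edge to degree-weighted core genes —
    mimicking interactomes where marginal genes (e.g. growth factors) hang off
    well-connected hubs.  The degree-1 genes are exactly the attached leaves.
    """
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(n_core, m_attach, seed=seed)
    core = list(range(n_core))
    for i in range(n_leaves):
        degs = np.array([g.degree(c) for c in core], dtype=float)
        target = int(rng.choice(core, p=degs / degs.sum()))
        g.add_edge(n_core + i, target)
    mapping = {i: f"{prefix}{i}" for i in g.nodes}
    return Network.from_networkx(nx.relabel_nodes(g, mapping))


def make_gene_sets(
    network: Network,
    n_sets: int,
    size_range: tuple[int, int] = (10, 30),
    seed: int = 0,
) -> dict[str, set[str]]:
    """Gene sets drawn as breadth-first balls around random seed nodes.

    Each set is connected within the network by construction, so the induced
    subgraphs behave like pathway subnetworks.
    """
    rng = np.random.default_rng(seed)
    g = network.to_networkx()
    sets: dict[str, set[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        start = network.labels[int(rng.integers(network.M))]
        order = [start]
        for _, v in nx.bfs_edges(g, start):
            order.append(v)
            if len(order) >= size:
                break
        sets[f"SET{i:03d}"] = set(order)
    return sets
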