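"""Seed-protein neighborhood statistics on a PPI network.

Three statistics describe how a gene set sits around a seed protein:

level-1 interactors
    gene-set members directly adjacent to the seed;
level-2 interactors
    gene-set members at shortest-path distance exactly 2 from the seed
    (the two categories partition the gene set by distance, so a member
    adjacent to the seed is never also level-2);
bridging proteins
    neighbors of the seed adjacent to at least one level-2 interactor,
    i.e. the intermediaries on the length-2 paths. Bridging is defined
    purely topologically: a bridging protein may itself belong to the
    gene set and then also appears among the level-1 interactors.

``compute_neighborhood`` is the production path (breadth-first expansion
truncated at depth 2); ``neighborhood_oracle`` recomputes the same contract
from an exhaustive all-pairs shortest-path table and shares no code with it,
serving as an independent cross-check on small graphs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx

from .network_io import InteractionNetwork

__all__ = [
    "NeighborhoodCounts",
    "SeedNeighborhoodIndex",
    "compute_neighborhood",
    "neighborhood_oracle",
    "write_members_tsv",
]

STATISTICS = ("level1", "level2", "bridging")


@dataclass(frozen=True)
class NeighborhoodCounts:
    """Observed member sets and counts for one seed / gene-set pair."""

    seed: str
    level1: frozenset[str]
    level2: frozenset[str]
    bridging: frozenset[str]

    @property
    def n_level1(self) -> int:
        return len(self.level1)

    @property
    def n_level2(self) -> int:
        return len(self.level2)

    @property
    def n_bridging(self) -> int:
        return len(self.bridging)

    def counts(self) -> dict[str, int]:
        return {
            "level1": self.n_level1,
            "level2": self.n_level2,
            "bridging": self.n_bridging,
        }


def _check_inputs(
    network: InteractionNetwork, seed: str, gene_set: Iterable[str]
) -> set[str]:
    if not network.has_node(seed):
        raise ValueError(f"seed protein {seed!r} is not a node of the network")
    gene_set = set(gene_set)
    if seed in gene_set:
        raise ValueError(
            f"gene set contains the seed {seed!r}; map it with map_gene_set first"
        )
    missing = [g for g in gene_set if not network.has_node(g)]
    if missing:
        raise ValueError(f"gene-set members absent from the network: {sorted(missing)[:5]}")
    return gene_set


class SeedNeighborhoodIndex:
    """Precomputed depth-2 structure around a seed for fast repeated counting.

    Built once per (network, seed), then ``counts(gene_set)`` is a few set
    operations — this is what makes resampling thousands of null sets cheap.
    """

    def __init__(self, network: InteractionNetwork, seed: str):
        if not network.has_node(seed):
            raise ValueError(f"seed protein {seed!r} is not a node of the network")
        adj = network.graph.adj
        self.seed = seed
        self.ring1: frozenset[str] = frozenset(adj[seed])
        shell: set[str] = set()
        for u in self.ring1:
            shell.update(adj[u])
        shell -= self.ring1
        shell.discard(seed)
        self.ring2: frozenset[str] = frozenset(shell)
        # for each distance-2 node, the seed-neighbors it attaches to
        self.bridges: dict[str, frozenset[str]] = {
            v: frozenset(self.ring1.intersection(adj[v])) for v in self.ring2
        }

    def member_sets(
        self, gene_set: set[str]
    ) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
        level1 = frozenset(self.ring1 & gene_set)
        level2 = frozenset(self.ring2 & gene_set)
        bridging: set[str] = set()
        for v in level2:
            bridging.update(self.bridges[v])
        return level1, level2, frozenset(bridging)

    def counts(self, gene_set: set[str]) -> tuple[int, int, int]:
        level1, level2, bridging = self.member_sets(gene_set)
        return len(level1), len(level2), len(bridging)


def compute_neighborhood(
    network: InteractionNetwork, seed: str, gene_set: Iterable[str]
) -> NeighborhoodCounts:
    """Compute level-1, level-2 and bridging member sets for a mapped gene set.

    Preconditions: the seed is a network node, the gene set is a subset of
    the node set and excludes the seed (use
    :func:`seedprox.network_io.map_gene_set`). An isolated seed yields
    all-empty sets, not an error.
    """
    gene_set = _check_inputs(network, seed, gene_set)
    index = SeedNeighborhoodIndex(network, seed)
    level1, level2, bridging = index.member_sets(gene_set)
    return NeighborhoodCounts(seed=seed, level1=level1, level2=level2, bridging=bridging)


_ORACLE_MAX_NODES = 200


def neighborhood_oracle(
    network: InteractionNetwork, seed: str, gene_set: Iterable[str]
) -> NeighborhoodCounts:
    """Independent reference implementation via all-pairs shortest paths.

    Same contract as :func:`compute_neighborhood` but derived from a full
    shortest-path-length table, with no shared traversal code. Quadratic by
    design; guarded to networks of at most 200 nodes.
    """
    if network.n_nodes > _ORACLE_MAX_NODES:
        raise ValueError(
            f"oracle is limited to {_ORACLE_MAX_NODES} nodes, got {network.n_nodes}"
        )
    gene_set = _check_inputs(network, seed, gene_set)
    table = dict(nx.all_pairs_shortest_path_length(network.graph))
    dist = table[seed]
    level1 = frozenset(v for v in gene_set if dist.get(v) == 1)
    level2 = frozenset(v for v in gene_set if dist.get(v) == 2)
    graph = network.graph
    bridging = frozenset(
        u
        for u in graph.nodes
        if dist.get(u) == 1 and any(graph.has_edge(u, v) for v in level2)
    )
    return NeighborhoodCounts(seed=seed, level1=level1, level2=level2, bridging=bridging)


def write_members_tsv(counts: NeighborhoodCounts, path: str | Path) -> None:
    """Export member sets as TSV rows (node id, category)."""
    with Path(path).open("w") as fh:
        fh.write("node\tcategory\n")
        for category in STATISTICS:
            for node in sorted(getattr(counts, category)):
                fh.write(f"{node}\t{category}\n")
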