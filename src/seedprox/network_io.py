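"""Readers, writers and identifier mapping for PPI edge lists and gene sets.

The package operates on an undirected simple protein–protein interaction
(PPI) graph and on named collections of gene sets (one per GWAS study).
Three edge-list dialects are supported:

``hippie``
    The tab-separated dialect of the HIPPIE resource: protein identifier,
    numeric gene id, protein identifier, numeric gene id, confidence score
    in [0, 1], free-text annotation. Columns 1 and 3 are used as node
    identifiers; column 5 may be thresholded at load time.
``simple``
    Two or three tab-separated columns: id1, id2[, score].
``sif``
    id1, relation, id2 [, id3 ...] — the relation column is ignored.

Identifiers are whitespace-trimmed and upper-cased on load so that the
network and the gene sets share one case-insensitive namespace; an optional
two-column mapping file (symbol -> network id) covers resources whose node
labels are not plain gene symbols (e.g. UniProt entry names).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

log = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "GeneSetCollection",
    "EdgeListParseError",
    "GeneSetParseError",
    "read_edge_list",
    "write_edge_list",
    "read_gene_sets",
    "write_gene_sets",
    "read_id_map",
    "map_gene_set",
    "normalize_symbol",
]


class EdgeListParseError(ValueError):
    """Malformed edge-list row (wrong column count, non-numeric score)."""


class GeneSetParseError(ValueError):
    """Malformed gene-set input (short GMT row, duplicate study name)."""


def normalize_symbol(symbol: str) -> str:
    """Trim whitespace and upper-case an identifier (the shared namespace policy)."""
    return symbol.strip().upper()


@dataclass
class InteractionNetwork:
    """Undirected simple PPI graph over string protein identifiers.

    Wraps a :class:`networkx.Graph`; edge confidence scores, when present,
    are stored in the ``score`` edge attribute. The graph never contains
    self-loops or parallel edges.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    min_score: float | None = None

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def edges(self) -> set[frozenset[str]]:
        """Edge set as unordered identifier pairs."""
        return {frozenset((u, v)) for u, v in self.graph.edges}

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    def neighbors(self, node: str) -> set[str]:
        return set(self.graph.adj[node])

    def confidence(self, u: str, v: str) -> float | None:
        return self.graph.edges[u, v].get("score")

    def has_node(self, node: str) -> bool:
        return self.graph.has_node(node)

    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loop edges present: {loops[:3]}")
        if self.min_score is not None:
            for u, v, data in self.graph.edges(data=True):
                score = data.get("score")
                if score is not None and score < self.min_score:
                    raise ValueError(
                        f"edge {u}-{v} score {score} below min_score {self.min_score}"
                    )


@dataclass
class GeneSetCollection:
    """Ordered map study name -> set of gene symbols, with optional provenance."""

    studies: dict[str, frozenset[str]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self) -> Iterator[str]:
        return iter(self.studies)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.studies[name]

    def __contains__(self, name: str) -> bool:
        return name in self.studies

    def names(self) -> list[str]:
        return list(self.studies)

    def add(self, name: str, members: Iterable[str], provenance: str = "") -> None:
        if name in self.studies:
            raise GeneSetParseError(f"duplicate study name: {name!r}")
        members = frozenset(normalize_symbol(m) for m in members if m.strip())
        if not members:
            raise GeneSetParseError(f"study {name!r} has no members after parsing")
        self.studies[name] = members
        if provenance:
            self.provenance[name] = provenance


def _parse_score(token: str, path: str, lineno: int) -> float:
    try:
        score = float(token)
    except ValueError:
        raise EdgeListParseError(
            f"{path}:{lineno}: non-numeric confidence score {token!r}"
        ) from None
    return score


def read_edge_list(
    path: str | Path,
    dialect: str = "simple",
    min_score: float | None = None,
) -> InteractionNetwork:
    """Read a PPI edge list, dropping self-loops and duplicate rows.

    Parameters
    ----------
    path
        Tab-separated edge-list file.
    dialect
        ``hippie``, ``simple`` or ``sif`` (see module docstring).
    min_score
        Optional confidence threshold in [0, 1]; rows scoring below it are
        excluded (dialects carrying a score column only). Default: keep all
        edges.

    Raises
    ------
    EdgeListParseError
        On a malformed row (names the line number) or an empty network
        after filtering.
    """
    path = Path(path)
    if dialect not in ("hippie", "simple", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if min_score is not None and not 0.0 <= min_score <= 1.0:
        raise ValueError(f"min_score must lie in [0, 1], got {min_score}")

    graph = nx.Graph()
    n_loops = n_dups = n_filtered = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            pairs = _parse_row(line, dialect, str(path), lineno)
            if pairs is None:  # header line
                continue
            for u, v, score in pairs:
                u, v = normalize_symbol(u), normalize_symbol(v)
                if u == v:
                    n_loops += 1
                    continue
                if min_score is not None and score is not None and score < min_score:
                    n_filtered += 1
                    continue
                if graph.has_edge(u, v):
                    n_dups += 1
                    continue
                if score is None:
                    graph.add_edge(u, v)
                else:
                    graph.add_edge(u, v, score=score)
    if n_loops or n_dups or n_filtered:
        log.info(
            "%s: dropped %d self-loops, %d duplicate rows, %d edges below min_score",
            path, n_loops, n_dups, n_filtered,
        )
    if graph.number_of_edges() == 0:
        raise EdgeListParseError(f"{path}: empty network after parsing/filtering")
    return InteractionNetwork(graph=graph, min_score=min_score)


def _parse_row(
    line: str, dialect: str, path: str, lineno: int
) -> list[tuple[str, str, float | None]] | None:
    """Parse one row into (id1, id2, score) triples; None signals a header."""
    cols = line.split("\t")
    if dialect == "hippie":
        if len(cols) < 5:
            raise EdgeListParseError(
                f"{path}:{lineno}: hippie dialect needs >= 5 columns, got {len(cols)}"
            )
        if lineno == 1:
            try:
                float(cols[4])
            except ValueError:
                return None  # header
        score = _parse_score(cols[4], path, lineno)
        return [(cols[0], cols[2], score)]
    if dialect == "simple":
        if len(cols) == 1:
            cols = line.split()
        if len(cols) not in (2, 3):
            raise EdgeListParseError(
                f"{path}:{lineno}: simple dialect needs 2-3 columns, got {len(cols)}"
            )
        score = _parse_score(cols[2], path, lineno) if len(cols) == 3 else None
        return [(cols[0], cols[1], score)]
    # sif: id1 relation id2 [id3 ...]
    if len(cols) == 1:
        cols = line.split()
    if len(cols) < 3:
        raise EdgeListParseError(
            f"{path}:{lineno}: sif rows need >= 3 columns, got {len(cols)}"
        )
    return [(cols[0], target, None) for target in cols[2:]]


def write_edge_list(
    network: InteractionNetwork, path: str | Path, dialect: str = "simple"
) -> None:
    """Write the network as a sorted simple TSV (id1, id2[, score])."""
    if dialect != "simple":
        raise ValueError("only the simple dialect is written")
    path = Path(path)
    rows = []
    for u, v, data in network.graph.edges(data=True):
        a, b = sorted((u, v))
        score = data.get("score")
        rows.append((a, b, score))
    rows.sort()
    with path.open("w") as fh:
        for a, b, score in rows:
            if score is None:
                fh.write(f"{a}\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\t{score:g}\n")


def read_gene_sets(path: str | Path, format: str = "gmt") -> GeneSetCollection:
    """Read gene sets from a GMT file or a directory of one-symbol-per-line lists.

    In ``list-directory`` mode every regular file in the directory becomes a
    study whose name is the file stem. Duplicate member symbols are collapsed
    (logged); a GMT row with fewer than three fields or a duplicate study
    name raises :class:`GeneSetParseError`.
    """
    path = Path(path)
    collection = GeneSetCollection()
    if format == "gmt":
        with path.open() as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip():
                    continue
                cols = line.split("\t")
                if len(cols) < 3:
                    raise GeneSetParseError(
                        f"{path}:{lineno}: GMT rows need >= 3 fields, got {len(cols)}"
                    )
                name, description, members = cols[0].strip(), cols[1], cols[2:]
                cleaned = [m for m in members if m.strip()]
                if len({normalize_symbol(m) for m in cleaned}) < len(cleaned):
                    log.info("%s:%d: duplicate symbols collapsed in %r", path, lineno, name)
                collection.add(name, cleaned, provenance=description)
    elif format == "list-directory":
        if not path.is_dir():
            raise GeneSetParseError(f"{path}: not a directory")
        for child in sorted(path.iterdir()):
            if not child.is_file():
                continue
            members = [line for line in child.read_text().splitlines() if line.strip()]
            collection.add(child.stem, members)
    else:
        raise ValueError(f"unknown gene-set format {format!r}")
    if len(collection) == 0:
        raise GeneSetParseError(f"{path}: no gene sets found")
    return collection


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    """Write the collection as GMT (name, description, members...)."""
    path = Path(path)
    with path.open("w") as fh:
        for name in collection:
            desc = collection.provenance.get(name, "")
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_id_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping gene symbol -> network identifier."""
    mapping: dict[str, str] = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise GeneSetParseError(
                    f"{path}:{lineno}: identifier map needs exactly 2 columns"
                )
            mapping[normalize_symbol(cols[0])] = normalize_symbol(cols[1])
    return mapping


def map_gene_set(
    network: InteractionNetwork,
    genes: Iterable[str],
    seed: str,
    id_map: Mapping[str, str] | None = None,
) -> tuple[set[str], set[str]]:
    """Map gene symbols onto network node identifiers.

    Returns ``(mapped, unmapped)`` where ``mapped`` is the intersection with
    the network's node set (after optional translation through ``id_map``)
    and never contains the seed — a gene set cannot count its own seed as an
    interactor, so a seed occurrence is dropped (logged). Deterministic;
    ``|mapped| <= |genes|`` always.
    """
    seed = normalize_symbol(seed)
    nodes = network.graph
    mapped: set[str] = set()
    unmapped: set[str] = set()
    for gene in genes:
        symbol = normalize_symbol(gene)
        node = id_map.get(symbol, symbol) if id_map else symbol
        if node == seed:
            log.info("seed %s removed from gene set before analysis", seed)
            continue
        if nodes.has_node(node):
            mapped.add(node)
        else:
            unmapped.add(symbol)
    if not mapped:
        log.warning("gene set has no members mappable to the network")
    return mapped, unmapped
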