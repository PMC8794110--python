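"""Readers, writers and preparation filters for PPI networks, GO annotations
and protein-complex benchmark sets.

All formats are plain UTF-8 text:

* edge lists — two whitespace/tab-separated columns per line, ``#`` comments
  (a thin column-mapping handles BioGRID TAB exports);
* annotations — three columns ``protein  term  category`` with category one
  of ``MF``, ``BP``, ``CC``;
* complex sets — either one complex per line (whitespace-separated members,
  CYC2008 style) or two-column ``complex_id  member`` pairs;
* community output — three columns ``node  community  hl``.

Node identifiers are opaque, case-sensitive strings; no gene-symbol
normalisation is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

#: The three non-overlapping Gene Ontology namespaces.
CATEGORIES = ("MF", "BP", "CC")


class ParseError(ValueError):
    """A malformed line in one of the text formats; message names the line."""


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def load_edge_list(
    path: str | Path,
    format: str = "simple-tsv",
    interactor_columns: tuple[int, int] = (0, 1),
) -> nx.Graph:
    """Read an undirected, unweighted PPI network from a text edge list.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"simple-tsv"`` expects at least two whitespace/tab-separated
        columns per non-comment line, interactors in the first two columns.
        ``"biogrid-tab"`` is the same parser with configurable interactor
        columns (defaults to the first two) so BioGRID TAB exports can be
        consumed after choosing the identifier columns.
    interactor_columns:
        Zero-based column indices of the two interactors (``biogrid-tab``).

    Returns
    -------
    networkx.Graph
        Simple graph: duplicate and reversed-duplicate edges collapsed,
        self-loops dropped with a warning.
    """
    if format not in ("simple-tsv", "biogrid-tab"):
        raise ValueError(f"unknown edge-list format: {format!r}")
    i, j = interactor_columns if format == "biogrid-tab" else (0, 1)
    graph = nx.Graph()
    n_loops = 0
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) <= max(i, j):
                raise ParseError(
                    f"{path}: line {lineno}: expected at least "
                    f"{max(i, j) + 1} columns, got {len(cols)}"
                )
            a, b = cols[i], cols[j]
            if a == b:
                n_loops += 1
                graph.add_node(a)
                continue
            graph.add_edge(a, b)
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_loops)
    return graph


def filter_small_components(net: nx.Graph, min_size: int = 3) -> nx.Graph:
    """Drop connected components smaller than ``min_size`` nodes.

    Components below three nodes cannot form a community, so the default
    threshold removes them before community detection.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    keep: set[str] = set()
    n_components = 0
    for component in nx.connected_components(net):
        n_components += 1
        if len(component) >= min_size:
            keep |= component
    removed = net.number_of_nodes() - len(keep)
    logger.info(
        "component filter: %d component(s), removed %d node(s) below size %d",
        n_components, removed, min_size,
    )
    return net.subgraph(keep).copy()


# ---------------------------------------------------------------------------
# GO annotations
# ---------------------------------------------------------------------------

@dataclass
class AnnotationMap:
    """Protein → {GO category → set of term identifiers}.

    Categories are exactly the three ontologies MF, BP, CC; term sets may be
    empty and proteins absent from the map are treated as unannotated.
    """

    entries: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def add(self, protein: str, term: str, category: str) -> None:
        if category not in CATEGORIES:
            raise ParseError(f"unknown GO category {category!r} for {protein!r}")
        slot = self.entries.setdefault(
            protein, {c: set() for c in CATEGORIES}
        )
        slot[category].add(term)

    def terms(self, protein: str, categories: Iterable[str] = CATEGORIES) -> frozenset[str]:
        """Union of the protein's terms over the selected categories."""
        slot = self.entries.get(protein)
        if slot is None:
            return frozenset()
        out: set[str] = set()
        for c in categories:
            out |= slot.get(c, set())
        return frozenset(out)

    def annotated(self, categories: Iterable[str] = CATEGORIES) -> set[str]:
        """Proteins carrying at least one term in at least one category."""
        cats = tuple(categories)
        return {p for p in self.entries if self.terms(p, cats)}


def load_annotations(path: str | Path) -> AnnotationMap:
    """Read a three-column ``protein  term  category`` annotation TSV.

    Repeated (protein, term, category) rows are deduplicated; an unknown
    category token raises :class:`ParseError`.
    """
    ann = AnnotationMap()
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 columns, got {len(cols)}"
                )
            protein, term, category = cols[0], cols[1], cols[2]
            if category not in CATEGORIES:
                raise ParseError(
                    f"{path}: line {lineno}: unknown GO category {category!r}"
                )
            ann.add(protein, term, category)
    return ann


def category_subnetwork(
    net: nx.Graph,
    ann: AnnotationMap | None,
    categories: Iterable[str] | str = CATEGORIES,
) -> tuple[nx.Graph, dict[str, frozenset[str]]]:
    """Induce the subnetwork of proteins annotated in the selected categories.

    Returns the induced subgraph together with per-node term sets g(v), the
    union of each kept protein's terms over the selected categories.  The
    special mode ``categories="none"`` keeps the full network and attaches
    empty term sets — this is the topology-only (LCDA) preparation.
    """
    if categories == "none":
        return net.copy(), {v: frozenset() for v in net.nodes}
    if isinstance(categories, str):
        categories = (categories,)
    cats = tuple(categories)
    if not cats:
        raise ValueError("categories must be non-empty (or 'none')")
    for c in cats:
        if c not in CATEGORIES:
            raise ValueError(f"unknown GO category {c!r}")
    if ann is None:
        raise ValueError("an AnnotationMap is required unless categories='none'")
    keep = ann.annotated(cats) & set(net.nodes)
    sub = net.subgraph(keep).copy()
    term_sets = {v: ann.terms(v, cats) for v in sub.nodes}
    return sub, term_sets


# ---------------------------------------------------------------------------
# complex sets
# ---------------------------------------------------------------------------

@dataclass
class ComplexSet:
    """A named list of protein sets (benchmark or predicted complexes)."""

    complexes: list[tuple[str, frozenset[str]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.complexes)

    @property
    def sizes(self) -> list[int]:
        return [len(members) for _, members in self.complexes]

    def member_sets(self) -> list[frozenset[str]]:
        return [members for _, members in self.complexes]


def load_complexes(path: str | Path, dialect: str = "one-per-line") -> ComplexSet:
    """Read a complex set.

    ``one-per-line`` (CYC2008 style): each line lists one complex's members,
    whitespace-separated.  ``pairs``: two-column ``complex_id  member`` rows.
    Duplicate members within a complex are collapsed; singleton complexes are
    kept but flagged in the log.  An empty file is an error.
    """
    if dialect not in ("one-per-line", "pairs"):
        raise ValueError(f"unknown complex-file dialect: {dialect!r}")
    named: dict[str, set[str]] = {}
    order: list[str] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if dialect == "one-per-line":
                name = f"complex_{len(order) + 1}"
                named[name] = set(cols)
                order.append(name)
            else:
                if len(cols) < 2:
                    raise ParseError(
                        f"{path}: line {lineno}: expected 2 columns, got {len(cols)}"
                    )
                cid, member = cols[0], cols[1]
                if cid not in named:
                    named[cid] = set()
                    order.append(cid)
                named[cid].add(member)
    if not order:
        raise ParseError(f"{path}: no complexes found")
    n_singletons = sum(1 for name in order if len(named[name]) == 1)
    if n_singletons:
        logger.warning("%s: %d singleton complex(es)", path, n_singletons)
    return ComplexSet([(name, frozenset(named[name])) for name in order])


# ---------------------------------------------------------------------------
# community output
# ---------------------------------------------------------------------------

def write_communities(
    partition: Mapping[str, set[str] | frozenset[str]],
    hop_levels: Mapping[str, int] | None,
    path: str | Path,
) -> None:
    """Write ``node  community  hl`` rows, sorted by community then node.

    ``hop_levels`` maps node → hop-level; missing entries are written as 1.
    Community labels are source-node identifiers by construction.
    """
    if not partition:
        raise ValueError("refusing to write an empty partition")
    hop_levels = hop_levels or {}
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("#node\tcommunity\thl\n")
        for label in sorted(partition):
            for node in sorted(partition[label]):
                handle.write(f"{node}\t{label}\t{hop_levels.get(node, 1)}\n")


def read_communities(path: str | Path) -> tuple[dict[str, set[str]], dict[str, int]]:
    """Inverse of :func:`write_communities`: (partition, hop-levels)."""
    partition: dict[str, set[str]] = {}
    hop_levels: dict[str, int] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 columns, got {len(cols)}"
                )
            node, label, hl = cols[0], cols[1], cols[2]
            partition.setdefault(label, set()).add(node)
            hop_levels[node] = int(hl)
    return partition, hop_levels
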