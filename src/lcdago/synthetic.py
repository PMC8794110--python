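"""Planted-partition benchmarks with community-specific GO annotations.

Real PPI evaluations couple an interaction network with a GO annotation
table and a gold-standard complex set.  This module produces all three from
a stochastic block model so the whole pipeline is testable offline: each
planted community is densely wired internally (``p_in``) and sparsely to the
rest (``p_out``), owns a characteristic subset of a small term vocabulary in
each GO category, and hands those terms to its members — optionally
corrupted by swapping terms for foreign ones with a configurable noise
probability.  Default vocabulary sizes (8 MF / 11 BP / 3 CC) mirror the
coarse Panther protein-class vocabulary.

All randomness is driven by an explicit seed; no global RNG state is used.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .lcda import AlgorithmState, NodeState
from .netio import CATEGORIES, AnnotationMap

#: Default per-category vocabulary sizes (coarse Panther-like classes).
DEFAULT_TERMS = {"MF": 8, "BP": 11, "CC": 3}

_RETRY_CAP = 50


@dataclass
class SyntheticSpec:
    """Parameters of one planted-partition benchmark.

    ``sizes`` lists the node count of each planted community (each >= 3);
    ``p_in``/``p_out`` are intra/inter-community edge probabilities with
    0 <= p_out < p_in <= 1; ``annotation_noise`` is the per-term probability
    that a node's term is swapped for a foreign term of the same category.
    """

    sizes: Sequence[int] = (10, 10, 10, 10)
    p_in: float = 0.9
    p_out: float = 0.02
    terms_per_category: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TERMS)
    )
    annotation_noise: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.sizes or any(s < 3 for s in self.sizes):
            raise ValueError("every planted community needs >= 3 nodes")
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if not 0 <= self.annotation_noise <= 1:
            raise ValueError("annotation_noise must be in [0, 1]")
        for c in self.terms_per_category:
            if c not in CATEGORIES:
                raise ValueError(f"unknown GO category {c!r}")


@dataclass
class PlantedNetwork:
    """A generated benchmark: network + ground-truth partition + annotations."""

    network: nx.Graph
    truth: dict[str, set[str]]
    annotations: AnnotationMap
    spec: SyntheticSpec

    def term_sets(self) -> dict[str, frozenset[str]]:
        """Per-node union of terms over all categories (algorithm input)."""
        return {v: self.annotations.terms(v) for v in self.network.nodes}

    def truth_complexes(self) -> list[frozenset[str]]:
        return [frozenset(m) for m in self.truth.values()]


def _community_vocabulary(spec: SyntheticSpec) -> dict[str, list[set[str]]]:
    """Characteristic term subsets per category, one per community.

    Each category's vocabulary is dealt round-robin across communities, so
    the subsets are pairwise disjoint; a sparse category (fewer terms than
    communities) simply leaves some communities without a term there.  A
    community left with no term in *any* category — possible only when
    there are more communities than terms overall, the realistic regime for
    a coarse vocabulary shared by many complexes — wraps around the largest
    category and shares a term, because a fully unannotated community
    cannot be emulated meaningfully in GO mode.
    """
    n_comm = len(spec.sizes)
    vocab: dict[str, list[set[str]]] = {}
    for cat, n_terms in spec.terms_per_category.items():
        per_community: list[set[str]] = [set() for _ in range(n_comm)]
        for j in range(n_terms):
            per_community[j % n_comm].add(f"{cat}:{j:02d}")
        vocab[cat] = per_community
    if vocab:
        largest = max(vocab, key=lambda c: spec.terms_per_category[c])
        n_largest = spec.terms_per_category[largest]
        for i in range(n_comm):
            if n_largest and not any(vocab[cat][i] for cat in vocab):
                vocab[largest][i].add(f"{largest}:{i % n_largest:02d}")
    return vocab


def generate(spec: SyntheticSpec) -> PlantedNetwork:
    """Draw one planted-partition benchmark from ``spec``.

    Edges follow a stochastic block model; the draw is retried (with seeds
    derived from ``spec.seed``) until every planted community is internally
    connected, and fails after a bounded number of attempts — relevant only
    at low ``p_in``.  Identical specs produce identical outputs.
    """
    spec.validate()
    master = random.Random(spec.seed)
    for _ in range(_RETRY_CAP):
        sbm_seed = master.randrange(2**31)
        graph = _draw_sbm(spec, sbm_seed)
        blocks = _blocks(spec)
        if all(
            nx.is_connected(graph.subgraph(block)) for block in blocks
        ):
            break
    else:
        raise RuntimeError(
            f"no draw with internally connected communities in "
            f"{_RETRY_CAP} attempts; increase p_in"
        )

    truth = {min(block): set(block) for block in blocks}
    annotations = _annotate(spec, blocks, master.randrange(2**31))
    return PlantedNetwork(
        network=graph, truth=truth, annotations=annotations, spec=spec
    )


def _blocks(spec: SyntheticSpec) -> list[list[str]]:
    blocks: list[list[str]] = []
    offset = 0
    for size in spec.sizes:
        blocks.append([f"n{offset + i:04d}" for i in range(size)])
        offset += size
    return blocks


def _draw_sbm(spec: SyntheticSpec, seed: int) -> nx.Graph:
    n_comm = len(spec.sizes)
    probs = [
        [spec.p_in if i == j else spec.p_out for j in range(n_comm)]
        for i in range(n_comm)
    ]
    raw = nx.stochastic_block_model(list(spec.sizes), probs, seed=seed)
    mapping = {i: f"n{i:04d}" for i in raw.nodes}
    graph = nx.Graph()
    graph.add_nodes_from(mapping.values())
    graph.add_edges_from((mapping[a], mapping[b]) for a, b in raw.edges)
    return graph


def _annotate(
    spec: SyntheticSpec, blocks: list[list[str]], seed: int
) -> AnnotationMap:
    rng = random.Random(seed)
    vocab = _community_vocabulary(spec)
    ann = AnnotationMap()
    for ci, block in enumerate(blocks):
        for node in block:
            for cat, per_community in vocab.items():
                own = per_community[ci]
                foreign = sorted(
                    set().union(*per_community) - own
                )
                for term in sorted(own):
                    if (
                        foreign
                        and spec.annotation_noise > 0
                        and rng.random() < spec.annotation_noise
                    ):
                        term = rng.choice(foreign)
                    ann.add(node, term, cat)
    return ann


def perturb(
    planted: PlantedNetwork, rewire_fraction: float, seed: int
) -> PlantedNetwork:
    """Rewire a fraction of edges uniformly at random, keeping the graph
    simple and the edge count fixed; truth labels are unchanged.

    Emulates the unreliability of screened interaction maps: rewired edges
    are false positives/negatives relative to the planted structure.
    """
    if not 0 <= rewire_fraction <= 1:
        raise ValueError("rewire_fraction must be in [0, 1]")
    graph = planted.network.copy()
    if rewire_fraction == 0 or graph.number_of_edges() == 0:
        return PlantedNetwork(
            network=graph,
            truth={k: set(v) for k, v in planted.truth.items()},
            annotations=planted.annotations,
            spec=planted.spec,
        )
    rng = random.Random(seed)
    edges = sorted(tuple(sorted(e)) for e in graph.edges)
    n_rewire = round(rewire_fraction * len(edges))
    to_remove = rng.sample(edges, n_rewire)
    graph.remove_edges_from(to_remove)
    nodes = sorted(graph.nodes)
    added = 0
    while added < n_rewire:
        a, b = rng.sample(nodes, 2)
        if not graph.has_edge(a, b):
            graph.add_edge(a, b)
            added += 1
    return PlantedNetwork(
        network=graph,
        truth={k: set(v) for k, v in planted.truth.items()},
        annotations=planted.annotations,
        spec=planted.spec,
    )


def fig1_fixture() -> tuple[nx.Graph, AlgorithmState]:
    """The canonical one-node decision neighbourhood used in unit tests.

    Node ``v`` sees three labelled neighbours: ``c`` (community 'a', hop
    level 1) and ``d`` (community 'a', hop level 2) versus ``t`` (community
    'x', hop level 3).  The surrounding paths back to the sources 'a' and
    'x' are present in the graph but their nodes are unvisited, exactly as
    the local-knowledge model prescribes.  Expected behaviour: candidate
    community 'a' (2 links vs 1), μ(v, 'a') = 1/3, and the expansion rules
    move v into 'a' at hop level min(1, 2, 3) + 1 = 2.
    """
    graph = nx.Graph()
    graph.add_edges_from([
        ("v", "c"), ("v", "d"), ("v", "t"),      # the visible neighbourhood
        ("a", "c"), ("c", "d"),                   # community 'a' scaffolding
        ("x", "y"), ("y", "z"), ("z", "t"),       # community 'x' scaffolding
    ])
    state = AlgorithmState()
    shared = frozenset({"MF:00"})
    for node, cl, hl in [("v", "v", 4), ("c", "a", 1), ("d", "a", 2), ("t", "x", 3)]:
        state.states[node] = NodeState(
            cl=cl, hl=hl, g=shared, k=graph.degree(node)
        )
    state.R = ["c", "d", "t", "v"]
    return graph, state
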