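"""The LCDA-GO local community detection algorithm and its topology-only
variant LCDA.

Each node carries three pieces of local state: a community label ``cl`` (the
identifier of the community's source node), a hop-level ``hl`` (its hop
distance from that source; sources sit at hl = 1), and a GO-term set ``g``.
Nodes are discovered breadth-first from a start node and repeatedly revise
their label using only the states of their first neighbours:

* the community influence degree ``λ(v, c) = ln(k_v / hl_v) · |g_v ∩ G_c|``
  scores how strongly community ``c`` pulls on ``v`` through shared function
  (in topology-only mode the GO factor is dropped and λ = ln(k_v / hl_v));
* the local community modularity ``μ(v, c) = (E_in − E_out)/(E_in + E_out)``
  compares v's links into ``c`` against its links into every other labelled
  community;
* the expansion rules (LCER) let ``v`` join the best-connected candidate
  community when μ > 0, declare itself a source when its neighbours already
  carry its label, or otherwise follow the neighbour with the highest
  influence.

The sweep repeats until a full pass changes no label (or a hard iteration
cap is hit).  Everything is deterministic given the start node / seed: all
tie-breaks are explicit and no global RNG state is touched.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

MODE_GO = "go"
MODE_TOPOLOGY = "topology"

#: Default initial hop-level assigned to a freshly visited node; any value
#: greater than 1 works, the level is revised as sources emerge.
DEFAULT_HL = 4


class UndefinedCommunityError(ValueError):
    """Raised when a score is requested w.r.t. a community with no link to v."""


class NoLabeledNeighborsError(ValueError):
    """Raised when μ is requested for a node with no labelled neighbour."""


class DisconnectedNetworkError(ValueError):
    """`run` requires a single connected component; use `run_multi`."""


@dataclass
class NodeState:
    """Local state of one node: label, hop-level, GO terms, cached degree."""

    cl: str
    hl: int
    g: frozenset[str]
    k: int


@dataclass
class AlgorithmState:
    """Mutable algorithm state: per-node states, visit list and counters."""

    states: dict[str, NodeState] = field(default_factory=dict)
    R: list[str] = field(default_factory=list)
    t: int = 0
    HL: int = DEFAULT_HL
    converged: bool = False
    changes_last_sweep: int = -1
    #: total neighbour-state touches across all sweeps (cost proxy used by
    #: the scaling checks; one unit per neighbour per node visit).
    n_neighbor_reads: int = 0


# ---------------------------------------------------------------------------
# local scores
# ---------------------------------------------------------------------------

def community_influence(
    v: str,
    c: str,
    state: AlgorithmState,
    net: nx.Graph,
    mode: str = MODE_GO,
    intersection: str = "union",
) -> float:
    """Community influence degree λ of node ``v`` towards community ``c``.

    ``λ = ln(k_v / hl_v) · |g_v ∩ G_c|`` where ``G_c`` aggregates the term
    sets of v's neighbours labelled ``c``.  With ``intersection="union"``
    (default) ``G_c`` is the union of those term sets; the alternative
    ``"per-neighbor-sum"`` sums ``|g_v ∩ g_u|`` over the same neighbours.
    Topology-only mode returns the bare ``ln(k_v / hl_v)``, which is negative
    whenever hl exceeds the degree; negative values are legitimate and are
    simply out-competed during selection.
    """
    sv = state.states[v]
    members = [
        u for u in net[v]
        if u in state.states and state.states[u].cl == c
    ]
    if not members:
        raise UndefinedCommunityError(f"{v!r} has no neighbour labelled {c!r}")
    base = math.log(sv.k / sv.hl)
    if mode == MODE_TOPOLOGY:
        return base
    if intersection == "union":
        pooled: set[str] = set()
        for u in members:
            pooled |= state.states[u].g
        return base * len(sv.g & pooled)
    if intersection == "per-neighbor-sum":
        return base * sum(len(sv.g & state.states[u].g) for u in members)
    raise ValueError(f"unknown intersection semantics: {intersection!r}")


def local_modularity(v: str, c: str, state: AlgorithmState, net: nx.Graph) -> float:
    """Local community modularity μ = (E_in − E_out)/(E_in + E_out) ∈ [−1, 1].

    E_in counts v's links to neighbours labelled ``c``; E_out counts v's
    links to every other neighbour — other communities and still-unvisited
    nodes alike.  μ > 0 therefore certifies that a strict majority of v's
    whole neighbourhood already sits in ``c``.  Undefined (raises) when no
    neighbour carries a label at all.
    """
    e_in = 0
    labelled = 0
    for u in net[v]:
        su = state.states.get(u)
        if su is None:
            continue
        labelled += 1
        if su.cl == c:
            e_in += 1
    if labelled == 0:
        raise NoLabeledNeighborsError(f"{v!r} has no labelled neighbour")
    degree = net.degree(v)
    return (2 * e_in - degree) / degree


def candidate_community(v: str, state: AlgorithmState, net: nx.Graph) -> str | None:
    """Label of the community with the most links to ``v``; None if no
    neighbour is labelled yet.

    Ties are broken deterministically: first by the smaller minimum hop-level
    among the tied community's neighbours (the community whose members sit
    closer to their source wins), then by lexicographically smallest label.
    """
    links: dict[str, int] = {}
    min_hl: dict[str, int] = {}
    for u in net[v]:
        su = state.states.get(u)
        if su is None:
            continue
        links[su.cl] = links.get(su.cl, 0) + 1
        min_hl[su.cl] = min(min_hl.get(su.cl, su.hl), su.hl)
    if not links:
        return None
    return min(links, key=lambda c: (-links[c], min_hl[c], c))


def _follow_score(v: str, p: str, state: AlgorithmState, mode: str) -> float:
    """Influence a labelled neighbour ``p`` exerts on ``v``.

    Mirrors λ from p's side using only p's own state — ``ln(k_p / hl_p)``
    weighted (in GO mode) by the functions p shares with v — so the choice
    of which neighbour to follow stays strictly first-neighbour-local.
    """
    sp = state.states[p]
    base = math.log(sp.k / sp.hl)
    if mode == MODE_TOPOLOGY:
        return base
    return base * len(state.states[v].g & sp.g)


# ---------------------------------------------------------------------------
# expansion rules
# ---------------------------------------------------------------------------

def lcer(
    v: str,
    state: AlgorithmState,
    net: nx.Graph,
    mode: str = MODE_GO,
    intersection: str = "union",
    follow_hl_increment: bool = False,
) -> bool:
    """Apply the local community expansion rules to ``v``; return True iff
    v's label changed.

    With candidate community ``u`` (most links to v):

    * μ(v, u) > 0 — v joins u; its hop-level becomes the minimum hop-level
      among its labelled neighbours plus one;
    * μ ≤ 0 and v already carries label u — v's neighbours have elected it:
      v becomes a source (hl = 1);
    * otherwise v temporarily follows the labelled neighbour ``p`` with the
      highest influence, copying p's label and hop-level (``hl_p + 1`` when
      ``follow_hl_increment`` is on).  Following demands strictly positive
      influence: a neighbour sharing no function with v (GO mode) or sitting
      too far from its source relative to its degree exerts no pull, and a
      node with no positive-influence neighbour starts its own community
      instead — this is what stops expansion from leaking across functional
      boundaries.

    A node with no labelled neighbour initialises itself as its own source.
    """
    sv = state.states[v]
    old = sv.cl
    u = candidate_community(v, state, net)
    if u is None:
        sv.cl = v
        sv.hl = 1
        return sv.cl != old
    mu = local_modularity(v, u, state, net)
    if mu > 0:
        labelled_hl = [
            state.states[w].hl for w in net[v] if w in state.states
        ]
        sv.hl = min(labelled_hl) + 1
        sv.cl = u
    elif sv.cl == u:
        sv.hl = 1
    else:
        best: str | None = None
        best_score = 0.0  # only strictly positive influence can recruit v
        for w in sorted(net[v]):
            if w not in state.states:
                continue
            score = _follow_score(v, w, state, mode)
            if score > best_score:
                best, best_score = w, score
        if best is None:
            sv.cl = v
            sv.hl = 1
        else:
            sp = state.states[best]
            sv.cl = sp.cl
            sv.hl = sp.hl + (1 if follow_hl_increment else 0)
    return sv.cl != old


def degree_rule(v: str, state: AlgorithmState, net: nx.Graph) -> None:
    """Decrement v's hop-level (floored at 1) when its degree strictly
    exceeds every neighbour's — local degree maxima drift towards sources."""
    sv = state.states[v]
    if net.degree(v) == 0:
        return
    if sv.k > max(net.degree(u) for u in net[v]):
        sv.hl = max(1, sv.hl - 1)


def stop_condition(state: AlgorithmState, net: nx.Graph) -> int:
    """1 iff the visit list covers the whole component and the last sweep
    changed no community label; 0 otherwise."""
    return int(
        len(state.R) == net.number_of_nodes()
        and state.changes_last_sweep == 0
    )


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

def run(
    net: nx.Graph,
    term_sets: Mapping[str, Iterable[str]] | None = None,
    *,
    hl_init: int = DEFAULT_HL,
    start_node: str | None = None,
    seed: int | None = None,
    max_iter: int = 100,
    mode: str = MODE_GO,
    intersection: str = "union",
    follow_hl_increment: bool = False,
) -> tuple[dict[str, set[str]], AlgorithmState]:
    """Run LCDA-GO (or LCDA, ``mode="topology"``) on one connected component.

    Parameters
    ----------
    net:
        A connected simple graph with at least 3 nodes.  Disconnected input
        raises :class:`DisconnectedNetworkError` — split into components and
        use :func:`run_multi` instead.
    term_sets:
        Node → GO-term set, as produced by
        :func:`lcdago.netio.category_subnetwork`.  Ignored in topology mode.
    hl_init:
        Initial hop-level for freshly visited nodes (> 1).
    start_node, seed:
        The sweep starts from ``start_node`` if given, else from a
        seed-chosen random node, else from the lexicographically smallest
        node.  Node discovery is breadth-first in sorted neighbour order, so
        the whole run is reproducible.
    max_iter:
        Hard cap on outer sweeps; hitting it flags non-convergence on the
        returned state instead of looping forever.

    Returns
    -------
    (partition, state):
        ``partition`` maps each community's source-node label to its member
        set (disjoint cover of the component); ``state`` exposes per-node
        hop-levels, the sweep counter ``t`` and the convergence flag.
    """
    if mode not in (MODE_GO, MODE_TOPOLOGY):
        raise ValueError(f"unknown mode: {mode!r}")
    if hl_init < 2:
        raise ValueError("hl_init must be > 1")
    n = net.number_of_nodes()
    if n < 3:
        raise ValueError("component too small: need >= 3 nodes")
    if not nx.is_connected(net):
        raise DisconnectedNetworkError(
            "input has several connected components; run each separately "
            "(run_multi does this)"
        )
    term_sets = term_sets or {}

    if start_node is None:
        if seed is not None:
            start_node = random.Random(seed).choice(sorted(net.nodes))
        else:
            start_node = min(net.nodes)
    elif start_node not in net:
        raise ValueError(f"start node {start_node!r} not in network")

    state = AlgorithmState(HL=hl_init)
    in_r: set[str] = set()

    def visit(node: str) -> None:
        # lazy initialisation: a node entering R starts as its own community
        state.states[node] = NodeState(
            cl=node,
            hl=hl_init,
            g=frozenset(term_sets.get(node, ())),
            k=net.degree(node),
        )
        state.R.append(node)
        in_r.add(node)

    visit(start_node)

    for t in range(1, max_iter + 1):
        state.t = t
        changes = 0
        i = 0
        # R may grow while sweeping: newly discovered neighbours are
        # processed later in the same sweep (BFS discovery order).
        while i < len(state.R):
            v = state.R[i]
            state.n_neighbor_reads += net.degree(v)
            degree_rule(v, state, net)
            if lcer(
                v, state, net,
                mode=mode,
                intersection=intersection,
                follow_hl_increment=follow_hl_increment,
            ):
                changes += 1
            for u in sorted(net[v]):
                if u not in in_r:
                    visit(u)
            i += 1
        state.changes_last_sweep = changes
        if stop_condition(state, net):
            state.converged = True
            break

    if not state.converged:
        logger.warning(
            "no convergence after %d sweeps (%d label changes in last sweep)",
            state.t, state.changes_last_sweep,
        )

    partition = _build_partition(state)
    return partition, state


def _build_partition(state: AlgorithmState) -> dict[str, set[str]]:
    """Group nodes by final label and normalise source hop-levels.

    Each community is labelled by its source node, which by convention sits
    at hl = 1.  In the rare case a label's node has itself drifted into
    another community, the community is relabelled to its member closest to
    the old source (minimum hl, then lexicographic).
    """
    groups: dict[str, set[str]] = {}
    for node, ns in state.states.items():
        groups.setdefault(ns.cl, set()).add(node)
    partition: dict[str, set[str]] = {}
    for label, members in groups.items():
        if label not in members:
            label = min(members, key=lambda v: (state.states[v].hl, v))
            logger.debug("relabelled orphaned community to %r", label)
            for v in members:
                state.states[v].cl = label
        state.states[label].hl = 1
        partition[label] = members
    return partition


def run_multi(
    net: nx.Graph,
    term_sets: Mapping[str, Iterable[str]] | None = None,
    *,
    min_component_size: int = 3,
    seed: int | None = None,
    **kwargs,
) -> tuple[dict[str, set[str]], AlgorithmState]:
    """Run the algorithm independently on every connected component.

    Components below ``min_component_size`` nodes are dropped (they cannot
    form a community).  Per-component start seeds are derived from ``seed``;
    community labels are source-node identifiers and therefore globally
    unique.  Returns the union partition and a merged state (``t`` is the
    maximum sweep count over components, ``converged`` the conjunction).
    """
    components = sorted(nx.connected_components(net), key=min)
    rng = random.Random(seed) if seed is not None else None
    merged = AlgorithmState(HL=kwargs.get("hl_init", DEFAULT_HL), converged=True)
    partition: dict[str, set[str]] = {}
    n_skipped = 0
    for component in components:
        sub_seed = rng.randrange(2**31) if rng is not None else None
        if len(component) < min_component_size:
            n_skipped += 1
            continue
        sub = net.subgraph(component)
        part, st = run(sub, term_sets, seed=sub_seed, **kwargs)
        partition.update(part)
        merged.states.update(st.states)
        merged.R.extend(st.R)
        merged.t = max(merged.t, st.t)
        merged.converged = merged.converged and st.converged
        merged.n_neighbor_reads += st.n_neighbor_reads
    if n_skipped:
        logger.info(
            "skipped %d component(s) below %d nodes", n_skipped, min_component_size
        )
    if not partition:
        logger.warning("no component of size >= %d: empty partition", min_component_size)
        merged.converged = True
    return partition, merged
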