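import math
import random

import networkx as nx
import pytest

from lcdago import lcda
from lcdago.lcda import AlgorithmState, NodeState

from oracles import brute_lambda, brute_mu


def make_state(net, entries):
    """entries: node -> (cl, hl, terms)."""
    state = AlgorithmState()
    for node, (cl, hl, terms) in entries.items():
        state.states[node] = NodeState(
            cl=cl, hl=hl, g=frozenset(terms), k=net.degree(node)
        )
    return state


class TestCommunityInfluence:
    def setup_method(self):
        # star around v: u1,u2 in community c1 carry terms overlapping g(v)
        self.net = nx.star_graph(["v", "u1", "u2", "u3", "u4"])
        self.state = make_state(self.net, {
            "v": ("v", 2, {"a", "b", "c", "d"}),
            "u1": ("c1", 1, {"a", "b"}),
            "u2": ("c1", 2, {"a", "c"}),
            "u3": ("x", 1, {"z"}),
        })

    def test_go_mode_direct_evaluation(self):
        # k_v=4, hl_v=2, |g_v ∩ (g_u1 ∪ g_u2)| = |{a,b,c}| = 3
        got = lcda.community_influence("v", "c1", self.state, self.net)
        assert got == pytest.approx(3 * math.log(2))

    def test_zero_shared_terms_is_zero(self):
        assert lcda.community_influence("v", "x", self.state, self.net) == 0.0

    def test_degree_equal_hop_level_is_zero(self):
        self.state.states["v"].hl = 4
        assert lcda.community_influence("v", "c1", self.state, self.net) == 0.0

    def test_topology_mode_is_bare_log_ratio(self):
        got = lcda.community_influence(
            "v", "c1", self.state, self.net, mode=lcda.MODE_TOPOLOGY
        )
        assert got == pytest.approx(math.log(4 / 2))

    def test_negative_when_hop_level_exceeds_degree(self):
        self.state.states["v"].hl = 8
        got = lcda.community_influence(
            "v", "c1", self.state, self.net, mode=lcda.MODE_TOPOLOGY
        )
        assert got < 0

    def test_per_neighbor_sum_semantics(self):
        got = lcda.community_influence(
            "v", "c1", self.state, self.net, intersection="per-neighbor-sum"
        )
        # |g_v ∩ g_u1| + |g_v ∩ g_u2| = 2 + 2
        assert got == pytest.approx(4 * math.log(2))

    def test_unknown_community_is_error(self):
        with pytest.raises(lcda.UndefinedCommunityError):
            lcda.community_influence("v", "nowhere", self.state, self.net)


class TestLocalModularity:
    def test_fig1_configuration(self, fig1):
        net, state = fig1
        assert lcda.local_modularity("v", "a", state, net) == pytest.approx(1 / 3)

    def test_all_neighbours_in_community(self, fig1):
        net, state = fig1
        state.states["t"].cl = "a"
        assert lcda.local_modularity("v", "a", state, net) == 1.0

    def test_no_link_to_community(self, fig1):
        net, state = fig1
        assert lcda.local_modularity("v", "x", state, net) == pytest.approx(-1 / 3)
        state.states["t"].cl = "a"
        assert lcda.local_modularity("v", "x", state, net) == -1.0

    def test_unvisited_neighbours_count_against(self):
        # frontier node: one labelled neighbour, two unvisited
        net = nx.star_graph(["v", "u1", "u2", "u3"])
        state = make_state(net, {"u1": ("c1", 1, set())})
        assert lcda.local_modularity("v", "c1", state, net) == pytest.approx(-1 / 3)

    def test_no_labelled_neighbour_is_undefined(self):
        net = nx.Graph([("v", "w")])
        state = make_state(net, {"v": ("v", 1, set())})
        with pytest.raises(lcda.NoLabeledNeighborsError):
            lcda.local_modularity("v", "c1", state, net)


class TestCandidateCommunity:
    def test_fig1_majority(self, fig1):
        net, state = fig1
        assert lcda.candidate_community("v", state, net) == "a"

    def test_tie_broken_by_min_neighbour_hop_level(self):
        net = nx.Graph([("v", "n1"), ("v", "n2")])
        state = make_state(net, {
            "n1": ("a", 1, set()),
            "n2": ("x", 3, set()),
        })
        assert lcda.candidate_community("v", state, net) == "a"

    def test_full_tie_broken_lexicographically(self):
        net = nx.Graph([("v", "n1"), ("v", "n2")])
        state = make_state(net, {
            "n1": ("x", 2, set()),
            "n2": ("a", 2, set()),
        })
        assert lcda.candidate_community("v", state, net) == "a"

    def test_no_labelled_neighbours_gives_none(self):
        net = nx.Graph([("v", "w")])
        state = AlgorithmState()
        assert lcda.candidate_community("v", state, net) is None


class TestLcer:
    def test_positive_modularity_joins_candidate(self, fig1):
        net, state = fig1
        changed = lcda.lcer("v", state, net)
        assert changed
        assert state.states["v"].cl == "a"
        assert state.states["v"].hl == 2  # min(1, 2, 3) + 1

    def test_elected_source_resets_hop_level(self):
        # v's own label is the candidate: neighbours elected v
        net = nx.star_graph(["v", "n1", "n2", "n3", "n4"])
        state = make_state(net, {
            "v": ("v", 4, {"a"}),
            "n1": ("v", 2, {"a"}),
            "n2": ("v", 2, {"a"}),
            "n3": ("x", 1, {"a"}),
        })  # mu = (2*2 - 4)/4 = 0
        lcda.lcer("v", state, net)
        assert state.states["v"].cl == "v"
        assert state.states["v"].hl == 1

    @staticmethod
    def _follow_net():
        # mu(v, 'x') = (2·1 − 4)/4 < 0 and v is not its own candidate;
        # n1 (community 'x', hl 3, degree 4) shares a function with v and
        # is the only neighbour with positive influence.
        net = nx.Graph([
            ("v", "n1"), ("v", "n2"), ("v", "n3"), ("v", "n4"),
            ("n1", "m1"), ("n1", "m2"), ("n1", "m3"),
        ])
        state = make_state(net, {
            "v": ("v", 4, {"a"}),
            "n1": ("x", 3, {"a"}),
            "n2": ("y", 4, set()),
        })
        return net, state

    def test_follow_best_neighbour_copies_state(self):
        net, state = self._follow_net()
        lcda.lcer("v", state, net)
        assert state.states["v"].cl == "x"
        assert state.states["v"].hl == 3

    def test_follow_hl_increment_variant(self):
        net, state = self._follow_net()
        lcda.lcer("v", state, net, follow_hl_increment=True)
        assert state.states["v"].hl == 4

    def test_no_positive_influence_starts_new_community(self):
        # only labelled neighbour shares no function: v seeds its own source
        net = nx.star_graph(["v", "n1", "n2", "n3"])
        state = make_state(net, {
            "v": ("q", 4, {"a"}),
            "n1": ("x", 1, {"z"}),
        })
        lcda.lcer("v", state, net)
        assert state.states["v"].cl == "v"
        assert state.states["v"].hl == 1

    def test_no_labelled_neighbour_becomes_own_source(self):
        net = nx.Graph([("v", "w"), ("w", "u")])
        state = make_state(net, {"v": ("v", 4, set())})
        lcda.lcer("v", state, net)
        assert state.states["v"].cl == "v"
        assert state.states["v"].hl == 1


class TestDegreeRule:
    def test_local_degree_maximum_decrements(self):
        net = nx.star_graph(["v", "a", "b", "c", "d", "e"])
        net.add_edge("a", "b")
        state = make_state(net, {"v": ("v", 4, set())})
        lcda.degree_rule("v", state, net)
        assert state.states["v"].hl == 3

    def test_equal_degree_leaves_hop_level(self, triangle):
        state = make_state(triangle, {"A": ("A", 4, set())})
        lcda.degree_rule("A", state, triangle)
        assert state.states["A"].hl == 4

    def test_floored_at_one(self):
        net = nx.star_graph(["v", "a", "b"])
        state = make_state(net, {"v": ("v", 1, set())})
        lcda.degree_rule("v", state, net)
        assert state.states["v"].hl == 1


class TestStopCondition:
    def test_full_coverage_and_no_changes(self, triangle):
        state = make_state(triangle, {n: (n, 1, set()) for n in triangle})
        state.R = list(triangle.nodes)
        state.changes_last_sweep = 0
        assert lcda.stop_condition(state, triangle) == 1

    def test_incomplete_coverage(self, triangle):
        state = make_state(triangle, {"A": ("A", 1, set())})
        state.R = ["A"]
        state.changes_last_sweep = 0
        assert lcda.stop_condition(state, triangle) == 0

    def test_label_change_blocks_stop(self, triangle):
        state = make_state(triangle, {n: (n, 1, set()) for n in triangle})
        state.R = list(triangle.nodes)
        state.changes_last_sweep = 1
        assert lcda.stop_condition(state, triangle) == 0


class TestRun:
    def test_triangle_single_community(self, triangle):
        partition, state = lcda.run(triangle, mode=lcda.MODE_TOPOLOGY)
        assert list(partition.values()) == [{"A", "B", "C"}]
        assert state.converged

    def test_two_cliques_with_distinct_functions_split(self, two_cliques):
        net, terms = two_cliques
        partition, state = lcda.run(net, terms, mode=lcda.MODE_GO)
        communities = {frozenset(m) for m in partition.values()}
        assert communities == {
            frozenset({"a1", "a2", "a3", "a4"}),
            frozenset({"b1", "b2", "b3", "b4"}),
        }
        for label in partition:
            assert state.states[label].hl == 1

    def test_determinism_same_seed_same_partition(self, two_cliques):
        net, terms = two_cliques
        p1, _ = lcda.run(net, terms, seed=11)
        p2, _ = lcda.run(net, terms, seed=11)
        assert p1 == p2

    def test_disconnected_input_rejected(self, triangle):
        net = triangle.copy()
        net.add_edges_from([("X", "Y"), ("Y", "Z"), ("X", "Z")])
        with pytest.raises(lcda.DisconnectedNetworkError):
            lcda.run(net)

    def test_too_small_component_rejected(self):
        with pytest.raises(ValueError):
            lcda.run(nx.Graph([("A", "B")]))

    def test_partition_invariants_hold(self, two_cliques):
        net, terms = two_cliques
        partition, state = lcda.run(net, terms)
        members = [m for m in partition.values()]
        covered = set().union(*members)
        assert covered == set(net.nodes)
        assert sum(len(m) for m in members) == len(covered)  # disjoint
        for label, group in partition.items():
            assert label in group
            assert state.states[label].hl == 1
        assert all(s.hl >= 1 for s in state.states.values())


class TestRunMulti:
    def test_two_disjoint_triangles(self, triangle):
        net = triangle.copy()
        net.add_edges_from([("X", "Y"), ("Y", "Z"), ("X", "Z")])
        partition, _ = lcda.run_multi(net, mode=lcda.MODE_TOPOLOGY)
        assert {frozenset(m) for m in partition.values()} == {
            frozenset({"A", "B", "C"}),
            frozenset({"X", "Y", "Z"}),
        }

    def test_single_component_matches_run(self, triangle):
        p1, _ = lcda.run(triangle, mode=lcda.MODE_TOPOLOGY)
        p2, _ = lcda.run_multi(triangle, mode=lcda.MODE_TOPOLOGY)
        assert p1 == p2

    def test_all_components_too_small_gives_empty_partition(self):
        net = nx.Graph([("A", "B"), ("C", "D")])
        partition, state = lcda.run_multi(net)
        assert partition == {}
        assert state.converged


class TestOracleEquivalence:
    """λ and μ agree with brute-force recomputation from the raw edge list
    on exhaustive random configurations of up to 12 nodes."""

    def test_scores_match_brute_force(self):
        rng = random.Random(42)
        for trial in range(30):
            n = rng.randint(4, 12)
            net = nx.gnp_random_graph(n, 0.5, seed=rng.randrange(10**6))
            net = nx.relabel_nodes(net, {i: f"p{i}" for i in net.nodes})
            labels = {v: rng.choice(["c1", "c2", "c3"]) for v in net.nodes}
            hls = {v: rng.randint(1, 5) for v in net.nodes}
            terms = {
                v: frozenset(rng.sample(["a", "b", "c", "d", "e"], rng.randint(0, 4)))
                for v in net.nodes
            }
            state = AlgorithmState()
            for v in net.nodes:
                state.states[v] = NodeState(
                    cl=labels[v], hl=hls[v], g=terms[v], k=net.degree(v)
                )
            edges = list(net.edges)
            degrees = dict(net.degree)
            for v in net.nodes:
                if net.degree(v) == 0:
                    continue
                for c in ("c1", "c2", "c3"):
                    has_member = any(labels[u] == c for u in net[v])
                    if not has_member:
                        continue
                    got = lcda.community_influence(v, c, state, net)
                    want = brute_lambda(edges, degrees, labels, hls, terms, v, c)
                    assert got == pytest.approx(want)
                    got_mu = lcda.local_modularity(v, c, state, net)
                    want_mu = brute_mu(edges, labels, v, c)
                    assert got_mu == pytest.approx(want_mu)
                    assert -1 <= got_mu <= 1


class _TrackingDict(dict):
    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        self.reads = set()

    def __getitem__(self, key):
        self.reads.add(key)
        return super().__getitem__(key)

    def get(self, key, default=None):
        self.reads.add(key)
        return super().get(key, default)


class TestLocality:
    def test_decision_reads_only_first_neighbour_states(self, two_cliques):
        net, terms = two_cliques
        state = make_state(net, {n: (n, 3, terms[n]) for n in net.nodes})
        tracker = _TrackingDict(state.states)
        state.states = tracker
        v = "a2"
        lcda.degree_rule(v, state, net)
        lcda.candidate_community(v, state, net)
        lcda.local_modularity(v, "a1", state, net)
        lcda.lcer(v, state, net)
        allowed = set(net[v]) | {v}
        assert tracker.reads <= allowed


class TestScaling:
    def test_sweep_cost_grows_subquadratically(self):
        from lcdago import SyntheticSpec, generate

        reads = {}
        for n in (250, 1000):
            planted = generate(
                SyntheticSpec(sizes=(10,) * (n // 10), p_in=0.9, p_out=3.0 / n, seed=1)
            )
            _, state = lcda.run_multi(planted.network, planted.term_sets(), seed=1)
            reads[n] = state.n_neighbor_reads
        ratio = reads[1000] / reads[250]
        assert ratio < 4**1.5  # quadratic growth would give ~16
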