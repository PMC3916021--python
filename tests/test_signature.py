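"""Subnetwork extraction, hub detection, Algorithm-style selection and
signature assembly."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rrhge import (
    GeneSignature,
    SubnetworkList,
    assemble_signature,
    build_subnetwork_list,
    compare_signatures,
    extract_subnetworks,
    find_hub_genes,
    hub_score,
    subnetwork_score,
)


def edge_frame(edges):
    return pd.DataFrame(
        [(a, b, t) for a, b, t in edges],
        columns=["gene_a", "gene_b", "theta"],
    )


def dfs_components(edges):
    """Independent depth-first labelling oracle."""
    adjacency = {}
    for a, b, _ in edges:
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
    seen, components = set(), []
    for start in adjacency:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            stack.extend(adjacency[node] - comp)
        seen |= comp
        components.append(frozenset(comp))
    return set(components)


class TestExtractSubnetworks:
    def test_components_of_toy_graph(self):
        subs = extract_subnetworks(
            edge_frame([("a", "b", 1.0), ("b", "c", 1.0), ("d", "e", 1.0)])
        )
        assert {s.genes for s in subs} == {frozenset("abc"), frozenset("de")}

    def test_empty_edges_give_no_subnetworks(self):
        assert extract_subnetworks(edge_frame([])) == []

    def test_matches_dfs_oracle_on_random_graphs(self, rng):
        for _ in range(20):
            n_edges = int(rng.integers(1, 100))
            edges = [
                (f"g{rng.integers(40)}", f"g{rng.integers(40)}", float(rng.uniform()))
                for _ in range(n_edges)
            ]
            edges = [(a, b, t) for a, b, t in edges if a != b]
            if not edges:
                continue
            subs = extract_subnetworks(edge_frame(edges))
            assert {s.genes for s in subs} == dfs_components(edges)
            covered = set().union(*({*s.genes} for s in subs))
            assert covered == {g for a, b, _ in edges for g in (a, b)}


class TestHubGenes:
    def test_star_centre(self):
        g = nx.star_graph(4)
        assert find_hub_genes(g) == {0}

    def test_path_midpoint(self):
        g = nx.path_graph(["a", "b", "c"])
        assert find_hub_genes(g) == {"b"}

    def test_cycle_all_tied(self):
        # every gene attains the maximal, equal interaction count
        g = nx.cycle_graph(["a", "b", "c", "d"])
        assert find_hub_genes(g) == {"a", "b", "c", "d"}

    def test_hubs_attain_max_degree_on_random_graphs(self, rng):
        for _ in range(20):
            g = nx.gnp_random_graph(15, 0.25, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            hubs = find_hub_genes(g)
            top = max(dict(g.degree()).values())
            assert hubs == {n for n, d in g.degree() if d == top}


class TestScores:
    def test_lambda_is_exact_theta_sum(self):
        assert subnetwork_score([0.2, 0.3, 0.5]) == pytest.approx(1.0)
        assert subnetwork_score([0.7]) == pytest.approx(0.7)

    def test_lambda_permutation_invariant(self, rng):
        thetas = list(rng.uniform(size=30))
        shuffled = list(thetas)
        rng.shuffle(shuffled)
        assert subnetwork_score(thetas) == pytest.approx(subnetwork_score(shuffled))

    def test_hub_score_is_mean_incident_theta(self):
        g = nx.Graph()
        g.add_edge("h", "x", theta=0.4)
        g.add_edge("h", "y", theta=0.6)
        assert hub_score(g, "h") == pytest.approx(0.5)
        g2 = nx.Graph()
        g2.add_edge("h", "x", theta=0.9)
        assert hub_score(g2, "h") == pytest.approx(0.9)

    def test_tied_hubs_take_max_chi(self):
        # path of 4: b and c both have degree 2; their incident means differ
        subs = extract_subnetworks(
            edge_frame([("a", "b", 0.1), ("b", "c", 0.5), ("c", "d", 0.9)])
        )
        (sub,) = subs
        assert sub.hub_genes == {"b", "c"}
        assert sub.hub_chi["b"] == pytest.approx(0.3)
        assert sub.hub_chi["c"] == pytest.approx(0.7)
        assert sub.chi == pytest.approx(0.7)


class TestSubnetworkListSelection:
    def test_qualifying_hub_neighbourhoods_added(self):
        # C1: max lambda, chi 0.5; C2: chi 0.8 qualifies; C3: chi 0.3 does not
        c1 = edge_frame([("a", "b", 1.0), ("b", "c", 1.0)])  # lam=2.0, hub b chi=1.0
        # tune thetas so chosen chi is 0.5: star hub with incident 0.5, 0.5
        c1 = edge_frame([("a", "b", 0.5), ("b", "c", 0.5), ("b", "d", 0.5),
                         ("a", "c", 0.5)])
        c2 = edge_frame([("p", "q", 0.8), ("q", "r", 0.8)])  # lam=1.6, hub q chi=0.8
        c3 = edge_frame([("x", "y", 0.3)])                   # lam=0.3, chi=0.3
        subs = extract_subnetworks(pd.concat([c1, c2, c3], ignore_index=True))
        chosen = max(subs, key=lambda s: s.lam)
        assert chosen.genes == frozenset("abcd")
        assert chosen.chi == pytest.approx(0.5)
        lst = build_subnetwork_list(subs, ("pos", 1))
        assert lst.genes == set("abcd") | {"p", "q", "r"}
        assert lst.provenance["q"] == {"hub_neighbourhood"}
        assert "x" not in lst.genes and "y" not in lst.genes
        assert all(lst.provenance[g] for g in lst.genes)

    def test_single_component_taken_whole(self):
        subs = extract_subnetworks(edge_frame([("a", "b", 0.4)]))
        lst = build_subnetwork_list(subs, ("pos", 2))
        assert lst.genes == {"a", "b"}
        assert lst.provenance["a"] == {"top_subnetwork"}

    def test_lambda_tie_break_deterministic(self):
        # equal lambda; the larger component wins
        big = edge_frame([("a", "b", 0.5), ("b", "c", 0.5)])
        small = edge_frame([("x", "y", 1.0)])
        subs = extract_subnetworks(pd.concat([big, small], ignore_index=True))
        lst = build_subnetwork_list(subs, ("neg", 1))
        assert {"a", "b", "c"} <= lst.genes

    def test_empty_list_warns(self):
        with pytest.warns(UserWarning, match="no subnetworks"):
            lst = build_subnetwork_list([], ("neg", 2))
        assert lst.genes == set()

    def test_top_subnetwork_genes_always_included(self, rng):
        for _ in range(10):
            edges = [
                (f"g{rng.integers(30)}", f"g{rng.integers(30)}", float(rng.uniform()))
                for _ in range(40)
            ]
            edges = [(a, b, t) for a, b, t in edges if a != b]
            subs = extract_subnetworks(edge_frame(edges))
            if not subs:
                continue
            best = max(subs, key=lambda s: (s.lam, len(s.genes)))
            lst = build_subnetwork_list(subs, ("pos", 3))
            assert best.genes <= lst.genes


def make_lists(pos_sets, neg_sets):
    out = {}
    for grade, genes in enumerate(pos_sets, start=1):
        lst = SubnetworkList(("pos", grade))
        for g in genes:
            lst.add(g, "top_subnetwork")
        out[("pos", grade)] = lst
    for grade, genes in enumerate(neg_sets, start=1):
        lst = SubnetworkList(("neg", grade))
        for g in genes:
            lst.add(g, "top_subnetwork")
        out[("neg", grade)] = lst
    return out


class TestAssembleSignature:
    def test_worked_intersection_and_cross_removal(self):
        lists = make_lists(
            [{"A", "B", "C"}, {"B", "C", "D"}, {"B", "C"}],
            [{"C", "E"}, {"C", "E", "F"}, {"C", "E"}],
        )
        sig = assemble_signature(lists)
        assert sig.er_pos_genes == {"B"}
        assert sig.er_neg_genes == {"E"}

    def test_identical_commons_rejected(self):
        lists = make_lists([{"A"}] * 3, [{"A"}] * 3)
        with pytest.raises(ValueError, match="no signature"):
            assemble_signature(lists)

    def test_two_of_three_threshold(self):
        lists = make_lists(
            [{"A", "B"}, {"B", "C"}, {"C"}],
            [{"Z"}, {"Z"}, {"Z"}],
        )
        sig = assemble_signature(lists, common_threshold=2)
        assert sig.er_pos_genes == {"B", "C"}

    def test_disjointness_on_random_inputs(self, rng):
        universe = [f"g{i}" for i in range(30)]
        for _ in range(20):
            pos = [set(rng.choice(universe, size=10, replace=False)) for _ in range(3)]
            neg = [set(rng.choice(universe, size=10, replace=False)) for _ in range(3)]
            try:
                sig = assemble_signature(make_lists(pos, neg), common_threshold=1)
            except ValueError:
                continue
            assert not (sig.er_pos_genes & sig.er_neg_genes)

    def test_signature_type_enforces_disjointness(self):
        with pytest.raises(ValueError, match="disjoint"):
            GeneSignature(frozenset("ab"), frozenset("bc"))


class TestCompareSignatures:
    @pytest.mark.parametrize(
        "sig1, sig2, count, pct",
        [({"A", "B", "C"}, {"B", "C", "D"}, 2, pytest.approx(66.67, abs=0.01)),
         ({"A"}, {"B"}, 0, 0.0)],
    )
    def test_overlap_counts(self, sig1, sig2, count, pct):
        assert compare_signatures(sig1, sig2) == (count, pct)

    def test_overlap_percentage_at_published_scale(self):
        # 175 shared genes out of a 471-gene signature
        sig1 = {f"g{i}" for i in range(471)}
        sig2 = {f"g{i}" for i in range(175)} | {f"x{i}" for i in range(50)}
        count, pct = compare_signatures(sig1, sig2)
        assert count == 175
        assert pct == pytest.approx(37.16, abs=0.01)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compare_signatures(set(), {"A"})
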