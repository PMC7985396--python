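from itertools import combinations

import numpy as np
import pytest

from scalenet.projections import (
    PROJECTION_KINDS,
    Construction,
    Scope,
    build_projection,
    degree_sequence,
    expand_dataset,
    largest_connected_component,
)
from scalenet.reactions import Reaction, ReactionDataset

from conftest import random_small_dataset


def brute_force_edges(dataset, construction):
    """Independent oracle: double loop over all pairs, testing the membership
    predicate each construction rule states."""
    construction = Construction(construction)
    compounds = sorted(dataset.compounds)
    rxns = dataset.reactions
    edges = set()
    if construction is Construction.BI_FULL:
        for c in compounds:
            for r in rxns:
                if c in (r.substrates | r.products):
                    edges.add(frozenset((c, r.reaction_id)))
    elif construction is Construction.UNI_COMPOUNDS:
        for c1, c2 in combinations(compounds, 2):
            if any(c1 in r.compounds and c2 in r.compounds for r in rxns):
                edges.add(frozenset((c1, c2)))
    elif construction is Construction.UNI_REACTIONS:
        for r1, r2 in combinations(rxns, 2):
            if r1.compounds & r2.compounds:
                edges.add(frozenset((r1.reaction_id, r2.reaction_id)))
    else:  # substrates on the same side stay unconnected
        for c1, c2 in combinations(compounds, 2):
            if any((c1 in r.substrates and c2 in r.products)
                   or (c2 in r.substrates and c1 in r.products) for r in rxns):
                edges.add(frozenset((c1, c2)))
    return edges


class TestToyProjections:
    """Hand-enumerated projections of R1: {A,B}->{C}; R2: {C}->{D,E}."""

    expected = {
        Construction.BI_FULL: (7, {("A", "R1"), ("B", "R1"), ("C", "R1"),
                                   ("C", "R2"), ("D", "R2"), ("E", "R2")}),
        Construction.UNI_COMPOUNDS: (5, {("A", "B"), ("A", "C"), ("B", "C"),
                                         ("C", "D"), ("C", "E"), ("D", "E")}),
        Construction.UNI_REACTIONS: (2, {("R1", "R2")}),
        Construction.UNI_SUBS_NOT_CONNECTED: (5, {("A", "C"), ("B", "C"),
                                                  ("C", "D"), ("C", "E")}),
    }

    @pytest.mark.parametrize("construction", list(Construction))
    def test_nodes_and_edges(self, toy_dataset, construction):
        proj = build_projection(toy_dataset, construction)
        n_nodes, edges = self.expected[construction]
        assert proj.n_nodes == n_nodes
        got = {tuple(sorted(e)) for e in proj.graph.edges()}
        assert got == edges

    def test_degree_sequences(self, toy_dataset):
        bi = build_projection(toy_dataset, Construction.BI_FULL)
        assert sorted(degree_sequence(bi).degrees) == [1, 1, 1, 1, 2, 3, 3]
        uc = build_projection(toy_dataset, Construction.UNI_COMPOUNDS)
        assert sorted(degree_sequence(uc).degrees) == [2, 2, 2, 2, 4]


def test_bipartite_edges_join_roles(toy_dataset):
    proj = build_projection(toy_dataset, Construction.BI_FULL)
    roles = proj.node_roles()
    for u, v in proj.graph.edges():
        assert {roles[u], roles[v]} == {"compound", "reaction"}


def test_self_loop_excluded_for_both_sides_compound():
    ds = ReactionDataset("d", "individual",
                         [Reaction("R1", {"A", "B"}, {"A", "C"})])
    for construction in Construction:
        proj = build_projection(ds, construction)
        assert all(u != v for u, v in proj.graph.edges())
    uns = build_projection(ds, Construction.UNI_SUBS_NOT_CONNECTED)
    got = {tuple(sorted(e)) for e in uns.graph.edges()}
    assert got == {("A", "B"), ("A", "C"), ("B", "C")}  # no A-A


def test_parallel_edges_collapse():
    ds = ReactionDataset("d", "individual", [
        Reaction("R1", {"A", "B"}, {"C"}),
        Reaction("R2", {"A", "B"}, {"D"}),  # shares two compounds with R1
    ])
    proj = build_projection(ds, Construction.UNI_REACTIONS)
    assert proj.n_edges == 1


class TestLCC:
    def test_connected_graph_unchanged_except_scope(self, toy_dataset):
        proj = build_projection(toy_dataset, Construction.UNI_COMPOUNDS)
        lcc = largest_connected_component(proj)
        assert lcc.kind.scope is Scope.LARGEST
        assert set(lcc.graph.nodes()) == set(proj.graph.nodes())
        assert set(lcc.graph.edges()) == set(proj.graph.edges())

    def test_picks_maximum_component(self):
        ds = ReactionDataset("d", "individual", [
            Reaction("R1", {"A", "B"}, {"C"}),   # 3-compound component
            Reaction("R2", {"X"}, {"Y"}),        # 2-compound component
        ])
        proj = build_projection(ds, Construction.UNI_COMPOUNDS)
        lcc = largest_connected_component(proj)
        assert set(lcc.graph.nodes()) == {"A", "B", "C"}

    def test_tie_breaks_lexicographically(self):
        ds = ReactionDataset("d", "individual", [
            Reaction("R1", {"B"}, {"Z"}),
            Reaction("R2", {"A"}, {"Y"}),
        ])
        proj = build_projection(ds, Construction.UNI_COMPOUNDS)
        lcc = largest_connected_component(proj)
        assert set(lcc.graph.nodes()) == {"A", "Y"}

    def test_idempotent(self, toy_dataset):
        proj = build_projection(toy_dataset, Construction.BI_FULL)
        once = largest_connected_component(proj)
        twice = largest_connected_component(once)
        assert set(once.graph.nodes()) == set(twice.graph.nodes())
        assert set(once.graph.edges()) == set(twice.graph.edges())


class TestExpandDataset:
    def test_eight_entries_with_matching_lccs(self, toy_dataset):
        out = expand_dataset(toy_dataset)
        assert set(out) == set(PROJECTION_KINDS)
        for kind, (graph, degs) in out.items():
            assert graph.kind == kind
            assert degs.n == graph.n_nodes
            assert sum(degs.degrees) == 2 * graph.n_edges

    def test_disconnected_reactions(self):
        ds = ReactionDataset("d", "individual", [
            Reaction("R1", {"A"}, {"B"}), Reaction("R2", {"X"}, {"Y"}),
        ])
        out = expand_dataset(ds)
        entire = next(g for k, (g, _) in out.items()
                      if k.construction is Construction.UNI_REACTIONS
                      and k.scope is Scope.ENTIRE)
        lcc = next(g for k, (g, _) in out.items()
                   if k.construction is Construction.UNI_REACTIONS
                   and k.scope is Scope.LARGEST)
        assert entire.n_nodes == 2 and entire.n_edges == 0
        assert lcc.n_nodes == 1

    def test_min_degree_positive_in_lcc_with_edges(self, rng):
        for _ in range(10):
            ds = random_small_dataset(rng)
            for kind, (graph, degs) in expand_dataset(ds).items():
                if kind.scope is Scope.LARGEST and graph.n_edges >= 1:
                    assert min(degs.degrees) >= 1


class TestOracleEquivalence:
    @pytest.mark.parametrize("construction", list(Construction))
    def test_random_datasets_match_brute_force(self, rng, construction):
        for _ in range(40):
            ds = random_small_dataset(rng)
            proj = build_projection(ds, construction)
            got = {frozenset(e) for e in proj.graph.edges()}
            assert got == brute_force_edges(ds, construction)

    def test_node_counts(self, rng):
        for _ in range(20):
            ds = random_small_dataset(rng)
            ur = build_projection(ds, Construction.UNI_REACTIONS)
            assert ur.n_nodes == len(ds)
            bi = build_projection(ds, Construction.BI_FULL)
            assert bi.n_nodes == len(ds.compounds) + len(ds)

    def test_cross_side_edges_subset_of_same_reaction_edges(self, rng):
        for _ in range(20):
            ds = random_small_dataset(rng)
            sub = {frozenset(e) for e in build_projection(
                ds, Construction.UNI_SUBS_NOT_CONNECTED).graph.edges()}
            sup = {frozenset(e) for e in build_projection(
                ds, Construction.UNI_COMPOUNDS).graph.edges()}
            assert sub <= sup


def test_invariant_under_reaction_permutation(rng):
    for _ in range(10):
        ds = random_small_dataset(rng)
        perm = list(ds.reactions)
        rng.shuffle(perm)
        ds2 = ReactionDataset(ds.dataset_id, ds.level, perm)
        for construction in Construction:
            a = build_projection(ds, construction)
            b = build_projection(ds2, construction)
            assert set(a.graph.nodes()) == set(b.graph.nodes())
            assert ({frozenset(e) for e in a.graph.edges()}
                    == {frozenset(e) for e in b.graph.edges()})
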