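"""Eight network projections of a reaction dataset.

Starting from the natural bipartite picture — compound nodes wired to the
reaction nodes they participate in — a reaction set can be coarse-grained
into four simple-graph constructions:

* ``bi_full`` — the bipartite compound/reaction graph itself;
* ``uni_compounds`` — compounds linked when they appear in the same reaction
  (either side);
* ``uni_reactions`` — reactions linked when they share a compound;
* ``uni_subs_not_connected`` — compounds linked only when they sit on
  opposite sides of the same reaction (same-side co-substrates stay
  unconnected).

Each construction is taken both for the entire graph and for its largest
connected component (LCC), giving eight projections per dataset.  All graphs
are simple: no self-loops (a compound occurring on both sides of one reaction
contributes no self-edge) and no parallel edges (two reactions sharing two
compounds still yield a single edge).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations, product
from typing import Iterator

import networkx as nx
import numpy as np

from .reactions import ReactionDataset

__all__ = [
    "Construction",
    "Scope",
    "ProjectionKind",
    "PROJECTION_KINDS",
    "ProjectionGraph",
    "DegreeSequence",
    "build_projection",
    "largest_connected_component",
    "degree_sequence",
    "expand_dataset",
]


class Construction(str, Enum):
    BI_FULL = "bi_full"
    UNI_COMPOUNDS = "uni_compounds"
    UNI_REACTIONS = "uni_reactions"
    UNI_SUBS_NOT_CONNECTED = "uni_subs_not_connected"


class Scope(str, Enum):
    ENTIRE = "entire"
    LARGEST = "largest"


@dataclass(frozen=True)
class ProjectionKind:
    construction: Construction
    scope: Scope

    def __str__(self) -> str:  # e.g. "uni_compounds-largest"
        return f"{self.construction.value}-{self.scope.value}"


#: the eight projection kinds, in a stable order
PROJECTION_KINDS: tuple[ProjectionKind, ...] = tuple(
    ProjectionKind(c, s) for c, s in product(Construction, Scope)
)


@dataclass
class ProjectionGraph:
    """A simple undirected projection with node roles (compound/reaction)."""

    kind: ProjectionKind
    graph: nx.Graph  # node attribute "role" in {"compound", "reaction"}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def mean_degree(self) -> float:
        n = self.n_nodes
        return 2.0 * self.n_edges / n if n else 0.0

    def node_roles(self) -> dict[str, str]:
        return dict(self.graph.nodes(data="role"))


@dataclass(frozen=True)
class DegreeSequence:
    """Multiset of node degrees; the object every distribution fit consumes."""

    degrees: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.degrees):
            raise ValueError("degrees must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.degrees)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.degrees, dtype=np.int64)

    def positive(self) -> np.ndarray:
        a = self.as_array()
        return a[a > 0]


def _bipartite(dataset: ReactionDataset) -> nx.Graph:
    g = nx.Graph()
    for rxn in dataset.reactions:
        g.add_node(rxn.reaction_id, role="reaction")
        for c in rxn.compounds:
            g.add_node(c, role="compound")
            g.add_edge(c, rxn.reaction_id)
    return g


def _uni_compounds(dataset: ReactionDataset) -> nx.Graph:
    g = nx.Graph()
    for rxn in dataset.reactions:
        comps = sorted(rxn.compounds)
        g.add_nodes_from(comps, role="compound")
        g.add_edges_from(combinations(comps, 2))
    return g


def _uni_reactions(dataset: ReactionDataset) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from((r.reaction_id for r in dataset.reactions), role="reaction")
    by_compound: dict[str, list[str]] = {}
    for rxn in dataset.reactions:
        for c in rxn.compounds:
            by_compound.setdefault(c, []).append(rxn.reaction_id)
    for rids in by_compound.values():
        g.add_edges_from(combinations(sorted(set(rids)), 2))
    return g


def _uni_subs_not_connected(dataset: ReactionDataset) -> nx.Graph:
    g = nx.Graph()
    for rxn in dataset.reactions:
        g.add_nodes_from(rxn.compounds, role="compound")
        # cross-side pairs only; a compound on both sides never self-links
        g.add_edges_from(
            (s, p) for s in rxn.substrates for p in rxn.products if s != p
        )
    return g


_BUILDERS = {
    Construction.BI_FULL: _bipartite,
    Construction.UNI_COMPOUNDS: _uni_compounds,
    Construction.UNI_REACTIONS: _uni_reactions,
    Construction.UNI_SUBS_NOT_CONNECTED: _uni_subs_not_connected,
}


def build_projection(
    dataset: ReactionDataset, construction: Construction | str
) -> ProjectionGraph:
    """Build the entire-scope projection of *dataset* for one construction."""
    construction = Construction(construction)
    if len(dataset) == 0:
        raise ValueError("dataset has no reactions")
    graph = _BUILDERS[construction](dataset)
    return ProjectionGraph(ProjectionKind(construction, Scope.ENTIRE), graph)


def largest_connected_component(proj: ProjectionGraph) -> ProjectionGraph:
    """Node-induced subgraph on a maximum connected component.

    Ties between equally large components are broken deterministically toward
    the component containing the lexicographically smallest node id.
    """
    g = proj.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comps = list(nx.connected_components(g))
    max_size = max(len(c) for c in comps)
    winner = min((c for c in comps if len(c) == max_size), key=min)
    sub = g.subgraph(winner).copy()
    return ProjectionGraph(ProjectionKind(proj.kind.construction, Scope.LARGEST), sub)


def degree_sequence(proj: ProjectionGraph) -> DegreeSequence:
    """Per-node degrees, pooling both node classes of bipartite graphs."""
    return DegreeSequence(tuple(d for _, d in proj.graph.degree()))


def expand_dataset(
    dataset: ReactionDataset,
) -> dict[ProjectionKind, tuple[ProjectionGraph, DegreeSequence]]:
    """All eight projections of a dataset with their degree sequences."""
    out: dict[ProjectionKind, tuple[ProjectionGraph, DegreeSequence]] = {}
    for construction in Construction:
        entire = build_projection(dataset, construction)
        lcc = largest_connected_component(entire)
        out[entire.kind] = (entire, degree_sequence(entire))
        out[lcc.kind] = (lcc, degree_sequence(lcc))
    return out


def iter_edges(proj: ProjectionGraph) -> Iterator[tuple[str, str]]:
    for u, v in proj.graph.edges():
        yield (u, v) if str(u) <= str(v) else (v, u)


def to_edge_list(proj: ProjectionGraph) -> str:
    """Two-column edge-list text export (isolated nodes listed singly)."""
    lines = [f"{u}\t{v}" for u, v in sorted(iter_edges(proj))]
    isolated = sorted(n for n, d in proj.graph.degree() if d == 0)
    lines += [f"{n}" for n in isolated]
    return "\n".join(lines) + "\n"


def to_json_bundle(proj: ProjectionGraph) -> dict:
    return {
        "kind": str(proj.kind),
        "nodes": sorted(proj.graph.nodes()),
        "edges": sorted(iter_edges(proj)),
        "roles": {n: r for n, r in sorted(proj.graph.nodes(data="role"))},
    }
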