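"""Residue contact networks and hop-count shortest paths.

Each chain is treated as a self-contained system: two residues are
connected iff the distance between any pair of atoms, one from each
residue, is strictly smaller than the sum of their van der Waals radii
plus an extra threshold (default 2.0 Å).  Edges are unweighted and simple;
all downstream quantities (layers, DNSC, centralities) are defined on
hop-count shortest paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Mapping

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from catres.config import DEFAULT_VDW_RADIUS, VDW_RADII
from catres.structure_io import Structure, vdw_radius

#: shortest-path sentinel for vertices not reachable from the source
UNREACHABLE = float("inf")


@dataclass
class ContactNetwork:
    """Undirected simple graph over the residues of one chain.

    ``vertices`` preserves the chain's residue order; ``graph`` is the
    underlying :class:`networkx.Graph` (node labels = residue keys).
    """

    vertices: list[Hashable]
    graph: nx.Graph = field(repr=False)

    def __post_init__(self) -> None:
        assert set(self.vertices) == set(self.graph.nodes)

    @classmethod
    def from_edges(cls, vertices: Iterable[Hashable],
                   edges: Iterable[tuple[Hashable, Hashable]]) -> "ContactNetwork":
        vertices = list(vertices)
        g = nx.Graph()
        g.add_nodes_from(vertices)
        g.add_edges_from((u, v) for u, v in edges if u != v)
        return cls(vertices=vertices, graph=g)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    def neighbors(self, v: Hashable) -> set:
        return set(self.graph[v])

    def index_of(self, v: Hashable) -> int:
        """Sequence position of a vertex (used for deterministic tie-breaks)."""
        return self.vertices.index(v)

    def adjacency_matrix(self) -> np.ndarray:
        return nx.to_numpy_array(self.graph, nodelist=self.vertices)


def build_network(structure: Structure, chain_id: str,
                  extra: float = 2.0,
                  radii: Mapping[str, float] | None = None,
                  default_radius: float = DEFAULT_VDW_RADIUS) -> ContactNetwork:
    """Build the residue contact network for one chain.

    An edge (u, v) exists iff min over atom pairs of
    ``dist - r_a - r_b < extra`` (strict).  Sequence-adjacent residues get
    no special treatment; they are tested by the same rule.
    """
    residues = structure.chain(chain_id)
    if not residues:
        raise ValueError(f"chain {chain_id!r} of {structure.pdb_id!r} is empty")
    radii = dict(VDW_RADII) if radii is None else dict(radii)

    keys = [r.key for r in residues]
    coords, atom_radius, atom_res = [], [], []
    for i, res in enumerate(residues):
        for atom in res.atoms:
            coords.append(atom.coord)
            atom_radius.append(vdw_radius(atom.element, radii, default_radius))
            atom_res.append(i)
    coords = np.asarray(coords)
    atom_radius = np.asarray(atom_radius)
    atom_res = np.asarray(atom_res)

    # any atom pair closer than r_a + r_b + extra; prune with a KD-tree at
    # the largest possible contact distance
    max_reach = 2.0 * atom_radius.max() + extra
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=max_reach, output_type="ndarray")

    edges: set[tuple[int, int]] = set()
    if len(pairs):
        ri, rj = atom_res[pairs[:, 0]], atom_res[pairs[:, 1]]
        mask = ri != rj
        pairs, ri, rj = pairs[mask], ri[mask], rj[mask]
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        contact = d < atom_radius[pairs[:, 0]] + atom_radius[pairs[:, 1]] + extra
        for a, b in zip(ri[contact], rj[contact]):
            edges.add((min(a, b), max(a, b)))

    return ContactNetwork.from_edges(
        keys, [(keys[a], keys[b]) for a, b in edges])


def shortest_paths(network: ContactNetwork, source: Hashable
                   ) -> dict[Hashable, float]:
    """Breadth-first hop distances from ``source`` to every vertex.

    Unreachable vertices carry :data:`UNREACHABLE`.
    """
    if source not in network.graph:
        raise KeyError(f"unknown source vertex {source!r}")
    dist = nx.single_source_shortest_path_length(network.graph, source)
    return {v: float(dist[v]) if v in dist else UNREACHABLE
            for v in network.vertices}


def write_edge_list(network: ContactNetwork, path: str | Path) -> None:
    """Export edges as TSV (resA, resB) for external graph tools."""
    with open(path, "w") as fh:
        fh.write("resA\tresB\n")
        for u, v in sorted(network.graph.edges,
                           key=lambda e: (network.index_of(e[0]),
                                          network.index_of(e[1]))):
            fh.write(f"{_fmt(u)}\t{_fmt(v)}\n")


def _fmt(key: Hashable) -> str:
    if isinstance(key, tuple):
        return ":".join(str(k) for k in key)
    return str(key)
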