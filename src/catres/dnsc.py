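"""DNSC: description of network signal communication.

A protein chain is modelled as a signal network in which a few central
residues — the *keyAAs*, the top residues ranked by closeness — act as
signal sources.  A signal flows along shortest paths and is attenuated by
a power law, so the intensity a residue receives from keyAA *i* at hop
distance d is

    f(d) = g_s            if d = 0 (the residue is the keyAA itself)
    f(d) = g_s · d^(-a)   if 1 <= d <= cutoff
    f(d) = 0              if d > cutoff or unreachable

with exponent a = 1, source intensity g_s = 1 and hop cutoff 5 by default.
A residue's DNSC descriptor is the vector of intensities from the k keyAAs
in rank order (k = 5 by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping

import numpy as np

from catres.contact_network import ContactNetwork, UNREACHABLE, shortest_paths
from catres.centrality import closeness


@dataclass(frozen=True)
class KeyAASet:
    """Top-k residues by closeness, descending; ties broken by sequence
    position (ascending) so the ranking is reproducible."""

    members: tuple[tuple[Hashable, float], ...]  # (vertex, closeness)
    k: int  # requested size; len(members) may be smaller

    @property
    def vertices(self) -> list[Hashable]:
        return [v for v, _ in self.members]

    def __len__(self) -> int:
        return len(self.members)


def select_keyaas(network: ContactNetwork,
                  closeness_table: Mapping[Hashable, float] | None = None,
                  k: int = 5) -> KeyAASet:
    """Rank residues by closeness and keep the top ``k``.

    If the chain has fewer than ``k`` residues, all are returned and
    consumers pad the DNSC vector with zeros.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if network.n_vertices == 0:
        raise ValueError("network has no vertices")
    if closeness_table is None:
        closeness_table = {v: closeness(network, v) for v in network.vertices}
    order = sorted(
        network.vertices,
        key=lambda v: (-closeness_table[v], network.index_of(v)),
    )
    top = order[:k]
    return KeyAASet(members=tuple((v, closeness_table[v]) for v in top), k=k)


def signal_intensity(d: float, a: float = 1.0, g_s: float = 1.0,
                     cutoff: int = 5) -> float:
    """Power-law attenuated signal intensity at hop distance ``d``."""
    if d == UNREACHABLE:
        return 0.0
    if d < 0:
        raise ValueError(f"negative path length {d}")
    if d == 0:
        return g_s
    if d > cutoff:
        return 0.0
    return g_s * float(d) ** (-a)


def dnsc_vector(network: ContactNetwork, residue: Hashable,
                keyaas: KeyAASet, a: float = 1.0, g_s: float = 1.0,
                cutoff: int = 5) -> np.ndarray:
    """Signal intensities a residue receives from each keyAA, rank order.

    Always length ``keyaas.k``; missing keyAAs (chain smaller than k)
    contribute zeros.
    """
    if residue not in network.graph:
        raise KeyError(f"unknown residue {residue!r}")
    dist = shortest_paths(network, residue)
    out = np.zeros(keyaas.k)
    for m, key in enumerate(keyaas.vertices):
        out[m] = signal_intensity(dist[key], a=a, g_s=g_s, cutoff=cutoff)
    return out


def dnsc_matrix(network: ContactNetwork, keyaas: KeyAASet,
                a: float = 1.0, g_s: float = 1.0,
                cutoff: int = 5) -> np.ndarray:
    """DNSC vectors for every vertex (row order = chain order).

    One BFS per keyAA instead of one per residue.
    """
    out = np.zeros((network.n_vertices, keyaas.k))
    idx = {v: i for i, v in enumerate(network.vertices)}
    for m, key in enumerate(keyaas.vertices):
        dist = shortest_paths(network, key)
        for v, d in dist.items():
            out[idx[v], m] = signal_intensity(d, a=a, g_s=g_s, cutoff=cutoff)
    return out
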