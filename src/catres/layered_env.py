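"""Layered description of a residue's structural environment.

The residues surrounding a target fall naturally into shortest-path
layers: layer 1 holds direct contacts (hop distance 1), layers 2 and 3
hold residues at hop distances 2 and 3.  Each layer is summarized by the
arithmetic mean of 14 per-residue features (conservation, polarity,
hydrophobicity, volume, ASA, rASA and the eight network parameters), so
the three-layer environment is a 42-dimensional vector.  Feature names
carry the layer number as a suffix (e.g. ``closeness_L1``).  An empty
layer contributes 14 zeros and is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Hashable

import numpy as np
import pandas as pd

from catres.contact_network import ContactNetwork, shortest_paths

#: the 14 per-residue features averaged within each layer, fixed order
LAYER_FEATURES = [
    "conservation", "polarity", "hydrophobicity", "volume", "asa", "rasa",
    "degree", "clustering", "hub_score", "cocitation", "coreness",
    "constraint", "betweenness", "closeness",
]


def layer_feature_names(depth: int = 3) -> list[str]:
    return [f"{feat}_L{m}" for m in range(1, depth + 1)
            for feat in LAYER_FEATURES]


@dataclass(frozen=True)
class LayerPartition:
    """Disjoint BFS rings around a target residue (the target is in none)."""

    target: Hashable
    layers: tuple[frozenset, ...]

    def layer(self, m: int) -> frozenset:
        """1-based layer access: layer(1) = direct contacts."""
        return self.layers[m - 1]


def layer_partition(network: ContactNetwork, target: Hashable,
                    depth: int = 3) -> LayerPartition:
    """Residues at hop distance 1..depth from the target."""
    if target not in network.graph:
        raise KeyError(f"unknown target {target!r}")
    dist = shortest_paths(network, target)
    layers = tuple(
        frozenset(v for v, d in dist.items() if d == m)
        for m in range(1, depth + 1)
    )
    return LayerPartition(target=target, layers=layers)


def layer_features(partition: LayerPartition,
                   properties: pd.DataFrame) -> tuple[np.ndarray, list[bool]]:
    """Mean per-feature per-layer environment vector.

    Parameters
    ----------
    partition
        Output of :func:`layer_partition`.
    properties
        Per-residue table indexed by residue key with (at least) the
        :data:`LAYER_FEATURES` columns.

    Returns
    -------
    vector, empty_flags
        ``vector`` has ``14 * depth`` entries in layer-major order;
        ``empty_flags[m]`` is True when layer m+1 was empty (its block is
        all zeros).
    """
    blocks, flags = [], []
    for members in partition.layers:
        if not members:
            blocks.append(np.zeros(len(LAYER_FEATURES)))
            flags.append(True)
            continue
        missing = [v for v in members if v not in properties.index]
        if missing:
            raise KeyError(f"no property row for residue(s) {missing}")
        sub = properties.loc[list(members), LAYER_FEATURES]
        blocks.append(sub.to_numpy(dtype=float).mean(axis=0))
        flags.append(False)
    return np.concatenate(blocks), flags


def write_layer_membership(network: ContactNetwork, targets: list[Hashable],
                           path: str | Path, depth: int = 3) -> None:
    """Export layer membership (target, layer, residue) as TSV."""
    with open(path, "w") as fh:
        fh.write("target\tlayer\tresidue\n")
        for t in targets:
            part = layer_partition(network, t, depth=depth)
            for m in range(1, depth + 1):
                for v in sorted(part.layer(m), key=network.index_of):
                    fh.write(f"{_fmt(t)}\t{m}\t{_fmt(v)}\n")


def _fmt(key: Hashable) -> str:
    if isinstance(key, tuple):
        return ":".join(str(k) for k in key)
    return str(key)
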