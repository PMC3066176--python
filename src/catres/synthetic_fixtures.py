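"""Synthetic structures, graphs, profiles and labeled datasets.

Everything in the pipeline is testable without downloads: this module
generates named graph topologies, idealized α-helical toy structures
(connected contact networks with sequence-local contacts), PSI-BLAST-style
profiles, and labeled catalytic-residue datasets that carry the two
statistical signals the method exploits — catalytic residues placed close
to high-closeness residues (keyAAs), and sequence conservation that decays
with network distance from the catalytic site.  A single ``enrichment``
knob in [0, 1] scales both signals, so ``enrichment=0`` is a true null
dataset and ``enrichment=1`` a maximally informative one.

All generators are deterministic given their seed; fixtures can be written
through the real file formats (PDB, annotation TSV, PSSM ASCII) so they
flow through the production readers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from catres.contact_network import (ContactNetwork, build_network,
                                    shortest_paths)
from catres.centrality import closeness
from catres.dnsc import select_keyaas
from catres.profile_features import AA_ALPHABET, ProfileMatrix, write_psiblast_pssm
from catres.structure_io import (ONE_TO_THREE, Atom, Residue, Structure,
                                 write_annotations, write_pdb)

import pandas as pd

#: helix geometry: rise per residue (Å), radius (Å), turn per residue (deg)
HELIX_RISE = 1.5
HELIX_RADIUS = 2.3
HELIX_TURN_DEG = 100.0

#: e-folding scale (hops) of the conservation signal around catalytic sites
CONSERVATION_DECAY = 1.5


def make_graph_fixture(kind: str, n: int, p: float | None = None,
                       seed: int | None = None) -> ContactNetwork:
    """Named graph topologies as :class:`ContactNetwork` (vertices 0..n-1)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if kind == "path":
        g = nx.path_graph(n)
    elif kind == "star":
        g = nx.star_graph(n - 1)  # vertex 0 is the center
    elif kind == "cycle":
        g = nx.cycle_graph(n)
    elif kind == "complete":
        g = nx.complete_graph(n)
    elif kind == "erdos_renyi":
        if p is None or not 0.0 <= p <= 1.0:
            raise ValueError(f"invalid edge probability {p}")
        if seed is None:
            raise ValueError("erdos_renyi requires a seed")
        g = nx.gnp_random_graph(n, p, seed=seed)
    else:
        raise ValueError(f"unknown graph kind {kind!r}")
    return ContactNetwork.from_edges(range(n), g.edges)


def make_helix_structure(n_residues: int, seed: int,
                         pdb_id: str = "synt", chain_id: str = "A"
                         ) -> Structure:
    """Idealized α-helix CA trace plus one jittered pseudo side-chain atom.

    Rise 1.5 Å, radius 2.3 Å, 100° per residue; the resulting contact
    network under the default 2 Å rule is connected and dominated by
    sequence-local contacts, which is all the downstream layers and keyAA
    machinery need.  Residue names are drawn uniformly from the 20
    standard amino acids.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    rng = np.random.default_rng(seed)
    residues = []
    for i in range(n_residues):
        theta = math.radians(HELIX_TURN_DEG) * i
        ca = np.array([HELIX_RADIUS * math.cos(theta),
                       HELIX_RADIUS * math.sin(theta),
                       HELIX_RISE * i])
        # pseudo side chain pointing radially outward, with small jitter
        out_dir = np.array([math.cos(theta), math.sin(theta), 0.0])
        cb = ca + 1.8 * out_dir + rng.normal(0.0, 0.15, size=3)
        one = AA_ALPHABET[rng.integers(0, 20)]
        residues.append(Residue(
            seq_number=i + 1, icode="", name=ONE_TO_THREE[one],
            chain_id=chain_id,
            atoms=[Atom("CA", "C", ca), Atom("CB", "C", cb)],
        ))
    return Structure(pdb_id=pdb_id, chains={chain_id: residues})


@dataclass
class LabeledDataset:
    """A synthetic study set: structures, catalytic annotations, profiles."""

    structures: dict[str, Structure]
    annotations: pd.DataFrame
    profiles: dict[str, ProfileMatrix]
    networks: dict[str, ContactNetwork] = field(default_factory=dict)
    chain_id: str = "A"

    @property
    def pdb_ids(self) -> list[str]:
        return list(self.structures)


def make_labeled_dataset(n_proteins: int, residues_per_protein: int,
                         seed: int, enrichment: float,
                         n_keyaas: int = 5) -> LabeledDataset:
    """Generate a labeled catalytic-residue dataset.

    Per protein: build a helix structure and its contact network; rank
    residues by closeness; draw 2–4 catalytic residues, each placed (with
    probability ``enrichment``) on a residue at hop distance <= 1 from a
    top-``n_keyaas`` closeness residue, otherwise uniformly.  Profiles give
    each position a frequency row that is a mixture of a delta at its own
    amino acid and a noisy background, with mixture weight
    ``enrichment * exp(-d_cat / 1.5)`` where ``d_cat`` is the hop distance
    to the nearest catalytic residue — so catalytic positions (and, more
    weakly, their spatial neighborhood) are conserved, and ``enrichment=0``
    removes the signal entirely.
    """
    if not 0.0 <= enrichment <= 1.0:
        raise ValueError(f"enrichment must be in [0, 1], got {enrichment}")
    structures: dict[str, Structure] = {}
    networks: dict[str, ContactNetwork] = {}
    profiles: dict[str, ProfileMatrix] = {}
    ann_rows = []
    for ip in range(n_proteins):
        rng = np.random.default_rng([seed, ip])
        pdb_id = f"syn{ip:04d}"
        structure = make_helix_structure(residues_per_protein,
                                         seed=int(rng.integers(2 ** 31)),
                                         pdb_id=pdb_id)
        network = build_network(structure, "A")
        keyaas = select_keyaas(network, k=n_keyaas)

        # candidate pool: keyAAs and their direct contacts
        pool = set(keyaas.vertices)
        for v in keyaas.vertices:
            pool |= network.neighbors(v)
        pool_list = sorted(pool, key=network.index_of)

        n_cat = int(rng.integers(2, 5))
        catalytic: list = []
        for _ in range(n_cat):
            near = rng.random() < enrichment
            candidates = [v for v in (pool_list if near else network.vertices)
                          if v not in catalytic]
            if not candidates:
                candidates = [v for v in network.vertices
                              if v not in catalytic]
            catalytic.append(candidates[rng.integers(len(candidates))])

        # hop distance from every residue to the nearest catalytic residue
        d_cat = {v: math.inf for v in network.vertices}
        for c in catalytic:
            for v, d in shortest_paths(network, c).items():
                d_cat[v] = min(d_cat[v], d)

        residues = structure.chain("A")
        letters = "".join(r.one_letter for r in residues)
        freqs = np.zeros((len(residues), 20))
        for i, res in enumerate(residues):
            background = rng.dirichlet(np.full(20, 5.0))
            d = d_cat[res.key]
            strength = 0.0 if math.isinf(d) else \
                enrichment * math.exp(-d / CONSERVATION_DECAY)
            delta = np.zeros(20)
            delta[AA_ALPHABET.index(res.one_letter)] = 1.0
            freqs[i] = strength * delta + (1.0 - strength) * background
        # log-odds consistent with the frequencies vs a uniform background
        logodds = np.round(2.0 * np.log2((freqs + 1e-4) / 0.05))
        profiles[pdb_id] = ProfileMatrix(letters, logodds, freqs)

        structures[pdb_id] = structure
        networks[pdb_id] = network
        for c in catalytic:
            chain, resnum, _ = c
            name = next(r.name for r in residues if r.key == c)
            ann_rows.append((pdb_id, chain, resnum, name, "catalytic"))

    annotations = pd.DataFrame(
        ann_rows, columns=["pdb_id", "chain", "resnum", "resname", "label"])
    return LabeledDataset(structures=structures, annotations=annotations,
                          profiles=profiles, networks=networks)


def write_dataset(dataset: LabeledDataset, out_dir: str | Path) -> None:
    """Write a dataset through the real file formats (PDB / TSV / PSSM)."""
    out_dir = Path(out_dir)
    (out_dir / "structures").mkdir(parents=True, exist_ok=True)
    (out_dir / "profiles").mkdir(parents=True, exist_ok=True)
    for pdb_id, structure in dataset.structures.items():
        write_pdb(structure, out_dir / "structures" / f"{pdb_id}.pdb")
    for pdb_id, profile in dataset.profiles.items():
        write_psiblast_pssm(profile, out_dir / "profiles" / f"{pdb_id}.pssm")
    write_annotations(dataset.annotations, out_dir / "annotations.tsv")
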