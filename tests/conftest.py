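"""Shared fixtures: tiny PDB/DSSP texts and small synthetic datasets."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from catres.synthetic_fixtures import make_labeled_dataset

# rASA > 1 flags on toy helices are expected; keep test output readable
logging.getLogger("catres").setLevel(logging.ERROR)
logging.getLogger("catres.profile_features").setLevel(logging.ERROR)


def pdb_atom_line(serial: int, name: str, resname: str, chain: str,
                  resnum: int, x: float, y: float, z: float,
                  element: str = "C", occupancy: float = 1.0,
                  altloc: str = " ", record: str = "ATOM") -> str:
    """One fixed-column PDB ATOM/HETATM record."""
    if len(name) < 4:
        name = f" {name:<3s}"
    return (f"{record:<6s}{serial:5d} {name:<4s}{altloc:1s}{resname:>3s} "
            f"{chain:1s}{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{occupancy:6.2f}{0.0:6.2f}          {element:>2s}")


TWO_RESIDUE_ATOMS = [
    # ALA 1: N, CA, C, O, CB
    ("N", "ALA", 1, 0.0, 0.0, 0.0, "N"),
    ("CA", "ALA", 1, 1.5, 0.0, 0.0, "C"),
    ("C", "ALA", 1, 2.2, 1.3, 0.0, "C"),
    ("O", "ALA", 1, 1.6, 2.4, 0.0, "O"),
    ("CB", "ALA", 1, 2.2, -1.3, 0.0, "C"),
    # GLY 2: N, CA, C, O
    ("N", "GLY", 2, 3.5, 1.3, 0.0, "N"),
    ("CA", "GLY", 2, 4.3, 2.5, 0.0, "C"),
    ("C", "GLY", 2, 5.8, 2.3, 0.0, "C"),
    ("O", "GLY", 2, 6.5, 3.3, 0.0, "O"),
]


@pytest.fixture
def two_residue_pdb(tmp_path):
    """A 2-residue ATOM-only fragment (ALA 1 + GLY 2, 9 atoms)."""
    lines = [pdb_atom_line(i + 1, n, rn, "A", num, x, y, z, el)
             for i, (n, rn, num, x, y, z, el) in enumerate(TWO_RESIDUE_ATOMS)]
    path = tmp_path / "frag.pdb"
    path.write_text("\n".join(lines + ["END"]) + "\n")
    return path


@pytest.fixture(scope="session")
def small_dataset():
    """10 proteins x 30 residues, enriched; shared by read-only tests."""
    return make_labeled_dataset(10, 30, seed=7, enrichment=0.9)


@pytest.fixture(scope="session")
def small_encoded(small_dataset):
    from catres.encoder_model import encode_dataset

    return encode_dataset(small_dataset.structures, small_dataset.annotations,
                          small_dataset.profiles,
                          networks=small_dataset.networks)


def random_network(rng: np.random.Generator, n: int, p: float):
    """An Erdős–Rényi draw as a ContactNetwork (test-side helper)."""
    from catres.contact_network import ContactNetwork

    edges = [(i, j) for i in range(n) for j in range(i + 1, n)
             if rng.random() < p]
    return ContactNetwork.from_edges(range(n), edges)
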