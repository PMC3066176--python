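"""Read protein structures and catalytic-residue annotations.

PDB files are parsed with Biopython and converted into a light chain-level
model (:class:`Structure` / :class:`Residue` / :class:`Atom`) that keeps
only what the contact-network construction needs: author residue numbering
(with insertion codes), atom coordinates and element symbols.  Only ATOM
records of the first model are retained; HETATM records (ligands, waters)
are dropped, except selenomethionine (MSE) which is mapped to MET.  For
alternate locations the highest-occupancy atom wins (ties keep the first
record seen).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from catres.config import DEFAULT_VDW_RADIUS, VDW_RADII

logger = logging.getLogger(__name__)

#: 3-letter -> 1-letter codes for the 20 standard amino acids
THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass
class Atom:
    """A single atom: label, element symbol and Cartesian coordinate (Å)."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = " "

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinate for atom {self.name!r}")


@dataclass
class Residue:
    """One residue of a chain, addressed by author number + insertion code."""

    seq_number: int
    icode: str
    name: str
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        """Unique within a structure: (chain_id, seq_number, icode)."""
        return (self.chain_id, self.seq_number, self.icode)

    @property
    def label(self) -> str:
        """Human-readable residue label, e.g. ``ASN22``."""
        return f"{self.name}{self.seq_number}{self.icode.strip()}"

    @property
    def one_letter(self) -> str | None:
        return THREE_TO_ONE.get(self.name)

    @property
    def is_standard(self) -> bool:
        return self.name in THREE_TO_ONE

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])


@dataclass
class Structure:
    """A parsed structure: ordered residues per chain, first model only."""

    pdb_id: str
    chains: dict[str, list[Residue]]
    model_number: int = 0

    def chain(self, chain_id: str) -> list[Residue]:
        if chain_id not in self.chains:
            raise KeyError(
                f"chain {chain_id!r} not in structure {self.pdb_id!r} "
                f"(available: {sorted(self.chains)})"
            )
        return self.chains[chain_id]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for ch in self.chains.values() for r in ch)


def vdw_radius(element: str, table: dict[str, float] | None = None,
               default: float = DEFAULT_VDW_RADIUS) -> float:
    """Van der Waals radius (Å) of an element symbol.

    Unknown symbols fall back to ``default`` (carbon's radius) with a
    logged warning, so structures with exotic atoms still build a network.
    """
    table = VDW_RADII if table is None else table
    el = element.strip().upper()
    if el in table:
        return table[el]
    logger.warning("unknown element %r, using default vdW radius %.2f Å",
                   element, default)
    return default


def read_pdb(path: str | Path, chain_id: str | None = None) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    Parameters
    ----------
    path
        PDB-format file (ATOM/HETATM fixed-column records).
    chain_id
        If given, only that chain is retained (it must exist).

    Notes
    -----
    Keeps ATOM records of the first model; drops HETATM except MSE
    (renamed MET); keeps the highest-occupancy alternate location;
    nonstandard ATOM residues are kept but flagged via
    :attr:`Residue.is_standard`.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        bio_structure = parser.get_structure(path.stem, str(path))
    try:
        model = next(iter(bio_structure))
    except StopIteration:  # pragma: no cover - empty file
        raise ValueError(f"no model parsed from {path}")

    chains: dict[str, list[Residue]] = {}
    for bio_chain in model:
        residues: list[Residue] = []
        for bio_res in bio_chain:
            hetflag, resseq, icode = bio_res.id
            name = bio_res.get_resname().strip()
            if hetflag != " ":
                if name == "MSE":
                    name = "MET"
                else:
                    continue  # ligands / waters excluded
            atoms = []
            for bio_atom in bio_res:
                # DisorderedAtom iteration yields the selected child,
                # which Biopython sets to the highest-occupancy altloc
                # (ties keep the first record seen).
                if bio_atom.is_disordered():
                    bio_atom = bio_atom.selected_child
                element = (bio_atom.element or "").strip() or _element_from_name(
                    bio_atom.get_name())
                atoms.append(Atom(
                    name=bio_atom.get_name(),
                    element=element,
                    coord=np.array(bio_atom.get_coord(), dtype=float),
                    occupancy=bio_atom.get_occupancy() or 1.0,
                    altloc=bio_atom.get_altloc() or " ",
                ))
            if not atoms:
                continue
            res = Residue(seq_number=resseq, icode=icode.strip(), name=name,
                          chain_id=bio_chain.id, atoms=atoms)
            if not res.is_standard:
                logger.warning("nonstandard residue %s in %s chain %s",
                               res.label, path.stem, bio_chain.id)
            residues.append(res)
        if residues:
            chains[bio_chain.id] = residues

    if chain_id is not None:
        if chain_id not in chains:
            raise KeyError(f"chain {chain_id!r} absent from {path}")
        chains = {chain_id: chains[chain_id]}
    if not chains or all(not r for r in chains.values()):
        raise ValueError(f"zero residues parsed from {path}")
    return Structure(pdb_id=path.stem, chains=chains, model_number=0)


def _element_from_name(atom_name: str) -> str:
    """Guess the element from the atom-name convention (columns 13-14)."""
    stripped = atom_name.strip()
    if stripped[:2] in ("FE", "ZN", "MG", "MN", "SE", "CL", "BR", "NA"):
        return stripped[:2]
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "C"


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` back out as fixed-column ATOM records."""
    lines = []
    serial = 1
    for chain_id in structure.chains:
        for res in structure.chains[chain_id]:
            for atom in res.atoms:
                name = atom.name
                # standard alignment: 1/2-char element names start in col 14
                if len(name) < 4:
                    name = f" {name:<3s}"
                x, y, z = atom.coord
                lines.append(
                    f"ATOM  {serial:5d} {name:<4.4s}{atom.altloc:1.1s}"
                    f"{res.name:>3s} {chain_id:1.1s}{res.seq_number:4d}"
                    f"{res.icode:1.1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2.2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


ANNOTATION_COLUMNS = ["pdb_id", "chain", "resnum", "resname", "label"]


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a catalytic-residue annotation table (TSV).

    Expected header: ``pdb_id  chain  resnum  resname  label`` with label in
    {catalytic, noncatalytic}.  Duplicate (pdb_id, chain, resnum) keys are
    rejected.  An empty body is valid and yields an empty table.
    """
    table = pd.read_csv(path, sep="\t", dtype={"pdb_id": str, "chain": str,
                                               "resname": str, "label": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"annotation table missing column(s): {missing}")
    dup = table.duplicated(subset=["pdb_id", "chain", "resnum"], keep=False)
    if dup.any():
        first = table[dup].iloc[0]
        raise ValueError(
            "duplicate annotation for "
            f"{first['pdb_id']}/{first['chain']}/{first['resnum']}"
        )
    bad = set(table["label"]) - {"catalytic", "noncatalytic"}
    if bad:
        raise ValueError(f"unknown annotation label(s): {sorted(bad)}")
    return table[ANNOTATION_COLUMNS]


def write_annotations(table: pd.DataFrame, path: str | Path) -> None:
    table[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def catalytic_keys(table: pd.DataFrame, pdb_id: str, chain_id: str
                   ) -> set[tuple[str, int, str]]:
    """Residue keys annotated catalytic for one chain."""
    sel = table[(table["pdb_id"] == pdb_id) & (table["chain"] == chain_id)
                & (table["label"] == "catalytic")]
    return {(chain_id, int(r), "") for r in sel["resnum"]}
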