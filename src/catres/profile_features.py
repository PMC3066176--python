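"""Sequence, physicochemical and accessibility features per residue.

Covers the conventional residue descriptors that complement the network
features: Shannon-entropy conservation from PSI-BLAST profiles, the PSSM
log-odds and weighted observed frequencies themselves, residue identity
and charge/polarity/hydrophobicity class codes, three quantitative
physicochemical scales, solvent accessible surface area (internal
Shrake–Rupley or a DSSP file) and DSSP secondary structure.

PSI-BLAST and DSSP are never executed here; their output files are parsed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.PDB.DSSP import make_dssp_dict
from scipy.spatial import cKDTree

from catres.config import DEFAULT_VDW_RADIUS, VDW_RADII
from catres.structure_io import THREE_TO_ONE, Structure, vdw_radius

logger = logging.getLogger(__name__)

#: fixed amino-acid order for all 20-dim blocks (alphabetical one-letter)
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: PSI-BLAST PSSM column order
PSSM_COLUMN_ORDER = "ARNDCQEGHILKMFPSTWYV"

# --- pinned physicochemical scales -------------------------------------
# Grantham polarity
POLARITY = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5,
    "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3,
    "M": 5.7, "F": 5.2, "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4,
    "Y": 6.2, "V": 5.9,
}
# Kyte–Doolittle hydropathy
HYDROPHOBICITY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}
# Zamyatnin residue volumes (Å³)
VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}
# Theoretical Gly-X-Gly maximum accessible surface areas (Å², Tien et al.)
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: residue classes for the 2-bit AAType code
CHARGED = set("DEKHR")
POLAR = set("CNQSTY")
HYDROPHOBIC = set("AFGILMPVW")

#: DSSP secondary-structure codes carried in the 7-dim one-hot; anything
#: else (including blank / '-') is coil = all zeros
SS_CODES = ["H", "G", "I", "E", "B", "T", "S"]


@dataclass
class ProfileMatrix:
    """Per-position PSI-BLAST profile.

    ``logodds`` and ``freqs`` are (n_positions, 20) arrays with columns in
    :data:`AA_ALPHABET` order; ``freqs`` rows are fractions summing to ~1,
    or all-zero for gappy columns (flagged in ``zero_rows``).
    """

    letters: str
    logodds: np.ndarray
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.logodds = np.asarray(self.logodds, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        n = len(self.letters)
        if self.logodds.shape != (n, 20) or self.freqs.shape != (n, 20):
            raise ValueError("profile blocks must be (n_positions, 20)")
        sums = self.freqs.sum(axis=1)
        if np.any(sums > 1.0001):
            raise ValueError("frequency row sums exceed 1")

    @property
    def n_positions(self) -> int:
        return len(self.letters)

    @property
    def zero_rows(self) -> np.ndarray:
        return ~self.freqs.any(axis=1)

    def conservation(self) -> np.ndarray:
        return np.array([conservation_score(row) for row in self.freqs])


def read_psiblast_pssm(path: str | Path) -> ProfileMatrix:
    """Parse a PSI-BLAST ASCII PSSM file.

    Expects the standard dialect: a header, then one row per position with
    the residue letter followed by 20 log-odds integers and 20 weighted
    observed percentages (plus trailing information/weight columns, which
    are ignored).  Percentages are divided by 100 into frequencies; the
    columns are reordered into :data:`AA_ALPHABET` order.
    """
    letters, logodds, percents = [], [], []
    reorder = [PSSM_COLUMN_ORDER.index(aa) for aa in AA_ALPHABET]
    for raw in Path(path).read_text().splitlines():
        parts = raw.split()
        if len(parts) < 42 or not parts[0].isdigit():
            continue  # header / footer / lambda lines
        if len(parts[1]) != 1 or not parts[1].isalpha():
            raise ValueError(f"malformed PSSM row: {raw!r}")
        values = parts[2:42]
        try:
            numbers = [float(x) for x in values]
        except ValueError as exc:
            raise ValueError(f"malformed PSSM row: {raw!r}") from exc
        letters.append(parts[1])
        logodds.append([numbers[j] for j in reorder])
        percents.append([numbers[20 + j] for j in reorder])
    if not letters:
        raise ValueError(f"no PSSM rows parsed from {path}")
    freqs = np.asarray(percents) / 100.0
    profile = ProfileMatrix("".join(letters), np.asarray(logodds), freqs)
    n_zero = int(profile.zero_rows.sum())
    if n_zero:
        logger.warning("%d all-zero frequency row(s) in %s", n_zero, path)
    return profile


def write_psiblast_pssm(profile: ProfileMatrix, path: str | Path) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect (fixture round-trips)."""
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "".join(f"{aa:>4s}" for aa in PSSM_COLUMN_ORDER) * 2,
    ]
    order = [AA_ALPHABET.index(aa) for aa in PSSM_COLUMN_ORDER]
    for i, letter in enumerate(profile.letters):
        lo = "".join(f"{int(round(profile.logodds[i, j])):4d}" for j in order)
        # percentages are rounded down, as in PSI-BLAST's own output
        pc = "".join(f"{int(profile.freqs[i, j] * 100 + 1e-9):4d}"
                     for j in order)
        lines.append(f"{i + 1:5d} {letter}  {lo}{pc}  0.00 0.00")
    lines += ["", "                      K         Lambda", ""]
    Path(path).write_text("\n".join(lines) + "\n")


def conservation_score(freqs: Sequence[float]) -> float:
    """Shannon entropy −Σ p ln p (nats) of an amino-acid frequency row.

    Lower values mean a more conserved position; a fully conserved column
    scores 0 and a uniform column ln 20.  All-zero rows (gappy profile
    columns) score 0 — they are flagged upstream, not imputed.
    """
    p = np.asarray(freqs, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative frequency")
    if p.sum() > 1.0 + 1e-4:
        raise ValueError(f"frequencies sum to {p.sum():.4f} > 1")
    nz = p[p > 0]
    if nz.size == 0:
        return 0.0
    return float(-(nz * np.log(nz)).sum()) + 0.0  # avoid -0.0


def aa_identity(resname: str) -> np.ndarray:
    """20-dim one-hot residue identity in :data:`AA_ALPHABET` order."""
    one = _to_one_letter(resname)
    out = np.zeros(20)
    out[AA_ALPHABET.index(one)] = 1.0
    return out


def aa_type(resname: str) -> np.ndarray:
    """2-bit class code: charged (0,0), polar (0,1), hydrophobic (1,0)."""
    one = _to_one_letter(resname)
    if one in CHARGED:
        return np.array([0.0, 0.0])
    if one in POLAR:
        return np.array([0.0, 1.0])
    return np.array([1.0, 0.0])


def physchem(resname: str) -> np.ndarray:
    """(polarity, hydrophobicity, volume) from the pinned scales."""
    one = _to_one_letter(resname)
    return np.array([POLARITY[one], HYDROPHOBICITY[one], VOLUME[one]])


def _to_one_letter(resname: str) -> str:
    name = resname.strip().upper()
    if len(name) == 1 and name in AA_ALPHABET:
        return name
    if name in THREE_TO_ONE:
        return THREE_TO_ONE[name]
    raise ValueError(f"nonstandard residue {resname!r}")


# --- accessible surface area -------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (golden-section spiral)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_asa(structure: Structure, chain_id: str,
                      probe: float = 1.4, n_points: int = 960,
                      radii: Mapping[str, float] | None = None,
                      default_radius: float = DEFAULT_VDW_RADIUS
                      ) -> dict[tuple, float]:
    """Per-residue solvent accessible surface area (Å²) by sphere sampling.

    Each atom is expanded by the probe radius and sampled with ``n_points``
    quasi-uniform sphere points; a point is accessible when it lies outside
    every other expanded atom sphere.  The chain is treated in isolation,
    matching the one-chain-one-system convention of the contact network.
    """
    residues = structure.chain(chain_id)
    radii = dict(VDW_RADII) if radii is None else dict(radii)

    coords, radius, res_idx = [], [], []
    for i, res in enumerate(residues):
        if not res.atoms:
            raise ValueError(f"residue {res.label} has no atoms")
        for atom in res.atoms:
            coords.append(atom.coord)
            radius.append(vdw_radius(atom.element, radii, default_radius) + probe)
            res_idx.append(i)
    coords = np.asarray(coords)
    radius = np.asarray(radius)
    unit = _sphere_points(n_points)

    tree = cKDTree(coords)
    max_r = radius.max()
    asa_per_atom = np.zeros(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + radius[i] * unit
        neighbor_ids = [j for j in tree.query_ball_point(coords[i],
                                                         radius[i] + max_r)
                        if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbor_ids:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > radius[j] ** 2
        frac = accessible.mean()
        asa_per_atom[i] = frac * 4.0 * math.pi * radius[i] ** 2

    out: dict[tuple, float] = {res.key: 0.0 for res in residues}
    for i, a in zip(res_idx, asa_per_atom):
        out[residues[i].key] += a
    return out


def relative_asa(asa: float, resname: str) -> float:
    """ASA divided by the residue's theoretical Gly-X-Gly maximum.

    Values above 1 are reported as-is (with a warning) rather than clipped.
    """
    one = _to_one_letter(resname)
    rasa = asa / MAX_ASA[one]
    if rasa > 1.0:
        logger.warning("rASA %.3f > 1 for %s (asa %.1f Å²)", rasa, resname, asa)
    return rasa


# --- DSSP ---------------------------------------------------------------

def read_dssp(path: str | Path) -> dict[tuple[str, int, str], tuple[float, str]]:
    """Parse a classic DSSP output file.

    Returns ``{(chain, resnum, icode): (asa, ss)}`` with blank secondary
    structure mapped to ``"coil"``.  Chain-break rows are skipped by the
    underlying parser.
    """
    dssp_dict, _keys = make_dssp_dict(str(path))
    out = {}
    for (chain, res_id), values in dssp_dict.items():
        _het, resnum, icode = res_id
        ss = values[1]
        asa = float(values[2])
        if ss in (" ", "-", ""):
            ss = "coil"
        out[(chain, int(resnum), icode.strip())] = (asa, ss)
    return out


def match_dssp(structure: Structure, chain_id: str,
               dssp: Mapping[tuple[str, int, str], tuple[float, str]]
               ) -> pd.DataFrame:
    """Align DSSP rows with a chain's residues.

    Structure residues missing from DSSP get ``ss="coil"`` and NaN ASA
    (flagged via the ``missing`` column); DSSP rows with no structure
    counterpart are dropped with a warning.
    """
    residues = structure.chain(chain_id)
    keys = {r.key for r in residues}
    for k in dssp:
        if (k[0] == chain_id) and ((k[0], k[1], k[2]) not in
                                   {(c, n, i) for c, n, i in keys}):
            logger.warning("DSSP row %s absent from structure, dropped", k)
    rows = []
    for res in residues:
        key = (res.chain_id, res.seq_number, res.icode)
        if key in dssp:
            asa, ss = dssp[key]
            rows.append((asa, ss, False))
        else:
            rows.append((np.nan, "coil", True))
    index = pd.Index([r.key for r in residues], tupleize_cols=False)
    return pd.DataFrame(rows, columns=["asa", "ss", "missing"], index=index)


def ss_onehot(ss: str) -> np.ndarray:
    """7-dim one-hot over (H, G, I, E, B, T, S); coil is all zeros."""
    if ss == "coil":
        return np.zeros(7)
    if ss not in SS_CODES:
        raise ValueError(f"unknown secondary-structure code {ss!r}")
    out = np.zeros(7)
    out[SS_CODES.index(ss)] = 1.0
    return out
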