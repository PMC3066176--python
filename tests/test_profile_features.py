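"""Profiles, conservation entropy, residue properties, ASA and DSSP."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from catres.profile_features import (AA_ALPHABET, MAX_ASA, PSSM_COLUMN_ORDER,
                                     ProfileMatrix, aa_identity, aa_type,
                                     conservation_score, match_dssp, physchem,
                                     read_dssp, read_psiblast_pssm,
                                     relative_asa, shrake_rupley_asa,
                                     ss_onehot, write_psiblast_pssm)
from catres.structure_io import Atom, Residue, Structure
from catres.synthetic_fixtures import make_helix_structure


# --- PSSM ----------------------------------------------------------------

def pssm_text(rows):
    """Minimal PSI-BLAST ASCII dialect: (letter, logodds20, percents20)."""
    header = ["", "Last position-specific scoring matrix computed",
              "            " + " ".join(PSSM_COLUMN_ORDER) * 2]
    body = []
    for i, (letter, lo, pc) in enumerate(rows):
        nums = "".join(f"{v:4d}" for v in lo) + \
            "".join(f"{v:4d}" for v in pc)
        body.append(f"{i + 1:5d} {letter}  {nums}  0.36 0.09")
    return "\n".join(header + body + ["", "   Lambda  K", ""]) + "\n"


class TestReadPssm:
    def test_single_certain_position(self, tmp_path):
        pc = [0] * 20
        pc[PSSM_COLUMN_ORDER.index("A")] = 100
        path = tmp_path / "a.pssm"
        path.write_text(pssm_text([("A", [1] * 20, pc)]))
        profile = read_psiblast_pssm(path)
        expected = np.zeros(20)
        expected[AA_ALPHABET.index("A")] = 1.0
        np.testing.assert_allclose(profile.freqs[0], expected)

    def test_all_zero_percentage_row_flagged(self, tmp_path):
        path = tmp_path / "z.pssm"
        path.write_text(pssm_text([("G", [0] * 20, [0] * 20)]))
        profile = read_psiblast_pssm(path)
        assert profile.zero_rows[0]
        assert conservation_score(profile.freqs[0]) == 0.0

    def test_three_position_fixture(self, tmp_path):
        rows = [("M", [1] * 20, [5] * 20),
                ("K", [0] * 20, [5] * 20),
                ("V", [-1] * 20, [5] * 20)]
        path = tmp_path / "t.pssm"
        path.write_text(pssm_text(rows))
        profile = read_psiblast_pssm(path)
        assert profile.n_positions == 3
        assert profile.letters == "MKV"

    def test_column_reordering_of_logodds(self, tmp_path):
        lo = list(range(20))  # position value = PSSM column index
        path = tmp_path / "r.pssm"
        path.write_text(pssm_text([("A", lo, [5] * 20)]))
        profile = read_psiblast_pssm(path)
        for j, aa in enumerate(AA_ALPHABET):
            assert profile.logodds[0, j] == PSSM_COLUMN_ORDER.index(aa)

    def test_malformed_row_rejected(self, tmp_path):
        path = tmp_path / "bad.pssm"
        numbers = " ".join(["1"] * 40)
        path.write_text(f"    1 GG {numbers}\n")
        with pytest.raises(ValueError):
            read_psiblast_pssm(path)

    def test_writer_reader_roundtrip(self, tmp_path):
        rng = np.random.default_rng(4)
        freqs = rng.dirichlet(np.ones(20), size=5)
        profile = ProfileMatrix("MKVAL", rng.integers(-5, 9, (5, 20)), freqs)
        path = tmp_path / "rt.pssm"
        write_psiblast_pssm(profile, path)
        back = read_psiblast_pssm(path)
        assert back.letters == "MKVAL"
        np.testing.assert_allclose(back.logodds, profile.logodds)
        # writer floors percentages, so each entry may lose < 0.01
        np.testing.assert_allclose(back.freqs, profile.freqs, atol=0.011)


class TestConservation:
    def test_delta_distribution_is_zero(self):
        p = np.zeros(20)
        p[3] = 1.0
        assert conservation_score(p) == 0.0

    def test_uniform_is_ln20(self):
        assert conservation_score(np.full(20, 0.05)) == \
            pytest.approx(math.log(20))

    def test_two_state_half_half_is_ln2(self):
        p = np.zeros(20)
        p[0] = p[1] = 0.5
        assert conservation_score(p) == pytest.approx(math.log(2))

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            conservation_score([-0.1] + [0.0] * 19)

    @given(st.lists(st.floats(0.001, 1.0), min_size=20, max_size=20))
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_uniform_maximizes_entropy(self, raw):
        p = np.array(raw)
        p /= p.sum()
        assert conservation_score(p) <= math.log(20) + 1e-12


class TestResidueProperties:
    def test_identity_first_and_last(self):
        assert aa_identity("ALA")[0] == 1.0 and aa_identity("ALA").sum() == 1
        assert aa_identity("TYR")[19] == 1.0

    def test_identity_is_bijective_over_standards(self):
        from catres.structure_io import ONE_TO_THREE

        positions = {tuple(aa_identity(ONE_TO_THREE[aa]))
                     for aa in AA_ALPHABET}
        assert len(positions) == 20

    @pytest.mark.parametrize("resname,code", [
        ("LYS", (0, 0)), ("SER", (0, 1)), ("TRP", (1, 0)),
        ("ASP", (0, 0)), ("TYR", (0, 1)), ("GLY", (1, 0)),
    ])
    def test_aa_type_classes(self, resname, code):
        np.testing.assert_allclose(aa_type(resname), code)

    def test_physchem_pinned_values(self):
        assert physchem("ILE")[1] == 4.5       # Kyte-Doolittle max
        assert physchem("ARG")[1] == -4.5      # Kyte-Doolittle min
        volumes = [physchem(r)[2] for r in
                   ("ALA", "GLY", "TRP", "SER", "VAL")]
        assert physchem("GLY")[2] == min(volumes)

    def test_nonstandard_rejected(self):
        for fn in (aa_identity, aa_type, physchem):
            with pytest.raises(ValueError):
                fn("XXX")


# --- accessible surface area --------------------------------------------

def single_atom_structure():
    res = Residue(seq_number=1, icode="", name="ALA", chain_id="A",
                  atoms=[Atom("CA", "C", np.zeros(3))])
    return Structure(pdb_id="one", chains={"A": [res]})


class TestShrakeRupley:
    def test_isolated_carbon_matches_sphere_area(self):
        asa = shrake_rupley_asa(single_atom_structure(), "A")
        expected = 4 * math.pi * (1.70 + 1.4) ** 2  # 120.76 A^2
        assert asa[("A", 1, "")] == pytest.approx(expected, rel=0.01)

    def test_fully_enclosed_atom_has_no_area(self):
        # central carbon caged by 26 overlapping neighbors
        center = Residue(seq_number=1, icode="", name="ALA", chain_id="A",
                         atoms=[Atom("CA", "C", np.zeros(3))])
        shell_atoms = []
        offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                   for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
        for idx, off in enumerate(offsets):
            shell_atoms.append(Atom(f"C{idx}", "C",
                                    1.8 * np.array(off, dtype=float)))
        shell = Residue(seq_number=2, icode="", name="GLY", chain_id="A",
                        atoms=shell_atoms)
        s = Structure(pdb_id="cage", chains={"A": [center, shell]})
        asa = shrake_rupley_asa(s, "A")
        assert asa[("A", 1, "")] == pytest.approx(0.0, abs=1e-6)

    def test_overlapping_pair_occludes(self):
        lone = shrake_rupley_asa(single_atom_structure(), "A")[("A", 1, "")]
        r1 = Residue(seq_number=1, icode="", name="ALA", chain_id="A",
                     atoms=[Atom("CA", "C", np.zeros(3))])
        r2 = Residue(seq_number=2, icode="", name="ALA", chain_id="A",
                     atoms=[Atom("CA", "C", np.array([2.0, 0.0, 0.0]))])
        s = Structure(pdb_id="pair", chains={"A": [r1, r2]})
        asa = shrake_rupley_asa(s, "A")
        assert asa[("A", 1, "")] + asa[("A", 2, "")] < 2 * lone

    def test_point_count_convergence(self):
        """960 vs 4000 sphere points differ < 2% on a 10-residue helix."""
        s = make_helix_structure(10, seed=3)
        coarse = shrake_rupley_asa(s, "A", n_points=960)
        fine = shrake_rupley_asa(s, "A", n_points=4000)
        total_coarse = sum(coarse.values())
        total_fine = sum(fine.values())
        assert abs(total_coarse - total_fine) / total_fine < 0.02

    def test_cross_check_against_biopython(self, tmp_path):
        """Independent Shrake–Rupley (Biopython, same radii) agrees to 2%."""
        from Bio.PDB import PDBParser
        from Bio.PDB.SASA import ShrakeRupley

        from catres.structure_io import write_pdb

        s = make_helix_structure(8, seed=9)
        path = tmp_path / "helix.pdb"
        write_pdb(s, path)
        ours = shrake_rupley_asa(s, "A", n_points=960)

        bio = PDBParser(QUIET=True).get_structure("helix", str(path))
        ShrakeRupley(probe_radius=1.4, n_points=960,
                     radii_dict={"C": 1.70}).compute(bio[0], level="R")
        for res in bio[0]["A"]:
            key = ("A", res.id[1], "")
            assert ours[key] == pytest.approx(res.sasa, rel=0.02, abs=0.5)


class TestRelativeAsa:
    def test_extremes_and_linearity(self):
        assert relative_asa(MAX_ASA["A"], "ALA") == 1.0
        assert relative_asa(0.0, "ALA") == 0.0
        assert relative_asa(MAX_ASA["W"] / 2, "TRP") == 0.5

    def test_above_one_reported_as_is(self):
        assert relative_asa(2 * MAX_ASA["G"], "GLY") == pytest.approx(2.0)


# --- DSSP ----------------------------------------------------------------

def dssp_text(rows, with_break=False):
    """Classic DSSP dialect: (resnum, chain, aa, ss, acc) per row."""
    lines = [
        "==== Secondary Structure Definition by the program DSSP ====",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N"
        "    N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA"
        "   Y-CA   Z-CA",
    ]
    idx = 1
    for resnum, chain, aa, ss, acc in rows:
        line = (f"{idx:5d}{resnum:5d} {chain}{'':1s}{aa}  {ss}"
                + " " * 17 + f"{acc:4d}"
                + f"{0:7d},{-0.5:4.1f}{0:6d},{-0.5:4.1f}"
                + f"{0:6d},{-0.5:4.1f}{0:6d},{-0.5:4.1f}"
                + " " * 20 + f"{-60.0:6.1f}{-45.0:6.1f}"
                + f"{0.0:7.1f}{0.0:7.1f}{0.0:7.1f}")
        lines.append(line)
        idx += 1
        if with_break:
            lines.append(f"{idx:5d}      ! chain break")
            idx += 1
            with_break = False
    return "\n".join(lines) + "\n"


class TestDssp:
    def test_three_residue_fixture(self, tmp_path):
        path = tmp_path / "t.dssp"
        path.write_text(dssp_text([(1, "A", "A", "H", 100),
                                   (2, "A", "G", "H", 50),
                                   (3, "A", "V", " ", 25)]))
        dssp = read_dssp(path)
        assert dssp[("A", 1, "")] == (100.0, "H")
        assert dssp[("A", 3, "")][1] == "coil"

    def test_chain_break_rows_skipped(self, tmp_path):
        path = tmp_path / "b.dssp"
        path.write_text(dssp_text([(1, "A", "A", "E", 10),
                                   (2, "A", "G", "E", 20)], with_break=True))
        dssp = read_dssp(path)
        assert set(dssp) == {("A", 1, ""), ("A", 2, "")}

    def test_match_structure_residues(self, tmp_path):
        s = make_helix_structure(3, seed=0)
        one_letters = [r.one_letter for r in s.chain("A")]
        path = tmp_path / "m.dssp"
        # DSSP covers residues 1 and 2; extra row 99 has no counterpart
        path.write_text(dssp_text([(1, "A", one_letters[0], "H", 80),
                                   (2, "A", one_letters[1], "T", 40),
                                   (99, "A", "K", "H", 10)]))
        matched = match_dssp(s, "A", read_dssp(path))
        assert list(matched["ss"]) == ["H", "T", "coil"]
        assert matched["missing"].tolist() == [False, False, True]
        assert np.isnan(matched.loc[[("A", 3, "")], "asa"]).all()


class TestSsOnehot:
    def test_helix_and_coil(self):
        np.testing.assert_allclose(ss_onehot("H"),
                                   [1, 0, 0, 0, 0, 0, 0])
        np.testing.assert_allclose(ss_onehot("coil"), np.zeros(7))

    def test_component_sum_in_01(self):
        for code in ("H", "G", "I", "E", "B", "T", "S", "coil"):
            assert ss_onehot(code).sum() in (0.0, 1.0)

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            ss_onehot("Z")
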