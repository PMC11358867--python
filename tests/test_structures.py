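"""3D structure generation, grafting, file I/O and energy ingestion."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import rdMolAlign

from bvstereo.barcodes import SubstituentSet, canonical_form, reflect
from bvstereo.structures import (
    HARTREE_TO_KJ,
    DEFAULT_QC_TEMPLATE,
    StructureError,
    build_isomer,
    core_mol,
    core_template,
    ingest_energies,
    read_qc_energy,
    read_xyz,
    write_energy_csv,
    write_qc_input,
    write_xyz,
)

BETA_BETA = canonical_form((0, 1, 0, 0, 1, 0, 0, 0, 0, 0))
BETA_GAMMA = canonical_form((0, 1, 0, 0, 0, 1, 0, 0, 0, 0))


class TestCoreTemplate:
    def test_composition(self):
        st = core_template()
        assert st.elements.count("C") == 10
        assert st.elements.count("H") == 10

    def test_position_map_bijective_onto_carbons(self):
        st = core_template()
        atoms = sorted(st.position_map.values())
        assert sorted(st.position_map) == list(range(10))
        assert len(set(atoms)) == 10
        assert all(st.elements[i] == "C" for i in atoms)

    def test_alpha_has_three_beta_neighbors(self):
        mol = core_mol()
        alpha = mol.GetAtomWithIdx(0)
        nbrs = sorted(n.GetIdx() for n in alpha.GetNeighbors())
        assert nbrs == [1, 4, 7]  # the three beta positions

    def test_core_bond_length_sanity(self):
        st = core_template()
        p = st.coords
        for i, j in ((3, 6), (6, 9), (9, 3)):  # cyclopropane delta-delta
            assert np.linalg.norm(p[i] - p[j]) == pytest.approx(1.5, abs=0.1)
        for i, j in ((1, 2), (4, 5), (7, 8)):  # olefinic beta=gamma
            assert np.linalg.norm(p[i] - p[j]) == pytest.approx(1.34, abs=0.1)


class TestBuildIsomer:
    def test_parent_matches_template_composition(self):
        st = build_isomer("0" * 10, SubstituentSet.from_counts([]), n_conf=2).best
        assert st.n_atoms == 20

    def test_dimethyl_formula(self, me2, me2_structures):
        st = me2_structures["0000100100"]
        # C10H10 core with two H -> CH3 replacements: C12H14
        assert st.elements.count("C") == 12
        assert st.elements.count("H") == 14
        assert set(st.attachment_map) == {4, 7}

    def test_heavy_atom_budget(self):
        s = SubstituentSet.from_spec(["CCO:1"])
        b = canonical_form((0, 1, 0, 0, 0, 0, 0, 0, 0, 0))
        st = build_isomer(b, s, n_conf=3).best
        heavy = sum(1 for e in st.elements if e != "H")
        assert heavy == 10 + 3

    def test_determinism_same_seed(self, me2):
        a = build_isomer(BETA_GAMMA, me2, n_conf=4, seed=7).best
        b = build_isomer(BETA_GAMMA, me2, n_conf=4, seed=7).best
        assert np.array_equal(a.coords, b.coords)

    def test_enantiomers_isoenergetic_and_mirror_superposable(self, me2):
        partner = canonical_form(reflect(BETA_GAMMA))
        a = build_isomer(BETA_GAMMA, me2, n_conf=10, seed=42).best
        b = build_isomer(partner, me2, n_conf=10, seed=42).best
        assert a.energy == pytest.approx(b.energy, abs=1e-3)  # kcal/mol
        mirrored = Chem.Mol(a.mol)
        conf = mirrored.GetConformer()
        for i in range(mirrored.GetNumAtoms()):
            p = conf.GetAtomPosition(i)
            conf.SetAtomPosition(i, (-p.x, p.y, p.z))
        rms = rdMolAlign.GetBestRMS(mirrored, b.mol)
        assert rms < 0.1

    def test_unparseable_smiles_rejected(self):
        s = SubstituentSet.from_counts([1])
        b = canonical_form((1, 0, 0, 0, 0, 0, 0, 0, 0, 0))
        with pytest.raises(StructureError, match="no structure"):
            build_isomer(b, s)

    def test_conformer_batch_sorted(self, me2):
        batch = build_isomer(BETA_GAMMA, me2, n_conf=8, keep=3, seed=1)
        energies = [st.energy for st in batch.structures]
        assert energies == sorted(energies)
        assert batch.n_kept <= batch.n_generated


class TestFileIO:
    def test_xyz_round_trip(self, tmp_path):
        st = core_template()
        path = tmp_path / "parent.xyz"
        write_xyz(st, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "20"
        assert lines[1] == "0000000000"
        back = read_xyz(path)
        assert back.elements == st.elements
        assert np.allclose(back.coords, st.coords, atol=1e-6)

    def test_qc_input_substitution(self, tmp_path):
        st = core_template()
        path = tmp_path / "parent.inp"
        write_qc_input(st, path, DEFAULT_QC_TEMPLATE)
        text = path.read_text()
        assert "* xyz 0 1" in text
        assert text.count("\nC ") + text.count("\nH ") == 20

    def test_custom_template_placeholders(self, tmp_path):
        st = core_template()
        path = tmp_path / "custom.inp"
        write_qc_input(st, path, "q={charge} m={multiplicity}\n{coords}\n",
                       charge=1, multiplicity=2)
        assert path.read_text().startswith("q=1 m=2")


class TestEnergyIngestion:
    def test_equal_energies_relative_to_zero(self, tmp_path):
        path = tmp_path / "e.csv"
        write_energy_csv({"0000100100": 5.0, "0000010010": 5.0}, path)
        rel, missing = ingest_energies(path)
        assert rel == {"0000100100": 0.0, "0000010010": 0.0}
        assert missing == []

    def test_hartree_conversion(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text(
            "barcode,energy,unit\n0000100100,0.0,hartree\n0000010010,1.0,hartree\n"
        )
        rel, _ = ingest_energies(path)
        assert rel["0000010010"] == pytest.approx(HARTREE_TO_KJ)

    def test_missing_isomers_reported(self, me2, tmp_path):
        from bvstereo.barcodes import barcode_string, enumerate_isomers

        barcodes = [barcode_string(b) for b in enumerate_isomers(me2)]
        path = tmp_path / "e.csv"
        write_energy_csv({b: 0.0 for b in barcodes[:-1]}, path)
        _, missing = ingest_energies(path, expected=barcodes)
        assert missing == [barcodes[-1]]

    def test_conflicting_duplicate_rejected(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text(
            "barcode,energy,unit\n0000100100,0.0,kJ/mol\n0000100100,3.0,kJ/mol\n"
        )
        with pytest.raises(StructureError, match="conflicting"):
            ingest_energies(path)

    def test_qc_output_parsing(self, tmp_path):
        orca = tmp_path / "a.out"
        orca.write_text("stuff\nFINAL SINGLE POINT ENERGY      -465.123456\nend\n")
        assert read_qc_energy(orca) == pytest.approx(-465.123456)
        gau = tmp_path / "b.log"
        gau.write_text(" SCF Done:  E(RPBE0) =  -465.654321  A.U. after 9 cycles\n")
        assert read_qc_energy(gau) == pytest.approx(-465.654321)
        empty = tmp_path / "c.out"
        empty.write_text("no energies here\n")
        with pytest.raises(StructureError, match="no parseable"):
            read_qc_energy(empty)

    def test_qc_source_mapping(self, tmp_path):
        out = tmp_path / "iso.out"
        out.write_text("FINAL SINGLE POINT ENERGY -1.000000\n")
        out2 = tmp_path / "iso2.out"
        out2.write_text("FINAL SINGLE POINT ENERGY -1.100000\n")
        rel, _ = ingest_energies({"0000100100": out, "0000010010": out2})
        assert rel["0000010010"] == 0.0
        assert rel["0000100100"] == pytest.approx(0.1 * HARTREE_TO_KJ)
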