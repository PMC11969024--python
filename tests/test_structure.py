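"""Structure loading, inter-chain contacts, bond typing and occlusion."""

import numpy as np
import pytest

from mutascan import (
    ContactRules,
    StructureModel,
    build_model_manifest,
    classify_contacts,
    contact_residues,
    make_toy_complex,
    occlusion,
    read_structure,
    summarize_bonds,
)
from mutascan.structure import Atom, Residue


def single_atom_chain(prefix, positions, res_name="GLY", atom_name="CA", element="C"):
    return [
        Residue(i + 1, res_name, (Atom(atom_name, element, tuple(p)),))
        for i, p in enumerate(positions)
    ]


def model_of(**chains):
    return StructureModel("toy", chains)


class TestReadStructure:
    def test_round_trip_atom_counts(self, tmp_path):
        cif, pdb = make_toy_complex(tmp_path / "toy", n_site=4, n_blocked=2)
        model = read_structure(cif)
        assert model.n_atoms == 12 + 4 + 2
        assert set(model.chains) == {"A", "B", "C"}

    def test_cif_and_pdb_give_identical_models(self, tmp_path):
        cif, pdb = make_toy_complex(tmp_path / "toy", n_site=5, n_blocked=1)
        m1, m2 = read_structure(cif), read_structure(pdb)
        assert set(m1.chains) == set(m2.chains)
        for ch in m1.chains:
            r1, r2 = m1.chains[ch], m2.chains[ch]
            assert [(r.index, r.name) for r in r1] == [(r.index, r.name) for r in r2]
            c1 = [a.xyz for r in r1 for a in r.atoms]
            c2 = [a.xyz for r in r2 for a in r.atoms]
            assert np.allclose(c1, c2, atol=1e-3)

    def test_missing_chain_errors_for_contact_workflow(self, tmp_path):
        cif, _ = make_toy_complex(tmp_path / "toy")
        model = read_structure(cif)
        with pytest.raises(KeyError, match="'Z'"):
            contact_residues(model, "A", "Z")


class TestContactResidues:
    def test_pair_at_4p9_contacts_both_ways(self):
        m = model_of(A=single_atom_chain("a", [(0, 0, 0)]),
                     B=single_atom_chain("b", [(4.9, 0, 0)]))
        assert contact_residues(m, "A", "B") == {1}
        assert contact_residues(m, "B", "A") == {1}

    def test_pair_at_5p1_is_empty(self):
        m = model_of(A=single_atom_chain("a", [(0, 0, 0)]),
                     B=single_atom_chain("b", [(5.1, 0, 0)]))
        assert contact_residues(m, "A", "B") == set()

    def test_matches_brute_force_oracle_on_random_chains(self):
        rng = np.random.default_rng(12)
        pos_a = rng.uniform(0, 30, size=(30, 3))
        pos_b = rng.uniform(0, 30, size=(30, 3))
        m = model_of(A=single_atom_chain("a", pos_a), B=single_atom_chain("b", pos_b))
        got = contact_residues(m, "A", "B")
        oracle = set()
        for i, pa in enumerate(pos_a):
            for pb in pos_b:
                if np.sqrt(((pa - pb) ** 2).sum()) <= 5.0:
                    oracle.add(i + 1)
        assert got == oracle

    def test_symmetry_under_chain_swap(self):
        rng = np.random.default_rng(13)
        pos_a = rng.uniform(0, 20, size=(15, 3))
        pos_b = rng.uniform(0, 20, size=(15, 3))
        m = model_of(A=single_atom_chain("a", pos_a), B=single_atom_chain("b", pos_b))
        ab = contact_residues(m, "A", "B")
        ba = contact_residues(m, "B", "A")
        assert bool(ab) == bool(ba)


def two_residue_model(res_a, atom_a, elem_a, res_b, atom_b, elem_b, dist):
    a = [Residue(1, res_a, (Atom(atom_a, elem_a, (0.0, 0.0, 0.0)),))]
    b = [Residue(1, res_b, (Atom(atom_b, elem_b, (dist, 0.0, 0.0)),))]
    return model_of(A=a, B=b)


class TestClassifyContacts:
    def classes(self, model):
        pairs = classify_contacts(model, "A", "B")
        assert len(pairs) == 1
        return pairs[0].classes

    def test_apolar_carbon_pair_is_hydrophobic(self):
        m = two_residue_model("LEU", "CD1", "C", "ALA", "CB", "C", 4.0)
        assert "hydrophobic" in self.classes(m)

    def test_backbone_n_to_o_is_hydrogen(self):
        m = two_residue_model("GLY", "N", "N", "GLY", "O", "O", 3.0)
        cls = self.classes(m)
        assert "hydrogen" in cls and "vdw" in cls

    def test_salt_bridge_by_distance(self):
        near = two_residue_model("LYS", "NZ", "N", "GLU", "OE1", "O", 3.5)
        far = two_residue_model("LYS", "NZ", "N", "GLU", "OE1", "O", 4.5)
        assert "ionic" in self.classes(near)
        assert "ionic" not in self.classes(far)

    def test_polar_excludes_charged_atoms(self):
        m = two_residue_model("SER", "OG", "O", "THR", "OG1", "O", 3.2)
        assert "polar" in self.classes(m)
        salt = two_residue_model("LYS", "NZ", "N", "GLU", "OE1", "O", 3.2)
        assert "polar" not in self.classes(salt)

    def test_carbonyl_and_aromatic_rules(self):
        carbonyl = two_residue_model("ALA", "C", "C", "ALA", "O", "O", 3.4)
        assert "carbonyl" in self.classes(carbonyl)
        aromatic = two_residue_model("PHE", "CZ", "C", "TYR", "CE1", "C", 3.9)
        assert "aromatic" in self.classes(aromatic)

    def test_proximity_without_typed_interaction(self):
        # backbone N vs apolar carbon at 4.8: within site cutoff, no class
        m = two_residue_model("GLY", "N", "N", "ALA", "CB", "C", 4.8)
        assert self.classes(m) == frozenset()

    def test_classified_pairs_are_contact_pairs(self):
        rng = np.random.default_rng(14)
        pos_a = rng.uniform(0, 15, size=(10, 3))
        pos_b = rng.uniform(0, 15, size=(10, 3))
        m = model_of(A=single_atom_chain("a", pos_a, "LEU", "CD1"),
                     B=single_atom_chain("b", pos_b, "ALA", "CB"))
        pairs = classify_contacts(m, "A", "B")
        site = contact_residues(m, "A", "B")
        assert {p.res_a for p in pairs} <= site | {p.res_a for p in pairs}
        for p in pairs:
            assert p.min_distance <= 5.0


class TestSummarizeBonds:
    def test_empty_is_all_zero(self):
        df = summarize_bonds([])
        assert df.empty

    def test_counts_by_class(self):
        m_hydro = two_residue_model("LEU", "CD1", "C", "ALA", "CB", "C", 4.0)
        m_h = two_residue_model("GLY", "N", "N", "GLY", "O", "O", 3.0)
        pairs = classify_contacts(m_hydro, "A", "B") * 3 + classify_contacts(m_h, "A", "B")
        df = summarize_bonds(pairs)
        row = df.loc["all_models"]
        assert row["hydrophobic"] == 3 and row["hydrogen"] == 1
        assert row["all"] == row[list(df.columns[:-1])].sum()

    def test_per_peptide_residue_grouping_matches_groupby_oracle(self):
        rng = np.random.default_rng(15)
        pos_a = rng.uniform(0, 12, size=(8, 3))
        pos_b = rng.uniform(0, 12, size=(8, 3))
        m = model_of(A=single_atom_chain("a", pos_a, "LEU", "CD1"),
                     B=single_atom_chain("b", pos_b, "ALA", "CB"))
        pairs = classify_contacts(m, "A", "B")
        df = summarize_bonds(pairs, by="peptide_residue")
        for res_b in {p.res_b for p in pairs}:
            expect = sum(1 for p in pairs if p.res_b == res_b and "hydrophobic" in p.classes)
            assert df.loc[res_b, "hydrophobic"] == expect


class TestOcclusion:
    def test_full_overlap_blocks_everything(self, tmp_path):
        cif, _ = make_toy_complex(tmp_path / "toy", n_site=6, n_blocked=6)
        m = read_structure(cif)
        s = occlusion(m, m, "A", "B", "C")
        assert s.total_site_residues == 6 and s.blocked == 6

    def test_opposite_face_blocks_nothing(self, tmp_path):
        cif, _ = make_toy_complex(tmp_path / "toy", n_site=6, n_blocked=0)
        m = read_structure(cif)
        s = occlusion(m, m, "A", "B", "C")
        assert s.total_site_residues == 6 and s.blocked == 0

    def test_partial_overlap_prescription(self, tmp_path):
        cif, _ = make_toy_complex(tmp_path / "toy", n_site=7, n_blocked=3)
        m = read_structure(cif)
        s = occlusion(m, m, "A", "B", "C")
        assert (s.total_site_residues, s.blocked) == (7, 3)
        # brute-force check of the blocked set
        site = contact_residues(m, "A", "B")
        pep = contact_residues(m, "A", "C")
        assert len(site & pep) == 3 and site >= site & pep

    def test_numbering_mismatch_errors(self, tmp_path):
        cif, _ = make_toy_complex(tmp_path / "toy", n_site=4, n_blocked=2)
        m = read_structure(cif)
        probe = StructureModel("probe", dict(m.chains))
        probe.chains["A"] = [
            Residue(r.index, "ALA" if r.index == 2 else r.name, r.atoms)
            for r in probe.chains["A"]
        ]
        with pytest.raises(ValueError, match="mismatch"):
            occlusion(m, probe, "A", "B", "C")


class TestManifest:
    def test_46_by_3_gives_138_tasks(self):
        df = build_model_manifest([f"CK{i}" for i in range(46)], ["P1", "P2", "P3"])
        assert len(df) == 138

    def test_single_pair(self):
        assert len(build_model_manifest(["CK"], ["P"])) == 1

    def test_duplicates_deduplicated_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            df = build_model_manifest(
                ["CK"], ["P"], receptor_pairs=[("CK", "R"), ("CK", "R")])
        assert len(df) == 2
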