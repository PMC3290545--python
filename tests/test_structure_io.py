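import numpy as np
import pytest

from leapfs import structure_io as sio
from conftest import make_domain, make_molecule, make_residue

THREE_RES_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  CA  GLY A   2       5.000   0.000   0.000  1.00 10.00           C
ATOM      4  CA  SER A   3       8.500   0.000   0.000  1.00 10.00           C
ATOM      5  HA  SER A   3       8.900   0.500   0.000  1.00 10.00           H
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.50 10.00           C
ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.50 10.00           C
ATOM      3  CA  GLY A   2       5.000   0.000   0.000  1.00 10.00           C
END
"""

TWO_ENTITY_CIF = """\
data_test
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.auth_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_asym_id
ATOM 1 C CA . ALA A 1 1 1 ? 0.000 0.000 0.000 1.00 10.00 A
ATOM 2 C CA . GLY A 1 2 2 ? 3.800 0.000 0.000 1.00 10.00 A
ATOM 3 C CA . ALA B 2 1 1 ? 0.000 8.000 0.000 1.00 10.00 B
ATOM 4 C CA . GLY B 2 2 2 ? 3.800 8.000 0.000 1.00 10.00 B
"""


class TestReadStructure:
    def test_three_residue_pdb(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(THREE_RES_PDB)
        data = sio.read_structure(p)
        assert len(data.residues) == 3
        ser = data.residues[2]
        assert [a.is_heavy for a in ser.atoms] == [True, False]

    def test_first_altloc_kept(self, tmp_path):
        p = tmp_path / "altloc.pdb"
        p.write_text(ALTLOC_PDB)
        data = sio.read_structure(p)
        ala = data.residues[0]
        assert len(ala.atoms) == 1
        np.testing.assert_allclose(ala.atoms[0].coords, [1.0, 0.0, 0.0])

    def test_mmcif_entities_partitioned(self, tmp_path):
        p = tmp_path / "two.cif"
        p.write_text(TWO_ENTITY_CIF)
        data = sio.read_structure(p)
        entities = {r.chain_id: r.entity_id for r in data.residues}
        assert entities["A"] != entities["B"]

    def test_unparseable_file(self, tmp_path):
        p = tmp_path / "junk.pdb"
        p.write_text("this is not a structure\n")
        with pytest.raises((sio.StructureFormatError, sio.EmptyStructureError)):
            sio.read_structure(p)


class TestDomainDef:
    def test_parse_simple_range(self):
        d = sio.parse_domain_def("d13gsa_ 13gs A:2-209")
        assert d.domain_id == "d13gsa_"
        assert d.segments == (("A", 2, 209),)

    def test_parse_whole_chain_and_negative(self):
        assert sio.parse_domain_def("dx 1abc B:").segments == (("B", None, None),)
        assert sio.parse_domain_def("dx 1abc A:-5-100").segments == (("A", -5, 100),)

    def test_parse_multi_segment(self):
        d = sio.parse_domain_def("dx 1abc A:1-50,A:80-120")
        assert d.segments == (("A", 1, 50), ("A", 80, 120))


class TestExtractDomain:
    def _structure(self, n=100):
        residues = [make_residue("A", i + 1, "ALA", [[i * 3.8, 0, 0]])
                    for i in range(n)]
        return sio.StructureData("test", residues)

    def test_range_subset(self):
        dom = sio.extract_domain(self._structure(),
                                 sio.parse_domain_def("d1 t A:1-50"))
        assert len(dom.residues) == 50

    def test_gap_in_range_ok(self):
        st = self._structure(20)
        st.residues = [r for r in st.residues if r.auth_seq_num not in (5, 6)]
        dom = sio.extract_domain(st, sio.parse_domain_def("d1 t A:1-10"))
        assert len(dom.residues) == 8

    def test_absent_chain_errors(self):
        with pytest.raises(sio.EmptyDomainError):
            sio.extract_domain(self._structure(),
                               sio.parse_domain_def("d1 t Z:1-50"))

    def test_peptide_chain_becomes_cochain(self):
        residues = [make_residue("A", i + 1, "ALA", [[i * 3.8, 0, 0]])
                    for i in range(10)]
        peptide = [make_residue("B", i + 1, "GLY", [[i * 3.8, 6, 0]],
                                subchain="Bxp") for i in range(3)]
        st = sio.StructureData("test", residues + peptide)
        dom = sio.extract_domain(st, sio.parse_domain_def("d1 t A:1-10"))
        assert len(dom.cochains) == 1
        assert dom.cochains[0].comp_ids == ("GLY", "GLY", "GLY")


class TestNSMSites:
    def _domain_with_ligand(self, dist):
        res = [make_residue("A", 1, "ALA", [[0, 0, 0]]),
               make_residue("A", 2, "GLY", [[20, 0, 0]])]
        mol = make_molecule(["LIG"], [[dist, 0, 0]])
        return make_domain(res, [mol])

    @pytest.mark.parametrize("dist,expected", [(4.9, 1), (5.1, 0)])
    def test_cutoff_boundary(self, dist, expected):
        sites = sio.find_nsm_sites(self._domain_with_ligand(dist))
        total = sum(len(s.residues) for s in sites)
        assert total == expected

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(0)
        res = [make_residue("A", i, "ALA", [rng.uniform(-8, 8, 3)])
               for i in range(1, 15)]
        mol = make_molecule(["LIG"], rng.uniform(-8, 8, (3, 3)).tolist())
        dom = make_domain(res, [mol])
        prev: set = set()
        for cutoff in (8.0, 6.0, 4.0, 2.0):
            sites = sio.find_nsm_sites(dom, cutoff=cutoff)
            cur = set().union(*(s.residues for s in sites)) if sites else set()
            if cutoff < 8.0:
                assert cur <= prev
            prev = cur

    def test_matches_brute_force(self):
        rng = np.random.default_rng(42)
        res = [make_residue("A", i, "ALA", rng.uniform(-10, 10, (2, 3)).tolist())
               for i in range(1, 20)]
        mol = make_molecule(["XYZ"], rng.uniform(-10, 10, (4, 3)).tolist())
        dom = make_domain(res, [mol])
        sites = sio.find_nsm_sites(dom, cutoff=5.0)
        got = set().union(*(s.residues for s in sites)) if sites else set()
        # oracle: direct all-pairs scan
        expected = set()
        mol_pts = mol.heavy_coords()
        for r in res:
            for a in r.heavy_coords():
                if np.any(np.linalg.norm(mol_pts - a, axis=1) <= 5.0):
                    expected.add(r.key)
        assert got == expected


class TestMoad:
    def _sites(self):
        res = frozenset([("A", 1, "")])
        return [
            sio.NSMSite("s1", ("SAS",), "C1", res),
            sio.NSMSite("s2", ("MES",), "C2", res),
            sio.NSMSite("s3", ("GGL", "CYS", "GLY"), "C3", res),
            sio.NSMSite("s4", ("GGL", "CYS", "GLY"), "C4", res),
            sio.NSMSite("s5", ("UNK",), "C5", res),
        ]

    def test_glutathione_transferase_example(self):
        """SAS valid, MES invalid, glutathione matched through a synonym."""
        records = [
            sio.MoadRecord("13gs", ("SAS",), "valid"),
            sio.MoadRecord("13gs", ("GLU", "CYS", "GLY"), "valid"),
            sio.MoadRecord("13gs", ("MES",), "invalid"),
        ]
        sites = sio.match_moad(self._sites(), records, "13gs",
                               synonyms={"GGL": "GLU"})
        validity = {s.site_id: s.validity for s in sites}
        assert validity == {"s1": "valid", "s2": "invalid", "s3": "valid",
                            "s4": "valid", "s5": "uncurated"}

    def test_without_synonym_glutathione_unmatched(self):
        records = [sio.MoadRecord("13gs", ("GLU", "CYS", "GLY"), "valid")]
        sites = sio.match_moad(self._sites(), records, "13gs")
        assert {s.validity for s in sites if s.site_id in ("s3", "s4")} == {"uncurated"}

    def test_load_moad_skips_malformed(self, tmp_path, caplog):
        p = tmp_path / "every_bind.csv"
        p.write_text("13gs,SAS,valid\nbadline\n13gs,GLU-CYS-GLY,valid\n"
                     "13gs,MES,bogus\n")
        recs = sio.load_moad(p)
        assert len(recs) == 2
        assert recs[1].codes == ("GLU", "CYS", "GLY")


class TestCSA:
    def test_lit_kept_psiblast_dropped(self, tmp_path):
        p = tmp_path / "csa.csv"
        p.write_text(
            "pdb_id,chain_id,auth_seq_num,comp_id,evidence\n"
            "13gs,A,7,TYR,LIT\n"
            "13gs,A,98,ARG,PSI-BLAST\n"
            "13gs,A,51,SER,GUESS\n"
        )
        anns = sio.load_csa(p)
        assert [(a.auth_seq_num, a.evidence) for a in anns] == [(7, "LIT")]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        assert sio.load_csa(p) == []
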