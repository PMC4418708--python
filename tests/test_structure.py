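import math

import numpy as np
import pytest

from dmipred.structure import (
    Atom,
    Residue,
    StructAlignment,
    Structure,
    TemplateComplex,
    accessible_surface,
    assign_psd_bin,
    filter_templates,
    interface_coverage,
    interfacial_residues,
    parse_pdb,
    read_struct_alignments,
    residue_asa,
    write_struct_alignments,
)
from dmipred.synthetic import generate_toy_complex

from conftest import point_residue, two_chain_complex

TOY_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
HETATM    3  O   HOH A 101      20.000  20.000  20.000  1.00  0.00           O
ATOM      4  CA  ALA B   1       0.000   5.000   0.000  1.00  0.00           C
TER
END
"""


class TestParsePdb:
    def test_two_chain_toy_file(self, tmp_path):
        pdb_text, template, _ = generate_toy_complex(prd_size=8, peptide_len=5)
        path = tmp_path / "t.pdb"
        path.write_text(pdb_text)
        s = parse_pdb(path)
        assert [len(s.chains["A"]), len(s.chains["B"])] == [8, 5]

    def test_first_model_only(self, tmp_path):
        text = (
            "MODEL        1\n"
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\nEND\n"
        )
        path = tmp_path / "m.pdb"
        path.write_text(text)
        assert len(parse_pdb(path).residues()) == 1

    def test_hetatm_skipped(self, tmp_path):
        path = tmp_path / "h.pdb"
        path.write_text(TOY_PDB)
        s = parse_pdb(path)
        assert sorted(s.chains) == ["A", "B"]
        assert len(s.residues()) == 3  # water ignored

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "e.pdb"
        path.write_text("")
        with pytest.raises(ValueError):
            parse_pdb(path)


class TestInterfacialResidues:
    def test_boundary_inclusive_at_4p4(self):
        assert interfacial_residues(two_chain_complex(4.4)) == {("A", 1, "")}

    def test_excluded_at_4p6(self):
        assert interfacial_residues(two_chain_complex(4.6)) == set()

    def test_rigid_translation_invariance(self):
        template = two_chain_complex(4.0)
        shifted_chains = {
            cid: [
                Residue(r.chain_id, r.resnum, r.icode, r.resname,
                        tuple(Atom(a.name, a.element, a.x + 10, a.y + 10, a.z + 10)
                              for a in r.atoms))
                for r in residues
            ]
            for cid, residues in template.structure.chains.items()
        }
        shifted = TemplateComplex("T", Structure(shifted_chains), "A", "B")
        assert interfacial_residues(shifted) == interfacial_residues(template)

    def test_cutoff_monotonicity(self):
        template = two_chain_complex(4.0)
        small = interfacial_residues(template, cutoff=3.0)
        large = interfacial_residues(template, cutoff=8.0)
        assert small <= large

    def test_empty_peptide_chain_is_an_error(self):
        s = Structure({"A": [point_residue("A", 1, (0, 0, 0))]})
        with pytest.raises(ValueError):
            interfacial_residues(TemplateComplex("T", s, "A", "B"))


def _rotation(theta_deg: float) -> np.ndarray:
    t = math.radians(theta_deg)
    return np.array(
        [[math.cos(t), -math.sin(t), 0], [math.sin(t), math.cos(t), 0], [0, 0, 1]]
    )


class TestAccessibleSurface:
    def test_isolated_atom_matches_closed_form(self):
        s = Structure({"A": [point_residue("A", 1, (0, 0, 0), element="C")]})
        asa = residue_asa(s)[("A", 1, "")]
        exact = 4 * math.pi * (1.7 + 1.4) ** 2
        assert asa == pytest.approx(exact, rel=0.02)
        assert accessible_surface(s) == {("A", 1, "")}

    def test_two_atom_spherical_cap(self):
        # overlap region: each sphere loses a cap of height R - (d^2+R^2-R'^2)/2d
        r1 = r2 = 1.7 + 1.4
        for d in (1.0, 1.8, 2.5, 3.3, 4.0):
            s = Structure({
                "A": [
                    point_residue("A", 1, (0, 0, 0)),
                    point_residue("A", 2, (d, 0, 0)),
                ]
            })
            h = r1 - (d * d + r1 * r1 - r2 * r2) / (2 * d)
            exact = 4 * math.pi * r1**2 - 2 * math.pi * r1 * h
            asa = residue_asa(s)
            assert asa[("A", 1, "")] == pytest.approx(exact, rel=0.02)
            assert asa[("A", 2, "")] == pytest.approx(exact, rel=0.02)

    def test_enclosed_atom_is_buried(self):
        # dense icosphere-ish shell of atoms around the center
        shell = []
        k = 1
        golden = math.pi * (3 - math.sqrt(5))
        for i in range(60):
            z = 1 - 2 * (i + 0.5) / 60
            r = math.sqrt(1 - z * z)
            shell.append(
                point_residue("A", k := k + 1, (3.0 * r * math.cos(golden * i),
                                                3.0 * r * math.sin(golden * i), 3.0 * z))
            )
        center = point_residue("A", 1, (0, 0, 0))
        s = Structure({"A": [center] + shell})
        assert residue_asa(s)[("A", 1, "")] < 1.0
        assert ("A", 1, "") not in accessible_surface(s)

    def test_deterministic(self):
        pdb_text, template, _ = generate_toy_complex()
        a = residue_asa(template.structure)
        b = residue_asa(template.structure)
        assert a == b

    def test_rotation_invariance(self):
        _, template, _ = generate_toy_complex(prd_size=8, peptide_len=5)
        rot = _rotation(37.0)
        rotated_chains = {
            cid: [
                Residue(r.chain_id, r.resnum, r.icode, r.resname,
                        tuple(Atom(a.name, a.element, *(rot @ [a.x, a.y, a.z]))
                              for a in r.atoms))
                for r in residues
            ]
            for cid, residues in template.structure.chains.items()
        }
        base = residue_asa(template.structure)
        rotated = residue_asa(Structure(rotated_chains))
        for ref, value in base.items():
            assert rotated[ref] == pytest.approx(value, abs=2.0)

    def test_agrees_with_biopython_shrake_rupley(self, tmp_path):
        """Independent oracle: Bio.PDB's sampler with the same radii."""
        from Bio.PDB import PDBParser
        from Bio.PDB.SASA import ShrakeRupley

        pdb_text, template, _ = generate_toy_complex(prd_size=10, peptide_len=6)
        path = tmp_path / "t.pdb"
        path.write_text(pdb_text)
        model = PDBParser(QUIET=True).get_structure("t", str(path))[0]
        ShrakeRupley(probe_radius=1.4, n_points=960, radii_dict={"C": 1.7}).compute(
            model, level="R"
        )
        mine = residue_asa(template.structure)
        for chain in model:
            for res in chain:
                ref = (chain.id, res.id[1], res.id[2].strip())
                assert mine[ref] == pytest.approx(res.sasa, rel=0.05, abs=1.0)


class TestInterfaceCoverage:
    def _aln(self, n_mapped):
        corr = {("A", i, ""): ("A", i, "") for i in range(1, n_mapped + 1)}
        return StructAlignment("T", "P1", 0.2, corr)

    def test_six_of_eight_passes_at_threshold(self):
        interfacial = {("A", i, "") for i in range(1, 9)}
        surface = {("A", i, "") for i in range(1, 7)}
        frac, ok = interface_coverage(self._aln(8), interfacial, surface)
        assert frac == pytest.approx(0.75)
        assert ok  # the 75% boundary is inclusive

    def test_five_of_eight_fails(self):
        interfacial = {("A", i, "") for i in range(1, 9)}
        surface = {("A", i, "") for i in range(1, 6)}
        frac, ok = interface_coverage(self._aln(8), interfacial, surface)
        assert frac == pytest.approx(0.625)
        assert not ok

    def test_empty_correspondence_is_zero_fail(self):
        interfacial = {("A", 1, "")}
        frac, ok = interface_coverage(
            StructAlignment("T", "P1", 0.2, {}), interfacial, {("A", 1, "")}
        )
        assert (frac, ok) == (0.0, False)

    def test_empty_interfacial_set_is_an_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            interface_coverage(self._aln(1), set(), set())


class TestPsdBins:
    @pytest.mark.parametrize(
        "psd, expected",
        [(0.25, "P1"), (0.3, "P1"), (0.5, "P2"), (0.64, "P2"), (0.65, None), (0.7, None)],
    )
    def test_bin_edges(self, psd, expected):
        assert assign_psd_bin(psd) == expected

    def test_negative_psd_is_an_error(self):
        with pytest.raises(ValueError):
            assign_psd_bin(-0.1)


class TestFilterTemplates:
    def _template(self, peptide_len, multimer=False):
        prd = [point_residue("A", 1, (0, 0, 0))]
        pep = [point_residue("B", j + 1, (4.0 * j, 0, 5.0)) for j in range(peptide_len)]
        return TemplateComplex("T", Structure({"A": prd, "B": pep}), "A", "B", multimer)

    def test_short_peptide_excluded(self):
        assert filter_templates([self._template(4)]) == []

    def test_length_35_monomer_retained(self):
        t = self._template(35)
        assert filter_templates([t]) == [t]

    def test_multimer_excluded(self):
        assert filter_templates([self._template(8, multimer=True)]) == []


def test_struct_alignment_round_trip(tmp_path):
    alignments = [
        StructAlignment("T1", "P1", 0.25, {("A", 1, ""): ("A", 3, ""), ("A", 2, ""): ("A", 4, "")}),
        StructAlignment("T2", "P2", 0.5, {("A", 1, ""): ("A", 1, "")}),
    ]
    write_struct_alignments(tmp_path / "a.tsv", alignments)
    back = read_struct_alignments(tmp_path / "a.tsv")
    assert back == alignments


def test_struct_alignment_requires_injective_correspondence():
    with pytest.raises(ValueError, match="injective"):
        StructAlignment("T", "P", 0.2, {("A", 1, ""): ("A", 1, ""), ("A", 2, ""): ("A", 1, "")})
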