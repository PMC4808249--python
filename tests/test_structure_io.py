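import numpy as np
import pytest

from ccprofile.fixtures import FixtureSpec, make_backbone, make_hinge_pair, write_fixture
from ccprofile.structure_io import (
    Atom,
    ChainNotFoundError,
    MappingError,
    Residue,
    heavy_atoms,
    longest_disordered_run,
    map_observed_to_seqres,
    read_pdb,
    write_pdb,
)


def _roundtrip(sf, tmp_path, name="f.pdb"):
    path = tmp_path / name
    write_fixture(sf, path)
    return read_pdb(path)


class TestReadPdb:
    def test_seqres_longer_than_observed(self, tmp_path):
        spec = FixtureSpec(length=30, deleted_free=[(5, 9)], free_id="1AAA")
        sf = _roundtrip(make_backbone(spec), tmp_path)
        chain = sf.chain("A")
        assert len(chain.seqres) == 30
        assert len(chain.observed) == 25
        assert chain.disordered == {5, 6, 7, 8, 9}

    def test_het_group_with_atom_count(self, tmp_path):
        spec = FixtureSpec(length=20, hinge_position=10,
                           ligands=[("GNP", 10, 5.0, 32)], free_id="1AAB")
        _, bound = make_hinge_pair(spec)
        sf = _roundtrip(bound, tmp_path)
        assert ("GNP", 32) in sf.het_groups

    def test_mse_translates_to_met(self, tmp_path):
        text = "\n".join([
            "SEQRES   1 A    3  ALA MSE GLY",
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C",
            "HETATM    2  CA  MSE A   2       3.800   0.000   0.000  1.00  0.00           C",
            "ATOM      3  CA  GLY A   3       7.600   0.000   0.000  1.00  0.00           C",
            "END",
        ])
        path = tmp_path / "mse.pdb"
        path.write_text(text)
        chain = read_pdb(path).chain("A")
        assert chain.seqres == "AMG"
        assert chain.observed[2].name3 == "MSE"

    def test_altloc_keeps_highest_occupancy_tie_first(self, tmp_path):
        text = "\n".join([
            "SEQRES   1 A    1  ALA",
            "ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.40  0.00           C",
            "ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.60  0.00           C",
            "ATOM      3  CB AALA A   1       3.000   0.000   0.000  0.50  0.00           C",
            "ATOM      4  CB BALA A   1       4.000   0.000   0.000  0.50  0.00           C",
            "END",
        ])
        path = tmp_path / "alt.pdb"
        path.write_text(text)
        res = read_pdb(path).chain("A").observed[1]
        assert res.atom("CA").coords[0] == pytest.approx(2.0)  # higher occupancy
        assert res.atom("CB").coords[0] == pytest.approx(3.0)  # tie -> first

    def test_waters_counted_not_stored(self, tmp_path):
        text = "\n".join([
            "SEQRES   1 A    1  ALA",
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C",
            "HETATM    2  O   HOH A 101       9.000   0.000   0.000  1.00  0.00           O",
            "HETATM    3  O   HOH A 102      12.000   0.000   0.000  1.00  0.00           O",
            "END",
        ])
        path = tmp_path / "wat.pdb"
        path.write_text(text)
        sf = read_pdb(path)
        assert sf.waters == 2
        assert not sf.het_residues

    def test_model_1_only(self, tmp_path):
        text = "\n".join([
            "SEQRES   1 A    1  ALA",
            "MODEL        1",
            "ATOM      1  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C",
            "ENDMDL",
            "MODEL        2",
            "ATOM      1  CA  ALA A   1       9.000   0.000   0.000  1.00  0.00           C",
            "ENDMDL",
            "END",
        ])
        path = tmp_path / "models.pdb"
        path.write_text(text)
        chain = read_pdb(path).chain("A")
        assert chain.observed[1].atom("CA").coords[0] == pytest.approx(1.0)

    def test_remark_metadata(self, tmp_path):
        text = "\n".join([
            "REMARK   2 RESOLUTION.    2.00 ANGSTROMS.",
            "REMARK 200  PH                             : 7.5",
            "REMARK 200  TEMPERATURE           (KELVIN) : 100",
            "SEQRES   1 A    1  ALA",
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C",
            "END",
        ])
        path = tmp_path / "meta.pdb"
        path.write_text(text)
        sf = read_pdb(path)
        assert sf.resolution == pytest.approx(2.0)
        assert sf.ph == pytest.approx(7.5)
        assert sf.temperature == pytest.approx(100.0)

    def test_missing_chain_raises_with_name(self, tmp_path):
        sf = _roundtrip(make_backbone(FixtureSpec(length=10)), tmp_path)
        with pytest.raises(ChainNotFoundError, match="'Z'"):
            sf.chain("Z")

    def test_unparseable_record_reports_line(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text("ATOM      1  CA  ALA A   1      badcoordinates here\n")
        with pytest.raises(Exception, match="bad.pdb:1"):
            read_pdb(path)


class TestObservedToSeqres:
    @staticmethod
    def _residues(letters, numbers, chain="A"):
        from ccprofile.constants import ONE_TO_THREE

        return [
            Residue(ONE_TO_THREE[l], chain, n, atoms=[Atom("CA", "C", (0, 0, 0))])
            for l, n in zip(letters, numbers)
        ]

    def test_identity_assignment(self):
        seq = "ACDEFG"
        obs = self._residues(seq, range(1, 7))
        assignment = map_observed_to_seqres(obs, seq)
        assert sorted(assignment) == [1, 2, 3, 4, 5, 6]
        assert all(assignment[i].one_letter() == seq[i - 1] for i in assignment)

    def test_deleted_interior_unassigned(self):
        seq = "ACDEFGHIKL"
        keep = [1, 2, 3, 4, 9, 10]  # drop 5..8
        obs = self._residues([seq[i - 1] for i in keep], keep)
        assignment = map_observed_to_seqres(obs, seq)
        assert set(assignment) == set(keep)

    def test_offset_numbering_found_by_scan(self):
        # oracle: exhaustive offset scan over author numbers
        seq = "MKVLAWQRTY"
        window = seq[2:8]
        numbers = [n + 10 for n in range(3, 9)]  # author numbering offset +10
        obs = self._residues(window, numbers)
        assignment = map_observed_to_seqres(obs, seq)

        def oracle():
            for delta in range(-30, 31):
                positions = [n + delta for n in numbers]
                if all(
                    1 <= p <= len(seq) and seq[p - 1] == l
                    for p, l in zip(positions, window)
                ):
                    return dict(zip(positions, obs))
            raise AssertionError("oracle found no offset")

        assert assignment.keys() == oracle().keys()

    def test_unembeddable_raises(self):
        obs = self._residues("WWW", [1, 2, 3])
        with pytest.raises(MappingError):
            map_observed_to_seqres(obs, "AAAA")

    def test_partition_invariant(self, tmp_path):
        spec = FixtureSpec(length=40, deleted_free=[(3, 5), (20, 29)])
        sf = _roundtrip(make_backbone(spec), tmp_path)
        chain = sf.chain("A")
        observed = set(chain.observed)
        assert observed | chain.disordered == set(range(1, 41))
        assert observed & chain.disordered == set()


class TestHeavyAtoms:
    def test_hydrogens_removed(self):
        res = Residue("ALA", "A", 1, atoms=[
            Atom("N", "N", (0, 0, 0)), Atom("CA", "C", (1, 0, 0)),
            Atom("C", "C", (2, 0, 0)), Atom("O", "O", (3, 0, 0)),
            Atom("CB", "C", (4, 0, 0)),
            Atom("H", "H", (5, 0, 0)), Atom("HA", "H", (6, 0, 0)),
            Atom("D1", "D", (7, 0, 0)),
        ])
        names = [a.name for a in heavy_atoms(res)]
        assert names == ["N", "CA", "C", "O", "CB"]

    def test_no_hydrogens_unchanged(self):
        res = Residue("GLY", "A", 1, atoms=[
            Atom("N", "N", (0, 0, 0)), Atom("CA", "C", (1, 0, 0)),
            Atom("C", "C", (2, 0, 0)), Atom("O", "O", (3, 0, 0)),
        ])
        assert heavy_atoms(res) == res.atoms

    def test_water_single_atom(self):
        res = Residue("HOH", "A", 1, atoms=[Atom("O", "O", (0, 0, 0))], is_het=True)
        assert len(heavy_atoms(res)) == 1

    def test_idempotent(self):
        res = Residue("ALA", "A", 1, atoms=[
            Atom("CA", "C", (0, 0, 0)), Atom("H", "H", (1, 0, 0)),
        ])
        once = heavy_atoms(res)
        res2 = Residue("ALA", "A", 1, atoms=once)
        assert heavy_atoms(res2) == once


class TestWritePdb:
    def test_roundtrip_atoms_and_coords(self, tmp_path):
        sf = make_backbone(FixtureSpec(length=15, geometry="helix"))
        chain = sf.chain("A")
        path = tmp_path / "rt.pdb"
        write_pdb([chain], path)
        back = read_pdb(path).chain("A")
        assert set(back.observed) == set(chain.observed)
        for i in chain.observed:
            a, b = chain.observed[i], back.observed[i]
            assert [x.name for x in a.atoms] == [x.name for x in b.atoms]
            for x, y in zip(a.atoms, b.atoms):
                assert np.allclose(x.coords, y.coords, atol=1e-3)

    def test_two_identical_models(self, tmp_path):
        chain = make_backbone(FixtureSpec(length=10)).chain("A")
        path = tmp_path / "two.pdb"
        write_pdb([chain, chain], path)
        text = path.read_text()
        assert text.count("ENDMDL") == 2
        assert len([l for l in text.splitlines() if l.startswith("MODEL")]) == 2
        m1 = [l for l in text.splitlines() if l.startswith("ATOM")]
        assert len(m1) == 2 * 4 * 10  # two models, 4 backbone atoms, 10 residues

    def test_single_structure_one_model_pair(self, tmp_path):
        chain = make_backbone(FixtureSpec(length=5)).chain("A")
        path = tmp_path / "one.pdb"
        write_pdb([chain], path)
        text = path.read_text()
        assert text.count("MODEL") == 1 + text.count("ENDMDL") - 1
        assert text.count("ENDMDL") == 1

    def test_nonfinite_coordinates_rejected(self, tmp_path):
        with pytest.raises(Exception):
            Atom("CA", "C", (np.nan, 0, 0))


class TestDisorderedRuns:
    def test_longest_run(self):
        chain = make_backbone(
            FixtureSpec(length=50, deleted_free=[(5, 6), (20, 26), (40, 42)])
        ).chain("A")
        assert longest_disordered_run(chain) == (20, 26)
        assert longest_disordered_run(chain, start=1, end=10) == (5, 6)

    def test_no_disorder_raises(self):
        chain = make_backbone(FixtureSpec(length=10)).chain("A")
        with pytest.raises(ValueError):
            longest_disordered_run(chain)
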