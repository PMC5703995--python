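"""SASA point sampling, burial thresholds, disulphide and heteroatom screens."""

import numpy as np
import pytest

from cysredox.structure import Atom, Chain, Residue, SSBondRecord, Structure, parse_structure
from cysredox.surface import (MissingAtomError, compute_sasa,
                              detect_disulphides, heteroatom_neighbors,
                              isolated_atom_sasa, sphere_lattice)
from cysredox.synth import make_ideal_helix

from conftest import make_cys_pair_pdb


def single_atom_structure(element="S", pos=(0, 0, 0)):
    atom = Atom(name="SG", element=element, pos=np.array(pos, dtype=float))
    res = Residue(chain_id="A", number=1, icode="", name="CYS", atoms=[atom])
    return Structure(id="one", chains=[Chain(id="A", residues=[res])])


class TestSasa:
    def test_isolated_sphere_analytic(self):
        st = single_atom_structure()
        result = compute_sasa(st, n_points=960)
        expected = 4 * np.pi * (1.8 + 1.4) ** 2
        assert result.sg_sasa[("A", 1, "")] == pytest.approx(expected, rel=0.01)
        assert isolated_atom_sasa("S") == pytest.approx(expected)

    def test_fully_overlapping_atoms_split_one_sphere(self):
        st = single_atom_structure()
        st.chains[0].residues.append(Residue(
            chain_id="A", number=2, icode="", name="CYS",
            atoms=[Atom(name="SG", element="S", pos=np.zeros(3))]))
        result = compute_sasa(st, n_points=960)
        total = sum(result.atom_sasa.values())
        one_sphere = 4 * np.pi * (1.8 + 1.4) ** 2
        assert result.atom_sasa[("A", 1, "", "SG")] == pytest.approx(
            one_sphere / 2, rel=0.01)
        assert total == pytest.approx(one_sphere, rel=0.01)

    def test_pair_against_dense_grid_oracle(self):
        st = single_atom_structure()
        st.chains[0].residues.append(Residue(
            chain_id="A", number=2, icode="", name="CYS",
            atoms=[Atom(name="SG", element="S", pos=np.array([3.0, 0, 0]))]))
        coarse = compute_sasa(st, n_points=960)
        dense = compute_sasa(st, n_points=100_000)
        for key in coarse.atom_sasa:
            assert coarse.atom_sasa[key] == pytest.approx(
                dense.atom_sasa[key], rel=0.01)

    def test_rotation_translation_invariance(self, rng):
        st = make_ideal_helix("ACAAAKACA")
        base = compute_sasa(st, n_points=960)
        # random proper rotation + shift
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = rng.normal(scale=20.0, size=3)
        moved = make_ideal_helix("ACAAAKACA")
        for res in moved.residues():
            for atom in res.atoms:
                atom.pos = q @ atom.pos + shift
        rotated = compute_sasa(moved, n_points=960)
        total_before = sum(base.atom_sasa.values())
        total_after = sum(rotated.atom_sasa.values())
        assert total_after == pytest.approx(total_before, rel=0.005)
        for key, v in base.atom_sasa.items():
            assert rotated.atom_sasa[key] == pytest.approx(v, abs=1.5)

    def test_distant_atom_changes_nothing(self):
        st = make_ideal_helix("ACAA")
        base = compute_sasa(st, n_points=960)
        st.chains[0].residues.append(Residue(
            chain_id="A", number=99, icode="", name="CYS",
            atoms=[Atom(name="SG", element="S", pos=np.array([500.0, 0, 0]))]))
        with_far = compute_sasa(st, n_points=960)
        for key, v in base.atom_sasa.items():
            assert with_far.atom_sasa[key] == pytest.approx(v, abs=1e-9)

    def test_burial_classifications_nested(self):
        st = make_ideal_helix("ACAAAAAAA")
        sasa = compute_sasa(st)
        key = ("A", 2, "")
        labels = [sasa.classify_sg(key, t) for t in (0.0, 0.1, 1.0)]
        # accessible at a high threshold implies accessible at lower ones
        if labels[2] == "accessible":
            assert labels[:2] == ["accessible", "accessible"]
        if labels[0] == "buried":
            assert labels[1:] == ["buried", "buried"]

    def test_lattice_is_deterministic_and_unit(self):
        a = sphere_lattice(960)
        b = sphere_lattice(960)
        assert np.array_equal(a, b)
        assert np.allclose(np.linalg.norm(a, axis=1), 1.0)


class TestDisulphides:
    @pytest.mark.parametrize("d,n_pairs", [(2.05, 1), (2.9, 0)])
    def test_geometric_cutoff(self, d, n_pairs):
        st = parse_structure(make_cys_pair_pdb(d))
        assert len(detect_disulphides(st)) == n_pairs

    def test_ssbond_record_trusted_beyond_cutoff(self):
        st = parse_structure(make_cys_pair_pdb(5.0))
        st.ssbonds = [SSBondRecord(a=("A", 1, ""), b=("A", 2, ""))]
        assert len(detect_disulphides(st)) == 1

    def test_greedy_closest_pairing_three_cysteines(self):
        st = parse_structure(make_cys_pair_pdb(2.0))
        # third cysteine 2.2 from the first, 2.5-ish from the second
        st.chains[0].residues.append(Residue(
            chain_id="A", number=3, icode="", name="CYS",
            atoms=[Atom(name="SG", element="S", pos=np.array([-2.2, 0.0, 0.0]))]))
        pairs = detect_disulphides(st)
        assert pairs == [(("A", 1, ""), ("A", 2, ""))]


class TestHeteroatomNeighbors:
    def hetero(self, st, positions):
        st.hetero_atoms = [Atom(name="C1", element="C",
                                pos=np.array(p, dtype=float),
                                parent_name="LIG") for p in positions]
        return st

    @pytest.mark.parametrize("x,count", [(3.9, 1), (4.1, 0)])
    def test_cutoff(self, x, count):
        st = parse_structure(make_cys_pair_pdb(30.0))
        self.hetero(st, [(x, 0, 0)])
        cys = st.get_residue("A", 1)
        assert heteroatom_neighbors(st, cys) == count

    def test_radial_ladder(self):
        st = parse_structure(make_cys_pair_pdb(30.0))
        self.hetero(st, [(r, 0, 0) for r in (1, 2, 3, 4, 5)])
        assert heteroatom_neighbors(st, st.get_residue("A", 1)) == 4

    def test_water_excluded_by_default(self):
        st = parse_structure(make_cys_pair_pdb(30.0))
        st.hetero_atoms = [Atom(name="O", element="O", pos=np.array([2.0, 0, 0]),
                                parent_name="HOH", is_water=True)]
        cys = st.get_residue("A", 1)
        assert heteroatom_neighbors(st, cys) == 0
        assert heteroatom_neighbors(st, cys, include_waters=True) == 1

    def test_missing_sg_is_error(self, tripeptide):
        res = tripeptide.get_residue("A", 1)
        res.name = "CYS"
        with pytest.raises(MissingAtomError, match="no SG"):
            heteroatom_neighbors(tripeptide, res)
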