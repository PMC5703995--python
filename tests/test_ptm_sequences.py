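"""Window extraction, MOD/NUL set construction, charge and fold-propensity
features, per-protein comparison and structure mapping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cysredox.ptm import (DisorderModel, ModificationRecord, WindowConfig,
                          build_mod_nul_sets, charge_profiles, extract_window,
                          fold_propensity, map_site_to_structure, net_charge,
                          per_protein_charge_comparison,
                          single_species_subset, window_profile)


def record(seq, mods=(), ubs=(), acc="P1", species="human"):
    return ModificationRecord(accession=acc, species=species, sequence=seq,
                              modified_cysteines=list(mods),
                              ubiquitinated_lysines=list(ubs))


W21 = WindowConfig(21)
W11 = WindowConfig(11)


class TestExtractWindow:
    def test_window_just_inside_nterm(self):
        seq = "A" * 10 + "C" + "A" * 89
        assert extract_window(record(seq), 11, W21) == seq[:21]

    def test_terminal_site_excluded(self):
        seq = "A" * 9 + "C" + "A" * 90
        assert extract_window(record(seq), 10, W21) is None

    def test_exact_fit_width_11(self):
        seq = "AAAAA" + "C" + "AAAAA"
        assert extract_window(record(seq), 6, W11) == seq

    def test_non_cysteine_position_is_error(self):
        with pytest.raises(ValueError, match="not C"):
            extract_window(record("A" * 30 + "C" + "A" * 30), 5, W21)

    @given(st.integers(min_value=1, max_value=60))
    @settings(max_examples=30, deadline=None)
    def test_reversal_symmetry(self, pos):
        rng = np.random.default_rng(pos)
        seq = "".join(rng.choice(list("ACDEKRAG"), size=60))
        seq = seq[:pos - 1] + "C" + seq[pos:]
        rev = seq[::-1]
        mirror = len(seq) - pos + 1
        w = extract_window(record(seq), pos, W21)
        wr = extract_window(record(rev, acc="P2"), mirror, W21)
        assert (w is None) == (wr is None)
        if w is not None:
            assert wr == w[::-1]
            assert net_charge(wr, W21) == net_charge(w, W21)


class TestModNulSets:
    def test_counts_and_disjointness(self):
        seq = ("A" * 30 + "C" + "A" * 30 + "C" + "A" * 30 + "C" + "A" * 30)
        pos = [i + 1 for i, a in enumerate(seq) if a == "C"]
        rec = record(seq, mods=[(pos[0], "palmitoylation")])
        mod, nul = build_mod_nul_sets([rec], "palmitoylation")
        assert len(mod) == 1 and len(nul) == 2
        assert {w.position for w in mod}.isdisjoint({w.position for w in nul})

    def test_terminal_mod_site_dropped(self):
        seq = "AAAAC" + "A" * 40 + "C" + "A" * 40
        rec = record(seq, mods=[(5, "palmitoylation")])
        mod, nul = build_mod_nul_sets([rec], "palmitoylation")
        assert len(mod) == 0 and len(nul) == 1

    def test_duplicate_records_deduplicated(self):
        seq = "A" * 30 + "C" + "A" * 30 + "C" + "A" * 30
        rec = record(seq, mods=[(31, "nitrosylation")])
        dup = record(seq, mods=[(31, "nitrosylation")])
        once = build_mod_nul_sets([rec], "nitrosylation")
        twice = build_mod_nul_sets([rec, dup], "nitrosylation")
        assert len(twice[0]) == len(once[0])
        assert len(twice[1]) == len(once[1])


class TestNetCharge:
    @pytest.mark.parametrize("window,expected", [
        ("AAAAAKKRAACDEAAAAAAAA", 1.0),   # 3 basic - 2 acidic
        ("A" * 21, 0.0),
        ("K" * 10 + "C" + "K" * 10, 20.0),
        ("H" * 10 + "C" + "H" * 10, 0.0),  # His neutral
    ])
    def test_charge_rule(self, window, expected):
        assert net_charge(window, W21) == expected

    def test_nonstandard_letter_counts_zero(self):
        assert net_charge("X" * 10 + "C" + "U" * 10, W21) == 0.0

    def test_wrong_width_rejected(self):
        with pytest.raises(ValueError):
            net_charge("ACA", W21)


class TestChargeProfiles:
    def windows(self, seqs):
        return [type("W", (), {"window": s, "accession": "P", "position": 0,
                               "label": "X"})() for s in seqs]

    def test_self_difference_is_zero(self):
        ws = self.windows(["AKACAAAAAAC" + "A" * 10, "DDACAAAAAAC" + "A" * 10])
        _, _, diff = charge_profiles(ws, list(ws), W21)
        assert np.allclose(diff, 0.0)

    def test_single_window_profile_is_its_own_charges(self):
        w = "KDACAAAAAAC" + "A" * 10
        p = window_profile(self.windows([w]), "MOD", W21)
        assert p.mean_charge[0] == 1.0 and p.mean_charge[1] == -1.0
        assert p.cumulative[-1] == pytest.approx(net_charge(w, W21))

    def test_antisymmetric_under_label_swap(self):
        a = self.windows(["KKACAAAAAAC" + "A" * 10])
        b = self.windows(["DDACAAAAAAC" + "A" * 10])
        _, _, d1 = charge_profiles(a, b, W21)
        _, _, d2 = charge_profiles(b, a, W21)
        assert np.allclose(d1, -d2)

    def test_empty_set_names_which(self):
        ws = self.windows(["A" * 21])
        with pytest.raises(ValueError, match="NUL"):
            charge_profiles(ws, [], W21)


class TestFoldPropensity:
    def test_poly_ile_is_ordered(self):
        index, call = fold_propensity("I" * 21)
        assert index == pytest.approx(1.634, abs=0.001)
        assert call == "ordered"

    def test_poly_glu_is_disordered(self):
        index, call = fold_propensity("E" * 21)
        assert index == pytest.approx(-1.842, abs=0.001)
        assert call == "disordered"

    def test_boundary_called_ordered(self):
        assert fold_propensity("I" * 21, DisorderModel(a=0.0, b=0.0))[1] == "ordered"


class TestPerProteinComparison:
    def protein(self, acc, mod_window, nul_window):
        seq = ("A" * 10 + mod_window + "A" * 10 + nul_window + "A" * 10)
        mod_pos = 10 + 11
        nul_pos = 10 + 21 + 10 + 11
        assert seq[mod_pos - 1] == "C" and seq[nul_pos - 1] == "C"
        return record(seq, mods=[(mod_pos, "palmitoylation")], acc=acc)

    BASIC = "K" * 10 + "C" + "K" * 10
    ACID = "D" * 10 + "C" + "D" * 10
    NEUT = "A" * 10 + "C" + "A" * 10

    def test_greater_and_tie_counting(self):
        recs = [
            self.protein("P1", self.BASIC, self.ACID),   # greater
            self.protein("P2", self.NEUT, self.NEUT),    # tie -> not greater
            self.protein("P3", self.ACID, self.BASIC),   # not greater
        ]
        out = per_protein_charge_comparison(recs, "palmitoylation")
        assert out["greater"] == 1
        assert out["not_greater"] == 2

    def test_no_qualifying_protein_is_error(self):
        rec = record("A" * 30 + "C" + "A" * 30,
                     mods=[(31, "palmitoylation")])  # no NUL cysteine
        with pytest.raises(ValueError):
            per_protein_charge_comparison([rec], "palmitoylation")


class TestStructureMappingAndSpecies:
    MAPPING = pd.DataFrame([
        {"accession": "P00533", "uniprot_position": 797, "pdb_id": "3poz",
         "chain": "A", "pdb_residue_number": 797},
        {"accession": "P00533", "uniprot_position": 797, "pdb_id": "3poz",
         "chain": "B", "pdb_residue_number": 797},
    ])

    def rec(self):
        seq = "A" * 796 + "C" + "A" * 100
        return record(seq, mods=[(797, "palmitoylation")], acc="P00533")

    def test_mapping_lookup(self):
        hits = map_site_to_structure(self.rec(), self.MAPPING, 797)
        assert ("3poz", "A", 797) in hits and ("3poz", "B", 797) in hits

    def test_absent_accession_maps_to_nothing(self):
        other = record("A" * 30 + "C" + "A" * 30, acc="Q99999",
                       mods=[(31, "palmitoylation")])
        assert map_site_to_structure(other, self.MAPPING, 31) == []

    def test_conflicting_rows_raise(self):
        bad = pd.concat([self.MAPPING, pd.DataFrame([
            {"accession": "P00533", "uniprot_position": 797, "pdb_id": "3poz",
             "chain": "A", "pdb_residue_number": 800}])])
        with pytest.raises(ValueError, match="conflicting"):
            map_site_to_structure(self.rec(), bad, 797)

    def test_species_filter(self):
        recs = [record("A" * 30 + "C" + "A" * 30, acc="H1",
                       mods=[(31, "palmitoylation")], species="human"),
                record("A" * 30 + "C" + "A" * 30, acc="M1",
                       mods=[(31, "palmitoylation")], species="mouse")]
        human = single_species_subset(recs, "human")
        assert [r.accession for r in human] == ["H1"]
        assert single_species_subset(recs, "yeast") == []
        mod_all, _ = build_mod_nul_sets(recs, "palmitoylation")
        mod_h, _ = build_mod_nul_sets(human, "palmitoylation")
        assert len(mod_h) <= len(mod_all)


class TestRecordValidation:
    def test_modified_position_must_be_cysteine(self):
        with pytest.raises(ValueError, match="not C"):
            record("AAAA", mods=[(2, "palmitoylation")])

    def test_ubiquitination_must_be_lysine(self):
        with pytest.raises(ValueError, match="not K"):
            record("CAAA", mods=[(1, "palmitoylation")], ubs=[3])
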