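"""Intrinsic-pKa arithmetic, hybrid coupling, Monte Carlo titration vs exact
partition-function enumeration, and the electrostatic direction properties."""

import numpy as np
import pytest

from cysredox.constants import MODEL_PKAS, SITE_POLARITY
from cysredox.electrostatics import ElectrostaticParameters
from cysredox.pka import predict_pkas
from cysredox.synth import make_ideal_helix
from cysredox.titration import (InteractionMatrix, TitrationConfig,
                                build_interaction_matrix,
                                compute_intrinsic_pka, enumerate_titration,
                                identify_sites, make_isolated_site,
                                mc_titration, optimize_hydroxyl_torsions,
                                pair_energy_dh)

PARAMS = ElectrostaticParameters()


class TestModelCompounds:
    def test_table_has_exactly_eight_entries_and_no_tyr(self):
        assert len(MODEL_PKAS) == 8
        assert "TYR" not in MODEL_PKAS
        assert MODEL_PKAS["CYS"] == 8.3
        assert set(MODEL_PKAS) == set(SITE_POLARITY)


class TestIntrinsicPka:
    def test_null_perturbation_returns_model_pka(self):
        site = make_isolated_site("GLU")
        assert compute_intrinsic_pka(site, 0.0, 0.0, PARAMS) == pytest.approx(4.4)

    def test_acid_destabilised_anion_raises_pka(self):
        site = make_isolated_site("CYS")
        # +2.73 kcal/mol over 2.303RT = 1.364 kcal/mol -> +2.0 pKa units
        assert compute_intrinsic_pka(site, 2.73, 0.0, PARAMS) == pytest.approx(
            10.3, abs=0.01)

    def test_base_destabilised_cation_lowers_pka(self):
        site = make_isolated_site("LYS")
        assert compute_intrinsic_pka(site, 2.73, 0.0, PARAMS) == pytest.approx(
            8.4, abs=0.01)


class TestInteractionMatrix:
    def two_sites(self, d=8.0):
        a = make_isolated_site("CYS")
        b = make_isolated_site("LYS")
        b.charge_atoms = [("NZ", np.array([d, 0.0, 0.0]), 1.0)]
        return a, b

    def test_fully_exposed_limit_is_debye_huckel(self):
        a, b = self.two_sites()
        m = build_interaction_matrix([a, b], PARAMS)
        assert m.w[0, 1] == pytest.approx(pair_energy_dh(a, b, PARAMS))
        assert m.w[0, 1] == m.w[1, 0]
        assert m.w[0, 0] == 0.0

    def test_single_site_matrix_is_zero(self):
        m = build_interaction_matrix([make_isolated_site("CYS")], PARAMS)
        assert m.w.shape == (1, 1)
        assert m.w[0, 0] == 0.0

    def test_overlapping_charges_rejected(self):
        a, b = self.two_sites(d=0.2)
        with pytest.raises(ValueError, match="overlapping"):
            build_interaction_matrix([a, b], PARAMS)


class TestMcTitration:
    @pytest.mark.parametrize("site_type", list(MODEL_PKAS))
    def test_single_site_recovers_model_pka(self, site_type):
        site = make_isolated_site(site_type)
        cfg = TitrationConfig(seed=7)
        res = mc_titration([site], np.array([site.model_pka]), None, cfg)
        assert res.pkas[0] == pytest.approx(site.model_pka, abs=0.05)
        assert not res.flag_high[0] and not res.flag_low[0]

    def test_single_site_curve_is_henderson_hasselbalch(self):
        site = make_isolated_site("CYS")
        cfg = TitrationConfig(seed=1)
        ladder = np.arange(5.0, 12.0, 0.5)
        res = mc_titration([site], np.array([8.3]), None, cfg, ph_ladder=ladder)
        hh = 1.0 / (1.0 + 10 ** (ladder - 8.3))
        assert np.abs(res.fractions[:, 0] - hh).max() < 0.01

    def test_two_sites_match_exact_enumeration(self):
        a = make_isolated_site("CYS")
        b = make_isolated_site("HIS")
        b.charge_atoms = [("ND1", np.array([5.0, 0.0, 0.0]), 1.0)]
        w = np.array([[0.0, -1.2], [-1.2, 0.0]])
        cfg = TitrationConfig(seed=11)
        ladder = np.arange(3.0, 13.0, 1.0)
        mc = mc_titration([a, b], np.array([8.3, 6.3]), w, cfg, ph_ladder=ladder)
        exact = enumerate_titration([a, b], np.array([8.3, 6.3]), w, cfg,
                                    ph_ladder=ladder)
        assert np.abs(mc.fractions - exact.fractions).max() < 0.01

    def test_ten_sites_match_exact_enumeration(self, rng):
        types = ["CYS", "ASP", "LYS", "HIS", "GLU",
                 "ARG", "CYS", "ASP", "LYS", "HIS"]
        sites = [make_isolated_site(t) for t in types]
        pkas = rng.uniform(3.0, 11.0, 10)
        w = rng.normal(0.0, 1.5, (10, 10))
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        cfg = TitrationConfig(seed=5)
        ladder = np.arange(2.0, 13.0, 2.0)
        mc = mc_titration(sites, pkas, w, cfg, ph_ladder=ladder)
        exact = enumerate_titration(sites, pkas, w, cfg, ph_ladder=ladder)
        assert np.abs(mc.fractions - exact.fractions).max() < 0.01

    def test_strong_coupling_with_double_flips_matches_enumeration(self):
        # |W| > 2 kcal/mol activates pair moves
        a = make_isolated_site("ASP")
        b = make_isolated_site("GLU")
        b.charge_atoms = [("OE1", np.array([4.0, 0.0, 0.0]), -1.0)]
        w = np.array([[0.0, 3.5], [3.5, 0.0]])
        cfg = TitrationConfig(seed=13)
        ladder = np.arange(1.0, 10.0, 1.0)
        mc = mc_titration([a, b], np.array([4.0, 4.4]), w, cfg, ph_ladder=ladder)
        exact = enumerate_titration([a, b], np.array([4.0, 4.4]), w, cfg,
                                    ph_ladder=ladder)
        assert np.abs(mc.fractions - exact.fractions).max() < 0.015

    def test_seed_determinism_bit_identical(self):
        site = make_isolated_site("CYS")
        cfg = TitrationConfig(seed=42)
        ladder = np.arange(6.0, 11.0, 1.0)
        r1 = mc_titration([site], np.array([8.3]), None, cfg, ph_ladder=ladder)
        r2 = mc_titration([site], np.array([8.3]), None, cfg, ph_ladder=ladder)
        assert np.array_equal(r1.fractions, r2.fractions)

    def test_site_order_swap_leaves_pkas_unchanged(self):
        a = make_isolated_site("CYS")
        b = make_isolated_site("LYS")
        b.charge_atoms = [("NZ", np.array([6.0, 0.0, 0.0]), 1.0)]
        w = pair_energy_dh(a, b, PARAMS)
        m = np.array([[0.0, w], [w, 0.0]])
        cfg = TitrationConfig(seed=3)
        f = enumerate_titration([a, b], np.array([8.3, 10.4]), m, cfg)
        r = enumerate_titration([b, a], np.array([10.4, 8.3]), m, cfg)
        assert f.pkas[0] == pytest.approx(r.pkas[1], abs=1e-9)
        assert f.pkas[1] == pytest.approx(r.pkas[0], abs=1e-9)

    def test_high_flag_when_half_protonation_beyond_15(self):
        site = make_isolated_site("CYS")
        cfg = TitrationConfig(seed=2)
        res = enumerate_titration([site], np.array([17.5]), None, cfg)
        assert res.flag_high[0]
        assert res.pka_label(0) == ">15"

    def test_low_flag_below_ladder(self):
        site = make_isolated_site("CYS")
        cfg = TitrationConfig(seed=2)
        res = enumerate_titration([site], np.array([-5.0]), None, cfg)
        assert res.flag_low[0]

    def test_non_monotonic_ladder_rejected(self):
        site = make_isolated_site("CYS")
        cfg = TitrationConfig(seed=2)
        with pytest.raises(ValueError):
            mc_titration([site], np.array([8.3]), None, cfg,
                         ph_ladder=np.array([7.0, 6.0, 8.0]))


class TestHydroxylTorsions:
    def test_oh_faces_nearby_carboxylate(self):
        st = make_ideal_helix("ASAA")  # Ser at residue 2 with OG placed
        sites = identify_sites(st, include_termini=False)
        # plant an acceptor anion near the serine
        ser = st.get_residue("A", 2)
        og = ser.atom("OG").pos
        from cysredox.titration import TitratableSite
        acceptor = TitratableSite(
            residue_key=None, chain_id="A", residue_number=99,
            site_type="ASP", charge_atoms=[("OD1", og + np.array([3.0, 0, 0]), -1.0)],
            model_pka=4.0, polarity="acid")
        optimize_hydroxyl_torsions(st, [acceptor])
        h = ser.atom("HO")
        assert h is not None
        # exhaustive 1-degree oracle: H should be within 30 deg of optimum
        best = _exhaustive_best(st, og, acceptor)
        cos = np.dot(_unit(h.pos - og), _unit(best - og))
        assert cos > np.cos(np.radians(30.0))

    def test_no_sites_places_default_torsion_deterministically(self):
        st1, st2 = make_ideal_helix("ASAA"), make_ideal_helix("ASAA")
        optimize_hydroxyl_torsions(st1, [])
        optimize_hydroxyl_torsions(st2, [])
        h1 = st1.get_residue("A", 2).atom("HO")
        h2 = st2.get_residue("A", 2).atom("HO")
        assert np.array_equal(h1.pos, h2.pos)


def _unit(v):
    return v / np.linalg.norm(v)


def _exhaustive_best(st, og, acceptor):
    import math
    ser = st.get_residue("A", 2)
    c = ser.atom("CB").pos
    g = ser.atom("CA").pos
    u = _unit(og - c)
    v0 = g - c
    v0 = _unit(v0 - np.dot(v0, u) * u)
    w = np.cross(u, v0)
    cos_t, sin_t = math.cos(math.radians(70.5)), math.sin(math.radians(70.5))
    best, best_e = None, None
    for tau_deg in range(360):
        tau = math.radians(tau_deg)
        d = cos_t * u + sin_t * (math.cos(tau) * v0 + math.sin(tau) * w)
        hpos = og + 0.96 * d
        e = sum(0.4 * q / np.linalg.norm(hpos - p)
                for _, p, q in acceptor.charge_atoms)
        if best_e is None or e < best_e:
            best, best_e = hpos, e
    return best


class TestDirectionProperties:
    def cys_pka(self, prediction):
        return prediction.table.query("site_type == 'CYS'")["pka"].iloc[0]

    def test_positive_charge_lowers_negative_raises_cys_pka(self):
        cfg = TitrationConfig(seed=1)
        st = make_ideal_helix("CAAAAAAAAAA")
        sg = st.get_residue("A", 1).atom("SG").pos
        probe = sg + np.array([0.0, 0.0, -5.0])
        base = predict_pkas(make_ideal_helix("CAAAAAAAAAA"), config=cfg)
        plus = predict_pkas(make_ideal_helix("CAAAAAAAAAA"), config=cfg,
                            background_charges=[(probe, +1.0)])
        minus = predict_pkas(make_ideal_helix("CAAAAAAAAAA"), config=cfg,
                             background_charges=[(probe, -1.0)])
        assert self.cys_pka(plus) < self.cys_pka(base) < self.cys_pka(minus)

    def test_helix_dipole_favours_ncap_thiolate(self):
        # +0.5/-0.5 axial charges mimic the helix macrodipole
        cfg = TitrationConfig(seed=1)

        def dipole(n):
            return [(np.array([0.0, 0.0, -2.5]), +0.5),
                    (np.array([0.0, 0.0, 1.5 * (n - 1) + 2.5]), -0.5)]

        ncap = predict_pkas(make_ideal_helix("CAAAAAAAAAA"), config=cfg,
                            background_charges=dipole(11))
        mid = predict_pkas(make_ideal_helix("AAAAACAAAAA"), config=cfg,
                           background_charges=dipole(11))
        assert self.cys_pka(ncap) < self.cys_pka(mid)


class TestPredictPkas:
    def test_table_one_row_per_site(self):
        cfg = TitrationConfig(seed=1)
        pred = predict_pkas(make_ideal_helix("CAAAAAAAAAA"), config=cfg)
        assert set(pred.table["site_type"]) == {"CYS", "NTERM", "CTERM"}
        assert len(pred.table) == 3

    def test_equivalent_site_averaging(self):
        import pandas as pd
        from cysredox.pka import PkaPrediction, average_equivalent_sites
        st = make_ideal_helix("CAAA")
        second = make_ideal_helix("CAAA")
        second.chains[0].id = "B"
        for res in second.chains[0].residues:
            res.chain_id = "B"
            for a in res.atoms:
                a.pos = a.pos + np.array([50.0, 0.0, 0.0])
        st.chains.append(second.chains[0])
        table = pd.DataFrame([
            {"chain": "A", "residue_number": 1, "site_type": "CYS",
             "pka": 7.6, "flag_high": False},
            {"chain": "B", "residue_number": 1, "site_type": "CYS",
             "pka": 7.8, "flag_high": False},
        ])
        pred = PkaPrediction(table=table, titration=None, sites=[], matrix=None)
        merged = average_equivalent_sites(pred, st)
        assert len(merged) == 1
        assert merged["pka"].iloc[0] == pytest.approx(7.7)
        assert merged["n_chains"].iloc[0] == 2

    def test_empty_structure_returns_empty_table(self):
        from cysredox.structure import Structure, Chain
        st = Structure(id="x", chains=[Chain(id="A", residues=[])])
        pred = predict_pkas(st, config=TitrationConfig(seed=0))
        assert pred.table.empty
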