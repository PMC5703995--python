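"""End-to-end pKa prediction for a parsed structure.

Order of operations: SASA and fractional burial -> hydroxyl torsion
optimisation -> per-site FDPB runs (desolvation by identical-grid
subtraction against the isolated-residue model compound) -> background
term from hydroxyl dipoles and any user-supplied fixed charges ->
burial-weighted interaction matrix -> Monte Carlo titration -> per-site
table, with equivalent sites averaged across identical chains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import VDW_RADII
from .electrostatics import ElectrostaticParameters, solve_fdpb
from .structure import Chain, Residue, Structure
from .surface import compute_sasa
from .titration import (InteractionMatrix, TitratableSite, TitrationConfig,
                        TitrationResult, build_interaction_matrix,
                        compute_intrinsic_pka, debye_huckel_energy,
                        hydroxyl_dipoles, identify_sites, mc_titration,
                        optimize_hydroxyl_torsions, pair_energy_dh)

logger = logging.getLogger(__name__)

BackgroundCharges = list[tuple[np.ndarray, float]]


def _cavity_atoms(structure: Structure, exclude_ligands: bool):
    pos, rad = [], []
    for res in structure.residues():
        for atom in res.atoms:
            if atom.element == "H":
                continue
            pos.append(atom.pos)
            rad.append(VDW_RADII.get(atom.element, 1.7))
    if not exclude_ligands:
        for atom in structure.hetero_atoms:
            if atom.is_water or atom.element == "H":
                continue
            pos.append(atom.pos)
            rad.append(VDW_RADII.get(atom.element, 1.7))
    return (np.array(pos) if pos else np.zeros((0, 3)),
            np.array(rad) if rad else np.zeros(0))


def _isolated_residue(structure: Structure, key) -> Structure:
    res = structure.get_residue(*key)
    clone = Residue(chain_id=res.chain_id, number=res.number,
                    icode=res.icode, name=res.name,
                    atoms=[a for a in res.atoms])
    return Structure(id="isolated", chains=[Chain(id=res.chain_id,
                                                  residues=[clone])])


def compute_burials(structure: Structure, sites: list[TitratableSite],
                    config: TitrationConfig) -> None:
    """Fractional burial of each site's charge atoms: 1 - SASA in context /
    SASA of the same atom in the residue extracted in isolation, clamped to
    [0, 1]; also records the representative-atom SASA."""
    sasa = compute_sasa(structure, n_points=config.sasa_points,
                        include_hetero=not config.exclude_ligands)
    iso_cache: dict[tuple, object] = {}
    for site in sites:
        if site.residue_key is None:
            site.burial = 0.0
            continue
        key = site.residue_key
        if key not in iso_cache:
            iso_cache[key] = compute_sasa(
                _isolated_residue(structure, key),
                n_points=config.sasa_points,
            )
        iso = iso_cache[key]
        ratios, rep_sasa = [], []
        for name, _pos, _q in site.charge_atoms:
            full = sasa.atom_sasa.get((*key, name))
            free = iso.atom_sasa.get((*key, name))
            if full is None or free is None or free <= 0:
                continue
            ratios.append(full / free)
            rep_sasa.append(full)
        if ratios:
            site.burial = float(np.clip(1.0 - np.mean(ratios), 0.0, 1.0))
            site.sasa = float(np.mean(rep_sasa))


def site_fdpb_energies(site: TitratableSite, structure: Structure,
                       params: ElectrostaticParameters,
                       config: TitrationConfig,
                       background: BackgroundCharges):
    """Desolvation (identical-grid subtraction) and the FDPB potential grid
    of the site's ionised charges in the protein dielectric map."""
    cav_pos, cav_rad = _cavity_atoms(structure, config.exclude_ligands)
    charges = [(pos, q) for _, pos, q in site.charge_atoms]
    grid_kw = dict(spacing=config.grid_spacing, padding=config.grid_padding)
    phi_prot = solve_fdpb(cav_pos, cav_rad, charges, params, **grid_kw)
    if site.residue_key is not None:
        iso = _isolated_residue(structure, site.residue_key)
        iso_pos, iso_rad = _cavity_atoms(iso, exclude_ligands=True)
    else:
        iso_pos, iso_rad = np.zeros((0, 3)), np.zeros(0)
    phi_model = solve_fdpb(iso_pos, iso_rad, charges, params, **grid_kw)
    ddg_desolv = 0.0
    for _, pos, q in site.charge_atoms:
        dphi = phi_prot.interpolate(pos)[0] - phi_model.interpolate(pos)[0]
        ddg_desolv += 0.5 * q * dphi

    ddg_background = 0.0
    for bpos, bq in background:
        e_dh = sum(debye_huckel_energy(q, bq, float(np.linalg.norm(pos - bpos)),
                                       params)
                   for _, pos, q in site.charge_atoms)
        if site.burial > 0.0 and phi_prot.contains(bpos, margin=2 * config.grid_spacing)[0]:
            e_fdpb = bq * phi_prot.interpolate(bpos)[0]
            ddg_background += site.burial * e_fdpb + (1 - site.burial) * e_dh
        else:
            ddg_background += e_dh
    return ddg_desolv, ddg_background, phi_prot


@dataclass
class PkaPrediction:
    table: pd.DataFrame            # one row per site
    titration: TitrationResult
    sites: list[TitratableSite]
    matrix: InteractionMatrix


def predict_pkas(structure: Structure,
                 params: ElectrostaticParameters | None = None,
                 config: TitrationConfig | None = None,
                 background_charges: BackgroundCharges | None = None
                 ) -> PkaPrediction:
    """Predict pKas for every titratable site of a structure.

    ``background_charges`` are fixed non-titrating charges (entering each
    site's background term only), e.g. helix-dipole mimics or test charges.
    """
    params = params or ElectrostaticParameters()
    config = config or TitrationConfig()
    sites = identify_sites(structure, include_termini=config.include_termini)
    if not sites:
        logger.warning("structure %r has no titratable sites", structure.id)
        return PkaPrediction(table=_empty_table(), titration=None, sites=[],
                             matrix=None)
    compute_burials(structure, sites, config)
    optimize_hydroxyl_torsions(structure, sites)
    background = list(hydroxyl_dipoles(structure))
    if background_charges:
        background.extend(
            (np.asarray(p, dtype=float), float(q)) for p, q in background_charges
        )
    grids = {}
    intrinsic = np.zeros(len(sites))
    for i, site in enumerate(sites):
        ddg_d, ddg_b, grid = site_fdpb_energies(site, structure, params,
                                                config, background)
        grids[i] = grid
        site.intrinsic_pka = compute_intrinsic_pka(site, ddg_d, ddg_b, params)
        intrinsic[i] = site.intrinsic_pka
    matrix = build_interaction_matrix(sites, params, grids)
    titration = mc_titration(sites, intrinsic, matrix, config)

    rows = []
    for i, site in enumerate(sites):
        rows.append({
            "chain": site.chain_id,
            "residue_number": site.residue_number,
            "site_type": site.site_type,
            "model_pka": site.model_pka,
            "intrinsic_pka": site.intrinsic_pka,
            "pka": titration.pkas[i],
            "pka_label": titration.pka_label(i, config.high_pka_cutoff),
            "flag_high": bool(titration.flag_high[i]),
            "flag_low": bool(titration.flag_low[i]),
            "sasa": site.sasa,
            "burial": site.burial,
        })
    return PkaPrediction(table=pd.DataFrame(rows), titration=titration,
                         sites=sites, matrix=matrix)


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "chain", "residue_number", "site_type", "model_pka", "intrinsic_pka",
        "pka", "pka_label", "flag_high", "flag_low", "sasa", "burial",
    ])


def average_equivalent_sites(prediction: PkaPrediction,
                             structure: Structure,
                             high_cutoff: float = 15.0) -> pd.DataFrame:
    """Average pKas of equivalent sites across chains of identical sequence
    (the asymmetric-unit rule).  Sites flagged high average only among
    themselves; a mixed flagged/unflagged group is reported as a range."""
    df = prediction.table
    if df.empty:
        return df.copy()
    seq_groups: dict[str, list[str]] = {}
    for chain in structure.chains:
        seq = structure.chain_sequence(chain.id)
        seq_groups.setdefault(seq, []).append(chain.id)
    chain_to_group = {c: i for i, (seq, chains) in enumerate(seq_groups.items())
                      for c in chains}
    df = df.assign(_group=df["chain"].map(chain_to_group))
    rows = []
    for (group, rtype, rnum), sub in df.groupby(
            ["_group", "site_type", "residue_number"]):
        high = sub["flag_high"].to_numpy()
        numeric = sub.loc[~sub["flag_high"], "pka"].dropna()
        if high.all():
            pka, label, mixed = np.nan, f">{high_cutoff:g}", False
        elif high.any():
            pka = float(numeric.mean()) if len(numeric) else np.nan
            label = f"{numeric.min():.2f}..>{high_cutoff:g}"
            mixed = True
        else:
            pka = float(numeric.mean()) if len(numeric) else np.nan
            label = f"{pka:.2f}" if np.isfinite(pka) else "n/a"
            mixed = False
        rows.append({
            "site_type": rtype, "residue_number": rnum,
            "n_chains": len(sub), "pka": pka, "pka_label": label,
            "mixed_flags": mixed,
            "chains": ",".join(sorted(sub["chain"])),
        })
    return pd.DataFrame(rows)
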