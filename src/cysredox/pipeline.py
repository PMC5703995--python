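"""End-to-end orchestration with provenance capture.

``run_structure_pipeline`` turns a structure list into per-cysteine property
tables (predicted pKa, SG SASA with the three burial labels, helix location,
disulphide status, heteroatom contacts) plus the helix-propensity table;
``run_sequence_pipeline`` turns PTM annotation tables into window charge
profiles, fold-propensity summaries, proximity differences and Mann-Whitney
statistics.  A RunManifest snapshots configuration, seeds and per-stage row
counts; all randomness flows from one top-level seed expanded per stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .electrostatics import ElectrostaticParameters
from .pka import predict_pkas
from .propensity import LocationScheme, propensity_table
from .proximity import (ProximityConfig, binned_difference, collect_distances)
from .ptm import (ModificationRecord, WindowConfig, build_mod_nul_sets,
                  charge_profiles, fold_propensity, net_charge,
                  per_protein_charge_comparison)
from .stats import mann_whitney_two_tailed
from .structure import Structure, helix_location, parse_structure
from .surface import (BURIAL_THRESHOLDS, compute_sasa, detect_disulphides,
                      heteroatom_neighbors)
from .titration import TitrationConfig

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    input_checksums: dict = field(default_factory=dict)
    row_counts: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _checksum(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31 - 1)


def run_structure_pipeline(structures: list[Structure | str],
                           config: TitrationConfig | None = None,
                           params: ElectrostaticParameters | None = None,
                           scheme: LocationScheme = LocationScheme(),
                           seed: int = 0) -> dict:
    """Per-cysteine pKa/SASA/location tables and the propensity table.

    Unreadable structures are skipped with a logged reason; an all-skipped
    run is an error.
    """
    config = config or TitrationConfig(seed=_stage_seed(seed, "titration"))
    params = params or ElectrostaticParameters()
    parsed: list[Structure] = []
    checksums = {}
    for item in structures:
        if isinstance(item, Structure):
            parsed.append(item)
            continue
        try:
            text = open(item).read()
            parsed.append(parse_structure(text, structure_id=str(item)))
            checksums[str(item)] = _checksum(text)
        except Exception as exc:  # noqa: BLE001 - skip-and-log contract
            logger.warning("skipping structure %s: %s", item, exc)
    if not parsed:
        raise ValueError("no readable structures")

    rows = []
    for st in parsed:
        prediction = predict_pkas(st, params, config)
        sasa = compute_sasa(st, n_points=config.sasa_points,
                            include_hetero=not config.exclude_ligands)
        ss_pairs = detect_disulphides(st)
        in_ssbond = {k for pair in ss_pairs for k in pair}
        pka_by_key = {
            (r.chain, r.residue_number): r
            for r in prediction.table.itertuples()
            if r.site_type == "CYS"
        }
        for cys in st.cysteines():
            loc = helix_location(cys, st)
            pk = pka_by_key.get((cys.chain_id, cys.number))
            sg = sasa.sg_sasa.get(cys.key)
            rows.append({
                "structure": st.id,
                "chain": cys.chain_id,
                "residue_number": cys.number,
                "pka": pk.pka if pk else np.nan,
                "pka_label": pk.pka_label if pk else "n/a",
                "intrinsic_pka": pk.intrinsic_pka if pk else np.nan,
                "sg_sasa": sg,
                **{f"accessible_{t:g}": (sg is not None and sg > t)
                   for t in BURIAL_THRESHOLDS},
                "in_helix": loc.in_helix,
                "helix_position": loc.position_from_nterm,
                "helix_region": loc.region,
                "nt_cys": loc.in_helix and loc.position_from_nterm == 1,
                "disulphide": cys.key in in_ssbond,
                "heteroatom_count": (
                    heteroatom_neighbors(st, cys)
                    if cys.atom("SG") is not None else np.nan),
            })
    pka_table = pd.DataFrame(rows)
    prop_table = propensity_table(parsed, scheme)
    manifest = RunManifest(
        config={"titration": dataclasses.asdict(config),
                "params": dataclasses.asdict(params)},
        seed=seed, input_checksums=checksums,
        row_counts={"structures": len(parsed), "cysteines": len(pka_table)},
    )
    return {"pka": pka_table, "propensity": prop_table, "manifest": manifest}


def select(table: pd.DataFrame, expr: str) -> pd.DataFrame:
    """Subset extraction by any flag combination, e.g.
    ``"nt_cys and sg_sasa > 0.1"``."""
    return table.query(expr)


def run_sequence_pipeline(records: list[ModificationRecord],
                          window: WindowConfig = WindowConfig(),
                          proximity: ProximityConfig = ProximityConfig(),
                          modification_types: list[str] | None = None,
                          seed: int = 0) -> dict:
    """Charge profiles, fold propensity, per-protein comparison, proximity
    differences and Mann-Whitney summaries per modification type."""
    if not records:
        raise ValueError("no modification records")
    types = modification_types or sorted(
        {t for r in records for _, t in r.modified_cysteines})
    bundle: dict = {"per_type": {}, "manifest": None}
    counts = {"records": len(records)}
    for mtype in types:
        mod, nul = build_mod_nul_sets(records, mtype, window)
        entry: dict = {"n_mod": len(mod), "n_nul": len(nul)}
        if mod and nul:
            pmod, pnul, diff = charge_profiles(mod, nul, window)
            entry["profiles"] = pd.DataFrame({
                "position": pmod.positions,
                "mod_mean_charge": pmod.mean_charge,
                "nul_mean_charge": pnul.mean_charge,
                "difference": diff,
                "mod_cumulative": pmod.cumulative,
                "nul_cumulative": pnul.cumulative,
            })
            mod_net = [net_charge(w.window, window) for w in mod]
            nul_net = [net_charge(w.window, window) for w in nul]
            mw = mann_whitney_two_tailed(mod_net, nul_net)
            entry["net_charge_mw"] = dataclasses.asdict(mw)
            entry["fold_index"] = {
                "mod": [fold_propensity(w.window)[0] for w in mod],
                "nul": [fold_propensity(w.window)[0] for w in nul],
            }
            try:
                entry["per_protein"] = {
                    k: v for k, v in per_protein_charge_comparison(
                        records, mtype, window).items() if k != "per_protein"
                }
            except ValueError:
                entry["per_protein"] = None
        if any(r.ubiquitinated_lysines for r in records):
            mod_d, nul_d = collect_distances(records, mtype, margin=0)
            if mod_d and nul_d:
                entry["proximity"] = binned_difference(mod_d, nul_d, proximity)
                mod_dm, nul_dm = collect_distances(
                    records, mtype, margin=proximity.terminal_margin)
                if mod_dm and nul_dm:
                    entry["proximity_terminal_excluded"] = binned_difference(
                        mod_dm, nul_dm, proximity)
        else:
            logger.info("no ubiquitination data; proximity stage skipped")
        bundle["per_type"][mtype] = entry
        counts[f"{mtype}_mod"] = len(mod)
        counts[f"{mtype}_nul"] = len(nul)
    bundle["manifest"] = RunManifest(
        config={"window": dataclasses.asdict(window),
                "proximity": dataclasses.asdict(proximity)},
        seed=seed, row_counts=counts,
    )
    return bundle
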