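"""Cysteine-to-ubiquitinated-lysine sequence proximity.

Distance is pure sequence separation |delta position|.  Distributions for
modified vs unmodified cysteines are converted to percentages per 10-residue
bin (half-open [10k, 10k+10)) and differenced MOD - NUL; the differences sum
to zero over the full support.  Proteins without any recorded ubiquitination
contribute no distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ptm import ModificationRecord


@dataclass(frozen=True)
class ProximityConfig:
    bin_width: int = 10
    terminal_margin: int = 50
    near_threshold: int = 10

    def __post_init__(self):
        if self.bin_width < 1 or self.terminal_margin < 0:
            raise ValueError("bin width must be >= 1 and margin >= 0")


def nearest_ub_distance(record: ModificationRecord,
                        cys_position: int) -> int | None:
    """min |cys - lys| over ubiquitinated lysines; None when the protein has
    no recorded ubiquitination."""
    if record.sequence[cys_position - 1] != "C":
        raise ValueError(
            f"{record.accession}: position {cys_position} is "
            f"{record.sequence[cys_position - 1]!r}, not C"
        )
    if not record.ubiquitinated_lysines:
        return None
    return min(abs(cys_position - k) for k in record.ubiquitinated_lysines)


def collect_distances(records: list[ModificationRecord],
                      modification_type: str,
                      margin: int = 0) -> tuple[list[int], list[int]]:
    """(MOD, NUL) nearest-ubiquitination distances across records, with
    optional terminal exclusion applied first."""
    mod_d: list[int] = []
    nul_d: list[int] = []
    for rec in records:
        mod_positions = {p for p, t in rec.modified_cysteines
                         if t == modification_type}
        if not mod_positions:
            continue
        for pos in terminal_exclusion(rec, margin):
            d = nearest_ub_distance(rec, pos)
            if d is None:
                continue
            (mod_d if pos in mod_positions else nul_d).append(d)
    return mod_d, nul_d


def terminal_exclusion(record: ModificationRecord, margin: int = 50) -> list[int]:
    """Cysteine positions with more than ``margin`` residues to both termini."""
    n = len(record.sequence)
    return [p for p in record.all_cysteines() if margin < p <= n - margin]


def binned_difference(mod_distances: list[int], nul_distances: list[int],
                      config: ProximityConfig = ProximityConfig()
                      ) -> pd.DataFrame:
    """Per-bin percentage difference MOD% - NUL% of the two distance
    distributions, bins [0,w), [w,2w), ..."""
    if not mod_distances or not nul_distances:
        raise ValueError("empty distance set "
                         + ("MOD" if not mod_distances else "NUL"))
    w = config.bin_width
    top = (max(max(mod_distances), max(nul_distances)) // w + 1) * w
    edges = np.arange(0, top + w, w)
    mod_pct = 100.0 * np.histogram(mod_distances, bins=edges)[0] / len(mod_distances)
    nul_pct = 100.0 * np.histogram(nul_distances, bins=edges)[0] / len(nul_distances)
    return pd.DataFrame({
        "bin_lower": edges[:-1],
        "mod_pct": mod_pct,
        "nul_pct": nul_pct,
        "difference": mod_pct - nul_pct,
    })


def burial_stratified_summary(records: list[ModificationRecord],
                              burial_labels: dict[tuple[str, int], str],
                              modification_type: str,
                              config: ProximityConfig = ProximityConfig()
                              ) -> dict[str, float | None]:
    """Per burial stratum ('accessible' / 'buried', zero-SASA rule applied
    upstream), the percentage of cysteines within the near threshold of a
    ubiquitinated lysine, differenced MOD - NUL.  Strata without members in
    either set are reported as None."""
    near: dict[str, dict[str, list[bool]]] = {
        "accessible": {"MOD": [], "NUL": []},
        "buried": {"MOD": [], "NUL": []},
    }
    for rec in records:
        mod_positions = {p for p, t in rec.modified_cysteines
                         if t == modification_type}
        if not mod_positions:
            continue
        for pos in rec.all_cysteines():
            stratum = burial_labels.get((rec.accession, pos))
            if stratum not in near:
                continue
            d = nearest_ub_distance(rec, pos)
            if d is None:
                continue
            label = "MOD" if pos in mod_positions else "NUL"
            near[stratum][label].append(d <= config.near_threshold)
    out: dict[str, float | None] = {}
    for stratum, groups in near.items():
        if not groups["MOD"] or not groups["NUL"]:
            out[stratum] = None
            continue
        mod_pct = 100.0 * np.mean(groups["MOD"])
        nul_pct = 100.0 * np.mean(groups["NUL"])
        out[stratum] = float(mod_pct - nul_pct)
    return out
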