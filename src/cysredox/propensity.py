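"""Relative amino-acid occupancy at helix-relative locations.

For a set of structures, each standard residue is assigned at most one
helix-relative location (positions NT1..NTk inside the helix counted from
its amino terminus, NT-1, NT-2 ... immediately preceding it).  The relative
occupancy of amino acid ``aa`` at location ``loc`` is

    R_aa,loc = P_aa,loc / P_aa,all - 1

with P the percentage compositions, so R is a signed enrichment (positive)
or depletion (negative, floored at -1).  The tally is independent of any
accessibility measure; helices shorter than 4 residues are skipped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .constants import STANDARD_AA1
from .structure import Structure


@dataclass(frozen=True)
class LocationScheme:
    """Helix-relative location labels: ``n_inside`` positions NT1.. from the
    first helical residue and ``n_before`` positions NT-1.. preceding it."""
    n_inside: int = 4
    n_before: int = 2
    min_helix_length: int = 4

    def labels(self) -> list[str]:
        return ([f"NT-{k}" for k in range(self.n_before, 0, -1)]
                + [f"NT{k}" for k in range(1, self.n_inside + 1)])


@dataclass
class OccupancyCounts:
    by_location: dict[str, Counter] = field(default_factory=dict)  # loc -> aa counts
    overall: Counter = field(default_factory=Counter)              # aa counts, all residues


def tally_locations(structures: list[Structure],
                    scheme: LocationScheme = LocationScheme()) -> OccupancyCounts:
    """Count amino-acid occupancies per helix-relative location and overall.

    A residue claimed by one helix's scheme is not counted again for another
    (first helix in record order wins).
    """
    if not structures:
        raise ValueError("no structures to tally")
    counts = OccupancyCounts(by_location={l: Counter() for l in scheme.labels()})
    for st in structures:
        claimed: set[tuple[str, int, str]] = set()
        residues_by_chain = {
            ch.id: {r.number: r for r in ch.residues if r.is_standard}
            for ch in st.chains
        }
        for helix in st.helices:
            if helix.dangling or helix.length < scheme.min_helix_length:
                continue
            chain = residues_by_chain.get(helix.chain_id, {})
            for k in range(1, scheme.n_before + 1):
                self_assign(chain, helix.start - k, f"NT-{k}", counts, claimed)
            for k in range(1, scheme.n_inside + 1):
                num = helix.start + k - 1
                if num > helix.end:
                    break
                self_assign(chain, num, f"NT{k}", counts, claimed)
        for res in st.residues():
            if res.is_standard:
                counts.overall[res.one_letter] += 1
    return counts


def self_assign(chain_residues, number, label, counts, claimed) -> None:
    res = chain_residues.get(number)
    if res is None:
        return
    if res.key in claimed:
        return
    claimed.add(res.key)
    counts.by_location[label][res.one_letter] += 1


def relative_propensity(counts: OccupancyCounts) -> pd.DataFrame:
    """PropensityTable: P_aa,loc, P_aa,all and R_aa,loc = P_loc/P_all - 1.

    Amino acids absent from the entire set have undefined R (NaN), never 0.
    """
    total_all = sum(counts.overall.values())
    if total_all == 0:
        raise ValueError("no residues tallied")
    rows = []
    for aa in STANDARD_AA1:
        n_all = counts.overall.get(aa, 0)
        p_all = 100.0 * n_all / total_all
        for loc, ctr in counts.by_location.items():
            total_loc = sum(ctr.values())
            p_loc = 100.0 * ctr.get(aa, 0) / total_loc if total_loc else float("nan")
            r = (p_loc / p_all - 1.0) if (n_all > 0 and total_loc) else float("nan")
            rows.append({"aa": aa, "location": loc, "count": ctr.get(aa, 0),
                         "P_aa_loc": p_loc, "P_aa_all": p_all, "R_aa_loc": r})
    return pd.DataFrame(rows)


def propensity_table(structures: list[Structure],
                     scheme: LocationScheme = LocationScheme()) -> pd.DataFrame:
    return relative_propensity(tally_locations(structures, scheme))
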