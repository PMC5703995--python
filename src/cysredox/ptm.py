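"""Sequence-window analysis around cysteine PTM sites.

Modified (MOD) cysteines are compared against unmodified (NUL) cysteines in
the same proteins, over odd-width windows (21 residues by default) that must
fit entirely inside the sequence — sites too close to a terminus are
excluded.  Charges at neutral pH: Asp/Glu -1, Lys/Arg +1, His 0.  Fold
propensity uses the hydropathy / net-charge discriminant with Kyte-Doolittle
hydropathy min-max normalised to [0, 1]:

    index = 2.785 <H> - |<R>| - 1.151,   ordered iff index >= 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import KYTE_DOOLITTLE

logger = logging.getLogger(__name__)

MODIFICATION_TYPES = ("palmitoylation", "glutathionylation", "nitrosylation")

_CHARGE_RULE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.0}

_KD_MIN = min(KYTE_DOOLITTLE.values())
_KD_MAX = max(KYTE_DOOLITTLE.values())


def residue_charge(letter: str) -> float:
    """Charge-rule value; nonstandard letters score 0 and are logged."""
    c = _CHARGE_RULE.get(letter)
    if c is not None:
        return c
    if letter not in KYTE_DOOLITTLE:
        logger.debug("nonstandard residue %r scored as charge 0", letter)
    return 0.0


def residue_hydropathy_norm(letter: str) -> float:
    """Min-max normalised Kyte-Doolittle hydropathy; nonstandard letters take
    the scale midpoint."""
    kd = KYTE_DOOLITTLE.get(letter)
    if kd is None:
        logger.debug("nonstandard residue %r given midpoint hydropathy", letter)
        return 0.5
    return (kd - _KD_MIN) / (_KD_MAX - _KD_MIN)


@dataclass
class ModificationRecord:
    accession: str
    species: str
    sequence: str
    modified_cysteines: list[tuple[int, str]] = field(default_factory=list)
    ubiquitinated_lysines: list[int] = field(default_factory=list)
    structure_mappings: list[tuple[int, str, str, int]] = field(default_factory=list)

    def __post_init__(self):
        for pos, mtype in self.modified_cysteines:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"{self.accession}: position {pos} outside sequence")
            if self.sequence[pos - 1] != "C":
                raise ValueError(
                    f"{self.accession}: modified position {pos} is "
                    f"{self.sequence[pos - 1]!r}, not C"
                )
        for pos in self.ubiquitinated_lysines:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"{self.accession}: position {pos} outside sequence")
            if self.sequence[pos - 1] != "K":
                raise ValueError(
                    f"{self.accession}: ubiquitination position {pos} is "
                    f"{self.sequence[pos - 1]!r}, not K"
                )

    def all_cysteines(self) -> list[int]:
        return [i + 1 for i, a in enumerate(self.sequence) if a == "C"]


@dataclass(frozen=True)
class WindowConfig:
    width: int = 21

    def __post_init__(self):
        if self.width < 3 or self.width % 2 == 0:
            raise ValueError("window width must be odd and >= 3")

    @property
    def halfwidth(self) -> int:
        return (self.width - 1) // 2


@dataclass(frozen=True)
class DisorderModel:
    """Hydropathy/charge discriminant constants for the ordered/disordered
    boundary."""
    a: float = 2.785
    b: float = 1.151


def extract_window(record: ModificationRecord, position: int,
                   config: WindowConfig = WindowConfig()) -> str | None:
    """The full-width window centred at a cysteine, or None when the window
    would run past a terminus (terminal sites are excluded, never padded)."""
    seq = record.sequence
    if not 1 <= position <= len(seq):
        raise ValueError(f"position {position} outside sequence of "
                         f"{record.accession}")
    if seq[position - 1] != "C":
        raise ValueError(f"position {position} of {record.accession} is "
                         f"{seq[position - 1]!r}, not C")
    hw = config.halfwidth
    if position - hw < 1 or position + hw > len(seq):
        return None
    return seq[position - hw - 1: position + hw]


@dataclass
class SiteWindow:
    accession: str
    position: int
    window: str
    label: str  # MOD | NUL


def build_mod_nul_sets(records: list[ModificationRecord],
                       modification_type: str,
                       config: WindowConfig = WindowConfig()
                       ) -> tuple[list[SiteWindow], list[SiteWindow]]:
    """MOD = eligible windows at cysteines carrying the modification; NUL =
    eligible windows at every other cysteine of the same proteins.
    Deduplicated at (accession, position)."""
    mod: list[SiteWindow] = []
    nul: list[SiteWindow] = []
    seen: set[tuple[str, int]] = set()
    for rec in records:
        mod_positions = {p for p, t in rec.modified_cysteines
                         if t == modification_type}
        if not mod_positions:
            continue
        for pos in rec.all_cysteines():
            key = (rec.accession, pos)
            if key in seen:
                continue
            seen.add(key)
            window = extract_window(rec, pos, config)
            if window is None:
                continue
            label = "MOD" if pos in mod_positions else "NUL"
            (mod if label == "MOD" else nul).append(
                SiteWindow(rec.accession, pos, window, label))
    return mod, nul


def net_charge(window: str, config: WindowConfig = WindowConfig()) -> float:
    """Summed charge over a full-width window."""
    if len(window) != config.width:
        raise ValueError(f"window length {len(window)} != width {config.width}")
    return sum(residue_charge(a) for a in window)


@dataclass
class WindowProfile:
    label: str
    positions: np.ndarray        # -hw..hw
    mean_charge: np.ndarray      # per-position mean charge
    cumulative: np.ndarray       # running sum along the window
    mean_charge_per_aa: float    # window net charge / width, averaged
    n_windows: int


def window_profile(windows: list[SiteWindow], label: str,
                   config: WindowConfig = WindowConfig()) -> WindowProfile:
    if not windows:
        raise ValueError(f"empty {label} window set")
    hw = config.halfwidth
    mat = np.array([[residue_charge(a) for a in w.window] for w in windows])
    mean = mat.mean(axis=0)
    return WindowProfile(
        label=label,
        positions=np.arange(-hw, hw + 1),
        mean_charge=mean,
        cumulative=np.cumsum(mean),
        mean_charge_per_aa=float(mat.sum(axis=1).mean() / config.width),
        n_windows=len(windows),
    )


def charge_profiles(mod: list[SiteWindow], nul: list[SiteWindow],
                    config: WindowConfig = WindowConfig()
                    ) -> tuple[WindowProfile, WindowProfile, np.ndarray]:
    """Per-position mean-charge profiles for MOD and NUL plus their
    elementwise MOD - NUL difference."""
    pmod = window_profile(mod, "MOD", config)
    pnul = window_profile(nul, "NUL", config)
    return pmod, pnul, pmod.mean_charge - pnul.mean_charge


def fold_propensity(window: str,
                    model: DisorderModel = DisorderModel()) -> tuple[float, str]:
    """Fold index of a window and its ordered/disordered call (index 0 is
    called ordered)."""
    h = np.mean([residue_hydropathy_norm(a) for a in window])
    r = np.mean([residue_charge(a) for a in window])
    index = model.a * h - abs(r) - model.b
    return float(index), ("ordered" if index >= 0 else "disordered")


def per_protein_charge_comparison(records: list[ModificationRecord],
                                  modification_type: str,
                                  config: WindowConfig = WindowConfig()
                                  ) -> dict:
    """Per protein, is the mean MOD window net charge more positive than the
    mean NUL window net charge?  Ties count as 'not greater'."""
    greater = 0
    not_greater = 0
    per_protein = []
    for rec in records:
        mod, nul = build_mod_nul_sets([rec], modification_type, config)
        if not mod or not nul:
            continue
        mod_mean = float(np.mean([net_charge(w.window, config) for w in mod]))
        nul_mean = float(np.mean([net_charge(w.window, config) for w in nul]))
        win = mod_mean > nul_mean
        greater += win
        not_greater += not win
        per_protein.append((rec.accession, mod_mean, nul_mean, win))
    if greater + not_greater == 0:
        raise ValueError("no protein with both eligible MOD and NUL windows")
    return {
        "greater": greater,
        "not_greater": not_greater,
        "ratio": greater / not_greater if not_greater else np.inf,
        "fraction_greater": greater / (greater + not_greater),
        "per_protein": per_protein,
    }


def map_site_to_structure(record: ModificationRecord,
                          mapping: pd.DataFrame,
                          position: int) -> list[tuple[str, str, int]]:
    """All (pdb id, chain, residue number) triples mapped to a UniProt-style
    site from a SIFTS-like table with columns accession, uniprot_position,
    pdb_id, chain, pdb_residue_number."""
    rows = mapping[(mapping["accession"] == record.accession)
                   & (mapping["uniprot_position"] == position)]
    if rows.empty:
        return []
    dup = rows.groupby(["pdb_id", "chain"])["pdb_residue_number"].nunique()
    conflicts = dup[dup > 1]
    if len(conflicts):
        raise ValueError(
            f"conflicting mapping rows for {record.accession}:{position} -> "
            + ", ".join(f"{p}/{c}" for p, c in conflicts.index)
        )
    return list(rows[["pdb_id", "chain", "pdb_residue_number"]]
                .drop_duplicates().itertuples(index=False, name=None))


def single_species_subset(records: list[ModificationRecord],
                          species: str) -> list[ModificationRecord]:
    """Exact-species filter (orthologue-free analysis path)."""
    out = [r for r in records if r.species == species]
    if not out:
        logger.warning("no records for species %r", species)
    return out
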