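"""Synthetic fixtures with known ground truth.

Four generator families cover every stage of the pipeline without any
database download: (1) Born spheres with closed-form desolvation energies,
(2) ideal alpha-helices with HELIX records and CB/SG pseudo-atoms,
(3) cysteine-PTM sequence sets with planted per-position basic excess,
planted ubiquitination proximity and a truth table, and (4) half-life /
abundance tables with a configurable log-scale shift for modified proteins.

Every generator is a pure function of its configuration, seed included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import ONE_TO_THREE, STANDARD_AA1
from .electrostatics import ElectrostaticParameters, born_analytic
from .ptm import ModificationRecord
from .structure import Atom, Chain, HelixRecord, Residue, Structure

_BASIC = ("K", "R")
_CHARGED = set("DEKR")


# ---------------------------------------------------------------------------
# electrostatics fixtures

@dataclass
class BornFixture:
    structure: Structure
    radius: float
    charge: float
    analytic_desolvation: float  # kcal/mol


def make_born_fixture(radius: float, charge: float = 1.0,
                      params: ElectrostaticParameters | None = None
                      ) -> BornFixture:
    """Single pseudo-atom of the given radius with a centred point charge,
    plus the closed-form Born transfer energy for the configured dielectrics."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    params = params or ElectrostaticParameters()
    atom = Atom(name="X", element="S", pos=np.zeros(3))
    res = Residue(chain_id="A", number=1, icode="", name="CYS", atoms=[atom])
    st = Structure(id="born", chains=[Chain(id="A", residues=[res])])
    return BornFixture(structure=st, radius=radius, charge=charge,
                       analytic_desolvation=born_analytic(radius, charge, params))


# ---------------------------------------------------------------------------
# ideal helix

def make_ideal_helix(sequence: str,
                     rise: float = 1.5,
                     twist_deg: float = 100.0,
                     structure_id: str = "helix") -> Structure:
    """Backbone (N, CA, C, O) plus CB and, for cysteines, SG pseudo-atoms on
    ideal alpha-helical geometry, with a HELIX record spanning the chain.

    Deterministic: identical input gives identical coordinates.
    """
    if len(sequence) < 4:
        raise ValueError("helix needs at least 4 residues")
    residues = []
    for i, letter in enumerate(sequence.upper()):
        if letter not in ONE_TO_THREE:
            raise ValueError(f"unknown residue letter {letter!r}")
        name = ONE_TO_THREE[letter]
        phi = math.radians(twist_deg) * i
        z = rise * i

        def cyl(r, dphi_deg, dz):
            a = phi + math.radians(dphi_deg)
            return np.array([r * math.cos(a), r * math.sin(a), z + dz])

        radial = np.array([math.cos(phi), math.sin(phi), 0.0])
        atoms = [
            Atom("N", "N", cyl(1.60, -28.0, -0.90)),
            Atom("CA", "C", cyl(2.30, 0.0, 0.0)),
            Atom("C", "C", cyl(1.70, 26.0, 0.55)),
        ]
        atoms.append(Atom("O", "O", atoms[2].pos + 1.23 * radial))
        if name != "GLY":
            cb_dir = radial * 0.95 + np.array([0.0, 0.0, -0.31])
            cb_dir /= np.linalg.norm(cb_dir)
            cb = atoms[1].pos + 1.53 * cb_dir
            atoms.append(Atom("CB", "C", cb))
            if name == "CYS":
                atoms.append(Atom("SG", "S", cb + 1.81 * radial))
            elif name == "SER":
                atoms.append(Atom("OG", "O", cb + 1.41 * radial))
        residues.append(Residue(chain_id="A", number=i + 1, icode="",
                                name=name, atoms=atoms))
    chain = Chain(id="A", residues=residues)
    helix = HelixRecord(chain_id="A", start=1, end=len(sequence))
    return Structure(id=structure_id, chains=[chain], helices=[helix])


def helix_axis_point(structure: Structure, z: float) -> np.ndarray:
    """Point on the ideal helix axis (the z-axis of make_ideal_helix)."""
    return np.array([0.0, 0.0, z])


# ---------------------------------------------------------------------------
# PTM sequence sets

@dataclass
class GeneratorConfig:
    """Planted-effect configuration for the PTM sequence generator.

    ``delta`` moves probability mass per window position from non-charged
    residues to Lys/Arg (half each) around modified cysteines, so the
    expected per-position MOD-NUL mean-charge difference equals delta.
    ``enriched_protein_fraction`` applies +delta to that fraction of
    proteins and -delta to the rest (per-protein ranking preset).
    """
    seed: int = 0
    n_proteins: int = 200
    sequence_length: int = 400
    n_mod_per_protein: int = 1
    n_nul_per_protein: int = 3
    modification_type: str = "palmitoylation"
    species: str = "human"
    delta: float = 0.0
    enriched_protein_fraction: float | None = None
    window_halfwidth: int = 10
    place_ubiquitination: bool = True
    mod_ub_mean_distance: float = 15.0
    n_background_ub: int = 2
    mod_buried_fraction: float = 0.5
    nul_buried_fraction: float = 0.5

    def __post_init__(self):
        base = 1.0 / len(STANDARD_AA1)
        n_donor = len(STANDARD_AA1) - len(_CHARGED)
        if abs(self.delta) / 2 / n_donor > base or abs(self.delta) > 2 * (1 - base):
            raise ValueError("delta pushes residue probabilities out of [0, 1]")


def _window_distribution(delta: float) -> tuple[np.ndarray, list[str]]:
    """Residue sampling distribution with basic excess delta (may be
    negative: acidic excess, mirrored onto D/E)."""
    letters = list(STANDARD_AA1)
    p = np.full(len(letters), 1.0 / len(letters))
    if delta == 0.0:
        return p, letters
    targets = _BASIC if delta > 0 else ("D", "E")
    donors = [i for i, a in enumerate(letters) if a not in _CHARGED]
    d = abs(delta)
    for t in targets:
        p[letters.index(t)] += d / 2.0
    for i in donors:
        p[i] -= d / len(donors)
    if (p < 0).any():
        raise ValueError("delta pushes residue probabilities out of [0, 1]")
    return p / p.sum(), letters


def generate_ptm_dataset(config: GeneratorConfig
                         ) -> tuple[list[ModificationRecord], pd.DataFrame]:
    """Sequence set with planted charge and proximity effects + truth table.

    Truth table rows record, per cysteine site: accession, position, MOD/NUL
    status, the delta applied to its window, the planted nearest-ubiquitination
    distance, and the buried flag — enough to recompute every planted effect
    independently of the analysis pipeline.
    """
    rng = np.random.default_rng(config.seed)
    letters = list(STANDARD_AA1)
    background_p = np.full(len(letters), 1.0 / len(letters))
    hw = config.window_halfwidth
    records: list[ModificationRecord] = []
    truth_rows = []

    for ip in range(config.n_proteins):
        acc = f"SYN{ip:05d}"
        length = config.sequence_length
        seq = list(rng.choice(letters, size=length, p=background_p))
        if config.enriched_protein_fraction is None:
            delta = config.delta
            enriched = delta > 0
        else:
            enriched = bool(rng.random() < config.enriched_protein_fraction)
            delta = config.delta if enriched else -config.delta
        window_p, _ = _window_distribution(delta)

        n_sites = config.n_mod_per_protein + config.n_nul_per_protein
        # non-overlapping site positions, windows clear of the termini
        lo, hi = hw + 1, length - hw
        positions = []
        attempts = 0
        while len(positions) < n_sites and attempts < 10000:
            cand = int(rng.integers(lo, hi + 1))
            if all(abs(cand - p) > 2 * hw + 1 for p in positions):
                positions.append(cand)
            attempts += 1
        rng.shuffle(positions)
        mod_pos = sorted(positions[:config.n_mod_per_protein])
        nul_pos = sorted(positions[config.n_mod_per_protein:])

        for p in mod_pos + nul_pos:
            seq[p - 1] = "C"
        # resample MOD windows with the planted excess
        for p in mod_pos:
            for off in range(-hw, hw + 1):
                if off == 0:
                    continue
                seq[p - 1 + off] = rng.choice(letters, p=window_p)
        # stray cysteines elsewhere would join the NUL set; neutralise them
        for i in range(length):
            if seq[i] == "C" and (i + 1) not in mod_pos and (i + 1) not in nul_pos:
                seq[i] = "A"

        ub_positions: list[int] = []
        site_ub: dict[int, int] = {}
        mod_iter = mod_pos if config.place_ubiquitination else []
        for p in mod_iter:
            d = int(rng.geometric(1.0 / config.mod_ub_mean_distance))
            side = rng.choice([-1, 1])
            k = p + side * d
            if not (1 <= k <= length) or seq[k - 1] == "C":
                k = p - side * d
            if 1 <= k <= length and seq[k - 1] != "C":
                seq[k - 1] = "K"
                ub_positions.append(k)
                site_ub[p] = d
        n_bg = config.n_background_ub if config.place_ubiquitination else 0
        for _ in range(n_bg):
            k = int(rng.integers(1, length + 1))
            if seq[k - 1] != "C":
                seq[k - 1] = "K"
                ub_positions.append(k)

        sequence = "".join(seq)
        records.append(ModificationRecord(
            accession=acc, species=config.species, sequence=sequence,
            modified_cysteines=[(p, config.modification_type) for p in mod_pos],
            ubiquitinated_lysines=sorted(set(ub_positions)),
        ))
        for p in mod_pos + nul_pos:
            is_mod = p in mod_pos
            buried_frac = (config.mod_buried_fraction if is_mod
                           else config.nul_buried_fraction)
            truth_rows.append({
                "accession": acc, "position": p,
                "set": "MOD" if is_mod else "NUL",
                "delta": delta if is_mod else 0.0,
                "enriched_protein": enriched,
                "planted_ub_distance": site_ub.get(p, np.nan),
                "buried": bool(rng.random() < buried_frac),
            })
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# half-life / abundance

@dataclass
class HalfLifeConfig:
    seed: int = 0
    n_mod: int = 300
    n_nul: int = 300
    log10_halflife_mean: float = 1.5    # ~32 h
    log10_halflife_sd: float = 0.4
    log10_abundance_mean: float = 5.0   # copies per cell
    log10_abundance_sd: float = 0.8
    halflife_shift: float = 0.0         # log10 shift added to MOD proteins
    abundance_shift: float = 0.0


def generate_halflife_abundance(config: HalfLifeConfig) -> pd.DataFrame:
    """Log-normal half-life (hours) and abundance (copies/cell) table with
    MOD proteins shifted by the configured log10 offsets."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for i in range(config.n_mod + config.n_nul):
        mod = i < config.n_mod
        hl = 10 ** (rng.normal(config.log10_halflife_mean
                               + (config.halflife_shift if mod else 0.0),
                               config.log10_halflife_sd))
        ab = 10 ** (rng.normal(config.log10_abundance_mean
                               + (config.abundance_shift if mod else 0.0),
                               config.log10_abundance_sd))
        rows.append({"accession": f"HL{i:05d}", "half_life_h": hl,
                     "copies_per_cell": ab, "modified": mod})
    return pd.DataFrame(rows)
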