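"""Site-based pKa prediction: intrinsic pKas, pairwise coupling, Monte Carlo
titration.

The scheme is the hybrid FDPB / Debye-Hückel (FDDH) approach: desolvation and
background terms for each titratable site come from finite-difference PB runs
(identical-grid subtraction against a model-compound reference), pairwise
couplings are a burial-weighted mix of FDPB and screened-Coulomb energies,
and predicted pKas come from Metropolis Monte Carlo sampling of protonation
microstates over a pH ladder.

State energy at a given pH, with x_i the protonation indicator of site i:

    E(x) = sum_i 2.303 RT gamma_i(x_i) (pH - pKa_intr,i)
         + sum_{i<j} W_ij c_i(x_i) c_j(x_j)

where gamma_i = 1 when protonated and c_i is the ionised-form charge when the
site is ionised (acids ionise on deprotonation, bases on protonation), else 0.

All cysteines are treated as titratable regardless of disulphide status, so
that ionisation is always permitted; tyrosine is not titrated and enters only
through its hydroxyl background dipole.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .constants import MODEL_PKAS, SITE_POLARITY, VDW_RADII
from .electrostatics import (ElectrostaticParameters, PotentialGrid,
                             debye_huckel_energy, solve_fdpb)
from .structure import Atom, Chain, Residue, Structure
from .surface import compute_sasa

logger = logging.getLogger(__name__)

# ionised-form formal charges on representative atoms
_CHARGE_MODEL = {
    "CYS": [("SG", -1.0)],
    "ASP": [("OD1", -0.5), ("OD2", -0.5)],
    "GLU": [("OE1", -0.5), ("OE2", -0.5)],
    "LYS": [("NZ", 1.0)],
    "ARG": [("NH1", 0.5), ("NH2", 0.5)],
    "HIS": [("ND1", 0.5), ("NE2", 0.5)],
}

_HYDROXYL_FRAMES = {
    # residue -> (O, parent, grandparent)
    "SER": ("OG", "CB", "CA"),
    "THR": ("OG1", "CB", "CA"),
    "TYR": ("OH", "CZ", "CE1"),
}

OH_DIPOLE_CHARGE = 0.4  # +-q on H/O of hydroxyl background dipoles


class MissingSiteAtomError(ValueError):
    pass


@dataclass
class TitratableSite:
    residue_key: tuple[str, int, str] | None  # None for termini pseudo-sites
    chain_id: str
    residue_number: int
    site_type: str                       # CYS/ASP/.../NTERM/CTERM
    charge_atoms: list[tuple[str, np.ndarray, float]]  # (name, pos, q_ionised)
    model_pka: float
    polarity: str                        # acid | base
    intrinsic_pka: float | None = None
    sasa: float | None = None            # representative-atom SASA, A^2
    burial: float = 0.0                  # fractional burial in [0, 1]

    @property
    def ionised_charge(self) -> float:
        return sum(q for _, _, q in self.charge_atoms)

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.site_type}{self.residue_number}"


@dataclass
class TitrationConfig:
    ph_start: float = -2.0
    ph_stop: float = 20.0
    ph_step: float = 0.25
    mc_steps: int = 100_000   # Metropolis sweeps (n attempted moves each)
    burnin: int = 10_000
    seed: int = 0
    double_flip_fraction: float = 0.1
    coupling_threshold: float = 2.0       # kcal/mol, |W| above => coupled pair
    grid_spacing: float = 0.5
    grid_padding: float = 10.0
    sasa_points: int = 960
    include_termini: bool = True
    exclude_ligands: bool = False
    high_pka_cutoff: float = 15.0

    def ladder(self) -> np.ndarray:
        n = int(round((self.ph_stop - self.ph_start) / self.ph_step)) + 1
        return self.ph_start + self.ph_step * np.arange(n)


@dataclass
class TitrationResult:
    ph_ladder: np.ndarray
    fractions: np.ndarray          # (n_ph, n_sites) protonation fractions
    pkas: np.ndarray               # (n_sites,), NaN when not crossed
    flag_high: np.ndarray          # half-protonation beyond the cutoff
    flag_low: np.ndarray           # still below 0.5 at the ladder start

    def pka_label(self, i: int, cutoff: float = 15.0) -> str:
        if self.flag_high[i]:
            return f">{cutoff:g}"
        if self.flag_low[i]:
            return f"<{self.ph_ladder[0]:g}"
        return f"{self.pkas[i]:.2f}"


def identify_sites(structure: Structure,
                   include_termini: bool = True) -> list[TitratableSite]:
    """Collect titratable sites; sites with missing charge-bearing atoms are
    excluded and logged, never approximated from the backbone."""
    sites: list[TitratableSite] = []
    for res in structure.residues():
        model = _CHARGE_MODEL.get(res.name)
        if model is None:
            continue
        atoms = []
        missing = False
        for name, q in model:
            atom = res.atom(name)
            if atom is None:
                missing = True
                break
            atoms.append((name, atom.pos.copy(), q))
        if missing:
            logger.warning("site %s/%s%d skipped: missing charge atom",
                           res.chain_id, res.name, res.number)
            continue
        sites.append(TitratableSite(
            residue_key=res.key, chain_id=res.chain_id,
            residue_number=res.number, site_type=res.name,
            charge_atoms=atoms, model_pka=MODEL_PKAS[res.name],
            polarity=SITE_POLARITY[res.name],
        ))
    if include_termini:
        for chain in structure.chains:
            if not chain.residues:
                continue
            first, last = chain.residues[0], chain.residues[-1]
            n_atom = first.atom("N")
            if n_atom is not None:
                sites.append(TitratableSite(
                    residue_key=first.key, chain_id=chain.id,
                    residue_number=first.number, site_type="NTERM",
                    charge_atoms=[("N", n_atom.pos.copy(), 1.0)],
                    model_pka=MODEL_PKAS["NTERM"], polarity="base",
                ))
            o_atom, oxt = last.atom("O"), last.atom("OXT")
            if o_atom is not None:
                pos = (0.5 * (o_atom.pos + oxt.pos) if oxt is not None
                       else o_atom.pos.copy())
                sites.append(TitratableSite(
                    residue_key=last.key, chain_id=chain.id,
                    residue_number=last.number, site_type="CTERM",
                    charge_atoms=[("O", pos, -1.0)],
                    model_pka=MODEL_PKAS["CTERM"], polarity="acid",
                ))
    return sites


# ---------------------------------------------------------------------------
# hydroxyl torsion optimisation

def optimize_hydroxyl_torsions(structure: Structure,
                               sites: list[TitratableSite],
                               step_deg: float = 30.0) -> Structure:
    """Place Ser/Thr/Tyr hydroxyl hydrogens at the discrete torsion angle
    (30 degree scan) minimising the Coulomb energy between the OH dipole and
    the ionised forms of all titratable sites.  The hydrogen is added to the
    residue as atom ``HO``; the structure is modified in place and returned.
    """
    charges = [(pos, q) for s in sites for _, pos, q in s.charge_atoms]
    for res in structure.residues():
        frame = _HYDROXYL_FRAMES.get(res.name)
        if frame is None:
            continue
        o, c, g = (res.atom(n) for n in frame)
        if o is None or c is None or g is None:
            logger.info("hydroxyl of %s/%s%d skipped: parent atoms missing",
                        res.chain_id, res.name, res.number)
            continue
        u = o.pos - c.pos
        u = u / np.linalg.norm(u)
        v0 = g.pos - c.pos
        v0 = v0 - np.dot(v0, u) * u
        v0 = v0 / np.linalg.norm(v0)
        w = np.cross(u, v0)
        # O-H bond 0.96 A at 109.5 deg from the C-O bond
        cos_t = math.cos(math.radians(70.5))
        sin_t = math.sin(math.radians(70.5))
        best = None
        taus = np.radians(np.arange(0.0, 360.0, step_deg))
        for tau in taus:
            d = cos_t * u + sin_t * (math.cos(tau) * v0 + math.sin(tau) * w)
            hpos = o.pos + 0.96 * d
            e = 0.0
            for pos, q in charges:
                r = np.linalg.norm(hpos - pos)
                if r > 1e-6:
                    e += OH_DIPOLE_CHARGE * q / r
            if best is None or e < best[0] - 1e-12:
                best = (e, hpos)
        prev = res.atom("HO")
        if prev is not None:
            prev.pos = best[1]
        else:
            res.atoms.append(Atom(name="HO", element="H", pos=best[1],
                                  parent_name=res.name))
    return structure


def hydroxyl_dipoles(structure: Structure) -> list[tuple[np.ndarray, float]]:
    """Background +-0.4 e charges on placed hydroxyl H/O pairs."""
    out: list[tuple[np.ndarray, float]] = []
    for res in structure.residues():
        frame = _HYDROXYL_FRAMES.get(res.name)
        if frame is None:
            continue
        o, h = res.atom(frame[0]), res.atom("HO")
        if o is None or h is None:
            continue
        out.append((o.pos, -OH_DIPOLE_CHARGE))
        out.append((h.pos, OH_DIPOLE_CHARGE))
    return out


# ---------------------------------------------------------------------------
# intrinsic pKas

def compute_intrinsic_pka(site: TitratableSite,
                          ddg_desolv: float,
                          ddg_background: float,
                          params: ElectrostaticParameters) -> float:
    """pKa_intr = pKa_model + s (ddG_desolv + ddG_background) / (2.303 RT).

    The ddG terms are the change of the ionised form's energy on transfer
    from the model compound to the protein, so destabilising the anion raises
    an acid's pKa (s = +1) and destabilising the cation lowers a base's
    (s = -1).
    """
    s = 1.0 if site.polarity == "acid" else -1.0
    return site.model_pka + s * (ddg_desolv + ddg_background) / params.ln10_rt


# ---------------------------------------------------------------------------
# interaction matrix

@dataclass
class InteractionMatrix:
    sites: list[TitratableSite]
    w: np.ndarray  # symmetric (n, n), kcal/mol between ionised forms


def pair_energy_dh(site_i: TitratableSite, site_j: TitratableSite,
                   params: ElectrostaticParameters) -> float:
    e = 0.0
    for _, pi, qi in site_i.charge_atoms:
        for _, pj, qj in site_j.charge_atoms:
            r = float(np.linalg.norm(pi - pj))
            e += debye_huckel_energy(qi, qj, r, params)
    return e


def pair_energy_from_grid(grid: PotentialGrid, site_j: TitratableSite,
                          site_i: TitratableSite,
                          params: ElectrostaticParameters) -> float:
    """FDPB pair energy: site i's potential map evaluated at site j's
    charges; charges outside the focused grid fall back to Debye-Hückel."""
    e = 0.0
    for _, pj, qj in site_j.charge_atoms:
        if grid.contains(pj, margin=2.0 * grid.spacing)[0]:
            e += qj * grid.interpolate(pj)[0]
        else:
            for _, pi, qi in site_i.charge_atoms:
                r = float(np.linalg.norm(pi - pj))
                e += debye_huckel_energy(qi, qj, r, params)
    return e


def build_interaction_matrix(sites: list[TitratableSite],
                             params: ElectrostaticParameters,
                             grids: dict[int, PotentialGrid] | None = None
                             ) -> InteractionMatrix:
    """Hybrid coupling W_ij = w_ij W_FDPB + (1 - w_ij) W_DH with
    w_ij the mean fractional burial of the pair; computed once per unordered
    pair (from the lower-index site's FDPB map when one is available)."""
    n = len(sites)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _check_separation(sites[i], sites[j])
            wij = 0.5 * (sites[i].burial + sites[j].burial)
            e_dh = pair_energy_dh(sites[i], sites[j], params)
            if wij > 0.0 and grids and i in grids:
                e_fdpb = pair_energy_from_grid(grids[i], sites[j], sites[i],
                                               params)
            else:
                e_fdpb = e_dh
            w[i, j] = w[j, i] = wij * e_fdpb + (1.0 - wij) * e_dh
    return InteractionMatrix(sites=sites, w=w)


def _check_separation(site_i: TitratableSite, site_j: TitratableSite) -> None:
    for _, pi, _ in site_i.charge_atoms:
        for _, pj, _ in site_j.charge_atoms:
            if np.linalg.norm(pi - pj) < 0.5:
                raise ValueError(
                    f"overlapping charge positions between {site_i.label} "
                    f"and {site_j.label}"
                )


# ---------------------------------------------------------------------------
# Monte Carlo titration

@njit(cache=True)
def _mc_single_ph(ph, pkas, ion_at_prot, charges, w, ln10rt, rt,
                  steps, burnin, seed, pairs, p_double):
    np.random.seed(seed)
    n = pkas.shape[0]
    x = np.zeros(n, dtype=np.int8)  # protonation indicators
    for i in range(n):
        if np.random.random() < 0.5:
            x[i] = 1
    acc = np.zeros(n)
    n_pairs = pairs.shape[0]
    # one step is a sweep of n attempted moves
    for step in range(steps + burnin):
        for _ in range(n):
            use_double = n_pairs > 0 and np.random.random() < p_double
            if use_double:
                kpair = np.random.randint(n_pairs)
                ka, kb = pairs[kpair, 0], pairs[kpair, 1]
                de = _flip_de(ka, x, ph, pkas, ion_at_prot, charges, w, ln10rt)
                # flip ka virtually, then kb
                x[ka] = 1 - x[ka]
                de += _flip_de(kb, x, ph, pkas, ion_at_prot, charges, w, ln10rt)
                x[ka] = 1 - x[ka]
                if de <= 0.0 or np.random.random() < math.exp(-de / rt):
                    x[ka] = 1 - x[ka]
                    x[kb] = 1 - x[kb]
            else:
                k = np.random.randint(n)
                de = _flip_de(k, x, ph, pkas, ion_at_prot, charges, w, ln10rt)
                if de <= 0.0 or np.random.random() < math.exp(-de / rt):
                    x[k] = 1 - x[k]
        if step >= burnin:
            for i in range(n):
                acc[i] += x[i]
    return acc / steps


@njit(cache=True)
def _flip_de(k, x, ph, pkas, ion_at_prot, charges, w, ln10rt):
    n = x.shape[0]
    dgamma = 1.0 - 2.0 * x[k]
    de = dgamma * ln10rt * (ph - pkas[k])
    ion_k = x[k] == ion_at_prot[k]
    dion = -1.0 if ion_k else 1.0
    s = 0.0
    for j in range(n):
        if j == k:
            continue
        if x[j] == ion_at_prot[j]:
            s += w[k, j] * charges[j]
    de += dion * charges[k] * s
    return de


def mc_titration(sites: list[TitratableSite],
                 intrinsic_pkas: np.ndarray,
                 matrix: InteractionMatrix | np.ndarray | None,
                 config: TitrationConfig,
                 ph_ladder: np.ndarray | None = None) -> TitrationResult:
    """Metropolis sampling of protonation states over a pH ladder.

    Moves are single-site flips plus a fraction of double flips over
    strongly coupled pairs (|W| above the coupling threshold).  Protonation
    fractions are averaged after burn-in; pKa is the linearly interpolated pH
    of half protonation, flagged high/low when the ladder is not crossed.
    """
    n = len(sites)
    if ph_ladder is None:
        ph_ladder = config.ladder()
    ph_ladder = np.asarray(ph_ladder, dtype=float)
    if len(ph_ladder) > 1 and not np.all(np.diff(ph_ladder) > 0):
        raise ValueError("pH ladder must be strictly increasing")
    if config.mc_steps < 1:
        raise ValueError("mc_steps must be positive")
    w = matrix.w if isinstance(matrix, InteractionMatrix) else matrix
    if w is None:
        w = np.zeros((n, n))
    w = np.asarray(w, dtype=float)
    pkas = np.asarray(intrinsic_pkas, dtype=float)
    ion_at_prot = np.array([1 if s.polarity == "base" else 0 for s in sites],
                           dtype=np.int8)
    charges = np.array([s.ionised_charge for s in sites], dtype=float)
    pairs = np.array([(i, j) for i in range(n) for j in range(i + 1, n)
                      if abs(w[i, j]) > config.coupling_threshold],
                     dtype=np.int64).reshape(-1, 2)
    params = ElectrostaticParameters()
    rt, ln10rt = params.rt, params.ln10_rt

    fractions = np.zeros((len(ph_ladder), n))
    for k, ph in enumerate(ph_ladder):
        seed = int((config.seed * 100003 + k) % (2 ** 31 - 1))
        fractions[k] = _mc_single_ph(
            ph, pkas, ion_at_prot, charges, w, ln10rt, rt,
            config.mc_steps, config.burnin, seed, pairs,
            config.double_flip_fraction,
        )
    return _extract_pkas(ph_ladder, fractions, config.high_pka_cutoff)


def enumerate_titration(sites: list[TitratableSite],
                        intrinsic_pkas: np.ndarray,
                        matrix: InteractionMatrix | np.ndarray | None,
                        config: TitrationConfig,
                        ph_ladder: np.ndarray | None = None
                        ) -> TitrationResult:
    """Exact titration by partition-function enumeration (up to ~16 sites).

    Serves as the small-system reference for the Monte Carlo sampler.
    """
    n = len(sites)
    if ph_ladder is None:
        ph_ladder = config.ladder()
    ph_ladder = np.asarray(ph_ladder, dtype=float)
    w = matrix.w if isinstance(matrix, InteractionMatrix) else matrix
    if w is None:
        w = np.zeros((n, n))
    pkas = np.asarray(intrinsic_pkas, dtype=float)
    ion_at_prot = np.array([1 if s.polarity == "base" else 0 for s in sites])
    charges = np.array([s.ionised_charge for s in sites])
    params = ElectrostaticParameters()
    rt, ln10rt = params.rt, params.ln10_rt

    states = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1)  # (S, n)
    ion = (states == ion_at_prot[None, :]).astype(float) * charges[None, :]
    e_pair = 0.5 * np.einsum("si,ij,sj->s", ion, w, ion)
    fractions = np.zeros((len(ph_ladder), n))
    for k, ph in enumerate(ph_ladder):
        e = (states * (ln10rt * (ph - pkas))[None, :]).sum(axis=1) + e_pair
        e -= e.min()
        boltz = np.exp(-e / rt)
        z = boltz.sum()
        fractions[k] = (boltz[:, None] * states).sum(axis=0) / z
    return _extract_pkas(ph_ladder, fractions, config.high_pka_cutoff)


def _extract_pkas(ph_ladder: np.ndarray, fractions: np.ndarray,
                  high_cutoff: float) -> TitrationResult:
    n = fractions.shape[1]
    pkas = np.full(n, np.nan)
    flag_high = np.zeros(n, dtype=bool)
    flag_low = np.zeros(n, dtype=bool)
    for i in range(n):
        f = fractions[:, i]
        if f[0] < 0.5:
            flag_low[i] = True
            continue
        above = np.nonzero(f >= 0.5)[0]
        last = above[-1]
        if last == len(ph_ladder) - 1:
            flag_high[i] = True
            continue
        f0, f1 = f[last], f[last + 1]
        p0, p1 = ph_ladder[last], ph_ladder[last + 1]
        pka = p0 + (0.5 - f0) * (p1 - p0) / (f1 - f0)
        pkas[i] = pka
        if pka > high_cutoff:
            flag_high[i] = True
    return TitrationResult(ph_ladder=ph_ladder, fractions=fractions,
                           pkas=pkas, flag_high=flag_high, flag_low=flag_low)


def make_isolated_site(site_type: str) -> TitratableSite:
    """A free model compound: one unit charge at the origin, model pKa,
    no perturbation — the single-site fixture for titration checks."""
    q = -1.0 if SITE_POLARITY[site_type] == "acid" else 1.0
    return TitratableSite(
        residue_key=None, chain_id="A", residue_number=1,
        site_type=site_type,
        charge_atoms=[("X", np.zeros(3), q)],
        model_pka=MODEL_PKAS[site_type],
        polarity=SITE_POLARITY[site_type],
        intrinsic_pka=MODEL_PKAS[site_type],
    )
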