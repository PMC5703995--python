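"""Solvent accessible surface area, burial classification and SG proximity.

SASA uses deterministic spherical point sampling (a golden-spiral lattice,
960 points per atom by default) with a 1.4 A probe and a fixed van der Waals
radius table.  Crystallographic waters are excluded from both the occluder
set and heteroatom counts unless asked for; hydrogens are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .constants import DEFAULT_PROBE_RADIUS, VDW_RADII
from .structure import Atom, Residue, Structure

#: SG-SASA thresholds (A^2) used for burial classification.
BURIAL_THRESHOLDS = (0.0, 0.1, 1.0)


class MissingAtomError(ValueError):
    pass


class UnknownElementError(ValueError):
    pass


def sphere_lattice(n_points: int) -> np.ndarray:
    """Deterministic unit-sphere lattice (golden-spiral), shape (n, 3)."""
    i = np.arange(n_points) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n_points)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


@dataclass
class SasaResult:
    atom_sasa: dict[tuple[str, int, str, str], float]  # (chain,num,icode,atom)->A^2
    residue_sasa: dict[tuple[str, int, str], float] = field(default_factory=dict)
    sg_sasa: dict[tuple[str, int, str], float] = field(default_factory=dict)

    def classify_sg(self, cys_key: tuple[str, int, str],
                    threshold: float) -> str:
        """'accessible' iff SG SASA strictly exceeds the threshold."""
        return "accessible" if self.sg_sasa[cys_key] > threshold else "buried"


def _atom_radius(atom: Atom, radii: dict[str, float] | None) -> float:
    table = radii or VDW_RADII
    r = table.get(atom.element)
    if r is None:
        raise UnknownElementError(
            f"no van der Waals radius for element {atom.element!r} (atom {atom.name})"
        )
    return r


def _collect_atoms(structure: Structure, include_waters: bool,
                   include_hetero: bool):
    """All non-hydrogen atoms with owner keys; heteroatoms occlude by default."""
    entries = []  # (key or None, atom)
    for res in structure.residues():
        for atom in res.atoms:
            if atom.element == "H":
                continue
            entries.append(((res.chain_id, res.number, res.icode, atom.name), atom))
    if include_hetero:
        for atom in structure.hetero_atoms:
            if atom.element == "H":
                continue
            if atom.is_water and not include_waters:
                continue
            entries.append((None, atom))
    return entries


def compute_sasa(structure: Structure,
                 probe_radius: float = DEFAULT_PROBE_RADIUS,
                 n_points: int = 960,
                 radii: dict[str, float] | None = None,
                 include_waters: bool = False,
                 include_hetero: bool = True) -> SasaResult:
    """Per-atom / per-residue / per-SG solvent accessible surface area.

    A sample point on the expanded sphere of atom i is accessible when it
    lies outside every other atom's expanded sphere; the atom's SASA is the
    accessible fraction times 4*pi*(r_i+probe)^2.
    """
    entries = _collect_atoms(structure, include_waters, include_hetero)
    if not entries:
        raise ValueError("structure has no atoms for SASA")
    positions = np.array([a.pos for _, a in entries])
    radii_arr = np.array([_atom_radius(a, radii) for _, a in entries])
    expanded = radii_arr + probe_radius
    lattice = sphere_lattice(n_points)

    tree = cKDTree(positions)
    max_reach = expanded.max()
    result = SasaResult(atom_sasa={})
    for i, (key, _atom) in enumerate(entries):
        pts = positions[i] + expanded[i] * lattice
        neighbours = [j for j in tree.query_ball_point(positions[i],
                                                       expanded[i] + max_reach)
                      if j != i]
        weight = np.ones(n_points)
        if neighbours:
            npos = positions[neighbours]
            nrad = expanded[neighbours]
            d = np.sqrt(((pts[:, None, :] - npos[None, :, :]) ** 2).sum(axis=2))
            inside = (d < nrad[None, :] - 1e-6).any(axis=1)
            # points shared by coincident expanded surfaces are split evenly
            shared = (np.abs(d - nrad[None, :]) <= 1e-6).sum(axis=1)
            weight = np.where(inside, 0.0, 1.0 / (1.0 + shared))
        area = 4.0 * np.pi * expanded[i] ** 2 * weight.mean()
        if key is not None:
            result.atom_sasa[key] = float(area)

    for res in structure.residues():
        rkey = (res.chain_id, res.number, res.icode)
        total = sum(result.atom_sasa.get((*rkey, a.name), 0.0)
                    for a in res.atoms if a.element != "H")
        result.residue_sasa[rkey] = total
        if res.name == "CYS":
            sg = result.atom_sasa.get((*rkey, "SG"))
            if sg is not None:
                result.sg_sasa[rkey] = sg
    return result


def detect_disulphides(structure: Structure, cutoff: float = 2.8
                       ) -> list[tuple[tuple[str, int, str], tuple[str, int, str]]]:
    """Disulphide pairs: SSBOND records (trusted as annotated) unioned with a
    geometric screen for SG-SG contacts within the cutoff.

    Geometric pairing is greedy closest-first and each cysteine joins at most
    one pair.
    """
    paired: dict[tuple[str, int, str], tuple[str, int, str]] = {}
    pairs: list[tuple[tuple[str, int, str], tuple[str, int, str]]] = []

    for bond in structure.ssbonds:
        a, b = bond.a, bond.b
        if a not in paired and b not in paired:
            paired[a] = b
            paired[b] = a
            pairs.append((a, b))

    cys = [(r, r.atom("SG")) for r in structure.cysteines()]
    cys = [(r, sg) for r, sg in cys if sg is not None]
    candidates = []
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            d = cys[i][1].distance_to(cys[j][1])
            if d <= cutoff:
                candidates.append((d, cys[i][0].key, cys[j][0].key))
    for _d, a, b in sorted(candidates):
        if a not in paired and b not in paired:
            paired[a] = b
            paired[b] = a
            pairs.append((a, b))
    return pairs


def heteroatom_neighbors(structure: Structure, cysteine: Residue,
                         cutoff: float = 4.0,
                         include_waters: bool = False) -> int:
    """Number of heteroatoms within ``cutoff`` of the cysteine SG atom."""
    sg = cysteine.atom("SG")
    if sg is None:
        raise MissingAtomError(
            f"cysteine {cysteine.chain_id}/{cysteine.number} has no SG atom"
        )
    count = 0
    for atom in structure.hetero_atoms:
        if atom.is_water and not include_waters:
            continue
        if np.linalg.norm(atom.pos - sg.pos) <= cutoff:
            count += 1
    return count


def isolated_atom_sasa(element: str, probe_radius: float = DEFAULT_PROBE_RADIUS,
                       radii: dict[str, float] | None = None) -> float:
    """Analytic SASA of an isolated atom: 4*pi*(r+probe)^2."""
    table = radii or VDW_RADII
    r = table.get(element)
    if r is None:
        raise UnknownElementError(f"no radius for element {element!r}")
    return 4.0 * np.pi * (r + probe_radius) ** 2
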