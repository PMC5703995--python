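"""PDB structure parsing and secondary-structure bookkeeping.

Parsing is delegated to gemmi; this module wraps the result in lightweight
domain types, resolves alternate locations (highest occupancy wins, ties by
altLoc letter), separates heteroatoms from the polymer, and provides the
helix-location assignment used throughout: each helical residue belongs to
either the N-terminal or the C-terminal half of its helix — never both —
with the transition at the helix midpoint.

Only MODEL 1 of multi-model files is read.  Secondary structure comes
exclusively from HELIX/SHEET records; there is no DSSP-style recomputation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .constants import STANDARD_AA3, THREE_TO_ONE, WATER_NAMES

# Heavy side-chain atoms expected for each standard residue (beyond N/CA/C/O).
_SIDECHAIN_ATOMS = {
    "ALA": {"CB"},
    "ARG": {"CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"},
    "ASN": {"CB", "CG", "OD1", "ND2"},
    "ASP": {"CB", "CG", "OD1", "OD2"},
    "CYS": {"CB", "SG"},
    "GLN": {"CB", "CG", "CD", "OE1", "NE2"},
    "GLU": {"CB", "CG", "CD", "OE1", "OE2"},
    "GLY": set(),
    "HIS": {"CB", "CG", "ND1", "CD2", "CE1", "NE2"},
    "ILE": {"CB", "CG1", "CG2", "CD1"},
    "LEU": {"CB", "CG", "CD1", "CD2"},
    "LYS": {"CB", "CG", "CD", "CE", "NZ"},
    "MET": {"CB", "CG", "SD", "CE"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "PRO": {"CB", "CG", "CD"},
    "SER": {"CB", "OG"},
    "THR": {"CB", "OG1", "CG2"},
    "TRP": {"CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"},
    "VAL": {"CB", "CG1", "CG2"},
}


class PDBParseError(ValueError):
    """Raised for malformed PDB input; carries the offending line number."""


class ResidueNotFoundError(KeyError):
    pass


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # (3,) angstrom
    occupancy: float = 1.0
    altloc: str = ""
    parent_name: str = ""      # residue name, for heteroatoms
    is_water: bool = False

    def distance_to(self, other: "Atom") -> float:
        return float(np.linalg.norm(self.pos - other.pos))


@dataclass
class Residue:
    chain_id: str
    number: int
    icode: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def is_standard(self) -> bool:
        return self.name in STANDARD_AA3

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    @property
    def incomplete(self) -> bool:
        """True when expected heavy side-chain atoms are missing."""
        expected = _SIDECHAIN_ATOMS.get(self.name)
        if expected is None:
            return False
        present = {a.name for a in self.atoms}
        return not expected <= present

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def get(self, number: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        return None


@dataclass
class HelixRecord:
    chain_id: str
    start: int
    end: int
    dangling: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class StrandRecord:
    chain_id: str
    start: int
    end: int
    dangling: bool = False


@dataclass
class SSBondRecord:
    a: tuple[str, int, str]  # (chain, number, icode)
    b: tuple[str, int, str]


@dataclass
class HelixLocation:
    in_helix: bool
    position_from_nterm: int | None = None
    region: str | None = None  # "N-terminal" | "C-terminal"


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    helices: list[HelixRecord] = field(default_factory=list)
    sheets: list[StrandRecord] = field(default_factory=list)
    ssbonds: list[SSBondRecord] = field(default_factory=list)
    hetero_atoms: list[Atom] = field(default_factory=list)

    def residues(self):
        for chain in self.chains:
            yield from chain.residues

    def get_residue(self, chain_id: str, number: int, icode: str = "") -> Residue:
        for chain in self.chains:
            if chain.id == chain_id:
                res = chain.get(number, icode)
                if res is not None:
                    return res
        raise ResidueNotFoundError(
            f"residue {chain_id}/{number}{icode} not in structure {self.id!r}"
        )

    def n_standard_residues(self) -> int:
        return sum(1 for r in self.residues() if r.is_standard)

    def cysteines(self) -> list[Residue]:
        return [r for r in self.residues() if r.name == "CYS"]

    def chain_sequence(self, chain_id: str) -> str:
        for chain in self.chains:
            if chain.id == chain_id:
                return "".join(r.one_letter for r in chain.residues if r.is_standard)
        raise ResidueNotFoundError(f"chain {chain_id!r} not in structure {self.id!r}")


def _validate_coordinate_lines(pdb_text: str) -> None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: coordinate record too short")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: unparseable {what} coordinate field "
                    f"{line[lo:hi]!r}"
                ) from None


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep the highest-occupancy conformer per atom name, ties by altLoc letter."""
    by_name: dict[str, Atom] = {}
    order: list[str] = []
    for atom in atoms:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            order.append(atom.name)
        elif (atom.occupancy, _alt_rank(atom.altloc)) > (
            prev.occupancy, _alt_rank(prev.altloc)
        ):
            by_name[atom.name] = atom
    return [by_name[n] for n in order]


def _alt_rank(altloc: str) -> int:
    # earlier letter wins a tie: higher rank for 'A' than 'B'
    return -ord(altloc) if altloc else 0


def parse_structure(pdb_text: str, structure_id: str = "") -> Structure:
    """Parse fixed-column PDB text into a :class:`Structure`.

    Alternate locations are resolved to a single conformer, heteroatoms
    (HETATM plus nonstandard polymer residues) are stored separately, and
    HELIX/SHEET/SSBOND records that reference residues absent from the model
    are flagged dangling rather than dropped.
    """
    _validate_coordinate_lines(pdb_text)
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0 or sum(len(ch) for ch in st[0]) == 0:
        raise PDBParseError("no atoms in model")
    st.setup_entities()
    model = st[0]

    out = Structure(id=structure_id or st.name.lower())
    for gchain in model:
        chain = Chain(id=gchain.name)
        for gres in gchain:
            atoms = []
            for ga in gres:
                atoms.append(Atom(
                    name=ga.name,
                    element=ga.element.name.upper(),
                    pos=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=ga.occ,
                    altloc=ga.altloc or "",
                    parent_name=gres.name,
                    is_water=gres.name in WATER_NAMES,
                ))
            atoms = _resolve_altlocs(atoms)
            if gres.name in STANDARD_AA3 and gres.het_flag != "H":
                chain.residues.append(Residue(
                    chain_id=gchain.name,
                    number=gres.seqid.num,
                    icode=(gres.seqid.icode or "").strip(),
                    name=gres.name,
                    atoms=atoms,
                ))
            else:
                # waters, ligands and nonstandard residues: heteroatom pool
                out.hetero_atoms.extend(atoms)
        if chain.residues:
            out.chains.append(chain)

    if not out.chains and not out.hetero_atoms:
        raise PDBParseError("no atoms in model")

    for gh in st.helices:
        rec = HelixRecord(
            chain_id=gh.start.chain_name,
            start=gh.start.res_id.seqid.num,
            end=gh.end.res_id.seqid.num,
        )
        rec.dangling = not _span_present(out, rec.chain_id, rec.start, rec.end)
        out.helices.append(rec)
    for gs in st.sheets:
        for strand in gs.strands:
            rec = StrandRecord(
                chain_id=strand.start.chain_name,
                start=strand.start.res_id.seqid.num,
                end=strand.end.res_id.seqid.num,
            )
            rec.dangling = not _span_present(out, rec.chain_id, rec.start, rec.end)
            out.sheets.append(rec)
    for con in st.connections:
        if con.type == gemmi.ConnectionType.Disulf:
            out.ssbonds.append(SSBondRecord(
                a=(con.partner1.chain_name, con.partner1.res_id.seqid.num,
                   (con.partner1.res_id.seqid.icode or "").strip()),
                b=(con.partner2.chain_name, con.partner2.res_id.seqid.num,
                   (con.partner2.res_id.seqid.icode or "").strip()),
            ))
    return out


def _span_present(structure: Structure, chain_id: str, start: int, end: int) -> bool:
    for chain in structure.chains:
        if chain.id == chain_id:
            numbers = {r.number for r in chain.residues}
            return start in numbers and end in numbers
    return False


def helix_location(residue: Residue, structure: Structure) -> HelixLocation:
    """Locate a residue relative to the annotated helices of its structure.

    The first helical residue has position 1; a residue is N-terminal iff its
    position from the helix start is <= ceil(L/2), so each helix is
    partitioned into two halves whose sizes differ by at most one.
    """
    # raise if the residue is not part of the structure
    structure.get_residue(residue.chain_id, residue.number, residue.icode)
    for helix in structure.helices:
        if helix.chain_id != residue.chain_id:
            continue
        if helix.start <= residue.number <= helix.end:
            pos = residue.number - helix.start + 1
            length = helix.length
            region = "N-terminal" if pos <= math.ceil(length / 2) else "C-terminal"
            return HelixLocation(True, pos, region)
    return HelixLocation(False)


def size_filter(structure: Structure, max_residues: int = 1500) -> bool:
    """True iff the asymmetric unit holds fewer than ``max_residues`` standard
    amino acids (the strict < mirrors the published filter)."""
    return structure.n_standard_residues() < max_residues


def write_pdb(structure: Structure) -> str:
    """Canonical fixed-column PDB writer (debug / round-trip use)."""
    lines: list[str] = []
    for i, h in enumerate(structure.helices, start=1):
        lines.append(
            f"HELIX  {i:>3} {i:>3} {'':>3} {h.chain_id:1}{h.start:>5} "
            f" {'':>3} {h.chain_id:1}{h.end:>5} {1:>2}{'':>30} {h.length:>5}"
        )
    for i, s in enumerate(structure.sheets, start=1):
        lines.append(
            f"SHEET  {i:>3} {'S':>3} 1 {'':>3} {s.chain_id:1}{s.start:>4}  "
            f"{'':>3} {s.chain_id:1}{s.end:>4}  0"
        )
    for i, b in enumerate(structure.ssbonds, start=1):
        lines.append(
            f"SSBOND {i:>3} CYS {b.a[0]:1} {b.a[1]:>4}{b.a[2]:>1}   "
            f"CYS {b.b[0]:1} {b.b[1]:>4}{b.b[2]:>1}"
        )
    serial = 1
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                lines.append(_atom_line("ATOM", serial, atom, res.name,
                                        chain.id, res.number, res.icode))
                serial += 1
        lines.append(f"TER   {serial:>5}")
        serial += 1
    for atom in structure.hetero_atoms:
        lines.append(_atom_line("HETATM", serial, atom,
                                atom.parent_name or "LIG", "Z", 1, ""))
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def _atom_line(record: str, serial: int, atom: Atom, resname: str,
               chain_id: str, resnum: int, icode: str) -> str:
    name = atom.name
    # column 13 is reserved for two-letter element symbols
    name_field = f" {name:<3}" if len(name) < 4 and len(atom.element) < 2 else f"{name:<4}"
    x, y, z = atom.pos
    return (
        f"{record:<6}{serial:>5} {name_field}{atom.altloc or ' ':1}{resname:>3} "
        f"{chain_id:1}{resnum:>4}{icode or ' ':1}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
        f"          {atom.element:>2}"
    )
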