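"""Tabular / FASTA input for the sequence analyses.

PTM sites arrive as TSV (accession, species, position, modification_type),
ubiquitinations as TSV (accession, position) in the shape of an mUbiSiDa
export, sequences as FASTA keyed by accession, and structure mappings as a
SIFTS-style TSV (accession, uniprot_position, pdb_id, chain,
pdb_residue_number).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .ptm import ModificationRecord

logger = logging.getLogger(__name__)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def read_mods_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"accession", "species", "position", "modification_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mods table missing columns: {sorted(missing)}")
    return df


def read_ub_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"accession", "position"} <= set(df.columns):
        raise ValueError("ubiquitination table needs accession and position")
    return df


def read_mapping_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"accession", "uniprot_position", "pdb_id", "chain",
                "pdb_residue_number"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mapping table missing columns: {sorted(missing)}")
    return df


def records_from_tables(mods: pd.DataFrame,
                        sequences: dict[str, str],
                        ub: pd.DataFrame | None = None
                        ) -> list[ModificationRecord]:
    """Assemble ModificationRecords from the tabular inputs; accessions
    without a sequence are skipped with a log entry."""
    ub_by_acc: dict[str, list[int]] = {}
    if ub is not None:
        for acc, grp in ub.groupby("accession"):
            ub_by_acc[acc] = sorted(int(p) for p in grp["position"])
    records = []
    skipped = 0
    for acc, grp in mods.groupby("accession"):
        seq = sequences.get(acc)
        if seq is None:
            skipped += 1
            logger.warning("no sequence for accession %s; skipped", acc)
            continue
        sites = sorted({(int(r.position), str(r.modification_type))
                        for r in grp.itertuples()})
        species = str(grp["species"].iloc[0])
        ub_positions = [p for p in ub_by_acc.get(acc, [])
                        if 1 <= p <= len(seq) and seq[p - 1] == "K"]
        records.append(ModificationRecord(
            accession=acc, species=species, sequence=seq,
            modified_cysteines=sites,
            ubiquitinated_lysines=ub_positions,
        ))
    if skipped and skipped > len(records):
        raise ValueError(
            f"{skipped} of {skipped + len(records)} accessions lack sequences "
            "— likely mismatched input files"
        )
    return records


def records_to_tables(records: list[ModificationRecord]
                      ) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Inverse of records_from_tables (used by the synth preset writers)."""
    mod_rows, ub_rows = [], []
    seqs = {}
    for rec in records:
        seqs[rec.accession] = rec.sequence
        for pos, mtype in rec.modified_cysteines:
            mod_rows.append({"accession": rec.accession, "species": rec.species,
                             "position": pos, "modification_type": mtype})
        for pos in rec.ubiquitinated_lysines:
            ub_rows.append({"accession": rec.accession, "position": pos})
    return pd.DataFrame(mod_rows), seqs, pd.DataFrame(ub_rows)


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc, seq in sequences.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
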