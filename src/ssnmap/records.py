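"""Sequence records and plain-text I/O.

The pipeline's atomic datum is a protein sequence with identifiers and
optional provenance labels (subgroup, architecture, taxonomic division,
linker-chain position).  Real inputs arrive as FASTA; synthetic inputs carry
a truth table alongside so downstream stages can be validated against the
planted structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

TRUTH_COLUMNS = [
    "id",
    "subgroup",
    "architecture",
    "has_pro1",
    "replacement",
    "taxon",
    "linker_pos",
]


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence with identifiers and optional truth labels."""

    id: str
    sequence: str
    description: str = ""
    taxon: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if not self.sequence:
            raise ValueError(f"sequence {self.id!r} is empty")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read protein sequences from a FASTA file."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(id=rec.id, sequence=str(rec.seq).upper(),
                           description=rec.description)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records to FASTA (60-column wrap)."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_truth_table(path: str | Path) -> pd.DataFrame:
    """Read a truth-table TSV written by :func:`ssnmap.synth.write_fixture`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"truth table missing columns: {sorted(missing)}")
    df["has_pro1"] = df["has_pro1"].map(
        {"True": True, "False": False, "1": True, "0": False}
    ).astype(bool)
    return df[TRUTH_COLUMNS]


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False, columns=TRUTH_COLUMNS)


def as_mapping(records: Iterable[SequenceRecord]) -> Mapping[str, SequenceRecord]:
    """Index records by id, rejecting duplicates."""
    out: dict[str, SequenceRecord] = {}
    for r in records:
        if r.id in out:
            raise ValueError(f"duplicate sequence id {r.id!r}")
        out[r.id] = r
    return out
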