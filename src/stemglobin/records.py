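"""Protein records and shared flat-file input/output.

FASTA files are read and written through Bio.SeqIO; tab-separated tables
through pandas.  Record ids follow the convention ``<species>|<gene>`` so a
sequence can always be traced back to its proteome of origin.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

_ID_RE = re.compile(r"^(?P<species>[^|]+)\|(?P<gene>.+)$")


class RecordError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    """A protein with its species of origin and provenance tag."""

    id: str
    species: str
    sequence: str
    source: str = "genome"  # genome | transcriptome

    def __post_init__(self) -> None:
        if not self.sequence:
            raise RecordError(f"empty sequence for {self.id!r}")
        seq = self.sequence.upper()
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise RecordError(
                f"{self.id!r}: residues outside the amino-acid alphabet: {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


def qualified_id(species: str, gene: str) -> str:
    return f"{species}|{gene}"


def split_id(record_id: str) -> tuple:
    """Split ``species|gene`` ids; species defaults to '?' when unqualified."""
    m = _ID_RE.match(record_id)
    if m:
        return m.group("species"), m.group("gene")
    return "?", record_id


def read_fasta(path, source: str = "genome") -> List[ProteinRecord]:
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        species, _ = split_id(rec.id)
        if rec.id in seen:
            raise RecordError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(id=rec.id, species=species, sequence=str(rec.seq), source=source)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def records_by_species(records: Sequence[ProteinRecord]) -> Dict[str, List[ProteinRecord]]:
    out: Dict[str, List[ProteinRecord]] = {}
    for rec in records:
        out.setdefault(rec.species, []).append(rec)
    return out


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
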