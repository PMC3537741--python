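"""Sequence records and plain-text format helpers (FASTA / TSV / newick)."""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENOME_LABELS = ("A", "S", "Ss", "Sb", "Ssh", "Sl", "D", "C", "M", "N", "T", "U")

SOURCES = ("cloned", "public", "simulated")


@dataclass(frozen=True)
class NucleotideRecord:
    """One cloned/public/simulated nucleotide sequence with genome metadata."""

    id: str
    genome: str
    residues: str
    source: str = "simulated"

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"record {self.id!r} has empty residues")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        bad = set(self.residues.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"record {self.id!r} has non-nucleotide characters {bad}")

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path, source: str = "cloned") -> list[NucleotideRecord]:
    """Read records from FASTA.

    Record ids of the form ``genome|gene|clone`` carry their genome label in
    the first field; other ids get genome 'other'.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        genome = rec.id.split("|")[0] if "|" in rec.id else "other"
        records.append(
            NucleotideRecord(id=rec.id, genome=genome, residues=str(rec.seq).upper(), source=source)
        )
    seen = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate record id {r.id!r}")
        seen.add(r.id)
    return records


def write_fasta(records: Iterable[NucleotideRecord] | dict[str, str], path: str | Path) -> None:
    if isinstance(records, dict):
        seqrecs = [SeqRecord(Seq(s), id=k, description="") for k, s in records.items()]
    else:
        seqrecs = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(seqrecs, fh, "fasta")


def fasta_string(records: Iterable[NucleotideRecord] | dict[str, str]) -> str:
    buf = _io.StringIO()
    if isinstance(records, dict):
        seqrecs = [SeqRecord(Seq(s), id=k, description="") for k, s in records.items()]
    else:
        seqrecs = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    SeqIO.write(seqrecs, buf, "fasta")
    return buf.getvalue()


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


def tree_from_string(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
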