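"""FASTA/FASTQ input and output (Phred+33), via Biopython."""

from __future__ import annotations

from typing import Iterable, List

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import ReadRecord


def read_fastq(path) -> List[ReadRecord]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            ReadRecord(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=list(rec.letter_annotations["phred_quality"]),
            )
        )
    return reads


def read_fasta(path) -> List[ReadRecord]:
    return [
        ReadRecord(read_id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_reads(path) -> List[ReadRecord]:
    """Sniff FASTA vs FASTQ from the first non-blank character."""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line[0]
                break
        else:
            return []
    if first == "@":
        return read_fastq(path)
    if first == ">":
        return read_fasta(path)
    raise ValueError(f"{path}: neither FASTA nor FASTQ")


def _to_seqrecord(read: ReadRecord) -> SeqRecord:
    rec = SeqRecord(Seq(read.sequence), id=read.read_id, description="")
    if read.qualities is not None:
        rec.letter_annotations["phred_quality"] = list(read.qualities)
    return rec


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    SeqIO.write((_to_seqrecord(r) for r in reads), str(path), "fastq")


def write_fasta(reads: Iterable[ReadRecord], path) -> None:
    SeqIO.write((_to_seqrecord(r) for r in reads), str(path), "fasta")


def write_named_fasta(named: Iterable[tuple], path) -> None:
    """Write (name, sequence) pairs as FASTA."""
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in named),
        str(path),
        "fasta",
    )
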