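"""FASTA and TSV helpers shared by the pipeline stages."""

from __future__ import annotations

from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["read_fasta", "write_fasta", "read_fasta_records", "gene_of"]


def read_fasta(path) -> dict[str, str]:
    """id -> uppercase sequence, preserving file order (dict is ordered)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def read_fasta_records(path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(seqs: Mapping[str, str] | Iterable[tuple[str, str]], path,
                descriptions: Mapping[str, str] | None = None) -> None:
    items = seqs.items() if isinstance(seqs, Mapping) else seqs
    records = []
    for sid, seq in items:
        desc = descriptions.get(sid, "") if descriptions else ""
        records.append(SeqRecord(Seq(seq), id=sid, description=desc))
    SeqIO.write(records, str(path), "fasta")


def gene_of(transcript_id: str) -> str:
    """Gene id of an isoform-style identifier (``AT1G01010.2`` -> ``AT1G01010``).

    Identifiers without a ``.`` isoform suffix are their own gene id.
    """
    return transcript_id.rsplit(".", 1)[0]
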