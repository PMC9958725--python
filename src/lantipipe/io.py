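"""FASTA and tabular I/O helpers (thin wrappers over Biopython/pandas)."""

from __future__ import annotations

import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .variants import PeptideRecord


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> ordered {id: upper-case sequence} mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: dict[str, str], path, *, descriptions=None) -> None:
    """Write {id: sequence} as FASTA (60-column wrapping, sorted ids off)."""
    descriptions = descriptions or {}
    records = [
        SeqRecord(Seq(s), id=name, description=descriptions.get(name, ""))
        for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_peptides(path) -> list[PeptideRecord]:
    """Read peptides from FASTA; the description carries the variant name."""
    peptides = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id):].strip()
        peptides.append(PeptideRecord(
            id=rec.id, core_seq=str(rec.seq).upper(), variant_name=desc,
        ))
    if not peptides:
        raise ValueError(f"no sequences in {path}")
    return peptides


def write_peptides(peptides, path) -> None:
    write_fasta(
        {p.id: p.core_seq for p in peptides},
        path,
        descriptions={p.id: p.variant_name for p in peptides},
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, ensure_ascii=False) + "\n")
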