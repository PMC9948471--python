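"""Sequence records and light FASTA/FASTQ I/O.

The in-memory unit throughout the package is :class:`SeqRecord` — a named
nucleotide (or peptide) string with an optional circularity flag and a free-form
metadata dict used to carry simulation truth (source genome, marker position,
...). File I/O goes through Biopython's ``SeqIO``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn",
                            "TGCAYRMKVBHDNtgcayrmkvbhdn")


@dataclass
class SeqRecord:
    """A named sequence with optional circularity flag and truth metadata."""

    id: str
    seq: str
    circular: bool = False
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SeqRecord":
        return SeqRecord(self.id, reverse_complement(self.seq),
                         circular=self.circular, meta=dict(self.meta))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """GC over unambiguous (A/C/G/T) bases only; 0.0 if none."""
    up = seq.upper()
    gc = up.count("G") + up.count("C")
    at = up.count("A") + up.count("T")
    return gc / (gc + at) if gc + at else 0.0


def read_fasta(path: str | Path) -> list[SeqRecord]:
    recs = []
    for r in SeqIO.parse(str(path), "fasta"):
        circular = "circular=true" in r.description.lower()
        recs.append(SeqRecord(r.id, str(r.seq).upper(), circular=circular))
    return recs


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = " circular=true" if rec.circular else ""
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def read_fastq(path: str | Path) -> list[SeqRecord]:
    return [SeqRecord(r.id, str(r.seq).upper())
            for r in SeqIO.parse(str(path), "fastq")]


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    # flat quality: the simulator does not model per-base qualities
    bio = (BioSeqRecord(Seq(r.seq), id=r.id, description="",
                        letter_annotations={"phred_quality": [40] * len(r.seq)})
           for r in records)
    SeqIO.write(bio, str(path), "fastq")
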