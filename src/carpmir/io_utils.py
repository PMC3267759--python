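"""I/O helpers: FASTA/FASTQ via Biopython and the DNA/RNA alphabet boundary.

On disk everything is DNA (T); in memory, post-parsing, small-RNA sequences
are RNA (U).  The conversion happens here and only here.
"""

from __future__ import annotations

from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_RC = str.maketrans("ACGTN", "TGCAN")
_RC_RNA = str.maketrans("ACGUN", "UGCAN")


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp_dna(seq: str) -> str:
    return seq.upper().translate(_RC)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.upper().translate(_RC_RNA)[::-1]


def read_fasta(path) -> dict[str, str]:
    """FASTA -> {id: uppercase DNA sequence} (order-preserving)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    """Write (id-or-header, DNA sequence) pairs; header may contain spaces."""
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n{seq}\n")


def read_fastq(path) -> Iterator[tuple[str, str, list[int]]]:
    """Yield (id, DNA sequence, Phred scores) per record.

    Malformed records fail with the record index in the message.
    """
    idx = 0
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]
            idx += 1
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ at record {idx}: {exc}") from exc


def write_fastq(path, records: Iterable[tuple[str, str, str]]) -> None:
    """Write (id, DNA sequence, quality string) triples as Sanger FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def parse_ncrna_fasta(path) -> list[tuple[str, str, str]]:
    """Parse a reference FASTA whose headers carry ``class=<cls>`` tags.

    Returns (id, class, RNA sequence) triples.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        cls = None
        for token in rec.description.split():
            if token.startswith("class="):
                cls = token.split("=", 1)[1]
        if cls is None:
            raise ValueError(f"record {rec.id} lacks a class= header tag")
        out.append((rec.id, cls, dna_to_rna(str(rec.seq))))
    return out
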