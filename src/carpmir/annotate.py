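"""ncRNA annotation of unique reads and exact-match genome mapping.

Annotation is exact sense-strand substring search against a small
rRNA/tRNA/snRNA/snoRNA reference (at 18-30 nt read length no alignment
heuristics are needed); annotated reads are excluded from all downstream
miRNA analysis.  Mapping is exact, full-length, zero-mismatch placement on
both genome strands through a k-mer index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings
from typing import Optional, Sequence

from .io_utils import dna_to_rna, revcomp_rna
from .preprocess import Annotation, UniqueRead

#: multi-hit annotation priority
NCRNA_PRIORITY = ("rRNA", "tRNA", "snRNA", "snoRNA")

_CLASS_TO_ANNOTATION = {
    "rRNA": Annotation.RRNA,
    "tRNA": Annotation.TRNA,
    "snRNA": Annotation.SNRNA,
    "snoRNA": Annotation.SNORNA,
}


@dataclass
class NcRNAReference:
    """(id, class, RNA sequence) records, classes limited to four kinds."""

    records: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        for rid, cls, seq in self.records:
            if cls not in NCRNA_PRIORITY:
                raise ValueError(f"record {rid}: unknown ncRNA class {cls!r}")
            if not seq:
                raise ValueError(f"record {rid}: empty sequence")

    def by_class(self, cls: str) -> list[str]:
        return [seq for _rid, c, seq in self.records if c == cls]


def annotate_ncrna(
    reads: Sequence[UniqueRead], ref: NcRNAReference
) -> tuple[list[UniqueRead], list[UniqueRead]]:
    """Partition reads into (annotated, remaining).

    A read is annotated iff it is an exact sense-strand substring of a
    reference record; when several classes hit, rRNA > tRNA > snRNA >
    snoRNA.  The two returned lists partition the input.
    """
    if not ref.records:
        warnings.warn("empty ncRNA reference: no reads can be annotated")
    per_class = {cls: ref.by_class(cls) for cls in NCRNA_PRIORITY}
    annotated, remaining = [], []
    for read in reads:
        hit = None
        for cls in NCRNA_PRIORITY:
            if any(read.sequence in seq for seq in per_class[cls]):
                hit = cls
                break
        if hit is not None:
            read.annotation = _CLASS_TO_ANNOTATION[hit]
            annotated.append(read)
        else:
            remaining.append(read)
    return annotated, remaining


@dataclass
class GenomeIndex:
    """k-mer index over a genome (RNA alphabet internally), both strands."""

    k: int
    contigs: dict[str, str]  # RNA
    table: dict[str, list[tuple[str, int]]] = field(repr=False, default_factory=dict)


def build_index(genome: dict[str, str], k: int = 12) -> GenomeIndex:
    """Index every forward-strand k-mer of the genome.

    Minus-strand placement is resolved at query time by looking up the
    reverse complement of the read, so one forward table serves both
    strands.  Contigs shorter than k are skipped with a warning.
    """
    if k < 4:
        raise ValueError("k must be >= 4")
    contigs = {name: dna_to_rna(seq) for name, seq in genome.items()}
    table: dict[str, list[tuple[str, int]]] = {}
    for name, seq in contigs.items():
        if len(seq) < k:
            warnings.warn(f"contig {name} shorter than k={k}, skipped")
            continue
        for i in range(len(seq) - k + 1):
            table.setdefault(seq[i : i + k], []).append((name, i))
    return GenomeIndex(k=k, contigs=contigs, table=table)


@dataclass
class MappingResult:
    """Per-read exact placements; every locus is substring-verified."""

    loci: dict[str, list[tuple[str, int, str]]]  # read sequence -> placements
    multi_mapped: set[str] = field(default_factory=set)

    def mapped(self, sequence: str) -> bool:
        return bool(self.loci.get(sequence))


def map_reads(
    reads: Sequence[UniqueRead], index: GenomeIndex, max_loci: int = 20
) -> MappingResult:
    """Exact, full-length, zero-mismatch mapping of reads to the genome.

    All loci are reported up to ``max_loci``; reads exceeding the cap are
    flagged multi-mapped (and keep their first ``max_loci`` placements).
    Minus-strand hits are reported at the + strand coordinate of the match
    window.  Each read's ``mapped_loci`` is updated in place.
    """
    result = MappingResult(loci={})
    for read in reads:
        seq = read.sequence
        if len(seq) < index.k:
            read.mapped_loci = []
            result.loci[seq] = []
            continue
        hits: list[tuple[str, int, str]] = []
        for query, strand in ((seq, "+"), (revcomp_rna(seq), "-")):
            for contig, pos in index.table.get(query[: index.k], ()):
                if index.contigs[contig][pos : pos + len(query)] == query:
                    hits.append((contig, pos, strand))
        hits = sorted(set(hits))
        if len(hits) > max_loci:
            result.multi_mapped.add(seq)
            hits = hits[:max_loci]
        read.mapped_loci = hits
        result.loci[seq] = hits
    return result
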