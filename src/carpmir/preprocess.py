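"""Raw-read cleaning, collapsing to unique sequences, and length distribution.

The cleaning cascade mirrors a standard small-RNA-seq primary analysis:
discard poor-quality reads, 5' adapter pollution, reads without a 3'
adapter, empty inserts, poly(A) artefacts and sub-18 nt inserts, in that
fixed order, so that every raw read is accounted for by exactly one
discard reason or survives as an insert.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from .io_utils import dna_to_rna


class Annotation(str, Enum):
    UNANNOTATED = "unannotated"
    RRNA = "rRNA"
    TRNA = "tRNA"
    SNRNA = "snRNA"
    SNORNA = "snoRNA"
    KNOWN_MIRNA = "known_miRNA"
    NOVEL_MIRNA = "novel_miRNA"


#: cleaning discard reasons, in cascade order
DISCARD_REASONS = (
    "low_quality",
    "adapter5_pollution",
    "no_3p_adapter",
    "no_insert",
    "polyA",
    "too_short",
)


@dataclass
class CleanParams:
    """Thresholds of the cleaning cascade (none are dictated by the assay)."""

    min_mean_quality: float = 20.0
    adapter5_min_prefix: int = 10
    adapter3_min_overlap: int = 8
    adapter3_max_mismatch_frac: float = 0.10
    polya_min_fraction: float = 0.80
    polya_min_run: int = 10
    min_insert_len: int = 18
    max_insert_len: int = 30


@dataclass
class CleaningReport:
    discards: dict[str, int] = field(default_factory=lambda: {r: 0 for r in DISCARD_REASONS})
    clean_read_total: int = 0

    @property
    def raw_total(self) -> int:
        return self.clean_read_total + sum(self.discards.values())


@dataclass
class UniqueRead:
    """A distinct insert sequence (RNA alphabet) with its aggregated count."""

    sequence: str
    count: int
    annotation: Annotation = Annotation.UNANNOTATED
    mapped_loci: list[tuple[str, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")


def find_3p_adapter(read: str, adapter: str, params: CleanParams) -> Optional[int]:
    """Locate the 3' adapter in a read by best ungapped match.

    Considers every start position with at least ``adapter3_min_overlap``
    aligned bases and at most ``adapter3_max_mismatch_frac`` mismatches.
    Best = fewest mismatches, then longest overlap, then leftmost.
    Returns the adapter start (= insert length) or None.
    """
    n, m = len(read), len(adapter)
    best: Optional[tuple[int, int, int]] = None  # (mismatches, -overlap, pos)
    for pos in range(0, n - params.adapter3_min_overlap + 1):
        overlap = min(m, n - pos)
        if overlap < params.adapter3_min_overlap:
            break
        limit = int(params.adapter3_max_mismatch_frac * overlap)
        mism = 0
        for a, b in zip(read[pos : pos + overlap], adapter):
            if a != b:
                mism += 1
                if mism > limit:
                    break
        else:
            key = (mism, -overlap, pos)
            if best is None or key < best:
                best = key
    return best[2] if best else None


def classify_read(
    seq: str,
    quality: Sequence[int],
    adapter_3p: str,
    adapter_5p: str,
    params: CleanParams,
) -> tuple[Optional[str], Optional[str]]:
    """Run one read through the cascade.

    Returns ``(insert, None)`` for a kept read or ``(None, reason)`` for a
    discard.  Sequences are DNA here; the RNA conversion happens when
    inserts are collapsed.
    """
    if len(seq) != len(quality):
        raise ValueError("sequence and quality length differ")
    if sum(quality) / max(len(quality), 1) < params.min_mean_quality:
        return None, "low_quality"
    k = params.adapter5_min_prefix
    if len(adapter_5p) >= k and seq.startswith(adapter_5p[:k]):
        return None, "adapter5_pollution"
    pos = find_3p_adapter(seq, adapter_3p, params)
    if pos is None:
        return None, "no_3p_adapter"
    insert = seq[:pos]
    if not insert:
        return None, "no_insert"
    a_frac = insert.count("A") / len(insert)
    if a_frac >= params.polya_min_fraction or "A" * params.polya_min_run in insert:
        return None, "polyA"
    if len(insert) < params.min_insert_len:
        return None, "too_short"
    # inserts longer than the gel-purification window are kept, truncated
    return insert[: params.max_insert_len], None


def clean_reads(
    raw: Iterable[tuple[str, str, Sequence[int]]],
    adapter_3p: str,
    adapter_5p: str,
    params: Optional[CleanParams] = None,
) -> tuple[list[str], CleaningReport]:
    """Apply the cleaning cascade to a stream of (id, sequence, phred) reads.

    Returns the surviving insert sequences (DNA) and a
    :class:`CleaningReport` whose discard counts plus the clean total equal
    the raw read total.
    """
    if not adapter_3p or not adapter_5p:
        raise ValueError("adapters must be non-empty")
    params = params or CleanParams()
    report = CleaningReport()
    inserts: list[str] = []
    for _rid, seq, qual in raw:
        insert, reason = classify_read(seq.upper(), qual, adapter_3p, adapter_5p, params)
        if reason is not None:
            report.discards[reason] += 1
        else:
            inserts.append(insert)
            report.clean_read_total += 1
    return inserts, report


def collapse(inserts: Iterable[str]) -> list[UniqueRead]:
    """Collapse clean inserts to unique sequences with counts.

    Output is RNA alphabet, sorted by descending count with lexicographic
    tie-breaking, so collapsed output is a pure function of the multiset of
    inputs (order-independent) and idempotent.
    """
    tally = Counter(dna_to_rna(s) for s in inserts)
    return [
        UniqueRead(sequence=s, count=c)
        for s, c in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def length_distribution(reads: Sequence[UniqueRead]) -> dict[int, tuple[int, int, float]]:
    """Per-length (unique_count, read_count, read_fraction), count-weighted.

    Fractions are weighted by read count, not by unique sequences, and sum
    to 1 over all lengths.
    """
    uniq: Counter = Counter()
    tot: Counter = Counter()
    for r in reads:
        uniq[len(r.sequence)] += 1
        tot[len(r.sequence)] += r.count
    grand = sum(tot.values())
    return {
        ln: (uniq[ln], tot[ln], tot[ln] / grand if grand else 0.0)
        for ln in sorted(tot)
    }
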