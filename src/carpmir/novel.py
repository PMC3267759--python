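"""Novel miRNA prediction from genome-mapped, unannotated reads.

For each candidate read locus two genomic windows are folded (read on the
5' arm with a long 3' flank, and the mirror arrangement).  The stem-loop
containing the read is excised from the window fold, refolded on its own,
and put through pre-miRNA criteria: single stem-loop topology, folding
energy, mature placement on one arm, Dicer-site plausibility, precursor
length and read support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .fold import ENERGY_PARAMS, SecondaryStructure, fold_mfe
from .io_utils import dna_to_rna, revcomp_dna
from .preprocess import UniqueRead


@dataclass
class HairpinParams:
    """Pre-miRNA acceptance thresholds (Mireap-style defaults)."""

    e_max: float = -18.0  # kcal/mol
    min_mature_paired: int = 14
    max_bulge_asym: int = 4
    dicer_slippage: int = 2
    precursor_min: int = 55
    precursor_max: int = 120
    mature_min: int = 18
    mature_max: int = 23
    min_count: int = 5
    window_short: int = 20
    window_long: int = 120


@dataclass
class HairpinCandidate:
    """A candidate precursor with its fold and the mature read placed in it."""

    sequence: str  # RNA, the candidate precursor
    structure: SecondaryStructure
    mature_start: int  # 0-based, within sequence
    mature_end: int  # half-open
    count: int = 0
    locus: Optional[tuple[str, int, int, str]] = None
    criteria: dict[str, bool] = field(default_factory=dict)

    @property
    def verdict(self) -> bool:
        return bool(self.criteria) and all(self.criteria.values())

    @property
    def mature_sequence(self) -> str:
        return self.sequence[self.mature_start : self.mature_end]


@dataclass
class NovelMiRNA:
    name: str
    mature_sequence: str
    count: int
    precursor_sequence: str
    precursor_locus: tuple[str, int, int, str]
    arm: str  # "5p" | "3p"
    structure: str
    energy: float


def _stem_outer_pair(
    pairs: dict[int, int], loop_pair: tuple[int, int], max_loop: int
) -> tuple[int, int]:
    """Walk outward from a hairpin-loop closing pair through its stem.

    Follows stacked pairs and internal/bulge loops of at most ``max_loop``
    unpaired bases; stops at a multiloop branch point or the exterior.
    Returns the outermost pair of the stem.
    """
    a, b = loop_pair
    while True:
        a2 = a - 1
        while a2 >= 0 and a2 not in pairs:
            a2 -= 1
        if a2 < 0:
            break
        b2 = pairs[a2]
        if b2 <= b:  # sibling helix, not an enclosing pair
            break
        if any(k in pairs for k in range(b + 1, b2)):
            break  # enclosing loop is a multiloop
        if (a - a2 - 1) + (b2 - b - 1) > max_loop:
            break
        a, b = a2, b2
    return a, b


def passes_criteria(candidate: HairpinCandidate, params: Optional[HairpinParams] = None) -> dict[str, bool]:
    """Evaluate the six pre-miRNA rules, each reported independently.

    The candidate must already carry a folded structure.  Updates and
    returns ``candidate.criteria``.
    """
    params = params or HairpinParams()
    ss = candidate.structure
    if ss is None:
        raise ValueError("candidate has not been folded")
    pairs = ss.pairs
    n = len(candidate.sequence)
    ms, me = candidate.mature_start, candidate.mature_end
    loops = ss.hairpin_loops()

    rules: dict[str, bool] = {}
    rules["single_stem"] = len(loops) == 1
    rules["energy"] = ss.energy <= params.e_max

    on_arm = False
    arm_ok = False
    if len(loops) == 1:
        li, lj = loops[0]  # closing pair; unpaired loop is li+1 .. lj-1
        on_5p = me - 1 <= li
        on_3p = ms >= lj
        on_arm = on_5p or on_3p
    paired_in_mature = sum(1 for k in range(ms, me) if k in pairs)
    bulge_ok = True
    closing = sorted((i, j) for i, j in pairs.items() if i < j)
    for i, j in closing:
        children = []
        k = i + 1
        while k < j:
            if k in pairs and pairs[k] > k:
                children.append((k, pairs[k]))
                k = pairs[k] + 1
            else:
                k += 1
        if len(children) == 1:
            (a, b) = children[0]
            l1, l2 = a - i - 1, j - b - 1
            if l1 + l2 == 0:
                continue
            side5 = range(i + 1, a)
            side3 = range(b + 1, j)
            touches = any(ms <= k < me for k in side5) or any(ms <= k < me for k in side3)
            if touches and abs(l1 - l2) > params.max_bulge_asym:
                bulge_ok = False
    rules["mature_in_stem"] = (
        on_arm and paired_in_mature >= params.min_mature_paired and bulge_ok
    )
    # Dicer-site plausibility: the mature 5' end must be anchored in the
    # stem (paired, or within a small slippage of a paired base), the
    # geometry that leaves the characteristic 2 nt 3' overhang on the duplex.
    rules["dicer_site"] = any(
        ms + d in pairs for d in range(0, params.dicer_slippage + 1)
    )
    rules["precursor_length"] = params.precursor_min <= n <= params.precursor_max
    rules["mature_support"] = (
        params.mature_min <= me - ms <= params.mature_max
        and candidate.count >= params.min_count
    )
    candidate.criteria = rules
    return rules


def excise_hairpin(
    window_seq: str, mature_start: int, mature_end: int
) -> Optional[tuple[int, int]]:
    """Fold a window and excise the stem-loop span harbouring the mature.

    Returns the (start, end) half-open span of the excised precursor within
    the window, or None if the mature does not sit on a hairpin stem.
    """
    ss = fold_mfe(window_seq)
    pairs = ss.pairs
    max_loop = ENERGY_PARAMS["max_loop"]
    best: Optional[tuple[int, int]] = None
    for li, lj in ss.hairpin_loops():
        oa, ob = _stem_outer_pair(pairs, (li, lj), max_loop)
        if oa <= mature_start and mature_end - 1 <= ob:
            span = (oa, ob + 1)
            if best is None or (span[1] - span[0]) > (best[1] - best[0]):
                best = span
    return best


def evaluate_precursor(
    precursor_rna: str,
    mature_start: int,
    mature_end: int,
    count: int = 0,
    params: Optional[HairpinParams] = None,
    locus: Optional[tuple[str, int, int, str]] = None,
) -> HairpinCandidate:
    """Fold a putative precursor and score it against the pre-miRNA rules."""
    ss = fold_mfe(precursor_rna)
    cand = HairpinCandidate(
        sequence=precursor_rna,
        structure=ss,
        mature_start=mature_start,
        mature_end=mature_end,
        count=count,
        locus=locus,
    )
    passes_criteria(cand, params)
    return cand


def _window_sequence(
    genome: dict[str, str],
    contig: str,
    start: int,
    end: int,
    strand: str,
    up: int,
    down: int,
) -> tuple[str, int, int]:
    """Genomic window around a read locus, in read orientation (RNA).

    Returns (window RNA, mature offset, window genomic start on + strand).
    """
    seq = genome[contig]
    if strand == "+":
        ws = max(0, start - up)
        we = min(len(seq), end + down)
        window = seq[ws:we]
        return dna_to_rna(window), start - ws, ws
    ws = max(0, start - down)
    we = min(len(seq), end + up)
    window = revcomp_dna(seq[ws:we])
    return dna_to_rna(window), we - end, ws


def predict_novel(
    reads: Sequence[UniqueRead],
    genome: dict[str, str],
    params: Optional[HairpinParams] = None,
) -> list[NovelMiRNA]:
    """Predict novel miRNAs from unannotated, catalog-unmatched, mapped reads.

    Reads whose genomic windows overlap are merged into one candidate
    precursor whose mature is the highest-count member.  For each merged
    locus two windows are folded (short 5' / long 3' flank and the mirror);
    the locus yields a novel miRNA iff at least one excised stem-loop
    passes all criteria.  Names ``CM1-mNNNN_5p|_3p`` are assigned in
    descending count order.
    """
    params = params or HairpinParams()
    genome = {k: v.upper() for k, v in genome.items()}
    ext = params.window_long

    # group mapped loci by (contig, strand), merge overlapping windows
    by_strand: dict[tuple[str, str], list[tuple[int, int, UniqueRead]]] = {}
    for r in reads:
        for contig, start, strand in r.mapped_loci:
            by_strand.setdefault((contig, strand), []).append(
                (start, start + len(r.sequence), r)
            )
    accepted: list[tuple[UniqueRead, HairpinCandidate, str]] = []
    seen_matures: set[str] = set()
    for (contig, strand), items in sorted(by_strand.items()):
        items.sort(key=lambda t: (t[0], t[1], t[2].sequence))
        clusters: list[list[tuple[int, int, UniqueRead]]] = []
        cur_end = None
        for s, e, r in items:
            if cur_end is not None and s - ext <= cur_end + ext:
                clusters[-1].append((s, e, r))
                cur_end = max(cur_end, e)
            else:
                clusters.append([(s, e, r)])
                cur_end = e
        for cluster in clusters:
            s, e, top = max(cluster, key=lambda t: (t[2].count, t[2].sequence[::-1]))
            if top.sequence in seen_matures:
                continue
            cand = _evaluate_locus(genome, contig, s, e, strand, top, params)
            if cand is not None:
                seen_matures.add(top.sequence)
                arm = _mature_arm(cand)
                accepted.append((top, cand, arm))

    accepted.sort(key=lambda t: (-t[0].count, t[0].sequence))
    out = []
    for idx, (read, cand, arm) in enumerate(accepted, start=1):
        out.append(
            NovelMiRNA(
                name=f"CM1-m{idx:04d}_{arm}",
                mature_sequence=read.sequence,
                count=read.count,
                precursor_sequence=cand.sequence,
                precursor_locus=cand.locus,
                arm=arm,
                structure=cand.structure.pairing,
                energy=cand.structure.energy,
            )
        )
    return out


def _mature_arm(cand: HairpinCandidate) -> str:
    loops = cand.structure.hairpin_loops()
    if loops and cand.mature_start >= loops[0][1]:
        return "3p"
    return "5p"


def _evaluate_locus(
    genome: dict[str, str],
    contig: str,
    start: int,
    end: int,
    strand: str,
    read: UniqueRead,
    params: HairpinParams,
) -> Optional[HairpinCandidate]:
    for up, down in ((params.window_short, params.window_long), (params.window_long, params.window_short)):
        window, moff, wstart = _window_sequence(genome, contig, start, end, strand, up, down)
        mlen = end - start
        if len(window) < mlen + 10:
            continue
        span = excise_hairpin(window, moff, moff + mlen)
        if span is None:
            continue
        ps, pe = span
        if not (ps <= moff and moff + mlen <= pe):
            continue
        prec = window[ps:pe]
        if len(prec) < 10:
            continue
        if strand == "+":
            locus = (contig, wstart + ps, wstart + pe, strand)
        else:
            wlen = len(window)
            locus = (contig, wstart + (wlen - pe), wstart + (wlen - ps), strand)
        cand = evaluate_precursor(
            prec, moff - ps, moff - ps + mlen, count=read.count, params=params, locus=locus
        )
        if cand.verdict:
            return cand
    return None
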