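"""Conserved miRNA identification, isomiR clustering and conservation analysis.

Reads of 18-23 nt are matched against a catalog of known mature miRNAs
(end trims/extensions of up to 5 nt total, at most 2 internal
substitutions, identical seed).  Matched reads are clustered into isomiR
categories by single linkage; the highest-count member represents each
category.  Categories are then partitioned by the set of species whose
catalogs contain the miRNA: conserved across vertebrate models, restricted
to teleosts, shared with invertebrates, or apparently species-specific.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .preprocess import UniqueRead

SEED_START, SEED_END = 1, 8  # 0-based slice of positions 2-8


def extract_seed(sequence: str) -> str:
    """Seed sequence: nucleotides 2-8 (1-based) of a mature miRNA."""
    if len(sequence) < 8:
        raise ValueError(f"sequence of length {len(sequence)} has no seed (need >= 8)")
    return sequence[SEED_START:SEED_END]


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    species: str
    sequence: str  # RNA


@dataclass
class MatureCatalog:
    """Known mature miRNAs with species codes; (name, species) pairs unique."""

    entries: list[CatalogEntry]

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            key = (e.name, e.species)
            if key in seen:
                raise ValueError(f"duplicate catalog entry {key}")
            seen.add(key)

    @classmethod
    def from_tsv(cls, path) -> "MatureCatalog":
        entries = []
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                name, species, seq = line.rstrip("\n").split("\t")[:3]
                entries.append(CatalogEntry(name, species, seq.upper().replace("T", "U")))
        return cls(entries)

    @classmethod
    def from_mirbase_fasta(cls, path) -> "MatureCatalog":
        """miRBase mature.fa dialect: ``>cca-miR-1 ...`` headers, U alphabet."""
        from Bio import SeqIO

        entries = []
        for rec in SeqIO.parse(str(path), "fasta"):
            species = rec.id.split("-", 1)[0]
            entries.append(
                CatalogEntry(rec.id, species, str(rec.seq).upper().replace("T", "U"))
            )
        return cls(entries)


def _end_alignment_edits(
    a: str, b: str, max_end: int, max_subs: int
) -> Optional[int]:
    """Fewest edits turning b into a by end trims/extensions + substitutions.

    An alignment is an ungapped overlay of a on b with 5' shift d5 and 3'
    shift d3; its cost is |d5| + |d3| + substitutions in the overlap.
    Returns the minimum cost over alignments with |d5|+|d3| <= max_end and
    substitutions <= max_subs, or None.
    """
    la, lb = len(a), len(b)
    best: Optional[int] = None
    for d5 in range(-max_end, max_end + 1):
        d3 = la - lb - d5  # a = d5 bases added at 5' + b + d3 bases at 3'
        if abs(d5) + abs(d3) > max_end:
            continue
        # overlap in a coordinates
        start = max(0, d5)
        end = min(la, lb + d5)
        if end - start < 1:
            continue
        subs = sum(1 for i in range(start, end) if a[i] != b[i - d5])
        if subs > max_subs:
            continue
        cost = abs(d5) + abs(d3) + subs
        if best is None or cost < best:
            best = cost
    return best


def match_known(
    reads: Sequence[UniqueRead],
    catalog: MatureCatalog,
    max_end_edits: int = 5,
    max_substitutions: int = 2,
) -> tuple[list[tuple[UniqueRead, CatalogEntry, int]], list[UniqueRead]]:
    """Match 18-23 nt reads against the catalog of known matures.

    A read matches an entry iff one is obtainable from the other by
    trimming/extending the ends by at most ``max_end_edits`` nt total with
    at most ``max_substitutions`` internal substitutions, and the two seeds
    (positions 2-8) are identical.  Best match = fewest edits, ties broken
    by catalog order.  Returns (matches, unmatched).
    """
    matches, unmatched = [], []
    by_seed: dict[str, list[tuple[int, CatalogEntry]]] = {}
    for order, e in enumerate(catalog.entries):
        if len(e.sequence) >= 8:
            by_seed.setdefault(extract_seed(e.sequence), []).append((order, e))
    for read in reads:
        best: Optional[tuple[int, int, CatalogEntry]] = None
        for order, entry in by_seed.get(extract_seed(read.sequence), ()):
            cost = _end_alignment_edits(
                read.sequence, entry.sequence, max_end_edits, max_substitutions
            )
            if cost is None:
                continue
            key = (cost, order)
            if best is None or key < (best[0], best[1]):
                best = (cost, order, entry)
        if best is None:
            unmatched.append(read)
        else:
            matches.append((read, best[2], best[0]))
    return matches, unmatched


@dataclass
class MiRNACategory:
    """An isomiR cluster with its highest-count representative."""

    members: list[UniqueRead]
    representative: UniqueRead
    assigned_name: str
    seed: str

    @property
    def read_total(self) -> int:
        return sum(m.count for m in self.members)


def category_compatible(
    a: str, b: str, max_len_diff: int = 5, max_mismatch: int = 1
) -> bool:
    """IsomiR compatibility: identical seed and an end-trim/extension
    relationship of at most ``max_len_diff`` nt with at most
    ``max_mismatch`` internal mismatches."""
    if extract_seed(a) != extract_seed(b):
        return False
    cost = _end_alignment_edits(a, b, max_len_diff, max_mismatch)
    return cost is not None


def cluster_categories(
    candidates: Sequence[tuple[UniqueRead, "CatalogEntry", int]],
) -> list[MiRNACategory]:
    """Single-linkage clustering of catalog-matched reads into categories.

    The representative is the member with the highest count (ties broken by
    lexicographically smallest sequence); the category is named after its
    representative's catalog entry.  Output order: descending total reads,
    then representative sequence, independent of input order.
    """
    items = sorted(
        candidates, key=lambda t: (t[0].sequence, t[1].name)
    )  # canonical order for permutation invariance
    n = len(items)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if category_compatible(items[i][0].sequence, items[j][0].sequence):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    categories = []
    for idxs in groups.values():
        members = [items[i][0] for i in idxs]
        rep_i = min(idxs, key=lambda i: (-items[i][0].count, items[i][0].sequence))
        rep, entry = items[rep_i][0], items[rep_i][1]
        categories.append(
            MiRNACategory(
                members=sorted(members, key=lambda m: (-m.count, m.sequence)),
                representative=rep,
                assigned_name=entry.name,
                seed=extract_seed(rep.sequence),
            )
        )
    categories.sort(key=lambda c: (-c.read_total, c.representative.sequence))
    return categories


# -- cross-species conservation ------------------------------------------------

#: species groups used for conservation classes
SPECIES_GROUPS = {
    "vertebrate_models": {"xtr", "dre", "gga", "mmu", "hsa"},
    "teleosts": {"dre", "ola", "fru", "tni", "hno", "hmo"},
    "invertebrates": {"cel", "dme"},
    "mammals": {"mmu", "hsa", "rno"},
}

KNOWN_SPECIES = frozenset(
    {"cca", "dre", "ola", "fru", "tni", "hno", "hmo", "xtr", "gga", "mmu", "hsa", "rno", "cel", "dme"}
)

CONSERVATION_CLASSES = (
    "pan_bilaterian",
    "vertebrate_conserved",
    "teleost_only",
    "carp_specific",
    "partially_conserved",
)


@dataclass
class ConservationProfile:
    mirna_name: str
    present_in: set[str]
    conservation_class: str


def classify_conservation(
    present_in: Iterable[str], groups: Optional[dict[str, set[str]]] = None
) -> str:
    """Conservation class from the set of species carrying the mature.

    Precedence: pan_bilaterian (an invertebrate and a mammal) >
    vertebrate_conserved (all five vertebrate models) > teleost_only
    (non-empty subset of teleosts) > carp_specific (empty) >
    partially_conserved (anything else).
    """
    groups = groups or SPECIES_GROUPS
    present = set(present_in)
    for sp in present:
        if sp not in KNOWN_SPECIES:
            raise ValueError(f"unknown species code {sp!r}")
    if present & groups["invertebrates"] and present & groups["mammals"]:
        return "pan_bilaterian"
    if groups["vertebrate_models"] <= present:
        return "vertebrate_conserved"
    if present and present <= groups["teleosts"]:
        return "teleost_only"
    if not present:
        return "carp_specific"
    return "partially_conserved"


_SPECIES_PREFIX = re.compile(r"^[a-z]{3}-")


def normalize_name(name: str, strip_arm: bool = False) -> str:
    """Normalize a miRNA name: strip the species prefix, case-fold and,
    optionally, drop a -5p/-3p arm suffix."""
    base = _SPECIES_PREFIX.sub("", name.strip()).lower()
    if strip_arm:
        base = re.sub(r"-[35]p$", "", base)
    return base


def conservation_partition(
    categories: Sequence[MiRNACategory],
    catalog: MatureCatalog,
    self_species: str = "cca",
    groups: Optional[dict[str, set[str]]] = None,
) -> list[ConservationProfile]:
    """Per-category conservation profile from catalog species presence.

    A species carries the miRNA iff the catalog holds an entry of that
    species whose normalized name equals the category's normalized name.
    The analysed species itself is excluded from the presence set.
    """
    by_name: dict[str, set[str]] = {}
    for e in catalog.entries:
        by_name.setdefault(normalize_name(e.name), set()).add(e.species)
    out = []
    for cat in categories:
        base = normalize_name(cat.assigned_name)
        present = {sp for sp in by_name.get(base, set()) if sp != self_species}
        out.append(
            ConservationProfile(
                mirna_name=cat.assigned_name,
                present_in=present,
                conservation_class=classify_conservation(present, groups),
            )
        )
    return out


def compare_external_set(
    categories: Sequence[MiRNACategory],
    other_species_names: Iterable[str],
    strip_arm: bool = False,
) -> float:
    """Fraction of category names also present in another species' miRNA set."""
    if not categories:
        raise ValueError("no categories to compare")
    ours = {normalize_name(c.assigned_name, strip_arm) for c in categories}
    theirs = {normalize_name(n, strip_arm) for n in other_species_names}
    return len(ours & theirs) / len(ours)
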