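"""Independent reference implementations used as test oracles.

Everything here is deliberately naive — exhaustive enumeration, full
scans, direct definitions — and shares no code path with the package
implementations it checks.
"""

from __future__ import annotations

from functools import lru_cache

from carpmir.fold import CANONICAL_PAIRS, ENERGY_PARAMS, _PAIR_WEIGHT

MINH = ENERGY_PARAMS["min_hairpin"]


def enumerate_structures(seq: str) -> list[tuple[tuple[int, int], ...]]:
    """All nested structures (as pair tuples) over canonical pairs."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> tuple:
        if j - i + 1 < MINH + 2:
            return ((),)
        out = list(rec(i + 1, j))
        for k in range(i + MINH + 1, j + 1):
            if (seq[i], seq[k]) in CANONICAL_PAIRS:
                for inner in rec(i + 1, k - 1):
                    for rest in rec(k + 1, j):
                        out.append(((i, k),) + inner + rest)
        return tuple(out)

    return list(rec(0, len(seq) - 1))


def score_structure(seq: str, pairlist) -> float:
    """Energy of a structure by direct recursive loop decomposition.

    Independent of the package's scorer: walks the pair tree recursively
    rather than iterating closing pairs.
    """
    p = ENERGY_PARAMS
    partner = {}
    for a, b in pairlist:
        partner[a] = b
        partner[b] = a

    def children_of(lo: int, hi: int):
        out = []
        k = lo
        while k <= hi:
            if k in partner and partner[k] > k:
                out.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        return out

    def loop_energy(i: int, j: int) -> float:
        kids = children_of(i + 1, j - 1)
        if not kids:
            return p["hairpin_a"] + p["hairpin_b"] * (j - i - 1)
        if len(kids) == 1:
            (a, b) = kids[0]
            l1, l2 = a - i - 1, j - b - 1
            if l1 == l2 == 0:
                return -(_PAIR_WEIGHT[(seq[i], seq[j])] + _PAIR_WEIGHT[(seq[a], seq[b])])
            if l1 + l2 > p["max_loop"]:
                return float("inf")
            return p["internal_a"] + p["internal_b"] * (l1 + l2)
        unpaired = (j - i - 1) - sum(b - a + 1 for a, b in kids)
        return p["multi_a"] + p["multi_b"] * (len(kids) + 1) + p["multi_c"] * unpaired

    total = 0.0
    stack = [(a, b) for a, b in children_of(0, len(seq) - 1)]
    while stack:
        i, j = stack.pop()
        total += loop_energy(i, j)
        stack.extend(children_of(i + 1, j - 1))
    return total


def brute_force_mfe(seq: str) -> float:
    """Exhaustive minimum energy over all nested structures (small n only)."""
    best = 0.0
    for st in enumerate_structures(seq):
        e = score_structure(seq, st)
        if e < best:
            best = e
    return best


def naive_scan_map(genome: dict[str, str], read_rna: str) -> list[tuple[str, int, str]]:
    """All exact placements of a read by scanning every genome position."""
    comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
    rc = "".join(comp.get(c, "N") for c in reversed(read_rna))
    hits = []
    for contig, seq in genome.items():
        seq = seq.upper().replace("T", "U")
        for query, strand in ((read_rna, "+"), (rc, "-")):
            start = 0
            while True:
                pos = seq.find(query, start)
                if pos < 0:
                    break
                hits.append((contig, pos, strand))
                start = pos + 1
    return sorted(set(hits))


def brute_force_match(read: str, entry: str, max_end: int = 5, max_subs: int = 2):
    """Direct-definition edit check between a read and a catalog mature.

    Slides the read along the entry; cost = end-length changes plus
    substitutions in the overlap; seed (positions 2-8) must be identical.
    Returns the minimal cost or None.
    """
    if read[1:8] != entry[1:8]:
        return None
    best = None
    for shift in range(-max_end, max_end + 1):
        # read[i] aligns entry[i - shift]
        d3 = (len(read) - shift) - len(entry)
        if abs(shift) + abs(d3) > max_end:
            continue
        ov = [
            (read[i], entry[i - shift])
            for i in range(len(read))
            if 0 <= i - shift < len(entry)
        ]
        if not ov:
            continue
        subs = sum(1 for a, b in ov if a != b)
        if subs > max_subs:
            continue
        cost = abs(shift) + abs(d3) + subs
        if best is None or cost < best:
            best = cost
    return best
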