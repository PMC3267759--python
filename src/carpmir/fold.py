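"""Minimum-free-energy RNA secondary-structure prediction for pre-miRNA hairpins.

Implements a Zuker-style dynamic program over nested (pseudoknot-free)
structures with a deliberately small, fully documented energy model:
per-class nearest-neighbour stacking terms plus loop penalties that are
linear in loop size.  The model is not the Turner 2004 parameter set; it is
sized for ~55-200 nt precursor windows where the question is "does this
fold back into one stable stem-loop", not for quantitative thermodynamics.
Parameters live in :data:`ENERGY_PARAMS` so a richer table can be dropped in.

Energies are handled internally as integer centi-kcal/mol so that the
optimum is exact and tie-breaking is reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

RNA_ALPHABET = frozenset("ACGU")

#: Watson-Crick plus G.U wobble pairs.
CANONICAL_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")]
)

# Pair "strength" classes (kcal/mol contributions to a stack, see stack_energy):
# a stack of pairs p1 over p2 contributes -(w[p1] + w[p2]).
_PAIR_WEIGHT = {
    ("C", "G"): 1.65,
    ("G", "C"): 1.65,
    ("A", "U"): 0.45,
    ("U", "A"): 0.45,
    ("G", "U"): 0.25,
    ("U", "G"): 0.25,
}

#: Tunable energy-model parameters (kcal/mol unless noted).
ENERGY_PARAMS = {
    # hairpin loop of L unpaired bases: a + b*L  (L >= 3)
    "hairpin_a": 4.5,
    "hairpin_b": 0.2,
    # internal loop / bulge with L unpaired bases total: a + b*L (1 <= L <= max_loop)
    "internal_a": 1.8,
    "internal_b": 0.5,
    # multiloop: a + b per branch (closing helix included) + c per unpaired base
    "multi_a": 3.4,
    "multi_b": 0.4,
    "multi_c": 0.1,
    # largest internal/bulge loop considered by the model
    "max_loop": 30,
    # minimum number of unpaired bases in a hairpin loop
    "min_hairpin": 3,
}

_INF = 2**30


def _centi(x: float) -> int:
    return int(round(x * 100))


def can_pair(a: str, b: str) -> bool:
    """True if (a, b) is a Watson-Crick or G.U pair."""
    return (a, b) in CANONICAL_PAIRS


def stack_energy(pair_outer: tuple[str, str], pair_inner: tuple[str, str]) -> float:
    """Stacking energy (kcal/mol) of pair_inner stacked directly on pair_outer."""
    return -(_PAIR_WEIGHT[pair_outer] + _PAIR_WEIGHT[pair_inner])


def hairpin_energy(n_unpaired: int) -> float:
    return ENERGY_PARAMS["hairpin_a"] + ENERGY_PARAMS["hairpin_b"] * n_unpaired


def internal_energy(n_unpaired: int) -> float:
    return ENERGY_PARAMS["internal_a"] + ENERGY_PARAMS["internal_b"] * n_unpaired


@dataclass
class SecondaryStructure:
    """A nested secondary structure: sequence, dot-bracket string and MFE.

    ``pairing[i]`` is the dot-bracket character for base i; ``pairs`` maps
    each paired position to its partner (both directions).
    """

    sequence: str
    pairing: str
    energy: float
    pairs: dict[int, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pairs and "(" in self.pairing:
            self.pairs = pair_table(self.pairing)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs) // 2

    def hairpin_loops(self) -> list[tuple[int, int]]:
        """Closing pairs (i, j) of hairpin loops (no pair strictly inside)."""
        out = []
        for i, j in self.pairs.items():
            if i < j and not any(i < k < j for k in self.pairs):
                out.append((i, j))
        return sorted(out)


def pair_table(dot_bracket: str) -> dict[int, int]:
    """Parse dot-bracket notation into a symmetric position->partner map."""
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, c in enumerate(dot_bracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairs[j] = i
            pairs[i] = j
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return pairs


def structure_energy(sequence: str, pairs: dict[int, int]) -> float:
    """Energy (kcal/mol) of a given nested structure under the model.

    Decomposes the structure into loops (stacks, hairpins, internal/bulge
    loops, multiloops, exterior) and sums their terms.  Used by the folding
    traceback self-check; tests re-derive the same decomposition
    independently.
    """
    return _structure_energy_centi(sequence, pairs) / 100.0


def _structure_energy_centi(sequence: str, pairs: dict[int, int]) -> int:
    n = len(sequence)
    p = ENERGY_PARAMS
    total = 0
    closing = sorted((i, j) for i, j in pairs.items() if i < j)
    for i, j in closing:
        # children: maximal pairs directly inside (i, j)
        children = []
        k = i + 1
        while k < j:
            if k in pairs and pairs[k] > k:
                children.append((k, pairs[k]))
                k = pairs[k] + 1
            else:
                k += 1
        if not children:
            loop = j - i - 1
            total += _centi(p["hairpin_a"]) + _centi(p["hairpin_b"]) * loop
        elif len(children) == 1:
            (a, b) = children[0]
            l1, l2 = a - i - 1, j - b - 1
            if l1 == 0 and l2 == 0:
                total += _centi(stack_energy((sequence[i], sequence[j]), (sequence[a], sequence[b])))
            else:
                if l1 + l2 > p["max_loop"]:
                    raise ValueError("internal loop larger than model maximum")
                total += _centi(p["internal_a"]) + _centi(p["internal_b"]) * (l1 + l2)
        else:
            unpaired = (j - i - 1) - sum(b - a + 1 for a, b in children)
            total += (
                _centi(p["multi_a"])
                + _centi(p["multi_b"]) * (len(children) + 1)
                + _centi(p["multi_c"]) * unpaired
            )
    return total


def fold_mfe(sequence: str) -> SecondaryStructure:
    """Fold an RNA sequence into its minimum-free-energy nested structure.

    Dynamic programming over all pseudoknot-free structures built from
    Watson-Crick and G.U pairs, with hairpin loops of at least
    ``min_hairpin`` unpaired bases and internal/bulge loops of at most
    ``max_loop`` unpaired bases.  Tie-breaking is deterministic: the
    traceback prefers stacked continuations (longer helices) and 5'-most
    branch points.

    Parameters
    ----------
    sequence : RNA string over {A, C, G, U}, length >= 10.

    Raises
    ------
    ValueError
        On an invalid alphabet (the offending position is named) or a
        too-short sequence.
    """
    seq = sequence.upper()
    for pos, c in enumerate(seq):
        if c not in RNA_ALPHABET:
            raise ValueError(f"invalid RNA base {c!r} at position {pos}")
    n = len(seq)
    if n < 10:
        raise ValueError(f"sequence too short to fold ({n} nt, need >= 10)")

    p = ENERGY_PARAMS
    minh = p["min_hairpin"]
    maxloop = p["max_loop"]
    ha, hb = _centi(p["hairpin_a"]), _centi(p["hairpin_b"])
    ia, ib = _centi(p["internal_a"]), _centi(p["internal_b"])
    ma, mb, mc = _centi(p["multi_a"]), _centi(p["multi_b"]), _centi(p["multi_c"])

    base_idx = np.frombuffer(seq.encode(), dtype=np.uint8)
    # stacking energy lookup by (outer pair code, inner pair code)
    codes = {ord(a) * 256 + ord(b): k for k, (a, b) in enumerate(sorted(_PAIR_WEIGHT))}
    stack_tab = np.zeros((6, 6), dtype=np.int64)
    for (pa, wa), ka in zip(sorted(_PAIR_WEIGHT.items()), range(6)):
        for (pb, wb), kb in zip(sorted(_PAIR_WEIGHT.items()), range(6)):
            stack_tab[ka, kb] = _centi(-(wa + wb))

    pairable = np.zeros((n, n), dtype=bool)
    paircode = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            key = int(base_idx[i]) * 256 + int(base_idx[j])
            if key in codes:
                pairable[i, j] = True
                paircode[i, j] = codes[key]

    V = np.full((n, n), _INF, dtype=np.int64)
    WM = np.full((n, n), _INF, dtype=np.int64)

    for span in range(minh + 1, n):
        for i in range(0, n - span):
            j = i + span
            if pairable[i, j]:
                best = ha + hb * (j - i - 1)
                # stack
                if span >= minh + 3 and pairable[i + 1, j - 1] and V[i + 1, j - 1] < _INF:
                    cand = V[i + 1, j - 1] + stack_tab[paircode[i, j], paircode[i + 1, j - 1]]
                    if cand < best:
                        best = cand
                # internal / bulge loops (vectorised over the bounded window)
                pmax = min(i + maxloop + 1, j - minh - 1)
                if pmax > i:
                    psl = slice(i + 1, pmax + 1)
                    qlo = max(j - maxloop - 1, i + 2)
                    qsl = slice(qlo, j)
                    sub = V[psl, qsl]
                    if sub.size and sub.min() < _INF:
                        parr = np.arange(psl.start, psl.stop)
                        qarr = np.arange(qsl.start, qsl.stop)
                        lsz = (parr - i - 1)[:, None] + (j - 1 - qarr)[None, :]
                        cost = np.where(
                            (sub < _INF) & (lsz >= 1) & (lsz <= maxloop),
                            sub + ia + ib * lsz,
                            _INF,
                        )
                        m = int(cost.min())
                        if m < best:
                            best = m
                # multiloop: a + b(closing) + two WM segments (>= 2 branches)
                if span >= 2 * (minh + 2) + 1:
                    left = WM[i + 1, i + 1 : j - 1]
                    right = WM[i + 2 : j, j - 1]
                    both = left + right
                    valid = (left < _INF) & (right < _INF)
                    if valid.any():
                        m = int(both[valid].min()) + ma + mb
                        if m < best:
                            best = m
                V[i, j] = best
            # WM: >= 1 branch, unpaired bases cost mc, each branch mb
            wbest = _INF
            if V[i, j] < _INF:
                wbest = V[i, j] + mb
            if WM[i, j - 1] < _INF:
                wbest = min(wbest, WM[i, j - 1] + mc)
            if WM[i + 1, j] < _INF:
                wbest = min(wbest, WM[i + 1, j] + mc)
            if span >= 2 * (minh + 2) - 1:
                # split k from i .. j-1: WM[i,k] + WM[k+1,j]
                left = WM[i, i:j]
                right = WM[i + 1 : j + 1, j]
                both = left + right
                valid = (left < _INF) & (right < _INF)
                if valid.any():
                    wbest = min(wbest, int(both[valid].min()))
            WM[i, j] = wbest

    # exterior loop: W[j] = best energy of prefix 0..j, unpaired bases free
    W = np.zeros(n + 1, dtype=np.int64)  # W[t] covers bases 0..t-1
    for t in range(1, n + 1):
        j = t - 1
        best = W[t - 1]
        for k in range(0, j - minh):
            if V[k, j] < _INF and W[k] + V[k, j] < best:
                best = W[k] + V[k, j]
        W[t] = best

    # traceback
    structure = ["."] * n
    pairs: dict[int, int] = {}

    def trace_V(i: int, j: int) -> None:
        structure[i], structure[j] = "(", ")"
        pairs[i], pairs[j] = j, i
        e = V[i, j]
        # prefer stack (extends the helix)
        if (
            j - i >= minh + 3
            and pairable[i + 1, j - 1]
            and V[i + 1, j - 1] < _INF
            and e == V[i + 1, j - 1] + stack_tab[paircode[i, j], paircode[i + 1, j - 1]]
        ):
            trace_V(i + 1, j - 1)
            return
        if e == ha + hb * (j - i - 1):
            return
        pmax = min(i + maxloop + 1, j - minh - 1)
        for ip in range(i + 1, pmax + 1):  # 5'-most inner pair first
            for jq in range(j - 1, max(j - maxloop - 2, ip + minh), -1):
                lsz = (ip - i - 1) + (j - 1 - jq)
                if 1 <= lsz <= maxloop and V[ip, jq] < _INF:
                    if e == V[ip, jq] + ia + ib * lsz:
                        trace_V(ip, jq)
                        return
        for k in range(i + 2, j):  # multiloop split, 5'-most
            if WM[i + 1, k - 1] < _INF and WM[k, j - 1] < _INF:
                if e == WM[i + 1, k - 1] + WM[k, j - 1] + ma + mb:
                    trace_WM(i + 1, k - 1)
                    trace_WM(k, j - 1)
                    return
        raise AssertionError("traceback failed in V")  # pragma: no cover

    def trace_WM(i: int, j: int) -> None:
        e = WM[i, j]
        if V[i, j] < _INF and e == V[i, j] + mb:
            trace_V(i, j)
            return
        if i < j and WM[i + 1, j] < _INF and e == WM[i + 1, j] + mc:
            trace_WM(i + 1, j)
            return
        if i < j and WM[i, j - 1] < _INF and e == WM[i, j - 1] + mc:
            trace_WM(i, j - 1)
            return
        for k in range(i, j):
            if WM[i, k] < _INF and WM[k + 1, j] < _INF and e == WM[i, k] + WM[k + 1, j]:
                trace_WM(i, k)
                trace_WM(k + 1, j)
                return
        raise AssertionError("traceback failed in WM")  # pragma: no cover

    t = n
    while t > 0:
        j = t - 1
        placed = False
        # prefer the 5'-most pairing that achieves W[t]
        for k in range(0, j - minh):
            if V[k, j] < _INF and W[t] == W[k] + V[k, j]:
                trace_V(k, j)
                t = k
                placed = True
                break
        if not placed:
            t -= 1

    energy = int(W[n])
    ss = SecondaryStructure(seq, "".join(structure), energy / 100.0, pairs)
    # internal consistency: the traced structure must re-score to the DP optimum
    assert _structure_energy_centi(seq, pairs) == energy
    return ss
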