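"""Unique loop decomposition of 3-noncrossing structures.

Every 3-noncrossing structure decomposes uniquely into hairpin,
interior, multi- and pseudoknot loops.  A pseudoknot loop is built from
an irreducible set of crossing arcs: arcs that are minimal (innermost)
among the arcs crossing some other arc, grouped by connectivity of the
crossing (dependency) graph; it additionally claims every unpaired
position inside its span that no hairpin/interior/multi-loop claims.

For the purposes of the arc-partition invariant each loop *owns* its
closing arc(s): a hairpin owns its arc, an interior or multi-loop owns
its outer (closing) arc, and a pseudoknot loop owns its whole crossing
arc set.  Branch/inner arcs are recorded separately in ``inner_arcs``.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .structures import (
    Arc,
    Structure,
    stacks_and_stems,
)

__all__ = [
    "Loop",
    "LoopDecomposition",
    "HAIRPIN",
    "INTERIOR",
    "MULTI",
    "PSEUDOKNOT",
    "crossing_set",
    "minimal_beta_crossing",
    "pseudoknot_arcs",
    "decompose",
    "order_loops",
    "interval_sequence",
]

HAIRPIN = "hairpin"
INTERIOR = "interior"
MULTI = "multi"
PSEUDOKNOT = "pseudoknot"


@dataclass(frozen=True)
class Loop:
    """One element of the loop decomposition.

    ``arcs`` are the arcs owned by the loop (the partition of the arc
    set); ``inner_arcs`` are the nested branch arcs bounding the loop
    from below (informational, owned by their own loops); ``unpaired``
    are the unpaired positions belonging to the loop; ``span`` is the
    interval [l(T_w), r(T_w)] covered by the loop.
    """

    kind: str
    arcs: frozenset[Arc]
    unpaired: frozenset[int]
    span: tuple[int, int]
    inner_arcs: tuple[Arc, ...] = ()

    def __repr__(self) -> str:
        arcs = ",".join(f"({a.l},{a.r})" for a in sorted(self.arcs))
        return (
            f"Loop({self.kind}, arcs=[{arcs}], "
            f"unpaired={sorted(self.unpaired)}, span={self.span})"
        )


@dataclass(frozen=True)
class LoopDecomposition:
    """All loops of a structure in their linear order, plus the induced
    interval sequence I_1..I_m (closed 1-based intervals, last = [1, n])."""

    loops: tuple[Loop, ...]
    intervals: tuple[tuple[int, int], ...]


# ---------------------------------------------------------------------------
# crossing sets and the nesting order


def crossing_set(S: Structure, alpha: Arc) -> frozenset[Arc]:
    """A_S(alpha): all S-arcs crossing alpha."""
    alpha = Arc(*alpha)
    if alpha not in S.arcs:
        raise ValueError(f"arc {alpha} not in structure")
    return frozenset(b for b in S.arcs if alpha.crosses(b))


def minimal_beta_crossing(S: Structure, alpha: Arc, beta: Arc) -> bool:
    """True iff alpha is a minimal beta-crossing arc.

    alpha must cross beta; it is minimal when no other arc crossing beta
    is strictly nested inside alpha (the nesting order is the partial
    order on arcs).  Note the asymmetry: alpha may be minimal
    beta-crossing while beta is not minimal alpha-crossing.
    """
    alpha, beta = Arc(*alpha), Arc(*beta)
    others = crossing_set(S, beta)
    if alpha not in others:
        raise ValueError(f"{alpha} does not cross {beta}")
    return not any(g != alpha and g.nested_in(alpha) for g in others)


def pseudoknot_arcs(S: Structure) -> frozenset[Arc]:
    """Arcs that belong to some pseudoknot loop: the arcs that are
    minimal beta-crossing for at least one arc beta."""
    pk: set[Arc] = set()
    for beta in S.arcs:
        crossers = [b for b in S.arcs if beta.crosses(b)]
        for a in crossers:
            if not any(g != a and g.nested_in(a) for g in crossers):
                pk.add(a)
    return frozenset(pk)


# ---------------------------------------------------------------------------
# decomposition


def _direct_parents(arcs: Sequence[Arc]) -> dict[Arc, Arc | None]:
    """Parent of each arc: the smallest-span arc strictly containing it
    (ties broken towards the larger left endpoint), or None."""
    out: dict[Arc, Arc | None] = {}
    for a in arcs:
        best = None
        for b in arcs:
            if a != b and a.nested_in(b):
                if best is None or (b.length, -b.l) < (best.length, -best.l):
                    best = b
        out[a] = best
    return out


def _innermost_enclosing(arcs: Sequence[Arc], p: int) -> Arc | None:
    best = None
    for b in arcs:
        if b.contains_position(p):
            if best is None or (b.length, -b.l) < (best.length, -best.l):
                best = b
    return best


def decompose(S: Structure) -> LoopDecomposition:
    """Compute the unique loop decomposition of a 3-noncrossing
    structure (arbitrary consistent diagrams are accepted; canonicity is
    not required here).

    Every arc is owned by exactly one loop and every unpaired position
    by at most one (positions in the exterior belong to no loop).
    """
    S.validate({"consistent", "crossing"})
    arcs = S.sorted_arcs()
    partners = S.partners()

    pk = pseudoknot_arcs(S)

    # pseudoknot loops: connected components of the crossing graph on pk arcs
    g = nx.Graph()
    g.add_nodes_from(pk)
    pk_list = sorted(pk)
    for i in range(len(pk_list)):
        for j in range(i + 1, len(pk_list)):
            if pk_list[i].crosses(pk_list[j]):
                g.add_edge(pk_list[i], pk_list[j])
    pk_components = [frozenset(c) for c in nx.connected_components(g)]
    component_of = {a: comp for comp in pk_components for a in comp}

    parent = _direct_parents(arcs)
    children: dict[Arc, list[Arc]] = {a: [] for a in arcs}
    for a, par in parent.items():
        if par is not None:
            children[par].append(a)

    # unpaired ownership: innermost strictly-enclosing arc
    unpaired = [w for w in range(1, S.n + 1) if partners[w] == 0]
    owner: dict[int, Arc | None] = {
        p: _innermost_enclosing(arcs, p) for p in unpaired
    }

    loops: list[Loop] = []
    claimed: set[int] = set()

    for a in arcs:
        if a in pk:
            continue
        kids = sorted(children[a])
        here = frozenset(p for p in unpaired if owner[p] == a)
        claimed |= here
        if not kids:
            loops.append(
                Loop(HAIRPIN, frozenset({a}), here, (a.l, a.r))
            )
            continue
        # group child arcs into branches: children belonging to the same
        # pseudoknot loop count as a single branch
        branches: list[list[Arc]] = []
        by_comp: dict[frozenset[Arc], list[Arc]] = {}
        for c in kids:
            if c in pk:
                comp = component_of[c]
                if comp not in by_comp:
                    by_comp[comp] = []
                    branches.append(by_comp[comp])
                by_comp[comp].append(c)
            else:
                branches.append([c])
        if len(branches) == 1 and len(branches[0]) == 1:
            loops.append(
                Loop(
                    INTERIOR,
                    frozenset({a}),
                    here,
                    (a.l, a.r),
                    inner_arcs=(kids[0],),
                )
            )
        else:
            loops.append(
                Loop(
                    MULTI,
                    frozenset({a}),
                    here,
                    (a.l, a.r),
                    inner_arcs=tuple(kids),
                )
            )

    for comp in sorted(pk_components, key=lambda c: min(c)):
        lo = min(a.l for a in comp)
        hi = max(a.r for a in comp)
        # P2: unpaired positions inside the span not claimed by any
        # hairpin/interior/multi-loop
        here = set()
        for p in unpaired:
            if p in claimed or not lo < p < hi:
                continue
            own = owner[p]
            if own is None or own in comp:
                here.add(p)
        claimed |= here
        loops.append(
            Loop(PSEUDOKNOT, frozenset(comp), frozenset(here), (lo, hi))
        )

    ordered = order_loops(loops)
    return LoopDecomposition(tuple(ordered), tuple(_intervals(S, ordered)))


# ---------------------------------------------------------------------------
# linear order and interval sequence


def _loop_cmp(a: Loop, b: Loop) -> int:
    (al, ar), (bl, br) = a.span, b.span
    if (al, ar) != (bl, br):
        if bl <= al and ar <= br:  # a nested in b
            return -1
        if al <= bl and br <= ar:  # b nested in a
            return 1
        if al != bl:
            return -1 if al < bl else 1
        return -1 if ar < br else 1
    return 0


def order_loops(loops: Iterable[Loop]) -> list[Loop]:
    """Linear ordering: nested loops precede their hosts; otherwise the
    loop whose start-point comes first precedes.  Deterministic."""
    return sorted(loops, key=functools.cmp_to_key(_loop_cmp))


def _stem_closure(S: Structure, span: tuple[int, int]) -> tuple[int, int]:
    """Widen a span to include, transitively, every stem owning an arc
    with an endpoint inside the span.

    Stems of crossing partners are pulled in as well, so the resulting
    interval never cuts an arc of S.
    """
    _, stems = stacks_and_stems(S)
    extent_of: dict[Arc, tuple[int, int]] = {}
    for stem in stems:
        for stack in stem.stacks:
            for a in stack.arcs:
                extent_of[a] = stem.extent
    lo, hi = span
    changed = True
    while changed:
        changed = False
        for a in S.arcs:
            if lo <= a.l <= hi or lo <= a.r <= hi:
                el, eh = extent_of[a]
                if el < lo or eh > hi:
                    lo, hi = min(lo, el), max(hi, eh)
                    changed = True
    return lo, hi


def _intervals(S: Structure, ordered: Sequence[Loop]) -> list[tuple[int, int]]:
    partners = S.partners()
    out: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for loop in ordered:
        a_w = _stem_closure(S, loop.span)
        lo, hi = a_w
        while lo > 1 and partners[lo - 1] == 0:
            lo -= 1
        while hi < S.n and partners[hi + 1] == 0:
            hi += 1
        b_w = (lo, hi)
        for iv in (a_w, b_w):
            if iv not in seen:
                seen.add(iv)
                out.append(iv)
    whole = (1, S.n)
    out = [iv for iv in out if iv != whole]
    if S.n > 0:
        out.append(whole)
    return out


def interval_sequence(S: Structure) -> list[tuple[int, int]]:
    """The interval sequence I_1..I_m driving the local search: for each
    ordered loop (widened to whole stems, and across crossings to whole
    pseudoknot groups) the interval a_w, then a_w extended by adjacent
    unpaired nucleotides (b_w), duplicates dropped; the final interval
    is always [1, n]."""
    return list(decompose(S).intervals)
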