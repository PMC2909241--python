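"""Pluggable folding oracle and its exhaustive reference implementation.

The inverse-folding search only requires a *folding oracle*: a callable
mapping ``(sequence, N)`` to an energy-sorted list of N admissible
structures, the first being the mfe structure.  The reference oracle
enumerates every 3-noncrossing, sigma-canonical structure with the
required minimum arc-length (feasible for modest lengths), scores each
compatible one under an additive loop-based energy, sorts and truncates.

The energy is a dimensionless toy model mirroring the relative
magnitudes of nearest-neighbor rules: stacked base pairs stabilize
(G-C strongest, G-U weakest) while loop closures are penalized, with
pseudoknot loops penalized hardest so that cross-serial pairs appear
only when strongly supported by the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator

import numpy as np

from .loops import HAIRPIN, MULTI, PSEUDOKNOT, decompose
from .seqspace import ALLOWED_PAIRS, ALPHABET, is_compatible
from .structures import (
    Arc,
    DEFAULT_MIN_ARC_LENGTH,
    DEFAULT_SIGMA,
    Structure,
)

__all__ = [
    "EnergyModel",
    "DEFAULT_MODEL",
    "Candidate",
    "FoldResult",
    "energy",
    "enumerate_structures",
    "ReferenceOracle",
    "get_oracle",
    "fold",
    "DEFAULT_EXHAUSTIVE_LIMIT",
    "FoldingOracle",
]

#: largest length the exhaustive enumerator accepts by default
DEFAULT_EXHAUSTIVE_LIMIT = 26

#: oracle contract: (sequence, N) -> FoldResult
FoldingOracle = Callable[[str, int], "FoldResult"]


@dataclass(frozen=True)
class EnergyModel:
    """Additive loop-based energy (dimensionless units).

    A stacked pair of adjacent arcs contributes
    ``-(w(p1) + w(p2)) / 2`` where w is the weight of the base pair on
    each arc; loops add fixed penalties (interior loops per unpaired
    member).  The total energy of a structure is the sum over the loops
    of its unique loop decomposition; the empty structure has energy 0.
    """

    gc_weight: float = 3.0
    au_weight: float = 2.0
    gu_weight: float = 1.0
    hairpin: float = 3.0
    interior_unpaired: float = 0.5
    multi: float = 4.0
    pseudoknot: float = 7.0

    def pair_weight(self, x: str, y: str) -> float:
        pair = frozenset((x, y))
        if pair == frozenset("GC"):
            return self.gc_weight
        if pair == frozenset("AU"):
            return self.au_weight
        if pair == frozenset("GU"):
            return self.gu_weight
        raise ValueError(f"({x}, {y}) is not an allowed base pair")


DEFAULT_MODEL = EnergyModel()


@dataclass(frozen=True)
class Candidate:
    structure: Structure
    energy: float


@dataclass(frozen=True)
class FoldResult:
    """Energy-sorted candidate list; the first element is the mfe
    structure."""

    candidates: tuple[Candidate, ...]

    @property
    def mfe(self) -> Structure:
        return self.candidates[0].structure

    @property
    def mfe_energy(self) -> float:
        return self.candidates[0].energy

    def structures(self) -> list[Structure]:
        return [c.structure for c in self.candidates]

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)


# ---------------------------------------------------------------------------
# energy


def energy(s: str, S: Structure, model: EnergyModel = DEFAULT_MODEL) -> float:
    """Loop-wise additive energy of sequence s folded on structure S."""
    if not is_compatible(s, S):
        raise ValueError("sequence is not compatible with the structure")
    total = 0.0
    for loop in decompose(S).loops:
        total += _loop_energy(s, loop, model)
    return total


def _loop_energy(s: str, loop, model: EnergyModel) -> float:
    if loop.kind == HAIRPIN:
        return model.hairpin
    if loop.kind == MULTI:
        return model.multi
    if loop.kind == PSEUDOKNOT:
        return model.pseudoknot
    # interior: stacked (no unpaired member) earns the stacking bonus
    if loop.unpaired:
        return model.interior_unpaired * len(loop.unpaired)
    (outer,) = loop.arcs
    (inner,) = loop.inner_arcs
    w1 = model.pair_weight(s[outer.l - 1], s[outer.r - 1])
    w2 = model.pair_weight(s[inner.l - 1], s[inner.r - 1])
    return -(w1 + w2) / 2.0


# ---------------------------------------------------------------------------
# exhaustive enumeration


def _all_stacks(n: int, sigma: int, min_arc_length: int) -> list[tuple[int, int, int]]:
    """All placements (i, j, size) of a stack of arcs
    (i, j), (i+1, j-1), ..., innermost arc-length >= min_arc_length."""
    out = []
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            smax = 0
            # innermost arc (i+s-1, j-s+1) must satisfy the length bound
            while (
                i + smax <= j - smax - 1
                and (j - smax) - (i + smax) >= min_arc_length
            ):
                smax += 1
            for s in range(sigma, smax + 1):
                out.append((i, j, s))
    return out


def _stack_arcs(st: tuple[int, int, int]) -> list[Arc]:
    i, j, s = st
    return [Arc(i + t, j - t) for t in range(s)]


def enumerate_structures(
    n: int,
    *,
    sigma: int = DEFAULT_SIGMA,
    min_arc_length: int = DEFAULT_MIN_ARC_LENGTH,
    limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
) -> Iterator[Structure]:
    """Emit every 3-noncrossing, sigma-canonical structure of length n
    with the required minimum arc-length, exactly once (the empty
    structure included).

    Structures are generated as sets of maximal stacks: stack placements
    that are position-disjoint, never the exact continuation of another
    chosen stack (which would merge into one larger stack) and jointly
    3-noncrossing.  Deterministic DFS order.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n > limit:
        raise ValueError(
            f"n={n} exceeds the exhaustive limit {limit}; plug in a "
            "heuristic oracle for longer sequences"
        )
    stacks = _all_stacks(n, sigma, min_arc_length)

    def positions(st):
        i, j, s = st
        return set(range(i, i + s)) | set(range(j - s + 1, j + 1))

    def continues(a, b) -> bool:
        return b[0] == a[0] + a[2] and b[1] == a[1] - a[2]

    pos_sets = [positions(st) for st in stacks]

    def rec(
        start: int, chosen_arcs: list[Arc], used: set[int]
    ) -> Iterator[Structure]:
        yield Structure(
            n,
            chosen_arcs,
            sigma=sigma,
            min_arc_length=min_arc_length,
        )
        for idx in range(start, len(stacks)):
            st = stacks[idx]
            if used & pos_sets[idx]:
                continue
            new_arcs = _stack_arcs(st)
            # no merging with an already chosen stack
            merged = False
            for prev_idx in chosen_stack_idx:
                prev = stacks[prev_idx]
                if continues(prev, st) or continues(st, prev):
                    merged = True
                    break
            if merged:
                continue
            # 3-noncrossing: a 3-crossing needs arcs of three distinct
            # stacks, so it suffices that no two existing arcs that both
            # cross a new arc cross each other
            ok = True
            for a in new_arcs:
                crossers = [b for b in chosen_arcs if a.crosses(b)]
                for x in range(len(crossers)):
                    for y in range(x + 1, len(crossers)):
                        if crossers[x].crosses(crossers[y]):
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                continue
            chosen_stack_idx.append(idx)
            yield from rec(idx + 1, chosen_arcs + new_arcs, used | pos_sets[idx])
            chosen_stack_idx.pop()

    chosen_stack_idx: list[int] = []
    yield from rec(0, [], set())


# ---------------------------------------------------------------------------
# reference oracle


class _Table:
    """Compiled per-length scoring table: every admissible structure with
    per-arc stacking coefficients and a sequence-independent constant."""

    def __init__(self, n: int, model: EnergyModel, sigma: int, min_arc_length: int, limit: int):
        structures = list(
            enumerate_structures(
                n, sigma=sigma, min_arc_length=min_arc_length, limit=limit
            )
        )
        # pre-sort by the lexicographic arc-list key: the stable energy
        # argsort then breaks ties deterministically by this key
        structures.sort(key=lambda S: tuple(S.sorted_arcs()))
        self.structures = structures
        const = np.zeros(len(structures))
        arc_l: list[int] = []
        arc_r: list[int] = []
        arc_sid: list[int] = []
        arc_coef: list[float] = []
        for sid, S in enumerate(structures):
            coef: dict[Arc, float] = {a: 0.0 for a in S.arcs}
            for loop in decompose(S).loops:
                if loop.kind == HAIRPIN:
                    const[sid] += model.hairpin
                elif loop.kind == MULTI:
                    const[sid] += model.multi
                elif loop.kind == PSEUDOKNOT:
                    const[sid] += model.pseudoknot
                elif loop.unpaired:
                    const[sid] += model.interior_unpaired * len(loop.unpaired)
                else:
                    (outer,) = loop.arcs
                    (inner,) = loop.inner_arcs
                    coef[outer] += 0.5
                    coef[inner] += 0.5
            for a in S.sorted_arcs():
                arc_l.append(a.l - 1)
                arc_r.append(a.r - 1)
                arc_sid.append(sid)
                arc_coef.append(coef[a])
        self.const = const
        self.arc_l = np.asarray(arc_l, dtype=np.int64)
        self.arc_r = np.asarray(arc_r, dtype=np.int64)
        self.arc_sid = np.asarray(arc_sid, dtype=np.int64)
        self.arc_coef = np.asarray(arc_coef)
        # 4x4 pair tables
        weight = np.zeros(16)
        allowed = np.zeros(16, dtype=bool)
        for x, y in ALLOWED_PAIRS:
            code = ALPHABET.index(x) * 4 + ALPHABET.index(y)
            allowed[code] = True
            weight[code] = model.pair_weight(x, y)
        self.pair_weight = weight
        self.pair_allowed = allowed
        self.base_code = {b: i for i, b in enumerate(ALPHABET)}


class ReferenceOracle:
    """Exhaustive folding oracle: filter the enumerated structures by
    sequence compatibility, score, sort (stable; ties broken by the
    lexicographic order of the sorted arc list) and truncate to N.

    Tables are cached per sequence length, so repeated folds at the
    same length cost a handful of vectorized passes over the arc table.
    """

    def __init__(
        self,
        model: EnergyModel = DEFAULT_MODEL,
        *,
        sigma: int = DEFAULT_SIGMA,
        min_arc_length: int = DEFAULT_MIN_ARC_LENGTH,
        limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
    ):
        self.model = model
        self.sigma = sigma
        self.min_arc_length = min_arc_length
        self.limit = limit
        self._tables: dict[int, _Table] = {}

    def _table(self, n: int) -> _Table:
        tab = self._tables.get(n)
        if tab is None:
            tab = _Table(n, self.model, self.sigma, self.min_arc_length, self.limit)
            self._tables[n] = tab
        return tab

    def fold(self, s: str, N: int = 1) -> FoldResult:
        if N < 1:
            raise ValueError("N must be >= 1")
        bad = set(s) - set(ALPHABET)
        if bad:
            raise ValueError(f"sequence contains letters outside ACGU: {sorted(bad)}")
        tab = self._table(len(s))
        codes = np.array([tab.base_code[c] for c in s], dtype=np.int64)
        nstruct = len(tab.structures)
        if tab.arc_sid.size:
            pcode = codes[tab.arc_l] * 4 + codes[tab.arc_r]
            ok_arc = tab.pair_allowed[pcode]
            n_bad = np.bincount(tab.arc_sid[~ok_arc], minlength=nstruct)
            w = np.where(ok_arc, tab.pair_weight[pcode], 0.0)
            contrib = np.bincount(
                tab.arc_sid, weights=-tab.arc_coef * w, minlength=nstruct
            )
            energies = tab.const + contrib
            feasible = np.flatnonzero(n_bad == 0)
        else:
            energies = tab.const
            feasible = np.arange(nstruct)
        order = feasible[np.argsort(energies[feasible], kind="stable")]
        top = order[:N]
        return FoldResult(
            tuple(
                Candidate(tab.structures[i], float(energies[i])) for i in top
            )
        )

    __call__ = fold


_oracle_cache: dict[tuple, ReferenceOracle] = {}


def get_oracle(
    model: EnergyModel | None = None,
    *,
    sigma: int = DEFAULT_SIGMA,
    min_arc_length: int = DEFAULT_MIN_ARC_LENGTH,
    limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
) -> ReferenceOracle:
    """Shared, table-caching reference oracle for the given model."""
    model = model or DEFAULT_MODEL
    key = (model, sigma, min_arc_length, limit)
    oracle = _oracle_cache.get(key)
    if oracle is None:
        oracle = ReferenceOracle(
            model, sigma=sigma, min_arc_length=min_arc_length, limit=limit
        )
        _oracle_cache[key] = oracle
    return oracle


def fold(
    s: str,
    N: int = 1,
    model: EnergyModel | None = None,
    *,
    sigma: int = DEFAULT_SIGMA,
    min_arc_length: int = DEFAULT_MIN_ARC_LENGTH,
    limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
) -> FoldResult:
    """Fold with the reference oracle: the energy-sorted list of the N
    best admissible structures for s (N defaults to 1, i.e. the mfe)."""
    return get_oracle(
        model, sigma=sigma, min_arc_length=min_arc_length, limit=limit
    ).fold(s, N)
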