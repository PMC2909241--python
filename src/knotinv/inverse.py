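"""The inverse-folding search.

Given a 3-noncrossing canonical target structure T, the search looks
for a sequence whose mfe fold equals T.  It proceeds in two stages:

* ADJUST-SEQ iteratively folds the current sequence, perturbs the arcs
  of the suboptimal folds into a set of *competitor* structures and
  mutates the sequence so that it stays compatible with T while
  breaking compatibility with as many competitors as possible (the
  negative paradigm: push energetically close rivals away).

* LOCAL-SEARCH then walks the interval sequence induced by the loop
  decomposition of T, optimizing each interval by random T-compatible
  point/pair mutations at positions that pair incorrectly (or next to
  such positions), accepting strict improvements always and bounded
  uphill moves with a small probability.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from . import folding
from .loops import interval_sequence
from .seqspace import ALLOWED_PAIRS, ALPHABET, can_pair, is_compatible, make_start
from .structures import Arc, Structure, restrict, structure_distance

__all__ = [
    "SearchConfig",
    "CompetitorSet",
    "InverseFoldResult",
    "perturb_arc",
    "build_competitors",
    "mutate_sequence",
    "adjust_seq",
    "local_search",
    "inverse_fold",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchConfig:
    """Heuristic constants of the search.

    N              suboptimal list size requested from the oracle
    window         distance slack for accepting a mutated sequence
                   (d <= d_min + window)
    p_accept       probability of accepting a bounded uphill move in
                   the local search
    step3_max      maximum repeats of the mutation step per iteration
    adjust_iters   ADJUST-SEQ iteration bound; None -> max(50, n)
    phase_max_factor   per-interval phase budget = factor * interval length
    seed           RNG seed (single generator threaded through the run)
    """

    N: int = 50
    window: int = 5
    p_accept: float = 0.1
    step3_max: int = 5
    adjust_iters: int | None = None
    phase_max_factor: int = 10
    seed: int | None = None

    def __post_init__(self):
        if self.N < 1 or self.window < 0 or self.step3_max < 1:
            raise ValueError("N, window, step3_max must be positive")
        if not 0.0 <= self.p_accept <= 1.0:
            raise ValueError("p_accept must lie in [0, 1]")
        if self.phase_max_factor < 1:
            raise ValueError("phase_max_factor must be positive")


@dataclass(frozen=True)
class CompetitorSet:
    """Deduplicated rival structures derived by arc perturbation.

    ``provenance`` records, for each member, the index of the suboptimal
    candidate and the arc whose perturbation produced it first.
    """

    members: tuple[Structure, ...]
    provenance: dict[Structure, tuple[int, Arc]] = field(
        default_factory=dict, compare=False, repr=False
    )

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


@dataclass(frozen=True)
class InverseFoldResult:
    """Outcome of a design run.  ``success`` is True iff the mfe fold of
    ``sequence`` equals the target exactly; ``distance`` is the residual
    structure distance (0 on success)."""

    success: bool
    sequence: str
    distance: int
    mfe: Structure
    energy: float

    def __bool__(self) -> bool:
        return self.success


# ---------------------------------------------------------------------------
# Step II: perturbation and competitors


def perturb_arc(S: Structure, a: Arc) -> list[Structure]:
    """The perturbation family nu(S, a): move each endpoint of a by at
    most one position (nine placements, a itself included) or remove a.

    Placements leaving [1, n] or violating l' < r' are dropped; an
    interior arc therefore yields ten structures.  Consistency and
    compatibility filtering is the caller's job.
    """
    a = Arc(*a)
    if a not in S.arcs:
        raise ValueError(f"arc {a} not in structure")
    rest = S.arcs - {a}
    out: list[Structure] = []
    seen: set[frozenset[Arc]] = set()
    for dl in (-1, 0, 1):
        for dr in (-1, 0, 1):
            l, r = a.l + dl, a.r + dr
            if not (1 <= l < r <= S.n):
                continue
            arcs = rest | {Arc(l, r)}
            if arcs not in seen:
                seen.add(arcs)
                out.append(Structure(S.n, arcs))
    if rest not in seen:
        out.append(Structure(S.n, rest))
    return out


def build_competitors(
    candidates: "folding.FoldResult | Iterable[Structure]",
    seq: str,
    T: Structure,
) -> CompetitorSet:
    """Perturb every arc of every suboptimal candidate and keep the
    distinct results that are consistent (no position paired twice),
    compatible with the current sequence and different from the target."""
    if isinstance(candidates, folding.FoldResult):
        structures = candidates.structures()
    else:
        structures = list(candidates)
    members: list[Structure] = []
    provenance: dict[Structure, tuple[int, Arc]] = {}
    seen: set[Structure] = set()
    for h, C in enumerate(structures):
        for a in C.sorted_arcs():
            for P in perturb_arc(C, a):
                if P in seen:
                    continue
                seen.add(P)
                if P == T or not P.is_consistent:
                    continue
                if not is_compatible(seq, P):
                    continue
                members.append(P)
                provenance[P] = (h, a)
    return CompetitorSet(tuple(members), provenance)


# ---------------------------------------------------------------------------
# Step III: mutation against the competitors


def _best_choices(options: Sequence, score: dict, full: int) -> list:
    """Options breaking every competitor if any exist, else the options
    breaking the most."""
    winners = [o for o in options if score[o] == full]
    if winners:
        return winners
    best = max(score[o] for o in options)
    return [o for o in options if score[o] == best]


def mutate_sequence(
    seq: str,
    T: Structure,
    competitors: CompetitorSet,
    rng: random.Random,
) -> str:
    """One pass of the mutation step: at every position where some
    competitor pairs differently from T, redraw the base (unpaired in T)
    or the base pair (left endpoint of a T-arc) so the sequence stays
    T-compatible and, where possible, becomes incompatible with every
    conflicting competitor.  Right endpoints are handled with their left
    partner."""
    if not is_compatible(seq, T):
        raise ValueError("sequence is not compatible with the target")
    s = list(seq)
    comp_partners = [C.partners() for C in competitors]
    tp = T.partners()
    for w in range(1, T.n + 1):
        pT = tp[w]
        conflict = [cp[w] for cp in comp_partners if cp[w] != pT]
        if not conflict:
            continue
        if pT == 0:
            # all conflicting competitors pair w with some u > 0; pick a
            # base that cannot pair with the competitor partner's base
            score = {
                b: sum(1 for u in conflict if not can_pair(b, s[u - 1]))
                for b in ALPHABET
            }
            choice = rng.choice(_best_choices(ALPHABET, score, len(conflict)))
            s[w - 1] = choice
        elif pT > w:
            v = pT
            cur = (s[w - 1], s[v - 1])
            options = [p for p in ALLOWED_PAIRS if p != cur]
            score = {
                p: sum(
                    1
                    for u in conflict
                    if u == 0 or not can_pair(p[0], s[u - 1])
                )
                for p in options
            }
            bw, bv = rng.choice(_best_choices(options, score, len(conflict)))
            s[w - 1] = bw
            s[v - 1] = bv
        # pT < w: the pair was already redrawn at its left endpoint
    return "".join(s)


# ---------------------------------------------------------------------------
# ADJUST-SEQ


def adjust_seq(
    start: str,
    T: Structure,
    cfg: SearchConfig,
    oracle: "folding.FoldingOracle",
    rng: random.Random | None = None,
) -> str:
    """Iteratively fold, build competitors and mutate; returns the
    adjusted sequence (the target's mfe realization if one is found
    along the way)."""
    if rng is None:
        rng = random.Random(cfg.seed)
    if not is_compatible(start, T):
        raise ValueError("start sequence is not compatible with the target")
    n = T.n
    iters = cfg.adjust_iters if cfg.adjust_iters is not None else max(50, n)
    lam = start
    d_min = math.inf
    seq_min = start
    seq_middle = start
    for i in range(iters):
        result = oracle(lam, cfg.N)
        d = structure_distance(result.mfe, T)
        logger.debug("adjust iter %d: d(mfe, T) = %d", i, d)
        if d == 0:
            return lam
        if d < d_min:
            d_min, seq_min = d, lam
        competitors = build_competitors(result, lam, T)
        if not competitors.members:
            break  # nothing to push against; mutation would be a no-op
        accepted = None
        best_try, best_d = None, math.inf
        for _ in range(cfg.step3_max):
            cand = mutate_sequence(lam, T, competitors, rng)
            dc = structure_distance(oracle(cand, 1).mfe, T)
            if dc < best_d:
                best_d, best_try = dc, cand
            if dc <= d_min + cfg.window:
                accepted = cand
                break
        if accepted is not None:
            lam = accepted
            seq_middle = accepted
        else:
            lam = best_try
    return seq_middle


# ---------------------------------------------------------------------------
# LOCAL-SEARCH


def _mutation_sites(
    mfe: Structure, subT: Structure
) -> tuple[list[int], list[tuple[int, int]]]:
    """U1 (unpaired-in-T sites) and U2 (T-pairs) around the positions
    that pair differently in the current fold and the target."""
    pm, pt = mfe.partners(), subT.partners()
    m = subT.n
    mismatch = [p for p in range(1, m + 1) if pm[p] != pt[p]]
    sites: set[int] = set()
    for p in mismatch:
        for q in (p - 1, p, p + 1):
            if 1 <= q <= m:
                sites.add(q)
    u1 = sorted(p for p in sites if pt[p] == 0)
    u2 = sorted({(min(p, pt[p]), max(p, pt[p])) for p in sites if pt[p] != 0})
    return u1, u2


def local_search(
    seq: str,
    T: Structure,
    intervals: Sequence[tuple[int, int]],
    cfg: SearchConfig,
    oracle: "folding.FoldingOracle",
    rng: random.Random | None = None,
) -> str:
    """Stochastic local search over the interval sequence of T.

    For each interval the subsequence is folded against the restricted
    target; random T-compatible mutations at mispairing positions (and
    their neighbors) are accepted on strict improvement, accepted with
    probability ``p_accept`` when the distance stays below
    d_min + window, and distance ties are resolved towards the lowest
    mfe energy.
    """
    if rng is None:
        rng = random.Random(cfg.seed)
    if not is_compatible(seq, T):
        raise ValueError("sequence is not compatible with the target")
    if structure_distance(oracle(seq, 1).mfe, T) == 0:
        return seq
    cur = seq
    for lo, hi in intervals:
        cur = _search_interval(cur, T, lo, hi, cfg, oracle, rng)
    return cur


def _search_interval(
    seq: str,
    T: Structure,
    lo: int,
    hi: int,
    cfg: SearchConfig,
    oracle,
    rng: random.Random,
) -> str:
    subT = restrict(T, lo, hi)
    m = subT.n

    def sub(s: str) -> str:
        return s[lo - 1 : hi]

    def subfold(s: str) -> "folding.FoldResult":
        return oracle(sub(s), 1)

    cur = seq
    res = subfold(cur)
    d_min = structure_distance(res.mfe, subT)
    max_phases = cfg.phase_max_factor * m
    phase = 0
    while d_min > 0 and phase < max_phases:
        phase += 1
        mfe = subfold(cur).mfe
        u1, u2 = _mutation_sites(mfe, subT)
        moves: list[tuple] = [("u", p) for p in u1] + [("p", pq) for pq in u2]
        if not moves:
            break
        rng.shuffle(moves)
        ties: list[str] = []
        restarted = False
        for kind, where in moves:
            cand = _apply_move(cur, kind, where, lo, rng)
            d = structure_distance(subfold(cand).mfe, subT)
            if d < d_min:
                d_min = d
                cur = cand
                logger.debug(
                    "local [%d,%d] phase %d: improved to d=%d", lo, hi, phase, d
                )
                restarted = True
                break
            if d_min < d < d_min + cfg.window and rng.random() < cfg.p_accept:
                cur = cand
                logger.debug(
                    "local [%d,%d] phase %d: uphill move to d=%d", lo, hi, phase, d
                )
                restarted = True
                break
            if d == d_min:
                ties.append(cand)
        if restarted:
            continue
        if ties:
            best_e = math.inf
            for cand in ties:
                e = subfold(cand).mfe_energy
                if e < best_e:
                    best_e = e
                    cur = cand
    return cur


def _apply_move(
    seq: str, kind: str, where, lo: int, rng: random.Random
) -> str:
    """One random T-compatible mutation; ``where`` is interval-local,
    ``lo`` the interval offset."""
    s = list(seq)
    if kind == "u":
        g = lo - 1 + where - 1
        s[g] = rng.choice([b for b in ALPHABET if b != s[g]])
    else:
        p, q = where
        gp, gq = lo - 1 + p - 1, lo - 1 + q - 1
        cur = (s[gp], s[gq])
        s[gp], s[gq] = rng.choice([x for x in ALLOWED_PAIRS if x != cur])
    return "".join(s)


# ---------------------------------------------------------------------------
# driver


def inverse_fold(
    T: Structure,
    cfg: SearchConfig | None = None,
    oracle: "folding.FoldingOracle | None" = None,
) -> InverseFoldResult:
    """Design a sequence whose mfe fold is T.

    The target is validated (3-noncrossing, canonical, minimum
    arc-length) before any search.  On success the returned sequence
    satisfies ``oracle(seq, 1).mfe == T`` exactly; otherwise the result
    carries the best sequence found and its residual distance.
    """
    cfg = cfg or SearchConfig()
    T.validate()
    if oracle is None:
        oracle = folding.get_oracle()
    rng = random.Random(cfg.seed)
    start = make_start(T, rng)
    logger.info("start sequence: %s", start)
    middle = adjust_seq(start, T, cfg, oracle, rng)
    intervals = interval_sequence(T)
    final = local_search(middle, T, intervals, cfg, oracle, rng)
    result = oracle(final, 1)
    d = structure_distance(result.mfe, T)
    if d != 0:
        # the adjusted sequence may be better than the locally searched one
        mid_result = oracle(middle, 1)
        d_mid = structure_distance(mid_result.mfe, T)
        if d_mid < d:
            final, result, d = middle, mid_result, d_mid
    logger.info("final distance %d (success=%s)", d, d == 0)
    return InverseFoldResult(
        success=(d == 0),
        sequence=final,
        distance=d,
        mfe=result.mfe,
        energy=result.mfe_energy,
    )
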