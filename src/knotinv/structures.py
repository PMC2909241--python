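"""Diagram model for k-noncrossing RNA pseudoknot structures.

An RNA structure is represented as a *diagram*: positions 1..n on a
horizontal line with arcs (i, j), i < j, drawn in the upper half-plane,
each position incident to at most one arc.  Secondary structures are the
noncrossing diagrams; pseudoknots introduce cross-serial arcs.  The
default target class is 3-noncrossing (no three mutually crossing arcs),
3-canonical (every stack has at least three base pairs) with minimum
arc-length four.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import networkx as nx

__all__ = [
    "Arc",
    "Structure",
    "Stack",
    "Stem",
    "ParseError",
    "ValidationError",
    "parse_structure",
    "write_structure",
    "crossing_number",
    "stacks_and_stems",
    "structure_distance",
    "pairing_partner",
    "core_and_lgraph",
    "lgraph",
    "restrict",
    "DEFAULT_MIN_ARC_LENGTH",
    "DEFAULT_SIGMA",
    "DEFAULT_K",
    "ALL_CHECKS",
]

DEFAULT_MIN_ARC_LENGTH = 4
DEFAULT_SIGMA = 3
DEFAULT_K = 3

#: bracket families for the extended dot-bracket alphabet ":()[]{}"
BRACKET_FAMILIES = (("(", ")"), ("[", "]"), ("{", "}"))
UNPAIRED_CHAR = ":"

#: names of the individual validator checks
ALL_CHECKS = frozenset(
    {"consistent", "no_adjacent", "arc_length", "crossing", "canonical"}
)


class Arc(NamedTuple):
    """A base pair (l, r) with 1-based endpoints, l < r."""

    l: int
    r: int

    @property
    def length(self) -> int:
        """Arc-length r - l."""
        return self.r - self.l

    def crosses(self, other: "Arc") -> bool:
        """True iff the two arcs cross (i1 < i2 < j1 < j2 in some order)."""
        a, b = (self, other) if self.l < other.l else (other, self)
        return a.l < b.l < a.r < b.r

    def nested_in(self, other: "Arc") -> bool:
        """True iff this arc is strictly nested inside ``other``."""
        return other.l < self.l and self.r < other.r

    def contains_position(self, p: int) -> bool:
        """True iff l < p < r."""
        return self.l < p < self.r


class ParseError(ValueError):
    """Raised for malformed extended dot-bracket input."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class ValidationError(ValueError):
    """A structure violates one of the diagram invariants.

    ``invariant`` names the violated check and ``arcs`` lists the
    offending arcs (or positions, for consistency violations).
    """

    def __init__(self, invariant: str, message: str, arcs: Sequence = ()):
        super().__init__(f"{invariant}: {message}")
        self.invariant = invariant
        self.arcs = tuple(arcs)


class Structure:
    """A diagram: length ``n`` plus a set of arcs.

    Construction is permissive: any arc set with 1 <= l < r <= n is
    accepted, including inconsistent ones (a position incident to two
    arcs), because intermediate structures produced by arc perturbation
    must be representable before they are filtered.  Use
    :meth:`validate` / :meth:`is_valid` to enforce the diagram
    invariants.

    ``min_arc_length``, ``sigma`` and ``k`` parametrize the validator
    (defaults 4, 3, 3) and do not take part in equality or hashing.
    """

    __slots__ = ("n", "arcs", "min_arc_length", "sigma", "k", "_partners", "_hash")

    def __init__(
        self,
        n: int,
        arcs: Iterable[tuple[int, int]] = (),
        *,
        min_arc_length: int = DEFAULT_MIN_ARC_LENGTH,
        sigma: int = DEFAULT_SIGMA,
        k: int = DEFAULT_K,
    ):
        self.n = int(n)
        if self.n < 0:
            raise ValueError("structure length must be >= 0")
        arcset = frozenset(Arc(int(a[0]), int(a[1])) for a in arcs)
        for a in arcset:
            if not (1 <= a.l < a.r <= self.n):
                raise ValueError(f"arc {a} out of range for n={self.n}")
        self.arcs = arcset
        self.min_arc_length = min_arc_length
        self.sigma = sigma
        self.k = k
        self._partners: tuple[int, ...] | None = None
        self._hash: int | None = None

    # -- identity ---------------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, Structure):
            return NotImplemented
        return self.n == other.n and self.arcs == other.arcs

    def __hash__(self) -> int:
        if self._hash is None:
            self._hash = hash((self.n, self.arcs))
        return self._hash

    def __repr__(self) -> str:
        arcs = ", ".join(f"({a.l},{a.r})" for a in self.sorted_arcs())
        return f"Structure(n={self.n}, arcs=[{arcs}])"

    # -- basic queries ----------------------------------------------------

    def sorted_arcs(self) -> list[Arc]:
        return sorted(self.arcs)

    @property
    def is_consistent(self) -> bool:
        """True iff every position is an endpoint of at most one arc."""
        seen: set[int] = set()
        for a in self.arcs:
            if a.l in seen or a.r in seen:
                return False
            seen.add(a.l)
            seen.add(a.r)
        return True

    def partners(self) -> tuple[int, ...]:
        """Partner vector ``p`` with ``p[w]`` the pairing partner of w (0 if
        unpaired); index 0 is unused.  Requires a consistent structure."""
        if self._partners is None:
            p = [0] * (self.n + 1)
            for a in self.arcs:
                if p[a.l] or p[a.r]:
                    raise ValidationError(
                        "consistent",
                        "position paired with more than one base",
                        [a],
                    )
                p[a.l] = a.r
                p[a.r] = a.l
            self._partners = tuple(p)
        return self._partners

    def partner(self, w: int) -> int:
        if not 1 <= w <= self.n:
            raise ValueError(f"position {w} out of range 1..{self.n}")
        return self.partners()[w]

    def unpaired_positions(self) -> list[int]:
        p = self.partners()
        return [w for w in range(1, self.n + 1) if p[w] == 0]

    # -- validation -------------------------------------------------------

    def violations(self, checks: Iterable[str] = ALL_CHECKS) -> list[ValidationError]:
        """Collect invariant violations without raising."""
        checks = set(checks)
        unknown = checks - ALL_CHECKS
        if unknown:
            raise ValueError(f"unknown checks: {sorted(unknown)}")
        out: list[ValidationError] = []

        if "consistent" in checks and not self.is_consistent:
            seen: dict[int, Arc] = {}
            bad = []
            for a in self.sorted_arcs():
                for p in (a.l, a.r):
                    if p in seen:
                        bad.extend([seen[p], a])
                    seen[p] = a
            out.append(
                ValidationError(
                    "consistent", "position paired with more than one base", bad
                )
            )
            return out  # further checks assume consistency

        if "no_adjacent" in checks:
            bad = [a for a in self.sorted_arcs() if a.length == 1]
            if bad:
                out.append(
                    ValidationError("no_adjacent", "arc of the form (i, i+1)", bad)
                )

        if "arc_length" in checks:
            bad = [a for a in self.sorted_arcs() if a.length < self.min_arc_length]
            if bad:
                out.append(
                    ValidationError(
                        "arc_length",
                        f"arc-length below minimum {self.min_arc_length}",
                        bad,
                    )
                )

        if "crossing" in checks:
            witness = _k_crossing_witness(self.sorted_arcs(), self.k)
            if witness:
                out.append(
                    ValidationError(
                        "crossing",
                        f"{self.k} mutually crossing arcs (structure must be "
                        f"{self.k}-noncrossing)",
                        witness,
                    )
                )

        if "canonical" in checks:
            stacks, _ = stacks_and_stems(self)
            bad_stacks = [s for s in stacks if len(s.arcs) < self.sigma]
            if bad_stacks:
                out.append(
                    ValidationError(
                        "canonical",
                        f"stack of size below sigma={self.sigma}",
                        [a for s in bad_stacks for a in s.arcs],
                    )
                )
        return out

    def validate(self, checks: Iterable[str] = ALL_CHECKS) -> "Structure":
        """Raise :class:`ValidationError` on the first violated invariant."""
        bad = self.violations(checks)
        if bad:
            raise bad[0]
        return self

    def is_valid(self, checks: Iterable[str] = ALL_CHECKS) -> bool:
        return not self.violations(checks)


@dataclass(frozen=True)
class Stack:
    """A maximal run of exactly nested, endpoint-adjacent arcs
    (i, j), (i+1, j-1), ..., ordered outermost first."""

    arcs: tuple[Arc, ...]

    @property
    def size(self) -> int:
        return len(self.arcs)

    @property
    def outer(self) -> Arc:
        return self.arcs[0]

    @property
    def inner(self) -> Arc:
        return self.arcs[-1]

    @property
    def extent(self) -> tuple[int, int]:
        return (self.outer.l, self.outer.r)


@dataclass(frozen=True)
class Stem:
    """A chain of nested stacks separated by unpaired nucleotides on at
    least one side, ordered outermost first."""

    stacks: tuple[Stack, ...]

    @property
    def length(self) -> int:
        return len(self.stacks)

    @property
    def extent(self) -> tuple[int, int]:
        return self.stacks[0].extent


# ---------------------------------------------------------------------------
# parsing / writing


def parse_structure(
    text: str,
    validate: bool | Iterable[str] = True,
    *,
    min_arc_length: int = DEFAULT_MIN_ARC_LENGTH,
    sigma: int = DEFAULT_SIGMA,
    k: int = DEFAULT_K,
) -> Structure:
    """Parse an extended dot-bracket string over ``:()[]{}``.

    Each bracket family is matched independently by nesting (LIFO per
    family); ``:`` (or ``.``) marks an unpaired base and whitespace is
    ignored.  ``validate`` selects the invariants to enforce: ``True``
    runs the full default validator, ``False`` none, or pass an iterable
    of check names (subset of :data:`ALL_CHECKS`).
    """
    open_of = {o: i for i, (o, _) in enumerate(BRACKET_FAMILIES)}
    close_of = {c: i for i, (_, c) in enumerate(BRACKET_FAMILIES)}
    stacks: list[list[int]] = [[] for _ in BRACKET_FAMILIES]
    arcs: list[tuple[int, int]] = []
    pos = 0
    for ch in text:
        if ch.isspace():
            continue
        pos += 1
        if ch in (UNPAIRED_CHAR, "."):
            continue
        if ch in open_of:
            stacks[open_of[ch]].append(pos)
        elif ch in close_of:
            fam = close_of[ch]
            if not stacks[fam]:
                raise ParseError(
                    f"unmatched '{ch}' at position {pos}", position=pos
                )
            arcs.append((stacks[fam].pop(), pos))
        else:
            raise ParseError(
                f"illegal character {ch!r} at position {pos}", position=pos
            )
    for fam, stk in enumerate(stacks):
        if stk:
            raise ParseError(
                f"unmatched '{BRACKET_FAMILIES[fam][0]}' at position {stk[-1]}",
                position=stk[-1],
            )
    s = Structure(
        pos, arcs, min_arc_length=min_arc_length, sigma=sigma, k=k
    )
    if validate is True:
        s.validate()
    elif validate is not False:
        s.validate(validate)
    return s


def write_structure(S: Structure) -> str:
    """Render a structure as an extended dot-bracket string.

    Bracket families are assigned by a greedy coloring of the
    arc-crossing conflict graph: arcs are visited by increasing left
    endpoint and each receives the lowest-index family whose
    already-assigned arcs do not cross it.  Three families suffice for
    3-noncrossing inputs under this scheme.
    """
    S.validate({"consistent"})
    chars = [UNPAIRED_CHAR] * S.n
    assigned: list[list[Arc]] = [[] for _ in BRACKET_FAMILIES]
    for a in sorted(S.arcs):
        for fam, members in enumerate(assigned):
            if not any(a.crosses(b) for b in members):
                members.append(a)
                chars[a.l - 1] = BRACKET_FAMILIES[fam][0]
                chars[a.r - 1] = BRACKET_FAMILIES[fam][1]
                break
        else:
            raise ValidationError(
                "crossing",
                "arc coloring needs more than three bracket families "
                "(input is not 3-noncrossing)",
                [a],
            )
    return "".join(chars)


# ---------------------------------------------------------------------------
# crossing analysis


def _k_crossing_witness(arcs: Sequence[Arc], k: int) -> list[Arc]:
    """Return k mutually crossing arcs if any exist, else [].

    For arcs, pairwise crossing implies mutual crossing (sorting the
    arcs of a pairwise-crossing set by left endpoint yields
    i1 < ... < ik < j1 < ... < jk), so a k-crossing is a k-clique in the
    crossing graph.
    """
    arcs = list(arcs)
    if k <= 0 or len(arcs) < k:
        return []
    g = nx.Graph()
    g.add_nodes_from(range(len(arcs)))
    for i in range(len(arcs)):
        for j in range(i + 1, len(arcs)):
            if arcs[i].crosses(arcs[j]):
                g.add_edge(i, j)
    for clique in nx.find_cliques(g):
        if len(clique) >= k:
            return [arcs[i] for i in sorted(clique[:k])]
    return []


def crossing_number(arcs: Iterable[tuple[int, int]]) -> int:
    """Largest m such that some m arcs are mutually crossing.

    A structure is k-noncrossing iff its crossing number is < k.
    Pairwise crossing of arcs is equivalent to mutual crossing, so this
    is the clique number of the crossing graph.
    """
    arcs = [Arc(*a) for a in arcs]
    if not arcs:
        return 0
    g = nx.Graph()
    g.add_nodes_from(range(len(arcs)))
    for i in range(len(arcs)):
        for j in range(i + 1, len(arcs)):
            if arcs[i].crosses(arcs[j]):
                g.add_edge(i, j)
    return max(len(c) for c in nx.find_cliques(g))


def lgraph(S: Structure) -> nx.Graph:
    """L(S): one vertex per arc, edges between crossing arcs."""
    g = nx.Graph()
    arcs = S.sorted_arcs()
    g.add_nodes_from(arcs)
    for i in range(len(arcs)):
        for j in range(i + 1, len(arcs)):
            if arcs[i].crosses(arcs[j]):
                g.add_edge(arcs[i], arcs[j])
    return g


# ---------------------------------------------------------------------------
# stacks, stems, core


def stacks_and_stems(S: Structure) -> tuple[list[Stack], list[Stem]]:
    """Decompose the arc set into maximal stacks and group stacks into
    stems.

    A stack is a maximal run (i, j), (i+1, j-1), ...; stack B continues
    the stem of stack A when B is nested directly below A's innermost
    arc with only unpaired nucleotides in between (on either side, not
    necessarily both).
    """
    S.validate({"consistent"})
    arcset = S.arcs
    stacks: list[Stack] = []
    for a in S.sorted_arcs():
        if Arc(a.l - 1, a.r + 1) in arcset:
            continue  # not the outermost arc of its stack
        run = [a]
        while Arc(run[-1].l + 1, run[-1].r - 1) in arcset:
            run.append(Arc(run[-1].l + 1, run[-1].r - 1))
        stacks.append(Stack(tuple(run)))

    partners = S.partners()

    def _continues(outer: Stack, inner: Stack) -> bool:
        oi, oj = outer.inner
        il, ir = inner.outer
        if not (oi < il and ir < oj):
            return False
        left = range(oi + 1, il)
        right = range(ir + 1, oj)
        return all(partners[p] == 0 for p in left) and all(
            partners[p] == 0 for p in right
        )

    successor: dict[int, int] = {}
    has_pred: set[int] = set()
    for i, outer in enumerate(stacks):
        for j, inner in enumerate(stacks):
            if i != j and _continues(outer, inner):
                successor[i] = j
                has_pred.add(j)
                break

    stems: list[Stem] = []
    for i in range(len(stacks)):
        if i in has_pred:
            continue
        chain = [stacks[i]]
        j = i
        while j in successor:
            j = successor[j]
            chain.append(stacks[j])
        stems.append(Stem(tuple(chain)))
    stems.sort(key=lambda st: st.extent)
    return stacks, stems


def core_and_lgraph(S: Structure) -> tuple[Structure, nx.Graph]:
    """The core c(S) (each maximal stack collapsed to its outermost arc)
    and the L-graph of S itself.

    The diagram length is kept, so core positions coincide with
    positions of S; only the number of arcs shrinks.
    """
    stacks, _ = stacks_and_stems(S)
    core = Structure(
        S.n,
        [st.outer for st in stacks],
        min_arc_length=S.min_arc_length,
        sigma=S.sigma,
        k=S.k,
    )
    return core, lgraph(S)


# ---------------------------------------------------------------------------
# distance and partners


def structure_distance(S1: Structure, S2: Structure) -> int:
    """Number of positions paired differently in S1 and S2.

    A position contributes 1 when it lies in different arcs (type I) or
    is paired in exactly one of the two structures (type II).  This is
    the Hamming distance between partner vectors, hence a metric.
    """
    if S1.n != S2.n:
        raise ValueError(f"length mismatch: {S1.n} != {S2.n}")
    p1, p2 = S1.partners(), S2.partners()
    return sum(1 for w in range(1, S1.n + 1) if p1[w] != p2[w])


def pairing_partner(S: Structure, w: int) -> int:
    """p(S, w): the position paired to w, or 0 if w is unpaired."""
    return S.partner(w)


def restrict(S: Structure, lo: int, hi: int) -> Structure:
    """Restriction of S to the closed interval [lo, hi], re-indexed to
    1..(hi - lo + 1).  Raises if an arc straddles the interval boundary."""
    if not (1 <= lo <= hi <= S.n):
        raise ValueError(f"bad interval [{lo}, {hi}] for n={S.n}")
    arcs = []
    for a in S.arcs:
        inside = (lo <= a.l <= hi, lo <= a.r <= hi)
        if all(inside):
            arcs.append((a.l - lo + 1, a.r - lo + 1))
        elif any(inside):
            raise ValueError(
                f"arc {a} straddles the interval [{lo}, {hi}]"
            )
    return Structure(
        hi - lo + 1,
        arcs,
        min_arc_length=S.min_arc_length,
        sigma=S.sigma,
        k=S.k,
    )
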