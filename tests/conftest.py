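"""Shared fixtures and independent brute-force oracles for the tests.

The helpers here deliberately avoid the package's own enumeration and
scoring paths so they can serve as independent cross-checks.
"""

from __future__ import annotations

import itertools
import random

import pytest

from knotinv.structures import Arc, Structure, parse_structure

PK18_TEXT = "(((..[[[..)))..]]]"


@pytest.fixture
def pk18() -> Structure:
    """18-mer with two crossing 3-stacks: the smallest convenient
    canonical pseudoknot."""
    return parse_structure(PK18_TEXT)


@pytest.fixture
def hairpin12() -> Structure:
    return parse_structure("((((....))))")


@pytest.fixture
def rng() -> random.Random:
    return random.Random(42)


def brute_force_diagrams(
    n: int, min_arc_length: int = 2, max_crossing: int | None = 2
) -> list[Structure]:
    """Every diagram of length n with vertex degree <= 1, no (i, i+1)
    arc and optionally bounded mutual crossing.  Straightforward
    recursion over the first free position; independent of the package
    enumerator."""
    out: list[Structure] = []

    def mutually_crossing_bound_ok(arcs: list[Arc]) -> bool:
        if max_crossing is None:
            return True
        for size in range(max_crossing + 1, len(arcs) + 1):
            for sub in itertools.combinations(arcs, size):
                if all(a.crosses(b) for a, b in itertools.combinations(sub, 2)):
                    return False
        return True

    def rec(pos: int, arcs: list[Arc], used: set[int]):
        if pos > n:
            if mutually_crossing_bound_ok(arcs):
                out.append(Structure(n, arcs))
            return
        if pos in used:
            rec(pos + 1, arcs, used)
            return
        rec(pos + 1, arcs, used)  # leave unpaired
        for q in range(pos + min_arc_length, n + 1):
            if q not in used:
                rec(pos + 1, arcs + [Arc(pos, q)], used | {pos, q})

    rec(1, [], set())
    return out


def brute_force_crossing_number(arcs) -> int:
    """Largest set of pairwise crossing arcs, by explicit subset search."""
    arcs = [Arc(*a) for a in arcs]
    best = 0
    for size in range(1, len(arcs) + 1):
        for sub in itertools.combinations(arcs, size):
            if all(a.crosses(b) for a, b in itertools.combinations(sub, 2)):
                best = max(best, size)
    return best


def random_structures(count: int, n_range=(10, 30), pk_fraction=0.4, seed=7):
    """Deterministic batch of validator-clean structures."""
    from knotinv.fixtures import FixtureSpec, random_structure

    lo, hi = n_range
    out = []
    master = random.Random(seed)
    for i in range(count):
        n = master.randint(lo, hi)
        spec = FixtureSpec(
            n=n,
            max_stems=2,
            allow_pseudoknot=master.random() < pk_fraction,
            seed=master.randrange(2**31),
        )
        out.append(random_structure(spec))
    return out
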