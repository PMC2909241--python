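"""Deterministic generation of valid test structures.

Random targets are assembled from stem placements (stacks of at least
``sigma`` pairs, minimum arc-length respected), optionally with one
crossing stem pair so that pseudoknotted targets are produced.
Placement is by seeded rejection sampling with a constructive fallback,
so the generator is total on any feasible spec and reproducible:
identical spec and seed yield identical structures.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .structures import Arc, Structure, parse_structure

__all__ = ["FixtureSpec", "random_structure", "worked_examples", "min_stem_span"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one random target draw."""

    n: int
    max_stems: int = 2
    allow_pseudoknot: bool = False
    sigma: int = 3
    min_arc_length: int = 4
    seed: int = 0


def min_stem_span(sigma: int, min_arc_length: int) -> int:
    """Positions spanned by the smallest admissible stack: the innermost
    arc needs arc-length >= min_arc_length below sigma stacked pairs."""
    return 2 * (sigma - 1) + min_arc_length + 1


def _stack_arcs(i: int, j: int, s: int) -> list[Arc]:
    return [Arc(i + t, j - t) for t in range(s)]


def _try_place(
    rng: random.Random, spec: FixtureSpec, want_cross: bool
) -> list[Arc] | None:
    n = spec.n
    span = min_stem_span(spec.sigma, spec.min_arc_length)
    if n < span:
        return []
    n_stems = rng.randint(1, spec.max_stems)
    chosen: list[tuple[int, int, int]] = []
    arcs: list[Arc] = []
    used: set[int] = set()
    for _ in range(n_stems):
        for _attempt in range(30):
            s = rng.randint(spec.sigma, spec.sigma + 1)
            width = 2 * (s - 1) + spec.min_arc_length
            if width + 1 > n:
                continue
            i = rng.randint(1, n - width)
            j = rng.randint(i + width, n)
            block = set(range(i, i + s)) | set(range(j - s + 1, j + 1))
            if block & used:
                continue
            new = _stack_arcs(i, j, s)
            crossing = any(a.crosses(b) for a in new for b in arcs)
            if crossing and not spec.allow_pseudoknot:
                continue
            cand = Structure(
                n,
                arcs + new,
                sigma=spec.sigma,
                min_arc_length=spec.min_arc_length,
            )
            if not cand.is_valid():
                continue
            chosen.append((i, j, s))
            arcs.extend(new)
            used |= block
            break
    if not arcs:
        return None
    if want_cross and not any(
        a.crosses(b) for a in arcs for b in arcs
    ):
        return None
    return arcs


def random_structure(spec: FixtureSpec) -> Structure:
    """Draw a validator-clean structure for the spec.

    With ``allow_pseudoknot`` and room for two stems, roughly half of
    the draws are required to contain a crossing stem pair.  Falls back
    to a single minimal left-anchored stack (or the empty structure when
    even that does not fit).
    """
    rng = random.Random(spec.seed)
    span = min_stem_span(spec.sigma, spec.min_arc_length)
    want_cross = (
        spec.allow_pseudoknot
        and spec.max_stems >= 2
        and spec.n >= 2 * span  # room for two interleaved stems
        and rng.random() < 0.5
    )
    for _ in range(200):
        arcs = _try_place(rng, spec, want_cross)
        if arcs is None:
            continue
        s = Structure(
            spec.n, arcs, sigma=spec.sigma, min_arc_length=spec.min_arc_length
        )
        if s.is_valid():
            return s
    if spec.n >= span:
        arcs = _stack_arcs(1, span, spec.sigma)
        return Structure(
            spec.n, arcs, sigma=spec.sigma, min_arc_length=spec.min_arc_length
        )
    return Structure(
        spec.n, (), sigma=spec.sigma, min_arc_length=spec.min_arc_length
    )


def worked_examples() -> list[tuple[str, object]]:
    """Small fixtures reconstructible from the literature on this
    structure class.

    * ``fig5_triple`` -- three mutually crossing arcs (1,7), (4,9),
      (5,11): the canonical 3-crossing witness (validation relaxed).
    * ``fig20_conflict`` -- the mutation scenario where the target pairs
      (5, 9) while a competitor pairs (5, 10): G-C at (5, 9) keeps the
      target compatible and breaks the competitor.
    * ``pk18`` -- an 18-mer with two crossing 3-stacks, the smallest
      convenient canonical pseudoknot used throughout the tests.
    """
    fig5 = Structure(11, [(1, 7), (4, 9), (5, 11)])
    fig20 = {"target_arc": Arc(5, 9), "competitor_arc": Arc(5, 10)}
    pk18 = parse_structure("(((..[[[..)))..]]]")
    return [
        ("fig5_triple", fig5),
        ("fig20_conflict", fig20),
        ("pk18", pk18),
    ]
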