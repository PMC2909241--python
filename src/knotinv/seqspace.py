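"""Compatible sequences and their neighborhood structure.

A sequence over {A, C, G, U} is *compatible* with a structure when every
arc carries one of the six allowed pairs (Watson-Crick plus the G-U
wobble).  Compatible sequence space is viewed as a product of a
four-letter cube over the unpaired positions and a six-letter cube over
the arcs: a u-neighbor changes one unpaired base, a p-neighbor replaces
the pair on one arc by one of the other five allowed pairs (Hamming
distance one or two on the letter level).
"""

from __future__ import annotations

import random

from .structures import Structure

__all__ = [
    "ALPHABET",
    "ALLOWED_PAIRS",
    "can_pair",
    "is_compatible",
    "make_start",
    "compatible_neighbors",
    "compatible_distance",
]

ALPHABET = "ACGU"

#: the six ordered allowed base pairs
ALLOWED_PAIRS: tuple[tuple[str, str], ...] = (
    ("A", "U"),
    ("C", "G"),
    ("G", "C"),
    ("G", "U"),
    ("U", "A"),
    ("U", "G"),
)

_PAIR_SET = frozenset(ALLOWED_PAIRS)


def can_pair(x: str, y: str) -> bool:
    """True iff (x, y) is one of the six allowed ordered pairs."""
    return (x, y) in _PAIR_SET


def _check_sequence(s: str) -> None:
    bad = set(s) - set(ALPHABET)
    if bad:
        raise ValueError(f"sequence contains letters outside ACGU: {sorted(bad)}")


def is_compatible(s: str, S: Structure) -> bool:
    """True iff every arc (i, j) of S carries an allowed pair (s_i, s_j)."""
    _check_sequence(s)
    if len(s) != S.n:
        raise ValueError(f"sequence length {len(s)} != structure length {S.n}")
    return all(can_pair(s[a.l - 1], s[a.r - 1]) for a in S.arcs)


def _require_compatible(s: str, S: Structure) -> None:
    if not is_compatible(s, S):
        raise ValueError("sequence is not compatible with the structure")


def make_start(S: Structure, rng: random.Random) -> str:
    """Draw a structure-compatible sequence uniformly at random: each
    unpaired position uniform over the four bases, each arc uniform over
    the six allowed pairs, all independent."""
    partners = S.partners()
    chars = [""] * S.n
    for w in range(1, S.n + 1):
        if partners[w] == 0:
            chars[w - 1] = ALPHABET[rng.randrange(4)]
    for a in sorted(S.arcs):
        x, y = ALLOWED_PAIRS[rng.randrange(6)]
        chars[a.l - 1] = x
        chars[a.r - 1] = y
    return "".join(chars)


def compatible_neighbors(s: str, S: Structure) -> list[str]:
    """All compatible neighbors of s: three u-neighbors per unpaired
    position and five p-neighbors per arc."""
    _require_compatible(s, S)
    partners = S.partners()
    out: list[str] = []
    for w in range(1, S.n + 1):
        if partners[w] == 0:
            for b in ALPHABET:
                if b != s[w - 1]:
                    t = s[: w - 1] + b + s[w:]
                    out.append(t)
    for a in sorted(S.arcs):
        cur = (s[a.l - 1], s[a.r - 1])
        for p in ALLOWED_PAIRS:
            if p != cur:
                t = list(s)
                t[a.l - 1], t[a.r - 1] = p
                out.append("".join(t))
    return out


def compatible_distance(s: str, t: str, S: Structure) -> int:
    """Minimum number of u-/p-moves transforming s into t within C[S].

    Unpaired positions contribute one move per differing base; each arc
    contributes one move when its pairs differ (any allowed pair reaches
    any other allowed pair in a single compensatory move).
    """
    _require_compatible(s, S)
    _require_compatible(t, S)
    if len(s) != len(t):
        raise ValueError("sequences differ in length")
    partners = S.partners()
    d = sum(
        1
        for w in range(1, S.n + 1)
        if partners[w] == 0 and s[w - 1] != t[w - 1]
    )
    d += sum(
        1
        for a in S.arcs
        if (s[a.l - 1], s[a.r - 1]) != (t[a.l - 1], t[a.r - 1])
    )
    return d
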