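# Methods

## Structure model

A structure of length n is a diagram: vertices 1..n, arcs (i, j) with
i < j in the upper half-plane, each vertex incident to at most one arc.
Coordinates are 1-based and intervals [i, j] are closed.  The default
validator accepts exactly the diagrams with

* degree ≤ 1 and no arc (i, i+1),
* arc-length j − i ≥ 4,
* no three mutually crossing arcs (3-noncrossing),
* every maximal stack of size ≥ σ = 3 (canonical).

`min_arc_length`, `sigma` and `k` are validator parameters carried on
the `Structure` (defaults 4, 3, 3) so that shorter illustrative
examples remain constructible with validation relaxed; they do not take
part in equality.  The empty structure is valid for every n.
`Structure` construction is deliberately permissive — arc perturbation
(below) produces transiently inconsistent diagrams that must exist as
objects before they are filtered out.

Because pairwise-crossing arcs are automatically *mutually* crossing
(sort a pairwise-crossing set by left endpoint and the definition
follows), the crossing number is the clique number of the crossing
graph; `crossing_number` uses networkx clique enumeration and is
cross-checked against an explicit subset search in the tests.

Dot-bracket output assigns bracket families greedily: arcs in order of
left endpoint, each taking the lowest-index family among `()`, `[]`,
`{}` whose already-assigned arcs it does not cross.  Three families
have always sufficed for 3-noncrossing inputs in practice; the writer
raises if they do not.  On input, each family is matched independently
by nesting (LIFO); the parser does not attempt to re-page ill-paged but
matchable inputs, and whitespace is ignored (`.` is accepted as a
synonym of `:` for unpaired positions).

## Loop decomposition

Every 3-noncrossing structure has a unique decomposition into hairpin,
interior, multi- and pseudoknot loops.  The implementation:

1. An arc α is a *pseudoknot arc* when it is minimal β-crossing for
   some β: α crosses β and no other arc crossing β is strictly nested
   inside α.  The partial order on arcs is nesting (α′ ≺ α iff α′
   strictly inside α), so the minimal crossing arcs are the innermost
   ones — stacked copies above them are not minimal and stay in
   interior loops.
2. Pseudoknot loops are the connected components of the crossing
   (dependency) graph restricted to pseudoknot arcs; each claims, in
   addition, every unpaired position inside its span that no
   hairpin/interior/multi-loop claims.
3. Every other arc closes exactly one classical loop, determined by its
   direct children in the nesting forest (parent = smallest-span arc
   strictly containing a position or arc, ties towards the larger left
   endpoint): no children → hairpin; exactly one child arc → interior
   (also when that child is a pseudoknot arc, which is how stacks
   continue above a knot); otherwise multi-loop, where children
   belonging to one pseudoknot loop count as a single branch.

For the arc-partition invariant each loop *owns* its closing arc(s)
only — a hairpin its arc, an interior/multi-loop its outer arc, a
pseudoknot loop its whole crossing set; nested branch arcs are recorded
separately as `inner_arcs`.  This makes Σ|arcs| over loops equal the
total arc count exactly.

Loops are ordered linearly: a loop nested (by span) inside another
precedes it; otherwise the earlier start-point wins.  The interval
sequence for the local search emits, per ordered loop, the loop span
widened transitively to whole stems — and across crossings to whole
pseudoknot groups, so no interval ever cuts an arc — followed by the
same interval extended over adjacent unpaired runs; duplicates are
dropped and the final interval is always [1, n].  A consequence is that
all loops of one stem collapse into a single interval, and an entire
pseudoknot becomes one interval: the knot is treated as one energetic
unit, which matches the additivity assumption (crossing stems are not
energy-independent of each other).

## Sequence space

Compatibility uses the six ordered pairs A-U, U-A, G-C, C-G, G-U, U-G.
A compatible sequence decomposes into independent coordinates: one
4-letter coordinate per unpaired position, one 6-letter coordinate per
arc.  `make_start` draws each coordinate uniformly and independently —
the tests verify the marginals with chi-square at α = 0.01 on 10,000
draws.  Neighborhoods follow the coordinate view: 3 u-neighbors per
unpaired position, 5 p-neighbors per arc (a single compensatory move
may change both endpoint letters).  The compatible distance is the
Hamming distance over coordinates, which equals BFS distance in the
neighbor graph (verified exhaustively on a small structure).

A caveat discovered by enumeration: Watson-Crick pairs have exactly one
p-neighbor at letter-Hamming distance 1, but wobble pairs have two
(G-U reaches both G-C and A-U in one letter).  The counting tests state
the Watson-Crick case.

## Folding oracle and energy model

The search depends only on the oracle contract
`(sequence, N) -> FoldResult` (energy-sorted, first element the mfe);
any external folder can be adapted behind it.  The reference oracle is
exhaustive: structures are enumerated as sets of maximal stacks
(position-disjoint, non-merging, jointly 3-noncrossing — a 3-crossing
needs arcs from three distinct stacks, so it suffices that no two
existing arcs crossing a new arc cross each other), which is feasible
up to the configured limit n ≤ 26 (15,562 structures at n = 24).

The energy is additive over the loop decomposition, in dimensionless
units chosen to mirror the relative magnitudes of nearest-neighbor
rules:

| term | value |
| --- | --- |
| stacked adjacent arcs | −(w₁ + w₂)/2, w(GC) = 3, w(AU) = 2, w(GU) = 1 |
| hairpin loop | +3 |
| interior loop | +0.5 per unpaired member |
| multi-loop | +4 |
| pseudoknot loop | +7 |

The pseudoknot penalty is deliberately harsh so that crossing stems
appear in the mfe only when the sequence strongly supports both stems —
e.g. two crossing GC 3-stacks score −12 + 7 = −5 against −3 for either
stem alone.  A minimal GU-only helix scores +1 and never forms, and an
AU/GU mixed 3-stack ties the open chain at 0; ties are broken by the
lexicographic order of the sorted arc list (empty structure first), so
repeated folds are bit-identical.

Per-length scoring tables are compiled once (per-structure constants
plus per-arc stacking coefficients) and evaluated with vectorized numpy
gathers, giving ~3 ms folds at n = 24 after a one-time table build.

## The search

`SearchConfig` defaults: N = 50 suboptimal structures, acceptance
window 5, uphill acceptance probability 0.1, at most 5 mutation
retries per iteration, adjustment bound max(50, n) iterations, and a
per-interval phase budget of 10 × interval length.  A single seeded
`random.Random` is threaded through every stochastic choice, so a
(target, seed) pair fully determines the run.

The adjustment stage accepts a mutated sequence when its mfe distance
to the target is ≤ d_min + window (the prose bound; the pseudocode-style
strict bound differs by one and the prose was followed); after the
retry budget the distance-minimizing variant is kept regardless.  The
mutation step processes each target pair once, at its left endpoint,
and redraws a different compatible pair preferring choices incompatible
with every conflicting competitor; when no fully breaking choice exists
(competitor partner bases {G, U} cover the whole alphabet, or the only
breaking pair is the current one) it breaks as many competitors as
possible, ties resolved by the RNG.  Distances are always measured
against the mfe structure only.

The local search compares the folded subsequence against the target
restricted to the interval (safe, because intervals never cut arcs) and
mutates only mismatching positions and their neighbors, in an order
randomized per phase.  Strict improvements restart the phase; moves
with d_min < d < d_min + window restart it with probability
`p_accept`; among distance ties the candidate with the lowest
subsequence mfe energy is kept.  If the locally searched sequence ends
farther from the target than the adjusted one, the driver returns the
better of the two.

## Fixture generation

Random targets are built from one or two stem placements (stack size
σ or σ+1, minimum arc-length respected) by seeded rejection sampling
with up to 200 attempts, optionally forcing one crossing stem pair
(probability 1/2 when a pseudoknot is allowed and fits); a constructive
fallback places a single minimal left-anchored stack, or returns the
empty structure when even that does not fit (n < 9 at the defaults).
Uniformity over the target class is *not* claimed — validity and
determinism are the requirements; identical spec + seed reproduce the
fixture exactly.

What the generator emulates: short canonical targets with realistic
stem/loop geometry and simple H-type-like knots.  What it does not:
natural base-composition biases, long-range multi-branch architectures
beyond two stems, and thermodynamic (Turner) energetics — the bundled
energy model is a structural toy.  Passing the design experiment
therefore demonstrates the correctness and effectiveness of the search
machinery against a consistent oracle, not wet-lab designability of the
sequences.

## Problem sizes and verification

The shipped experiments use: oracle-equivalence over 50 random
sequences with 9 ≤ n ≤ 16 against a brute-force minimum of the
loop-wise energy; decomposition soundness over 200 generated structures
with n ≤ 40; distance-metric axioms exhaustively over all diagrams of
length 8 (vectorized partner-vector comparison); and the design
experiment over 50 generated targets with 10 ≤ n ≤ 24 (about 40%
drawn with a knot allowed), every reported success re-certified by
scanning the exhaustive enumeration for a lower-energy compatible
structure.  `scripts/acceptance.py` recomputes all of these from a
single `--seed`.

## Known limitations

* The exhaustive oracle caps practical target lengths at ~26 nt; longer
  targets need an external oracle behind the adapter contract.
* Diagrams with ≥ 3 mutual crossings are rejected, not processed.
* The loop-ordering comparator resolves span overlaps (possible between
  a pseudoknot loop and loops of its partner stems) by start-point;
  this is a total order in all generated cases but is not proven
  transitive for adversarial span patterns.
* No GC-content or sequence-constraint handling, and no batch design
  optimization.
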