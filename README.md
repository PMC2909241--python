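# knotinv

Inverse folding of RNA **pseudoknot** structures: given a target
structure that may contain cross-serial base pairs, find RNA sequences
whose minimum-free-energy (mfe) fold equals the target.

Classical inverse-folding tools (RNAinverse, RNA-SSD, INFO-RNA) are
limited to secondary structures — noncrossing base pairings.  Many
functional RNAs (tRNA mimics, ribosomal frameshift elements, telomerase
RNA) depend on pseudoknots, i.e. crossing arcs in the diagram
representation.  `knotinv` designs sequences for the class of
**3-noncrossing, canonical** structures: diagrams over positions
1..n with

* vertex degree ≤ 1 and no arc (i, i+1),
* no three mutually crossing arcs (k = 3),
* minimum arc-length 4 (an arc (i, j) has arc-length j − i),
* every stack of at least σ = 3 parallel base pairs.

## The method

A target T is parsed from an extended dot-bracket string over
`:()[]{}` (or bpseq/CT).  The design loop is a stochastic local search
built on three components:

1. **Unique loop decomposition.**  Every 3-noncrossing structure
   decomposes uniquely into hairpin, interior, multi- and pseudoknot
   loops; pseudoknot loops are irreducible sets of crossing arcs
   (minimal β-crossing arcs, grouped by connectivity of the crossing
   graph).  Energies are additive over loops, so the target can be
   optimized interval by interval.
2. **Competitor perturbation (ADJUST-SEQ).**  Starting from a uniformly
   random T-compatible sequence, the current sequence λ is folded into
   its N = 50 lowest-energy structures.  Each arc a of each suboptimal
   fold is perturbed into the ten structures ν(S, a) (nine one-step
   endpoint displacements plus removal); after discarding inconsistent
   structures, structures incompatible with λ and the target itself,
   the surviving *competitors* C(λ) drive a mutation step: at every
   position where some competitor pairs differently from T, the base
   (or base pair, redrawn at the left endpoint) is resampled so that λ
   stays T-compatible while breaking compatibility with as many
   competitors as possible.
3. **Interval-wise local search (LOCAL-SEARCH).**  The ordered loops of
   T induce a nested interval sequence I₁ ⊆ … ⊆ I_m = [1, n] (loops are
   widened to whole stems, and across crossings to whole pseudoknot
   groups, so intervals never cut an arc).  Each interval is optimized
   by random T-compatible mutations at positions that pair incorrectly
   (or next to them), accepting improvements in structure distance
   always, bounded uphill moves with probability 0.1, and resolving
   distance ties towards the lowest mfe.

Folding is delegated to a pluggable **oracle** — any callable
`(sequence, N) -> FoldResult`.  The bundled reference oracle
exhaustively enumerates all admissible structures (practical up to
n ≈ 26) and scores them with an additive loop-based energy
(dimensionless): stacked pairs contribute −(w₁+w₂)/2 with
w(GC) = 3, w(AU) = 2, w(GU) = 1; hairpin +3, interior +0.5 per unpaired
base, multi-loop +4, pseudoknot +7.

The structure distance d(S₁, S₂) counts positions paired differently —
the Hamming distance between pairing-partner vectors, a metric.

## Worked example

```python
from knotinv import SearchConfig, fold, inverse_fold, parse_structure, write_structure

T = parse_structure("(((..[[[..)))..]]]")     # an 18-mer pseudoknot
result = inverse_fold(T, SearchConfig(seed=1))
print(result.success, result.sequence, result.distance, result.energy)
# True UCUUAUCACCGGGCCUGA 0 -2.0
```

The returned sequence folds back into the target exactly
(`result.distance == 0`); its mfe energy is −2.0 and the mfe structure
rendered with `write_structure(result.mfe)` is
`(((::[[[::)))::]]]` — the target, with the crossing stem written as a
second bracket family.  Forward folding shows the energy ranking:

```python
for cand in fold("GGGGAAAACCCC", 3):
    print(write_structure(cand.structure), cand.energy)
# ((((::::)))) -6.0
# (((:::::))): -3.0
# (((::::::))) -3.0
```

The same functionality is exposed on the command line:

```
knotinv design --target "(((..[[[..)))..]]]" --seed 1
knotinv fold --seq GGGGAAAACCCC --num 3
knotinv decompose "(((..[[[..)))..]]]"
knotinv distance "((((....))))" "::::::::::::"
knotinv fixtures --n 20 --count 5 --pseudoknot --out fixtures/
```

`knotinv design` prints a JSON run report and exits non-zero when the
target was not hit.

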