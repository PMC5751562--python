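# Methods

## Problem and utility model

`hugseq` mines *high-utility gene-regulation sequential patterns* from
time-course expression data. Each patient's trajectory is reduced to an
ordered list of **genesets**: the set of regulation items (gene, up/down)
active at each time sample, annotated with the magnitude of the signed fold
change against the first (baseline) sample. A disease-specific
**gene-importance table** (DisGeNET-style scores in [0, 1]) supplies the
external utility; the fold-change magnitude is the internal utility.

For an item *g* at time sample *d* of patient *r*:

    GU(g, P_r^d) = f(GI(g), IGU(g, P_r^d))        with  f(x, y) = x · y

The combiner *f* is pluggable (any two-argument function); the product is the
default and the only form the tests pin. Utilities aggregate as:

* geneset (element) utility: sum of the matched items' utilities — items of
  the geneset not named by the element do not count;
* occurrence utility: sum over the pattern's elements, one matched geneset
  per element at strictly increasing time samples;
* in-patient utility `GU(α, P_r)`: **maximum** over all occurrences
  (the pattern is credited with its best embedding);
* dataset utility `GU(α, D)`: **sum** of in-patient utilities.

A pattern is a top-k pattern when fewer than k patterns have strictly
greater dataset utility; the fixed-threshold mode instead returns every
pattern with `GU(α, D) ≥ δ` (inclusive).

## Preprocessing

Fold changes are signed ratios against the baseline sample: `r = v(t)/v(0)`
reported as `r` when `r ≥ 1`, else `−1/r`, so induction and repression are
symmetric around ±1 and the baseline column is exactly 1. Non-positive
values (zero baselines or zero measurements) follow a configurable policy:
drop the trajectory (default), substitute an epsilon, or fail.

Discretization at a regulation threshold `γ > 1` (default 1.5) keeps a cell
as an up-item when `f > γ` and as a down-item (with internal utility `|f|`)
when `f < −γ`; the comparison is **strict**, so `±γ` counts as "normal".
Sub-threshold items are removed *before* any utility is computed; the
worked-example utilities reproduce only under this order of operations.
Empty genesets are dropped; patients left empty are kept as empty sequences.

## Search

The miner explores a lexicographic pattern tree. Each node carries a
*sequence utility list*: `(patient, last time sample, occurrence utility)`
tuples keeping only the maximal utility per (patient, last time sample).
Dominated partial occurrences are discarded safely because any extension
adds the same suffix utility to every occurrence ending at the same sample,
so only the per-sample maximum can ever produce the per-patient maximum.
Children come from an **I-step** (add one item to the last element; only
items lexicographically greater than the current last item, so each pattern
is generated exactly once) or an **S-step** (open a new singleton element at
a strictly later sample, keeping the best predecessor utility per landing
sample).

A fixed-capacity **top-k list** holds the best k patterns seen, deduplicated
by pattern identity; the dynamic threshold `minUtil` is the k-th utility
once full and never decreases. Rank-boundary ties resolve to the
lexicographically smallest pattern (the `rank, pattern` order is total, so
runs are deterministic).

The **rest utility** of a node,

    Ψ(α, P_r) = GU(α, P_r) + GU(restSeq(P_r, α)),    Ψ(α, D) = Σ_r Ψ(α, P_r),

adds the total item utility of the suffix starting at the last geneset of
the *first* (earliest-ending) occurrence; ties among earliest-ending
embeddings go to the lexicographically smallest time-sample vector so the
rest sequence is well defined. `Ψ(α, D)` upper-bounds `GU(β, D)` for every
extension β of α. The search prunes a subtree whenever `Ψ < minUtil` —
sound by the bound, and applied in every mode (the threshold mode prunes
against δ). Two optional strategies accelerate the threshold's rise
without changing the output:

* **PES** (pre-evaluation) seeds the top-k list before the tree is built
  with every single-item pattern at its exact utility and every
  whole-patient sequence at its summed item utility. The whole-sequence
  value is a lower bound of that pattern's true dataset utility; seeding it
  *as a pattern entry* (rather than an anonymous value) keeps the threshold
  sound even when two seeds coincide on the same pattern, and the tree later
  revisits the pattern with its exact utility whenever it matters.
* **RSO** expands sibling extensions in descending `Ψ` order (ties: S-steps
  before I-steps, then item order), so high-utility regions are reached
  while the threshold is still rising.

### Pattern size cap

`max_size` bounds the **total item count** of a pattern. Each tree step adds
exactly one item, so the cap bounds search depth uniformly across element
growth and sequence growth; the brute-force oracle applies the same cap.
When the cap is active, PES skips whole-sequence seeds with more items than
the cap (their patterns would be unreachable, and an unreachable seed could
otherwise survive into the reported top-k with a stale lower-bound value).
Mining mode default is uncapped; the cap exists for oracle-comparable runs
and desk-scale experiments.

### Numerical policy

Utilities are floats; all equality/ordering decisions (top-k ranking,
threshold comparisons, pruning) use values rounded to 1e−9. Rounding is
monotone, so the pruning argument survives quantization, and the miner and
the oracle — which accumulate sums in different orders — agree exactly on
ranked output. Tests compare utilities at an absolute tolerance of 1e−9.

## Brute-force oracle

`oracle.enumerate_patterns` regenerates every pattern by direct subsequence
enumeration (per patient: every strictly increasing choice of genesets,
every non-empty item subset per chosen geneset) and accumulates per-pattern
per-patient maxima. It shares only the elementary utility arithmetic with
the miner — none of the utility-list joins — so miner-vs-oracle agreement is
a genuine dual-route check. A work cap (default 2·10⁶ visited embeddings)
makes the enumerator refuse non-toy inputs explicitly.

## Synthetic data

The generator emulates a time-course microarray study: log-normal baseline
intensities per (patient, gene) (default log-mean 5.5 ≈ 245 intensity
units, log-sd 0.6), i.i.d. multiplicative log-normal noise per later time
sample (default log-sd 0.25, making ≈10 % of background cells cross
γ = 1.5 in either direction), and planted patterns written multiplicatively
(`baseline · m` for up, `baseline / m` for down, default m = 3) so that
fold-change computation followed by discretization recovers the planted
items exactly regardless of noise elsewhere. Planted genes score 0.9
importance; background genes draw from U(0.05, 0.3). A truth record lists
every realized injection site.

The standard benchmark plants two two-element patterns on disjoint genes in
disjoint five-patient blocks of a 10-patient × 20-gene × 8-sample study.
Disjoint blocks are essential for recovery experiments: if two planted
patterns shared patients, the interleaving of their items would itself be a
pattern of strictly higher utility, and "the planted patterns are exactly
the top-k" would be false by construction.

What the generator does **not** emulate: probe effects, dye bias,
normalization artifacts, missing values, correlated co-regulation of
background genes. Passing recovery tests therefore show that the search
finds what the utility model values — not that the utility model is a
validated biomarker-discovery method on real cohorts.

## Evaluation metrics

Against a ranked disease-gene list of length R (rank 1 best), an item of a
listed gene weighs `R − rank + 1`, an unlisted gene weighs 1, and both
regulation directions share the gene's weight. Pattern popularity is the
mean weight over all items, repeats included — a literal item-wise sum, so a
gene appearing in several elements counts each time. The composites are
plain harmonic means, `GU-Pop = 2·GU·Pop/(GU+Pop)` and analogously
`Sup-Pop`, defined as 0 when the denominator vanishes. A support-ranked
exhaustive top-k (ties by utility, then pattern order) serves as the
frequency-based comparator.

## Test problem sizes

The completeness and bound-soundness suites run 20 generator-seeded studies
of 4 patients × 3 genes (6 regulation items) × 5 time samples at noise 0.6,
with k ∈ {1, 3, 5, 10}, size cap 4, and all four strategy combinations —
small enough for exhaustive enumeration, dense enough that pruning and
tie-breaking are exercised. Efficiency-direction checks use the standard
benchmark at size cap 3 and k = 5. With that cap in place PES adds nothing
over the baseline's own level-1 seeding (whole-sequence seeds exceed the
cap), so its candidate count ties the baseline and the assertion is the
ordering PES+RSO ≤ PES ≤ baseline; PES's separate benefit appears in
uncapped runs where whole sequences are seedable.

## Known limitations

* The miner is pure Python and intended for cohort-scale, not
  compendium-scale, inputs; no parallelism.
* Pattern utilities assume the best-occurrence semantics; alternatives
  (sum over occurrences) are not implemented.
* The importance table is static per run; time-varying or condition-specific
  importance is out of scope.
* Probe-to-gene mapping, normalization and imputation are upstream concerns;
  the pipeline starts from expression values it takes at face value.
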