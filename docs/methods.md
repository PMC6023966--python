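# Methods

## Problem setting

A miRNA-based cell classifier is a synthetic gene circuit that senses the
expression levels of a handful of miRNAs in a living cell and triggers an
output (for instance an apoptosis signal) when the cell's state is
classified as diseased. After binarizing each miRNA level into High (1)
or Low (0), the design problem becomes Boolean function synthesis: find
an f : {0,1}^n → {0,1} in conjunctive normal form — an AND of *gates*,
each gate an OR of possibly negated miRNA literals — whose output matches
the 0/1 annotation of every training sample (a *perfect* classifier), or
misses at most a bounded number of samples (an *imperfect* one,
characterized by false-negative and false-positive counts).

Not every CNF can be built in the lab. The *core constraints* restrict a
design to at most 6 gates with at most 8 inputs overall, and every gate
must match one of a small repertoire of gate types, each described by
five bounds: lower/upper bounds on non-negated and on negated inputs per
gate, plus a cap on how many gates of the type one classifier may use.
The default repertoire has an OR gate (≥1 non-negated inputs, no negated
ones) and a NOT gate (exactly one negated input). Optional extensions are
FN/FP error bounds and a unique-input flag (no miRNA shared across
gates). Per-type occurrence caps default to the gate bound itself — the
least restrictive choice — and are user-overridable in the constraint
config.

## Optimization hierarchy and relaxation

Accuracy sits above simplicity: the solver first fixes the error bounds,
then minimizes structure under one of four strategies — Opt1 (inputs),
Opt2 (gates), Opt3 (inputs then gates), Opt4 (gates then inputs) — or
merely checks feasibility. Bi-level strategies are realized as two
sequential complete solves (fix the upper-level optimum, minimize the
lower level); a test checks this agrees with a one-shot weighted-sum
objective over the feasible set.

When no perfect classifier exists (for example because two identical
profiles carry opposite labels), the error bounds are relaxed stepwise:
(0,0), (1,0), (0,1), (1,1), … The continuation beyond the first totals is
ordered by total error ascending and, within a total, FN-first; the rule
is configurable, and one error axis can be forbidden entirely
(`forbid_fp` / `forbid_fn`). The first step with a solution is returned,
optimized under the chosen strategy.

## The search engine

No off-the-shelf constraint solver is used; the engine is a complete
branch-and-bound written for this gate grammar. Sample sets are encoded
as machine integers (one bit per sample), so "gate true on sample set"
is a single AND/popcount. Classifiers are explored as lexicographically
increasing sequences of distinct gates (duplicate gates are redundant
under conjunction and are excluded), which visits every gate *set*
exactly once. Optimization is iterative deepening over the objective:
the smallest input (or gate) budget admitting a feasible classifier is
the global optimum, and exhausting a level proves the lower bound.

Three prune rules keep the search tractable; each is exact:

1. **FN doom.** While a gate is being built, any still-accepted positive
   sample that no remaining literal can satisfy is a guaranteed false
   negative; the branch dies once these exceed the FN budget. Suffix
   unions of literal masks make this O(1) per step.
2. **Irredundancy (feasibility mode only).** Every gate after the first
   must reject at least one negative sample not rejected by its
   predecessors. Any feasible classifier can be reduced — by deleting
   gates whose negative-rejections are covered by the others — to this
   form without raising errors or worsening the objective, so the rule
   is sound for existence questions.
3. **Superset dominance (feasibility mode only).** A gate already true on
   every accepted positive, whose signature fits a gate type without a
   binding occurrence cap, is never extended: adding literals only
   shrinks its rejection set.

Literals are explored in a static order (descending coverage of the
positive class), which both finds witnesses early and sharpens rule 1.
All-optima enumeration re-runs the search at the proven-optimal budget
with rules 2–3 disabled, then reduces the solutions to isomorphism-class
representatives: literals sorted by (marker token, sign), gates sorted
lexicographically, one canonical representative per class, output in
deterministic text order. The engine contains no randomness; the `seed`
parameter exists for interface stability.

An independent oracle (`brute_force_oracle`) enumerates the entire
structurally valid classifier space by plain combinatorial generation
(guarded to ≤8 markers and ≤4 total inputs) and is compared with the
engine — objective values and full canonical solution sets — across
hundreds of seeded random instances and all five strategies, including
profiles with tight occurrence caps, mixed-sign gate types and the
unique-input flag.

Custom per-miRNA input weights (penalizing or favoring markers) are
supported for the input-minimizing strategies by scanning input-count
levels and bounding the weighted cost from below by count × minimum
weight; this path trades speed for generality and is intended for the
moderate problem sizes where weighting matters.

## Evaluation scores

Boolean setting: FN rate = FN/#positives, FP rate = FP/#negatives, kept
at full precision internally and presented at two decimals, half-up.

Continuous setting: a surrogate output model maps real-valued profiles
through the circuit. Each literal responds with a Hill function of
threshold K (expression units; a natural default is the dataset's
binarization threshold) and steepness k (default 4): activation
x^k/(x^k+K^k), repression K^k/(x^k+K^k). A gate's activation is the max
over its literals (OR), the circuit output is the product of gate
activations times a plateau constant (default 1.0), plus a basal leak
(default 1e-6) that keeps the output strictly positive, as leaky
expression does in practice. In the saturating limit the model
reproduces the Boolean evaluation. The model is a pluggable callable, so
a published mechanistic ODE model can be substituted; published absolute
score values from such models are therefore not comparable to the
surrogate's and are not asserted anywhere.

From the per-sample outputs we compute S_AUC (ROC area of the output as
a ranking score for the positive class, midpoint tie convention, via
scikit-learn), the average margin Ma (mean positive output / mean
negative output), the worst margin Mw (min positive / max negative —
equivalently the smallest output ratio over all positive/negative
pairs), and S_m = λ·Ma + (1−λ)·Mw with λ = 0.5 by default. The margins
are reported either as raw ratios (default, matching the verbal
definition) or log-ratios; λ is applied after the selected transform.
Solution sets are ranked by (S_AUC desc, S_m desc, canonical text asc).

## Synthetic benchmark and cross-validation

Benchmark instances are random 0-1 matrices (i.i.d. fair coins) labeled
by a hidden *annotation classifier*. Setup 1 draws the annotator
gate-by-gate with uniform choices and rejection-samples until it passes
the core constraints, so a zero-error solution always exists. Setup 2
draws up to ⌊n/10⌋ gates ("n" read as the number of miRNA columns) of up
to 5 inputs, keeping each gate and each input with probability 1/2;
markers are assigned uniformly without replacement within a gate, and —
a choice this package makes, since the construction is otherwise
under-determined — each literal's sign is a fair coin. A gate whose
input coins all fail is dropped; if no gate materializes, one
single-input gate is forced (annotation requires a function). The full
published grid runs both axes 10…500 in steps of 10 (2,500 instances);
one instance per cell is shared across solve modes, and
`run_benchmark` checkpoints per instance so interrupted grids resume.

Cross-validation shuffles rows by seed into k contiguous near-equal
parts (sizes differ by ≤1; class balance deliberately ignored, with an
optional stratified mode off by default), solves each training split
with the full relaxation procedure, and counts prediction mismatches on
the held-out part. It is *conservative*: a fold whose solve exhausts its
wall-clock budget contributes its whole held-out part as mismatches, so
timeouts inflate rather than hide the generalization error.

What the generator does not emulate: real miRNA levels are strongly
correlated across markers and samples, classes are heavily imbalanced in
clinical tables, and discretization noise sits near the threshold.
Passing tests on these instances demonstrate the correctness of the
synthesis/score machinery and the planted-solution recovery property,
not clinical performance.

## Problem sizes and numerical choices

The shipped tests verify the engine against the oracle on 200 random
6-marker/8-sample instances, certify optimality by bound tightening,
solve 100 Setup 1 instances at 50×50 under a 5-second per-instance
budget (timeouts are reported, never hidden), and exercise the benchmark
grid at 2×2; these sizes keep the default suite fast while covering
every contract. Ties everywhere are broken deterministically
(lexicographic canonical text); degenerate inputs (single-class
datasets, all-ones matrices, zero-marker tables) are either handled or
rejected with a named error. Report rounding is two decimals, half-up.

## Known limitations

* The engine's worst case is exponential — global optimality over an
  NP-hard space cannot be cheaper; the time limit turns long runs into
  explicit TIMEOUT results instead of silent stalls.
* All-optima enumeration can be large when the optimum is loose (e.g.
  Opt2 with a generous input budget); enumeration respects the time
  limit.
* The continuous scores depend on the surrogate's parameters; they are
  comparative tools for ranking optima, not calibrated predictions of
  circuit chemistry.
* Discretization of continuous data is the user's responsibility; only a
  fixed-threshold helper is provided.
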