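# Methods

## Model

A two-binary-event situation is identified with a point on the
3-simplex: the four joint-cell probabilities
x = (P(A∩B), P(A∩¬B), P(¬A∩B), P(¬A∩¬B)), non-negative and summing to 1.
All other quantities are linear or rational functions of x: marginals are
sums of two cells, conditionals are a cell divided by a marginal.  The
cells are therefore the canonical internal state; everything else is
derived, never stored independently, so the four net rules (line,
triangle, V, X) hold *by construction* for every completed situation —
`check_rules` at tolerance 0 is a tautology there, and is exposed for
auditing hand-filled or perturbed assignments.

## Solver

Each given quantity is translated into one linear equation over x:

* marginal P(Y) = v  →  sum of Y's two cells = v;
* joint = v          →  one cell = v;
* conditional P(X|Y) = v  →  cell(X∩Y) − v·(sum of Y's cells) = 0
  (the multiplication rule, cleared of the denominator — this keeps the
  system linear and is valid even when P(Y) = 0).

Together with normalization Σx = 1 and x ≥ 0, the feasible set is a
polytope.  Exact Gauss–Jordan elimination over `fractions.Fraction`
determines rank and consistency; with full rank the unique solution is
checked for non-negativity, with deficient rank feasibility is decided by
exact Fourier–Motzkin elimination over the free parameters (at most 4
inequalities in 3 variables — no numerical LP is needed or wanted, since
all acceptance values are exact fractions like 8/57).  Status is
*complete* (unique feasible point), *underdetermined* (free dimensions
remain; their count is reported), or *inconsistent* (no feasible point;
diagnostics include any violated rule instances evaluable from the givens,
e.g. four joints summing to 0.9 report an X-rule violation).

Degenerate conditioning is handled explicitly: a conditional *derived* on
a zero-probability event is **undefined** (None), propagates to rendering
as an unlabeled branch, and is an error in natural-frequency conversion; a
conditional *given* for an event the constraints force to probability 0
makes the specification inconsistent.  The test suite cross-checks solver
status against an independent sympy oracle (exact rank plus enumeration of
basic feasible solutions) on randomly drawn small-denominator
specifications.

### Numerics

Internal arithmetic is exact rational throughout.  Decimal strings,
percent strings and fraction strings parse exactly; binary floats are
taken at their shortest round-tripping decimal and flag the specification
as inexact, which switches the inconsistency tolerance from 0 to an
absolute 10⁻⁹ (configurable).  No other tolerances exist in the
completion path.

## Frequencies

`to_frequencies` scales by a population size N with three policies:
`exact` (counts stay rational), `round` (round-half-up per *cell*, then
margins rebuilt by additivity so the table invariants can never break),
and `require_integer` (raises, naming the offending quantity).  A
natural frequency for P(X|Y) is the nested pair (N·P(X∩Y), N·P(Y)) —
"160 out of 1,140" — with the conditioning event as the reference set;
joints and marginals refer to the whole population.  No continuity
correction or pseudo-counts anywhere: frequencies are expected counts, as
in teaching stimuli.

## Diagrams

The four visualizations are built as explicit graphs so that structure is
testable independent of rendering:

* **net** — 9 nodes (1 center, 4 margins on the axes, 4 cells on the
  diagonals at equal radius), 16 branches: 4 marginal (solid), 4 joint
  (dashed, diagonal), 8 conditional (border).  No crossings, no doubled
  node.  Both simple trees, the frequency 2×2 table (corner + margin
  nodes) and the probability 2×2 table (joint branches) are embedded in
  it, and the test suite asserts those embeddings value-by-value.
* **double-tree** — 6 nodes; the total node appears twice (top and
  bottom); the four middle branches carry both reading directions
  (downward P(B|A)-style, upward P(A|B)-style); the A↔¬B and ¬A↔B
  branches cross.
* **tree** — 7 nodes, 6 edges; only 4 of the 8 conditionals fit, which is
  exactly its didactic limitation.
* **2×2 table** — a 4×4 node grid (headers, cells, margins, total), no
  edges; in probability mode it shows joints and marginals but no
  conditional anywhere.

Modes: `prob` labels branches with probabilities, `freq` puts counts in
nodes, `both` does both.  Exact geometry is not prescribed by the
diagrams' printed tradition; the fixed layout table above is this
package's choice.  Percent labels default to one decimal with
trailing-zero trimming (80%, 1.6%, 0.5%), counts use thousands
separators (1,140).

The SVG renderer is deterministic given graph + layout.  In the default
double-tree layout the two upward labels of the crossing branches anchor
at the *same* point — deliberately reproducing the ambiguity of printed
double-trees, where e.g. 86% (P(¬A|B)) and 0.5% (P(A|¬B)) cannot be
assigned to their branches; the `disambiguated` layout pulls each label
toward its lower node, separated by a configurable minimum distance.

## Strategy catalogue and coding

Strategies are stored as expressions over the schematic letter notation
(lowercase probabilities b, c, d, …, q; uppercase counts A, B, …, I) and
evaluated exactly against a task's completed situation; frequency-pair
predictions evaluate against the task's *printed* (possibly rounded)
frequency table, so the economics conditional predicts 205 out of 613
even though 1,000 × 0.2048 = 204.8.  The letters e, h, i / E, H, I are
not fixed by the published tables and are completed by the evident
complement pattern; the two double-tree confusions have no published
formula and are reconstructed from their prose description (I answers
with the other upward conditional l; II applies the multiplication rule
with the swapped branch, e·l) — both are marked interpretive.

Correctness coding generalizes the published rule: an answer is accepted
if it equals the exact value or lies in the rounding interval to the next
full percentage point (granularity 0.1 point when the exact value is
below 1%, so 0.4% accepts 0.4–0.5%); an interval endpoint becomes
*exclusive* when a different catalogued prediction displays as that
endpoint at the same granularity.  This reproduces the one documented
case — 0.5% is the p-error's display value and is rejected for the
mammography joint question — and extends the same logic elsewhere (for
the economics joint question, 12% is excluded because the independence
error 12.39% displays as 12%); where the rule is an extension rather
than a documented bound, it errs on the conservative side.  Classification
matches a probability response to every strategy within 0.5 percentage
points (default) or within that strategy's interval, returns *all*
matches ordered by distance, and leaves ambiguity to the caller; the
built-in `collision_audit` lists prediction pairs closer than the
tolerance (for the mammography joint question: correct/p-error at 0.051
points, correct/double-joint, p-error/double-joint).  Frequency-pair
responses match on exact equality only.  Free-text answers ("algorithm
correct, no result") are out of scope; only numeric responses are coded.

## Task bank and design

The two built-in tasks carry the conventional parameters — mammography:
base rate 2%, sensitivity 80%, false-alarm rate 10%, N = 10,000 (all nine
counts integral); economics course: 32%, 64%, 60%, N = 1,000.  The
economics frequency material prints the rounded count 205 (from 204.8),
making its frequency version minutely inconsistent with its probability
parameters (P(B|A) = 205/320 = 64.06%); the task records this in
`rounding_note`, and a task whose expected counts are non-integral
*must* carry such a note.  Cover stories and question wordings are
stored as fixtures; every statistical number in generated material is
produced by the solver/frequency pipeline, never typed into a template.
Problem documents follow the material's design rule: visualization
versions embed the diagram and omit the statistics sentences.  Question
order is fixed (conditional first, as in the study design the bank
reproduces).  The booklet generator enumerates all assignments in which
one context appears with probabilities and the other with frequencies
and the two visualizations differ, and shuffles them deterministically
by seed; the 16 design cells are all covered.

## Known limitations

* Two binary events only — the net does not extend to 2-test or 3-test
  cascades the way tree diagrams do, and the package does not try.
* Quantities are givens, not estimates: no sampling variability,
  confidence intervals or tests.
* The strategy catalogue encodes the two canonical question templates
  (the inverse conditional P(A|B) and the joint P(A∩¬B)); other targets
  would need their own letter tables.
* The classifier reports ambiguity instead of resolving it; studies that
  need one label per response should take the first match, as the coding
  convention does.
* Generated stimuli are faithful to the printed wording conventions but
  are plain text/SVG; no typesetting, timing or data collection.
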