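# freqnet

Exact completion of two-binary-event probability situations, the
**frequency net** and its companion visualizations, and coding of numeric
answers against the catalogue of correct and erroneous Bayesian
strategies.

## The problem

A situation with two dichotomous events A and B — disease × test result,
course choice × personality trait — carries **16 probabilities**: the four
marginals P(A), P(¬A), P(B), P(¬B), the four joints P(A∩B), P(A∩¬B),
P(¬A∩B), P(¬A∩¬B), and the eight conditionals P(A|B), …, P(¬B|¬A).
Teaching material and diagnostic statistics usually state only a
determining subset — typically the base rate P(A), the sensitivity
P(B|A) and the false-alarm rate P(B|¬A) — and everything else, including
the Bayesian target quantity

```
P(A|B) = P(A)·P(B|A) / (P(A)·P(B|A) + P(¬A)·P(B|¬A))
```

(the positive predictive value), has to be derived. `freqnet` does this
derivation exactly: every given quantity becomes a linear equation over
the four joint cells, the system is solved in rational arithmetic, and
the status (complete / underdetermined / inconsistent) is reported with
diagnostics. Completed situations satisfy, exactly, the four net rules:

* **line rule** — complementary marginals sum to 1,
* **triangle rule** — marginal × conditional = joint,
* **V-rule** — adjoining joints sum to the enclosed marginal,
* **X-rule** — the four joints sum to 1.

On top of the solver the package provides:

* probability ↔ natural-frequency conversion ("160 out of 1,140" instead
  of 14.04%), with exact, rounding, and integers-required policies;
* the four standard visualizations as explicit node/edge graphs — 2×2
  table, tree, double-tree, and the nine-node/sixteen-branch frequency
  net, which uniquely shows all 16 probabilities and all 9 frequencies at
  once — rendered as monospaced text and as SVG;
* an executable catalogue of answer strategies (correct, joint-occurrence,
  Fisherian, base-rate-only, p-/q-/m-/n-errors, independence error,
  double-joint, the two double-tree confusions, …) that predicts each
  strategy's answer for a task and classifies numeric responses,
  including the study-style correctness coding with its exclusive
  interval bounds;
* a task bank (mammography and economics-course contexts) and a balanced
  16-version booklet design generator for the 4 presentations × 2 formats
  × 2 contexts layout.

Intended users: statistics-education and risk-communication researchers
preparing stimuli or coding responses, and anyone who wants exact
contingency-table completion with honest degenerate-case handling.

## Worked example

Put the classic screening parameters in `mam.json`:

```json
{
  "events": {"A": "breast cancer", "notA": "no breast cancer",
             "B": "positive test result", "notB": "negative test result"},
  "given": {"P(A)": "2%", "P(B|A)": "80%", "P(B|notA)": "10%"},
  "N": 10000
}
```

Then `freqnet solve mam.json` prints all sixteen quantities, exactly:

```
status: complete
  P(A) = 0.02 (2%)
  ...
  P(A&notB) = 0.004 (0.4%)
  ...
  P(A|B) = 8/57 (14.04%)
  P(notA|B) = 49/57 (85.96%)
  P(A|notB) = 2/443 (0.45%)
  ...
```

P(A|B) = 8/57 is the positive predictive value: of the 1,140 women in
10,000 with a positive result, only 160 actually have the condition —
about 14%, far below most people's intuition. The same library call is
`freqnet.solve(spec)`; diagrams come from `freqnet render mam.json --kind
net --mode both --out net.svg`.

Classifying a response to the joint question ("negative test result *and*
breast cancer", correct answer 0.4%):

```
$ freqnet classify --task mammography --question joint --answer "0.5%"
coded_correct: False
  p_error  (distance 0.04853 pp)
  correct  (distance 0.1 pp)
  double_joint  (distance 0.3 pp)
```

0.5% is the displayed value of the p-error P(A|¬B) = 2/443, so it is an
expected wrong solution and is excluded from the correct-answer interval
even though it is numerically close to 0.4%.

## Module map

| module | contents |
|---|---|
| `freqnet.quantities` | the 17 quantity identifiers, canonical strings, schematic letter maps |
| `freqnet.situation` | exact types, solver, rule checker, frequency conversion, spec-file I/O |
| `freqnet.diagrams` | graph builders for net / double-tree / tree / 2×2, text and SVG renderers |
| `freqnet.strategies` | strategy catalogue, predictions, classification, correctness coding |
| `freqnet.stimuli` | task bank, problem rendering, booklet design matrix |
| `freqnet.cli` | `freqnet solve / render / classify / stimulus` |

See `docs/methods.md` for the model, the coding rule, and the design
decisions.
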