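"""Catalogue of correct and erroneous Bayesian answer strategies.

The empirical literature on Bayesian reasoning tasks records a stable set
of wrong answers: for a conditional-probability question (the positive
predictive value) people answer with the joint probability, the transposed
conditional ("Fisherian"), the base rate alone, and so on; for a
joint-probability question they answer with one of the two corresponding
conditionals (p-error / q-error), a misread conditional (m-/n-error), the
product of marginals (independence error), or twice the joint
(double-joint error).  Each strategy is encoded here as an executable
definition in the schematic letter notation (lowercase = probabilities,
uppercase = absolute frequencies), so that for any task the strategy's
predicted answer can be computed and numeric responses can be classified.

The two double-tree confusions have no published formula; they are
reconstructed from the prose description of confused crossing branches
(I answers with the other upward conditional l, II multiplies e·l) and
should be read as interpretive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from ._format import round_half_up
from .quantities import LOWERCASE_SYMBOLS, UPPERCASE_SYMBOLS, QuantityId
from .situation import CompletedSituation, FrequencyTable, to_exact_fraction

__all__ = [
    "QuestionSpec",
    "StrategyDefinition",
    "StrategyMatch",
    "ClassificationResult",
    "NotApplicableError",
    "builtin_strategies",
    "predicted_answer",
    "classify",
    "code_correct",
    "coding_interval",
    "collision_audit",
    "classify_table",
]

Number = Union[int, float, Fraction, str]
FrequencyPair = Tuple[int, int]


class NotApplicableError(ValueError):
    """Raised when a strategy has no prediction in the requested format."""


@dataclass(frozen=True)
class QuestionSpec:
    """A question about one target quantity, as posed in a task."""

    target: QuantityId
    answer_format: str  # 'probability' | 'frequency_pair'
    event_order_in_wording: Tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if self.target.kind not in ("conditional", "joint"):
            raise ValueError("question target must be a conditional or joint")
        if self.answer_format not in ("probability", "frequency_pair"):
            raise ValueError(f"unknown answer format {self.answer_format!r}")

    @property
    def kind(self) -> str:
        return self.target.kind


@dataclass(frozen=True)
class StrategyDefinition:
    """A named answer-generating rule, correct or erroneous.

    ``prob_expr`` is an arithmetic expression over the lowercase letters
    (e.g. ``"b*j/(b*j + m*c)"``); ``freq_pair`` a pair of uppercase letters
    read as "X out of Y".  Either may be None ("not applicable")."""

    id: str
    name: str
    question_kind: str  # 'conditional' | 'joint'
    prob_expr: Optional[str]
    freq_pair: Optional[Tuple[str, str]]
    note: str = ""


# Conditional-question catalogue (target: the inverse conditional k).
_CONDITIONAL = [
    StrategyDefinition(
        "correct", "Correct (Bayesian)", "conditional",
        "b*j/(b*j + m*c)", ("F", "D"),
        "k = f/d; the positive predictive value",
    ),
    StrategyDefinition(
        "joint_occurrence", "Joint occurrence", "conditional",
        "b*j", ("F", "A"),
        "answers with the joint f instead of the conditional k",
    ),
    StrategyDefinition(
        "fisherian", "Fisherian (transposed conditional)", "conditional",
        "j", ("F", "B"),
        "answers with j = P(B|A) instead of k = P(A|B)",
    ),
    StrategyDefinition(
        "base_rate_only", "Base rate only / conservatism", "conditional",
        "b", ("B", "A"),
        "repeats the base rate",
    ),
    StrategyDefinition(
        "evidence_only", "Evidence only", "conditional",
        "d", ("D", "A"),
        "answers with the marginal of the evidence event",
    ),
    StrategyDefinition(
        "likelihood_subtraction", "Likelihood subtraction", "conditional",
        "j - m", None,
        "difference of the two likelihoods; probability form only",
    ),
    StrategyDefinition(
        "pre_bayes", "Pre-Bayes", "conditional",
        None, ("B", "D"),
        "frequency form only",
    ),
    StrategyDefinition(
        "pos_rate_over_false_rate", "Correct rate / false-positive rate",
        "conditional", "j/m", None,
        "ratio of the two likelihoods; may exceed 1",
    ),
]

# Joint-question catalogue (target: the joint h = P(A∩¬B)).
_JOINT = [
    StrategyDefinition(
        "correct", "Correct (multiplication rule)", "joint",
        "b*q", ("H", "A"),
        "h = b·q, the asked-for joint probability",
    ),
    StrategyDefinition(
        "q_error", "q-error", "joint",
        "q", ("H", "B"),
        "answers with the conditional q = P(notB|A)",
    ),
    StrategyDefinition(
        "p_error", "p-error", "joint",
        "p", ("H", "E"),
        "answers with the conditional p = P(A|notB)",
    ),
    StrategyDefinition(
        "m_error", "m-error", "joint",
        "m", ("G", "C"),
        "misread negations: answers with m = P(B|notA)",
    ),
    StrategyDefinition(
        "n_error", "n-error", "joint",
        "n", ("I", "C"),
        "misread negations: answers with n = P(notB|notA)",
    ),
    StrategyDefinition(
        "independence_error", "Independence error", "joint",
        "b*e", None,
        "multiplies the associated marginals as if independent",
    ),
    StrategyDefinition(
        "double_joint", "Double joint probability", "joint",
        "2*b*q", None,
        "adds the two (each correct) routes to the joint: twice the answer",
    ),
    StrategyDefinition(
        "double_tree_confusion_I", "Double-tree confusion I", "joint",
        "l", ("G", "D"),
        "p-error with the crossing branches l and p confused (interpretive)",
    ),
    StrategyDefinition(
        "double_tree_confusion_II", "Double-tree confusion II", "joint",
        "e*l", None,
        "multiplication rule with the swapped branch l (interpretive)",
    ),
]


def builtin_strategies(question_kind: Optional[str] = None) -> List[StrategyDefinition]:
    """The built-in catalogue, optionally filtered by question kind."""
    cat = _CONDITIONAL + _JOINT
    if question_kind is not None:
        cat = [s for s in cat if s.question_kind == question_kind]
    return list(cat)


# ---------------------------------------------------------------------------
# evaluation

def _letter_values(situation: CompletedSituation) -> Dict[str, Optional[Fraction]]:
    return {
        letter: situation.value(q) for letter, q in LOWERCASE_SYMBOLS.items()
    }


def _count_values(table: FrequencyTable) -> Dict[str, Union[int, Fraction]]:
    return {letter: table.count(q) for letter, q in UPPERCASE_SYMBOLS.items()}


def _eval_expr(expr: str, values: Dict[str, Optional[Fraction]]) -> Fraction:
    used = {c for c in expr if c.isalpha()}
    for letter in used:
        if values.get(letter) is None:
            raise NotApplicableError(
                f"letter {letter!r} is undefined for this situation"
            )
    return eval(expr, {"__builtins__": {}}, dict(values))  # noqa: S307 — closed letter vocabulary


def predicted_answer(
    strategy: StrategyDefinition,
    task,
    question: QuestionSpec,
    answer_format: Optional[str] = None,
) -> Union[Fraction, FrequencyPair]:
    """The strategy's predicted answer for a task, exact.

    Probability predictions are evaluated from the task's completed
    situation; frequency pairs from its (possibly rounded) frequency
    table, matching the counts printed in the task material.
    """
    fmt = answer_format or question.answer_format
    if strategy.question_kind != question.kind:
        raise NotApplicableError(
            f"{strategy.id} applies to {strategy.question_kind} questions"
        )
    if fmt == "probability":
        if strategy.prob_expr is None:
            raise NotApplicableError(f"{strategy.id} has no probability form")
        return _eval_expr(strategy.prob_expr, _letter_values(task.situation))
    if fmt == "frequency_pair":
        if strategy.freq_pair is None:
            raise NotApplicableError(f"{strategy.id} has no frequency form")
        counts = _count_values(task.frequency_table)
        num, den = (counts[letter] for letter in strategy.freq_pair)
        return (int(num), int(den))
    raise ValueError(f"unknown answer format {fmt!r}")


# ---------------------------------------------------------------------------
# coding rule (correctness intervals)

def coding_interval(
    exact: Fraction,
    other_predictions: Sequence[Fraction] = (),
) -> Tuple[Fraction, Fraction, bool, bool]:
    """The correctness interval on the percent scale.

    An answer is accepted when it rounds to the exact value at the next
    full percentage point (granularity 1 point; 0.1 point for exact values
    below 1%).  Returns ``(lo, hi, lo_inclusive, hi_inclusive)``; an
    endpoint becomes exclusive when a different catalogued prediction
    displays as that endpoint at the interval granularity — the
    documented "0.5% was one of the expected wrong solutions" case.
    """
    pct = exact * 100
    g = Fraction(1) if pct >= 1 else Fraction(1, 10)
    lo = (pct // g) * g
    hi = lo + g

    def _excluded(endpoint: Fraction) -> bool:
        for other in other_predictions:
            opct = other * 100
            if opct == pct:
                continue
            if round_half_up(opct / g) * g == endpoint:
                return True
        return False

    return lo, hi, not _excluded(lo), not _excluded(hi)


def _in_interval(
    value_pct: Fraction,
    interval: Tuple[Fraction, Fraction, bool, bool],
) -> bool:
    lo, hi, lo_inc, hi_inc = interval
    above = value_pct >= lo if lo_inc else value_pct > lo
    below = value_pct <= hi if hi_inc else value_pct < hi
    return above and below


def _predictions_for(
    task, question: QuestionSpec
) -> List[Tuple[StrategyDefinition, Fraction]]:
    out = []
    for s in builtin_strategies(question.kind):
        if s.prob_expr is None:
            continue
        try:
            out.append((s, predicted_answer(s, task, question, "probability")))
        except NotApplicableError:
            continue
    return out


def code_correct(task, question: QuestionSpec, response) -> bool:
    """Apply the study's correctness coding to a numeric response.

    Frequency format: both numbers must equal the correct natural
    frequency exactly.  Probability format: the response must equal the
    exact value or fall in the rounding interval to the next (sub-)
    percentage point, with exclusive bounds where an expected wrong
    answer coincides with an endpoint.
    """
    correct = next(
        s for s in builtin_strategies(question.kind) if s.id == "correct"
    )
    if isinstance(response, tuple):
        pred = predicted_answer(correct, task, question, "frequency_pair")
        return tuple(int(v) for v in response) == pred
    resp = to_exact_fraction(response)[0]
    exact = predicted_answer(correct, task, question, "probability")
    if resp == exact:
        return True
    others = [v for s, v in _predictions_for(task, question) if s.id != "correct"]
    return _in_interval(resp * 100, coding_interval(exact, others))


# ---------------------------------------------------------------------------
# classification

@dataclass(frozen=True)
class StrategyMatch:
    strategy_id: str
    distance: Fraction  # absolute distance in percentage points (0 = exact)


@dataclass
class ClassificationResult:
    matches: List[StrategyMatch] = field(default_factory=list)
    coded_correct: bool = False
    unclassified: bool = True
    malformed: bool = False

    @property
    def best(self) -> Optional[str]:
        return self.matches[0].strategy_id if self.matches else None


def classify(
    task,
    question: QuestionSpec,
    response,
    tolerance: Number = Fraction(1, 2),
) -> ClassificationResult:
    """Match a numeric response against every applicable strategy.

    Probability responses (on the 0–1 scale) match a strategy when they
    are within `tolerance` percentage points of its prediction, or fall in
    the coding interval around it.  Frequency-pair responses match only on
    exact equality of both counts.  All matches are returned, ordered by
    distance (exact first), ties broken by catalogue order.
    """
    tol = to_exact_fraction(tolerance)[0]
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    result = ClassificationResult()

    if isinstance(response, tuple):
        num, den = response
        if num > den:
            result.malformed = True
            return result
        for s in builtin_strategies(question.kind):
            if s.freq_pair is None:
                continue
            pred = predicted_answer(s, task, question, "frequency_pair")
            if (int(num), int(den)) == pred:
                result.matches.append(StrategyMatch(s.id, Fraction(0)))
        result.unclassified = not result.matches
        result.coded_correct = code_correct(task, question, response)
        return result

    resp = to_exact_fraction(response)[0]
    preds = _predictions_for(task, question)
    all_values = [v for _, v in preds]
    scored = []
    for idx, (s, pred) in enumerate(preds):
        dist = abs(resp - pred) * 100
        others = [v for v in all_values if v != pred]
        in_int = _in_interval(resp * 100, coding_interval(pred, others))
        if dist <= tol or in_int:
            scored.append((dist, idx, s))
    scored.sort(key=lambda t: (t[0], t[1]))
    result.matches = [StrategyMatch(s.id, d) for d, _, s in scored]
    result.unclassified = not result.matches
    result.coded_correct = code_correct(task, question, resp)
    return result


def collision_audit(
    task,
    question_kind: str,
    tolerance: Number = Fraction(1, 2),
) -> List[Tuple[str, str, Fraction]]:
    """All strategy pairs whose predictions are closer than `tolerance`
    percentage points for this task — responses near either prediction are
    ambiguous between the two."""
    tol = to_exact_fraction(tolerance)[0]
    question = QuestionSpec(
        QuantityId.A_GIVEN_B if question_kind == "conditional"
        else QuantityId.A_AND_NOT_B,
        "probability",
    )
    preds = _predictions_for(task, question)
    out = []
    for i, (s1, v1) in enumerate(preds):
        for s2, v2 in preds[i + 1:]:
            d = abs(v1 - v2) * 100
            if d < tol:
                out.append((s1.id, s2.id, d))
    return out


# ---------------------------------------------------------------------------
# CSV response tables

def classify_table(
    responses: pd.DataFrame,
    tasks: Dict[str, object],
    tolerance: Number = Fraction(1, 2),
) -> pd.DataFrame:
    """Classify a response table.

    Expects columns ``task_id, question_type, format,
    response_numerator, response_denominator_or_blank``; returns a copy
    with ``matched_strategy, distance, coded_correct`` appended.
    """
    rows = []
    for _, rec in responses.iterrows():
        task = tasks[rec["task_id"]]
        qkind = rec["question_type"]
        question = next(
            q for q in task.questions if q.kind == qkind
        )
        den = rec.get("response_denominator_or_blank")
        if den is not None and not pd.isna(den) and str(den).strip() != "":
            resp = (int(rec["response_numerator"]), int(den))
        else:
            resp = to_exact_fraction(str(rec["response_numerator"]))[0]
        res = classify(task, question, resp, tolerance)
        rows.append({
            "matched_strategy": res.best or "",
            "distance": float(res.matches[0].distance) if res.matches else None,
            "coded_correct": res.coded_correct,
        })
    return pd.concat(
        [responses.reset_index(drop=True), pd.DataFrame(rows)], axis=1
    )
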