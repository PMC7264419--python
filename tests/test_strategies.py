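"""The answer-strategy catalogue, prediction, classification and coding."""

from fractions import Fraction as F

import pandas as pd
import pytest

from freqnet.quantities import QuantityId as Q
from freqnet.strategies import (
    NotApplicableError,
    QuestionSpec,
    builtin_strategies,
    classify,
    classify_table,
    code_correct,
    coding_interval,
    collision_audit,
    predicted_answer,
)


def _by_id(kind, sid):
    return next(s for s in builtin_strategies(kind) if s.id == sid)


def _question(task, kind):
    return next(q for q in task.questions if q.kind == kind)


# ---------------------------------------------------------------------------
# catalogue contents

def test_conditional_catalogue_has_eight_strategies():
    cat = builtin_strategies("conditional")
    assert len(cat) == 8
    assert cat[0].id == "correct"
    assert {s.id for s in cat} >= {
        "joint_occurrence", "fisherian", "base_rate_only", "evidence_only",
        "likelihood_subtraction", "pre_bayes", "pos_rate_over_false_rate",
    }


def test_joint_catalogue_contents():
    ids = {s.id for s in builtin_strategies("joint")}
    assert ids == {
        "correct", "q_error", "p_error", "m_error", "n_error",
        "independence_error", "double_joint", "double_tree_confusion_I",
        "double_tree_confusion_II",
    }


def test_pre_bayes_is_frequency_only(mammography):
    s = _by_id("conditional", "pre_bayes")
    assert s.prob_expr is None
    q = _question(mammography, "conditional")
    with pytest.raises(NotApplicableError):
        predicted_answer(s, mammography, q, "probability")
    assert predicted_answer(s, mammography, q, "frequency_pair") == (200, 1140)


def test_likelihood_subtraction_has_no_frequency_form(mammography):
    s = _by_id("conditional", "likelihood_subtraction")
    assert s.freq_pair is None
    q = _question(mammography, "conditional")
    assert predicted_answer(s, mammography, q, "probability") == F(7, 10)


# ---------------------------------------------------------------------------
# predictions

@pytest.mark.parametrize("sid,expected", [
    ("correct", F(8, 57)),
    ("joint_occurrence", F("0.016")),
    ("fisherian", F("0.8")),
    ("base_rate_only", F("0.02")),
    ("evidence_only", F("0.114")),
    ("pos_rate_over_false_rate", F(8)),
])
def test_mammography_conditional_predictions(mammography, sid, expected):
    q = _question(mammography, "conditional")
    s = _by_id("conditional", sid)
    assert predicted_answer(s, mammography, q, "probability") == expected


@pytest.mark.parametrize("sid,expected", [
    ("correct", F("0.004")),
    ("q_error", F("0.2")),
    ("p_error", F(2, 443)),          # ≈ 0.45%, displayed as 0.5%
    ("m_error", F("0.1")),
    ("n_error", F("0.9")),
    ("independence_error", F("0.02") * F("0.886")),  # 1.772%
    ("double_joint", F("0.008")),
    ("double_tree_confusion_I", F(49, 57)),
    ("double_tree_confusion_II", F("0.886") * F(49, 57)),  # ≈ 76.16%
])
def test_mammography_joint_predictions(mammography, sid, expected):
    q = _question(mammography, "joint")
    s = _by_id("joint", sid)
    assert predicted_answer(s, mammography, q, "probability") == expected


@pytest.mark.parametrize("kind,sid,pair", [
    ("conditional", "correct", (160, 1140)),
    ("conditional", "joint_occurrence", (160, 10_000)),
    ("conditional", "fisherian", (160, 200)),
    ("joint", "correct", (40, 10_000)),
    ("joint", "q_error", (40, 200)),
    ("joint", "p_error", (40, 8860)),
])
def test_mammography_frequency_predictions(mammography, kind, sid, pair):
    q = _question(mammography, kind)
    assert predicted_answer(_by_id(kind, sid), mammography, q,
                            "frequency_pair") == pair


def test_economics_frequency_predictions_use_printed_counts(economics):
    """The rounded stimulus counts (205/613) drive the frequency answers."""
    q = _question(economics, "conditional")
    assert predicted_answer(_by_id("conditional", "correct"), economics, q,
                            "frequency_pair") == (205, 613)
    jq = _question(economics, "joint")
    assert predicted_answer(_by_id("joint", "correct"), economics, jq,
                            "frequency_pair") == (115, 1000)


# ---------------------------------------------------------------------------
# classification

def test_fourteen_percent_classified_correct(mammography):
    q = _question(mammography, "conditional")
    res = classify(mammography, q, F(14, 100))
    assert res.best == "correct" and res.coded_correct


def test_frequency_pair_matches_joint_occurrence(mammography):
    q = _question(mammography, "conditional")
    res = classify(mammography, q, (160, 10_000))
    assert res.best == "joint_occurrence"
    assert not res.coded_correct


def test_half_percent_is_p_error_not_correct(mammography):
    """0.5% sits in the correct-answer interval but is the expected wrong
    solution, so it is coded incorrect and classified as p-error first."""
    q = _question(mammography, "joint")
    res = classify(mammography, q, F(1, 200))
    assert res.best == "p_error"
    assert not res.coded_correct


def test_independence_error_classified(mammography):
    q = _question(mammography, "joint")
    res = classify(mammography, q, F(1772, 100_000))
    assert res.best == "independence_error"


def test_far_off_response_unclassified(mammography):
    q = _question(mammography, "conditional")
    res = classify(mammography, q, F(1, 2))
    assert res.unclassified and res.matches == []


def test_malformed_frequency_pair_flagged(mammography):
    q = _question(mammography, "conditional")
    res = classify(mammography, q, (2000, 1140))
    assert res.malformed and res.unclassified


def test_classifier_self_consistency(tasks):
    """Every strategy's own predicted answer is classified as itself."""
    for task in tasks.values():
        for question in task.questions:
            for s in builtin_strategies(question.kind):
                for fmt in ("probability", "frequency_pair"):
                    try:
                        pred = predicted_answer(s, task, question, fmt)
                    except NotApplicableError:
                        continue
                    res = classify(task, question, pred)
                    assert s.id in [m.strategy_id for m in res.matches], (
                        task.id, question.kind, s.id, fmt
                    )


def test_correct_strategy_agrees_with_situation_module(tasks):
    """Cross-module check: the catalogue's correct answer equals the
    derived target quantity."""
    for task in tasks.values():
        for question in task.questions:
            pred = predicted_answer(
                _by_id(question.kind, "correct"), task, question, "probability"
            )
            assert pred == task.situation.value(question.target)


def test_collision_audit_contains_correct_p_error_pair(mammography):
    pairs = {(a, b) for a, b, _ in collision_audit(mammography, "joint")}
    assert ("correct", "p_error") in pairs


# ---------------------------------------------------------------------------
# coding rule

def test_mammography_joint_interval_excludes_upper_bound(mammography):
    q = _question(mammography, "joint")
    assert code_correct(mammography, q, F(45, 10_000))   # 0.45%
    assert code_correct(mammography, q, F(49, 10_000))   # 0.49%
    assert code_correct(mammography, q, F(4, 1000))      # exact 0.4%
    assert not code_correct(mammography, q, F(5, 1000))  # 0.5% excluded


def test_economics_joint_interval(economics):
    q = _question(economics, "joint")
    assert code_correct(economics, q, F(113, 1000))      # 11.3%
    assert code_correct(economics, q, F(1152, 10_000))   # exact 11.52%
    assert not code_correct(economics, q, F(107, 1000))  # 10.7%


def test_conditional_rounding_to_next_full_point(economics):
    q = _question(economics, "conditional")
    assert code_correct(economics, q, F(33, 100))
    assert code_correct(economics, q, F(334, 1000))
    assert code_correct(economics, q, F(34, 100))
    assert not code_correct(economics, q, F(35, 100))


def test_frequency_coding_requires_both_numbers_exact(mammography):
    q = _question(mammography, "conditional")
    assert code_correct(mammography, q, (160, 1140))
    assert not code_correct(mammography, q, (160, 10_000))
    assert not code_correct(mammography, q, (159, 1140))


def test_coding_interval_shape():
    lo, hi, lo_inc, hi_inc = coding_interval(F(8, 57))
    assert (lo, hi) == (14, 15) and lo_inc and hi_inc
    lo, hi, lo_inc, hi_inc = coding_interval(F("0.004"), [F(2, 443)])
    assert (lo, hi) == (F("0.4"), F("0.5")) and lo_inc and not hi_inc


# ---------------------------------------------------------------------------
# CSV interface

def test_classify_table_appends_columns(tasks):
    df = pd.DataFrame([
        {"task_id": "mammography", "question_type": "conditional",
         "format": "probability", "response_numerator": "0.14",
         "response_denominator_or_blank": ""},
        {"task_id": "mammography", "question_type": "conditional",
         "format": "frequency_pair", "response_numerator": "160",
         "response_denominator_or_blank": "200"},
        {"task_id": "economics", "question_type": "joint",
         "format": "probability", "response_numerator": "0.115",
         "response_denominator_or_blank": ""},
    ])
    out = classify_table(df, tasks)
    assert list(out["matched_strategy"]) == ["correct", "fisherian", "correct"]
    assert list(out["coded_correct"]) == [True, False, True]
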