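"""Task bank and generator of problem materials.

Two classic study tasks ship as fixtures: the *mammography problem*
(base rate 2%, sensitivity 80%, false-alarm rate 10%, N = 10,000) and a
short *economics-course problem* (32%, 64%, 60%, N = 1,000).  Each task
can be rendered in a 4 × 2 design: four presentations (text only, 2×2
table, double-tree, net diagram) × two information formats (probabilities,
natural frequencies); with the two contexts this spans the full 16-version
design.  In visualization versions the statistics sentences are omitted —
the diagram is the only carrier of the statistical information.

Every number in the generated material is derived from the task
parameters through the situation module; the economics frequency material
deliberately carries the conventional rounded counts (205 from 204.8),
which makes its frequency version minutely inconsistent with its
probability parameters — the task records that in ``rounding_note``.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from ._format import format_count, format_percent
from .diagrams import DiagramGraph, build_double_tree, build_net, build_two_by_two, render_text
from .quantities import QuantityId
from .situation import (
    CompletedSituation,
    EventPair,
    FrequencyTable,
    PartialSpecification,
    from_frequencies,
    solve,
    to_frequencies,
)
from .strategies import QuestionSpec

__all__ = [
    "TaskSpec",
    "ProblemDocument",
    "ProblemVersion",
    "Booklet",
    "builtin_tasks",
    "render_problem",
    "design_matrix",
    "enumerate_versions",
    "booklets_to_frame",
    "VISUALIZATIONS",
    "FORMATS",
]

VISUALIZATIONS = ("text_only", "two_by_two", "double_tree", "net")
FORMATS = ("probabilities", "frequencies")


@dataclass
class TaskSpec:
    """A parameterized problem context.

    ``prob_sentences`` / ``freq_sentences`` are templates whose number
    slots are filled from the solved situation, never typed by hand.
    """

    id: str
    events: EventPair
    parameters: PartialSpecification
    N: int
    cover_story: str
    questions: Tuple[QuestionSpec, QuestionSpec]
    prob_sentences: str
    freq_sentences: str
    question_texts: Dict[Tuple[str, str], str]  # (question kind, format) -> text
    rounding_note: Optional[str] = None
    situation: CompletedSituation = field(init=False)
    frequency_table: FrequencyTable = field(init=False)
    frequency_situation: CompletedSituation = field(init=False)

    def __post_init__(self) -> None:
        result = solve(self.parameters, self.events)
        if result.status != "complete":
            raise ValueError(
                f"task parameters must form a determining set; got {result.status}"
            )
        object.__setattr__(self, "situation", result.situation)
        self.situation.population_size = self.N
        exact = to_frequencies(self.situation, self.N, policy="exact")
        self.frequency_table = to_frequencies(self.situation, self.N, policy="round")
        if not exact.exact_counts or any(
            not isinstance(v, int) for v in exact.counts().values()
        ):
            if self.rounding_note is None:
                raise ValueError(
                    "expected counts are non-integral at this N; "
                    "attach a rounding_note"
                )
        # the situation implied by the (rounded) printed counts
        self.frequency_situation = from_frequencies(self.frequency_table, self.events)

    def statistics_text(self, format: str) -> str:
        s, tab = self.situation, self.frequency_table
        if format == "probabilities":
            return self.prob_sentences.format(
                base_rate=format_percent(s.value(QuantityId.A)),
                sensitivity=format_percent(s.value(QuantityId.B_GIVEN_A)),
                false_rate=format_percent(s.value(QuantityId.B_GIVEN_NOT_A)),
            )
        return self.freq_sentences.format(
            n=format_count(tab.total),
            n_a=format_count(tab.n_a),
            n_na=format_count(tab.n_na),
            n_ab=format_count(tab.n_ab),
            n_nab=format_count(tab.n_na_b),
        )


@dataclass
class ProblemDocument:
    """One rendered problem: cover story, statistics, questions."""

    task_id: str
    format: str
    visualization: str
    cover_story: str
    statistics_text: Optional[str]
    diagram: Optional[DiagramGraph]
    questions: List[Tuple[str, str]]  # (question text, answer blank)

    def text(self) -> str:
        parts = [self.cover_story, ""]
        if self.statistics_text is not None:
            parts.append(self.statistics_text)
        if self.diagram is not None:
            parts.append(render_text(self.diagram))
        for q, blank in self.questions:
            parts += ["", q, f"Answer: {blank}"]
        return "\n".join(parts) + "\n"


_PROB_BLANK = "_______"
_FREQ_BLANK = "____ out of ____"


def builtin_tasks() -> Dict[str, TaskSpec]:
    """The two built-in task fixtures, keyed 'mammography' and 'economics'."""
    mam_events = EventPair(
        first_event_label="breast cancer",
        second_event_label="positive test result",
        negation_labels=("no breast cancer", "negative test result"),
    )
    mammography = TaskSpec(
        id="mammography",
        events=mam_events,
        parameters=PartialSpecification(probabilities={
            QuantityId.A: "2%",
            QuantityId.B_GIVEN_A: "80%",
            QuantityId.B_GIVEN_NOT_A: "10%",
        }),
        N=10_000,
        cover_story=(
            "Imagine you are a reporter for a women's magazine and you want "
            "to write an article about breast cancer. As a part of your "
            "research, you focus on mammography as an indicator of breast "
            "cancer. You are especially interested in the question of what "
            "it means when a woman has a positive result (which indicates "
            "breast cancer) in such a medical test. A physician explains "
            "the situation with the following information:"
        ),
        questions=(
            QuestionSpec(QuantityId.A_GIVEN_B, "probability", ("B", "A")),
            QuestionSpec(QuantityId.A_AND_NOT_B, "probability", ("notB", "A")),
        ),
        prob_sentences=(
            "The probability of breast cancer is {base_rate} for a woman who "
            "participates in routine screening. If a woman who participates "
            "in routine screening has breast cancer, the probability is "
            "{sensitivity} that she will have a positive test result. If a "
            "woman who participates in routine screening does not have "
            "breast cancer, the probability is {false_rate} that she will "
            "have a positive test result."
        ),
        freq_sentences=(
            "{n_a} out of {n} women who participate in routine screening "
            "have breast cancer. Out of {n_a} women who participate in "
            "routine screening and have breast cancer, {n_ab} will have a "
            "positive result. Out of {n_na} women who participate in "
            "routine screening and have no breast cancer, {n_nab} will also "
            "have a positive result."
        ),
        question_texts={
            ("conditional", "probabilities"): (
                "What is the probability that a woman who participates in "
                "routine screening and receives a positive test result has "
                "breast cancer?"
            ),
            ("conditional", "frequencies"): (
                "How many of the women who participate in routine screening "
                "and receive a positive test result have breast cancer?"
            ),
            ("joint", "probabilities"): (
                "What is the probability that a woman who participates in "
                "routine screening receives a negative test result and has "
                "breast cancer?"
            ),
            ("joint", "frequencies"): (
                "How many of the women who participate in routine screening "
                "receive a negative test result and have breast cancer?"
            ),
        },
    )

    eco_events = EventPair(
        first_event_label="attends the economics course",
        second_event_label="career-oriented",
        negation_labels=(
            "does not attend the economics course",
            "not career-oriented",
        ),
    )
    economics = TaskSpec(
        id="economics",
        events=eco_events,
        parameters=PartialSpecification(probabilities={
            QuantityId.A: "32%",
            QuantityId.B_GIVEN_A: "64%",
            QuantityId.B_GIVEN_NOT_A: "60%",
        }),
        N=1_000,
        cover_story=(
            "Imagine you are interested in the question, of whether "
            "career-oriented students are more likely to attend an "
            "economics course. Therefore the school psychological service "
            "evaluates the correlations between personality characteristics "
            "and choice of courses for you. The following information is "
            "available:"
        ),
        questions=(
            QuestionSpec(QuantityId.A_GIVEN_B, "probability", ("A", "B")),
            QuestionSpec(QuantityId.A_AND_NOT_B, "probability", ("A", "notB")),
        ),
        prob_sentences=(
            "The probability that a student attends the economics course is "
            "{base_rate}. If a student attends the economics course, the "
            "probability that he is career-oriented is {sensitivity}. If a "
            "student does not attend the economics course, the probability "
            "that he is still career-oriented is {false_rate}."
        ),
        freq_sentences=(
            "{n_a} out of {n} students attend the economics course. Out of "
            "{n_a} students who attend the economics course, {n_ab} are "
            "career-oriented. Out of {n_na} students who not attend the "
            "economics course, {n_nab} are still career-oriented."
        ),
        question_texts={
            ("conditional", "probabilities"): (
                "What is the probability that a student attends the "
                "economics course if he is career-oriented?"
            ),
            ("conditional", "frequencies"): (
                "How many of the students who are career-oriented attend "
                "the economics course?"
            ),
            ("joint", "probabilities"): (
                "What is the probability that a student attends the "
                "economics course and is not career-oriented?"
            ),
            ("joint", "frequencies"): (
                "How many of the students are not career-oriented and "
                "attend the economics course?"
            ),
        },
        rounding_note=(
            "At N = 1,000 the expected count for the attends-and-career cell "
            "is 204.8; the frequency material prints the rounded 205, so the "
            "frequency version is minutely inconsistent with the probability "
            "parameters (P(career|attends) becomes 205/320 = 64.06%)."
        ),
    )
    return {"mammography": mammography, "economics": economics}


def render_problem(
    task: TaskSpec, format: str, visualization: str
) -> ProblemDocument:
    """Render one of the 16 design cells for a task.

    Visualization versions embed the diagram in the matching mode and omit
    the statistics sentences (the design rule of the material)."""
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}")
    if visualization not in VISUALIZATIONS:
        raise ValueError(f"unknown visualization {visualization!r}")

    stats_text = None
    diagram = None
    if visualization == "text_only":
        stats_text = task.statistics_text(format)
    else:
        mode = "prob" if format == "probabilities" else "freq"
        # frequency material carries the printed (possibly rounded) counts
        sit = task.situation if mode == "prob" else task.frequency_situation
        builder = {
            "two_by_two": build_two_by_two,
            "double_tree": build_double_tree,
            "net": build_net,
        }[visualization]
        diagram = builder(sit, N=task.N, mode=mode)

    blank = _PROB_BLANK if format == "probabilities" else _FREQ_BLANK
    questions = [
        (task.question_texts[(q.kind, format)], blank) for q in task.questions
    ]
    return ProblemDocument(
        task_id=task.id,
        format=format,
        visualization=visualization,
        cover_story=task.cover_story,
        statistics_text=stats_text,
        diagram=diagram,
        questions=questions,
    )


@dataclass(frozen=True)
class ProblemVersion:
    task_id: str
    format: str
    visualization: str


@dataclass(frozen=True)
class Booklet:
    """Two problems for one participant: different contexts, different
    formats, different visualizations."""

    first: ProblemVersion
    second: ProblemVersion


def enumerate_versions(tasks: Dict[str, TaskSpec]) -> List[ProblemVersion]:
    """All context × format × visualization cells (16 for two tasks)."""
    return [
        ProblemVersion(tid, fmt, vis)
        for tid in sorted(tasks)
        for fmt in FORMATS
        for vis in VISUALIZATIONS
    ]


def design_matrix(
    tasks: Dict[str, TaskSpec], seed: int = 0
) -> List[Booklet]:
    """Balanced booklet assignment, deterministic given `seed`.

    Each booklet pairs the two contexts, one with probabilities and the
    other with frequencies, and never repeats a visualization."""
    ids = sorted(tasks)
    if len(ids) < 2:
        raise ValueError("need at least two tasks")
    booklets: List[Booklet] = []
    for t1 in ids:
        for t2 in ids:
            if t1 == t2:
                continue
            for fmt1, fmt2 in (
                ("probabilities", "frequencies"),
                ("frequencies", "probabilities"),
            ):
                for v1 in VISUALIZATIONS:
                    for v2 in VISUALIZATIONS:
                        if v1 == v2:
                            continue
                        booklets.append(Booklet(
                            ProblemVersion(t1, fmt1, v1),
                            ProblemVersion(t2, fmt2, v2),
                        ))
    rng = random.Random(seed)
    rng.shuffle(booklets)
    return booklets


def booklets_to_frame(booklets: Sequence[Booklet]) -> pd.DataFrame:
    """Booklet manifest in long form, one row per problem."""
    rows = []
    for i, b in enumerate(booklets):
        for pos, v in enumerate((b.first, b.second), start=1):
            rows.append({
                "booklet": i,
                "position": pos,
                "task_id": v.task_id,
                "format": v.format,
                "visualization": v.visualization,
            })
    return pd.DataFrame(rows)
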