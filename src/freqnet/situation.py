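"""Exact representation and completion of two-binary-event situations.

A probabilistic situation with two dichotomous events A and B (say,
*breast cancer* and *positive mammogram*) is fully determined by the four
joint-cell probabilities P(A∩B), P(A∩¬B), P(¬A∩B), P(¬A∩¬B).  From the
cells, all 16 probabilities (4 marginals, 4 joints, 8 conditionals) follow,
and they satisfy four families of algebraic constraints, named after their
geometric appearance in the net diagram:

* line rule      — complementary marginals sum to 1,
* triangle rule  — marginal × conditional = joint (multiplication rule),
* V-rule         — two adjoining joints sum to the enclosed marginal
                   (addition rule),
* X-rule         — the four joints sum to 1.

This module completes a situation from any determining subset of the 16
quantities (the textbook case being base rate, sensitivity and
false-alarm rate), checks the four rule families on arbitrary assignments,
and converts between probabilities and absolute frequencies.  All internal
arithmetic is exact rational (`fractions.Fraction`); decimals at the API
boundary are parsed exactly from their decimal string form.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import yaml

from .quantities import QuantityId, parse_quantity

__all__ = [
    "EventPair",
    "CellDistribution",
    "PartialSpecification",
    "CompletedSituation",
    "SolveResult",
    "RuleViolation",
    "FrequencyTable",
    "NaturalFrequency",
    "complete_from_cells",
    "solve",
    "check_rules",
    "to_frequencies",
    "from_frequencies",
    "natural_frequency",
    "to_exact_fraction",
    "fraction_to_string",
    "load_spec",
    "situation_to_dict",
    "save_situation",
]

Number = Union[int, float, Fraction, str]

# unknown ordering used throughout: x = (A∩B, A∩¬B, ¬A∩B, ¬A∩¬B)
_CELL_IDS = (
    QuantityId.A_AND_B,
    QuantityId.A_AND_NOT_B,
    QuantityId.NOT_A_AND_B,
    QuantityId.NOT_A_AND_NOT_B,
)
_CELL_INDEX = {
    frozenset(("A", "B")): 0,
    frozenset(("A", "notB")): 1,
    frozenset(("notA", "B")): 2,
    frozenset(("notA", "notB")): 3,
}
_MARGINAL_COEFFS = {
    "A": (1, 1, 0, 0),
    "notA": (0, 0, 1, 1),
    "B": (1, 0, 1, 0),
    "notB": (0, 1, 0, 1),
}
_MARGINAL_IDS = {
    "A": QuantityId.A,
    "notA": QuantityId.NOT_A,
    "B": QuantityId.B,
    "notB": QuantityId.NOT_B,
}


# ---------------------------------------------------------------------------
# numeric parsing

def to_exact_fraction(value: Number) -> Tuple[Fraction, bool]:
    """Convert a boundary value to an exact Fraction.

    Returns ``(fraction, exact)`` where *exact* is False only for binary
    floats, whose decimal intent is unknowable; strings like "0.02", "2%",
    "8/57" and int/Fraction inputs are exact.
    """
    if isinstance(value, Fraction):
        return value, True
    if isinstance(value, bool):
        raise TypeError("boolean is not a probability value")
    if isinstance(value, int):
        return Fraction(value), True
    if isinstance(value, float):
        # repr() of a float is its shortest round-tripping decimal; we take
        # that as the intended value but flag the input as inexact.
        return Fraction(repr(value)), False
    if isinstance(value, str):
        s = value.strip()
        if s.endswith("%"):
            return Fraction(s[:-1].strip()) / 100, True
        return Fraction(s), True
    raise TypeError(f"cannot interpret {value!r} as a probability")


def fraction_to_string(value: Fraction) -> str:
    """Serialize exactly: decimal string if terminating, else 'num/den'."""
    den = value.denominator
    while den % 2 == 0:
        den //= 2
    while den % 5 == 0:
        den //= 5
    if den == 1:
        f = float(value)
        text = repr(f)
        if Fraction(text) == value:
            return text
    return f"{value.numerator}/{value.denominator}"


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class EventPair:
    """Labels for the two events and their negations."""

    first_event_label: str = "A"
    second_event_label: str = "B"
    negation_labels: Tuple[str, str] = ("not A", "not B")

    def __post_init__(self) -> None:
        labels = [
            self.first_event_label,
            self.second_event_label,
            *self.negation_labels,
        ]
        if any(not str(lab).strip() for lab in labels):
            raise ValueError("event labels must be non-empty")
        if len(set(labels)) != 4:
            raise ValueError("event labels must be pairwise distinct")

    def label(self, token: str) -> str:
        """Label for an atomic event token ('A', 'notA', 'B', 'notB')."""
        return {
            "A": self.first_event_label,
            "B": self.second_event_label,
            "notA": self.negation_labels[0],
            "notB": self.negation_labels[1],
        }[token]


@dataclass(frozen=True)
class CellDistribution:
    """The four joint-cell probabilities — the canonical internal state."""

    p_ab: Fraction
    p_a_nb: Fraction
    p_na_b: Fraction
    p_na_nb: Fraction

    def __post_init__(self) -> None:
        for name, v in zip(("p_ab", "p_a_nb", "p_na_b", "p_na_nb"), self):
            if not isinstance(v, Fraction):
                object.__setattr__(self, name, to_exact_fraction(v)[0])
        for v in self:
            if not 0 <= v <= 1:
                raise ValueError(f"cell probability {v} outside [0, 1]")
        if sum(self) != 1:
            raise ValueError(
                f"cells must sum to exactly 1 (X-rule); got {sum(self)}"
            )

    def __iter__(self):
        return iter((self.p_ab, self.p_a_nb, self.p_na_b, self.p_na_nb))

    def as_tuple(self) -> Tuple[Fraction, Fraction, Fraction, Fraction]:
        return (self.p_ab, self.p_a_nb, self.p_na_b, self.p_na_nb)


@dataclass
class PartialSpecification:
    """A subset of the 16 probabilities and/or absolute frequencies.

    Frequencies are interpreted as count / population_size.  At most one
    entry per quantity across both maps.
    """

    probabilities: Dict[QuantityId, Fraction] = field(default_factory=dict)
    frequencies: Dict[QuantityId, int] = field(default_factory=dict)
    population_size: Optional[int] = None
    exact_inputs: bool = True

    def __post_init__(self) -> None:
        probs: Dict[QuantityId, Fraction] = {}
        for q, v in self.probabilities.items():
            if q is QuantityId.TOTAL:
                raise ValueError("TOTAL is not a probability quantity")
            fr, exact = to_exact_fraction(v)
            if not exact:
                self.exact_inputs = False
            if not 0 <= fr <= 1:
                raise ValueError(f"{q} = {fr} outside [0, 1]")
            probs[q] = fr
        self.probabilities = probs
        if self.frequencies:
            if self.population_size is None:
                raise ValueError("frequencies given without population_size")
            for q, c in self.frequencies.items():
                if q is QuantityId.TOTAL:
                    raise ValueError("give TOTAL via population_size")
                if not 0 <= c <= self.population_size:
                    raise ValueError(
                        f"count {c} for {q} outside [0, {self.population_size}]"
                    )
                if q in self.probabilities:
                    raise ValueError(f"{q} given both as probability and count")
        if self.population_size is not None and self.population_size < 1:
            raise ValueError("population_size must be a positive integer")

    def effective(self) -> Dict[QuantityId, Fraction]:
        """Merge counts (as count/N) into one quantity→probability map."""
        out = dict(self.probabilities)
        for q, c in self.frequencies.items():
            out[q] = Fraction(c, self.population_size)
        return out


@dataclass
class CompletedSituation:
    """All 16 probabilities of a situation, derived from exact cells.

    Conditionals whose conditioning event has probability zero are
    *undefined* and carried as None.
    """

    event_pair: EventPair
    cells: CellDistribution
    population_size: Optional[int] = None
    derived: Dict[QuantityId, Optional[Fraction]] = field(init=False)

    def __post_init__(self) -> None:
        x = self.cells.as_tuple()
        d: Dict[QuantityId, Optional[Fraction]] = {QuantityId.TOTAL: Fraction(1)}
        for token, coeffs in _MARGINAL_COEFFS.items():
            d[_MARGINAL_IDS[token]] = sum(c * v for c, v in zip(coeffs, x))
        for q, v in zip(_CELL_IDS, x):
            d[q] = v
        for q in QuantityId:
            if q.kind != "conditional":
                continue
            cond = q.conditioning_event
            targ = q.target_event
            marg = d[_MARGINAL_IDS[cond]]
            joint = x[_CELL_INDEX[frozenset((targ, cond))]]
            d[q] = None if marg == 0 else joint / marg
        self.derived = d

    def value(self, q: QuantityId) -> Optional[Fraction]:
        return self.derived[q]

    def __getitem__(self, q: Union[QuantityId, str]) -> Optional[Fraction]:
        if isinstance(q, str):
            q = parse_quantity(q)
        return self.derived[q]


@dataclass
class SolveResult:
    """Outcome of completing a partial specification."""

    status: str  # 'complete' | 'underdetermined' | 'inconsistent'
    situation: Optional[CompletedSituation] = None
    free_degrees: Optional[int] = None
    diagnostics: List[str] = field(default_factory=list)
    rule_violations: List["RuleViolation"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status == "complete":
            assert self.situation is not None
        else:
            assert self.situation is None


@dataclass(frozen=True)
class RuleViolation:
    """One violated instance of a net rule."""

    family: str  # 'line' | 'triangle' | 'V' | 'X'
    quantities: Tuple[QuantityId, ...]
    residual: Fraction

    def __str__(self) -> str:
        qs = ", ".join(str(q) for q in self.quantities)
        return f"{self.family}-rule violation ({qs}): residual {float(self.residual):g}"


@dataclass
class FrequencyTable:
    """The nine absolute frequencies of a situation at population size N."""

    total: Union[int, Fraction]
    n_a: Union[int, Fraction]
    n_na: Union[int, Fraction]
    n_b: Union[int, Fraction]
    n_nb: Union[int, Fraction]
    n_ab: Union[int, Fraction]
    n_a_nb: Union[int, Fraction]
    n_na_b: Union[int, Fraction]
    n_na_nb: Union[int, Fraction]
    exact_counts: bool = True

    def __post_init__(self) -> None:
        checks = [
            ("n_a", self.n_a, self.n_ab + self.n_a_nb),
            ("n_na", self.n_na, self.n_na_b + self.n_na_nb),
            ("n_b", self.n_b, self.n_ab + self.n_na_b),
            ("n_nb", self.n_nb, self.n_a_nb + self.n_na_nb),
            ("total", self.total, self.n_a + self.n_na),
            ("total", self.total, self.n_b + self.n_nb),
        ]
        for name, have, want in checks:
            if have != want:
                raise ValueError(
                    f"additivity violated for {name}: {have} != {want}"
                )
        for v in self.counts().values():
            if v < 0:
                raise ValueError("counts must be non-negative")

    def counts(self) -> Dict[QuantityId, Union[int, Fraction]]:
        return {
            QuantityId.TOTAL: self.total,
            QuantityId.A: self.n_a,
            QuantityId.NOT_A: self.n_na,
            QuantityId.B: self.n_b,
            QuantityId.NOT_B: self.n_nb,
            QuantityId.A_AND_B: self.n_ab,
            QuantityId.A_AND_NOT_B: self.n_a_nb,
            QuantityId.NOT_A_AND_B: self.n_na_b,
            QuantityId.NOT_A_AND_NOT_B: self.n_na_nb,
        }

    def count(self, q: QuantityId) -> Union[int, Fraction]:
        return self.counts()[q]


@dataclass(frozen=True)
class NaturalFrequency:
    """A conditional proportion as nested counts: 'numerator out of denominator'."""

    numerator: Union[int, Fraction]
    denominator: Union[int, Fraction]
    reference_set: str

    def __str__(self) -> str:
        return f"{self.numerator} out of {self.denominator} ({self.reference_set})"


# ---------------------------------------------------------------------------
# operations

def complete_from_cells(
    cells: CellDistribution,
    events: Optional[EventPair] = None,
    N: Optional[int] = None,
) -> CompletedSituation:
    """Derive all 16 quantities from the four joint cells."""
    return CompletedSituation(events or EventPair(), cells, N)


def _constraint_rows(
    given: Mapping[QuantityId, Fraction],
) -> List[Tuple[List[Fraction], Fraction, str]]:
    """Translate quantities into linear equations over the four cells."""
    rows: List[Tuple[List[Fraction], Fraction, str]] = [
        ([Fraction(1)] * 4, Fraction(1), "normalization (X-rule)")
    ]
    for q, v in given.items():
        if q.kind == "marginal":
            coeffs = [Fraction(c) for c in _MARGINAL_COEFFS[q.events[0]]]
            rows.append((coeffs, v, f"{q} = {fraction_to_string(v)}"))
        elif q.kind == "joint":
            coeffs = [Fraction(0)] * 4
            coeffs[_CELL_INDEX[frozenset(q.events)]] = Fraction(1)
            rows.append((coeffs, v, f"{q} = {fraction_to_string(v)}"))
        elif q.kind == "conditional":
            cond = q.conditioning_event
            targ = q.target_event
            coeffs = [
                -v * Fraction(c) for c in _MARGINAL_COEFFS[cond]
            ]
            coeffs[_CELL_INDEX[frozenset((targ, cond))]] += 1
            rows.append((coeffs, Fraction(0), f"{q} = {fraction_to_string(v)}"))
        else:
            raise ValueError(f"{q} cannot appear in a specification")
    return rows


def _fm_feasible(ineqs: List[Tuple[List[Fraction], Fraction]], nvars: int) -> bool:
    """Exact Fourier–Motzkin: is {t : const + coeffs·t >= 0 for all} nonempty?"""
    for var in range(nvars):
        lower, upper, rest = [], [], []
        for coeffs, const in ineqs:
            a = coeffs[var]
            if a == 0:
                rest.append((coeffs, const))
            elif a > 0:
                lower.append((coeffs, const))
            else:
                upper.append((coeffs, const))
        new = rest
        for lc, lk in lower:
            for uc, uk in upper:
                a_lo, a_up = lc[var], uc[var]
                coeffs = [
                    (-a_up) * lv + a_lo * uv for lv, uv in zip(lc, uc)
                ]
                new.append((coeffs, (-a_up) * lk + a_lo * uk))
        ineqs = new
    return all(const >= 0 for _, const in ineqs)


def solve(
    spec: PartialSpecification,
    events: Optional[EventPair] = None,
    tolerance: Optional[Fraction] = None,
) -> SolveResult:
    """Complete a partial specification by exact linear solving.

    Every given quantity becomes a linear equation over the four cell
    unknowns; the system (plus normalization and non-negativity) is solved
    exactly.  Status reflects the rank of the feasible set: a unique
    feasible point is *complete*, a feasible set of positive dimension is
    *underdetermined*, an empty one *inconsistent*.  A conditional given
    together with an implied zero conditioning marginal is inconsistent.

    `tolerance` (absolute, on probabilities) defaults to 0 for exact inputs
    and 1e-9 when the caller supplied binary floats.
    """
    events = events or EventPair()
    given = spec.effective()
    if tolerance is None:
        tolerance = Fraction(0) if spec.exact_inputs else Fraction(1, 10**9)
    tol = to_exact_fraction(tolerance)[0]

    rows = _constraint_rows(given)
    aug = [list(coeffs) + [rhs] for coeffs, rhs, _ in rows]
    descs = [d for _, _, d in rows]

    # exact Gauss-Jordan elimination
    pivot_cols: List[int] = []
    r = 0
    for col in range(4):
        piv = next((i for i in range(r, len(aug)) if aug[i][col] != 0), None)
        if piv is None:
            continue
        aug[r], aug[piv] = aug[piv], aug[r]
        p = aug[r][col]
        aug[r] = [v / p for v in aug[r]]
        for i in range(len(aug)):
            if i != r and aug[i][col] != 0:
                f = aug[i][col]
                aug[i] = [v - f * w for v, w in zip(aug[i], aug[r])]
        pivot_cols.append(col)
        r += 1

    # rows reduced to 0 = c: conflicting constraints when |c| beyond tolerance
    conflicts = [i for i in range(r, len(aug)) if abs(aug[i][4]) > tol]
    if conflicts:
        diags = ["constraints are mutually inconsistent:"] + descs[1:]
        viols = check_rules(given, tol)
        return SolveResult(
            "inconsistent", diagnostics=diags, rule_violations=viols
        )

    dof = 4 - r
    if dof == 0:
        x = [aug[pivot_cols.index(c)][4] if c in pivot_cols else Fraction(0)
             for c in range(4)]
        negatives = [
            (q, v) for q, v in zip(_CELL_IDS, x) if v < -tol
        ]
        if negatives:
            diags = [
                f"implied cell {q} = {fraction_to_string(v)} is negative"
                for q, v in negatives
            ]
            return SolveResult(
                "inconsistent",
                diagnostics=diags,
                rule_violations=check_rules(given, tol),
            )
        if tol > 0:
            x = [max(v, Fraction(0)) for v in x]
            s = sum(x)
            x = [v / s for v in x]
        # a given conditional whose conditioning event ends up impossible
        for q in given:
            if q.kind == "conditional":
                coeffs = _MARGINAL_COEFFS[q.conditioning_event]
                marg = sum(Fraction(c) * v for c, v in zip(coeffs, x))
                if marg == 0:
                    return SolveResult(
                        "inconsistent",
                        diagnostics=[
                            f"{q} was given but its conditioning event has "
                            "probability 0"
                        ],
                    )
        situation = complete_from_cells(
            CellDistribution(*x), events, spec.population_size
        )
        return SolveResult("complete", situation=situation)

    # underdetermined rank: parametrize x = x0 + T t and test feasibility
    free_cols = [c for c in range(4) if c not in pivot_cols]
    x0 = [Fraction(0)] * 4
    for i, c in enumerate(pivot_cols):
        x0[c] = aug[i][4]
    directions = []
    for fc in free_cols:
        v = [Fraction(0)] * 4
        v[fc] = Fraction(1)
        for i, c in enumerate(pivot_cols):
            v[c] = -aug[i][fc]
        directions.append(v)
    ineqs = [
        ([d[i] for d in directions], x0[i]) for i in range(4)
    ]
    if not _fm_feasible(ineqs, len(free_cols)):
        return SolveResult(
            "inconsistent",
            diagnostics=["constraints admit no non-negative cell distribution"]
            + descs[1:],
            rule_violations=check_rules(given, tol),
        )
    for q in given:
        if q.kind == "conditional":
            coeffs = [Fraction(c) for c in _MARGINAL_COEFFS[q.conditioning_event]]
            const = all(
                sum(c * dv for c, dv in zip(coeffs, d)) == 0 for d in directions
            )
            value = sum(c * v for c, v in zip(coeffs, x0))
            if const and value == 0:
                return SolveResult(
                    "inconsistent",
                    diagnostics=[
                        f"{q} was given but its conditioning event has "
                        "probability 0"
                    ],
                )
    return SolveResult(
        "underdetermined",
        free_degrees=dof,
        diagnostics=[f"{dof} free degrees of freedom"],
    )


# rule instances: (family, quantities); line/V/X are sum rules, triangle a
# product rule.
_LINE_RULES = [
    (QuantityId.A, QuantityId.NOT_A),
    (QuantityId.B, QuantityId.NOT_B),
]
_TRIANGLE_RULES = [
    (QuantityId.A, QuantityId.B_GIVEN_A, QuantityId.A_AND_B),
    (QuantityId.A, QuantityId.NOT_B_GIVEN_A, QuantityId.A_AND_NOT_B),
    (QuantityId.NOT_A, QuantityId.B_GIVEN_NOT_A, QuantityId.NOT_A_AND_B),
    (QuantityId.NOT_A, QuantityId.NOT_B_GIVEN_NOT_A, QuantityId.NOT_A_AND_NOT_B),
    (QuantityId.B, QuantityId.A_GIVEN_B, QuantityId.A_AND_B),
    (QuantityId.B, QuantityId.NOT_A_GIVEN_B, QuantityId.NOT_A_AND_B),
    (QuantityId.NOT_B, QuantityId.A_GIVEN_NOT_B, QuantityId.A_AND_NOT_B),
    (QuantityId.NOT_B, QuantityId.NOT_A_GIVEN_NOT_B, QuantityId.NOT_A_AND_NOT_B),
]
_V_RULES = [
    (QuantityId.A_AND_B, QuantityId.A_AND_NOT_B, QuantityId.A),
    (QuantityId.NOT_A_AND_B, QuantityId.NOT_A_AND_NOT_B, QuantityId.NOT_A),
    (QuantityId.A_AND_B, QuantityId.NOT_A_AND_B, QuantityId.B),
    (QuantityId.A_AND_NOT_B, QuantityId.NOT_A_AND_NOT_B, QuantityId.NOT_B),
]
_X_RULE = (
    QuantityId.A_AND_B,
    QuantityId.A_AND_NOT_B,
    QuantityId.NOT_A_AND_B,
    QuantityId.NOT_A_AND_NOT_B,
)


def check_rules(
    assignment: Mapping[QuantityId, Number],
    tolerance: Number = 0,
) -> List[RuleViolation]:
    """Evaluate every instantiable line/triangle/V/X rule instance.

    An instance is instantiable when all its participating quantities are
    present (and not None).  Violations whose absolute residual exceeds
    `tolerance` are returned; an empty list means the assignment is
    consistent at that tolerance.
    """
    tol = to_exact_fraction(tolerance)[0]
    vals: Dict[QuantityId, Fraction] = {}
    for q, v in assignment.items():
        if v is None or q is QuantityId.TOTAL:
            continue
        vals[q] = to_exact_fraction(v)[0]

    out: List[RuleViolation] = []

    def have(*qs: QuantityId) -> bool:
        return all(q in vals for q in qs)

    for a, b in _LINE_RULES:
        if have(a, b):
            res = vals[a] + vals[b] - 1
            if abs(res) > tol:
                out.append(RuleViolation("line", (a, b), abs(res)))
    for marg, cond, joint in _TRIANGLE_RULES:
        if have(marg, cond, joint):
            res = vals[marg] * vals[cond] - vals[joint]
            if abs(res) > tol:
                out.append(
                    RuleViolation("triangle", (marg, cond, joint), abs(res))
                )
    for j1, j2, marg in _V_RULES:
        if have(j1, j2, marg):
            res = vals[j1] + vals[j2] - vals[marg]
            if abs(res) > tol:
                out.append(RuleViolation("V", (j1, j2, marg), abs(res)))
    if have(*_X_RULE):
        res = sum(vals[q] for q in _X_RULE) - 1
        if abs(res) > tol:
            out.append(RuleViolation("X", _X_RULE, abs(res)))
    return out


def _round_half_up(value: Fraction) -> int:
    return math.floor(value + Fraction(1, 2))


def to_frequencies(
    situation: CompletedSituation,
    N: Optional[int] = None,
    policy: str = "exact",
) -> FrequencyTable:
    """Scale the situation to absolute frequencies at population size N.

    * ``exact``           — counts are N×probability, kept rational;
    * ``round``           — round-half-up each *cell*, margins recomputed
                            by additivity so the table invariants hold;
    * ``require_integer`` — raise if any N×probability is non-integral.
    """
    if N is None:
        N = situation.population_size
    if N is None or N < 1:
        raise ValueError("a positive population size N is required")
    exact_cells = [N * v for v in situation.cells]
    integral = all(v.denominator == 1 for v in exact_cells)

    if policy == "require_integer":
        for q, v in zip(_CELL_IDS, exact_cells):
            if v.denominator != 1:
                raise ValueError(
                    f"N×{q} = {fraction_to_string(v)} is not an integer"
                )
        cells = [int(v) for v in exact_cells]
    elif policy == "round":
        cells = [_round_half_up(v) for v in exact_cells]
    elif policy == "exact":
        cells = [int(v) if v.denominator == 1 else v for v in exact_cells]
    else:
        raise ValueError(f"unknown rounding policy {policy!r}")

    ab, anb, nab, nanb = cells
    return FrequencyTable(
        total=ab + anb + nab + nanb,
        n_a=ab + anb,
        n_na=nab + nanb,
        n_b=ab + nab,
        n_nb=anb + nanb,
        n_ab=ab,
        n_a_nb=anb,
        n_na_b=nab,
        n_na_nb=nanb,
        exact_counts=(policy != "round") or integral,
    )


def from_frequencies(
    table: FrequencyTable, events: Optional[EventPair] = None
) -> CompletedSituation:
    """Recover the situation whose cells are count/N; N becomes the
    population size.  Round-trips with ``to_frequencies(..., 'exact')``."""
    N = table.total
    if N <= 0:
        raise ValueError("total count must be positive")
    cells = CellDistribution(
        Fraction(table.n_ab, 1) / N,
        Fraction(table.n_a_nb, 1) / N,
        Fraction(table.n_na_b, 1) / N,
        Fraction(table.n_na_nb, 1) / N,
    )
    n_int = int(N) if Fraction(N).denominator == 1 else None
    return complete_from_cells(cells, events, n_int)


def natural_frequency(
    situation: CompletedSituation,
    N: Optional[int] = None,
    q: QuantityId = QuantityId.A_GIVEN_B,
) -> NaturalFrequency:
    """Express a quantity as nested counts, e.g. P(A|B) → '160 out of 1,140'.

    For a conditional P(X|Y) the pair is (N·P(X∩Y), N·P(Y)) with the
    conditioning event as reference set; marginals and joints refer to the
    whole population.
    """
    if N is None:
        N = situation.population_size
    if N is None or N < 1:
        raise ValueError("a positive population size N is required")
    if q is QuantityId.TOTAL:
        raise ValueError("TOTAL has no natural-frequency form")
    ev = situation.event_pair

    def _tidy(v: Fraction) -> Union[int, Fraction]:
        return int(v) if v.denominator == 1 else v

    if q.kind == "conditional":
        if situation.value(q) is None:
            raise ValueError(f"{q} is undefined (conditioning event impossible)")
        cond = q.conditioning_event
        targ = q.target_event
        joint = situation.cells.as_tuple()[_CELL_INDEX[frozenset((targ, cond))]]
        marg = situation.value(_MARGINAL_IDS[cond])
        ref = f"cases with {ev.label(cond)}"
        return NaturalFrequency(_tidy(N * joint), _tidy(N * marg), ref)
    value = situation.value(q)
    return NaturalFrequency(
        _tidy(N * value), N, f"all {N} cases"
    )


# ---------------------------------------------------------------------------
# spec-file reading/writing (JSON and equivalent YAML)

def _events_from_dict(d: Mapping[str, str]) -> EventPair:
    return EventPair(
        first_event_label=d.get("A", "A"),
        second_event_label=d.get("B", "B"),
        negation_labels=(d.get("notA", "not A"), d.get("notB", "not B")),
    )


def load_spec(
    source: Union[str, Path, Mapping],
) -> Tuple[PartialSpecification, EventPair]:
    """Read a situation spec from a JSON/YAML file or an equivalent dict.

    Format::

        {"events": {"A": ..., "notA": ..., "B": ..., "notB": ...},
         "given": {"P(A)": 0.02, "P(B|A)": "80%", ...},
         "frequencies": {"P(A&B)": 160, ...},
         "N": 10000}
    """
    if isinstance(source, Mapping):
        data = source
    else:
        path = Path(source)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            # parse_float receives the raw digit string: exact decimals
            data = json.loads(text, parse_float=lambda s: Fraction(s))
    events = _events_from_dict(data.get("events", {}))
    given = {
        parse_quantity(k): to_exact_fraction(v)[0]
        for k, v in (data.get("given") or {}).items()
    }
    exact = all(
        not isinstance(v, float) for v in (data.get("given") or {}).values()
    )
    freqs = {
        parse_quantity(k): int(v)
        for k, v in (data.get("frequencies") or {}).items()
    }
    spec = PartialSpecification(
        probabilities=given,
        frequencies=freqs,
        population_size=data.get("N"),
        exact_inputs=exact,
    )
    return spec, events


def situation_to_dict(situation: CompletedSituation) -> Dict:
    """Serialize to the spec-file format with all 16 quantities in 'given'."""
    ev = situation.event_pair
    given = {
        str(q): fraction_to_string(v)
        for q, v in situation.derived.items()
        if q is not QuantityId.TOTAL and v is not None
    }
    out: Dict = {
        "events": {
            "A": ev.first_event_label,
            "notA": ev.negation_labels[0],
            "B": ev.second_event_label,
            "notB": ev.negation_labels[1],
        },
        "given": given,
    }
    if situation.population_size is not None:
        out["N"] = situation.population_size
    return out


def save_situation(situation: CompletedSituation, path: Union[str, Path]) -> None:
    path = Path(path)
    data = situation_to_dict(situation)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")
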