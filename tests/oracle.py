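"""Independent symbolic oracle for the solver, used by the test suite only.

Solver status is re-derived with sympy from first principles: exact rank
computation on the linear system over the four cells, plus exact
enumeration of basic solutions (vertices of the constrained simplex) for
feasibility.  This shares no code with the package's own Gauss/
Fourier–Motzkin path.
"""

import itertools
import random
from fractions import Fraction as F

import sympy

from freqnet.quantities import QuantityId as Q


def oracle_status(given):
    x = sympy.symbols("x0 x1 x2 x3")
    margins = {
        "A": x[0] + x[1], "notA": x[2] + x[3],
        "B": x[0] + x[2], "notB": x[1] + x[3],
    }
    cells = {
        frozenset(("A", "B")): x[0], frozenset(("A", "notB")): x[1],
        frozenset(("notA", "B")): x[2], frozenset(("notA", "notB")): x[3],
    }
    eqs = [x[0] + x[1] + x[2] + x[3] - 1]
    for q, v in given.items():
        v = sympy.Rational(v)
        if q.kind == "marginal":
            eqs.append(margins[q.events[0]] - v)
        elif q.kind == "joint":
            eqs.append(cells[frozenset(q.events)] - v)
        else:
            cell = cells[frozenset((q.target_event, q.conditioning_event))]
            eqs.append(cell - v * margins[q.conditioning_event])
    A, b = sympy.linear_eq_to_matrix(eqs, x)
    rank = A.rank()
    if A.row_join(b).rank() > rank:
        return "inconsistent"
    dof = 4 - rank

    def basic_solutions():
        for zero_set in itertools.combinations(range(4), dof):
            sol = sympy.linsolve(eqs + [x[i] for i in zero_set], x)
            if sol is sympy.S.EmptySet:
                continue
            (expr,) = sol
            point = [e.subs({s: 0 for s in expr.free_symbols}) for e in expr]
            if all(p >= 0 for p in point):
                yield point

    feasible = next(iter(basic_solutions()), None)
    if feasible is None:
        return "inconsistent"
    for q in given:
        if q.kind != "conditional":
            continue
        marg = margins[q.conditioning_event]
        c, _ = sympy.linear_eq_to_matrix([marg], x)
        if A.col_join(c).rank() == rank:
            if marg.subs(dict(zip(x, feasible))) == 0:
                return "inconsistent"
    return "complete" if dof == 0 else "underdetermined"


def random_grid_spec(rng: random.Random):
    """1–3 quantities with values on a small rational grid."""
    quantities = [q for q in Q if q is not Q.TOTAL]
    chosen = rng.sample(quantities, rng.randint(1, 3))
    vals = {}
    for q in chosen:
        den = rng.choice([2, 4, 5, 10, 20])
        vals[q] = F(rng.randint(0, den), den)
    return vals
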