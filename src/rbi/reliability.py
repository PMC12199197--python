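"""Series-parallel reliability evaluation of Boolean rules.

A regulated gene (or a GPR-controlled reaction) is treated as a *system*
whose *components* are the regulators appearing in its Boolean rule. Each
component has a probability of being active; the rule's operator structure
maps onto reliability-theory component arrangements:

* ``AND`` is a series structure: ``r = prod(p_i)``,
* ``OR`` is a parallel structure: ``r = 1 - prod(1 - p_i)``,
* ``NOT`` is the complement: ``r = 1 - p``.

The recursion treats repeated occurrences of the same variable as
independent at every composition step. That is deliberate and normative: on
the ATP-synthase rule ``(AtpF0 AND AtpF1) OR (AtpF0 AND AtpF1 AND AtpI)``
with all probabilities 0.9 the compositional value is
``1 - (1 - 0.81)(1 - 0.729) = 0.948510``, which differs from the exact
Boolean probability 0.9477 obtained by enumerating truth assignments.
:func:`exact_probability` provides the enumeration as an independent oracle;
on read-once expressions (each variable appearing once) the two coincide.
"""

from __future__ import annotations

import math
from itertools import product
from typing import Mapping

from .rules import And, BooleanExpr, Not, Or, Var, variables

__all__ = ["reliability", "exact_probability", "MissingProbabilityError"]


class MissingProbabilityError(KeyError):
    """A rule references a component with no probability assigned."""

    def __init__(self, name: str) -> None:
        super().__init__(name)
        self.name = name

    def __str__(self) -> str:
        return f"no probability supplied for component {self.name!r}"


def _prob(name: str, probs: Mapping[str, float]) -> float:
    try:
        p = float(probs[name])
    except KeyError:
        raise MissingProbabilityError(name) from None
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability of {name!r} is {p}, outside [0, 1]")
    return p


def reliability(expr: BooleanExpr, probs: Mapping[str, float]) -> float:
    """Compositional series-parallel reliability of ``expr``.

    Parameters
    ----------
    expr
        Parsed Boolean rule.
    probs
        Component name -> probability of being active, each in [0, 1].
        Knocked-out components must map to exactly 0.

    Returns
    -------
    float
        System reliability in [0, 1].

    Raises
    ------
    MissingProbabilityError
        If a rule variable has no entry in ``probs``.
    """
    if isinstance(expr, Var):
        return _prob(expr.name, probs)
    if isinstance(expr, Not):
        return 1.0 - reliability(expr.child, probs)
    if isinstance(expr, And):
        r = 1.0
        for c in expr.children:
            r *= reliability(c, probs)
        return r
    if isinstance(expr, Or):
        q = 1.0
        for c in expr.children:
            q *= 1.0 - reliability(c, probs)
        return 1.0 - q
    raise TypeError(f"not a BooleanExpr: {expr!r}")


def _truth(expr: BooleanExpr, state: Mapping[str, bool]) -> bool:
    if isinstance(expr, Var):
        return state[expr.name]
    if isinstance(expr, Not):
        return not _truth(expr.child, state)
    if isinstance(expr, And):
        return all(_truth(c, state) for c in expr.children)
    if isinstance(expr, Or):
        return any(_truth(c, state) for c in expr.children)
    raise TypeError(f"not a BooleanExpr: {expr!r}")


def exact_probability(
    expr: BooleanExpr, probs: Mapping[str, float], max_variables: int = 20
) -> float:
    """Exact Boolean satisfaction probability by full enumeration.

    Sums ``prod_i p_i^{a_i} (1 - p_i)^{1 - a_i}`` over all 2^k truth
    assignments under which ``expr`` evaluates true. This is the independent
    test oracle for :func:`reliability`; the two agree (to rounding) exactly
    when the expression is read-once.

    Raises
    ------
    ValueError
        If the expression has more than ``max_variables`` distinct variables.
    """
    names = sorted(variables(expr))
    if len(names) > max_variables:
        raise ValueError(
            f"{len(names)} distinct variables exceed the enumeration limit "
            f"of {max_variables}"
        )
    p = [_prob(n, probs) for n in names]
    total = 0.0
    for assignment in product((False, True), repeat=len(names)):
        state = dict(zip(names, assignment))
        if _truth(expr, state):
            weight = math.prod(
                pi if ai else 1.0 - pi for pi, ai in zip(p, assignment)
            )
            total += weight
    return total
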