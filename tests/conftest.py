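"""Shared fixtures and random-expression generators.

All fixtures are generated programmatically; nothing is read from disk
except files the tests themselves write to tmp_path.
"""

from __future__ import annotations

import cobra
import numpy as np
import pytest

from rbi.rules import And, BooleanExpr, Not, Or, Var


def make_chain_model() -> cobra.Model:
    """EX_S (lb=-10) -> S --R1--> B -> BIOMASS; unique optimum 10."""
    model = cobra.Model("chain")
    s = cobra.Metabolite("S_c", compartment="c")
    b = cobra.Metabolite("B_c", compartment="c")
    ex = cobra.Reaction("EX_S", lower_bound=-10.0, upper_bound=1000.0)
    ex.add_metabolites({s: -1.0})
    r1 = cobra.Reaction("R1", lower_bound=0.0, upper_bound=1000.0)
    r1.add_metabolites({s: -1.0, b: 1.0})
    dm = cobra.Reaction("BIOMASS", lower_bound=0.0, upper_bound=1000.0)
    dm.add_metabolites({b: -1.0})
    model.add_reactions([ex, r1, dm])
    model.objective = "BIOMASS"
    return model


@pytest.fixture
def chain_model() -> cobra.Model:
    return make_chain_model()


def _flat(cls, children):
    """Flatten nested same-operator children (the parser's canonical form)."""
    out = []
    for c in children:
        if isinstance(c, cls):
            out.extend(c.children)
        else:
            out.append(c)
    return cls(tuple(out))


def random_expression(
    rng: np.random.Generator,
    max_depth: int = 4,
    n_vars: int = 8,
    allow_not: bool = True,
) -> BooleanExpr:
    """Random Boolean expression tree (variables may repeat)."""
    names = [f"x{i}" for i in range(n_vars)]

    def build(depth: int) -> BooleanExpr:
        if depth >= max_depth or rng.random() < 0.3:
            return Var(names[rng.integers(len(names))])
        kind = rng.choice(["and", "or", "not"] if allow_not else ["and", "or"])
        if kind == "not":
            return Not(build(depth + 1))
        width = int(rng.integers(2, 4))
        cls = And if kind == "and" else Or
        return _flat(cls, (build(depth + 1) for _ in range(width)))

    return build(0)


def random_read_once(
    rng: np.random.Generator,
    names: list[str],
    allow_not: bool = True,
    depth: int = 0,
) -> BooleanExpr:
    """Random read-once expression over exactly the given fresh names."""
    if allow_not and depth > 0 and rng.random() < 0.25:
        return Not(random_read_once(rng, names, allow_not, depth + 1))
    if len(names) == 1:
        return Var(names[0])
    n_groups = int(rng.integers(2, min(4, len(names)) + 1))
    cuts = sorted(
        rng.choice(np.arange(1, len(names)), size=n_groups - 1, replace=False)
    )
    groups, start = [], 0
    for cut in list(cuts) + [len(names)]:
        groups.append(names[start:cut])
        start = cut
    cls = And if rng.random() < 0.5 else Or
    return _flat(
        cls, (random_read_once(rng, g, allow_not, depth + 1) for g in groups)
    )


def not_parities(expr: BooleanExpr) -> dict[str, int]:
    """Number of NOT nodes above each variable occurrence, summed per name.

    For read-once expressions this is the NOT depth of the unique
    occurrence: even parity means the system is monotone increasing in that
    component, odd means decreasing.
    """
    parity: dict[str, int] = {}

    def walk(node: BooleanExpr, depth: int) -> None:
        if isinstance(node, Var):
            parity[node.name] = parity.get(node.name, 0) + depth
        elif isinstance(node, Not):
            walk(node.child, depth + 1)
        else:
            for c in node.children:
                walk(c, depth)

    walk(expr, 0)
    return parity
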