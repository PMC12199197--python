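"""Synthetic toy inputs: metabolic models, GRNs, expression, knockout schemes.

Everything the pipeline consumes can be generated here deterministically
from a seed, so the whole package builds and tests without any external
model or dataset. The toy metabolic models are branched uptake->drain
networks (one substrate exchange at -10 mmol/gDW/h, unit-stoichiometry
pathways feeding a biomass drain and a target-metabolite drain) with GPR
rules cycling through the structural forms that matter to the reliability
engine: single gene, complex (AND), isozymes (OR) and a nested
OR-of-ANDs. The GRN generator mirrors a one-layer TF->gene topology with
optional inhibition (NOT) and the nested activation/inhibition motif
``(TFa AND (NOT TFb)) OR TFb`` seen in empirical networks.

These toys emulate the *structure* real inputs expose (compartments,
boundary reactions, GPR dialects, rule shapes, bimodal expression); they do
not emulate genome-scale topology, which real users supply themselves.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence, Union

import cobra
import numpy as np
import pandas as pd

from .model import KnockoutScheme
from .regnet import GRNModel

__all__ = [
    "make_toy_model",
    "make_toy_grn",
    "make_expression",
    "make_schemes",
    "make_activation_fixture",
    "write_fixture_dir",
]

_GPR_FORMS = ("single", "and", "or", "nested")


def _gpr(form: str, genes: Sequence[str]) -> str:
    if form == "single":
        return genes[0]
    if form == "and":
        return f"{genes[0]} and {genes[1]}"
    if form == "or":
        return f"{genes[0]} or {genes[1]}"
    if form == "nested":
        g0, g1, g2 = genes[0], genes[1], genes[2]
        return f"({g0} and {g1}) or ({g0} and {g1} and {g2})"
    raise ValueError(form)


def make_toy_model(n_branches: int = 1, seed: int = 0) -> cobra.Model:
    """Branched toy metabolic model, feasible with wild-type optimum 10.

    One substrate exchange (lb = -10), ``n_branches`` unit-stoichiometry
    pathways of 2-4 internal reactions each with a distinct GPR (cycling
    single/AND/OR/nested forms), a biomass drain (the objective) and — when
    a target pathway exists, i.e. ``n_branches >= 2`` — a target-metabolite
    drain. Odd-numbered branches feed biomass, even-numbered ones the
    target, so with two or more branches both drains can carry flux
    simultaneously. Deterministic given ``seed``.
    """
    if n_branches < 1:
        raise ValueError(f"n_branches must be >= 1, got {n_branches}")
    rng = np.random.default_rng(seed)
    model = cobra.Model(f"toy_{n_branches}_branches")
    substrate = cobra.Metabolite("S_c", compartment="c")
    biomass_met = cobra.Metabolite("BM_c", compartment="c")
    reactions = []

    ex = cobra.Reaction("EX_S", lower_bound=-10.0, upper_bound=1000.0)
    ex.add_metabolites({substrate: -1.0})
    reactions.append(ex)

    target_met = None
    gpr_index = 0
    for branch in range(1, n_branches + 1):
        if branch % 2 == 1:
            end = biomass_met
        else:
            if target_met is None:
                target_met = cobra.Metabolite("TGT_c", compartment="c")
            end = target_met
        # first (biomass) chain kept short so the one-branch model stays tiny
        length = int(rng.integers(2, 4)) if branch == 1 else int(rng.integers(2, 5))
        previous = substrate
        for step in range(1, length + 1):
            if step < length:
                nxt = cobra.Metabolite(f"M{branch}_{step}_c", compartment="c")
            else:
                nxt = end
            rxn = cobra.Reaction(f"B{branch}R{step}", lower_bound=0.0, upper_bound=1000.0)
            rxn.add_metabolites({previous: -1.0, nxt: 1.0})
            form = _GPR_FORMS[gpr_index % len(_GPR_FORMS)]
            gpr_index += 1
            genes = [f"b{branch}r{step}g{k}" for k in range(1, 4)]
            rxn.gene_reaction_rule = _gpr(form, genes)
            reactions.append(rxn)
            previous = nxt

    dm_biomass = cobra.Reaction("BIOMASS", lower_bound=0.0, upper_bound=1000.0)
    dm_biomass.add_metabolites({biomass_met: -1.0})
    reactions.append(dm_biomass)
    if target_met is not None:
        dm_target = cobra.Reaction("EX_TGT", lower_bound=0.0, upper_bound=1000.0)
        dm_target.add_metabolites({target_met: -1.0})
        reactions.append(dm_target)

    model.add_reactions(reactions)
    model.objective = "BIOMASS"
    return model


_RULE_FORMS = ("var", "and", "or", "not", "motif")


def _rule(form: str, tfs: Sequence[str]) -> str:
    a, b = tfs[0], tfs[1]
    if form == "var":
        return a
    if form == "and":
        return f"{a} AND {b}"
    if form == "or":
        return f"{a} OR {b}"
    if form == "not":
        return f"NOT {a}"
    if form == "motif":
        return f"({a} AND (NOT {b})) OR {b}"
    raise ValueError(form)


def make_toy_grn(
    model: cobra.Model,
    frac_regulated: float = 0.5,
    include_inhibition: bool = True,
    seed: int = 0,
) -> GRNModel:
    """Assign Boolean rules over 2-6 synthetic TFs to model genes.

    A ``frac_regulated`` share of the model's genes (rounded) receives a
    rule; the rest stay unregulated (reliability one downstream). With
    ``include_inhibition`` the first two regulated genes get the nested
    activation/inhibition motif and a pure NOT rule, guaranteeing both
    interaction types appear. Deterministic given ``seed``.
    """
    if not 0.0 <= frac_regulated <= 1.0:
        raise ValueError(f"frac_regulated must be in [0, 1], got {frac_regulated}")
    rng = np.random.default_rng(seed)
    genes = sorted(g.id for g in model.genes)
    n_tfs = int(rng.integers(2, 7))
    tfs = [f"TF{i}" for i in range(1, n_tfs + 1)]
    n_regulated = int(round(frac_regulated * len(genes)))
    order = rng.permutation(len(genes))
    regulated = [genes[i] for i in order[:n_regulated]]

    forms = _RULE_FORMS if include_inhibition else _RULE_FORMS[:3]
    rules: dict[str, str] = {}
    for idx, gene in enumerate(regulated):
        if include_inhibition and idx == 0:
            form = "motif"
        elif include_inhibition and idx == 1:
            form = "not"
        else:
            form = forms[idx % 3]
        pick = rng.choice(n_tfs, size=2, replace=False)
        rules[gene] = _rule(form, [tfs[pick[0]], tfs[pick[1]]])
    return GRNModel.from_strings(rules)


def make_expression(
    genes: Sequence[str],
    d: int = 20,
    high_fraction: Union[float, Mapping[str, float]] = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Bimodal genes x samples expression matrix.

    Per gene, ``round(high_fraction * d)`` of the ``d`` samples are drawn
    from a high component (N(10, 0.15)) and the rest from a low component
    (N(2, 0.15)), at shuffled positions, so that binarization at the pooled
    median of a mixed panel recovers ~``high_fraction`` as the on-fraction.
    ``high_fraction`` may be a scalar or a per-gene mapping. Deterministic
    given ``seed``.
    """
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes:
        if isinstance(high_fraction, Mapping):
            frac = float(high_fraction.get(gene, 0.5))
        else:
            frac = float(high_fraction)
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"high_fraction for {gene!r} outside [0, 1]: {frac}")
        n_high = int(round(frac * d))
        low = rng.normal(2.0, 0.15, size=d)
        high = rng.normal(10.0, 0.15, size=d)
        mask = np.zeros(d, dtype=bool)
        mask[rng.permutation(d)[:n_high]] = True
        rows.append(np.where(mask, high, low))
    return pd.DataFrame(
        np.array(rows).reshape(len(genes), d),
        index=list(genes),
        columns=[f"S{j}" for j in range(1, d + 1)],
    )


def make_schemes(grn: GRNModel, max_pairs: int = 3, seed: int = 0) -> list[KnockoutScheme]:
    """Knockout schemes: wild type, every single TF, a few seeded pairs."""
    rng = np.random.default_rng(seed)
    tfs = sorted(grn.regulators)
    schemes = [KnockoutScheme("WT", frozenset())]
    schemes += [KnockoutScheme(f"d{tf}", frozenset((tf,))) for tf in tfs]
    if len(tfs) >= 2:
        for _ in range(max_pairs):
            pick = rng.choice(len(tfs), size=2, replace=False)
            pair = frozenset((tfs[pick[0]], tfs[pick[1]]))
            name = "d" + "+d".join(sorted(pair))
            if all(s.tfs != pair for s in schemes):
                schemes.append(KnockoutScheme(name, pair))
    return schemes


def make_activation_fixture(inhibit: bool = False) -> tuple[cobra.Model, GRNModel]:
    """Three-reaction chain whose sole flux-carrying reaction is regulated.

    ``EX_S (lb=-10) -> S --R1--> B -> BIOMASS`` with R1 carrying GPR ``G1``.
    The GRN rule is ``G1 = T`` (sole activator; knocking out T kills all
    flux) or, with ``inhibit=True``, ``G1 = NOT T`` (knocking out T leaves
    the wild-type optimum intact).
    """
    model = cobra.Model("chain_regulated")
    s = cobra.Metabolite("S_c", compartment="c")
    b = cobra.Metabolite("B_c", compartment="c")
    ex = cobra.Reaction("EX_S", lower_bound=-10.0, upper_bound=1000.0)
    ex.add_metabolites({s: -1.0})
    r1 = cobra.Reaction("R1", lower_bound=0.0, upper_bound=1000.0)
    r1.add_metabolites({s: -1.0, b: 1.0})
    r1.gene_reaction_rule = "G1"
    dm = cobra.Reaction("BIOMASS", lower_bound=0.0, upper_bound=1000.0)
    dm.add_metabolites({b: -1.0})
    model.add_reactions([ex, r1, dm])
    model.objective = "BIOMASS"
    rule = "NOT T" if inhibit else "T"
    return model, GRNModel.from_strings({"G1": rule})


def write_fixture_dir(
    out: str | Path,
    n_branches: int = 3,
    seed: int = 0,
    d: int = 20,
    frac_regulated: float = 0.8,
) -> dict[str, Path]:
    """Emit a complete on-disk fixture set: model.json, grn.tsv, expr.tsv,
    schemes.csv. Returns the paths written."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    model = make_toy_model(n_branches, seed=seed)
    grn = make_toy_grn(model, frac_regulated=frac_regulated, seed=seed + 1)
    regulators = sorted(grn.regulators)
    fractions = {tf: float(rng.uniform(0.2, 0.8)) for tf in regulators}
    expression = make_expression(regulators, d=d, high_fraction=fractions, seed=seed + 2)
    schemes = make_schemes(grn, seed=seed + 3)

    paths = {
        "model": out / "model.json",
        "grn": out / "grn.tsv",
        "expression": out / "expr.tsv",
        "schemes": out / "schemes.csv",
    }
    cobra.io.save_json_model(model, str(paths["model"]))
    grn.to_tsv(paths["grn"])
    expression.to_csv(paths["expression"], sep="\t", float_format="%.6f")
    lines = ["scheme,tfs"]
    lines += [f"{s.name},{';'.join(sorted(s.tfs))}" for s in schemes]
    paths["schemes"].write_text("\n".join(lines) + "\n")
    return paths
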