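"""Metabolic model I/O, exempt-reaction classification and reaction reliabilities.

The in-memory container is :class:`cobra.Model` (stoichiometry, bounds in
mmol/gDW/h, GPR rule strings, objective), read from SBML Level 3 + FBC or
COBRA JSON. This module adds what the integration needs on top:

* validation of the loaded model (bounds ordered, objective present),
* classification of reactions exempt from regulatory bound updates —
  exchange/boundary reactions, cross-compartment transporters and the ATP
  maintenance pseudo-reaction are structural and stay untouched,
* reaction reliabilities: each GPR rule evaluated by the series-parallel
  engine with gene reliabilities as component probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import cobra
import pandas as pd

from .regnet import RBIParams
from .reliability import reliability
from .rules import parse_rule

__all__ = [
    "read_model",
    "validate_model",
    "classify_exempt",
    "reaction_reliabilities",
    "ReliabilityReport",
]


def read_model(path: str | Path, fmt: Optional[str] = None) -> cobra.Model:
    """Load a genome-scale metabolic model from SBML or COBRA JSON.

    ``fmt`` is 'sbml' or 'json'; when omitted it is inferred from the file
    extension (.xml/.sbml -> SBML, .json -> JSON). Unset bounds default to
    +/-1000 (the cobra convention). The loaded model is validated: bounds
    must be ordered and an objective must be set.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    if fmt is None:
        suffix = path.suffix.lower()
        if suffix in (".xml", ".sbml"):
            fmt = "sbml"
        elif suffix == ".json":
            fmt = "json"
        else:
            raise ValueError(
                f"cannot infer model format from extension {suffix!r}; "
                "pass fmt='sbml' or fmt='json'"
            )
    if fmt == "sbml":
        model = cobra.io.read_sbml_model(str(path))
    elif fmt == "json":
        model = cobra.io.load_json_model(str(path))
    else:
        raise ValueError(f"unknown model format {fmt!r}")
    validate_model(model)
    return model


def validate_model(model: cobra.Model) -> None:
    """Raise ``ValueError`` on unordered bounds or a missing objective."""
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            raise ValueError(
                f"reaction {rxn.id!r} has lower bound {rxn.lower_bound} above "
                f"upper bound {rxn.upper_bound}"
            )
    coefficients = cobra.util.solver.linear_reaction_coefficients(model)
    if not coefficients:
        raise ValueError("model has no objective reaction set")


def classify_exempt(
    model: cobra.Model,
    include_exchanges: bool = True,
    extra: Iterable[str] = (),
) -> frozenset[str]:
    """Reaction ids never touched by regulatory bound updates.

    The union of (a) exchange/boundary reactions (single-metabolite
    stoichiometry), (b) transport reactions, i.e. reactions whose metabolites
    span two or more compartments, and (c) the ATP maintenance
    pseudo-reaction, matched case-insensitively on the id ``ATPM`` plus any
    ids in ``extra`` (model dialects vary: ATPM, R_ATPM, NGAM...).

    ``include_exchanges=False`` restricts (a)+(b) to cross-compartment
    transporters only.
    """
    extra_upper = {e.upper() for e in extra}
    exempt: set[str] = set()
    for rxn in model.reactions:
        if rxn.id.upper() == "ATPM" or rxn.id.upper() in extra_upper:
            exempt.add(rxn.id)
            continue
        if include_exchanges and len(rxn.metabolites) == 1:
            exempt.add(rxn.id)
            continue
        compartments = {m.compartment for m in rxn.metabolites if m.compartment}
        if len(compartments) >= 2:
            exempt.add(rxn.id)
    return frozenset(exempt)


def reaction_reliabilities(
    model: cobra.Model, gene_rel: Mapping[str, float]
) -> dict[str, float]:
    """Reliability of every reaction from its GPR rule.

    The GPR Boolean expression is evaluated by the series-parallel engine
    with gene reliabilities as component probabilities; a reaction without
    a GPR is unregulated and gets reliability 1.0.
    """
    out: dict[str, float] = {}
    for rxn in model.reactions:
        rule = rxn.gene_reaction_rule
        if not rule or not rule.strip():
            out[rxn.id] = 1.0
        else:
            out[rxn.id] = reliability(parse_rule(rule), gene_rel)
    return out


@dataclass
class ReliabilityReport:
    """Every intermediate quantity of one integration run.

    TF probabilities, gene reliabilities ``r_MG``, reaction reliabilities
    ``r_RF``, the exempt set, the FVA reference intervals and the bounds
    before/after the update, plus the parameters and knockouts used.
    """

    params: RBIParams
    knockouts: frozenset[str]
    tf_probabilities: dict[str, float]
    gene_reliabilities: dict[str, float]
    reaction_reliabilities: dict[str, float]
    exempt: frozenset[str]
    reference_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    bounds_before: dict[str, tuple[float, float]] = field(default_factory=dict)
    bounds_after: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Per-reaction table: reliability, exemption flag, old/new bounds."""
        rows = []
        for rid in sorted(self.reaction_reliabilities):
            lb0, ub0 = self.bounds_before.get(rid, (float("nan"), float("nan")))
            lb1, ub1 = self.bounds_after.get(rid, (lb0, ub0))
            ref = self.reference_bounds.get(rid, (float("nan"), float("nan")))
            rows.append(
                {
                    "reaction": rid,
                    "reliability": self.reaction_reliabilities[rid],
                    "exempt": rid in self.exempt,
                    "ref_lb": ref[0],
                    "ref_ub": ref[1],
                    "old_lb": lb0,
                    "old_ub": ub0,
                    "new_lb": lb1,
                    "new_ub": ub1,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.9g")
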