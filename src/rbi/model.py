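"""The reliability-based integration pipeline and strain design.

:class:`RBIModel` ties a genome-scale metabolic model, an empirical GRN and
(optionally) an expression matrix together; ``fit(knockouts=...)`` executes
the ten-step procedure and returns an :class:`RBIResults`:

1.  gather inputs (metabolic model, GRN, expression data),
2.  choose the TFs to knock out,
3.  initial TF probabilities per variant (knocked-out TFs -> 0),
4.  gene reliabilities ``r_MG`` by series-parallel evaluation of GRN rules,
5.  unregulated metabolic genes get probability one,
6.  reaction reliabilities ``r_RF`` from GPR rules,
7.  reference flux intervals ``[lb*, ub*]`` by FVA,
8.  soft regulatory constraints: for every non-exempt reaction with
    ``r <= beta``, ``ub = r ub* + gamma`` and ``lb = r lb* - gamma``
    (transport, exchange and ATP-maintenance reactions are exempt),
9.  FBA on the constrained model,
10. the optimal flux distribution.

Strain design (``design``/:func:`simulate_scheme`) runs the pipeline for a
TF-knockout scheme and reports growth, target production under a minimum
growth requirement (two-stage FBA: constrain biomass, then maximize the
target drain) and whether the mutant is growth-coupled.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import cobra
import pandas as pd

from .lp import OPTIMAL, FluxBounds, FluxDistribution, fba, fva
from .metnet import (
    ReliabilityReport,
    classify_exempt,
    reaction_reliabilities,
    validate_model,
)
from .regnet import (
    GRNModel,
    RBIParams,
    binarize_expression,
    gene_reliabilities,
    initial_tf_probabilities,
    read_expression,
    read_grn,
)
from .metnet import read_model

__all__ = [
    "RBIModel",
    "RBIResults",
    "KnockoutScheme",
    "DesignResult",
    "apply_regulatory_constraints",
    "run_rbi",
    "simulate_scheme",
    "read_schemes",
    "default_gamma",
]


def default_gamma(model: cobra.Model) -> float:
    """Soft-constraint slack used when none is given: 0.001 x max |bound|."""
    biggest = max(
        (max(abs(r.lower_bound), abs(r.upper_bound)) for r in model.reactions),
        default=1000.0,
    )
    return 0.001 * biggest


def apply_regulatory_constraints(
    model: cobra.Model,
    r_rf: Mapping[str, float],
    ref: FluxBounds,
    beta: float,
    gamma: float,
    exempt: Optional[Iterable[str]] = None,
    clip_to_original: bool = False,
) -> cobra.Model:
    """Return a copy of ``model`` with reliability-softened bounds.

    Every reaction ``k`` that is not exempt and has ``r_rf[k] <= beta``
    gets ``ub_k = r ub*_k + gamma`` and ``lb_k = r lb*_k - gamma``; all
    other reactions keep their original bounds. With
    ``clip_to_original=True`` the updated interval is additionally
    intersected with the original bounds (off by default: the update is
    applied literally).
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    exempt_set = frozenset(exempt) if exempt is not None else classify_exempt(model)
    missing = [r.id for r in model.reactions if r.id not in r_rf or r.id not in ref]
    if missing:
        raise ValueError(
            f"reliabilities/reference bounds missing for reactions: {missing[:5]}"
        )
    constrained = model.copy()
    for rxn in constrained.reactions:
        if rxn.id in exempt_set:
            continue
        r = r_rf[rxn.id]
        if r > beta:
            continue
        lb_star, ub_star = ref[rxn.id]
        new_lb = r * lb_star - gamma
        new_ub = r * ub_star + gamma
        if clip_to_original:
            new_lb = max(new_lb, rxn.lower_bound)
            new_ub = min(new_ub, rxn.upper_bound)
            if new_lb > new_ub:  # disjoint after clipping: collapse to nearest point
                new_lb = new_ub = max(rxn.lower_bound, min(rxn.upper_bound, 0.0))
        rxn.bounds = (new_lb, new_ub)
    return constrained


@dataclass(frozen=True)
class KnockoutScheme:
    """A named set of transcription factors to delete in silico."""

    name: str
    tfs: frozenset[str]

    @classmethod
    def of(cls, *tfs: str, name: Optional[str] = None) -> "KnockoutScheme":
        return cls(name or "+".join(sorted(tfs)) or "WT", frozenset(tfs))


def read_schemes(path: str | Path) -> list[KnockoutScheme]:
    """Read knockout schemes from CSV (``scheme,tfs`` with ';'-separated TFs)
    or from a plain list (one TF set per line, whitespace-separated)."""
    path = Path(path)
    schemes: list[KnockoutScheme] = []
    text = path.read_text()
    if path.suffix.lower() == ".csv":
        reader = csv.DictReader(text.splitlines())
        if reader.fieldnames is None or "scheme" not in reader.fieldnames:
            raise ValueError(f"{path}: expected CSV with a 'scheme' column")
        for row in reader:
            tfs = [t for t in (row.get("tfs") or "").replace(";", " ").split() if t]
            schemes.append(KnockoutScheme(row["scheme"], frozenset(tfs)))
    else:
        for i, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tfs = line.split()
            schemes.append(KnockoutScheme(f"scheme{i}", frozenset(tfs)))
    return schemes


@dataclass(frozen=True)
class DesignResult:
    """Outcome of simulating one knockout scheme against a target drain."""

    scheme: KnockoutScheme
    growth: float
    production: float
    growth_coupled: bool
    min_growth: float
    status: str

    def as_row(self) -> dict:
        return {
            "scheme": self.scheme.name,
            "knockouts": ";".join(sorted(self.scheme.tfs)),
            "growth": self.growth,
            "production": self.production,
            "growth_coupled": self.growth_coupled,
            "min_growth": self.min_growth,
            "status": self.status,
        }


class RBIResults:
    """Results of one integration run.

    Attributes
    ----------
    fluxes : FluxDistribution
        Optimal flux distribution of the constrained model (status carries
        infeasibility instead of raising).
    report : ReliabilityReport
        Every intermediate quantity: TF probabilities, gene and reaction
        reliabilities, exemptions, reference intervals, old/new bounds.
    constrained_model : cobra.Model
        The bound-updated model (for follow-up analyses such as design).
    """

    def __init__(
        self,
        model: "RBIModel",
        fluxes: FluxDistribution,
        report: ReliabilityReport,
        constrained_model: cobra.Model,
    ) -> None:
        self.model = model
        self.fluxes = fluxes
        self.report = report
        self.constrained_model = constrained_model

    @property
    def objective_value(self) -> float:
        return self.fluxes.objective_value

    @property
    def status(self) -> str:
        return self.fluxes.status

    def to_tsv(self, path: str | Path) -> None:
        self.report.to_tsv(path)

    def summary(self) -> str:
        """Human-readable run summary."""
        rep = self.report
        p = rep.params
        n_updated = sum(
            1
            for rid, (lb0, ub0) in rep.bounds_before.items()
            if rep.bounds_after.get(rid, (lb0, ub0)) != (lb0, ub0)
        )
        lines = [
            "Reliability-based integration results",
            "=" * 45,
            f"variant:              {p.variant}",
            f"alpha / beta / gamma: {p.alpha} / {p.beta} / {rep.params.gamma}",
            f"fva fraction:         {p.fva_fraction}",
            f"knockouts:            {', '.join(sorted(rep.knockouts)) or '(none)'}",
            f"reactions:            {len(rep.reaction_reliabilities)}"
            f"  (exempt: {len(rep.exempt)}, bounds updated: {n_updated})",
            f"regulated genes:      "
            f"{sum(1 for r in rep.gene_reliabilities.values() if r != 1.0)}"
            f" of {len(rep.gene_reliabilities)} below reliability 1",
            f"solver status:        {self.status}",
            f"objective value:      {self.objective_value:.6f}"
            if self.status == OPTIMAL
            else "objective value:      n/a",
        ]
        return "\n".join(lines)


class RBIModel:
    """Reliability-based regulatory-metabolic integration.

    Parameters
    ----------
    metabolic_model
        A validated :class:`cobra.Model` (bounds in mmol/gDW/h, GPR rule
        strings, objective set).
    grn
        Empirical GRN mapping regulated genes to Boolean rules over TFs.
    expression
        Genes x samples matrix; required for variants T2/T3.
    params
        :class:`~rbi.regnet.RBIParams`; ``gamma=None`` resolves to
        ``0.001 x max |bound|``.
    component_probs
        Optional probability overrides for individual regulators, e.g.
        environmental-condition literals.
    gene_knockouts
        Metabolic genes whose reliability is forced to 0 (an extension
        beyond TF knockouts).
    """

    def __init__(
        self,
        metabolic_model: cobra.Model,
        grn: GRNModel,
        expression: Optional[pd.DataFrame] = None,
        params: Optional[RBIParams] = None,
        component_probs: Optional[Mapping[str, float]] = None,
        gene_knockouts: Iterable[str] = (),
        include_exchanges_exempt: bool = True,
        extra_exempt: Iterable[str] = (),
        propagate: bool = False,
        clip_to_original: bool = False,
    ) -> None:
        validate_model(metabolic_model)
        self.metabolic_model = metabolic_model
        self.grn = grn
        self.expression = expression
        self.params = params or RBIParams()
        self.component_probs = dict(component_probs) if component_probs else None
        self.gene_knockouts = frozenset(gene_knockouts)
        self.include_exchanges_exempt = include_exchanges_exempt
        self.extra_exempt = tuple(extra_exempt)
        self.propagate = propagate
        self.clip_to_original = clip_to_original
        if self.params.variant in ("T2", "T3") and expression is None:
            raise ValueError(
                f"variant {self.params.variant} requires an expression matrix"
            )

    @classmethod
    def from_files(
        cls,
        model_path: str | Path,
        grn_path: str | Path,
        expression_path: Optional[str | Path] = None,
        params: Optional[RBIParams] = None,
        **kwargs,
    ) -> "RBIModel":
        expression = (
            read_expression(expression_path) if expression_path is not None else None
        )
        return cls(
            read_model(model_path), read_grn(grn_path), expression, params, **kwargs
        )

    def _resolved_gamma(self) -> float:
        if self.params.gamma is not None:
            return self.params.gamma
        return default_gamma(self.metabolic_model)

    def fit(self, knockouts: Iterable[str] = ()) -> RBIResults:
        """Run the full pipeline for one TF-knockout set."""
        params = self.params
        knockouts = frozenset(knockouts)
        gamma = self._resolved_gamma()

        binary = None
        if params.variant in ("T2", "T3"):
            binary = binarize_expression(self.expression, params.alpha)

        tf_probs = initial_tf_probabilities(
            self.grn,
            variant=params.variant,
            knockouts=knockouts,
            binary=binary,
            component_probs=self.component_probs,
        )
        model_genes = {g.id for g in self.metabolic_model.genes}
        gene_rel = gene_reliabilities(
            self.grn, tf_probs, model_genes, propagate=self.propagate
        )
        for gene in self.gene_knockouts:
            gene_rel[gene] = 0.0
        r_rf = reaction_reliabilities(self.metabolic_model, gene_rel)
        exempt = classify_exempt(
            self.metabolic_model,
            include_exchanges=self.include_exchanges_exempt,
            extra=self.extra_exempt,
        )
        reference = fva(self.metabolic_model, params.fva_fraction)
        constrained = apply_regulatory_constraints(
            self.metabolic_model,
            r_rf,
            reference,
            params.beta,
            gamma,
            exempt=exempt,
            clip_to_original=self.clip_to_original,
        )
        solution = fba(constrained)

        report = ReliabilityReport(
            params=params.with_gamma(gamma),
            knockouts=knockouts,
            tf_probabilities=tf_probs,
            gene_reliabilities=gene_rel,
            reaction_reliabilities=r_rf,
            exempt=exempt,
            reference_bounds={rid: reference[rid] for rid in reference},
            bounds_before={
                r.id: (r.lower_bound, r.upper_bound)
                for r in self.metabolic_model.reactions
            },
            bounds_after={
                r.id: (r.lower_bound, r.upper_bound) for r in constrained.reactions
            },
        )
        return RBIResults(self, solution, report, constrained)

    def design(
        self,
        scheme: KnockoutScheme,
        target: str,
        min_growth: Optional[float] = None,
        biomass: Optional[str] = None,
    ) -> DesignResult:
        """Simulate one knockout scheme and score growth coupling.

        Growth is the FBA optimum of the biomass objective on the
        constrained model; production is the FBA optimum of ``target``
        with biomass constrained to at least ``min_growth`` (two-stage).
        ``min_growth`` defaults to 5% of the wild-type (unconstrained,
        no-knockout) growth. The scheme is growth-coupled when the mutant
        both reaches ``min_growth`` and produces the target.
        """
        if min_growth is not None and min_growth < 0:
            raise ValueError(f"min_growth must be >= 0, got {min_growth}")
        if target not in self.metabolic_model.reactions:
            raise KeyError(f"target reaction {target!r} not in model")
        if biomass is None:
            coefs = cobra.util.solver.linear_reaction_coefficients(self.metabolic_model)
            biomass = next(iter(coefs)).id
        if min_growth is None:
            wild_type = fba(self.metabolic_model, objective=biomass)
            min_growth = 0.05 * max(wild_type.objective_value, 0.0)

        result = self.fit(knockouts=scheme.tfs)
        constrained = result.constrained_model
        growth_solution = fba(constrained, objective=biomass)
        growth = (
            growth_solution.objective_value
            if growth_solution.status == OPTIMAL
            else 0.0
        )
        with constrained as m:
            m.reactions.get_by_id(biomass).lower_bound = min_growth
            production_solution = fba(m, objective=target)
        if production_solution.status == OPTIMAL:
            production = production_solution.objective_value
        else:
            production = 0.0
        coupled = (
            growth_solution.status == OPTIMAL
            and growth >= min_growth
            and production > 0.0
        )
        return DesignResult(
            scheme=scheme,
            growth=growth,
            production=production,
            growth_coupled=coupled,
            min_growth=min_growth,
            status=growth_solution.status,
        )


def run_rbi(
    model: cobra.Model,
    grn: GRNModel,
    expression: Optional[pd.DataFrame] = None,
    params: Optional[RBIParams] = None,
    knockouts: Iterable[str] = (),
    **kwargs,
) -> tuple[FluxDistribution, ReliabilityReport]:
    """Functional one-shot entry point; see :class:`RBIModel.fit`."""
    results = RBIModel(model, grn, expression, params, **kwargs).fit(knockouts)
    return results.fluxes, results.report


def simulate_scheme(
    model: cobra.Model,
    grn: GRNModel,
    expression: Optional[pd.DataFrame],
    params: Optional[RBIParams],
    scheme: KnockoutScheme,
    target: str,
    min_growth: Optional[float] = None,
    **kwargs,
) -> DesignResult:
    """Functional one-shot entry point; see :class:`RBIModel.design`."""
    return RBIModel(model, grn, expression, params, **kwargs).design(
        scheme, target, min_growth=min_growth
    )
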