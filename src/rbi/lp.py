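"""Linear-programming kernel: FBA and FVA over a cobra model.

Thin, deterministic wrappers around cobra's optlang/GLPK interface. FBA
maximizes (or minimizes) one reaction's flux subject to steady state
``S v = 0`` and the flux bounds; FVA computes per-reaction min/max flux,
optionally requiring the objective to stay at a fraction of its optimum,
yielding the reference intervals ``[lb*, ub*]`` used by the regulatory
bound update.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import cobra
from cobra.flux_analysis import flux_variability_analysis

__all__ = [
    "FluxDistribution",
    "FluxBounds",
    "fba",
    "fva",
    "export_lp",
    "InfeasibleModelError",
]

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"


class InfeasibleModelError(RuntimeError):
    """The base model admits no steady-state flux distribution."""


@dataclass(frozen=True)
class FluxDistribution:
    """One FBA solution: fluxes, objective value and solver status.

    When ``status != 'optimal'`` the fluxes dict is empty and
    ``objective_value`` is ``nan``.
    """

    fluxes: dict[str, float]
    objective_value: float
    status: str

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


@dataclass(frozen=True)
class FluxBounds:
    """Per-reaction flux intervals ``[lb*, ub*]`` from FVA."""

    bounds: dict[str, tuple[float, float]]

    def __getitem__(self, reaction_id: str) -> tuple[float, float]:
        return self.bounds[reaction_id]

    def __contains__(self, reaction_id: str) -> bool:
        return reaction_id in self.bounds

    def __iter__(self) -> Iterator[str]:
        return iter(self.bounds)

    def __len__(self) -> int:
        return len(self.bounds)


def _status(solution: "cobra.Solution") -> str:
    status = solution.status
    if status not in (OPTIMAL, INFEASIBLE, UNBOUNDED):
        # optlang may report e.g. 'undefined' for GLPK infeasibilities
        return INFEASIBLE
    return status


def fba(
    model: cobra.Model,
    objective: Optional[str] = None,
    sense: str = "max",
) -> FluxDistribution:
    """Flux balance analysis.

    Parameters
    ----------
    model
        Valid metabolic model; it is not modified (objective changes are
        applied inside a context and rolled back).
    objective
        Reaction id to optimize; default: the model's configured objective.
    sense
        'max' or 'min'.

    Infeasible or unbounded problems are encoded in the returned status,
    not raised.
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    with model as m:
        if objective is not None:
            if objective not in m.reactions:
                raise KeyError(f"objective reaction {objective!r} not in model")
            m.objective = objective
        m.objective_direction = sense
        solution = m.optimize()
        status = _status(solution)
        if status != OPTIMAL:
            return FluxDistribution({}, float("nan"), status)
        return FluxDistribution(
            dict(solution.fluxes), float(solution.objective_value), status
        )


def fva(model: cobra.Model, fraction_of_optimum: float = 0.0) -> FluxBounds:
    """Flux variability analysis over every reaction.

    Solves 2n LPs: per reaction the min and max flux subject to steady
    state, the model bounds and (for ``fraction_of_optimum > 0``) the
    objective held at at least that fraction of its FBA optimum.
    ``fraction_of_optimum = 0`` gives the widest feasible reference
    intervals with no growth requirement.

    Raises
    ------
    InfeasibleModelError
        If the base model has no feasible flux distribution.
    """
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError(
            f"fraction_of_optimum must be in [0, 1], got {fraction_of_optimum}"
        )
    base = fba(model)
    if base.status != OPTIMAL:
        raise InfeasibleModelError(
            f"cannot compute FVA reference: base model is {base.status}"
        )
    frame = flux_variability_analysis(
        model, fraction_of_optimum=fraction_of_optimum, processes=1
    )
    bounds = {
        rid: (float(row["minimum"]), float(row["maximum"]))
        for rid, row in frame.iterrows()
    }
    # guard against solver noise inverting tight intervals
    bounds = {rid: (min(lo, hi), max(lo, hi)) for rid, (lo, hi) in bounds.items()}
    return FluxBounds(bounds)


def export_lp(model: cobra.Model, path) -> None:
    """Write the model's LP in optlang's text form, for debugging."""
    from pathlib import Path

    Path(path).write_text(str(model.solver))
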