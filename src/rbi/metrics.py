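"""Validation statistics and parameter tuning.

Predicted-vs-observed agreement is scored with four measures:

* ``RMSE = sqrt(mean((y - yhat)^2))``,
* Pearson correlation ``rho = cov(y, yhat) / (sigma_y sigma_yhat)``
  (population moments; the ratio is the same either way),
* ``R^2 = 1 - SSE/SST`` with ``SSE = sum((y - yhat)^2)`` and
  ``SST = sum((y - mean(y))^2)`` (can be negative: predictions worse than
  the mean),
* ``bias = mean(yhat - y)`` (positive: systematic overestimation).

Parameter tuning maximizes ``fitness = 1/RMSE`` over candidate
``(alpha, beta, gamma)`` triples by deterministic grid search plus seeded
uniform random refinement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import KnockoutScheme, RBIModel
from .regnet import GRNModel, RBIParams

__all__ = ["ValidationStats", "validate", "fitness", "tune_parameters"]


@dataclass(frozen=True)
class ValidationStats:
    """Agreement between observed ``y`` and predicted ``yhat`` vectors.

    ``pcc`` / ``r_squared`` are ``None`` when undefined (zero variance in
    either vector, resp. zero total variation) rather than silently 0.
    """

    rmse: float
    pcc: Optional[float]
    r_squared: Optional[float]
    bias: float
    n: int


def validate(actual: Sequence[float], predicted: Sequence[float]) -> ValidationStats:
    """Compute RMSE, Pearson correlation, R^2 and bias.

    Raises
    ------
    ValueError
        On length mismatch or empty vectors.
    """
    y = np.asarray(actual, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.ndim != 1 or yhat.ndim != 1:
        raise ValueError("validate expects 1-D vectors")
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape[0]} vs {yhat.shape[0]}")
    n = y.shape[0]
    if n == 0:
        raise ValueError("empty vectors")
    residual = y - yhat
    rmse = float(np.sqrt(np.mean(residual**2)))
    bias = float(np.mean(yhat - y))

    pcc: Optional[float] = None
    if n >= 2:
        sd_y = float(np.std(y))
        sd_yhat = float(np.std(yhat))
        if sd_y > 0 and sd_yhat > 0:
            cov = float(np.mean((y - y.mean()) * (yhat - yhat.mean())))
            pcc = cov / (sd_y * sd_yhat)

    sst = float(np.sum((y - y.mean()) ** 2))
    r_squared: Optional[float] = None
    if sst > 0:
        sse = float(np.sum(residual**2))
        r_squared = 1.0 - sse / sst
    return ValidationStats(rmse=rmse, pcc=pcc, r_squared=r_squared, bias=bias, n=n)


def fitness(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Tuning fitness: the multiplicative inverse of the RMSE.

    A perfect fit (RMSE 0) returns ``+inf``.
    """
    rmse = validate(actual, predicted).rmse
    if rmse == 0.0:
        return float("inf")
    return 1.0 / rmse


def _predict(
    model: RBIModel,
    schemes: Sequence[KnockoutScheme],
    quantity: str,
    target: Optional[str],
    min_growth: Optional[float],
) -> list[float]:
    values = []
    for scheme in schemes:
        if quantity == "growth":
            result = model.fit(knockouts=scheme.tfs)
            value = result.objective_value if result.status == "optimal" else 0.0
        elif quantity == "production":
            if target is None:
                raise ValueError("quantity='production' requires a target reaction")
            value = model.design(scheme, target, min_growth=min_growth).production
        else:
            raise ValueError(f"unknown quantity {quantity!r}")
        values.append(float(value))
    return values


def tune_parameters(
    metabolic_model,
    grn: GRNModel,
    expression: Optional[pd.DataFrame],
    variant: str,
    schemes: Sequence[KnockoutScheme],
    reference: Sequence[float],
    grid: Optional[Iterable[tuple[float, float, float]]] = None,
    random_budget: int = 0,
    seed: int = 0,
    gamma_range: tuple[float, float] = (0.0, 1.0),
    quantity: str = "growth",
    target: Optional[str] = None,
    min_growth: Optional[float] = None,
    fva_fraction: float = 0.0,
    **model_kwargs,
) -> tuple[RBIParams, pd.DataFrame]:
    """Search (alpha, beta, gamma) for maximal 1/RMSE fitness.

    Candidates are the explicit ``grid`` triples followed by
    ``random_budget`` draws uniform in [0,1] x [0,1] x ``gamma_range``
    from a generator seeded with ``seed`` (fully deterministic). Each
    candidate is scored by simulating every scheme and comparing the
    chosen ``quantity`` ('growth' or 'production' of ``target``) against
    the observed ``reference`` vector.

    Returns the argmax parameters (first candidate on ties, which also
    resolves several exact fits) and the full evaluation trace.

    Raises
    ------
    ValueError
        If no candidates are given, the reference is misaligned, or every
        candidate is infeasible (the trace is attached to the error).
    """
    reference = [float(v) for v in reference]
    if len(reference) != len(schemes):
        raise ValueError(
            f"reference length {len(reference)} does not match "
            f"{len(schemes)} schemes"
        )
    candidates = [tuple(map(float, triple)) for triple in (grid or [])]
    rng = np.random.default_rng(seed)
    for _ in range(random_budget):
        lo, hi = gamma_range
        candidates.append(
            (
                float(rng.uniform(0, 1)),
                float(rng.uniform(0, 1)),
                float(rng.uniform(lo, hi)),
            )
        )
    if not candidates:
        raise ValueError("no candidates: supply a grid and/or random_budget >= 1")

    rows = []
    best: Optional[tuple[float, RBIParams]] = None
    for alpha, beta, gamma in candidates:
        params = RBIParams(
            alpha=alpha,
            beta=beta,
            gamma=gamma,
            variant=variant,
            fva_fraction=fva_fraction,
        )
        try:
            model = RBIModel(
                metabolic_model, grn, expression, params, **model_kwargs
            )
            predicted = _predict(model, schemes, quantity, target, min_growth)
            fit = fitness(reference, predicted)
        except Exception as err:  # infeasible/invalid candidate: record and move on
            rows.append(
                {
                    "alpha": alpha,
                    "beta": beta,
                    "gamma": gamma,
                    "fitness": float("nan"),
                    "rmse": float("nan"),
                    "error": str(err),
                }
            )
            continue
        rmse = 0.0 if np.isinf(fit) else 1.0 / fit
        rows.append(
            {
                "alpha": alpha,
                "beta": beta,
                "gamma": gamma,
                "fitness": fit,
                "rmse": rmse,
                "error": "",
            }
        )
        if best is None or fit > best[0]:
            best = (fit, params)
    trace = pd.DataFrame(rows)
    if best is None:
        raise ValueError(f"all candidates failed; trace:\n{trace}")
    return best[1], trace
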