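"""Gene-regulatory network handling and transcription-factor probabilities.

Holds the empirical GRN (a map from regulated metabolic gene to a Boolean
rule over its transcription factors), derives initial TF activity
probabilities for the three algorithm variants, and turns them into gene
reliabilities:

* **T1** — every non-knocked TF is equally likely active or inactive:
  ``p = 0.5``.
* **T2** — ``p = n(TF = 1) / d``: the fraction of samples in which the TF is
  "on" after PROM-style binarization of a gene-expression matrix at
  quantile ``alpha``.
* **T3** — the midpoint of T1 and T2: ``p = (0.5 + n(TF = 1)/d) / 2``.

Knocked-out TFs always get probability exactly 0, in every variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from graphlib import CycleError, TopologicalSorter
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .reliability import reliability
from .rules import BooleanExpr, parse_rule, serialize, variables

__all__ = [
    "GRNModel",
    "RBIParams",
    "read_grn",
    "read_expression",
    "binarize_expression",
    "initial_tf_probabilities",
    "gene_reliabilities",
]

logger = logging.getLogger(__name__)

VARIANTS = ("T1", "T2", "T3")


@dataclass(frozen=True)
class GRNModel:
    """Empirical gene-regulatory network: regulated gene -> Boolean rule.

    ``regulators`` is the union of variables over all rules; a gene may
    appear both as a regulator and as a regulated gene.
    """

    rules: Mapping[str, BooleanExpr]

    @property
    def regulated_genes(self) -> frozenset[str]:
        return frozenset(self.rules)

    @property
    def regulators(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for expr in self.rules.values():
            out |= variables(expr)
        return out

    @classmethod
    def from_strings(cls, rules: Mapping[str, str]) -> "GRNModel":
        return cls({gene: parse_rule(text) for gene, text in rules.items()})

    def to_tsv(self, path: str | Path) -> None:
        lines = [
            f"{gene}\t{serialize(expr)}" for gene, expr in sorted(self.rules.items())
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def read_grn(path: str | Path) -> GRNModel:
    """Read a two-column TSV (gene <TAB> Boolean rule) into a :class:`GRNModel`."""
    rules: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(
                f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
            )
        gene, rule = parts[0].strip(), parts[1].strip()
        if gene in rules:
            raise ValueError(f"{path}:{lineno}: duplicate rule for gene {gene!r}")
        rules[gene] = rule
    return GRNModel.from_strings(rules)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression table (TSV or CSV by extension).

    First column holds gene identifiers; remaining columns are samples.
    Rows with missing values are rejected (imputation is out of scope).
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: expression matrix needs at least one sample")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"{path}: missing values in rows {bad}")
    return df.astype(float)


@dataclass(frozen=True)
class RBIParams:
    """Tunable parameters of the integration.

    alpha
        Binarization quantile in [0, 1] used to threshold normalized
        expression (T2/T3 only). Default 0.33, the common choice for
        PROM-style on/off calling.
    beta
        Reliability cutoff in [0, 1]: only non-exempt reactions with
        ``r <= beta`` have their bounds updated. Default 1.0 applies the
        update to every non-exempt reaction (the most conservative reading
        of the cutoff).
    gamma
        Additive soft-constraint slack in flux units (mmol/gDW/h), >= 0,
        widening each updated bound so regulation never makes a reaction
        strictly infeasible. ``None`` resolves at run time to
        ``0.001 * max |bound|`` of the model.
    variant
        'T1', 'T2' or 'T3' (initial TF probability scheme).
    fva_fraction
        fraction-of-optimum passed to FVA when computing reference flux
        intervals; 0 gives the widest feasible reference.
    """

    alpha: float = 0.33
    beta: float = 1.0
    gamma: Optional[float] = None
    variant: str = "T1"
    fva_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if self.gamma is not None and self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if not 0.0 <= self.fva_fraction <= 1.0:
            raise ValueError(
                f"fva_fraction must be in [0, 1], got {self.fva_fraction}"
            )

    def with_gamma(self, gamma: float) -> "RBIParams":
        return replace(self, gamma=gamma)


def _quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Rank-average quantile normalization across samples (columns).

    Each column's distribution is replaced by the mean of the column-sorted
    values; tied ranks receive the mean of the pooled values they span. A
    single-gene matrix is returned unchanged (with one value per column the
    procedure is degenerate: it would collapse every sample to the panel
    mean and destroy the only ordering information present).
    """
    if df.shape[0] == 1:
        return df.copy()
    ranks = df.rank(axis=0, method="average")
    reference = np.sort(df.to_numpy(), axis=0).mean(axis=1)
    # average ranks may be half-integers; interpolate the reference curve
    positions = np.arange(1, df.shape[0] + 1, dtype=float)
    out = np.empty_like(df.to_numpy(), dtype=float)
    for j in range(df.shape[1]):
        out[:, j] = np.interp(ranks.iloc[:, j].to_numpy(), positions, reference)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def binarize_expression(
    expr: pd.DataFrame, alpha: float, per_gene: bool = False
) -> pd.DataFrame:
    """PROM-style binarization of a genes x samples expression matrix.

    Samples are quantile-normalized (rank-average), all normalized values
    are pooled, the threshold ``t`` is the ``alpha``-quantile of the pool,
    and an entry becomes 1 iff its normalized value is strictly greater
    than ``t``. ``alpha = 0`` marks everything above the minimum;
    ``alpha = 1`` yields an all-zero matrix.

    With ``per_gene=True`` the threshold is instead the ``alpha``-quantile
    of each gene's own normalized row.
    """
    if expr.shape[0] == 0 or expr.shape[1] == 0:
        raise ValueError("expression matrix is empty")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    norm = _quantile_normalize(expr)
    values = norm.to_numpy()
    if per_gene:
        thresholds = np.quantile(values, alpha, axis=1, keepdims=True)
        binary = values > thresholds
    else:
        threshold = np.quantile(values, alpha)
        binary = values > threshold
    return pd.DataFrame(binary.astype(int), index=expr.index, columns=expr.columns)


def initial_tf_probabilities(
    grn: GRNModel,
    variant: str = "T1",
    knockouts: Iterable[str] = (),
    binary: Optional[pd.DataFrame] = None,
    component_probs: Optional[Mapping[str, float]] = None,
) -> dict[str, float]:
    """Initial activity probability for every regulator in the GRN.

    Knocked-out TFs map to exactly 0 regardless of variant. Otherwise T1
    assigns 0.5; T2 the binarized on-fraction ``n(TF=1)/d``; T3 the midpoint
    of the two. A T2/T3 regulator absent from the binarized matrix falls
    back to 0.5 with a logged warning, so runs stay total on partial data.

    ``component_probs`` overrides individual non-knocked components; use it
    for environmental-condition literals in empirical rules (e.g. forcing
    an oxygen-availability flag to 1 or 0 for aerobic/anaerobic settings).

    Raises
    ------
    ValueError
        If a knockout name is not a regulator of the GRN, or variant T2/T3
        is requested without a binary matrix.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    regulators = grn.regulators
    knockouts = set(knockouts)
    unknown = sorted(knockouts - regulators)
    if unknown:
        raise ValueError(f"knockout names not found among GRN regulators: {unknown}")
    if variant in ("T2", "T3") and binary is None:
        raise ValueError(f"variant {variant} requires a binarized expression matrix")

    probs: dict[str, float] = {}
    for tf in sorted(regulators):
        if tf in knockouts:
            probs[tf] = 0.0
            continue
        if component_probs is not None and tf in component_probs:
            p = float(component_probs[tf])
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"override probability for {tf!r} outside [0, 1]")
            probs[tf] = p
            continue
        if variant == "T1":
            probs[tf] = 0.5
        else:
            if binary is not None and tf in binary.index:
                on_fraction = float(binary.loc[tf].mean())
            else:
                logger.warning(
                    "regulator %s absent from expression matrix; using 0.5", tf
                )
                on_fraction = 0.5
            probs[tf] = on_fraction if variant == "T2" else 0.5 * (0.5 + on_fraction)
    return probs


def _propagated_order(grn: GRNModel) -> list[str]:
    """Regulated genes in topological order of the TF-regulation subgraph.

    Only edges between genes that are themselves regulated matter; cycles
    are broken by dropping the in-edges of cycle members (they keep their
    initial probabilities).
    """
    regulated = grn.regulated_genes
    deps = {
        g: {v for v in variables(expr) if v in regulated}
        for g, expr in grn.rules.items()
    }
    while True:
        try:
            return [g for g in TopologicalSorter(deps).static_order() if g in regulated]
        except CycleError as err:
            cycle = err.args[1]
            for g in cycle:
                if g in deps and deps[g]:
                    deps[g] = set()
                    break


def gene_reliabilities(
    grn: GRNModel,
    tf_probs: Mapping[str, float],
    all_metabolic_genes: Iterable[str] = (),
    propagate: bool = False,
) -> dict[str, float]:
    """Reliability of every regulated gene plus 1.0 for unregulated ones.

    Each regulated gene's reliability is the series-parallel evaluation of
    its rule under ``tf_probs``. Metabolic genes with no rule in the GRN
    get probability one ("no information that TFs regulate them").

    By default the network is evaluated in a single pass: a TF that is
    itself a regulated gene still contributes its *initial* probability
    when it appears on the right-hand side of another rule. With
    ``propagate=True`` rules are instead evaluated in topological order and
    a regulated TF contributes its computed reliability downstream (cycles
    fall back to initial values).
    """
    rel: dict[str, float] = {}
    if propagate:
        working = dict(tf_probs)
        for gene in _propagated_order(grn):
            r = reliability(grn.rules[gene], working)
            rel[gene] = r
            working[gene] = r
    else:
        for gene, expr in grn.rules.items():
            rel[gene] = reliability(expr, tf_probs)
    for gene in all_metabolic_genes:
        if gene not in rel:
            rel[gene] = 1.0
    return rel
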