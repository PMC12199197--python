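# Methods

## Model

The package treats the regulatory state of a metabolic network
probabilistically. Each transcription factor TFᵢ has a probability
`p_TFi ∈ [0, 1]` of being active; each regulated metabolic gene MGⱼ is a
*system* whose components are the TFs in its Boolean rule, and its
reliability `r_MGj` is obtained by mapping the rule's operators onto
series–parallel reliability formulas:

- `AND` → series: the product of component reliabilities,
- `OR` → parallel: one minus the product of component unreliabilities,
- `NOT` → complement: `1 − r(child)`, applied to arbitrary
  sub-expressions (empirical rules contain `NOT` over parenthesized
  groups, so the complement is defined on the recursive value, not only
  on leaves).

The same recursion, with gene reliabilities as component probabilities,
gives each reaction's reliability `r_RFk` from its GPR rule. A gene with no
GRN rule and a reaction with no GPR get reliability exactly 1.

**Repeated components.** The recursion treats every occurrence of a
variable as independent. On *read-once* expressions (each variable appears
once) this equals the exact Boolean probability — a property the test
suite verifies against a brute-force enumeration oracle. On rules with
repeated variables the two diverge, and the compositional value is
normative here: the ATP-synthase rule
`(AtpF0 AND AtpF1) OR (AtpF0 AND AtpF1 AND AtpI)` at all-0.9 probabilities
evaluates compositionally to 0.948510, although the rule is logically
equivalent to `AtpF0 AND AtpF1` (exact probability 0.81). The same
convention applies when one TF appears with opposite signs in a single
rule; the package documents rather than resolves this, and
`exact_probability` is available for diagnostic comparison (up to 20
distinct variables).

**One regulatory layer.** Reliabilities are computed in a single pass: a
TF that is itself a regulated gene still contributes its *initial*
probability where it appears as a regulator. An optional propagation mode
evaluates rules in topological order and feeds computed reliabilities
downstream, breaking cycles by reverting cycle members to their initial
values; it is off by default because the core procedure is defined on one
layer.

## Initial probabilities and binarization

Knocked-out TFs get probability exactly 0 in every variant. Otherwise:

- **T1**: `p = 0.5` (maximum-entropy prior — active and inactive equally
  likely);
- **T2**: `p = n(TF = 1)/d`, the fraction of `d` expression samples in
  which the TF is "on";
- **T3**: the midpoint `(0.5 + n(TF=1)/d)/2`, which by construction lies
  in `[0.25, 0.75]` for non-knocked TFs.

The on/off call is PROM-style: samples are quantile-normalized
(rank-average; tied ranks interpolate the reference distribution), all
normalized values are pooled, and an entry is "on" iff it strictly exceeds
the pooled `α`-quantile. A per-gene thresholding mode is exposed
(`per_gene=True`) since published descriptions are ambiguous on pooling;
pooled is the default. A single-gene matrix skips normalization — with one
value per sample the procedure degenerates to the panel mean and would
erase the only ordering information present. TFs absent from the
expression matrix fall back to `p = 0.5` with a logged warning rather than
aborting a run on partial data. Environmental-condition literals appearing
in empirical rules (e.g. oxygen availability) are ordinary components;
their probabilities can be pinned via `component_probs` (1/0 for declared
aerobic/anaerobic settings), defaulting to the variant value otherwise.

## The constraint update

Reference intervals `[lb*, ub*]` come from FVA at
`fva_fraction` of the optimum (default 0 — the widest physiologically
feasible reference, imposing no growth requirement). Each reaction that is
**not exempt** and has `r_RF ≤ β` is re-bounded to
`[r·lb* − γ, r·ub* + γ]`; all other reactions keep their original bounds.
Exempt are boundary/exchange reactions (single-metabolite stoichiometry),
transporters (stoichiometry spanning ≥ 2 compartments) and the ATP
maintenance pseudo-reaction (id `ATPM`, case-insensitive, extensible via
`extra_exempt` for dialects like `R_ATPM`); exchanges can be un-exempted
with `include_exchanges_exempt=False` since "transport" is ambiguous
between the two readings. The update is applied literally — bounds are not
clipped back into the original interval when `γ` pushes past them — with a
`clip_to_original` flag for the conservative alternative.

Because `r ∈ [0, 1]` and `γ ≥ 0`, the updated interval always contains
`r·[lb*, ub*]` and is ordered, the feasible region only widens as `γ`
grows (the objective is non-decreasing in `γ`), and at `r = 1, γ = 0,
fva_fraction = 0` the update reproduces the FVA envelope so the
constrained optimum equals the unconstrained one.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `alpha` | 0.33 | quantile | binarization threshold (T2/T3); 0.33 is the common on/off calling level for expression compendia |
| `beta` | 1.0 | — | reliability cutoff; 1.0 applies the update to every non-exempt reaction (the most conservative reading of "≤ β") |
| `gamma` | `0.001 · max abs bound` | mmol·gDW⁻¹·h⁻¹ | soft slack keeping regulation from making reactions strictly infeasible; resolved per model at run time |
| `fva_fraction` | 0.0 | fraction | growth requirement during the FVA reference |
| `min_growth` (design) | 5% of wild-type growth | mmol·gDW⁻¹·h⁻¹ | survival threshold for growth coupling |

All defaults are overridable; tuned values for a specific organism should
come from `tune_parameters`, which scores candidate (α, β, γ) triples by
`1/RMSE` against observed knockout phenotypes using a deterministic grid
plus seeded uniform random refinement (the fitness function is the
contract; the search strategy is deliberately simple). Ties, including
multiple exact fits, resolve to the first candidate in evaluation order.

## Strain design

For a knockout scheme, growth is the FBA optimum of biomass on the
constrained model. Production is computed two-stage: biomass is fixed to
at least `min_growth`, then the target drain is maximized. Reporting both
quantities requires the two solves; a single weighted objective would
conflate them. A scheme is growth-coupled when growth reaches
`min_growth` and production is strictly positive.

## Numerical choices

- LP backend: GLPK via optlang, single-threaded, one process for FVA, so
  repeated runs agree bitwise on status and to solver precision on
  objectives. Infeasible/unbounded FBA is reported in the result status
  (fluxes empty, objective NaN), never raised; an infeasible *base* model
  during FVA raises, since no reference exists.
- Feasibility assertions in tests use 1e−6; reliability-engine equalities
  use 1e−10–1e−12 (plain double-precision products; expressions are
  shallow, so no log-space accumulation is needed).
- `validate` uses population (1/n) moments for both covariance and
  standard deviations; the Pearson ratio is invariant either way. A zero
  variance in either vector flags PCC as undefined (`None`) rather than
  silently 0, and `SST = 0` likewise makes R² undefined.
- `fitness` returns `+inf` at RMSE 0 (a perfect fit dominates any finite
  candidate).

## What the synthetic generators do and do not emulate

`make_toy_model` builds branched uptake→drain networks: one substrate
exchange at −10 mmol·gDW⁻¹·h⁻¹, unit-stoichiometry pathways of 2–4
reactions feeding a biomass drain (odd branches) or a target-metabolite
drain (even branches), GPRs cycling through single-gene, AND, OR and
nested OR-of-AND forms. Wild-type growth is 10 by construction, which
makes hand LP solutions available as oracles. The target drain exists from
two branches up; the one-branch model is a bare 4–5-reaction chain.
`make_toy_grn` assigns rules over 2–6 synthetic TFs, guaranteeing a NOT
rule and the nested `(TFa AND (NOT TFb)) OR TFb` motif when inhibition is
requested. `make_expression` draws bimodal values (low N(2, 0.15) vs high
N(10, 0.15)) with a per-gene high fraction, sized at 20 samples by default
— small but enough for on-fraction estimates to be stable.

These toys exercise the structure the method consumes — compartments,
boundary reactions, GPR dialects, rule shapes, bimodal expression — not
genome-scale properties: no loops, no cofactor coupling, no alternate
optima beyond branch choices, no noisy/partially-observed expression.
Passing tests therefore demonstrate correctness of the integration
machinery, not predictive accuracy on real organisms, which depends on the
quality of the user-supplied model, GRN and expression data. Problem sizes
in the test and acceptance runs (3-branch toys; one ~520-reaction model
for the scale check; grids of ≤ 8 tuning candidates) were chosen so a
single desk run completes in seconds while still exercising the
FVA-dominated quadratic cost path.

## Known limitations

- Regulation is static: no iterative regulatory-state updates (rFBA-style)
  and no mixed-integer steady-state regulation.
- The compositional treatment of repeated variables is an approximation
  the method inherits by design (see above).
- Empirical GRN availability is the binding constraint in practice; the
  package deliberately does not infer GRNs from expression data.
- Signaling networks are out of scope.
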