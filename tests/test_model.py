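"""Integration pipeline: bound update mechanics, knockout logic, design."""

import cobra
import pytest

from rbi.lp import FluxBounds, fba, fva
from rbi.model import (
    KnockoutScheme,
    RBIModel,
    apply_regulatory_constraints,
    read_schemes,
    run_rbi,
    simulate_scheme,
)
from rbi.regnet import GRNModel, RBIParams
from rbi.synthetic import (
    make_activation_fixture,
    make_expression,
    make_toy_grn,
    make_toy_model,
)

T1 = RBIParams(variant="T1", gamma=0.0)


def _ref(model) -> FluxBounds:
    return fva(model, fraction_of_optimum=0.0)


class TestApplyRegulatoryConstraints:
    def test_identity_scaling_recovers_reference(self, chain_model):
        ref = _ref(chain_model)
        r = {rxn.id: 1.0 for rxn in chain_model.reactions}
        updated = apply_regulatory_constraints(chain_model, r, ref, beta=1.0, gamma=0.0)
        assert updated.reactions.R1.bounds == pytest.approx(ref["R1"], abs=1e-9)

    def test_direct_arithmetic_half_reliability(self, chain_model):
        chain_model.reactions.R1.bounds = (-10.0, 10.0)
        ref = FluxBounds({rxn.id: (-10.0, 10.0) for rxn in chain_model.reactions})
        r = {rxn.id: 0.5 for rxn in chain_model.reactions}
        updated = apply_regulatory_constraints(
            chain_model, r, ref, beta=1.0, gamma=0.001, exempt=set()
        )
        assert updated.reactions.R1.bounds == pytest.approx((-5.001, 5.001), abs=1e-12)

    def test_reliability_above_beta_untouched(self, chain_model):
        ref = _ref(chain_model)
        r = {rxn.id: 0.9 for rxn in chain_model.reactions}
        updated = apply_regulatory_constraints(chain_model, r, ref, beta=0.5, gamma=0.0)
        for rxn in chain_model.reactions:
            assert updated.reactions.get_by_id(rxn.id).bounds == rxn.bounds

    def test_exempt_reaction_untouched_even_at_zero_reliability(self, chain_model):
        atp = cobra.Metabolite("atp_c", compartment="c")
        chain_model.reactions.R1.add_metabolites({atp: 1.0})
        atpm = cobra.Reaction("ATPM", lower_bound=0.0, upper_bound=1000.0)
        atpm.add_metabolites({atp: -1.0})
        chain_model.add_reactions([atpm])
        ref = _ref(chain_model)
        r = {rxn.id: 0.0 for rxn in chain_model.reactions}
        updated = apply_regulatory_constraints(chain_model, r, ref, beta=1.0, gamma=0.0)
        assert updated.reactions.ATPM.bounds == chain_model.reactions.ATPM.bounds
        assert updated.reactions.EX_S.bounds == chain_model.reactions.EX_S.bounds
        assert updated.reactions.R1.bounds == (0.0, 0.0)  # non-exempt, r = 0

    def test_negative_gamma_rejected(self, chain_model):
        ref = _ref(chain_model)
        r = {rxn.id: 1.0 for rxn in chain_model.reactions}
        with pytest.raises(ValueError, match="gamma"):
            apply_regulatory_constraints(chain_model, r, ref, beta=1.0, gamma=-0.1)

    def test_bounds_stay_ordered(self, chain_model):
        ref = _ref(chain_model)
        r = {rxn.id: 0.3 for rxn in chain_model.reactions}
        updated = apply_regulatory_constraints(chain_model, r, ref, beta=1.0, gamma=0.01)
        for rxn in updated.reactions:
            assert rxn.lower_bound <= rxn.upper_bound


class TestRunRBI:
    def test_unregulated_model_keeps_wild_type_optimum(self):
        for seed in range(3):
            model = make_toy_model(n_branches=2, seed=seed)
            wild_type = fba(model).objective_value
            fluxes, report = run_rbi(
                model, GRNModel({}), params=T1, knockouts=()
            )
            assert fluxes.status == "optimal"
            assert fluxes.objective_value == pytest.approx(wild_type, abs=1e-6)
            assert all(r == 1.0 for r in report.reaction_reliabilities.values())

    def test_sole_activator_knockout_kills_growth(self):
        model, grn = make_activation_fixture(inhibit=False)
        fluxes, report = run_rbi(model, grn, params=T1, knockouts={"T"})
        assert fluxes.status == "optimal"
        assert fluxes.objective_value == pytest.approx(0.0, abs=1e-9)
        assert report.gene_reliabilities["G1"] == 0.0
        assert report.reaction_reliabilities["R1"] == 0.0
        assert report.bounds_after["R1"] == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_inhibitor_knockout_restores_wild_type(self):
        model, grn = make_activation_fixture(inhibit=True)
        wild_type = fba(model).objective_value
        fluxes, report = run_rbi(model, grn, params=T1, knockouts={"T"})
        assert report.reaction_reliabilities["R1"] == pytest.approx(1.0)
        assert fluxes.objective_value == pytest.approx(wild_type, abs=1e-6)

    def test_gamma_monotonicity(self):
        """Widening the soft constraint can only help the objective."""
        for seed in range(10):
            model = make_toy_model(n_branches=1 + seed % 3, seed=seed)
            grn = make_toy_grn(model, frac_regulated=0.7, seed=seed)
            ko = {sorted(grn.regulators)[0]}
            previous = -1.0
            for gamma in (0.0, 1e-3, 1e-2, 1e-1):
                params = RBIParams(variant="T1", gamma=gamma)
                fluxes, _ = run_rbi(model, grn, params=params, knockouts=ko)
                assert fluxes.status == "optimal"
                assert fluxes.objective_value >= previous - 1e-9
                previous = fluxes.objective_value

    def test_report_complete_and_deterministic(self):
        model = make_toy_model(3, seed=4)
        grn = make_toy_grn(model, frac_regulated=0.6, seed=4)
        ko = {sorted(grn.regulators)[0]}
        runs = [run_rbi(model, grn, params=T1, knockouts=ko) for _ in range(2)]
        (f1, r1), (f2, r2) = runs
        assert f1.objective_value == f2.objective_value
        assert f1.fluxes == f2.fluxes
        assert r1.reaction_reliabilities == r2.reaction_reliabilities
        assert r1.bounds_after == r2.bounds_after
        ids = {rxn.id for rxn in model.reactions}
        assert set(r1.reaction_reliabilities) == ids
        assert set(r1.bounds_before) == ids
        assert set(r1.bounds_after) == ids
        assert set(r1.reference_bounds) == ids
        frame = r1.to_frame()
        assert set(frame["reaction"]) == ids
        assert set(frame.columns) >= {"reliability", "exempt", "new_lb", "new_ub"}

    def test_t2_requires_expression(self):
        model, grn = make_activation_fixture()
        with pytest.raises(ValueError, match="T2"):
            RBIModel(model, grn, params=RBIParams(variant="T2"))

    def test_all_variants_run_on_generated_triples(self):
        model = make_toy_model(3, seed=9)
        grn = make_toy_grn(model, frac_regulated=0.8, seed=9)
        regs = sorted(grn.regulators)
        expression = make_expression(regs, d=16, high_fraction=0.5, seed=9)
        for variant in ("T1", "T2", "T3"):
            params = RBIParams(variant=variant, gamma=0.0)
            fluxes, report = run_rbi(
                model, grn, expression, params, knockouts={regs[0]}
            )
            assert fluxes.status == "optimal"
            assert all(0.0 <= p <= 1.0 for p in report.tf_probabilities.values())

    def test_gene_knockout_extension_forces_zero_reliability(self):
        model, grn = make_activation_fixture()
        fluxes, report = run_rbi(
            model, grn, params=T1, knockouts=(), gene_knockouts={"G1"}
        )
        assert report.gene_reliabilities["G1"] == 0.0
        assert fluxes.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_summary_mentions_key_quantities(self):
        model, grn = make_activation_fixture()
        results = RBIModel(model, grn, params=T1).fit(knockouts={"T"})
        text = results.summary()
        assert "T1" in text and "optimal" in text and "knockouts" in text


class TestDesign:
    def test_empty_scheme_reproduces_wild_type_baselines(self):
        model = make_toy_model(2, seed=1)
        grn = make_toy_grn(model, frac_regulated=0.0, seed=1)
        wild_growth = fba(model).objective_value
        result = simulate_scheme(
            model, grn, None, T1, KnockoutScheme.of(name="WT"), target="EX_TGT"
        )
        assert result.growth == pytest.approx(wild_growth, abs=1e-6)
        assert result.min_growth == pytest.approx(0.05 * wild_growth, abs=1e-9)
        assert result.production >= 0.0

    def test_activator_knockout_not_growth_coupled(self):
        model, grn = make_activation_fixture()
        # add a trivial target drain so the API has a target to optimize
        z = cobra.Metabolite("Z_c", compartment="c")
        rz = cobra.Reaction("EX_Z", lower_bound=0.0, upper_bound=1000.0)
        rz.add_metabolites({z: -1.0})
        model.add_reactions([rz])
        result = simulate_scheme(
            model, grn, None, T1, KnockoutScheme.of("T"), target="EX_Z"
        )
        assert result.growth == pytest.approx(0.0, abs=1e-9)
        assert result.growth_coupled is False

    def test_inhibitor_release_boosts_production_branch(self):
        """Two-branch toy: the target branch reaction is inhibited by TF T
        (GPR gene regulated by NOT T at T1 probabilities halves its
        bounds); knocking T out releases the branch and production rises
        strictly above the constrained baseline."""
        model = make_toy_model(2, seed=0)
        target_gene = model.reactions.B2R1.gene_reaction_rule
        assert target_gene  # generator assigns a GPR to internal reactions
        first_gene = sorted(g.id for g in model.reactions.B2R1.genes)[0]
        grn = GRNModel.from_strings({first_gene: "NOT T"})
        baseline = simulate_scheme(
            model, grn, None, T1, KnockoutScheme.of(name="WT"), target="EX_TGT"
        )
        released = simulate_scheme(
            model, grn, None, T1, KnockoutScheme.of("T"), target="EX_TGT"
        )
        assert released.production > baseline.production + 1e-6
        assert released.growth_coupled

    def test_min_growth_validation_and_missing_target(self):
        model, grn = make_activation_fixture()
        rbi_model = RBIModel(model, grn, params=T1)
        with pytest.raises(KeyError):
            rbi_model.design(KnockoutScheme.of("T"), target="NOPE")
        z = cobra.Metabolite("Z_c", compartment="c")
        rz = cobra.Reaction("EX_Z", lower_bound=0.0, upper_bound=1000.0)
        rz.add_metabolites({z: -1.0})
        model.add_reactions([rz])
        with pytest.raises(ValueError, match="min_growth"):
            rbi_model.design(KnockoutScheme.of("T"), target="EX_Z", min_growth=-1.0)


class TestSchemesIO:
    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "schemes.csv"
        path.write_text("scheme,tfs\nWT,\ndouble,TF1;TF2\n")
        schemes = read_schemes(path)
        assert schemes[0] == KnockoutScheme("WT", frozenset())
        assert schemes[1] == KnockoutScheme("double", frozenset({"TF1", "TF2"}))

    def test_plain_list(self, tmp_path):
        path = tmp_path / "schemes.txt"
        path.write_text("TF1\nTF1 TF2\n# comment\n")
        schemes = read_schemes(path)
        assert [s.tfs for s in schemes] == [
            frozenset({"TF1"}),
            frozenset({"TF1", "TF2"}),
        ]
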