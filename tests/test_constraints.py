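"""Bespoke photoheterotroph constraints: rubisco coexpression, the
photosynthetic ATP caps, and the three-nitrogenase set."""

import pytest

from rpalme import constraints, solver
from rpalme.constraints import (AtpCapSpec, RubiscoCoexpressionSpec,
                                TABLE_ATP_CAPS, apply_atp_cap,
                                apply_rubisco_coexpression,
                                calibrate_rubisco_coexpression,
                                rubisco_coexpression_value)
from rpalme.model import ModelError


# ---------------------------------------------------------------------------
# rubisco coexpression (analytic)
# ---------------------------------------------------------------------------

def test_coexpression_vanishes_at_maximal_growth_and_co2():
    assert rubisco_coexpression_value(0.5, 0.5, 10.0, 10.0, 3.7, 6.6) == 0.0


def test_coexpression_vanishes_at_rest():
    assert rubisco_coexpression_value(0.0, 0.5, 0.0, 10.0, 3.7, 6.6) == 0.0


def test_coexpression_half_growth_example():
    # direct evaluation: (0 + 0.5 * 10) * 3.7/6.6
    value = rubisco_coexpression_value(0.25, 0.5, 0.0, 10.0, 3.7, 6.6)
    assert value == pytest.approx(5.0 * 3.7 / 6.6)


def test_coexpression_spec_validation():
    with pytest.raises(ModelError):
        RubiscoCoexpressionSpec("r", [], mu_max=0.0, sum_vCO2_max=1.0,
                                kcat_I=3.7, kcat_II=6.6)
    with pytest.raises(ModelError):
        rubisco_coexpression_value(0.1, 0.5, 1.0, 1.0, 3.7, 0.0)


# ---------------------------------------------------------------------------
# rubisco coexpression (LP)
# ---------------------------------------------------------------------------

def _residual(model, spec, sol):
    sum_co2 = sum(sol.fluxes.get(r, 0.0) for r in spec.sum_vCO2)
    target = rubisco_coexpression_value(sol.mu, spec.mu_max, sum_co2,
                                        spec.sum_vCO2_max, spec.kcat_I,
                                        spec.kcat_II)
    return sol.fluxes[spec.v_rubisco_I] - target


def test_strict_coexpression_residual_within_1e8(capped_model):
    model = capped_model.copy()
    spec = calibrate_rubisco_coexpression(model, {"succinate": 2.0}, tol=1e-4)
    apply_rubisco_coexpression(model, spec, mode="strict")
    sol = solver.max_growth(model, {"succinate": 2.0}, tol=1e-4)
    assert sol.status == "optimal"
    assert abs(_residual(model, spec, sol)) <= 1e-8


def test_coexpression_forces_form_I_expression(capped_model):
    # doubling the calibrated CO2 ceiling makes the bracket positive at the
    # optimum, so form I must carry flux alongside form II
    model = capped_model.copy()
    spec = calibrate_rubisco_coexpression(model, {"succinate": 2.0}, tol=1e-4)
    boosted = RubiscoCoexpressionSpec(
        v_rubisco_I=spec.v_rubisco_I, sum_vCO2=spec.sum_vCO2,
        mu_max=spec.mu_max, sum_vCO2_max=2.0 * spec.sum_vCO2_max,
        kcat_I=spec.kcat_I, kcat_II=spec.kcat_II)
    apply_rubisco_coexpression(model, boosted, mode="strict")
    sol = solver.max_growth(model, {"succinate": 2.0}, tol=1e-4)
    assert sol.fluxes["CBB_rubisco_I"] > 1e-4
    assert abs(_residual(model, boosted, sol)) <= 1e-8


def test_relaxed_mode_clamps_negative_bracket_at_zero(capped_model):
    # at half the calibrated mu_max the bracket goes negative; the relaxed
    # pair of inequalities plus the parsimonious objective pin v_I at zero
    model = capped_model.copy()
    spec = calibrate_rubisco_coexpression(model, {"succinate": 2.0}, tol=1e-4)
    apply_rubisco_coexpression(model, spec, mode="relaxed")
    sol = solver.pfba_fluxes(model, spec.mu_max / 2.0, {"succinate": 2.0})
    assert sol.status == "optimal"
    sum_co2 = sum(sol.fluxes.get(r, 0.0) for r in spec.sum_vCO2)
    target = rubisco_coexpression_value(sol.mu, spec.mu_max, sum_co2,
                                        spec.sum_vCO2_max, spec.kcat_I,
                                        spec.kcat_II)
    assert sol.fluxes["CBB_rubisco_I"] == pytest.approx(max(0.0, target),
                                                        abs=1e-6)


# ---------------------------------------------------------------------------
# photosynthetic ATP caps
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("substrate, cap", sorted(TABLE_ATP_CAPS.items()))
def test_table_caps_applied_per_substrate(toy_model, substrate, cap):
    model = toy_model.copy()
    apply_atp_cap(model, substrate)
    rid = model.annotations["atp_synthase_reaction"]
    assert model.reactions[rid].upper_bound == cap


def test_cap_ratio_equals_yield_ratio():
    spec = AtpCapSpec(substrate="anything", v_PS_ace=54.0, phi_S=1.7,
                      phi_ace=0.85)
    assert spec.cap == pytest.approx(54.0 * 2.0)
    same = AtpCapSpec(substrate="x", v_PS_ace=54.0, phi_S=0.9, phi_ace=0.9)
    assert same.cap == pytest.approx(54.0)


def test_unknown_substrate_cap_rejected(toy_model):
    with pytest.raises(ModelError):
        apply_atp_cap(toy_model.copy(), "glucose")


# ---------------------------------------------------------------------------
# nitrogenases
# ---------------------------------------------------------------------------

def test_register_rejects_unordered_costs(toy_model):
    model = toy_model.copy()
    for iso in ("Mo", "V", "Fe"):
        del model.reactions[f"NFIX_{iso}"]
    with pytest.raises(ModelError):
        constraints.register_nitrogenases(model, {"Mo": 30.0, "V": 20.0,
                                                  "Fe": 40.0})


def test_wild_type_expresses_single_nitrogenase_and_isoform(succinate_solution):
    f = succinate_solution.fluxes
    assert f["NFIX_Mo"] > 0.1
    assert abs(f["NFIX_V"]) <= 1e-9 and abs(f["NFIX_Fe"]) <= 1e-9
    # the parsimonious objective also picks a single rubisco isoform (the
    # cheaper form II by synthesis cost per catalytic capacity)
    assert f["CBB_rubisco_II"] > 1e-3
    assert abs(f["CBB_rubisco_I"]) <= 1e-9


def test_mutant_growth_ordering_follows_atp_cost(capped_model):
    from rpalme.model import knockout

    gs = capped_model.annotations["nitrogenase_gene_sets"]
    mu = {"WT": solver.max_growth(capped_model, {"succinate": 4.0}, tol=1e-3).mu}
    for iso in ("Mo", "V", "Fe"):
        others = [g for k, v in gs.items() if k != iso for g in v]
        mu[iso] = solver.max_growth(knockout(capped_model, others),
                                    {"succinate": 4.0}, tol=1e-3).mu
    assert mu["WT"] == pytest.approx(mu["Mo"], abs=2e-3)
    assert mu["Mo"] > mu["V"] > mu["Fe"] > 0


def test_symmetric_isozymes_are_degenerate_under_pfba(capped_model):
    # equal costs and k_cats: the flux split is arbitrary, so a flux range
    # is the honest report rather than a single winner
    model = capped_model.copy()
    mo = model.reactions["NFIX_Mo"]
    for iso in ("V", "Fe"):
        rxn = model.reactions[f"NFIX_{iso}"]
        rxn.stoichiometry = dict(mo.stoichiometry)
        rxn.mu_coupled_terms = dict(mo.mu_coupled_terms)
        rxn.enzyme_id = mo.enzyme_id
    mu = 0.25
    sol = solver.pfba_fluxes(model, mu, {"succinate": 4.0})
    total = sum(sol.fluxes[f"NFIX_{i}"] for i in ("Mo", "V", "Fe"))
    for iso in ("Mo", "V", "Fe"):
        lo, hi = solver.flux_range(model, mu, f"NFIX_{iso}",
                                   {"succinate": 4.0},
                                   pin_total_flux=sol.total_flux)
        assert lo == pytest.approx(0.0, abs=1e-6)
        assert hi == pytest.approx(total, abs=1e-5)
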