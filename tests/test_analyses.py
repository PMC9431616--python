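"""Analysis stages: region classification, oxidation states, fold-change
scoring, growth profiles, electron sweeps and the temperature scan."""

import numpy as np
import pytest

from rpalme import analyses, solver
from rpalme.analyses import (GrowthProfile, classify_regions,
                             fold_change_validation,
                             mean_carbon_oxidation_state, table_growth_excess,
                             REGION_SNL, REGION_JANUSIAN, REGION_SPL)
from rpalme.model import ModelError


def _profile(u, mu):
    n = len(u)
    z = [0.0] * n
    return GrowthProfile(substrate="x", uptake_grid=list(u), mu=list(mu),
                         v_nfix=z, v_cfix=z, v_mdh=z, v_g3pdh=z)


# ---------------------------------------------------------------------------
# region classification
# ---------------------------------------------------------------------------

def test_linear_growth_curve_is_all_nutrient_limited():
    u = [1, 2, 3, 4, 5]
    assert classify_regions(_profile(u, [0.1 * x for x in u])) == [REGION_SNL] * 5


def test_flat_tail_is_proteome_limited():
    labels = classify_regions(_profile([1, 2, 3, 4, 5, 6],
                                       [0.1, 0.2, 0.3, 0.3, 0.3, 0.3]))
    assert labels[-2:] == [REGION_SPL, REGION_SPL]
    assert labels[0] == REGION_SNL


def test_saturating_curve_yields_three_contiguous_blocks():
    # exponential saturation: steepest at the origin, flat at the plateau
    u = np.linspace(0.5, 12, 14)
    mu = 0.5 * (1 - np.exp(-u / 2.5))
    labels = classify_regions(_profile(u, mu))
    assert set(labels) == {REGION_SNL, REGION_JANUSIAN, REGION_SPL}
    # contiguity in canonical order
    order = [labels[0]]
    for lab in labels[1:]:
        if lab != order[-1]:
            order.append(lab)
    assert order == [REGION_SNL, REGION_JANUSIAN, REGION_SPL]


def test_region_labels_invariant_to_uptake_rescaling():
    u = np.linspace(0.5, 12, 12)
    mu = 0.4 * np.tanh(u / 4)
    assert (classify_regions(_profile(u, mu))
            == classify_regions(_profile(10 * u, mu)))


def test_non_monotone_growth_curve_is_an_error():
    with pytest.raises(ModelError):
        classify_regions(_profile([1, 2, 3, 4], [0.1, 0.3, 0.2, 0.35]))


def test_too_few_points_rejected():
    with pytest.raises(ModelError):
        classify_regions(_profile([1, 2, 3], [0.1, 0.2, 0.3]))


# ---------------------------------------------------------------------------
# oxidation states
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("formula, charge, expected", [
    # hand-assigned per-atom oracle (H +1, O -2, N -3, S -2; neutral unless
    # noted): e.g. succinic acid HOOC-CH2-CH2-COOH = 2x(+3) + 2x(-2) -> +0.5
    ({"C": 4, "H": 6, "O": 4}, 0, 0.5),      # succinic acid
    ({"C": 2, "H": 4, "O": 2}, 0, 0.0),      # acetic acid
    ({"C": 4, "H": 8, "O": 2}, 0, -1.0),     # butyric acid
    ({"C": 9, "H": 8, "O": 3}, 0, -2.0 / 9),  # p-coumaric acid
    ({"C": 1, "O": 2}, 0, 4.0),              # CO2
    ({"C": 1, "H": 4}, 0, -4.0),             # CH4
    ({"C": 1, "H": 4, "O": 1}, 0, -2.0),     # methanol
    ({"C": 6, "H": 12, "O": 6}, 0, 0.0),     # glucose
    ({"C": 2, "H": 5, "N": 1, "O": 2}, 0, 1.0),  # glycine (+3 carboxyl, -1 CH2)
    ({"C": 2, "H": 3, "O": 2}, -1, 0.0),     # acetate anion: charge honored
])
def test_mean_carbon_oxidation_state_library(formula, charge, expected):
    assert mean_carbon_oxidation_state(formula, charge) == pytest.approx(expected)


def test_oxidation_state_requires_carbon():
    with pytest.raises(ModelError):
        mean_carbon_oxidation_state({"H": 2, "O": 1})


# ---------------------------------------------------------------------------
# fold-change validation
# ---------------------------------------------------------------------------

def test_fold_change_hand_count_and_permutation_invariance():
    a = {"g1": 2.0, "g2": 1.0, "g3": 3.0, "g4": 0.5}
    b = {"g1": 1.0, "g2": 2.0, "g3": 1.0, "g4": 1.0}
    exp = {"g1": "up", "g2": "up", "g3": "up", "g4": "down"}  # g2 mismatch
    res = fold_change_validation(a, b, exp)
    assert (res.n_compared, res.n_correct, res.accuracy_percent) == (4, 3, 75)
    shuffled = dict(reversed(list(exp.items())))
    assert fold_change_validation(a, b, shuffled).accuracy_percent == 75


def test_fold_change_tie_is_flagged_and_excluded():
    a = {"g1": 1.0, "g2": 2.0}
    b = {"g1": 1.0, "g2": 1.0}
    res = fold_change_validation(a, b, {"g1": "up", "g2": "up"})
    assert res.n_ties_excluded == 1 and res.tied_genes == ["g1"]
    assert res.n_compared == 1 and res.accuracy_percent == 100


def test_fold_change_zero_baseline_uses_pseudo_flux():
    res = fold_change_validation({"g1": 1.0}, {"g1": 0.0}, {"g1": "up"})
    assert res.accuracy_percent == 100


def test_fold_change_empty_overlap_is_an_error():
    with pytest.raises(ModelError):
        fold_change_validation({"a": 1.0}, {"a": 1.0}, {"b": "up"})


def test_accuracy_rounding_is_half_up():
    # 25/37 = 67.57 -> 68; 1/8 = 12.5 -> 13
    a = {f"g{i}": 2.0 for i in range(8)}
    b = {f"g{i}": 1.0 for i in range(8)}
    exp = {f"g{i}": ("up" if i == 0 else "down") for i in range(8)}
    assert fold_change_validation(a, b, exp).accuracy_percent == 13


# ---------------------------------------------------------------------------
# growth-excess arithmetic
# ---------------------------------------------------------------------------

def test_growth_excess_rounds_to_integer_percent():
    out = table_growth_excess({"s": 0.74, "b": 0.86}, {"s": 0.70, "b": 0.82})
    assert out == {"s": 6, "b": 5}
    with pytest.raises(ModelError):
        table_growth_excess({"s": 1.0}, {"s": 0.0})


# ---------------------------------------------------------------------------
# model-backed stages (kept small; the full suites run in acceptance)
# ---------------------------------------------------------------------------

def test_growth_profile_matches_single_point_solves(capped_model):
    grid = [0.5, 2.0, 6.0, 10.0]
    prof = analyses.growth_profile(capped_model, "succinate", grid, tol=1e-3)
    for u, mu in zip(grid, prof.mu):
        direct = solver.max_growth(capped_model, {"succinate": u}, tol=1e-3).mu
        assert mu == pytest.approx(direct, abs=1e-9)
    assert prof.regions and len(prof.regions) == len(grid)


def test_growth_profile_requires_sorted_grid(capped_model):
    with pytest.raises(ModelError):
        analyses.growth_profile(capped_model, "succinate", [2.0, 1.0])


def test_ferredoxin_electron_conservation_in_solution(capped_model,
                                                      succinate_solution):
    # oracle: electrons loaded onto ferredoxin equal electrons drained by
    # nitrogenases and the FNR return valve
    f = succinate_solution.fluxes
    loaded = f["ETFD"]
    drained = sum(-capped_model.reactions[rid].stoichiometry["fd_red"] * f[rid]
                  for rid in ("NFIX_Mo", "NFIX_V", "NFIX_Fe", "FNR"))
    assert loaded == pytest.approx(drained, abs=1e-6)


def test_temperature_scan_reports_mutant_growth_and_crossover(capped_model):
    frame = analyses.nitrogenase_temperature_scan(
        capped_model, [1.0, 1e-3, 1e-4], "succinate", 4.0, tol=1e-3)
    assert list(frame["multiplier"]) == [1.0, 1e-3, 1e-4]
    row0 = frame.iloc[0]
    assert row0["mu_Mo_only"] > row0["mu_V_only"] > row0["mu_Fe_only"]
    gamma = frame.attrs["crossover_multiplier"]
    assert gamma < 1.0  # ordering flips at a reduced Mo turnover
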