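"""Downstream analyses over a solved ME model.

These are the reusable pipeline stages behind the core physiological questions: how
growth, carbon fixation and nitrogen fixation respond to substrate uptake
(and where the strictly-nutrient-limited / Janusian / strictly-proteome-
limited regions lie); how pinning the electron transport through
ferredoxin (ETFD) partitions electrons between the carbon- and nitrogen-
fixing modules; how tuning nitrogenase k_cat values (a temperature proxy
via the Arrhenius relation) reorders the Mo/V/Fe mutant growth rates; and
how predicted expression fold-change directions score against an
experimental direction table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import MEModel, ModelError, knockout, set_enzyme_kcat
from . import solver

__all__ = [
    "GrowthProfile",
    "EtfdSweepResult",
    "ValidationResult",
    "MolecularFormula",
    "growth_profile",
    "classify_regions",
    "etfd_sweep",
    "fold_change_validation",
    "mean_carbon_oxidation_state",
    "nitrogenase_temperature_scan",
    "table_growth_excess",
    "alternate_sink_report",
    "REGION_SNL",
    "REGION_JANUSIAN",
    "REGION_SPL",
]

REGION_SNL = "SNL"
REGION_JANUSIAN = "Janusian"
REGION_SPL = "SPL"

#: Published reference growth rates (day^-1) for anaerobic nitrogen-fixing
#: photoheterotrophic growth on each substrate: experimental measurements
#: and the genome-scale ME-model predictions they are compared against.
EXPERIMENTAL_GROWTH_RATES = {"succinate": 0.70, "acetate": 0.74, "butyrate": 0.82}
PREDICTED_GROWTH_RATES = {"succinate": 0.74, "acetate": 0.77,
                          "butyrate": 0.86, "p-coumarate": 1.21}


@dataclass
class GrowthProfile:
    substrate: str
    uptake_grid: list[float]
    mu: list[float]
    v_nfix: list[float]
    v_cfix: list[float]
    v_mdh: list[float]
    v_g3pdh: list[float]
    regions: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "uptake": self.uptake_grid, "mu": self.mu,
            "v_nfix": self.v_nfix, "v_cfix": self.v_cfix,
            "v_mdh": self.v_mdh, "v_g3pdh": self.v_g3pdh,
            "region": self.regions or [""] * len(self.mu),
        })


@dataclass
class EtfdSweepResult:
    substrate: str
    etfd_level: float
    label: str
    cfix_grid: list[float]
    v_nfix: list[float]  # NaN where the (ETFD, cfix) pin is infeasible

    def feasible_points(self) -> tuple[list[float], list[float]]:
        pairs = [(c, n) for c, n in zip(self.cfix_grid, self.v_nfix)
                 if not math.isnan(n)]
        return [p[0] for p in pairs], [p[1] for p in pairs]

    def nfix_correlation(self) -> float:
        c, n = self.feasible_points()
        if len(c) < 3 or np.ptp(c) <= 0:
            return float("nan")
        if np.ptp(n) <= 1e-6 * max(np.max(np.abs(n)), 1e-12):
            return float("nan")  # constant within solver noise
        return float(np.corrcoef(c, n)[0, 1])

    def nfix_relative_range(self) -> float:
        """Spread of the nitrogenase flux over feasible points, relative to
        its magnitude (zero means invariant)."""
        _, n = self.feasible_points()
        if not n:
            return float("nan")
        return float(np.ptp(n) / max(np.max(np.abs(n)), 1e-12))


@dataclass
class ValidationResult:
    n_compared: int
    n_correct: int
    accuracy_percent: int
    n_ties_excluded: int = 0
    tied_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= self.n_compared:
            raise ModelError("correct-call count outside [0, n_compared]")


@dataclass
class MolecularFormula:
    C: float = 0
    H: float = 0
    O: float = 0
    N: float = 0
    S: float = 0
    charge: int = 0


def _nfix_total(model: MEModel, fluxes: Mapping[str, float]) -> float:
    rids = model.annotations.get("nitrogenase_reactions", {}).values()
    return sum(fluxes.get(r, 0.0) for r in rids)


def _cfix_total(model: MEModel, fluxes: Mapping[str, float]) -> float:
    rids = model.annotations.get("carbon_fixation_reactions", [])
    return sum(fluxes.get(r, 0.0) for r in rids)


def growth_profile(model: MEModel, substrate: str, uptake_grid: Sequence[float],
                   tol: float = solver.DEFAULT_MU_TOL,
                   alpha: float = 0.9, beta: float = 0.05) -> GrowthProfile:
    """Maximal growth and key parsimonious fluxes along an uptake grid.

    Each grid point is an independent max-growth bisection followed by a
    parsimonious flux solve; the recorded fluxes are total nitrogen
    fixation, total carbon fixation (both rubisco forms), and the two
    NADH-reoxidizing sink dehydrogenases.
    """
    grid = list(uptake_grid)
    if grid != sorted(grid):
        raise ModelError("uptake grid must be sorted ascending")
    mus, nfix, cfix, mdh, g3pdh = [], [], [], [], []
    sinks = model.annotations.get("sink_reactions", {})
    for u in grid:
        sol = solver.max_growth(model, {substrate: u}, tol=tol)
        if sol.status != "optimal":
            raise ModelError(f"infeasible at uptake {u}; model broken at mu=0")
        mus.append(sol.mu)
        nfix.append(_nfix_total(model, sol.fluxes))
        cfix.append(_cfix_total(model, sol.fluxes))
        mdh.append(sol.fluxes.get(sinks.get("mdh", ""), 0.0))
        g3pdh.append(sol.fluxes.get(sinks.get("g3pdh", ""), 0.0))
    profile = GrowthProfile(substrate=substrate, uptake_grid=grid, mu=mus,
                            v_nfix=nfix, v_cfix=cfix, v_mdh=mdh, v_g3pdh=g3pdh)
    profile.regions = classify_regions(profile, alpha=alpha, beta=beta,
                                       mu_tol=2 * tol)
    return profile


def classify_regions(profile: GrowthProfile, alpha: float = 0.9,
                     beta: float = 0.05, mu_tol: float = 1e-3) -> list[str]:
    """Label grid points SNL / Janusian / SPL from the growth-curve slope.

    Central-difference slopes s_i are compared with the maximal slope:
    points with s_i >= alpha * s_max are strictly nutrient limited, points
    with s_i <= beta * s_max strictly proteome limited.  Contiguity is
    enforced structurally (an SNL prefix, an SPL suffix, Janusian between),
    so the labels always partition the grid into at most three blocks in
    order.  A non-monotone growth curve is an upstream error.
    """
    u = np.asarray(profile.uptake_grid, dtype=float)
    mu = np.asarray(profile.mu, dtype=float)
    if len(u) < 4:
        raise ModelError("need at least 4 grid points to classify regions")
    if np.any(np.diff(mu) < -mu_tol):
        raise ModelError("growth curve is not non-decreasing; upstream bug")
    s = np.gradient(mu, u)
    s_max = float(np.max(s))
    if s_max <= 0:  # flat curve: proteome-limited everywhere
        return [REGION_SPL] * len(u)
    snl_end = 0
    while snl_end < len(u) and s[snl_end] >= alpha * s_max:
        snl_end += 1
    spl_start = len(u)
    while spl_start > snl_end and s[spl_start - 1] <= beta * s_max:
        spl_start -= 1
    return ([REGION_SNL] * snl_end
            + [REGION_JANUSIAN] * (spl_start - snl_end)
            + [REGION_SPL] * (len(u) - spl_start))


def etfd_sweep(model: MEModel, substrate: str, mu_pin: float, uptake_pin: float,
               etfd_levels: Mapping[str, float], cfix_grid: Sequence[float],
               ) -> list[EtfdSweepResult]:
    """Electron-distribution sweep at fixed growth and fixed uptake.

    For each named ETFD level (e.g. the parsimonious solution value, an
    intermediate, and a high level) the ETFD flux is pinned, the total
    carbon-fixation flux is pinned to each grid value in turn, and the
    resulting parsimonious nitrogen-fixation flux is recorded.  Infeasible
    (ETFD, cfix) combinations are recorded as NaN, never fabricated.
    """
    etfd_id = model.annotations.get("etfd_reaction")
    if etfd_id is None:
        raise ModelError("model has no designated ETFD reaction")
    cfix_ids = model.annotations.get("carbon_fixation_reactions", [])
    ex = model.annotations["substrate_exchanges"][substrate]
    out = []
    for label, level in etfd_levels.items():
        nfix_vals = []
        for c in cfix_grid:
            sol = solver.pfba_fluxes(
                model, mu_pin,
                pinned_fluxes={ex: -uptake_pin, etfd_id: level},
                pinned_sums={"cfix": ({r: 1.0 for r in cfix_ids}, float(c))},
            )
            nfix_vals.append(_nfix_total(model, sol.fluxes)
                             if sol.status == "optimal" else float("nan"))
        out.append(EtfdSweepResult(substrate=substrate, etfd_level=level,
                                   label=label, cfix_grid=list(cfix_grid),
                                   v_nfix=nfix_vals))
    return out


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def fold_change_validation(flux_A: Mapping[str, float],
                           flux_B: Mapping[str, float],
                           experimental_directions: Mapping[str, str],
                           eps: float = 1e-9) -> ValidationResult:
    """Score predicted fold-change directions against an experimental table.

    Fold change per gene is flux_A / flux_B with condition B the baseline;
    > 1 is called up, < 1 down.  A pseudo-flux ``eps`` is added to both
    conditions so zero baselines stay finite; exact ties are classified
    "unchanged", excluded from the accuracy denominator and reported.
    Accuracy is the percentage of direction matches, rounded half-up to the
    nearest integer.
    """
    genes = [g for g in experimental_directions
             if g in flux_A and g in flux_B]
    if not genes:
        raise ModelError("no overlap between predictions and experimental table")
    n_correct = 0
    ties: list[str] = []
    for g in genes:
        fc = (flux_A[g] + eps) / (flux_B[g] + eps)
        if fc == 1.0:
            ties.append(g)
            continue
        predicted = "up" if fc > 1.0 else "down"
        if predicted == experimental_directions[g]:
            n_correct += 1
    n_compared = len(genes) - len(ties)
    if n_compared == 0:
        raise ModelError("all fold changes tied; nothing to compare")
    return ValidationResult(
        n_compared=n_compared, n_correct=n_correct,
        accuracy_percent=_round_half_up(100.0 * n_correct / n_compared),
        n_ties_excluded=len(ties), tied_genes=ties)


def mean_carbon_oxidation_state(formula: MolecularFormula | Mapping[str, float],
                                charge: int | None = None) -> float:
    """Mean carbon oxidation state of a molecule.

    With the conventional fixed states H=+1, O=-2, N=-3, S=-2 and the
    molecular charge honored, the carbon atoms carry the remainder:

        (charge - nH + 2 nO + 3 nN + 2 nS) / nC

    which for a neutral CxHyOz molecule reduces to (2z - y) / x.
    """
    if isinstance(formula, MolecularFormula):
        f = {"C": formula.C, "H": formula.H, "O": formula.O,
             "N": formula.N, "S": formula.S}
        q = formula.charge if charge is None else charge
    else:
        f = {el: formula.get(el, 0) for el in ("C", "H", "O", "N", "S")}
        q = charge or 0
    if f["C"] < 1:
        raise ModelError("molecule contains no carbon")
    return (q - f["H"] + 2 * f["O"] + 3 * f["N"] + 2 * f["S"]) / f["C"]


def nitrogenase_temperature_scan(model: MEModel, kcat_multipliers: Sequence[float],
                                 substrate: str, uptake: float,
                                 tol: float = solver.DEFAULT_MU_TOL,
                                 target_isozyme: str = "Mo") -> pd.DataFrame:
    """Maximal growth of WT and single-nitrogenase mutants while scaling
    one isozyme's k_cat (an Arrhenius temperature proxy).

    Returns a table with one row per multiplier and mu_max columns for
    WT / Mo-only / V-only / Fe-only, plus the crossover multiplier (the
    largest scanned multiplier at which the V-only mutant outgrows the
    Mo-only mutant) in ``frame.attrs["crossover_multiplier"]``.
    """
    gene_sets = model.annotations.get("nitrogenase_gene_sets")
    if not gene_sets:
        raise ModelError("model lacks nitrogenase gene-set annotation")
    enzyme_id = f"enz_nase_{target_isozyme}"
    base_kcat = model.enzymes[enzyme_id].kcat
    rows = []
    for gamma in kcat_multipliers:
        scaled = set_enzyme_kcat(model.copy(), enzyme_id, base_kcat * gamma)
        strains = {
            "WT": scaled,
            "Mo_only": knockout(scaled, gene_sets["V"] + gene_sets["Fe"]),
            "V_only": knockout(scaled, gene_sets["Mo"] + gene_sets["Fe"]),
            "Fe_only": knockout(scaled, gene_sets["Mo"] + gene_sets["V"]),
        }
        row = {"multiplier": gamma}
        for name, strain in strains.items():
            row[f"mu_{name}"] = solver.max_growth(strain, {substrate: uptake},
                                                  tol=tol).mu
        rows.append(row)
    frame = pd.DataFrame(rows)
    crossed = frame[frame["mu_V_only"] > frame["mu_Mo_only"] + tol]
    frame.attrs["crossover_multiplier"] = (
        float(crossed["multiplier"].max()) if len(crossed) else float("nan"))
    return frame


def table_growth_excess(predicted: Mapping[str, float],
                        experimental: Mapping[str, float]) -> dict[str, int]:
    """Percent excess of predicted over experimental growth rate per
    substrate, rounded half-up to the nearest integer percent."""
    out = {}
    for s, exp in experimental.items():
        if s not in predicted:
            continue
        if exp <= 0:
            raise ModelError(f"non-positive experimental growth rate for {s}")
        out[s] = _round_half_up(100.0 * (predicted[s] - exp) / exp)
    return out


def alternate_sink_report(model: MEModel, profile: GrowthProfile,
                          threshold: float = 1e-6) -> dict[str, dict[str, float]]:
    """NADH-reoxidizing reactions whose flux strictly increases between the
    carbon-fixation peak point and the growth plateau point."""
    if not profile.mu:
        raise ModelError("empty profile")
    i_peak = int(np.argmax(profile.v_cfix))
    i_plateau = len(profile.mu) - 1
    report = {}
    for name, series in (("mdh", profile.v_mdh), ("g3pdh", profile.v_g3pdh)):
        rise = series[i_plateau] - series[i_peak]
        if rise > threshold:
            rid = model.annotations.get("sink_reactions", {}).get(name, name)
            report[rid] = {"at_cfix_peak": series[i_peak],
                           "at_plateau": series[i_plateau],
                           "increase": rise}
    return report
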