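"""Bespoke photoheterotroph constraints.

Three pieces of biology that a plain ME formulation misses:

1. Rubisco form I / form II coexpression.  Expression of the L8S8 form I
   is tied to cellular CO2 production: the form I flux is set to

       v_I = [ -sum(vCO2) + (mu/mu_max) * sum(vCO2,max) ] * kcat_I / kcat_II

   where sum(vCO2) is the total flux of CO2-producing reactions and the
   calibration pair (mu_max, sum(vCO2,max)) comes from a first solve
   without the constraint (two-pass protocol).  The bracket can go
   negative at low growth; the default "relaxed" mode implements
   v_I = max(0, bracket * ratio) as a pair of inequalities (v_I >= 0 and
   v_I >= bracket * ratio) that the parsimonious objective pins at the
   maximum; a "strict" equality mode is available.

2. Photosynthetic ATP caps.  Cyclic photophosphorylation is the dominant
   ATP source, and its maximal output on each substrate is capped in
   proportion to the measured photosynthetic yield relative to acetate:
   v_PS(S) = v_PS(ace) * phi(S) / phi(ace).  The published per-substrate
   caps (mmol gDW^-1 day^-1): acetate 54.0, succinate 45.7, butyrate 56.7,
   p-coumarate 85.4.

3. The three nitrogenase isozymes (Mo-, V-, Fe-) as independent
   ferredoxin- and ATP-consuming N2-fixation reactions with the ordered
   ATP costs Mo < V < Fe and SASA-normalized k_cat values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .kcat import assign_kcat
from .model import (EnzymeSpec, ExtraConstraint, MEModel, ModelError,
                    Reaction, attach_enzyme_usage)
from . import solver

__all__ = [
    "TABLE_ATP_CAPS",
    "RubiscoCoexpressionSpec",
    "AtpCapSpec",
    "rubisco_coexpression_value",
    "calibrate_rubisco_coexpression",
    "apply_rubisco_coexpression",
    "apply_atp_cap",
    "register_nitrogenases",
    "NITROGENASE_ORDER",
]

#: Maximum photophosphorylation ATP production per substrate,
#: mmol gDW^-1 day^-1, computed from photosynthetic yields.
TABLE_ATP_CAPS = {
    "acetate": 54.0,
    "succinate": 45.7,
    "butyrate": 56.7,
    "p-coumarate": 85.4,
}

NITROGENASE_ORDER = ("Mo", "V", "Fe")


@dataclass
class RubiscoCoexpressionSpec:
    v_rubisco_I: str  # flux variable (reaction id) of the form I reaction
    sum_vCO2: list[str]  # CO2-producing reaction ids entering the sum
    mu_max: float
    sum_vCO2_max: float
    kcat_I: float
    kcat_II: float

    def __post_init__(self) -> None:
        if self.mu_max <= 0:
            raise ModelError("mu_max must be positive")
        if self.kcat_II <= 0:
            raise ModelError("kcat_II must be positive")
        if self.sum_vCO2_max < 0:
            raise ModelError("sum_vCO2_max must be non-negative")


@dataclass
class AtpCapSpec:
    substrate: str
    v_PS_ace: float = TABLE_ATP_CAPS["acetate"]
    phi_S: float | None = None  # photosynthetic yields (dimensionless)
    phi_ace: float | None = None
    table_caps: dict[str, float] = field(default_factory=lambda: dict(TABLE_ATP_CAPS))

    @property
    def cap(self) -> float:
        if self.phi_S is not None and self.phi_ace is not None:
            if self.phi_ace <= 0:
                raise ModelError("acetate photosynthetic yield must be positive")
            return self.v_PS_ace * self.phi_S / self.phi_ace
        if self.substrate not in self.table_caps:
            raise ModelError(f"no ATP cap known for substrate {self.substrate!r}")
        return self.table_caps[self.substrate]


def rubisco_coexpression_value(mu: float, mu_max: float, sum_vco2: float,
                               sum_vco2_max: float, kcat_I: float,
                               kcat_II: float) -> float:
    """Direct evaluation of the coexpression target for the form I flux."""
    if mu_max <= 0 or kcat_II <= 0:
        raise ModelError("mu_max and kcat_II must be positive")
    return (-sum_vco2 + (mu / mu_max) * sum_vco2_max) * kcat_I / kcat_II


def calibrate_rubisco_coexpression(model: MEModel, uptake_bounds: dict[str, float],
                                   kcat_I: float | None = None,
                                   kcat_II: float | None = None,
                                   tol: float = solver.DEFAULT_MU_TOL,
                                   ) -> RubiscoCoexpressionSpec:
    """Two-pass calibration: solve the unconstrained model to obtain
    mu_max and the CO2 production at mu_max, then build the spec.

    The CO2-producing reaction set is read from the model's emitted
    ``co2_producers`` annotation (every reaction producing cytosolic CO2,
    the CO2 exchange excluded).
    """
    ann = model.annotations
    try:
        rub_I = ann["rubisco_I_reaction"]
        producers = list(ann["co2_producers"])
    except KeyError as exc:
        raise ModelError(f"model annotation missing: {exc.args[0]}") from exc
    sol = solver.max_growth(model, uptake_bounds, tol=tol)
    sum_max = sum(sol.fluxes.get(r, 0.0) for r in producers)
    if kcat_I is None or kcat_II is None:
        defs = ann.get("rubisco_site_kcats", {})
        kcat_I = defs.get("I") if kcat_I is None else kcat_I
        kcat_II = defs.get("II") if kcat_II is None else kcat_II
    if kcat_I is None or kcat_II is None:
        raise ModelError("rubisco k_cat values not supplied and not annotated")
    return RubiscoCoexpressionSpec(v_rubisco_I=rub_I, sum_vCO2=producers,
                                   mu_max=sol.mu, sum_vCO2_max=sum_max,
                                   kcat_I=kcat_I, kcat_II=kcat_II)


def apply_rubisco_coexpression(model: MEModel, spec: RubiscoCoexpressionSpec,
                               mode: str = "relaxed") -> MEModel:
    """Add the coexpression row(s) linking the form I flux to total CO2
    production at the solve's mu.

    The LP row reads  v_I + ratio * sum(vCO2)  (sense)  ratio *
    (sum_vCO2_max / mu_max) * mu,  with ratio = kcat_I / kcat_II.  In
    "strict" mode the sense is equality; a negative implied v_I then makes
    the solve infeasible (surfaced, never clamped).  In "relaxed" mode the
    sense is >= with v_I >= 0, i.e. v_I = max(0, bracket * ratio) once the
    parsimonious objective minimizes v_I.
    """
    if spec.v_rubisco_I not in model.reactions:
        raise ModelError(f"unknown rubisco form I reaction {spec.v_rubisco_I}")
    ratio = spec.kcat_I / spec.kcat_II
    coeffs = {spec.v_rubisco_I: 1.0}
    for rid in spec.sum_vCO2:
        if rid not in model.reactions:
            raise ModelError(f"unknown CO2 producer {rid}")
        coeffs[rid] = coeffs.get(rid, 0.0) + ratio
    sense = {"relaxed": ">=", "strict": "=="}.get(mode)
    if sense is None:
        raise ModelError(f"unknown coexpression mode {mode!r}")
    model.extra_constraints.append(ExtraConstraint(
        name="rubisco_coexpression",
        coeffs=coeffs,
        sense=sense,
        rhs_const=0.0,
        rhs_mu=ratio * spec.sum_vCO2_max / spec.mu_max,
    ))
    model.annotations["rubisco_coexpression"] = {
        "mode": mode,
        "mu_max": spec.mu_max,
        "sum_vCO2_max": spec.sum_vCO2_max,
        "kcat_ratio": ratio,
    }
    return model


def apply_atp_cap(model: MEModel, substrate: str,
                  spec: AtpCapSpec | None = None) -> MEModel:
    """Upper-bound the designated photophosphorylation ATP reaction at the
    substrate's photosynthetic-yield cap."""
    rid = model.annotations.get("atp_synthase_reaction")
    if rid is None or rid not in model.reactions:
        raise ModelError("model has no designated photophosphorylation ATP reaction")
    spec = spec or AtpCapSpec(substrate=substrate)
    if spec.substrate != substrate:
        raise ModelError("AtpCapSpec substrate does not match the requested substrate")
    cap = spec.cap
    if cap <= 0:
        raise ModelError("ATP cap must be positive")
    model.reactions[rid].upper_bound = cap
    model.annotations.setdefault("applied_atp_caps", {})[substrate] = cap
    return model


def register_nitrogenases(model: MEModel, costs: dict[str, float],
                          kcats: dict[str, float] | None = None) -> MEModel:
    """Add the three independent N2-fixation reactions.

    ``costs`` maps isozyme ("Mo" | "V" | "Fe") to ATP hydrolyzed per N2,
    which must be ordered Mo < V < Fe.  Stoichiometry per N2 at cost ``a``:

        N2 + (a/2) fd_red + a ATP -> 2 NH3 + (a/4 - 3) H2 + (a/2) fd_ox + ...

    i.e. half the ATP count in reduced-ferredoxin electrons, six of which
    reduce N2 and the surplus leaves as obligatory H2 (a >= 12 required).
    Enzymes must already exist as ``enz_nase_<iso>`` (their k_cat values
    are SASA-normalized from the complex mass unless given explicitly).
    """
    missing = [i for i in NITROGENASE_ORDER if i not in costs]
    if missing:
        raise ModelError(f"nitrogenase ATP costs missing for {missing}")
    if not costs["Mo"] < costs["V"] < costs["Fe"]:
        raise ModelError("nitrogenase ATP costs must be ordered Mo < V < Fe")
    rids = {}
    for iso in NITROGENASE_ORDER:
        a = float(costs[iso])
        fd = a / 2.0
        h2 = fd / 2.0 - 3.0
        if h2 < 0:
            raise ModelError(f"{iso}-nitrogenase ATP cost {a} is below the "
                             "8-electron minimum of 12 ATP per N2")
        enz_id = f"enz_nase_{iso}"
        if enz_id not in model.enzymes:
            raise ModelError(f"nitrogenase enzyme {enz_id} not in model")
        enz = model.enzymes[enz_id]
        if kcats and iso in kcats:
            enz.kcat = kcats[iso]
        elif enz.kcat <= 0:
            enz.kcat = assign_kcat(enz.molecular_weight)
        stoich = {"n2_c": -1.0, "fd_red": -fd, "fd_ox": fd,
                  "atp": -a, "adp": a, "pi": a, "nh3_c": 2.0}
        if h2 > 0:
            stoich["h2_c"] = h2
        rxn = Reaction(id=f"NFIX_{iso}", stoichiometry=stoich, rclass="metabolic",
                       gpr=model.annotations.get("nitrogenase_gprs", {}).get(iso))
        model.add_reaction(rxn)
        if enz_id in model.metabolites:
            # usage coupling only makes sense when the expression layer can
            # actually synthesize the enzyme species
            attach_enzyme_usage(rxn, enz)
        rids[iso] = rxn.id
    model.annotations["nitrogenase_reactions"] = rids
    model.annotations["nitrogenase_atp_costs"] = dict(costs)
    return model
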