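"""Seeded synthetic toy ME models of an anoxygenic photoheterotroph.

The generator emulates the network motifs that drive the growth analyses
of a purple nonsulfur bacterium growing anaerobically in the light on an
organic acid while fixing N2:

* cyclic photophosphorylation: photosystem -> quinone pool -> bc1 complex
  -> proton-motive ATP synthesis, with a ferredoxin branch and an explicit
  electron-transport-through-ferredoxin (ETFD) reaction feeding
  nitrogenase;
* a lumped Calvin-Benson-Bassham (CBB) carbon-fixation reaction duplicated
  for rubisco form I (L8S8) and form II (L2) with distinct enzymes and
  turnover numbers, plus a ribulose-5P -> ribose-5P drain into biomass
  precursors;
* three nitrogenase isozymes (Mo/V/Fe) with ordered ATP costs;
* NADH-reoxidizing overflow sinks: a malate-dehydrogenase branch secreting
  succinate and a glycerol-3-phosphate-dehydrogenase branch secreting
  glycerol;
* a growth-coupled expression layer (transcription, translation, enzyme
  complex formation, biomass protein/mRNA bookkeeping, biomass dilution).

Assimilation reactions release a fixed quarter of substrate carbon as CO2
together with NADH (obligatory decarboxylation).  This is what creates
genuine redox stress on every substrate and makes refixing that CO2 via
the CBB module a net electron sink, so that carbon fixation is active at
intermediate uptake and collapses at the ATP-capped growth plateau in
favor of the dehydrogenase sinks.

Everything is deterministic under a fixed seed (byte-identical serialized
output) and element-balanced in C/H/O for all metabolic reactions; redox
and energy carriers use minimal transferable-atom formulas (NADH = NAD +
2H, reduced ferredoxin = oxidized + H, ATP/ADP/Pi massless), documented in
the methods note.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import pandas as pd

from . import constraints as _constraints
from .kcat import KcatDefaults, assign_kcat, convert_per_site_kcat
from .model import (EnzymeSpec, Gene, MEModel, Metabolite, ModelError,
                    Reaction, add_biomass_dilution, attach_enzyme_usage,
                    build_transcription_reaction, build_translation_reaction,
                    check_element_balance, molecular_weight, translate,
                    RNAP_ID, RIBOSOME_ID, BIOMASS_PROTEIN, BIOMASS_MRNA, INF)

__all__ = [
    "ToyNetworkConfig",
    "ExpressionFixture",
    "SUBSTRATE_FORMULAS",
    "build_toy_me_model",
    "make_expression_fixture",
]

#: Neutral-acid molecular formulas of the four study substrates.
SUBSTRATE_FORMULAS = {
    "acetate": {"C": 2.0, "H": 4.0, "O": 2.0},
    "succinate": {"C": 4.0, "H": 6.0, "O": 4.0},
    "butyrate": {"C": 4.0, "H": 8.0, "O": 2.0},
    "p-coumarate": {"C": 9.0, "H": 8.0, "O": 3.0},
}

_DEFAULT_SUBSTRATES = ("acetate", "succinate", "butyrate", "p-coumarate")

#: Fraction of assimilated substrate carbon released as CO2.
DECARBOXYLATION_FRACTION = 0.25

#: Upper bound on the ferredoxin:NAD+ reductase flux (mmol gDW^-1 day^-1),
#: a lumped enzyme-capacity stand-in.  Reduced ferredoxin is consumed only
#: by the nitrogenases and this capped return valve, so electron transport
#: through ferredoxin (ETFD) is the sole gateway to nitrogen fixation.
FNR_CAPACITY = 1.0

#: Biomass composition per unit dilution flux (mmol/gDW for small
#: molecules, g/gDW for the macromolecule mass species).
BIOMASS_SMALL_MOLECULES = {"prec": 10.0, "aa": 1.0, "r5p": 0.5, "atp": 30.0}
BIOMASS_PROTEIN_FRACTION = 0.55  # g protein / gDW
BIOMASS_RNA_FRACTION = 0.06  # g RNA / gDW

# (locus, coding length nt, protein species).  Lengths loosely follow the
# real operon products; sequences themselves are seeded random codons.
_GENE_TABLE = [
    ("rbcL1", 1434, "prot_rbcL1"),
    ("rbcS1", 363, "prot_rbcS1"),
    ("rbcL2", 1383, "prot_rbcL2"),
    ("nifDK", 1503, "prot_nifDK"),
    ("nifH", 903, "prot_nifH"),
    ("vnfDK", 1530, "prot_vnfDK"),
    ("vnfH", 903, "prot_vnfH"),
    ("anfDK", 1557, "prot_anfDK"),
    ("anfH", 906, "prot_anfH"),
    ("mdh", 963, "prot_mdh"),
    ("g3pd", 1005, "prot_g3pd"),
    ("rpoA", 933, "prot_rpoA"),
    ("rpoB", 3990, "prot_rpoB"),
    ("rpoC", 4203, "prot_rpoC"),
    ("rpoZ", 273, "prot_rpoZ"),
    ("rps", 399, "prot_rps"),
    ("avg", 849, "prot_avg"),
    ("gf1a", 600, "prot_gf1a"),
    ("gf1b", 600, "prot_gf1b"),
]
_RRNA_LENGTH = 120 + 2900 + 1542  # 5S + 23S + 16S


@dataclass
class ToyNetworkConfig:
    seed: int = 0
    n_filler_reactions: int = 10
    substrates: tuple[str, ...] = _DEFAULT_SUBSTRATES
    include_expression_layer: bool = True
    nitrogenase_atp_costs: dict[str, float] = field(
        default_factory=lambda: {"Mo": 16.0, "V": 24.0, "Fe": 40.0})
    photon_uptake_cap: float = 1000.0  # mmol gDW^-1 day^-1
    atp_caps: dict[str, float] = field(
        default_factory=lambda: dict(_constraints.TABLE_ATP_CAPS))
    gc_fraction: float = 0.65

    def __post_init__(self) -> None:
        costs = self.nitrogenase_atp_costs
        if not {"Mo", "V", "Fe"} <= set(costs):
            raise ModelError("nitrogenase ATP costs must name Mo, V and Fe")
        if not costs["Mo"] < costs["V"] < costs["Fe"]:
            raise ModelError("nitrogenase ATP costs must be ordered Mo < V < Fe")
        unknown = set(self.substrates) - set(SUBSTRATE_FORMULAS)
        if unknown:
            raise ModelError(f"unknown substrates {sorted(unknown)}")
        if not self.substrates:
            raise ModelError("at least one substrate is required")
        if self.photon_uptake_cap < 0 or self.n_filler_reactions < 0:
            raise ModelError("photon cap and filler count must be non-negative")


@dataclass
class ExpressionFixture:
    """Synthetic per-gene expression-flux fixture for the fold-change
    validation pipeline (artifact plumbing, not biology)."""

    gene_ids: list[str]
    condition_A_flux: dict[str, float]  # test condition
    condition_B_flux: dict[str, float]  # baseline condition
    experimental_direction: dict[str, str]  # "up" | "down"
    n_injected_mismatches: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene_id": self.gene_ids,
            "flux_A": [self.condition_A_flux[g] for g in self.gene_ids],
            "flux_B": [self.condition_B_flux[g] for g in self.gene_ids],
            "experimental_direction": [self.experimental_direction[g]
                                       for g in self.gene_ids],
        })


# ---------------------------------------------------------------------------
# Sequence generation
# ---------------------------------------------------------------------------

_STOP = {"TAA", "TAG", "TGA"}


def _codon_weights(gc: float) -> tuple[list[str], list[float]]:
    codons, weights = [], []
    p = {"G": gc / 2, "C": gc / 2, "A": (1 - gc) / 2, "T": (1 - gc) / 2}
    for a in "ACGT":
        for b in "ACGT":
            for c in "ACGT":
                cod = a + b + c
                if cod in _STOP:
                    continue
                codons.append(cod)
                weights.append(p[a] * p[b] * p[c])
    return codons, weights


def _random_cds(rng: random.Random, length_nt: int, gc: float) -> str:
    if length_nt % 3:
        raise ModelError("coding length must be divisible by 3")
    codons, weights = _codon_weights(gc)
    n = length_nt // 3 - 1
    body = rng.choices(codons, weights=weights, k=n)
    return "ATG" + "".join(body)


def _random_rna_gene(rng: random.Random, length_nt: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choices("ACGT", weights=p, k=length_nt))


# ---------------------------------------------------------------------------
# Builder
# ---------------------------------------------------------------------------

def _met(model: MEModel, sid: str, formula: dict[str, float] | None = None,
         compartment: str = "c", kind: str = "small-molecule") -> None:
    model.add_metabolite(Metabolite(id=sid, name=sid, formula=formula or {},
                                    compartment=compartment, kind=kind))


def _assim_coefficients(formula: dict[str, float]) -> tuple[float, float, float, float]:
    """(prec, co2, h2o_in, nadh_out) per substrate assimilated."""
    x, y, z = formula["C"], formula["H"], formula["O"]
    d = DECARBOXYLATION_FRACTION * x
    p = x - d
    beta = p + 2 * d - z
    n = (y + 2 * beta - 2 * p) / 2
    return p, d, beta, n


def _oxidation_coefficients(formula: dict[str, float]) -> tuple[float, float]:
    """(h2o_in, nadh_out) for complete oxidation to CO2."""
    x, y, z = formula["C"], formula["H"], formula["O"]
    w = 2 * x - z
    return w, (y + 2 * w) / 2


def build_toy_me_model(config: ToyNetworkConfig) -> MEModel:
    """Build the seeded toy photoheterotroph ME model."""
    rng = random.Random(config.seed)
    m = MEModel(id=f"toy_photoheterotroph_seed{config.seed}")
    expr = config.include_expression_layer

    # --- species ----------------------------------------------------------
    _met(m, "photon_e", {}, "e")
    _met(m, "photon_c", {})
    for s in config.substrates:
        _met(m, f"{s}_e", SUBSTRATE_FORMULAS[s], "e")
        _met(m, f"{s}_c", SUBSTRATE_FORMULAS[s])
    if "succinate" not in config.substrates:  # MDH sink product
        _met(m, "succinate_e", SUBSTRATE_FORMULAS["succinate"], "e")
        _met(m, "succinate_c", SUBSTRATE_FORMULAS["succinate"])
    if "acetate" not in config.substrates:  # overflow product
        _met(m, "acetate_e", SUBSTRATE_FORMULAS["acetate"], "e")
        _met(m, "acetate_c", SUBSTRATE_FORMULAS["acetate"])
    _met(m, "co2_c", {"C": 1, "O": 2})
    _met(m, "co2_e", {"C": 1, "O": 2}, "e")
    _met(m, "h2o_c", {"H": 2, "O": 1})
    _met(m, "h2o_e", {"H": 2, "O": 1}, "e")
    _met(m, "n2_c", {"N": 2})
    _met(m, "n2_e", {"N": 2}, "e")
    _met(m, "nh3_c", {"N": 1, "H": 3})
    _met(m, "nh3_e", {"N": 1, "H": 3}, "e")
    _met(m, "h2_c", {"H": 2})
    _met(m, "h2_e", {"H": 2}, "e")
    _met(m, "glyc_c", {"C": 3, "H": 8, "O": 3})
    _met(m, "glyc_e", {"C": 3, "H": 8, "O": 3}, "e")
    # lumped acyl-chain overflow product downstream of glycerol-3P (the
    # fatty-acid-biosynthesis electron valve); more reduced per carbon
    # (5 e-/C) than any substrate except butyrate (equal)
    _met(m, "lipid_c", {"C": 4, "H": 8, "O": 2})
    _met(m, "lipid_e", {"C": 4, "H": 8, "O": 2}, "e")
    # carriers: transferable-atom formulas keep C/H/O balance checkable
    _met(m, "nad", {})
    _met(m, "nadh", {"H": 2})
    _met(m, "fd_ox", {})
    _met(m, "fd_red", {"H": 1})
    _met(m, "q_ox", {})
    _met(m, "q_red", {"H": 2})
    _met(m, "psA_ox", {})  # photosystem primary acceptor
    _met(m, "psA_red", {"H": 1})
    _met(m, "pmf", {})
    for sid in ("atp", "adp", "pi"):
        _met(m, sid, {})
    # anabolic pools
    _met(m, "prec", {"C": 1, "H": 2, "O": 1})
    _met(m, "aa", {"C": 2, "H": 5, "N": 1, "O": 2})
    _met(m, "ru5p", {"C": 5, "H": 10, "O": 5})
    _met(m, "r5p", {"C": 5, "H": 10, "O": 5})
    _met(m, "dhap", {"C": 3, "H": 6, "O": 3})
    _met(m, "oaa", {"C": 4, "H": 4, "O": 5})
    _met(m, "mal", {"C": 4, "H": 6, "O": 5})
    _met(m, "fum", {"C": 4, "H": 4, "O": 4})
    for b in "acgu":
        _met(m, f"ntp_{b}", {"C": 5, "H": 10, "O": 5})

    def rxn(rid, stoich, lb=0.0, ub=INF, rclass="metabolic", enzyme=None, gpr=None):
        r = Reaction(id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
                     rclass=rclass, gpr=gpr)
        m.add_reaction(r)
        if enzyme is not None:
            r.enzyme_id = enzyme  # coupled later once EnzymeSpecs exist
        return r

    # --- exchanges and transport ------------------------------------------
    rxn("EX_photon_e", {"photon_e": -1}, -config.photon_uptake_cap, 0.0, "exchange")
    rxn("T_photon", {"photon_e": -1, "photon_c": 1}, enzyme="enz_generic")
    for s in config.substrates:
        rxn(f"EX_{s}_e", {f"{s}_e": -1}, 0.0, INF, "exchange")
        rxn(f"T_{s}_uptake", {f"{s}_e": -1, f"{s}_c": 1}, enzyme="enz_generic")
    if "succinate" not in config.substrates:
        rxn("EX_succinate_e", {"succinate_e": -1}, 0.0, INF, "exchange")
    rxn("T_succinate_secretion", {"succinate_c": -1, "succinate_e": 1},
        enzyme="enz_generic")
    if "acetate" not in config.substrates:
        rxn("EX_acetate_e", {"acetate_e": -1}, 0.0, INF, "exchange")
    rxn("T_acetate_secretion", {"acetate_c": -1, "acetate_e": 1},
        enzyme="enz_generic")
    rxn("EX_co2_e", {"co2_e": -1}, 0.0, INF, "exchange")
    rxn("T_co2_out", {"co2_c": -1, "co2_e": 1}, enzyme="enz_generic")
    rxn("EX_h2o_e", {"h2o_e": -1}, -INF, INF, "exchange")
    rxn("T_h2o_in", {"h2o_e": -1, "h2o_c": 1}, enzyme="enz_generic")
    rxn("T_h2o_out", {"h2o_c": -1, "h2o_e": 1}, enzyme="enz_generic")
    rxn("EX_n2_e", {"n2_e": -1}, -INF, 0.0, "exchange")
    rxn("T_n2_in", {"n2_e": -1, "n2_c": 1}, enzyme="enz_generic")
    rxn("EX_nh3_e", {"nh3_e": -1}, 0.0, INF, "exchange")
    rxn("T_nh3_out", {"nh3_c": -1, "nh3_e": 1}, enzyme="enz_generic")
    rxn("EX_h2_e", {"h2_e": -1}, 0.0, INF, "exchange")
    rxn("T_h2_out", {"h2_c": -1, "h2_e": 1}, enzyme="enz_generic")
    rxn("EX_glyc_e", {"glyc_e": -1}, 0.0, INF, "exchange")
    rxn("T_glyc_out", {"glyc_c": -1, "glyc_e": 1}, enzyme="enz_generic")
    rxn("EX_lipid_e", {"lipid_e": -1}, 0.0, INF, "exchange")
    rxn("T_lipid_out", {"lipid_c": -1, "lipid_e": 1}, enzyme="enz_generic")

    # --- catabolism and anabolism -----------------------------------------
    co2_producers: list[str] = []
    for s in config.substrates:
        f = SUBSTRATE_FORMULAS[s]
        w, n = _oxidation_coefficients(f)
        rxn(f"OX_{s}", {f"{s}_c": -1, "h2o_c": -w, "co2_c": f["C"],
                        "nad": -n, "nadh": n}, enzyme="enz_generic")
        co2_producers.append(f"OX_{s}")
        p, d, beta, na = _assim_coefficients(f)
        rxn(f"ASSIM_{s}", {f"{s}_c": -1, "h2o_c": -beta, "prec": p,
                           "co2_c": d, "nad": -na, "nadh": na},
            enzyme="enz_generic")
        co2_producers.append(f"ASSIM_{s}")
    co2_producers.append("MAL_TO_DHAP")

    # --- CBB module ---------------------------------------------------------
    cbb = {"co2_c": -1, "nadh": -2, "nad": 2,
           "atp": -3, "adp": 3, "pi": 3, "ru5p": 0.2, "h2o_c": 1}
    rxn("CBB_rubisco_I", dict(cbb), enzyme="enz_rubisco_I", gpr="rbcL1 and rbcS1")
    rxn("CBB_rubisco_II", dict(cbb), enzyme="enz_rubisco_II", gpr="rbcL2")
    rxn("RU5P_TO_PREC", {"ru5p": -1, "prec": 5}, enzyme="enz_generic")
    rxn("PREC_TO_RU5P", {"prec": -5, "atp": -1, "adp": 1, "pi": 1, "ru5p": 1},
        enzyme="enz_generic")
    rxn("R5P_ISOMERASE", {"ru5p": -1, "r5p": 1}, enzyme="enz_generic")

    # --- cyclic photophosphorylation ---------------------------------------
    # substrate electrons enter the quinone pool via NADH dehydrogenase; the
    # photosystem lifts them to its primary acceptor; from there they either
    # return through the bc1 complex (pumping protons; the cyclic loop) or
    # branch onto ferredoxin through the explicit ETFD reaction that feeds
    # nitrogenase and the CBB reductant pool
    rxn("NDH", {"nadh": -1, "nad": 1, "q_ox": -1, "q_red": 1},
        enzyme="enz_generic")
    rxn("PSI", {"photon_c": -2, "q_red": -1, "q_ox": 1,
                "psA_ox": -2, "psA_red": 2}, enzyme="enz_generic")
    rxn("BC1", {"psA_red": -2, "psA_ox": 2, "q_ox": -1, "q_red": 1, "pmf": 2},
        enzyme="enz_generic")
    rxn("ATP_SYNTHASE", {"pmf": -2, "adp": -1, "pi": -1, "atp": 1},
        enzyme="enz_generic")
    rxn("ETFD", {"psA_red": -1, "psA_ox": 1, "fd_ox": -1, "fd_red": 1},
        enzyme="enz_generic")
    # ferredoxin:NAD+ reductase: a finite-capacity relief valve returning
    # ferredoxin electrons to the NADH pool (capacity is an enzyme-amount
    # proxy; without a cap, a pinned ETFD flux could be short-circuited)
    rxn("FNR", {"fd_red": -2, "fd_ox": 2, "nad": -1, "nadh": 1},
        ub=FNR_CAPACITY, enzyme="enz_generic")

    # --- nitrogen assimilation and redox sinks -----------------------------
    rxn("AA_SYNTHESIS", {"prec": -2, "nh3_c": -1, "aa": 1, "nad": -1, "nadh": 1},
        enzyme="enz_generic")
    # redox-neutral carbon overflow (acetate excretion), giving the cell a
    # way to vent excess carbon at precursor oxidation state
    rxn("OVERFLOW_ACETATE", {"prec": -2, "acetate_c": 1}, enzyme="enz_generic")
    rxn("OAA_SYNTHESIS", {"prec": -3, "co2_c": -1, "oaa": 1, "nad": -1, "nadh": 1},
        enzyme="enz_generic")
    rxn("MDH", {"oaa": -1, "nadh": -1, "nad": 1, "mal": 1},
        enzyme="enz_mdh", gpr="mdh")
    rxn("FUMARASE", {"mal": -1, "fum": 1, "h2o_c": 1}, enzyme="enz_generic")
    rxn("FUMARATE_REDUCTASE", {"fum": -1, "nadh": -1, "nad": 1, "succinate_c": 1},
        enzyme="enz_generic")
    # gluconeogenic triose supply runs through malate (malic enzyme +
    # gluconeogenesis, lumped), so the lipid valve engages both marker
    # dehydrogenases: OAA + NADH -> malate (MDH), malate -> DHAP + CO2,
    # DHAP + NADH -> glycerol-3P (G3PDH)
    rxn("MAL_TO_DHAP", {"mal": -1, "dhap": 1, "co2_c": 1}, enzyme="enz_generic")
    rxn("G3PDH", {"dhap": -1, "nadh": -1, "nad": 1, "glyc_c": 1},
        enzyme="enz_g3pdh", gpr="g3pd")
    # glycerol-3P feeds lumped fatty-acid synthesis; the acyl product can
    # accumulate/secrete, making the G3PDH branch a true electron valve
    rxn("FATTY_ACID_SYNTHESIS",
        {"glyc_c": -4, "nadh": -2, "nad": 2, "lipid_c": 3, "h2o_c": 6},
        enzyme="enz_generic")

    # --- NTP supply ---------------------------------------------------------
    act = 2.0
    for b in "acgu":
        rxn(f"NTP_SYNTHESIS_{b.upper()}",
            {"r5p": -1, "atp": -act, "adp": act, "pi": act, f"ntp_{b}": 1},
            enzyme="enz_generic")

    # --- filler reactions (seeded; blocked by construction) -----------------
    filler_sizes = [rng.randint(2, 6) for _ in range(config.n_filler_reactions)]
    for i, a in enumerate(filler_sizes, start=1):
        _met(m, f"filler_met_{i}", {"C": a, "H": 2 * a, "O": a})
        if i == 1:
            rxn("FILLER_1_isoA", {"prec": -a, "filler_met_1": 1},
                enzyme="enz_f1a" if expr else "enz_generic",
                gpr="gf1a or gf1b")
            rxn("FILLER_1_isoB", {"prec": -a, "filler_met_1": 1},
                enzyme="enz_f1b" if expr else "enz_generic",
                gpr="gf1a or gf1b")
        else:
            rxn(f"FILLER_{i}", {"prec": -a, f"filler_met_{i}": 1},
                enzyme="enz_generic")

    # --- expression layer ---------------------------------------------------
    genes: dict[str, Gene] = {}
    if expr:
        for locus, length, product in _GENE_TABLE:
            genes[locus] = Gene(locus_tag=locus,
                                sequence=_random_cds(rng, length, config.gc_fraction),
                                product=product)
        rrna_gene = Gene(locus_tag="rrn", product="",
                         sequence=_random_rna_gene(rng, _RRNA_LENGTH,
                                                   config.gc_fraction))

        def prot_mw(locus: str) -> float:
            return molecular_weight(translate(genes[locus].sequence))

        def enz(eid, subunits, kcat=None, sites=1):
            mw = sum(prot_mw(l) * c for l, c in subunits.items())
            spec = EnzymeSpec(id=eid,
                              subunits={genes[l].product: c for l, c in subunits.items()},
                              molecular_weight=mw,
                              kcat=kcat if kcat is not None else assign_kcat(mw),
                              active_sites=sites)
            m.add_enzyme(spec)
            _met(m, eid, {}, kind="enzyme-complex")
            return spec

        kd = KcatDefaults()
        enz("enz_generic", {"avg": 1})
        enz("enz_rubisco_I", {"rbcL1": 8, "rbcS1": 8},
            kcat=convert_per_site_kcat(kd.rubisco_I_kcat_site, 8), sites=8)
        enz("enz_rubisco_II", {"rbcL2": 2},
            kcat=convert_per_site_kcat(kd.rubisco_II_kcat_site, 2), sites=2)
        enz("enz_nase_Mo", {"nifDK": 2, "nifH": 2})
        enz("enz_nase_V", {"vnfDK": 2, "vnfH": 2})
        enz("enz_nase_Fe", {"anfDK": 2, "anfH": 2})
        enz("enz_mdh", {"mdh": 2})
        enz("enz_g3pdh", {"g3pd": 2})
        enz("enz_f1a", {"gf1a": 1})
        enz("enz_f1b", {"gf1b": 1})
        rnap = EnzymeSpec(id=RNAP_ID,
                          subunits={"prot_rpoA": 2, "prot_rpoB": 1,
                                    "prot_rpoC": 1, "prot_rpoZ": 1},
                          molecular_weight=(2 * prot_mw("rpoA") + prot_mw("rpoB")
                                            + prot_mw("rpoC") + prot_mw("rpoZ")),
                          kcat=0.0)
        rnap.kcat = assign_kcat(rnap.molecular_weight)
        m.add_enzyme(rnap)
        _met(m, RNAP_ID, {}, kind="enzyme-complex")
        rrna_mw = molecular_weight(rrna_gene.sequence.replace("T", "U"), "rna")
        ribo = EnzymeSpec(id=RIBOSOME_ID, subunits={"prot_rps": 52},
                          molecular_weight=52 * prot_mw("rps") + rrna_mw,
                          kcat=0.0)
        ribo.kcat = assign_kcat(ribo.molecular_weight)
        m.add_enzyme(ribo)
        _met(m, RIBOSOME_ID, {}, kind="enzyme-complex")
        _met(m, "rrna", {}, kind="mRNA")

        # transcription + translation per gene, in table order
        for locus, _, product in _GENE_TABLE:
            g = genes[locus]
            build_transcription_reaction(m, g)
            mrna_mw = molecular_weight(g.sequence.replace("T", "U"), "rna")
            build_translation_reaction(m, g, mrna_kcat=assign_kcat(mrna_mw))
        build_transcription_reaction(m, rrna_gene, to_species="rrna")

        # bulk (non-catalytic) transcriptome and proteome: the mass of RNA
        # and protein that is not one of the modeled catalysts, produced at
        # average composition so the biomass fractions can be met
        avg = genes["avg"]
        bulk_tx = Gene(locus_tag="bulk_rna", sequence=avg.sequence, product="")
        m.add_gene(bulk_tx)
        build_transcription_reaction(m, bulk_tx, bulk_only=True)
        bulk_tl = Gene(locus_tag="bulk_protein", sequence=avg.sequence, product="")
        m.add_gene(bulk_tl)
        build_translation_reaction(m, bulk_tl, mrna_kcat=1.0, bulk_only=True)

        # complex formation
        for eid, spec in m.enzymes.items():
            if eid == RIBOSOME_ID:
                stoich = {p: -c for p, c in spec.subunits.items()}
                stoich["rrna"] = -1.0
                stoich[eid] = 1.0
            else:
                stoich = {p: -c for p, c in spec.subunits.items()}
                stoich[eid] = 1.0
            rxn(f"FORM_{eid}", stoich, rclass="complex-formation")

        # couple every enzyme-tagged metabolic reaction to its catalyst
        for r2 in m.reactions.values():
            if r2.rclass == "metabolic" and r2.enzyme_id:
                attach_enzyme_usage(r2, m.enzymes[r2.enzyme_id])
    else:
        for r2 in m.reactions.values():
            r2.enzyme_id = None

    # --- nitrogenases (Mo < V < Fe ATP costs) -------------------------------
    if not expr:
        # enzyme records exist (for bookkeeping) but carry no usage coupling
        for iso, mw in (("Mo", 176.0), ("V", 179.0), ("Fe", 181.0)):
            m.add_enzyme(EnzymeSpec(id=f"enz_nase_{iso}", subunits={},
                                    molecular_weight=mw, kcat=assign_kcat(mw)))
    _constraints.register_nitrogenases(m, config.nitrogenase_atp_costs)

    # --- biomass ------------------------------------------------------------
    composition = dict(BIOMASS_SMALL_MOLECULES)
    composition["adp"] = -composition["atp"]
    composition["pi"] = -composition["atp"]
    if expr:
        composition[BIOMASS_PROTEIN] = BIOMASS_PROTEIN_FRACTION
        composition[BIOMASS_MRNA] = BIOMASS_RNA_FRACTION
    add_biomass_dilution(m, composition)

    # --- annotations ---------------------------------------------------------
    m.annotations.update({
        "expression_layer": expr,
        "substrate_exchanges": {s: f"EX_{s}_e" for s in config.substrates},
        "photon_exchange": "EX_photon_e",
        "atp_synthase_reaction": "ATP_SYNTHASE",
        "etfd_reaction": "ETFD",
        "rubisco_I_reaction": "CBB_rubisco_I",
        "rubisco_II_reaction": "CBB_rubisco_II",
        "carbon_fixation_reactions": ["CBB_rubisco_I", "CBB_rubisco_II"],
        "co2_producers": co2_producers,
        "sink_reactions": {"mdh": "MDH", "g3pdh": "G3PDH"},
        "rubisco_site_kcats": {"I": KcatDefaults().rubisco_I_kcat_site,
                               "II": KcatDefaults().rubisco_II_kcat_site},
        "nitrogenase_gene_sets": {"Mo": ["nifDK", "nifH"],
                                  "V": ["vnfDK", "vnfH"],
                                  "Fe": ["anfDK", "anfH"]},
        "atp_caps": dict(config.atp_caps),
        "config": {
            "seed": config.seed,
            "n_filler_reactions": config.n_filler_reactions,
            "substrates": list(config.substrates),
            "include_expression_layer": expr,
            "nitrogenase_atp_costs": dict(config.nitrogenase_atp_costs),
            "photon_uptake_cap": config.photon_uptake_cap,
            "gc_fraction": config.gc_fraction,
        },
    })

    bad = check_element_balance(m)
    if bad:
        raise ModelError(f"toy model element imbalance: {bad}")
    return m


def make_expression_fixture(model: MEModel, seed: int, n_mismatches: int,
                            n_genes: int | None = None) -> ExpressionFixture:
    """Build a seeded expression fixture with known ground truth.

    Simulated condition-A/-B transcription fluxes are drawn per gene with a
    clear (never tied) direction, and the experimental direction table is
    the simulated one with exactly ``n_mismatches`` directions flipped, so
    downstream fold-change accuracy equals (n - n_mismatches) / n.  If
    ``n_genes`` exceeds the model's protein-coding gene count the id list
    is padded with synthetic ids (fixture plumbing only).
    """
    if not model.annotations.get("expression_layer", False):
        raise ModelError("model has no expression layer")
    gene_ids = sorted(t for t, g in model.genes.items() if g.product)
    if n_genes is not None:
        if n_genes < 1:
            raise ModelError("n_genes must be positive")
        if n_genes <= len(gene_ids):
            gene_ids = gene_ids[:n_genes]
        else:
            gene_ids = gene_ids + [f"synth_gene_{k:03d}"
                                   for k in range(n_genes - len(gene_ids))]
    if n_mismatches > len(gene_ids):
        raise ModelError("cannot inject more mismatches than genes")
    rng = random.Random(seed)
    flux_b, flux_a, direction = {}, {}, {}
    for g in gene_ids:
        b = rng.uniform(0.5, 5.0)
        ratio = rng.uniform(1.2, 3.0)
        up = rng.random() < 0.5
        flux_b[g] = b
        flux_a[g] = b * ratio if up else b / ratio
        direction[g] = "up" if up else "down"
    flipped = rng.sample(gene_ids, n_mismatches)
    experimental = {g: ("down" if direction[g] == "up" else "up")
                    if g in flipped else direction[g]
                    for g in gene_ids}
    return ExpressionFixture(gene_ids=gene_ids, condition_A_flux=flux_a,
                             condition_B_flux=flux_b,
                             experimental_direction=experimental,
                             n_injected_mismatches=n_mismatches)
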