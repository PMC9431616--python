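"""Core data model for metabolism-and-expression (ME) networks.

An ME model extends a stoichiometric metabolic network with explicit
transcription and translation reactions whose machinery demand is coupled
to the growth rate: a reaction catalyzed by enzyme ``E`` with turnover
number ``k_cat`` consumes ``(mu / k_cat) * v`` units of ``E`` at growth
rate ``mu`` and flux ``v``.  Macromolecule mass produced by expression
reactions is booked into ``biomass_protein`` / ``biomass_mRNA`` species
(with stoichiometric coefficients equal to the product molecular weight in
kDa) that are drained by a single biomass-dilution reaction pinned to
``mu`` during solving.  Fixing ``mu`` makes the whole system a linear
program.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

__all__ = [
    "Metabolite",
    "Gene",
    "EnzymeSpec",
    "Reaction",
    "ExtraConstraint",
    "CouplingParameters",
    "MEModel",
    "ModelError",
    "molecular_weight",
    "translate",
    "nucleotide_counts",
    "build_transcription_reaction",
    "build_translation_reaction",
    "attach_enzyme_usage",
    "add_biomass_dilution",
    "knockout",
    "set_enzyme_kcat",
    "check_element_balance",
    "validate_model",
    "AMINO_ACID_MASS",
    "NMP_MASS",
    "WATER_MASS",
    "CODON_TABLE",
]

INF = 1000.0

# Free-monomer monoisotopic-average masses in g/mol.  Polymer mass is the
# monomer sum minus one water per phosphodiester / peptide bond.
WATER_MASS = 18.0153

AMINO_ACID_MASS = {
    "A": 89.0932, "R": 174.2010, "N": 132.1179, "D": 133.1027,
    "C": 121.1582, "E": 147.1293, "Q": 146.1445, "G": 75.0666,
    "H": 155.1546, "I": 131.1729, "L": 131.1729, "K": 146.1876,
    "M": 149.2113, "F": 165.1887, "P": 115.1305, "S": 105.0926,
    "T": 119.1192, "W": 204.2252, "Y": 181.1881, "V": 117.1463,
}

# Free ribonucleoside monophosphates.
NMP_MASS = {"A": 347.2212, "C": 323.1965, "G": 363.2206, "U": 324.1813}

# Standard genetic code (DNA codons); "*" marks stop.
_BASES = "TCAG"
_AA_ORDER = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    a + b + c: _AA_ORDER[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


class ModelError(ValueError):
    """Raised for structurally invalid models or model operations."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: dict[str, float] = field(default_factory=dict)
    charge: int = 0
    compartment: str = "c"  # "c" cytosol | "e" extracellular
    kind: str = "small-molecule"  # | mRNA | protein | enzyme-complex | biomass-component

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.formula.values()):
            raise ModelError(f"negative element count in formula of {self.id}")


@dataclass
class Gene:
    locus_tag: str
    sequence: str
    product: str  # protein species id ("" for non-coding genes such as rRNA)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ModelError(f"gene {self.locus_tag} has an empty sequence")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ModelError(f"gene {self.locus_tag}: non-ACGT characters {sorted(bad)}")


@dataclass
class EnzymeSpec:
    """An enzyme complex: subunit composition, mass, SASA proxy, turnover."""

    id: str
    subunits: dict[str, int]  # protein species id -> copy number
    molecular_weight: float  # kDa
    kcat: float  # day^-1 (complex level)
    active_sites: int = 1

    @property
    def sasa(self) -> float:
        # Solvent-accessible surface area proxy: MW^(3/4).  Recomputed,
        # never stored, so it cannot go stale when MW changes.
        return self.molecular_weight ** 0.75


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = INF
    rclass: str = "metabolic"
    # metabolic | transcription | translation | complex-formation |
    # exchange | biomass-dilution | demand
    gpr: str | None = None
    enzyme_id: str | None = None
    # species id -> coefficient applied per unit of mu (an enzyme usage term
    # of -1/k_cat becomes a stoichiometric coefficient of -mu/k_cat once mu
    # is fixed).
    mu_coupled_terms: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelError(f"reaction {self.id}: lower bound exceeds upper bound")


@dataclass
class ExtraConstraint:
    """A linear row over reaction fluxes with a mu-affine right-hand side:

    sum_j coeffs[j] * v_j  (sense)  rhs_const + rhs_mu * mu
    """

    name: str
    coeffs: dict[str, float]
    sense: str  # "==" | ">=" | "<="
    rhs_const: float = 0.0
    rhs_mu: float = 0.0


@dataclass
class CouplingParameters:
    """Expression-machinery bookkeeping parameters.

    ``m_aa`` is consistent with a 31.09 kDa / 283-residue average bacterial
    protein.  ``m_rr`` defaults to the summed mass of the stated rRNA
    species (5S 120 nt + 23S 2900 nt + 16S 1542 nt) at the mean NMP residue
    mass.  ``f_rRNA`` is the fraction of cellular RNA that is rRNA.
    """

    m_aa: float = 0.109  # kDa per average amino acid residue
    f_rRNA: float = 0.86
    rrna_nucleotides: dict[str, int] = field(
        default_factory=lambda: {"rrn5S": 120, "rrn23S": 2900, "rrn16S": 1542}
    )
    ribosome_proteins: dict[str, int] = field(
        default_factory=lambda: {"large": 31, "small": 21}
    )
    rnap_composition: dict[str, int] = field(
        default_factory=lambda: {"alpha": 2, "beta": 1, "beta_prime": 1, "omega": 1}
    )
    m_rr: float = field(default=0.0)
    atp_per_residue: float = 4.0  # ATP hydrolyzed per peptide bond formed
    atp_per_ntp_activation: float = 2.0  # ATP per NTP regenerated from R5P

    def __post_init__(self) -> None:
        if not 0.0 < self.f_rRNA < 1.0:
            raise ModelError("f_rRNA must lie strictly between 0 and 1")
        if self.m_rr == 0.0:
            mean_nmp = sum(NMP_MASS.values()) / len(NMP_MASS) / 1000.0
            self.m_rr = sum(self.rrna_nucleotides.values()) * (mean_nmp - WATER_MASS / 1000.0)


@dataclass
class MEModel:
    id: str = "me_model"
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    genes: dict[str, Gene] = field(default_factory=dict)
    enzymes: dict[str, EnzymeSpec] = field(default_factory=dict)
    coupling: CouplingParameters = field(default_factory=CouplingParameters)
    biomass_dilution_id: str | None = None
    extra_constraints: list[ExtraConstraint] = field(default_factory=list)
    # Free-form machine-readable notes: substrate -> exchange reaction id,
    # designated ATP-synthase / ETFD / rubisco / nitrogenase reaction ids,
    # the emitted list of CO2-producing reactions, etc.
    annotations: dict = field(default_factory=dict)

    # -- construction helpers -------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ModelError(f"duplicate metabolite id {met.id}")
        self.metabolites[met.id] = met
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ModelError(f"duplicate reaction id {rxn.id}")
        missing = [s for s in rxn.stoichiometry if s not in self.metabolites]
        if missing:
            raise ModelError(f"reaction {rxn.id}: unknown species {missing}")
        self.reactions[rxn.id] = rxn
        return rxn

    def add_gene(self, gene: Gene) -> Gene:
        if gene.locus_tag in self.genes:
            raise ModelError(f"duplicate gene {gene.locus_tag}")
        self.genes[gene.locus_tag] = gene
        return gene

    def add_enzyme(self, enz: EnzymeSpec) -> EnzymeSpec:
        if enz.id in self.enzymes:
            raise ModelError(f"duplicate enzyme {enz.id}")
        self.enzymes[enz.id] = enz
        return enz

    def copy(self) -> "MEModel":
        return _copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Sequence arithmetic
# ---------------------------------------------------------------------------

def molecular_weight(sequence: str, alphabet: str = "protein",
                     masses: Mapping[str, float] | None = None) -> float:
    """Polymer molecular weight in kDa: monomer masses minus one
    condensation water per bond.

    ``alphabet`` selects the default monomer table ("protein" uses free
    amino acids, "rna" free NMPs); a custom ``masses`` mapping (g/mol)
    overrides it.
    """
    if not sequence:
        raise ModelError("empty sequence")
    if masses is None:
        if alphabet == "protein":
            masses = AMINO_ACID_MASS
        elif alphabet == "rna":
            masses = NMP_MASS
        else:
            raise ModelError(f"unknown alphabet {alphabet!r}")
    try:
        total = sum(masses[r] for r in sequence)
    except KeyError as exc:
        raise ModelError(f"unknown residue {exc.args[0]!r} in sequence") from exc
    total -= WATER_MASS * (len(sequence) - 1)
    return total / 1000.0


def translate(sequence: str) -> str:
    """Translate a coding DNA sequence with the standard genetic code.

    The length must be divisible by three; a trailing stop codon is
    stripped, internal stops are an error.
    """
    if len(sequence) % 3 != 0:
        raise ModelError("coding sequence length is not divisible by 3")
    codons = [sequence[i:i + 3] for i in range(0, len(sequence), 3)]
    aa = [CODON_TABLE[c] for c in codons]
    if aa and aa[-1] == "*":
        aa = aa[:-1]
    if "*" in aa:
        raise ModelError("internal stop codon in coding sequence")
    return "".join(aa)


def nucleotide_counts(sequence: str) -> dict[str, int]:
    """Per-base counts of the transcript (template-independent: the mRNA
    carries the coding-strand composition with T read as U)."""
    counts = {"A": 0, "C": 0, "G": 0, "U": 0}
    for b in sequence:
        counts["U" if b == "T" else b] += 1
    return counts


# ---------------------------------------------------------------------------
# Expression-reaction builders
# ---------------------------------------------------------------------------

RNAP_ID = "RNAP"
RIBOSOME_ID = "ribosome"
BIOMASS_PROTEIN = "biomass_protein"
BIOMASS_MRNA = "biomass_mRNA"


def _ensure_species(model: MEModel, sid: str, kind: str, compartment: str = "c") -> None:
    if sid not in model.metabolites:
        model.add_metabolite(Metabolite(id=sid, name=sid, formula={}, kind=kind,
                                        compartment=compartment))


def mrna_id(gene: Gene) -> str:
    return f"mRNA_{gene.locus_tag}"


def build_transcription_reaction(model: MEModel, gene: Gene,
                                 to_species: str | None = None,
                                 bulk_only: bool = False) -> Reaction:
    """Add the transcription reaction for ``gene``.

    Consumes NTPs according to the transcript composition, produces one
    transcript species plus ``biomass_mRNA`` with a coefficient equal to
    the transcript molecular weight in kDa, and carries an RNA-polymerase
    usage term of mu/k_cat(RNAP).  With ``bulk_only`` the reaction
    produces only the biomass-mRNA mass term (the bulk, non-catalytic
    transcriptome).
    """
    if RNAP_ID not in model.enzymes:
        raise ModelError("RNA polymerase enzyme is missing; build it first")
    if gene.locus_tag not in model.genes:
        model.add_gene(gene)
    counts = nucleotide_counts(gene.sequence)
    rna_seq = gene.sequence.replace("T", "U")
    mw = molecular_weight(rna_seq, "rna")

    stoich: dict[str, float] = {}
    for base, n in counts.items():
        if n:
            sid = f"ntp_{base.lower()}"
            _ensure_species(model, sid, "small-molecule")
            stoich[sid] = -float(n)
    _ensure_species(model, BIOMASS_MRNA, "biomass-component")
    stoich[BIOMASS_MRNA] = mw
    if not bulk_only:
        target = to_species or mrna_id(gene)
        _ensure_species(model, target, "mRNA")
        stoich[target] = 1.0

    rnap = model.enzymes[RNAP_ID]
    rxn = Reaction(
        id=f"TX_{gene.locus_tag}" if not bulk_only else "TX_biomass_bulk",
        stoichiometry=stoich,
        rclass="transcription",
        gpr=gene.locus_tag,
        enzyme_id=RNAP_ID,
        mu_coupled_terms={RNAP_ID: -1.0 / rnap.kcat},
    )
    return model.add_reaction(rxn)


def build_translation_reaction(model: MEModel, gene: Gene,
                               mrna_kcat: float,
                               bulk_only: bool = False) -> Reaction:
    """Add the translation reaction for ``gene``.

    Consumes one amino acid from the pooled ``aa`` species per residue and
    ATP for peptide-bond formation, produces the protein species plus
    ``biomass_protein`` with a coefficient equal to the protein molecular
    weight in kDa.  Carries a ribosome usage term (mu/k_cat(ribosome)) and
    an mRNA usage term (mu/k_cat_effective of the transcript): the message
    is a catalyst diluted by growth, not a stoichiometric substrate.
    """
    if RIBOSOME_ID not in model.enzymes:
        raise ModelError("ribosome enzyme is missing; build it first")
    protein_seq = translate(gene.sequence)
    if not protein_seq:
        raise ModelError(f"gene {gene.locus_tag} encodes an empty protein")
    n_aa = float(len(protein_seq))
    mw = molecular_weight(protein_seq, "protein")
    atp_cost = model.coupling.atp_per_residue * n_aa

    for sid in ("aa", "atp", "adp", "pi"):
        _ensure_species(model, sid, "small-molecule")
    _ensure_species(model, BIOMASS_PROTEIN, "biomass-component")
    stoich: dict[str, float] = {
        "aa": -n_aa,
        "atp": -atp_cost, "adp": atp_cost, "pi": atp_cost,
        BIOMASS_PROTEIN: mw,
    }
    if not bulk_only:
        _ensure_species(model, gene.product, "protein")
        stoich[gene.product] = 1.0

    ribo = model.enzymes[RIBOSOME_ID]
    usage = {RIBOSOME_ID: -1.0 / ribo.kcat}
    transcript = mrna_id(gene)
    if transcript in model.metabolites:
        if mrna_kcat <= 0:
            raise ModelError("mRNA effective k_cat must be positive")
        usage[transcript] = -1.0 / mrna_kcat

    rxn = Reaction(
        id=f"TL_{gene.locus_tag}" if not bulk_only else "TL_biomass_bulk",
        stoichiometry=stoich,
        rclass="translation",
        gpr=gene.locus_tag,
        enzyme_id=RIBOSOME_ID,
        mu_coupled_terms=usage,
    )
    return model.add_reaction(rxn)


def attach_enzyme_usage(reaction: Reaction, enzyme: EnzymeSpec) -> Reaction:
    """Couple ``reaction`` to its catalyzing enzyme.

    At growth rate mu the reaction consumes ``(mu / k_cat) * v`` units of
    the enzyme species; the term is stored as a per-mu coefficient so the
    LP stays linear once mu is fixed.
    """
    if enzyme.kcat <= 0:
        raise ModelError(f"enzyme {enzyme.id}: k_cat must be positive")
    reaction.enzyme_id = enzyme.id
    reaction.mu_coupled_terms[enzyme.id] = -1.0 / enzyme.kcat
    return reaction


def add_biomass_dilution(model: MEModel, composition: Mapping[str, float],
                         reaction_id: str = "biomass_dilution") -> MEModel:
    """Add the single biomass-dilution reaction.

    ``composition`` maps species to the amount consumed per unit of
    dilution flux; the flux itself is pinned to mu by the solver.  Energy
    release (ADP/Pi from growth-associated ATP) is encoded with negative
    composition entries.
    """
    if model.biomass_dilution_id is not None:
        raise ModelError("model already has a biomass-dilution reaction")
    stoich = {sid: -float(coef) for sid, coef in composition.items()}
    rxn = Reaction(id=reaction_id, stoichiometry=stoich, rclass="biomass-dilution")
    model.add_reaction(rxn)
    model.biomass_dilution_id = reaction_id
    return model


def knockout(model: MEModel, genes: str | Gene | Iterable[str | Gene]) -> MEModel:
    """Return a copy of the model with the given genes knocked out.

    The translation reaction of each gene's product is bounded to zero, so
    any enzyme complex containing that product becomes unproducible and the
    reactions it catalyzes are starved of catalyst at any mu > 0.
    """
    if isinstance(genes, (str, Gene)):
        genes = [genes]
    tags = [g.locus_tag if isinstance(g, Gene) else g for g in genes]
    out = model.copy()
    for tag in tags:
        if tag not in out.genes:
            raise ModelError(f"unknown gene {tag}")
        tl = out.reactions.get(f"TL_{tag}")
        if tl is not None:
            tl.lower_bound = 0.0
            tl.upper_bound = 0.0
    return out


def set_enzyme_kcat(model: MEModel, enzyme_id: str, kcat: float) -> MEModel:
    """Set an enzyme k_cat in place and refresh every usage term citing it."""
    if kcat <= 0:
        raise ModelError("k_cat must be positive")
    if enzyme_id not in model.enzymes:
        raise ModelError(f"unknown enzyme {enzyme_id}")
    model.enzymes[enzyme_id].kcat = kcat
    for rxn in model.reactions.values():
        if enzyme_id in rxn.mu_coupled_terms:
            rxn.mu_coupled_terms[enzyme_id] = -1.0 / kcat
    return model


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def check_element_balance(model: MEModel, elements: tuple[str, ...] = ("C", "H", "O"),
                          rclasses: tuple[str, ...] = ("metabolic",),
                          tol: float = 1e-9) -> dict[str, dict[str, float]]:
    """Return per-reaction element imbalances for the given reaction classes.

    Only small-molecule chemistry is checked: expression and formation
    reactions balance by construction of macromolecule bookkeeping and are
    excluded by default.
    """
    bad: dict[str, dict[str, float]] = {}
    for rxn in model.reactions.values():
        if rxn.rclass not in rclasses:
            continue
        imbalance = {}
        for el in elements:
            total = 0.0
            for sid, coef in rxn.stoichiometry.items():
                total += coef * model.metabolites[sid].formula.get(el, 0.0)
            if abs(total) > tol:
                imbalance[el] = total
        if imbalance:
            bad[rxn.id] = imbalance
    return bad


def validate_model(model: MEModel) -> list[str]:
    """Structural validation; returns a list of human-readable problems."""
    problems: list[str] = []
    for rxn in model.reactions.values():
        for sid in rxn.stoichiometry:
            if sid not in model.metabolites:
                problems.append(f"{rxn.id}: dangling species {sid}")
        for sid in rxn.mu_coupled_terms:
            if sid not in model.metabolites and sid not in model.enzymes:
                problems.append(f"{rxn.id}: dangling usage species {sid}")
        if rxn.mu_coupled_terms and rxn.enzyme_id is None and rxn.rclass == "metabolic":
            problems.append(f"{rxn.id}: usage terms without a catalyzing enzyme")
    dilutions = [r.id for r in model.reactions.values() if r.rclass == "biomass-dilution"]
    if len(dilutions) != 1:
        problems.append(
            "model must contain exactly one biomass-dilution reaction "
            f"(found {len(dilutions)}); expression mass has no growth drain without it"
        )
    elif model.biomass_dilution_id != dilutions[0]:
        problems.append("biomass_dilution_id does not match the dilution reaction")
    for tag, gene in model.genes.items():
        if gene.product and f"TL_{tag}" in model.reactions:
            tl = model.reactions[f"TL_{tag}"]
            if tl.gpr != tag:
                problems.append(f"translation reaction TL_{tag} maps to {tl.gpr}")
    bad = check_element_balance(model)
    for rid, imbalance in bad.items():
        problems.append(f"{rid}: element imbalance {imbalance}")
    return problems
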