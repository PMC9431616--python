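"""Core ME data model: sequence arithmetic, expression-reaction builders,
coupling terms, biomass dilution and gene knockouts."""

import pytest

from rpalme import solver
from rpalme.model import (AMINO_ACID_MASS, NMP_MASS, WATER_MASS,
                          CouplingParameters, EnzymeSpec, Gene, MEModel,
                          Metabolite, ModelError, Reaction,
                          add_biomass_dilution, attach_enzyme_usage,
                          build_transcription_reaction,
                          build_translation_reaction, knockout,
                          molecular_weight, nucleotide_counts, translate,
                          validate_model, RNAP_ID, RIBOSOME_ID,
                          BIOMASS_MRNA, BIOMASS_PROTEIN)


# ---------------------------------------------------------------------------
# molecular weight
# ---------------------------------------------------------------------------

def test_molecular_weight_single_glycine_is_free_glycine_mass():
    assert molecular_weight("G") == pytest.approx(75.0666 / 1000.0)


def test_molecular_weight_dipeptide_matches_hand_summed_monomers():
    # brute-force oracle: sum free residues, subtract one condensation water
    expected = (AMINO_ACID_MASS["A"] + AMINO_ACID_MASS["G"] - WATER_MASS) / 1000.0
    assert molecular_weight("AG") == pytest.approx(expected, abs=1e-12)


def test_molecular_weight_mean_residue_protein_gives_average_enzyme_mass():
    # a 283-residue protein whose residues each weigh (31.09 kDa)/283 after
    # condensation reproduces the canonical average bacterial enzyme
    residue = (31.09 * 1000.0 + 282 * WATER_MASS) / 283
    assert molecular_weight("X" * 283, masses={"X": residue}) == pytest.approx(31.09)


def test_molecular_weight_against_biopython_oracle():
    from Bio.SeqUtils import molecular_weight as bio_mw

    peptide = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
    ours = molecular_weight(peptide) * 1000.0
    theirs = bio_mw(peptide, seq_type="protein")
    assert ours == pytest.approx(theirs, rel=1e-3)
    rna = "AUGGCGUUAGCC"
    assert molecular_weight(rna, "rna") * 1000.0 == pytest.approx(
        bio_mw(rna, seq_type="RNA"), rel=1e-3)


@pytest.mark.parametrize("sequence, alphabet", [("", "protein"), ("AZB?", "protein"),
                                                ("ACGT", "rna")])
def test_molecular_weight_rejects_bad_sequences(sequence, alphabet):
    with pytest.raises(ModelError):
        molecular_weight(sequence, alphabet)


def test_translate_matches_biopython_and_validates_length():
    from Bio.Seq import Seq

    cds = "ATGGCTAAAGGTTTACGT"
    assert translate(cds) == str(Seq(cds).translate())
    with pytest.raises(ModelError):
        translate(cds + "AA")  # not divisible by 3
    with pytest.raises(ModelError):
        translate("ATGTAAGGT")  # internal stop


# ---------------------------------------------------------------------------
# expression-reaction builders (on a minimal scaffold)
# ---------------------------------------------------------------------------

def _scaffold() -> MEModel:
    m = MEModel(id="scaffold", coupling=CouplingParameters())
    for sid in ("aa", "atp", "adp", "pi"):
        m.add_metabolite(Metabolite(id=sid))
    m.add_enzyme(EnzymeSpec(id=RNAP_ID, subunits={}, molecular_weight=400.0,
                            kcat=1e5))
    m.add_metabolite(Metabolite(id=RNAP_ID, kind="enzyme-complex"))
    m.add_enzyme(EnzymeSpec(id=RIBOSOME_ID, subunits={}, molecular_weight=2500.0,
                            kcat=1e5))
    m.add_metabolite(Metabolite(id=RIBOSOME_ID, kind="enzyme-complex"))
    return m


def test_transcription_consumes_ntps_by_composition_and_books_mrna_mass():
    m = _scaffold()
    gene = Gene(locus_tag="g1", sequence="AAAAAAAAA", product="prot_g1")
    rxn = build_transcription_reaction(m, gene)
    assert rxn.stoichiometry["ntp_a"] == -9  # {A: 9} for a 9-nt homopolymer
    assert rxn.stoichiometry["mRNA_g1"] == 1
    expected_mw = (9 * NMP_MASS["A"] - 8 * WATER_MASS) / 1000.0
    assert rxn.stoichiometry[BIOMASS_MRNA] == pytest.approx(expected_mw)
    assert rxn.mu_coupled_terms[RNAP_ID] == pytest.approx(-1.0 / 1e5)


def test_transcription_of_identical_sequences_identical_up_to_ids():
    m = _scaffold()
    r1 = build_transcription_reaction(m, Gene("g1", "ACGGGTACG", "prot_g1"))
    r2 = build_transcription_reaction(m, Gene("g2", "ACGGGTACG", "prot_g2"))
    s1 = {k.replace("g1", "*"): v for k, v in r1.stoichiometry.items()}
    s2 = {k.replace("g2", "*"): v for k, v in r2.stoichiometry.items()}
    assert s1 == s2 and r1.mu_coupled_terms == r2.mu_coupled_terms


def test_transcription_requires_rna_polymerase():
    m = _scaffold()
    del m.enzymes[RNAP_ID]
    with pytest.raises(ModelError):
        build_transcription_reaction(m, Gene("g1", "AAA", "p"))


def test_translation_counts_residues_and_books_protein_mass():
    m = _scaffold()
    gene = Gene(locus_tag="g1", sequence="ATGGCTAAA", product="prot_g1")
    build_transcription_reaction(m, gene)
    rxn = build_translation_reaction(m, gene, mrna_kcat=2e5)
    assert rxn.stoichiometry["aa"] == -3  # 9 nt -> 3 residues
    assert rxn.stoichiometry["prot_g1"] == 1
    assert rxn.stoichiometry[BIOMASS_PROTEIN] == pytest.approx(
        molecular_weight(translate(gene.sequence)))
    # the transcript is a usage (dilution) term, not a consumed substrate
    assert "mRNA_g1" not in rxn.stoichiometry
    assert rxn.mu_coupled_terms["mRNA_g1"] == pytest.approx(-1.0 / 2e5)


def test_translation_rejects_frameshifted_gene():
    m = _scaffold()
    with pytest.raises(ModelError):
        build_translation_reaction(m, Gene("g1", "ATGGCTAA", "p"), mrna_kcat=1e5)


# ---------------------------------------------------------------------------
# enzyme usage coupling
# ---------------------------------------------------------------------------

def test_enzyme_usage_coefficient_algebra():
    enz = EnzymeSpec(id="e", subunits={}, molecular_weight=50.0, kcat=4.0)
    rxn = Reaction(id="r", stoichiometry={})
    attach_enzyme_usage(rxn, enz)
    per_mu = rxn.mu_coupled_terms["e"]
    assert per_mu * 0.0 == 0.0                       # no demand at mu = 0
    assert per_mu * enz.kcat == pytest.approx(-1.0)  # mu = kcat -> unit usage
    enz2 = EnzymeSpec(id="e", subunits={}, molecular_weight=50.0, kcat=8.0)
    rxn2 = Reaction(id="r2", stoichiometry={})
    attach_enzyme_usage(rxn2, enz2)
    assert rxn2.mu_coupled_terms["e"] == pytest.approx(per_mu / 2.0)


def test_enzyme_usage_rejects_nonpositive_kcat():
    enz = EnzymeSpec(id="e", subunits={}, molecular_weight=50.0, kcat=0.0)
    with pytest.raises(ModelError):
        attach_enzyme_usage(Reaction(id="r", stoichiometry={}), enz)


# ---------------------------------------------------------------------------
# biomass dilution and validation
# ---------------------------------------------------------------------------

def test_biomass_dilution_is_unique_and_pinned_to_mu(capped_model,
                                                     succinate_solution):
    with pytest.raises(ModelError):
        add_biomass_dilution(capped_model.copy().copy(), {"prec": 1.0})
    dil = capped_model.biomass_dilution_id
    assert succinate_solution.fluxes[dil] == pytest.approx(succinate_solution.mu)


def test_validation_flags_missing_dilution(toy_model):
    broken = toy_model.copy()
    rid = broken.biomass_dilution_id
    del broken.reactions[rid]
    broken.biomass_dilution_id = None
    assert any("biomass-dilution" in p for p in validate_model(broken))
    assert not any("biomass-dilution" in p for p in validate_model(toy_model))


def test_biomass_protein_production_balances_dilution(capped_model,
                                                      succinate_solution):
    produced = sum(
        rxn.stoichiometry.get(BIOMASS_PROTEIN, 0.0) * succinate_solution.fluxes[rid]
        for rid, rxn in capped_model.reactions.items())
    assert produced == pytest.approx(0.0, abs=1e-6)  # production = dilution


# ---------------------------------------------------------------------------
# knockouts
# ---------------------------------------------------------------------------

def test_knockout_unknown_gene_raises(toy_model):
    with pytest.raises(ModelError):
        knockout(toy_model, "no_such_gene")


def test_triple_nitrogenase_knockout_abolishes_diazotrophic_growth(capped_model):
    gs = capped_model.annotations["nitrogenase_gene_sets"]
    mutant = knockout(capped_model, gs["Mo"] + gs["V"] + gs["Fe"])
    sol = solver.max_growth(mutant, {"succinate": 4.0}, tol=1e-3)
    assert sol.mu <= 2e-3  # N2 is the sole nitrogen source


def test_mo_only_mutant_still_grows(capped_model):
    gs = capped_model.annotations["nitrogenase_gene_sets"]
    mo_only = knockout(capped_model, gs["V"] + gs["Fe"])
    assert solver.max_growth(mo_only, {"succinate": 4.0}, tol=1e-3).mu > 0.3


def test_filler_isozyme_knockout_leaves_growth_unchanged(capped_model):
    mu_wt = solver.max_growth(capped_model, {"succinate": 4.0}, tol=1e-3).mu
    mutant = knockout(capped_model, "gf1a")  # gf1b backs the same reaction
    mu_ko = solver.max_growth(mutant, {"succinate": 4.0}, tol=1e-3).mu
    assert mu_ko == pytest.approx(mu_wt, abs=2e-3)
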