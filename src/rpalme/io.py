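"""Readers, writers and run configuration.

The canonical on-disk form is a documented JSON dialect (COBRA-style field
names where they exist) because the expression layer has no standard SBML
home; writing is canonical (sorted keys, fixed indentation) so that equal
models serialize to identical bytes.  A lossy SBML Level 3 export of the
metabolic subset is provided for interoperability with standard
constraint-based tooling.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, ConfigDict

from .model import (CouplingParameters, EnzymeSpec, ExtraConstraint, Gene,
                    MEModel, Metabolite, ModelError, Reaction)

__all__ = [
    "FORMAT_VERSION",
    "SchemaError",
    "RunConfig",
    "load_run_config",
    "model_to_dict",
    "model_from_dict",
    "write_model",
    "read_model",
    "model_digest",
    "export_sbml",
    "import_sbml_stoichiometry",
    "write_fluxes_tsv",
    "write_table_tsv",
    "parse_formula",
]

FORMAT_VERSION = "1.0.0"


class SchemaError(ModelError):
    """Document violates the model schema."""


# ---------------------------------------------------------------------------
# JSON model dialect
# ---------------------------------------------------------------------------

def model_to_dict(model: MEModel) -> dict:
    return {
        "format_version": FORMAT_VERSION,
        "id": model.id,
        "metabolites": [asdict(x) for x in model.metabolites.values()],
        "reactions": [asdict(x) for x in model.reactions.values()],
        "genes": [asdict(x) for x in model.genes.values()],
        "enzymes": [asdict(x) for x in model.enzymes.values()],
        "coupling": asdict(model.coupling),
        "biomass_dilution_id": model.biomass_dilution_id,
        "extra_constraints": [asdict(x) for x in model.extra_constraints],
        "annotations": model.annotations,
    }


def _require(doc: dict, key: str) -> object:
    if key not in doc:
        raise SchemaError(f"document is missing required section {key!r}")
    return doc[key]


def model_from_dict(doc: dict) -> MEModel:
    if not isinstance(doc, dict):
        raise SchemaError("model document must be a JSON object")
    version = str(_require(doc, "format_version"))
    if version.split(".")[0] != FORMAT_VERSION.split(".")[0]:
        raise SchemaError(f"unsupported format version {version}")
    model = MEModel(id=doc.get("id", "me_model"),
                    coupling=CouplingParameters(**_require(doc, "coupling")),
                    biomass_dilution_id=doc.get("biomass_dilution_id"),
                    annotations=doc.get("annotations", {}))
    try:
        for x in _require(doc, "metabolites"):
            model.add_metabolite(Metabolite(**x))
        for x in _require(doc, "genes"):
            model.add_gene(Gene(**x))
        for x in _require(doc, "enzymes"):
            model.add_enzyme(EnzymeSpec(**x))
        for x in _require(doc, "reactions"):
            model.add_reaction(Reaction(**x))
    except (TypeError, ModelError) as exc:
        raise SchemaError(f"invalid model document: {exc}") from exc
    for x in doc.get("extra_constraints", []):
        model.extra_constraints.append(ExtraConstraint(**x))
    dilutions = [r.id for r in model.reactions.values()
                 if r.rclass == "biomass-dilution"]
    if len(dilutions) != 1 or model.biomass_dilution_id != dilutions[0]:
        raise SchemaError(
            "document must declare exactly one biomass-dilution reaction "
            f"matching biomass_dilution_id (found {dilutions})")
    for rxn in model.reactions.values():
        for sid in rxn.mu_coupled_terms:
            if sid not in model.metabolites:
                raise SchemaError(f"{rxn.id}: dangling usage species {sid!r}")
    return model


def _canonical_bytes(doc: dict) -> bytes:
    return (json.dumps(doc, indent=1, sort_keys=True) + "\n").encode()


def write_model(model: MEModel, path: str | Path) -> Path:
    path = Path(path)
    path.write_bytes(_canonical_bytes(model_to_dict(model)))
    return path


def read_model(path: str | Path) -> MEModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON (line {exc.lineno}): {exc.msg}") from exc
    return model_from_dict(doc)


def model_digest(model: MEModel) -> str:
    """Stable sha256 of the canonical serialization (logged per run)."""
    return hashlib.sha256(_canonical_bytes(model_to_dict(model))).hexdigest()


# ---------------------------------------------------------------------------
# SBML export (metabolic subset; expression layer flattened out -- lossy)
# ---------------------------------------------------------------------------

_SBML_CLASSES = ("metabolic", "exchange")


def _sid(raw: str) -> str:
    s = re.sub(r"[^A-Za-z0-9_]", "_", raw)
    return s if re.match(r"[A-Za-z_]", s) else "_" + s


def export_sbml(model: MEModel, path: str | Path) -> Path:
    """Write the metabolic + exchange subset as SBML Level 3.

    The expression layer (transcription/translation/complex formation,
    usage coupling, biomass bookkeeping) has no SBML representation and is
    flattened out; the export is flagged lossy in the model notes.
    """
    import libsbml

    doc = libsbml.SBMLDocument(3, 2)
    sbml = doc.createModel()
    sbml.setId(_sid(model.id))
    sbml.setNotes(
        "<body xmlns='http://www.w3.org/1999/xhtml'><p>Lossy export: "
        "metabolic and exchange reactions only; the growth-coupled "
        "expression layer is not representable in SBML core.</p></body>")
    for comp_id in ("c", "e"):
        comp = sbml.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)
        comp.setSize(1.0)
        comp.setSpatialDimensions(3)

    keep = [r for r in model.reactions.values() if r.rclass in _SBML_CLASSES]
    species_ids = sorted({s for r in keep for s in r.stoichiometry})
    for sid in species_ids:
        met = model.metabolites[sid]
        sp = sbml.createSpecies()
        sp.setId(_sid(sid))
        sp.setName(met.name or sid)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(True)
        sp.setInitialAmount(0.0)
    for rxn in keep:
        rr = sbml.createReaction()
        rr.setId(_sid(rxn.id))
        rr.setReversible(rxn.lower_bound < 0)
        for sid, coef in sorted(rxn.stoichiometry.items()):
            ref = rr.createReactant() if coef < 0 else rr.createProduct()
            ref.setSpecies(_sid(sid))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
    path = Path(path)
    libsbml.writeSBMLToFile(doc, str(path))
    return path


def import_sbml_stoichiometry(path: str | Path) -> dict[str, dict[str, float]]:
    """Read an SBML file back into a reaction -> species -> coefficient map
    (used to verify the export reproduces the stoichiometry exactly)."""
    import libsbml

    doc = libsbml.readSBML(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise SchemaError(f"{path}: SBML read errors")
    sbml = doc.getModel()
    out: dict[str, dict[str, float]] = {}
    for i in range(sbml.getNumReactions()):
        rxn = sbml.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        out[rxn.getId()] = stoich
    return out


# ---------------------------------------------------------------------------
# Run configuration and tables
# ---------------------------------------------------------------------------

class RunConfig(BaseModel):
    """Schema-validated run configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    substrate: str = "succinate"
    uptake_grid: list[float] = [0.5, 1.0, 2.0, 4.0, 8.0, 16.0]
    mu_tol: float = 1e-4
    kcat_overrides: dict[str, float] = {}
    apply_atp_cap: bool = True
    apply_rubisco_coexpression: bool = False
    region_alpha: float = 0.9
    region_beta: float = 0.05
    seed: int = 0
    outdir: str = "results"


def load_run_config(path: str | Path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def write_fluxes_tsv(model: MEModel, fluxes: dict[str, float],
                     path: str | Path) -> Path:
    rows = [{"reaction_id": rid,
             "flux": fluxes.get(rid, 0.0),
             "lower_bound": rxn.lower_bound,
             "upper_bound": rxn.upper_bound,
             "class": rxn.rclass}
            for rid, rxn in model.reactions.items()]
    return write_table_tsv(pd.DataFrame(rows), path)


def write_table_tsv(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return path


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def parse_formula(text: str) -> dict[str, float]:
    """Parse a Hill-style formula string like ``C4H6O4`` into counts."""
    pos = 0
    counts: dict[str, float] = {}
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ModelError(f"cannot parse formula {text!r}")
        el, num = match.groups()
        counts[el] = counts.get(el, 0.0) + (float(num) if num else 1.0)
        pos = match.end()
    if pos != len(text) or not counts:
        raise ModelError(f"cannot parse formula {text!r}")
    return counts
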