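"""Model I/O: native TSV dialect, SBML Level 3, JSON evidence tables.

TSV dialect: a ``# metabolites`` section (id, name, compartment,
carbon_count) followed by a ``# reactions`` section with one reaction per
line: ``id<TAB>equation<TAB>reversible<TAB>subsystem<TAB>genes<TAB>confidence``;
equation syntax ``a A + b B -> c C`` with rational coefficients
(``3/2``-style).  Round-tripping is lossless for stoichiometry,
reversibility, subsystem, genes and confidence.
"""

from __future__ import annotations

import json
import logging
import warnings
from fractions import Fraction
from pathlib import Path

from .model import (Metabolite, ModelError, Reaction, StoichiometricModel,
                    parse_equation)

log = logging.getLogger("methyloflux")


class FormatError(ModelError):
    """Parse failure, with file/line context."""


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def write_tsv(model: StoichiometricModel, path):
    lines = ["# methyloflux model TSV", "# metabolites"]
    for m in model.metabolites.values():
        lines.append(f"{m.id}\t{m.name}\t{m.compartment}\t{m.carbon_count}")
    lines.append("# reactions")
    for r in model.reactions.values():
        lines.append("\t".join([
            r.id, r.equation(), "1" if r.reversible else "0", r.subsystem,
            ",".join(r.genes), str(r.confidence)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_tsv(path) -> StoichiometricModel:
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    section = None
    for ln, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            tag = line.lstrip("# ").lower()
            if tag.startswith("metabolite"):
                section = "met"
            elif tag.startswith("reaction"):
                section = "rxn"
            continue
        parts = raw.split("\t")
        try:
            if section == "met":
                mid, name, comp, ncarb = parts[:4]
                mets.append(Metabolite(mid, name, comp, int(ncarb)))
            elif section == "rxn":
                rid, eq, rev, sub = parts[:4]
                genes = parts[4].split(",") if len(parts) > 4 and parts[4] else []
                conf = int(parts[5]) if len(parts) > 5 else 2
                stoich, arrow_rev = parse_equation(eq)
                rxns.append(Reaction(rid, stoich, rev == "1" or arrow_rev,
                                     sub, genes, conf))
            else:
                raise ModelError("data before a section header")
        except (ValueError, IndexError, ModelError) as exc:
            raise FormatError(f"{path}:{ln}: {exc} in line {raw!r}") from exc
    return StoichiometricModel(mets, rxns)


# ---------------------------------------------------------------------------
# SBML Level 3
# ---------------------------------------------------------------------------

def write_sbml(model: StoichiometricModel, path):
    import libsbml
    doc = libsbml.SBMLDocument(3, 2)
    sm = doc.createModel("methyloflux_core")
    for comp in ("cytoplasm", "periplasm", "extracellular"):
        c = sm.createCompartment()
        c.setId(comp)
        c.setConstant(True)
    for m in model.metabolites.values():
        s = sm.createSpecies()
        s.setId(m.id)
        s.setName(m.name)
        s.setCompartment(m.compartment)
        s.setConstant(False)
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setNotes(f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                   f"<p>carbon_count: {m.carbon_count}</p></body>")
    for r in model.reactions.values():
        rx = sm.createReaction()
        rx.setId(r.id)
        rx.setName(r.name or r.id)
        rx.setReversible(r.reversible)
        notes = [f"<p>subsystem: {r.subsystem}</p>",
                 f"<p>confidence: {r.confidence}</p>"]
        if r.genes:
            notes.append(f"<p>genes: {' '.join(r.genes)}</p>")
        # exact rational stoichiometry (doubles are lossy)
        rat = " ".join(f"{m}={c}" for m, c in sorted(r.stoichiometry.items()))
        notes.append(f"<p>rational: {rat}</p>")
        rx.setNotes("<body xmlns='http://www.w3.org/1999/xhtml'>"
                    + "".join(notes) + "</body>")
        for met, coeff in sorted(r.stoichiometry.items()):
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies(met)
            ref.setStoichiometry(float(abs(coeff)))
            ref.setConstant(True)
    libsbml.writeSBMLToFile(doc, str(path))


def _note_fields(notes: str) -> dict[str, str]:
    import re
    return dict(re.findall(r"<p>\s*(\w+):\s*(.*?)\s*</p>", notes or ""))


def read_sbml(path) -> StoichiometricModel:
    import libsbml
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        err = doc.getError(0)
        raise FormatError(f"{path}: SBML parse error at line "
                          f"{err.getLine()}: {err.getMessage()}")
    sm = doc.getModel()
    if sm is None:
        raise FormatError(f"{path}: no model element")
    mets = []
    for i in range(sm.getNumSpecies()):
        s = sm.getSpecies(i)
        fields = _note_fields(s.getNotesString())
        mets.append(Metabolite(s.getId(), s.getName() or s.getId(),
                               s.getCompartment() or "cytoplasm",
                               int(fields.get("carbon_count", 0))))
    rxns = []
    for i in range(sm.getNumReactions()):
        rx = sm.getReaction(i)
        stoich: dict[str, Fraction] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            c = Fraction(ref.getStoichiometry()).limit_denominator(10**9)
            if c == 0:
                raise FormatError(f"{path}: zero-coefficient species "
                                  f"{ref.getSpecies()} in {rx.getId()}")
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), Fraction(0)) - c
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            c = Fraction(ref.getStoichiometry()).limit_denominator(10**9)
            if c == 0:
                raise FormatError(f"{path}: zero-coefficient species "
                                  f"{ref.getSpecies()} in {rx.getId()}")
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), Fraction(0)) + c
        if rx.isSetReversible():
            rev = rx.getReversible()
        else:
            rev = False
            warnings.warn(f"{rx.getId()}: reversibility flag missing; "
                          "defaulting to irreversible")
            log.warning("%s: reversibility flag missing; default irreversible",
                        rx.getId())
        fields = _note_fields(rx.getNotesString())
        if "rational" in fields:
            stoich = {tok.split("=")[0]: Fraction(tok.split("=")[1])
                      for tok in fields["rational"].split()}
        rxns.append(Reaction(
            rx.getId(), stoich, rev, fields.get("subsystem", "transport"),
            fields.get("genes", "").split() if fields.get("genes") else [],
            int(fields.get("confidence", 2)), rx.getName() or ""))
    return StoichiometricModel(mets, rxns)


# ---------------------------------------------------------------------------
# dispatch + JSON helpers
# ---------------------------------------------------------------------------

def write_model(model: StoichiometricModel, path):
    path = Path(path)
    if path.suffix in (".xml", ".sbml"):
        write_sbml(model, path)
    else:
        write_tsv(model, path)


def read_model(path) -> StoichiometricModel:
    path = Path(path)
    if path.suffix in (".xml", ".sbml"):
        return read_sbml(path)
    return read_tsv(path)


def write_json(obj, path):
    Path(path).write_text(json.dumps(obj, indent=1, default=str) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
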