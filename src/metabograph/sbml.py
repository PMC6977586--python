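"""Strict-subset SBML Level 2 Version 4 import.

Reads only compartments, species, reactions, reversibility, and
species-reference stoichiometry.  Kinetic laws, rules, events, units, and
annotations other than identifier URIs are ignored with a logged notice.
Species marked ``boundaryCondition`` keep their compartment; boundary
handling is the caller's concern via the artifact filter.
"""

from __future__ import annotations

import logging
import os

import libsbml

from .model import (
    Compartment,
    MetabolicModel,
    Metabolite,
    ModelParseError,
    Participant,
    Reaction,
)

logger = logging.getLogger(__name__)

# MIRIAM-style URI fragments -> our reference namespaces
_URI_NAMESPACES = {
    "hmdb": "hmdb",
    "pubchem": "pubchem",
    "metanetx": "metanetx",
    "chebi": "chebi",
    "kegg": "kegg",
    "ec-code": "enzyme",
}


def _references_from_annotation(element) -> dict[str, list[str]]:
    references: dict[str, list[str]] = {}
    for i in range(element.getNumCVTerms()):
        term = element.getCVTerm(i)
        for j in range(term.getNumResources()):
            uri = term.getResourceURI(j)
            for fragment, namespace in _URI_NAMESPACES.items():
                if fragment in uri.lower():
                    value = uri.rstrip("/").rsplit("/", 1)[-1]
                    references.setdefault(namespace, [])
                    if value not in references[namespace]:
                        references[namespace].append(value)
    return references


def read_sbml_subset(path) -> MetabolicModel:
    """Parse an SBML file, reading the documented structural subset only."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    document = libsbml.readSBML(str(path))
    if document.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        error = document.getError(0)
        raise ModelParseError(
            f"{path}: line {error.getLine()}: {error.getMessage().strip()}"
        )
    sbml_model = document.getModel()
    if sbml_model is None:
        raise ModelParseError(f"{path}: no <model> element")

    ignored = []
    if sbml_model.getNumRules():
        ignored.append("rules")
    if sbml_model.getNumEvents():
        ignored.append("events")
    if any(
        sbml_model.getReaction(i).isSetKineticLaw()
        for i in range(sbml_model.getNumReactions())
    ):
        ignored.append("kinetic laws")
    if ignored:
        logger.info("SBML subset reader ignoring: %s", ", ".join(ignored))

    model = MetabolicModel()
    for i in range(sbml_model.getNumCompartments()):
        comp = sbml_model.getCompartment(i)
        model.compartments[comp.getId()] = Compartment(
            comp.getId(), comp.getName() or comp.getId()
        )

    species_compartment: dict[str, str] = {}
    for i in range(sbml_model.getNumSpecies()):
        species = sbml_model.getSpecies(i)
        identifier = species.getId()
        species_compartment[identifier] = species.getCompartment()
        model.metabolites[identifier] = Metabolite(
            identifier=identifier,
            name=species.getName() or identifier,
            charge=species.getCharge() if species.isSetCharge() else 0,
            references=_references_from_annotation(species),
        )

    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        participants = []
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            participants.append(
                Participant(
                    metabolite=ref.getSpecies(),
                    role="reactant",
                    compartment=species_compartment.get(ref.getSpecies(), ""),
                    stoichiometry=ref.getStoichiometry() or 1.0,
                )
            )
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            participants.append(
                Participant(
                    metabolite=ref.getSpecies(),
                    role="product",
                    compartment=species_compartment.get(ref.getSpecies(), ""),
                    stoichiometry=ref.getStoichiometry() or 1.0,
                )
            )
        model.reactions[rxn.getId()] = Reaction(
            identifier=rxn.getId(),
            name=rxn.getName() or rxn.getId(),
            reversible=rxn.getReversible(),
            participants=participants,
            references=_references_from_annotation(rxn),
        )
    model.validate()
    return model
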