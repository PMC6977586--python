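"""Metabolic model representation, serialization, and curation filters.

A :class:`MetabolicModel` summarizes the chemical reactions of an organism:
metabolites with chemical attributes and cross-references to external
databases (HMDB, PubChem, MetaNetX, ChEBI, KEGG), reactions with reactant and
product participants in subcellular compartments, membership in metabolic
processes (pathways), and references to genes and enzymes.

Two file formats are supported:

* ``native`` — a documented JSON serialization mirroring the data model
  one-to-one (UTF-8, sorted keys, stable across round-trips).
* ``sbml_subset`` — a strict subset of SBML Level 2 Version 4 read through
  libsbml: compartments, species, reactions, reversibility, and
  species-reference stoichiometry.  Kinetic laws, rules, events, and
  annotations other than identifier URIs are ignored with a logged notice.

Curation here is generic machinery: classify each reaction as chemical
conversion and/or compartmental transport, strip reactions that only serve
flux simulations (boundary exchange, biomass accumulation, protein
assembly/degradation), propagate process membership onto transport reactions,
and summarize counts and reference coverage.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

REFERENCE_NAMESPACES = ("hmdb", "pubchem", "metanetx", "chebi", "kegg", "enzyme")

#: Reference classes whose union defines "identifiable" coverage in summaries.
METABOLITE_COVERAGE = ("hmdb", "pubchem")


class ModelValidationError(ValueError):
    """Raised when a model violates referential integrity."""


class ModelParseError(ValueError):
    """Raised when a model file cannot be parsed."""


@dataclass
class Compartment:
    identifier: str
    name: str = ""


@dataclass
class Process:
    identifier: str
    name: str = ""


@dataclass
class Metabolite:
    """A small molecule with chemical attributes and database references."""

    identifier: str
    name: str = ""
    formula: str = ""
    charge: int = 0
    references: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ModelValidationError("metabolite identifier must be non-empty")
        # reference lists must be duplicate-free; order is preserved
        for namespace, values in self.references.items():
            seen: list[str] = []
            for value in values:
                if value not in seen:
                    seen.append(value)
            self.references[namespace] = seen


@dataclass
class Participant:
    """One metabolite's role in a reaction, within one compartment."""

    metabolite: str
    role: str  # "reactant" | "product"
    compartment: str
    stoichiometry: float = 1.0

    def __post_init__(self) -> None:
        if self.role not in ("reactant", "product"):
            raise ModelValidationError(f"invalid participant role {self.role!r}")
        if not self.stoichiometry > 0:
            raise ModelValidationError("stoichiometry must be positive")


@dataclass
class Reaction:
    """A chemical event converting and/or transporting metabolites."""

    identifier: str
    name: str = ""
    reversible: bool = False
    participants: list[Participant] = field(default_factory=list)
    processes: list[str] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    references: dict[str, list[str]] = field(default_factory=dict)
    behavior: str = "unset"  # conversion | transport | both | unset

    def reactants(self) -> list[Participant]:
        return [p for p in self.participants if p.role == "reactant"]

    def products(self) -> list[Participant]:
        return [p for p in self.participants if p.role == "product"]

    def compartments(self) -> set[str]:
        return {p.compartment for p in self.participants}


@dataclass
class MetabolicModel:
    """Keyed collections of metabolites, reactions, compartments, processes."""

    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    compartments: dict[str, Compartment] = field(default_factory=dict)
    processes: dict[str, Process] = field(default_factory=dict)
    boundary_compartment: str | None = None
    extracellular_compartment: str | None = None

    def validate(self) -> None:
        """Check referential integrity; raise listing all offenders."""
        dangling: list[str] = []
        for reaction in self.reactions.values():
            if not reaction.reactants() or not reaction.products():
                dangling.append(
                    f"reaction {reaction.identifier}: needs >=1 reactant and >=1 product"
                )
            for part in reaction.participants:
                if part.metabolite not in self.metabolites:
                    dangling.append(
                        f"reaction {reaction.identifier}: unknown metabolite {part.metabolite}"
                    )
                if part.compartment not in self.compartments:
                    dangling.append(
                        f"reaction {reaction.identifier}: unknown compartment {part.compartment}"
                    )
            for process in reaction.processes:
                if process not in self.processes:
                    dangling.append(
                        f"reaction {reaction.identifier}: unknown process {process}"
                    )
        if dangling:
            raise ModelValidationError(
                "model failed validation:\n" + "\n".join(dangling)
            )

    def copy(self) -> "MetabolicModel":
        return model_from_dict(model_to_dict(self))


# ---------------------------------------------------------------------------
# Native JSON serialization


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "compartments": [
            {"identifier": c.identifier, "name": c.name}
            for c in sorted(model.compartments.values(), key=lambda c: c.identifier)
        ],
        "processes": [
            {"identifier": p.identifier, "name": p.name}
            for p in sorted(model.processes.values(), key=lambda p: p.identifier)
        ],
        "metabolites": [
            {
                "identifier": m.identifier,
                "name": m.name,
                "formula": m.formula,
                "charge": m.charge,
                "references": {k: list(v) for k, v in sorted(m.references.items())},
            }
            for m in sorted(model.metabolites.values(), key=lambda m: m.identifier)
        ],
        "reactions": [
            {
                "identifier": r.identifier,
                "name": r.name,
                "reversible": r.reversible,
                "participants": [
                    {
                        "metabolite": p.metabolite,
                        "role": p.role,
                        "compartment": p.compartment,
                        "stoichiometry": p.stoichiometry,
                    }
                    for p in r.participants
                ],
                "processes": list(r.processes),
                "genes": list(r.genes),
                "references": {k: list(v) for k, v in sorted(r.references.items())},
                "behavior": r.behavior,
            }
            for r in sorted(model.reactions.values(), key=lambda r: r.identifier)
        ],
        "boundary_compartment": model.boundary_compartment,
        "extracellular_compartment": model.extracellular_compartment,
    }


def model_from_dict(data: dict) -> MetabolicModel:
    model = MetabolicModel(
        boundary_compartment=data.get("boundary_compartment"),
        extracellular_compartment=data.get("extracellular_compartment"),
    )
    for entry in data.get("compartments", []):
        comp = Compartment(entry["identifier"], entry.get("name", ""))
        if comp.identifier in model.compartments:
            raise ModelValidationError(f"duplicate compartment {comp.identifier}")
        model.compartments[comp.identifier] = comp
    for entry in data.get("processes", []):
        proc = Process(entry["identifier"], entry.get("name", ""))
        if proc.identifier in model.processes:
            raise ModelValidationError(f"duplicate process {proc.identifier}")
        model.processes[proc.identifier] = proc
    for entry in data.get("metabolites", []):
        met = Metabolite(
            identifier=entry["identifier"],
            name=entry.get("name", ""),
            formula=entry.get("formula", ""),
            charge=int(entry.get("charge", 0)),
            references={k: list(v) for k, v in entry.get("references", {}).items()},
        )
        if met.identifier in model.metabolites:
            raise ModelValidationError(f"duplicate metabolite {met.identifier}")
        model.metabolites[met.identifier] = met
    for entry in data.get("reactions", []):
        reaction = Reaction(
            identifier=entry["identifier"],
            name=entry.get("name", ""),
            reversible=bool(entry.get("reversible", False)),
            participants=[
                Participant(
                    metabolite=p["metabolite"],
                    role=p["role"],
                    compartment=p["compartment"],
                    stoichiometry=float(p.get("stoichiometry", 1.0)),
                )
                for p in entry.get("participants", [])
            ],
            processes=list(entry.get("processes", [])),
            genes=list(entry.get("genes", [])),
            references={k: list(v) for k, v in entry.get("references", {}).items()},
            behavior=entry.get("behavior", "unset"),
        )
        if reaction.identifier in model.reactions:
            raise ModelValidationError(f"duplicate reaction {reaction.identifier}")
        model.reactions[reaction.identifier] = reaction
    model.validate()
    return model


def read_model(path, format: str = "native") -> MetabolicModel:
    """Read a metabolic model from ``native`` JSON or an SBML L2V4 subset."""
    if format == "native":
        try:
            with open(path, encoding="utf-8") as handle:
                data = json.load(handle)
        except json.JSONDecodeError as exc:
            raise ModelParseError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
        return model_from_dict(data)
    if format == "sbml_subset":
        from .sbml import read_sbml_subset

        return read_sbml_subset(path)
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: MetabolicModel, path) -> None:
    """Serialize to the native JSON format; ``read_model`` inverts this."""
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(model_to_dict(model), handle, ensure_ascii=False, indent=1,
                  sort_keys=True)
        handle.write("\n")


# ---------------------------------------------------------------------------
# Curation operations


def classify_reaction_behavior(reaction: Reaction, model: MetabolicModel) -> str:
    """Classify a reaction as ``conversion``, ``transport``, or ``both``.

    Transport: some metabolite appears among reactants in one compartment and
    among products in a different compartment (no net chemical change for that
    metabolite — identity is compared on consensus identifiers).  Conversion:
    the stoichiometry-weighted multiset of reactant metabolite identities
    differs from the product multiset.  Both conditions can hold at once.
    """
    reactant_comps: dict[str, set[str]] = {}
    product_comps: dict[str, set[str]] = {}
    reactant_counts: Counter = Counter()
    product_counts: Counter = Counter()
    for part in reaction.participants:
        if part.role == "reactant":
            reactant_comps.setdefault(part.metabolite, set()).add(part.compartment)
            reactant_counts[part.metabolite] += part.stoichiometry
        else:
            product_comps.setdefault(part.metabolite, set()).add(part.compartment)
            product_counts[part.metabolite] += part.stoichiometry
    transport = any(
        met in product_comps and product_comps[met] - comps
        for met, comps in reactant_comps.items()
    )
    conversion = reactant_counts != product_counts
    if transport and conversion:
        return "both"
    if transport:
        return "transport"
    return "conversion"


def classify_all(model: MetabolicModel) -> MetabolicModel:
    """Return a copy with every reaction's ``behavior`` field set."""
    out = model.copy()
    for reaction in out.reactions.values():
        reaction.behavior = classify_reaction_behavior(reaction, out)
    return out


@dataclass
class ArtifactFilterConfig:
    """Which simulation-only reactions to strip from a model.

    ``boundary_compartments`` are compartments that only exist to exchange
    mass with the outside of the system; any reaction with a participant
    there is an exchange artifact.  ``name_patterns`` are case-insensitive
    regular expressions matched against reaction names and identifiers to
    catch biomass accumulation and protein assembly/degradation reactions.
    """

    boundary_compartments: list[str] = field(default_factory=list)
    name_patterns: list[str] = field(default_factory=list)


def filter_simulation_artifacts(
    model: MetabolicModel, config: ArtifactFilterConfig
) -> MetabolicModel:
    """Remove flux-simulation reactions, then orphaned metabolites.

    The input model is left unmodified.  Patterns that match nothing produce
    a logged warning, not an error.  The operation is idempotent.
    """
    out = model.copy()
    patterns = [re.compile(p, re.IGNORECASE) for p in config.name_patterns]
    boundary = set(config.boundary_compartments)
    if model.boundary_compartment:
        boundary.add(model.boundary_compartment)

    matched_any = [False] * len(patterns)
    removed: list[str] = []
    for identifier, reaction in list(out.reactions.items()):
        drop = any(p.compartment in boundary for p in reaction.participants)
        for index, pattern in enumerate(patterns):
            if pattern.search(reaction.name) or pattern.search(reaction.identifier):
                matched_any[index] = True
                drop = True
        if drop:
            removed.append(identifier)
            del out.reactions[identifier]
    for index, hit in enumerate(matched_any):
        if patterns and not hit:
            logger.warning(
                "artifact filter pattern %r matched no reaction",
                config.name_patterns[index],
            )
    if removed:
        logger.info("removed %d simulation-artifact reactions", len(removed))

    in_use = {
        part.metabolite
        for reaction in out.reactions.values()
        for part in reaction.participants
    }
    for identifier in list(out.metabolites):
        if identifier not in in_use:
            del out.metabolites[identifier]
    return out


def assign_transport_processes(model: MetabolicModel) -> MetabolicModel:
    """Give transport reactions membership in the processes they bridge.

    A transport reaction joins every process that (a) has member reactions in
    two or more compartments and (b) shares at least one metabolite and one
    compartment with the transport reaction.  Requires behaviors classified.
    """
    out = model.copy()
    process_compartments: dict[str, set[str]] = {}
    process_metabolites: dict[str, set[str]] = {}
    for reaction in out.reactions.values():
        for process in reaction.processes:
            process_compartments.setdefault(process, set()).update(
                reaction.compartments()
            )
            process_metabolites.setdefault(process, set()).update(
                p.metabolite for p in reaction.participants
            )
    spanning = {
        proc for proc, comps in process_compartments.items() if len(comps) >= 2
    }
    for reaction in out.reactions.values():
        if reaction.behavior not in ("transport", "both"):
            continue
        mets = {p.metabolite for p in reaction.participants}
        comps = reaction.compartments()
        for process in sorted(spanning):
            if process in reaction.processes:
                continue
            if mets & process_metabolites[process] and comps & process_compartments[process]:
                reaction.processes.append(process)
    return out


@dataclass
class CurationSummary:
    """Counts and reference-coverage percentages of a curated model."""

    n_metabolites: int
    n_reactions: int
    n_compartments: int
    n_processes: int
    metabolite_coverage_percent: float  # HMDB-or-PubChem reference
    reaction_coverage_percent: float  # gene-or-enzyme reference
    empty: bool = False

    def to_tsv(self) -> str:
        header = "entity\tcount\treference_class\tcovered\tpercent"
        met_covered = round(self.n_metabolites * self.metabolite_coverage_percent / 100)
        rxn_covered = round(self.n_reactions * self.reaction_coverage_percent / 100)
        rows = [
            header,
            f"metabolite\t{self.n_metabolites}\thmdb_or_pubchem\t{met_covered}\t"
            f"{self.metabolite_coverage_percent:.2f}",
            f"reaction\t{self.n_reactions}\tgene_or_enzyme\t{rxn_covered}\t"
            f"{self.reaction_coverage_percent:.2f}",
            f"compartment\t{self.n_compartments}\t\t\t",
            f"process\t{self.n_processes}\t\t\t",
        ]
        return "\n".join(rows) + "\n"


def coverage_percent(covered: int, total: int) -> float:
    """Percentage of entities with the named reference class, 2 decimals."""
    if total == 0:
        return 0.0
    return round(100.0 * covered / total, 2)


def summarize_curation(model: MetabolicModel) -> CurationSummary:
    """Count entities and reference coverage (HMDB/PubChem, gene/enzyme)."""
    met_covered = sum(
        1
        for met in model.metabolites.values()
        if any(met.references.get(ns) for ns in METABOLITE_COVERAGE)
    )
    rxn_covered = sum(
        1
        for rxn in model.reactions.values()
        if rxn.genes or rxn.references.get("enzyme")
    )
    empty = not model.metabolites and not model.reactions
    if empty:
        logger.warning("summarizing an empty model; percentages reported as 0")
    return CurationSummary(
        n_metabolites=len(model.metabolites),
        n_reactions=len(model.reactions),
        n_compartments=len(model.compartments),
        n_processes=len(model.processes),
        metabolite_coverage_percent=coverage_percent(
            met_covered, len(model.metabolites)
        ),
        reaction_coverage_percent=coverage_percent(rxn_covered, len(model.reactions)),
        empty=empty,
    )
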