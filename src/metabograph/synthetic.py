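"""Synthetic metabolic models and simulated measurement studies.

Everything downstream — network construction, metrics, measurement
integration, module search — is testable on the output of these generators,
so no external model or repository download is ever required.  Toy models
emulate the canonical motifs of metabolic graphs: linear and cyclical
pathways, duplicated compartmental instances joined by transport reactions,
and high-degree hub metabolites.  Measurement studies draw per-analyte
abundances from a log2-normal baseline with multiplicative group effects,
matching the log2 fold-change analysis downstream.

All generators are pure functions of their specification (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .measurements import MeasurementStudy
from .model import (
    Compartment,
    MetabolicModel,
    Metabolite,
    Participant,
    Process,
    Reaction,
    classify_all,
)


@dataclass
class ToySpec:
    """Parameters of a synthetic pathway-structured metabolic model."""

    n_pathways: int = 1
    pathway_length: int = 4
    cyclic: bool = True
    n_compartments: int = 1
    transport_pairs: int = 0
    hub_metabolites: list[tuple[str, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pathways, self.pathway_length, self.n_compartments) < 1:
            raise ValueError("counts must be >= 1")
        if self.transport_pairs and self.n_compartments < 2:
            raise ValueError("transport requires >= 2 compartments")


def generate_toy_model(spec: ToySpec) -> MetabolicModel:
    """Deterministic pathway model with optional compartments, transports, hubs."""
    rng = np.random.default_rng(spec.seed)
    model = MetabolicModel()
    compartments = [f"c{k + 1}" for k in range(spec.n_compartments)]
    for comp in compartments:
        model.compartments[comp] = Compartment(comp, f"compartment {comp}")

    pubchem_counter = 100
    metabolite_ids: list[str] = []
    for p in range(spec.n_pathways):
        process = f"proc{p + 1}"
        model.processes[process] = Process(process, f"pathway {p + 1}")
        members = [f"P{p + 1}M{i + 1}" for i in range(spec.pathway_length)]
        for met in members:
            pubchem_counter += 1
            model.metabolites[met] = Metabolite(
                met, name=met, references={"pubchem": [str(pubchem_counter)]}
            )
        metabolite_ids.extend(members)
        steps = spec.pathway_length if spec.cyclic else spec.pathway_length - 1
        for comp in compartments:
            for i in range(steps):
                source = members[i]
                target = members[(i + 1) % spec.pathway_length]
                identifier = f"P{p + 1}R{i + 1}{comp}"
                model.reactions[identifier] = Reaction(
                    identifier=identifier,
                    name=f"{source} to {target} ({comp})",
                    participants=[
                        Participant(source, "reactant", comp),
                        Participant(target, "product", comp),
                    ],
                    processes=[process],
                    genes=[f"gene_{identifier}"],
                )

    for t in range(spec.transport_pairs):
        met = metabolite_ids[int(rng.integers(len(metabolite_ids)))]
        source_comp, target_comp = compartments[t % (spec.n_compartments - 1)], (
            compartments[t % (spec.n_compartments - 1) + 1]
        )
        identifier = f"T{t + 1}"
        model.reactions[identifier] = Reaction(
            identifier=identifier,
            name=f"transport {met} {source_comp}->{target_comp}",
            participants=[
                Participant(met, "reactant", source_comp),
                Participant(met, "product", target_comp),
            ],
        )

    conversions = [
        r for r in model.reactions.values() if not r.identifier.startswith("T")
    ]
    for hub, degree in spec.hub_metabolites:
        if degree > len(conversions):
            raise ValueError(
                f"hub {hub}: degree {degree} infeasible with {len(conversions)} reactions"
            )
        pubchem_counter += 1
        model.metabolites[hub] = Metabolite(
            hub, name=hub, references={"pubchem": [str(pubchem_counter)]}
        )
        chosen = rng.choice(len(conversions), size=degree, replace=False)
        for index in sorted(int(i) for i in chosen):
            reaction = conversions[index]
            comp = reaction.participants[0].compartment
            reaction.participants.append(Participant(hub, "product", comp))

    model.validate()
    return classify_all(model)


# ---------------------------------------------------------------------------
# Named fixtures (hand-specified so tests can enumerate them exactly)


def toy4() -> MetabolicModel:
    """Four-metabolite irreversible cycle A->B->C->D->A in one compartment."""
    model = MetabolicModel()
    model.compartments["c"] = Compartment("c", "cytosol")
    model.processes["cycle"] = Process("cycle", "toy cycle")
    chain = ["A", "B", "C", "D"]
    for index, met in enumerate(chain):
        model.metabolites[met] = Metabolite(
            met, name=met, references={"pubchem": [str(101 + index)]}
        )
    for index in range(4):
        source, target = chain[index], chain[(index + 1) % 4]
        identifier = f"R{index + 1}"
        model.reactions[identifier] = Reaction(
            identifier=identifier,
            name=f"{source} to {target}",
            participants=[
                Participant(source, "reactant", "c"),
                Participant(target, "product", "c"),
            ],
            processes=["cycle"],
            genes=[f"gene_{identifier}"],
        )
    model.validate()
    return classify_all(model)


def toyhub() -> MetabolicModel:
    """TOY4 plus hub metabolite H as an extra product of all four reactions."""
    model = toy4()
    model.metabolites["H"] = Metabolite("H", name="H", references={"pubchem": ["199"]})
    for reaction in model.reactions.values():
        reaction.participants.append(Participant("H", "product", "c"))
    model.validate()
    return classify_all(model)


def toycomp() -> MetabolicModel:
    """TOY4 pathway duplicated in two compartments, joined by two transports."""
    model = MetabolicModel()
    for comp in ("c1", "c2"):
        model.compartments[comp] = Compartment(comp, f"compartment {comp}")
    model.processes["cycle"] = Process("cycle", "toy cycle")
    chain = ["A", "B", "C", "D"]
    for index, met in enumerate(chain):
        model.metabolites[met] = Metabolite(
            met, name=met, references={"pubchem": [str(101 + index)]}
        )
    for comp in ("c1", "c2"):
        for index in range(4):
            source, target = chain[index], chain[(index + 1) % 4]
            identifier = f"R{index + 1}{comp}"
            model.reactions[identifier] = Reaction(
                identifier=identifier,
                name=f"{source} to {target} ({comp})",
                participants=[
                    Participant(source, "reactant", comp),
                    Participant(target, "product", comp),
                ],
                processes=["cycle"],
                genes=[f"gene_R{index + 1}"],
            )
    for t, met in enumerate(("A", "C")):
        identifier = f"T{t + 1}"
        model.reactions[identifier] = Reaction(
            identifier=identifier,
            name=f"transport {met} c1->c2",
            participants=[
                Participant(met, "reactant", "c1"),
                Participant(met, "product", "c2"),
            ],
        )
    model.validate()
    return classify_all(model)


FIXTURES = {"toy4": toy4, "toyhub": toyhub, "toycomp": toycomp}


# ---------------------------------------------------------------------------
# Simulated measurement studies


@dataclass
class EffectSpec:
    """Group-difference design for a simulated measurement study.

    ``effects`` maps metabolite identifiers to log2 effect sizes applied to
    the case group.  ``sigma`` is per-measurement noise on the log2 scale;
    baselines are log2-normal with mean ``baseline_mu`` and spread
    ``baseline_sigma`` (also log2 scale).  Paired mode draws one shared
    baseline per (analyte, pair) so the pair difference isolates the effect.
    Defaults give a dependent-samples t-test at n = 10 pairs essentially
    full power for a 2-fold effect (effect / sd(pair ratio) = 1 / 0.354).
    """

    effects: dict[str, float] = field(default_factory=dict)
    n_per_group: int = 10
    paired: bool = False
    sigma: float = 0.25
    baseline_mu: float = 10.0
    baseline_sigma: float = 2.0
    pair_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need n >= 2 per group")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


def generate_measurements(model: MetabolicModel, effects: EffectSpec) -> MeasurementStudy:
    """One analyte per model metabolite; case group scaled by 2^effect.

    PubChem references are copied from the model so analyte matching
    succeeds downstream.  Deterministic given the spec's seed.
    """
    unknown = set(effects.effects) - set(model.metabolites)
    if unknown:
        raise ValueError(f"effects name unknown metabolites: {sorted(unknown)}")
    rng = np.random.default_rng(effects.seed)
    metabolites = sorted(model.metabolites)
    n = effects.n_per_group
    case_ids = [f"case{i + 1}" for i in range(n)]
    control_ids = [f"ctrl{i + 1}" for i in range(n)]
    sample_rows = [
        {
            "sample": case_ids[i],
            "group": "case",
            "pair": f"pair{i + 1}" if effects.paired else None,
        }
        for i in range(n)
    ] + [
        {
            "sample": control_ids[i],
            "group": "control",
            "pair": f"pair{i + 1}" if effects.paired else None,
        }
        for i in range(n)
    ]
    samples = pd.DataFrame(sample_rows).set_index("sample")

    analyte_rows = []
    matrix = np.zeros((len(metabolites), 2 * n))
    columns = case_ids + control_ids
    for row, met in enumerate(metabolites):
        baseline = rng.normal(effects.baseline_mu, effects.baseline_sigma)
        effect = effects.effects.get(met, 0.0)
        if effects.paired:
            pair_base = baseline + rng.normal(0.0, effects.pair_sigma, size=n)
            case_log = pair_base + effect + rng.normal(0.0, effects.sigma, size=n)
            control_log = pair_base + rng.normal(0.0, effects.sigma, size=n)
        else:
            case_log = baseline + effect + rng.normal(0.0, effects.sigma, size=n)
            control_log = baseline + rng.normal(0.0, effects.sigma, size=n)
        matrix[row, :n] = np.exp2(case_log)
        matrix[row, n:] = np.exp2(control_log)
        analyte_rows.append(
            {
                "analyte": f"a_{met}",
                "name": model.metabolites[met].name,
                "pubchem": list(model.metabolites[met].references.get("pubchem", [])),
            }
        )
    analytes = pd.DataFrame(analyte_rows).set_index("analyte")
    signals = pd.DataFrame(matrix, index=analytes.index, columns=columns)
    study = MeasurementStudy(samples, analytes, signals, paired=effects.paired)
    study.validate()
    return study
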