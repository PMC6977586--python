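"""Model representation, serialization, classification, and curation filters."""

import json

import pytest

import metabograph as mg
from metabograph.model import (
    ArtifactFilterConfig,
    Compartment,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Participant,
    Process,
    Reaction,
    coverage_percent,
    model_to_dict,
)

SBML_TOY = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
 <model id="toy" name="toy">
  <listOfCompartments>
   <compartment id="c" name="cytosol"/>
  </listOfCompartments>
  <listOfSpecies>
   <species id="A" name="alpha" compartment="c"/>
   <species id="B" name="beta" compartment="c"/>
  </listOfSpecies>
  <listOfReactions>
   <reaction id="R1" name="alpha to beta" reversible="false">
    <listOfReactants><speciesReference species="A" stoichiometry="1"/></listOfReactants>
    <listOfProducts><speciesReference species="B" stoichiometry="1"/></listOfProducts>
   </reaction>
  </listOfReactions>
 </model>
</sbml>
"""


def _two_compartment_model():
    model = MetabolicModel()
    for comp in ("c1", "c2"):
        model.compartments[comp] = Compartment(comp)
    for met in ("A", "B", "X"):
        model.metabolites[met] = Metabolite(met, name=met)
    return model


@pytest.mark.parametrize("fixture", ["toy4", "toyhub", "toycomp"])
def test_native_round_trip_is_identity(fixture, tmp_path):
    model = mg.synthetic.FIXTURES[fixture]()
    path = tmp_path / "model.json"
    mg.write_model(model, path)
    again = mg.read_model(path)
    assert model_to_dict(again) == model_to_dict(model)


def test_empty_model_round_trips(tmp_path):
    path = tmp_path / "empty.json"
    mg.write_model(MetabolicModel(), path)
    model = mg.read_model(path)
    assert not model.reactions and not model.metabolites


def test_unicode_names_serialize_stably(tmp_path):
    model = MetabolicModel()
    model.compartments["c"] = Compartment("c", "细胞质")
    model.metabolites["glc"] = Metabolite("glc", name="α-D-glucose")
    model.metabolites["pyr"] = Metabolite("pyr", name="pyruvate")
    model.reactions["r"] = Reaction(
        "r",
        name="glycolyse—résumé",
        participants=[
            Participant("glc", "reactant", "c"),
            Participant("pyr", "product", "c"),
        ],
    )
    first, second = tmp_path / "a.json", tmp_path / "b.json"
    mg.write_model(model, first)
    mg.write_model(mg.read_model(first), second)
    assert first.read_bytes() == second.read_bytes()


def test_parse_error_names_location(tmp_path):
    path = tmp_path / "broken.json"
    path.write_text('{"metabolites": [')
    with pytest.raises(mg.model.ModelParseError, match="line"):
        mg.read_model(path)


def test_dangling_reference_lists_offenders():
    model = MetabolicModel()
    model.compartments["c"] = Compartment("c")
    model.metabolites["A"] = Metabolite("A")
    model.metabolites["B"] = Metabolite("B")
    model.reactions["r"] = Reaction(
        "r",
        participants=[
            Participant("A", "reactant", "c"),
            Participant("ghost", "product", "c"),
        ],
    )
    with pytest.raises(ModelValidationError, match="ghost"):
        model.validate()


def test_sbml_subset_reads_species_and_reaction(tmp_path):
    path = tmp_path / "toy.xml"
    path.write_text(SBML_TOY)
    model = mg.read_model(path, format="sbml_subset")
    assert sorted(model.metabolites) == ["A", "B"]
    assert sorted(model.compartments) == ["c"]
    reaction = model.reactions["R1"]
    assert not reaction.reversible
    assert [(p.metabolite, p.role, p.compartment, p.stoichiometry)
            for p in reaction.participants] == [
        ("A", "reactant", "c", 1.0),
        ("B", "product", "c", 1.0),
    ]
    assert model.metabolites["A"].name == "alpha"


@pytest.mark.parametrize(
    "participants, expected",
    [
        # chemically unchanged metabolite crossing a membrane
        ([("X", "reactant", "c1"), ("X", "product", "c2")], "transport"),
        # single-compartment chemical change
        ([("A", "reactant", "c1"), ("B", "product", "c1")], "conversion"),
        # conversion and co-transport at once
        (
            [
                ("A", "reactant", "c1"),
                ("X", "reactant", "c1"),
                ("B", "product", "c1"),
                ("X", "product", "c2"),
            ],
            "both",
        ),
    ],
)
def test_classify_reaction_behavior(participants, expected):
    model = _two_compartment_model()
    reaction = Reaction(
        "r", participants=[Participant(m, role, c) for m, role, c in participants]
    )
    model.reactions["r"] = reaction
    assert mg.classify_reaction_behavior(reaction, model) == expected


def test_classification_invariant_under_participant_order():
    import itertools

    model = _two_compartment_model()
    parts = [
        Participant("A", "reactant", "c1"),
        Participant("X", "reactant", "c1"),
        Participant("B", "product", "c1"),
        Participant("X", "product", "c2"),
    ]
    results = set()
    for permutation in itertools.permutations(parts):
        reaction = Reaction("r", participants=list(permutation))
        results.add(mg.classify_reaction_behavior(reaction, model))
    assert results == {"both"}


def _exchange_model():
    model = MetabolicModel(boundary_compartment="b")
    model.compartments["b"] = Compartment("b", "boundary")
    model.compartments["c"] = Compartment("c", "cytosol")
    for met in ("A", "B"):
        model.metabolites[met] = Metabolite(met)
    model.reactions["EX_A"] = Reaction(
        "EX_A",
        name="A exchange",
        reversible=True,
        participants=[
            Participant("A", "reactant", "b"),
            Participant("A", "product", "c"),
        ],
    )
    model.reactions["CONV"] = Reaction(
        "CONV",
        participants=[
            Participant("A", "reactant", "c"),
            Participant("B", "product", "c"),
        ],
    )
    return model


def test_artifact_filter_removes_exchange_then_orphans():
    model = _exchange_model()
    filtered = mg.filter_simulation_artifacts(model, ArtifactFilterConfig())
    assert sorted(filtered.reactions) == ["CONV"]
    assert sorted(filtered.metabolites) == ["A", "B"]
    # original untouched
    assert sorted(model.reactions) == ["CONV", "EX_A"]


def test_artifact_filter_empty_config_is_identity(toy4_model):
    filtered = mg.filter_simulation_artifacts(toy4_model, ArtifactFilterConfig())
    assert model_to_dict(filtered) == model_to_dict(toy4_model)


def test_artifact_filter_annihilates_exchange_only_model():
    model = _exchange_model()
    del model.reactions["CONV"]
    filtered = mg.filter_simulation_artifacts(model, ArtifactFilterConfig())
    assert not filtered.reactions and not filtered.metabolites


def test_artifact_filter_idempotent():
    model = _exchange_model()
    config = ArtifactFilterConfig(name_patterns=["biomass"])
    once = mg.filter_simulation_artifacts(model, config)
    twice = mg.filter_simulation_artifacts(once, config)
    assert model_to_dict(once) == model_to_dict(twice)


def test_name_pattern_matches_biomass():
    model = _exchange_model()
    model.metabolites["bm"] = Metabolite("bm")
    model.reactions["GROW"] = Reaction(
        "GROW",
        name="biomass accumulation",
        participants=[
            Participant("A", "reactant", "c"),
            Participant("bm", "product", "c"),
        ],
    )
    filtered = mg.filter_simulation_artifacts(
        model, ArtifactFilterConfig(name_patterns=["biomass"])
    )
    assert "GROW" not in filtered.reactions
    assert "bm" not in filtered.metabolites


def test_transport_joins_spanning_process():
    model = _two_compartment_model()
    model.processes["P"] = Process("P")
    model.reactions["r1"] = Reaction(
        "r1",
        processes=["P"],
        participants=[
            Participant("X", "reactant", "c1"),
            Participant("A", "product", "c1"),
        ],
    )
    model.reactions["r2"] = Reaction(
        "r2",
        processes=["P"],
        participants=[
            Participant("B", "reactant", "c2"),
            Participant("X", "product", "c2"),
        ],
    )
    model.reactions["t"] = Reaction(
        "t",
        participants=[
            Participant("X", "reactant", "c1"),
            Participant("X", "product", "c2"),
        ],
    )
    model = mg.classify_all(model)
    out = mg.assign_transport_processes(model)
    assert out.reactions["t"].processes == ["P"]


def test_single_compartment_processes_get_no_transport():
    model = _two_compartment_model()
    model.processes["P"] = Process("P")
    model.reactions["r1"] = Reaction(
        "r1",
        processes=["P"],
        participants=[
            Participant("A", "reactant", "c1"),
            Participant("B", "product", "c1"),
        ],
    )
    model.reactions["t"] = Reaction(
        "t",
        participants=[
            Participant("X", "reactant", "c1"),
            Participant("X", "product", "c2"),
        ],
    )
    out = mg.assign_transport_processes(mg.classify_all(model))
    assert out.reactions["t"].processes == []


def test_transport_sharing_no_metabolite_not_assigned():
    model = _two_compartment_model()
    model.processes["P"] = Process("P")
    model.reactions["r1"] = Reaction(
        "r1",
        processes=["P"],
        participants=[
            Participant("A", "reactant", "c1"),
            Participant("B", "product", "c2"),
        ],
    )
    model.reactions["t"] = Reaction(
        "t",
        participants=[
            Participant("X", "reactant", "c1"),
            Participant("X", "product", "c2"),
        ],
    )
    out = mg.assign_transport_processes(mg.classify_all(model))
    assert out.reactions["t"].processes == []


def test_curation_summary_counts_and_coverage():
    model = MetabolicModel()
    model.compartments["c"] = Compartment("c")
    refs = [{"pubchem": ["1"]}, {"hmdb": ["HMDB1"]}, {}, {"kegg": ["C1"]}]
    for index, reference in enumerate(refs):
        met = f"m{index}"
        model.metabolites[met] = Metabolite(met, references=reference)
    model.reactions["r1"] = Reaction(
        "r1",
        genes=["g1"],
        participants=[
            Participant("m0", "reactant", "c"),
            Participant("m1", "product", "c"),
        ],
    )
    model.reactions["r2"] = Reaction(
        "r2",
        participants=[
            Participant("m2", "reactant", "c"),
            Participant("m3", "product", "c"),
        ],
    )
    summary = mg.summarize_curation(model)
    assert summary.n_metabolites == 4 and summary.n_reactions == 2
    assert summary.metabolite_coverage_percent == 50.0
    assert summary.reaction_coverage_percent == 50.0
    # matches an independent count over the raw collections
    independent = 100 * sum(
        1 for m in model.metabolites.values()
        if m.references.get("hmdb") or m.references.get("pubchem")
    ) / len(model.metabolites)
    assert summary.metabolite_coverage_percent == independent


def test_curation_summary_empty_model_flags():
    summary = mg.summarize_curation(MetabolicModel())
    assert summary.empty
    assert summary.metabolite_coverage_percent == 0.0


@pytest.mark.parametrize(
    "covered, total, expected",
    [(0, 10, 0.0), (2640, 3486, 75.73), (1025, 1722, 59.52)],
)
def test_coverage_percent_two_decimals(covered, total, expected):
    assert coverage_percent(covered, total) == expected


def test_summary_tsv_has_documented_header():
    summary = mg.summarize_curation(mg.toy4())
    assert summary.to_tsv().splitlines()[0] == "entity\tcount\treference_class\tcovered\tpercent"
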