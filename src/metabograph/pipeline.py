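"""Pipeline orchestration: curate -> define -> analyze -> measure -> integrate.

A single YAML configuration file drives every stage; all tunables of the
method (hub lists, degree threshold 50, module set size 25, search depth 2,
overlap thresholds 0.25/0.50/0.75, ensemble replicates and seeds) surface
here with their standard values as defaults.  Stages exchange data through
files in the output directory, so any subset can be re-run; reruns with the
same configuration and seeds are byte-identical (the configuration hash is
recorded in the log).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import measurements as meas
from . import metrics as met
from . import model as mod
from . import modules as modu
from . import network as netw
from . import synthetic as synth

logger = logging.getLogger(__name__)

STAGES = ("simulate", "curate", "network", "metrics", "measure", "integrate", "clusters")

DEFAULT_CONFIG: dict = {
    "paths": {"model": None, "measurements": None, "output": "output"},
    "log_level": "INFO",
    "synthetic": {
        "toy": "toy4",
        "effects": {},
        "n_per_group": 10,
        "paired": False,
        "sigma": 0.25,
        "seed": 0,
    },
    "curation": {"boundary_compartments": [], "name_patterns": []},
    "network": {
        "compartmentalize": False,
        "compartment_filter": None,
        "process_filter": None,
        "hubs_category1": [],
        "hubs_category2": [],
        "degree_threshold": 50,
        "keep_largest_component": True,
    },
    "metrics": {"mode": "metabolite", "replicates": 10, "seed": 0},
    "measure": {"coverage_min_fraction": 0.5, "welch": False},
    "clusters": {
        "n_modules": 25,
        "depth": 2,
        "overlap_thresholds": [0.25, 0.50, 0.75],
        "seed": 0,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if key not in base:
            raise ValueError(f"unknown configuration key {key!r}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = _merge(base[key], value)
        else:
            out[key] = value
    return out


@dataclass
class RunConfig:
    """Validated pipeline configuration (defaults merged in)."""

    data: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_CONFIG)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        return cls(_merge(DEFAULT_CONFIG, raw))

    def section(self, name: str) -> dict:
        return self.data[name]

    def network_spec(self) -> netw.NetworkSpec:
        section = self.section("network")
        excluded = set(section["hubs_category1"]) | set(section["hubs_category2"])
        return netw.NetworkSpec(
            compartmentalize=section["compartmentalize"],
            compartment_filter=(
                set(section["compartment_filter"])
                if section["compartment_filter"]
                else None
            ),
            process_filter=(
                set(section["process_filter"]) if section["process_filter"] else None
            ),
            excluded_metabolites=excluded,
            degree_threshold=section["degree_threshold"],
            keep_largest_component=section["keep_largest_component"],
        )

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.data, sort_keys=True).encode()
        ).hexdigest()[:16]


class StageError(RuntimeError):
    """A stage prerequisite is missing or a stage failed."""


def _out(config: RunConfig) -> Path:
    path = Path(config.section("paths")["output"])
    path.mkdir(parents=True, exist_ok=True)
    return path


def _load_model(config: RunConfig, out: Path) -> mod.MetabolicModel:
    for candidate in (out / "curated_model.json", out / "model.json"):
        if candidate.exists():
            return mod.read_model(candidate)
    explicit = config.section("paths")["model"]
    if explicit and Path(explicit).exists():
        return mod.read_model(explicit)
    raise StageError(
        "no model available: run the 'simulate' or 'curate' stage first, "
        "or set paths.model"
    )


def _load_network(out: Path, spec: netw.NetworkSpec) -> netw.MetabolicNetwork:
    path = out / "network.graphml"
    if not path.exists():
        raise StageError("no network available: run the 'network' stage first")
    return netw.import_graphml(path, spec)


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", float_format="%.10g")


def run_pipeline(config: RunConfig, stages) -> dict[str, Path]:
    """Run the requested stages in canonical order; return artifact paths."""
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    ordered = [s for s in STAGES if s in stages]
    out = _out(config)
    logging.basicConfig(level=config.section("log_level"))
    logger.info("pipeline start: stages=%s config_hash=%s", ordered, config.hash())
    with open(out / "pipeline.log", "a", encoding="utf-8") as handle:
        handle.write(f"stages={ordered} config_hash={config.hash()}\n")
    artifacts: dict[str, Path] = {}

    for stage in ordered:
        if stage == "simulate":
            section = config.section("synthetic")
            model = synth.FIXTURES[section["toy"]]()
            mod.write_model(model, out / "model.json")
            artifacts["model"] = out / "model.json"
            effects = synth.EffectSpec(
                effects=dict(section["effects"]),
                n_per_group=section["n_per_group"],
                paired=section["paired"],
                sigma=section["sigma"],
                seed=section["seed"],
            )
            study = synth.generate_measurements(model, effects)
            meas.write_measurements(study, out / "measurements.tsv")
            artifacts["measurements"] = out / "measurements.tsv"

        elif stage == "curate":
            model = _load_model(config, out)
            section = config.section("curation")
            model = mod.classify_all(model)
            model = mod.filter_simulation_artifacts(
                model,
                mod.ArtifactFilterConfig(
                    boundary_compartments=section["boundary_compartments"],
                    name_patterns=section["name_patterns"],
                ),
            )
            model = mod.assign_transport_processes(model)
            mod.write_model(model, out / "curated_model.json")
            summary = mod.summarize_curation(model)
            (out / "curation_summary.tsv").write_text(summary.to_tsv())
            artifacts["curated_model"] = out / "curated_model.json"
            artifacts["curation_summary"] = out / "curation_summary.tsv"

        elif stage == "network":
            model = _load_model(config, out)
            spec = config.network_spec()
            network = netw.build_network(model, spec)
            netw.export_network(network, out / "network.graphml", "graphml")
            netw.export_network(network, out / "network", "cytoscape_tables")
            artifacts["network"] = out / "network.graphml"

        elif stage == "metrics":
            spec = config.network_spec()
            network = _load_network(out, spec)
            section = config.section("metrics")
            report = met.metrics_report(
                network,
                mode=section["mode"],
                replicates=section["replicates"],
                seed=section["seed"],
            )
            (out / "metrics_report.tsv").write_text(report.to_tsv_row())
            _write_tsv(report.node_table, out / "centralities.tsv")
            _write_tsv(met.rank_metabolites(report.node_table), out / "ranks.tsv")
            artifacts["metrics_report"] = out / "metrics_report.tsv"

        elif stage == "measure":
            path = config.section("paths")["measurements"] or out / "measurements.tsv"
            if not Path(path).exists():
                raise StageError(
                    "no measurements available: run 'simulate' or set paths.measurements"
                )
            study = meas.read_measurements(path)
            section = config.section("measure")
            study = meas.filter_coverage(study, section["coverage_min_fraction"])
            model = _load_model(config, out)
            match = meas.match_analytes(study, model)
            study = meas.resolve_redundancy(study, match.mapping)
            study = meas.normalize_total_signal(study)
            comparisons = meas.compare_groups(study, welch=section["welch"])
            comparisons["metabolite"] = [
                match.mapping.get(a) for a in comparisons.index
            ]
            _write_tsv(comparisons, out / "comparisons.tsv")
            _write_tsv(meas.volcano_data(comparisons), out / "volcano.tsv")
            artifacts["comparisons"] = out / "comparisons.tsv"

        elif stage == "integrate":
            spec = config.network_spec()
            network = _load_network(out, spec)
            if not (out / "comparisons.tsv").exists():
                raise StageError("no comparisons available: run the 'measure' stage first")
            comparisons = pd.read_csv(out / "comparisons.tsv", sep="\t", index_col=0)
            annotated = meas.annotate_network(network, comparisons)
            netw.export_network(annotated, out / "annotated.graphml", "graphml")
            netw.export_network(annotated, out / "annotated", "cytoscape_tables")
            artifacts["annotated"] = out / "annotated.graphml"

        elif stage == "clusters":
            spec = config.network_spec()
            path = out / "annotated.graphml"
            if not path.exists():
                raise StageError("no annotated network: run the 'integrate' stage first")
            network = netw.import_graphml(path, spec)
            comparisons = pd.read_csv(out / "comparisons.tsv", sep="\t", index_col=0)
            z_scores = modu.node_z_scores(comparisons)
            section = config.section("clusters")
            clusters = modu.search_modules(
                network,
                z_scores,
                n_modules=section["n_modules"],
                depth=section["depth"],
                overlap_thresholds=tuple(section["overlap_thresholds"]),
                seed=section["seed"],
            )
            filtered = modu.filter_clusters(clusters, network)
            modu.export_clusters(clusters, network, out / "clusters_raw")
            modu.export_clusters(filtered, network, out / "clusters")
            artifacts["clusters"] = out / "clusters_metabolites.tsv"

    logger.info("pipeline done: %s", sorted(artifacts))
    return artifacts
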