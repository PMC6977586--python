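"""Metabolomic measurement processing: coverage, normalization, group tests.

The pipeline mirrors standard relative-quantification practice for
chromatography/mass-spectrometry metabolomics: drop analytes with inadequate
coverage, collapse redundant analytes for the same chemical entity to the
one with least relative variance (index of dispersion) in the control group,
normalize each sample to its total signal, then compare experimental groups
per analyte with base-2 log fold changes and two-sided t-tests (dependent
for paired designs, independent otherwise).  Analytes match to model
metabolites through shared PubChem references.

Measurement tables travel in a small TSV dialect::

    #sample<TAB><sample id><TAB><group: case|control><TAB>[pair id]
    ...one line per sample...
    analyte<TAB>name<TAB>pubchem<TAB><sample id 1><TAB><sample id 2>...
    a1<TAB>alanine<TAB>5950<TAB>12.1<TAB>13.4...

The ``pubchem`` cell holds ``;``-separated identifiers; empty signal cells
mean "not measured" and stay missing through the pipeline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GROUPS = ("case", "control")


@dataclass
class MeasurementStudy:
    """Samples with group/pair labels and analyte signal matrix."""

    samples: pd.DataFrame  # index: sample id; columns: group, pair
    analytes: pd.DataFrame  # index: analyte id; columns: name, pubchem (list)
    signals: pd.DataFrame  # index: analyte id; columns: sample id; float
    paired: bool = False

    def validate(self) -> None:
        groups = set(self.samples["group"])
        if groups != set(GROUPS):
            raise ValueError(
                f"expected exactly the groups {GROUPS}, found {sorted(groups)}"
            )
        if (self.signals.to_numpy(dtype=float) < 0).any():
            raise ValueError("signals must be non-negative")
        if list(self.signals.index) != list(self.analytes.index):
            raise ValueError("signal rows must align with the analyte table")
        if list(self.signals.columns) != list(self.samples.index):
            raise ValueError("signal columns must align with the sample table")
        if self.paired:
            pairs = self.samples.dropna(subset=["pair"])
            if len(pairs) != len(self.samples):
                raise ValueError("paired study requires a pair label on every sample")
            for pair_id, members in self.samples.groupby("pair"):
                if sorted(members["group"]) != ["case", "control"]:
                    raise ValueError(
                        f"pair {pair_id!r} must hold exactly one case and one control"
                    )

    def group_samples(self, group: str) -> list[str]:
        return list(self.samples.index[self.samples["group"] == group])

    def pairs(self) -> list[tuple[str, str]]:
        """(case sample, control sample) per pair, sorted by pair id."""
        out = []
        for pair_id, members in sorted(self.samples.groupby("pair")):
            case = members.index[members["group"] == "case"][0]
            control = members.index[members["group"] == "control"][0]
            out.append((case, control))
        return out

    def copy(self) -> "MeasurementStudy":
        return MeasurementStudy(
            self.samples.copy(), self.analytes.copy(), self.signals.copy(), self.paired
        )


def read_measurements(path) -> MeasurementStudy:
    """Parse the measurement TSV dialect documented in this module."""
    sample_rows = []
    header = None
    data_rows = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if cells[0] == "#sample":
                pair = cells[3] if len(cells) > 3 and cells[3] else None
                sample_rows.append(
                    {"sample": cells[1], "group": cells[2], "pair": pair}
                )
            elif header is None:
                header = cells
            else:
                data_rows.append(cells)
    if header is None or header[:3] != ["analyte", "name", "pubchem"]:
        raise ValueError(f"{path}: missing analyte header line")
    samples = pd.DataFrame(sample_rows).set_index("sample")
    sample_ids = header[3:]
    analytes = []
    signals = []
    for cells in data_rows:
        cells = cells + [""] * (len(header) - len(cells))
        analytes.append(
            {
                "analyte": cells[0],
                "name": cells[1],
                "pubchem": [p for p in cells[2].split(";") if p],
            }
        )
        signals.append(
            [float(c) if c != "" else np.nan for c in cells[3 : 3 + len(sample_ids)]]
        )
    analyte_table = pd.DataFrame(analytes).set_index("analyte")
    signal_table = pd.DataFrame(
        signals, index=analyte_table.index, columns=sample_ids, dtype=float
    )
    paired = samples["pair"].notna().any()
    study = MeasurementStudy(samples, analyte_table, signal_table, paired)
    study.validate()
    return study


def write_measurements(study: MeasurementStudy, path) -> None:
    """Serialize a study to the TSV dialect; ``read_measurements`` inverts it."""
    with open(path, "w", encoding="utf-8") as handle:
        for sample_id, row in study.samples.iterrows():
            pair = row["pair"] if pd.notna(row["pair"]) else ""
            handle.write(f"#sample\t{sample_id}\t{row['group']}\t{pair}\n")
        handle.write("analyte\tname\tpubchem\t" + "\t".join(study.signals.columns) + "\n")
        for analyte_id, row in study.analytes.iterrows():
            values = [
                "" if pd.isna(v) else format(v, ".10g")
                for v in study.signals.loc[analyte_id]
            ]
            handle.write(
                f"{analyte_id}\t{row['name']}\t{';'.join(row['pubchem'])}\t"
                + "\t".join(values)
                + "\n"
            )


def filter_coverage(study: MeasurementStudy, min_fraction: float = 0.5) -> MeasurementStudy:
    """Drop analytes measured in less than ``min_fraction`` of either group."""
    keep = []
    for analyte in study.signals.index:
        fractions = []
        for group in GROUPS:
            columns = study.group_samples(group)
            measured = study.signals.loc[analyte, columns].notna().sum()
            fractions.append(measured / len(columns) if columns else 0.0)
        if all(f >= min_fraction for f in fractions):
            keep.append(analyte)
        else:
            logger.info("coverage filter dropped analyte %s", analyte)
    out = study.copy()
    out.analytes = out.analytes.loc[keep]
    out.signals = out.signals.loc[keep]
    return out


def dispersion_index(values: pd.Series) -> float:
    """Variance-to-mean ratio (sample variance, n-1 denominator)."""
    values = values.dropna()
    mean = values.mean()
    if len(values) < 2 or mean == 0:
        return math.inf
    return float(values.var(ddof=1) / mean)


def resolve_redundancy(
    study: MeasurementStudy, chemistry_key: dict[str, str]
) -> MeasurementStudy:
    """Keep one analyte per chemical entity: least control-group dispersion.

    ``chemistry_key`` maps analyte identifier to metabolite identifier.
    Among analytes sharing a metabolite, the one with the smallest
    variance-to-mean ratio in control samples wins; zero control means give
    infinite dispersion (deprioritized); ties break lexicographically.
    """
    control_columns = study.group_samples("control")
    by_metabolite: dict[str, list[str]] = {}
    for analyte in study.analytes.index:
        metabolite = chemistry_key.get(analyte)
        if metabolite is not None:
            by_metabolite.setdefault(metabolite, []).append(analyte)
    drop: set[str] = set()
    for metabolite, analytes in by_metabolite.items():
        if len(analytes) < 2:
            continue
        ranked = sorted(
            analytes,
            key=lambda a: (
                dispersion_index(study.signals.loc[a, control_columns]),
                a,
            ),
        )
        drop.update(ranked[1:])
        logger.info(
            "redundancy for %s resolved to %s (dropped %s)",
            metabolite,
            ranked[0],
            ranked[1:],
        )
    keep = [a for a in study.analytes.index if a not in drop]
    out = study.copy()
    out.analytes = out.analytes.loc[keep]
    out.signals = out.signals.loc[keep]
    return out


def normalize_total_signal(study: MeasurementStudy) -> MeasurementStudy:
    """Divide each value by its sample's total signal over measured analytes."""
    totals = study.signals.sum(axis=0, skipna=True)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"zero total signal in samples: {list(zero)}")
    out = study.copy()
    out.signals = study.signals / totals
    return out


def _safe_p(t_stat: float, p_value: float, mean_diff: float) -> float:
    """Map degenerate zero-variance tests onto the (0, 1] interval."""
    if np.isnan(p_value):
        return 1.0 if mean_diff == 0 else np.finfo(float).tiny
    return max(float(p_value), np.finfo(float).tiny)


def compare_groups(study: MeasurementStudy, welch: bool = False) -> pd.DataFrame:
    """Per-analyte log2 fold change (case over control) and two-sided t-test.

    Paired designs take the mean of per-pair ``log2(case/control)`` ratios
    and test those ratios against zero (dependent-samples t-test); unpaired
    designs take ``log2(mean_case/mean_control)`` and an independent
    two-sample t-test (equal-variance by default, Welch by flag).  Analytes
    whose fold change would take a log of a non-positive value are excluded
    with a log entry.  Incomplete pairs are dropped per analyte.
    """
    rows = []
    control_columns = study.group_samples("control")
    case_columns = study.group_samples("case")
    for analyte in study.analytes.index:
        dispersion = dispersion_index(study.signals.loc[analyte, control_columns])
        if study.paired:
            ratios = []
            for case_sample, control_sample in study.pairs():
                case_value = study.signals.at[analyte, case_sample]
                control_value = study.signals.at[analyte, control_sample]
                if pd.isna(case_value) or pd.isna(control_value):
                    continue
                if case_value <= 0 or control_value <= 0:
                    ratios = None
                    break
                ratios.append(math.log2(case_value / control_value))
            if ratios is None:
                logger.warning("analyte %s: non-positive value in a pair; excluded", analyte)
                continue
            if len(ratios) < 2:
                logger.warning("analyte %s: fewer than 2 complete pairs; excluded", analyte)
                continue
            log2fc = float(np.mean(ratios))
            t_stat, p_value = stats.ttest_1samp(ratios, 0.0)
            rows.append(
                {
                    "analyte": analyte,
                    "metabolite": None,
                    "log2_fold_change": log2fc,
                    "p_value": _safe_p(t_stat, p_value, log2fc),
                    "n_pairs": len(ratios),
                    "n_case": len(ratios),
                    "n_control": len(ratios),
                    "dispersion_control": dispersion,
                }
            )
        else:
            case_values = study.signals.loc[analyte, case_columns].dropna()
            control_values = study.signals.loc[analyte, control_columns].dropna()
            if len(case_values) < 2 or len(control_values) < 2:
                logger.warning("analyte %s: fewer than 2 observations per group; excluded", analyte)
                continue
            if case_values.mean() <= 0 or control_values.mean() <= 0:
                logger.warning("analyte %s: non-positive group mean; excluded", analyte)
                continue
            log2fc = math.log2(case_values.mean() / control_values.mean())
            t_stat, p_value = stats.ttest_ind(
                case_values, control_values, equal_var=not welch
            )
            rows.append(
                {
                    "analyte": analyte,
                    "metabolite": None,
                    "log2_fold_change": log2fc,
                    "p_value": _safe_p(t_stat, p_value, log2fc),
                    "n_pairs": 0,
                    "n_case": len(case_values),
                    "n_control": len(control_values),
                    "dispersion_control": dispersion,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "analyte",
            "metabolite",
            "log2_fold_change",
            "p_value",
            "n_pairs",
            "n_case",
            "n_control",
            "dispersion_control",
        ],
    ).set_index("analyte")


def add_bh_correction(comparisons: pd.DataFrame) -> pd.DataFrame:
    """Opt-in Benjamini-Hochberg adjusted p-values as an extra column."""
    out = comparisons.copy()
    out["p_adjusted"] = stats.false_discovery_control(out["p_value"], method="bh")
    return out


def normalize_pubchem(value: str) -> str:
    """Canonical PubChem CID string: trimmed, no leading zeros, no prefix."""
    value = value.strip()
    for prefix in ("CID:", "CID", "cid:"):
        if value.startswith(prefix):
            value = value[len(prefix):]
    value = value.strip().lstrip("0")
    return value


@dataclass
class MatchResult:
    """Analyte-to-metabolite matching outcome with an ambiguity report."""

    mapping: dict[str, str] = field(default_factory=dict)
    unmatched: list[str] = field(default_factory=list)
    ambiguous: dict[str, list[str]] = field(default_factory=dict)


def match_analytes(study: MeasurementStudy, model_or_network) -> MatchResult:
    """Match analytes to metabolites by shared normalized PubChem references.

    Accepts a :class:`~metabograph.model.MetabolicModel` or a built network
    (consensus metabolite nodes carrying ``references``).  An analyte whose
    references intersect several metabolites lands in the ambiguity report
    rather than being silently assigned.
    """
    metabolite_refs: dict[str, set[str]] = {}
    if hasattr(model_or_network, "metabolites"):
        for met in model_or_network.metabolites.values():
            refs = {normalize_pubchem(v) for v in met.references.get("pubchem", [])}
            if refs:
                metabolite_refs[met.identifier] = refs
    else:
        graph = model_or_network.graph
        for node, data in graph.nodes(data=True):
            if data.get("kind") != "metabolite":
                continue
            refs = {
                normalize_pubchem(v)
                for v in data.get("references", {}).get("pubchem", [])
            }
            if refs:
                metabolite_refs[data.get("metabolite", node)] = refs

    result = MatchResult()
    for analyte, row in study.analytes.iterrows():
        refs = {normalize_pubchem(v) for v in row["pubchem"]}
        hits = sorted(
            met for met, met_refs in metabolite_refs.items() if refs & met_refs
        )
        if not hits:
            result.unmatched.append(analyte)
        elif len(hits) == 1:
            result.mapping[analyte] = hits[0]
        else:
            result.ambiguous[analyte] = hits
            logger.warning("analyte %s matches multiple metabolites: %s", analyte, hits)
    return result


def annotate_network(network, comparisons: pd.DataFrame):
    """Attach (log2 fold change, p-value) payloads to metabolite nodes.

    ``comparisons`` must carry a ``metabolite`` column (from matching).
    Returns an annotated copy; comparisons naming absent nodes warn.
    """
    from .network import METABOLITE, MetabolicNetwork

    graph = network.graph.copy()
    by_metabolite = {
        row["metabolite"]: (row["log2_fold_change"], row["p_value"])
        for _, row in comparisons.iterrows()
        if row["metabolite"] is not None and pd.notna(row["metabolite"])
    }
    node_of = {
        data.get("metabolite", node): node
        for node, data in graph.nodes(data=True)
        if data.get("kind") == METABOLITE
    }
    annotated = 0
    for metabolite, (log2fc, p_value) in sorted(by_metabolite.items()):
        node = node_of.get(metabolite)
        if node is None:
            logger.warning("comparison references absent metabolite %s", metabolite)
            continue
        graph.nodes[node]["log2fc"] = float(log2fc)
        graph.nodes[node]["p_value"] = float(p_value)
        annotated += 1
    logger.info("annotated %d metabolite nodes", annotated)
    return MetabolicNetwork(
        graph, network.spec, provenance=network.provenance + " + annotations"
    )


def volcano_data(comparisons: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready (log2 fold change, -log10 p) coordinates per analyte."""
    if comparisons.empty:
        raise ValueError("no comparisons to plot")
    return pd.DataFrame(
        {
            "log2_fold_change": comparisons["log2_fold_change"],
            "neg_log10_p": -np.log10(comparisons["p_value"]),
        },
        index=comparisons.index,
    )


def volcano_plot(comparisons: pd.DataFrame, path, alpha: float = 0.05) -> None:
    """Thin matplotlib layer over :func:`volcano_data`."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = volcano_data(comparisons)
    figure, axes = plt.subplots(figsize=(5, 4))
    significant = comparisons["p_value"] < alpha
    axes.scatter(
        data.loc[~significant, "log2_fold_change"],
        data.loc[~significant, "neg_log10_p"],
        s=12, color="grey", label=f"p >= {alpha}",
    )
    axes.scatter(
        data.loc[significant, "log2_fold_change"],
        data.loc[significant, "neg_log10_p"],
        s=12, color="crimson", label=f"p < {alpha}",
    )
    axes.axhline(-np.log10(alpha), linestyle="--", linewidth=0.8, color="black")
    axes.set_xlabel("log2 fold change (case / control)")
    axes.set_ylabel("-log10 p-value")
    axes.legend(frameon=False)
    figure.tight_layout()
    figure.savefig(path, dpi=150)
    plt.close(figure)
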