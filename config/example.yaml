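# Annotated pipeline configuration. Every key shown here is optional;
# omitted keys fall back to the defaults in metabograph.pipeline.
#
# The hub lists and thresholds below are the standard working defaults for
# human genome-scale networks. Identifiers must match the metabolite
# identifiers of YOUR model; the names in comments say what is meant.

paths:
  model: null              # native JSON model; null -> use simulate output
  measurements: null       # measurement TSV; null -> use simulate output
  output: output

log_level: INFO

synthetic:                 # only used by the `simulate` stage
  toy: toy4                # toy4 | toyhub | toycomp
  effects: {}              # e.g. {A: 1.0, C: -1.0} log2 effects on case group
  n_per_group: 10
  paired: false
  sigma: 0.25              # per-measurement noise, log2 scale
  seed: 0

curation:
  boundary_compartments: []     # compartments that only exchange with outside
  name_patterns:                # case-insensitive regexes on reaction names/ids
    - "biomass"
    - "protein (assembly|degradation)"
    - "^EX_"                    # exchange reactions by identifier convention

network:
  compartmentalize: false
  compartment_filter: null      # e.g. [mitochondrion] to restrict
  process_filter: null          # e.g. [citric acid cycle]
  # Category 1 hubs: chemically ubiquitous, rarely informative in
  # metabolomics — proton, water, dioxygen, phosphate, diphosphate, carbon
  # dioxide, sulfate, hydrogen peroxide, ammonium, sulfite, sodium,
  # hydrogen carbonate, hydroxide. Excluded unconditionally.
  hubs_category1: []
  # Category 2 hubs: biologically relevant but prolifically connected —
  # coenzyme A, acetyl-CoA, acyl carrier protein, carnitine, NAD(H)/NADP(H),
  # FAD(H2), nucleoside phosphates. Conventionally excluded when their
  # degree exceeds the threshold below; list the chosen ones here.
  hubs_category2: []
  degree_threshold: 50          # exclude metabolites with degree > 50
  keep_largest_component: true

metrics:
  mode: metabolite              # single-mode set the report refers to
  replicates: 10                # random ensemble size for sigma
  seed: 0

measure:
  coverage_min_fraction: 0.5    # analyte must be measured in >= this
                                # fraction of samples in each group
  welch: false                  # unequal-variance t-test variant

clusters:
  n_modules: 25                 # clusters emitted per overlap threshold
  depth: 2                      # search depth in links
  overlap_thresholds: [0.25, 0.50, 0.75]
  seed: 0
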