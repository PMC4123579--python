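# Methods

This note records the models, conventions, and design choices behind
`enzynet`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Enzyme network construction

Reactions are chained by the substrate→product rule: for every ordered
pair of *distinct* reactions (R_a, R_b) with a shared non-currency
compound between R_a's products and R_b's substrates, a directed edge is
added from every EC catalyzing R_a to every EC catalyzing R_b, annotated
with the mediating compounds. Conventions:

- **Currency metabolites.** Ubiquitous cofactors connect nearly every
  enzyme pair and are excluded from chaining. The default list (ATP,
  ADP, H2O, NAD+, NADH, CO2, Pi, H+) is overridable, including with the
  empty set to chain through every compound literally.
- **Reversibility.** Reversible reactions contribute both orientations
  of their substrate/product sets.
- **Within-reaction pairs.** Two ECs catalyzing the same reaction are
  *not* connected by that reaction; only across-reaction chaining
  creates edges. A reaction is likewise never chained with itself, so a
  reversible reaction does not self-connect its own enzymes.
- **Self-loops** (an enzyme feeding itself through two reactions) are
  dropped unless explicitly enabled. Partial EC numbers ("1.1.1.-") are
  legal node ids compared as exact strings.
- Parallel edges merge, unioning mediating-compound sets. Spontaneous
  (enzyme-less) reactions are retained on read but contribute no edges.

MCODE and the clustering coefficient are defined on simple undirected
graphs, so analyses that need them use an undirected view (directions
and parallel edges collapsed, self-loops dropped; idempotent).

## Subcellular localization

Compartment assignment backtracks every cellular-component annotation of
every gene/protein mapped to an enzyme through the ontology, treating
`is_a` and `part_of` identically, and collects the anchors found among
the ancestors (the six defaults are the canonical GO ids for cytoplasm,
mitochondrion, Golgi apparatus, extracellular region, nucleus, and
endoplasmic reticulum; all configurable). Choices made where the design
was open:

- **Union, not intersection**, across a multi-gene enzyme's proteins:
  GO annotations are genuinely multi-localized, and intersection would
  empty the assignment for most multi-subunit enzymes. An enzyme may
  therefore sit in several subnetworks.
- Enzymes whose annotations reach no anchor — or that have no mapped
  genes — go to the "uncertain" bucket and never enter a compartment
  subnetwork. Every network enzyme lands in exactly one of
  {≥1 compartment, uncertain}.
- Evidence codes are not filtered by default; an exclusion list (e.g.
  IEA) is a config key.

## Reporter statistic

Gene P-values are mapped to Z-scores by the inverse standard-normal
survival function; P-values are clamped to [1e-300, 1] beforehand so the
transform stays finite. A gene with zero variance in both groups and
equal means gets P = 1 by convention (not an error). The gene-level test
defaults to Welch's t, two-sided, with Wilcoxon as an option — the
appropriate default for a two-group normalized-expression contrast.

Per enzyme, the k gene Z-scores are aggregated by the **median**
(mean-of-middle-two for even k); the arithmetic mean is available as
`mode="mean"`. The method description this implements contains a genuine
text/formula discrepancy between "median of the k genes" and a displayed
(1/k)Σ; the median is the default because it is the operative prose
description and is robust to a single outlier gene, and both modes are
tested.

The background null samples, for each k, `rounds` (default 10000) sets
of k scores **without replacement** from the pool of gene Z-scores
mapped to the network under scoring, aggregates each with the configured
mode, and uses the mean and SD of the aggregates as (μ_k, σ_k). Sampling
"sets of k enzymes" cannot directly calibrate a k-gene aggregate, so the
gene-pool reading is implemented as the default (it is the standard
reporter-feature construction); a variant that pools one aggregated
Z-score per enzyme is available as `null_pool="enzyme"`. Each network —
the overall one and every compartment subnetwork — gets its own pool,
and each cell-type contrast its own null. Per-k moments are derived from
`default_rng([seed, k])`, so they depend only on (seed, pool, mode,
rounds, k), never on the order ks are requested; the cache extends on
demand reproducibly. A pool whose aggregates have zero SD raises a
degenerate-null error rather than dividing by zero.

Corrected scores Z^corr = (Z − μ_k)/σ_k become P = 1 − Φ(Z^corr);
flagging is strictly below the threshold (default 0.05), and reporter
enzymes are those flagged in **every** per-cell-type table over the same
network. Enzyme-level multiple-testing correction is deliberately off by
default (the operative threshold is a raw 0.05 cut); the enrichment
stage, by contrast, is always FDR-corrected.

## Module detection

The MCODE stages follow the published molecular-complex-detection
algorithm: vertex weight = k_max × density of the highest k-core of the
closed neighborhood; seeded growth admitting neighbors with weight
strictly above (1 − vwp) × seed weight; post-processing that discards
complexes lacking a 2-core (the "K-core ≥ 2" setting) and haircuts
vertices of within-module degree < 2. Defaults: vwp 0.2, haircut on,
fluff off — the algorithm's published defaults; degree cutoff 2 is read
as MCODE's degree-cutoff parameter (vertices of degree < 2 are not
weighted). Determinism notes:

- Seed-selection ties break lexicographically on enzyme id.
- Visited vertices are never reseeded, so modules are vertex-disjoint.
- Haircut is implemented as the module's 2-core (iterated pruning of
  degree-<2 vertices). For a connected grown complex this cannot
  disconnect it — pruning only ever removes leaves — but `postprocess`
  also accepts externally supplied vertex sets, and there each connected
  component is emitted separately so module members always induce a
  connected subgraph.
- Module score = density × size of the final member set.

Whether modules must merely *contain* reporter enzymes or be *seeded*
from them is ambiguous in the source description; containment filtering
with `min_reporters=1` is the default, and seeding-from-reporters can be
emulated by intersecting with modules whose seed is a reporter.

## Enrichment and function classes

Enrichment is the upper-tail hypergeometric test of a module's gene set
against each term's gene set, both intersected with the universe, with
Benjamini–Hochberg adjustment **within each module** (one FDR family per
module, matching how module-by-module annotation tools behave). The
universe is all genes mapped to enzymes of the network under analysis,
not the genome: the modules are drawn from that network, and a
genome-wide background would manufacture significance for every
network-biased term.

The four function classes (death, CHD, lipid, basic metabolic) are a
shipped, editable YAML of term ids and case-insensitive name keywords,
matched in order with the most specific disease classes first and the
broad metabolic catch-all last; explicit term ids take precedence over
keywords. The classification principles behind published class tallies
of this kind are not enumerable, so the scheme is configuration, not
code, and class counts on real data depend on it.

## Topology

Shortest-path statistics (characteristic path length, diameter) are
computed on the largest connected component of the undirected view; the
clustering coefficient is the mean local clustering over all nodes with
degree-<2 nodes contributing 0. The power-law check is a least-squares
fit of log(count) against log(degree) on the nonzero-degree histogram,
reported as f(x) = a·x^b with an RMS log-scale residual — the regression
reading of a reported (a, b) pair, not a maximum-likelihood exponent
estimate, and not a rigorous heavy-tail hypothesis test. The
reporter-vs-background comparison uses the two-sided Wilcoxon rank-sum
test on degree and on local clustering (degree distributions are heavy
tailed; t-test assumptions fail), with exact small-sample P-values via
scipy's method selection and P = 1 when every value is tied.

## Synthetic data generator

The generator defines the study conditions the tests operate under:

- **Reactions**: 700 background reactions over 800 compounds plus 6
  currency analogues, 1–2 substrates/products each, 1–2 ECs, 30%
  reversible. Compound choice follows sublinear preferential attachment
  (weight = usage^0.5), with currency analogues weighted so they appear
  in a large share of reactions, mimicking cofactor ubiquity. The
  resulting 400-enzyme network has mean degree ≈ 20, clustering ≈ 0.24,
  and a clearly negative log-log degree slope — the scale-free-like
  regime expected of a metabolic enzyme graph.
- **Planted cluster**: the first 20 enzymes catalyze a dedicated
  circulant chain (enzyme i consumes compound m_i, produces m_{i+1} and
  m_{i+2}), making them mutually adjacent with within-cluster degree 4
  and a guaranteed 2-core, loosely bridged to the background graph.
- **Gene map**: 1 + Poisson(1) genes per enzyme; 10% of background gene
  slots reuse an existing gene (many-to-many). Planted enzymes keep
  private genes so the planted signal stays confined.
- **Ontology/annotations**: six compartment anchors under the CC root,
  each with a depth-2 × branching-3 descendant tree mixing is_a and
  part_of; off-anchor terms absorb the `fraction_uncertain` (default
  0.1) of background enzymes. Planted enzymes are pinned to the
  mitochondria branch (they become uncertain only in the degenerate
  fraction_uncertain = 1 case) and their genes are annotated coherently
  to death-keyword process terms; background genes get 1–3 random
  process terms.
- **Expression**: two cell types ("macrophage", "foam_cell"), 15
  disease vs 15 control samples each — the emulated study's group sizes
  — standard-normal background, and a +2 SD disease-group shift on every
  planted gene in *both* datasets, so the two-contrast intersection can
  recover the cluster. Per-stage seeds derive from the master seed, so
  each stage reproduces independently.

What the generator does **not** emulate: probe-level microarray noise,
normalization artifacts, probe→gene collapsing, correlated background
expression, or the actual content of any reaction database or GO
release. Passing tests therefore demonstrate the statistical machinery
and its calibration under the assumed model, not performance on real
arrays.

## Problem sizes and numerical choices

Tests and the acceptance script run the generator at its defaults (400
enzymes, 2000 genes, 10000 sampling rounds) for calibration and
recovery checks, and at reduced sizes (60–120 enzymes, 300–500 rounds)
where only structural behavior or determinism is asserted; the
module-detection equivalence checks cover the complete atlas of
connected graphs up to 7 vertices, exhaustively enumerated labeled
graphs up to 5 vertices, seeded random 8-vertex connected graphs, and
random graphs up to 100 vertices. Null-model sampling uses
random-key argpartition for without-replacement draws, processed in
blocks of 2000 rounds to bound memory. Score tables serialize with
`%.10g` floats; manifests carry config, derived seeds, per-network
counts, and SHA-256 checksums, and deliberately omit wall-clock
timestamps so identical runs are byte-identical (timestamps go to the
log stream instead).

## Known limitations

- Gene-level P-values are taken as given (or computed by Welch/Wilcoxon
  from a supplied matrix); upstream normalization and probe collapsing
  are out of scope.
- The hypergeometric enrichment ignores the GO DAG's dependence
  structure (no elim/weight decorrelation) and term-size bias.
- The power-law fit is descriptive; no goodness-of-fit test against
  alternatives is performed.
- Compartment assignment trusts annotation quality; no evidence-code
  weighting beyond the optional exclusion list.
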