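# enzynet

Reporter-enzyme analysis of metabolic enzyme networks, aimed at studies of
coronary heart disease (CHD) from the perspective of programmed cell death
in macrophages and foam cells — and, more generally, at any two-contrast
differential-expression experiment projected onto a metabolic
reconstruction.

Atherosclerotic plaques are driven by monocyte-derived macrophages that
ingest oxidized LDL, turn into lipid-laden foam cells, and die. The
package asks which *enzymes* carry coordinated transcriptional
dysregulation in both cell types, where those enzymes sit in the cell,
and whether they cluster into dense network modules whose functional
annotation points at programmed cell death.

## The method

**Enzyme network.** From a metabolic reaction table (an EHMN-style
reconstruction: reaction id, substrates, products, EC numbers,
reversibility), enzymes become nodes and a directed edge E_i → E_j is
drawn whenever a reaction catalyzed by E_i produces a compound consumed
by a reaction catalyzed by E_j. Ubiquitous currency metabolites (ATP,
H2O, NAD+, ...) are excluded from the chaining by a configurable list.

**Compartments.** Each enzyme's proteins carry GO cellular-component
annotations (GAF); every annotated term is backtracked through the
ontology's is_a/part_of hierarchy (OBO) to six anchors — cytoplasm,
mitochondria, Golgi, extracellular, nucleus, endoplasmic reticulum.
Enzymes reaching no anchor are "uncertain" and screened out. The network
is split into six compartment subnetworks.

**Reporter enzymes.** Per cell type, gene-level two-sided P-values
(Welch's t by default) are converted to Z-scores,

    Z_g = Φ⁻¹(1 − P_g),

an enzyme with k mapped genes aggregates them (median by default),

    Z_E = median(Z_g1, …, Z_gk),

and the aggregate is corrected against a background built by sampling
10000 size-k gene-score sets from the network's gene pool:

    Z_E^corr = (Z_E − μ_k) / σ_k,     P_E = 1 − Φ(Z_E^corr).

Enzymes with P_E < 0.05 in **both** the macrophage and foam-cell
contrasts are the reporter enzymes.

**Modules and classification.** An MCODE reimplementation (local k-core
density weighting, seeded growth, haircut; degree cutoff 2, k-core 2)
finds dense modules; modules containing reporter enzymes are tested for
GO-term enrichment (upper-tail hypergeometric, Benjamini–Hochberg FDR <
0.05 per module) and each significant term is classified as programmed
cell death / CHD / lipid / basic metabolism by an editable keyword
scheme. Topology summaries (degree distribution with a log-log power-law
fit f(x) = a·x^b, path lengths, clustering) and a rank-sum comparison of
reporter vs background topology round out the report.

A synthetic-data generator emulates the whole input bundle — a
scale-free-ish reaction network, a many-to-many gene↔EC map, a toy GO
DAG, and two 15-vs-15 expression datasets with a planted, dense,
mitochondria-localized, death-annotated reporter cluster — so the full
pipeline runs and is testable without any external download.

## Worked example

```bash
enzynet generate --outdir data --seed 1
enzynet run --config config.yaml --outdir results
```

with `config.yaml` pointing at the generated files (see
`tests/test_pipeline.py` for the full key list). The run prints a
per-network summary; with seed 1 and default settings:

```
"overall":       { "nodes": 400, "edges": 4211, "reporters": 20, "modules": 1, ... }
"mitochondria":  { "nodes": 130, "edges": 363,  "reporters": 17, "modules": 1,
                   "class_counts": { ..., "death": 5 } }
```

Reading: of 400 enzymes in the overall network, 20 pass the reporter
intersection (they are exactly the generator's planted cluster); 17 of
them survive inside the 130-enzyme mitochondria subnetwork, where module
detection isolates one 20-enzyme module (MCODE score 4.21) whose gene
set enriches five death-class terms at FDR < 0.05 — e.g.
`programmed cell death, hits 24/39, FDR 2.4e-08`. The other compartments
stay near the 5% false-positive floor, as they should: no signal was
planted there.

Per-stage subcommands (`build-network`, `partition`, `score`, `modules`,
`enrich`, `topology`) expose the same steps for real data; all paper
parameters (rounds, alpha, aggregation mode, MCODE settings, FDR level)
are config keys.

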