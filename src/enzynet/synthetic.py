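"""Synthetic input bundles with the statistical structure the analysis assumes.

The generator stands in for the study's raw resources — a genome-scale
human metabolic reaction set, GO localization data, and a two-cell-type
(macrophage / foam cell) disease-vs-control expression experiment — so
the full pipeline runs and is testable without any download. It emulates:

* a reaction table whose compound reuse follows preferential attachment,
  so the derived enzyme network has an approximately scale-free degree
  distribution, with a handful of ubiquitous "currency" compounds;
* a many-to-many gene-to-enzyme map (gene count per enzyme drawn from
  1 + Poisson(1));
* a toy GO DAG with a cellular-component branch (six compartment anchors
  under the root, each with a small descendant tree, plus off-anchor
  terms that localize nowhere) and a biological-process branch whose term
  names carry death / CHD / lipid / metabolic keywords;
* two expression datasets (15 disease vs 15 control samples each, the
  study's group sizes) with standard-normal background and a planted
  mean shift — in both cell types — on the genes of a designated set of
  reporter enzymes;
* a planted dense enzyme cluster (a circulant chaining pattern) pinned to
  the mitochondria compartment and annotated coherently to death-branch
  terms, re-creating the structure of the analysis's headline module.

What it does not emulate: probe-level microarray noise, normalization
artifacts, or the actual content of any real reaction database or GO
release.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import (
    Annotation,
    ExpressionDataset,
    GeneEnzymeMap,
    Reaction,
    write_gaf,
    write_gene_enzyme_map,
    write_reactions,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticBundle",
    "generate_reactions",
    "generate_gene_map",
    "generate_ontology_and_annotations",
    "generate_expression",
    "generate_bundle",
    "write_bundle",
    "write_obo",
]

CC_ROOT = "GO:0005575"
BP_ROOT = "GO:0008150"

#: (label, anchor id) pairs mirrored from the localization defaults.
ANCHORS: tuple[tuple[str, str], ...] = (
    ("cytoplasm", "GO:0005737"),
    ("mitochondria", "GO:0005739"),
    ("golgi", "GO:0005794"),
    ("extracellular", "GO:0005576"),
    ("nucleus", "GO:0005634"),
    ("endoplasmic_reticulum", "GO:0005783"),
)

#: Function-branch term names per class; death terms double as the
#: coherent annotation target of the planted module.
FUNCTION_TERM_NAMES: dict[str, tuple[str, ...]] = {
    "death": (
        "programmed cell death",
        "apoptotic process",
        "regulation of programmed cell death",
        "autophagy",
        "necrotic cell death",
    ),
    "chd": (
        "inflammatory response",
        "angiogenesis",
        "heart development",
        "blood vessel remodeling",
    ),
    "lipid": (
        "lipid metabolic process",
        "cholesterol transport",
        "fatty acid beta-oxidation",
        "sterol biosynthetic process",
    ),
    "basic_metabolic": (
        "amino acid metabolic process",
        "glucose metabolic process",
        "trna aminoacylation for protein translation",
        "nucleotide biosynthetic process",
        "oxidation-reduction process",
    ),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults are the emulated study conditions."""

    n_reactions: int = 700
    n_compounds: int = 800
    n_currency: int = 6
    attachment_exponent: float = 0.5  # sublinear preferential attachment
    n_enzymes: int = 400
    n_genes: int = 2000
    mean_extra_genes_per_enzyme: float = 1.0  # genes per enzyme ~ 1 + Poisson(this)
    gene_reuse_prob: float = 0.1  # chance a gene slot reuses an existing gene
    n_samples_per_group: int = 15
    n_planted_reporter_enzymes: int = 20
    effect_size: float = 2.0  # disease-group mean shift, in SD units
    fraction_uncertain: float = 0.1
    second_compartment_prob: float = 0.1
    ontology_depth: int = 2
    ontology_branching: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_reactions, self.n_compounds, self.n_enzymes, self.n_genes) < 1:
            raise ValueError("all counts must be >= 1")
        if self.n_samples_per_group < 2:
            raise ValueError("need >= 2 samples per group")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")
        if not (0.0 <= self.fraction_uncertain <= 1.0):
            raise ValueError("fraction_uncertain must lie in [0, 1]")


@dataclass
class SyntheticBundle:
    """Everything the pipeline consumes, generated from one master seed."""

    config: SyntheticConfig
    reactions: list[Reaction]
    currency_compounds: frozenset[str]
    gene_map: GeneEnzymeMap
    ontology: nx.DiGraph
    annotations: list[Annotation]
    expression: dict[str, ExpressionDataset]  # cell type -> dataset
    planted_enzymes: list[str]
    function_terms: dict[str, list[str]] = field(default_factory=dict)


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([seed, stage])


def _enzyme_id(i: int) -> str:
    # EC-like four-field identifiers, deterministic in i
    return f"{i % 6 + 1}.{i % 9 + 1}.{i % 20 + 1}.{i + 1}"


def planted_enzyme_ids(cfg: SyntheticConfig) -> list[str]:
    """The first n_planted enzyme ids are the designated reporter cluster."""
    return [_enzyme_id(i) for i in range(cfg.n_planted_reporter_enzymes)]


def generate_reactions(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[list[Reaction], frozenset[str]]:
    """Reaction table with preferential-attachment compound reuse.

    Returns the reactions plus the ids of the currency-analogue compounds
    (heavily reused cofactor stand-ins, ``cur_*``). Background reactions
    draw 1-2 substrates, 1-2 products and 1-2 enzymes; the planted
    cluster's enzymes catalyze a dedicated circulant chain of reactions
    over their own module compounds so they are mutually adjacent and
    dense in the derived network.
    """
    if cfg.n_compounds < 2:
        raise ValueError("need >= 2 compounds")
    currency = [f"cur_{i}" for i in range(cfg.n_currency)]
    ordinary = [f"c{i:04d}" for i in range(cfg.n_compounds)]
    compounds = ordinary + currency
    # preferential-attachment weights; currency compounds start heavy
    # enough to appear in a large share of reactions even after the
    # sublinear exponent flattens the distribution
    usage = np.ones(len(compounds))
    usage[len(ordinary):] = 2000.0

    enzymes = [_enzyme_id(i) for i in range(cfg.n_enzymes)]
    planted = enzymes[: cfg.n_planted_reporter_enzymes]
    background_enzymes = enzymes[cfg.n_planted_reporter_enzymes :]

    reactions: list[Reaction] = []

    # planted circulant cluster: enzyme i consumes m_i, produces m_{i+1}, m_{i+2}
    m = len(planted)
    module_compounds = [f"mc{i:03d}" for i in range(m)]
    for i, enzyme in enumerate(planted):
        reactions.append(
            Reaction(
                reaction_id=f"RP{i:03d}",
                substrates=frozenset({module_compounds[i]}),
                products=frozenset(
                    {module_compounds[(i + 1) % m], module_compounds[(i + 2) % m]}
                ),
                enzymes=frozenset({enzyme}),
                reversible=False,
            )
        )

    def draw_compounds(k: int) -> frozenset[str]:
        weights = usage ** cfg.attachment_exponent
        probs = weights / weights.sum()
        idx = rng.choice(len(compounds), size=k, replace=False, p=probs)
        for j in idx:
            usage[j] += 1.0
        return frozenset(compounds[j] for j in idx)

    for r in range(cfg.n_reactions):
        subs = draw_compounds(int(rng.integers(1, 3)))
        prods = draw_compounds(int(rng.integers(1, 3)))
        while prods == subs:  # avoid degenerate identical sides
            prods = draw_compounds(int(rng.integers(1, 3)))
        n_ecs = int(rng.integers(1, 3))
        if r < len(background_enzymes):  # every enzyme catalyzes something
            ecs = {background_enzymes[r]}
            if n_ecs == 2:
                ecs.add(background_enzymes[int(rng.integers(len(background_enzymes)))])
        else:
            ecs = {
                background_enzymes[int(rng.integers(len(background_enzymes)))]
                for _ in range(n_ecs)
            }
        reactions.append(
            Reaction(
                reaction_id=f"R{r:04d}",
                substrates=subs,
                products=prods,
                enzymes=frozenset(ecs),
                reversible=bool(rng.random() < 0.3),
            )
        )

    # one loose bridge from the planted cluster into the background graph
    if background_enzymes and m:
        reactions.append(
            Reaction(
                reaction_id="RBRIDGE",
                substrates=frozenset({module_compounds[0]}),
                products=frozenset({ordinary[0]}),
                enzymes=frozenset({background_enzymes[0]}),
                reversible=False,
            )
        )
    return reactions, frozenset(currency)


def generate_gene_map(cfg: SyntheticConfig, rng: np.random.Generator) -> GeneEnzymeMap:
    """Many-to-many gene-to-enzyme map; planted enzymes get private genes.

    Each enzyme receives ``1 + Poisson(mean_extra_genes_per_enzyme)``
    gene slots; with probability ``gene_reuse_prob`` a background slot
    reuses an already-assigned gene (the many-to-many part). Genes of the
    planted enzymes are never shared, so the planted expression signal
    stays confined to the planted cluster.
    """
    planted = set(planted_enzyme_ids(cfg))
    pairs: list[tuple[str, str]] = []
    next_gene = 0
    assigned: list[str] = []

    def fresh_gene() -> str:
        nonlocal next_gene
        gene = f"g{next_gene:05d}"
        next_gene += 1
        return gene

    for i in range(cfg.n_enzymes):
        enzyme = _enzyme_id(i)
        n_genes = 1 + int(rng.poisson(cfg.mean_extra_genes_per_enzyme))
        chosen: set[str] = set()
        for _ in range(n_genes):
            if (
                enzyme not in planted
                and assigned
                and rng.random() < cfg.gene_reuse_prob
            ):
                gene = assigned[int(rng.integers(len(assigned)))]
            else:
                gene = fresh_gene()
            chosen.add(gene)
        for gene in sorted(chosen):
            pairs.append((gene, enzyme))
            if enzyme not in planted:
                assigned.append(gene)
    return GeneEnzymeMap(pairs)


def _go_id(n: int) -> str:
    return f"GO:{9000000 + n:07d}"


def generate_ontology_and_annotations(
    cfg: SyntheticConfig,
    enzymes: list[str],
    gene_map: GeneEnzymeMap,
    rng: np.random.Generator,
) -> tuple[nx.DiGraph, list[Annotation], dict[str, list[str]]]:
    """Toy GO DAG plus gene annotations.

    The cellular-component branch holds the six canonical compartment
    anchors under the CC root, each with a depth x branching descendant
    tree (a mix of is_a and part_of edges), plus off-anchor terms for the
    "uncertain" fraction. The biological-process branch holds function
    terms named with death / CHD / lipid / basic-metabolic keywords.

    Background enzymes get a uniformly random home compartment (a second
    one with small probability); planted enzymes are pinned to the
    mitochondria branch and their genes are annotated coherently to the
    death-branch terms. Returns (dag, annotations, function class ->
    term ids).
    """
    dag = nx.DiGraph()
    dag.add_node(CC_ROOT, name="cellular_component", namespace="cellular_component")
    dag.add_node(BP_ROOT, name="biological_process", namespace="biological_process")

    counter = 0

    def new_term(name: str, namespace: str, parent: str, relation: str = "is_a") -> str:
        nonlocal counter
        counter += 1
        term = _go_id(counter)
        dag.add_node(term, name=name, namespace=namespace)
        dag.add_edge(term, parent, relation=relation)
        return term

    anchor_descendants: dict[str, list[str]] = {}
    for label, anchor in ANCHORS:
        dag.add_node(anchor, name=label.replace("_", " "), namespace="cellular_component")
        dag.add_edge(anchor, CC_ROOT, relation="is_a")
        level = [anchor]
        descendants = [anchor]
        for depth in range(cfg.ontology_depth):
            nxt = []
            for parent in level:
                for b in range(cfg.ontology_branching):
                    rel = "part_of" if (depth + b) % 2 else "is_a"
                    child = new_term(
                        f"{label} subterm d{depth}b{b}", "cellular_component", parent, rel
                    )
                    nxt.append(child)
            level = nxt
            descendants.extend(nxt)
        anchor_descendants[label] = descendants

    # off-anchor CC terms: localize nowhere under the scheme
    off_anchor = [
        new_term(f"unanchored compartment {i}", "cellular_component", CC_ROOT)
        for i in range(4)
    ]

    function_terms: dict[str, list[str]] = {}
    for cls, names in FUNCTION_TERM_NAMES.items():
        function_terms[cls] = [
            new_term(name, "biological_process", BP_ROOT) for name in names
        ]

    planted = planted_enzyme_ids(cfg)
    planted_set = set(planted)
    labels = [label for label, _ in ANCHORS]
    annotations: list[Annotation] = []

    for i, enzyme in enumerate(sorted(enzymes)):
        genes = sorted(gene_map.genes_of(enzyme))
        if not genes:
            continue
        if enzyme in planted_set:
            uncertain = cfg.fraction_uncertain >= 1.0
            homes = ["mitochondria"]
        else:
            uncertain = bool(rng.random() < cfg.fraction_uncertain)
            homes = [labels[int(rng.integers(len(labels)))]]
            if rng.random() < cfg.second_compartment_prob:
                homes.append(labels[int(rng.integers(len(labels)))])
        for gene in genes:
            if uncertain:
                term = off_anchor[int(rng.integers(len(off_anchor)))]
                annotations.append(Annotation(gene, term, "IEA", "C"))
            else:
                for home in homes:
                    pool = anchor_descendants[home]
                    term = pool[int(rng.integers(len(pool)))]
                    annotations.append(Annotation(gene, term, "IDA", "C"))
            # function annotations (aspect P)
            if enzyme in planted_set:
                death = function_terms["death"]
                picks = rng.choice(len(death), size=min(3, len(death)), replace=False)
                for j in picks:
                    annotations.append(Annotation(gene, death[j], "IDA", "P"))
            else:
                all_terms = [t for terms in function_terms.values() for t in terms]
                for _ in range(1 + int(rng.integers(3))):
                    term = all_terms[int(rng.integers(len(all_terms)))]
                    annotations.append(Annotation(gene, term, "IEA", "P"))
    # stable order, unique records
    annotations = sorted(set(annotations))
    return dag, annotations, function_terms


def generate_expression(
    cfg: SyntheticConfig,
    gene_map: GeneEnzymeMap,
    planted_enzymes: list[str],
    rng_seed: int,
) -> dict[str, ExpressionDataset]:
    """Two cell-type datasets sharing the planted differential signal.

    Background genes are N(0, 1) in both groups; every gene of a planted
    enzyme gets a ``+effect_size`` mean shift in the disease group, in
    both datasets, so intersecting per-cell-type reporters recovers the
    planted set. Per-dataset seeds derive from the master seed, so the
    two datasets differ while sharing the planted structure.
    """
    mapped = sorted(gene_map.gene_to_enzymes)
    extra = max(0, cfg.n_genes - len(mapped))
    genes = mapped + [f"bg{i:05d}" for i in range(extra)]
    planted_genes = sorted(
        {g for e in planted_enzymes for g in gene_map.genes_of(e)}
    )
    planted_idx = [genes.index(g) for g in planted_genes]

    n = cfg.n_samples_per_group
    datasets: dict[str, ExpressionDataset] = {}
    for offset, cell_type in enumerate(["macrophage", "foam_cell"]):
        rng = _stage_rng(rng_seed, 100 + offset)
        values = rng.standard_normal((len(genes), 2 * n))
        values[np.array(planted_idx, dtype=int), :n] += cfg.effect_size
        samples = [f"{cell_type}_d{i:02d}" for i in range(n)] + [
            f"{cell_type}_c{i:02d}" for i in range(n)
        ]
        groups = pd.Series(
            ["disease"] * n + ["control"] * n, index=samples, name="group"
        )
        frame = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
        datasets[cell_type] = ExpressionDataset(
            cell_type=cell_type, values=frame, groups=groups
        )
    return datasets


def generate_bundle(cfg: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticBundle:
    """Generate the full input bundle from one master seed.

    Stage-level seeds are derived from the master so each stage is
    reproducible on its own.
    """
    cfg = cfg or SyntheticConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    reactions, currency = generate_reactions(cfg, _stage_rng(cfg.seed, 1))
    gene_map = generate_gene_map(cfg, _stage_rng(cfg.seed, 2))
    enzymes = [_enzyme_id(i) for i in range(cfg.n_enzymes)]
    dag, annotations, function_terms = generate_ontology_and_annotations(
        cfg, enzymes, gene_map, _stage_rng(cfg.seed, 3)
    )
    planted = planted_enzyme_ids(cfg)
    expression = generate_expression(cfg, gene_map, planted, cfg.seed)
    return SyntheticBundle(
        config=cfg,
        reactions=reactions,
        currency_compounds=currency,
        gene_map=gene_map,
        ontology=dag,
        annotations=annotations,
        expression=expression,
        planted_enzymes=planted,
        function_terms=function_terms,
    )


def write_obo(dag: nx.DiGraph, path: str | Path) -> None:
    """Serialize a child->parent term DAG as OBO 1.2 (obonet-readable)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("format-version: 1.2\nontology: synthetic\n")
        for term in sorted(dag.nodes):
            data = dag.nodes[term]
            handle.write(f"\n[Term]\nid: {term}\n")
            handle.write(f"name: {data.get('name', term)}\n")
            handle.write(f"namespace: {data.get('namespace', '')}\n")
            for _, parent, edata in sorted(dag.out_edges(term, data=True)):
                if edata.get("relation") == "part_of":
                    handle.write(f"relationship: part_of {parent}\n")
                else:
                    handle.write(f"is_a: {parent}\n")


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle to a directory; returns artifact name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reactions": outdir / "reactions.tsv",
        "ontology": outdir / "ontology.obo",
        "annotations": outdir / "annotations.gaf",
        "gene_map": outdir / "gene_map.tsv",
        "currency": outdir / "currency_compounds.txt",
        "planted": outdir / "planted_enzymes.txt",
    }
    write_reactions(bundle.reactions, paths["reactions"])
    write_obo(bundle.ontology, paths["ontology"])
    write_gaf(bundle.annotations, paths["annotations"])
    write_gene_enzyme_map(bundle.gene_map, paths["gene_map"])
    paths["currency"].write_text("\n".join(sorted(bundle.currency_compounds)) + "\n")
    paths["planted"].write_text("\n".join(bundle.planted_enzymes) + "\n")
    for cell_type, ds in bundle.expression.items():
        mpath = outdir / f"expression_{cell_type}.tsv"
        gpath = outdir / f"groups_{cell_type}.tsv"
        ds.values.to_csv(mpath, sep="\t", float_format="%.6g")
        ds.groups.rename_axis("sample").reset_index().to_csv(gpath, sep="\t", index=False)
        paths[f"expression_{cell_type}"] = mpath
        paths[f"groups_{cell_type}"] = gpath
    return paths
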