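"""Readers and validators for the pipeline's input artifacts.

Four kinds of input are consumed downstream: a metabolic reaction table
(TSV, optionally converted from SBML), a Gene Ontology OBO file plus GAF
protein annotations for subcellular localization, a gene-to-enzyme (EC
number) mapping, and per-cell-type expression matrices (or precomputed
gene-level P-value tables).

The reaction TSV dialect is the canonical on-disk form: UTF-8, header row
``reaction_id  substrates  products  ec_numbers  reversible``, with
multi-valued cells joined by ``;`` and reversibility given as the literals
``true``/``false``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, NamedTuple

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from Bio.UniProt import GOA
from scipy import stats

__all__ = [
    "Reaction",
    "GeneEnzymeMap",
    "ExpressionDataset",
    "Annotation",
    "FormatError",
    "ValidationError",
    "read_reactions",
    "write_reactions",
    "read_gaf",
    "write_gaf",
    "read_obo",
    "read_gene_enzyme_map",
    "write_gene_enzyme_map",
    "read_expression",
    "read_gene_pvalues",
    "write_gene_pvalues",
    "gene_pvalues_from_expression",
    "validate_pvalues",
]

#: Floor applied to P-values before inverse-normal conversion; the standard
#: normal quantile of exactly 0 is +inf.
P_FLOOR = 1e-300

REACTION_COLUMNS = ["reaction_id", "substrates", "products", "ec_numbers", "reversible"]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """A file parses but violates a content invariant."""


@dataclass(frozen=True)
class Reaction:
    """A metabolic reaction: compounds in and out plus catalyzing enzymes.

    Compound ids are namespace-free opaque strings compared by exact match.
    ``enzymes`` holds EC-number strings, partial ECs ("1.1.1.-") included;
    it may be empty for spontaneous reactions, which are retained on read
    and contribute nothing at network construction.
    """

    reaction_id: str
    substrates: frozenset[str]
    products: frozenset[str]
    enzymes: frozenset[str] = frozenset()
    reversible: bool = False

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise ValidationError(
                f"reaction {self.reaction_id!r}: substrates and products must be non-empty"
            )


class Annotation(NamedTuple):
    """One GAF record reduced to the fields the pipeline uses."""

    object_id: str
    term_id: str
    evidence: str
    aspect: str  # GAF aspect column: C, F or P


@dataclass
class GeneEnzymeMap:
    """Many-to-many gene <-> enzyme (EC number) mapping.

    ``k(E) = len(enzyme_to_genes[E])`` is the gene count that indexes the
    background null during reporter scoring.
    """

    pairs: list[tuple[str, str]]
    gene_to_enzymes: dict[str, set[str]] = field(init=False, repr=False)
    enzyme_to_genes: dict[str, set[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.gene_to_enzymes = {}
        self.enzyme_to_genes = {}
        for gene, ec in self.pairs:
            self.gene_to_enzymes.setdefault(gene, set()).add(ec)
            self.enzyme_to_genes.setdefault(ec, set()).add(gene)

    def genes_of(self, enzyme: str) -> set[str]:
        return self.enzyme_to_genes.get(enzyme, set())


@dataclass
class ExpressionDataset:
    """A two-group (disease vs control) expression matrix for one cell type."""

    cell_type: str
    values: pd.DataFrame  # genes x samples
    groups: pd.Series  # sample -> "disease" | "control"

    def __post_init__(self) -> None:
        if set(self.values.columns) != set(self.groups.index):
            raise ValidationError(
                f"{self.cell_type}: sample columns and group labels disagree"
            )
        labels = set(self.groups.unique())
        if not labels <= {"disease", "control"} or len(labels) != 2:
            raise ValidationError(
                f"{self.cell_type}: need both 'disease' and 'control' groups, got {sorted(labels)}"
            )
        if self.values.index.hasnans or self.values.index.duplicated().any():
            raise ValidationError(f"{self.cell_type}: gene ids missing or duplicated")

    @property
    def n_disease(self) -> int:
        return int((self.groups == "disease").sum())

    @property
    def n_control(self) -> int:
        return int((self.groups == "control").sum())


def _split_multi(cell: str) -> frozenset[str]:
    return frozenset(tok.strip() for tok in cell.split(";") if tok.strip())


def read_reactions(path: str | Path, dialect: Literal["tsv", "sbml"] = "tsv") -> list[Reaction]:
    """Read the reaction table into :class:`Reaction` records.

    ``dialect="sbml"`` accepts an SBML level-2/3 file and converts it on
    the fly to the same records (see :func:`reactions_from_sbml`).
    """
    path = Path(path)
    if dialect == "sbml":
        return reactions_from_sbml(path)
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = [c for c in REACTION_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        reactions: list[Reaction] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            rid = row["reaction_id"].strip()
            if rid in seen:
                raise ValidationError(f"{path}: duplicate reaction_id {rid!r}")
            seen.add(rid)
            substrates = _split_multi(row["substrates"])
            products = _split_multi(row["products"])
            if not substrates or not products:
                raise ValidationError(
                    f"{path}: row {lineno}: empty substrate or product cell"
                )
            rev_literal = row["reversible"].strip().lower()
            if rev_literal not in ("true", "false"):
                raise FormatError(
                    f"{path}: row {lineno}: reversible must be 'true' or 'false'"
                )
            reactions.append(
                Reaction(
                    reaction_id=rid,
                    substrates=substrates,
                    products=products,
                    enzymes=_split_multi(row["ec_numbers"]),
                    reversible=rev_literal == "true",
                )
            )
    return reactions


def write_reactions(reactions: Iterable[Reaction], path: str | Path) -> None:
    """Write reactions in the canonical TSV dialect (round-trips with read)."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(REACTION_COLUMNS)
        for r in reactions:
            writer.writerow(
                [
                    r.reaction_id,
                    ";".join(sorted(r.substrates)),
                    ";".join(sorted(r.products)),
                    ";".join(sorted(r.enzymes)),
                    "true" if r.reversible else "false",
                ]
            )


def reactions_from_sbml(path: str | Path) -> list[Reaction]:
    """Thin SBML -> Reaction converter (the TSV dialect is canonical).

    Species ids become opaque compound ids; EC numbers are taken from
    ``ec-code`` annotations or, failing that, from a reaction note of the
    form ``EC: a.b.c.d``.
    """
    import re
    from xml.etree import ElementTree

    tree = ElementTree.parse(path)
    ns = {"s": tree.getroot().tag.split("}")[0].strip("{")}
    reactions = []
    for rx in tree.getroot().iter(f"{{{ns['s']}}}reaction"):
        rid = rx.get("id")
        subs = frozenset(
            ref.get("species")
            for ref in rx.findall(f"./{{{ns['s']}}}listOfReactants/{{{ns['s']}}}speciesReference")
        )
        prods = frozenset(
            ref.get("species")
            for ref in rx.findall(f"./{{{ns['s']}}}listOfProducts/{{{ns['s']}}}speciesReference")
        )
        blob = ElementTree.tostring(rx, encoding="unicode")
        ecs = frozenset(
            m.group(1)
            for m in re.finditer(r"(?:ec-code[:/]|EC[:\s]+)(\d+\.\d+\.\d+\.(?:\d+|-))", blob)
        )
        reversible = rx.get("reversible", "true").lower() == "true"
        reactions.append(Reaction(rid, subs, prods, ecs, reversible))
    return reactions


def read_gaf(path: str | Path) -> list[Annotation]:
    """Read a GAF 2.x annotation file.

    Records whose qualifier contains NOT are dropped; comment lines
    (leading ``!``) are ignored. Returns ``(object id, GO id, evidence,
    aspect)`` tuples.
    """
    annotations: list[Annotation] = []
    with open(path, encoding="utf-8") as handle:
        try:
            for rec in GOA.gafiterator(handle):
                if "NOT" in rec.get("Qualifier", []):
                    continue
                annotations.append(
                    Annotation(
                        rec["DB_Object_ID"], rec["GO_ID"], rec["Evidence"], rec["Aspect"]
                    )
                )
        except (KeyError, IndexError, ValueError) as exc:
            raise FormatError(f"{path}: malformed GAF record ({exc})") from exc
    return annotations


def write_gaf(annotations: Iterable[Annotation], path: str | Path, db: str = "SYN") -> None:
    """Write annotations as a minimal GAF 2.2 file (round-trips with read)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("!gaf-version: 2.2\n")
        for a in annotations:
            cols = [""] * 17
            cols[0] = db
            cols[1] = a.object_id
            cols[2] = a.object_id
            cols[3] = "involved_in" if a.aspect == "P" else "located_in"
            cols[4] = a.term_id
            cols[5] = "REF:0"
            cols[6] = a.evidence
            cols[8] = a.aspect
            cols[9] = a.object_id
            cols[11] = "protein"
            cols[12] = "taxon:9606"
            cols[13] = "20140101"
            cols[14] = db
            handle.write("\t".join(cols) + "\n")


def read_obo(path: str | Path) -> nx.DiGraph:
    """Read an OBO 1.2 ontology into a child->parent DiGraph.

    Both ``is_a`` and ``part_of`` relationships become edges; all other
    relationship types are dropped, as are obsolete terms. Node attributes
    carry ``name`` and ``namespace``.
    """
    multi = obonet.read_obo(path)
    dag = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        dag.add_node(node, name=data.get("name", ""), namespace=data.get("namespace", ""))
    for child, parent, rel in multi.edges(keys=True):
        if rel in ("is_a", "part_of"):
            dag.add_edge(child, parent, relation=rel)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise ValidationError(f"{path}: ontology contains a cycle: {cycle}")
    return dag


def read_gene_enzyme_map(path: str | Path) -> GeneEnzymeMap:
    """Read a two-column (gene, EC number) TSV with header ``gene\\tec_number``."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene", "ec_number"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return GeneEnzymeMap(list(frame[["gene", "ec_number"]].itertuples(index=False, name=None)))


def write_gene_enzyme_map(gene_map: GeneEnzymeMap, path: str | Path) -> None:
    pd.DataFrame(gene_map.pairs, columns=["gene", "ec_number"]).to_csv(
        path, sep="\t", index=False
    )


def read_expression(
    matrix_path: str | Path, groups_path: str | Path, cell_type: str
) -> ExpressionDataset:
    """Read an expression matrix TSV (first column gene id, remaining columns
    samples) plus its two-column ``sample\\tgroup`` companion file."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    groups_frame = pd.read_csv(groups_path, sep="\t", dtype=str)
    if list(groups_frame.columns[:2]) != ["sample", "group"]:
        raise FormatError(f"{groups_path}: expected columns 'sample' and 'group'")
    groups = groups_frame.set_index("sample")["group"]
    return ExpressionDataset(cell_type=cell_type, values=values, groups=groups)


def validate_pvalues(pvals: dict[str, float]) -> dict[str, float]:
    for gene, p in pvals.items():
        if not (0.0 < p <= 1.0):
            raise ValidationError(f"gene {gene!r}: P-value {p} outside (0, 1]")
    return pvals


def read_gene_pvalues(path: str | Path) -> dict[str, float]:
    """Read a two-column ``gene\\tp_value`` TSV into a gene -> P mapping."""
    frame = pd.read_csv(path, sep="\t")
    if list(frame.columns[:2]) != ["gene", "p_value"]:
        raise FormatError(f"{path}: expected columns 'gene' and 'p_value'")
    return validate_pvalues(dict(zip(frame["gene"].astype(str), frame["p_value"].astype(float))))


def write_gene_pvalues(pvals: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"gene": list(pvals.keys()), "p_value": list(pvals.values())}
    ).to_csv(path, sep="\t", index=False)


def gene_pvalues_from_expression(
    ds: ExpressionDataset, method: Literal["welch_t", "wilcoxon"] = "welch_t"
) -> dict[str, float]:
    """Two-sided gene-level differential-expression P-values.

    Welch's t (default) or the Wilcoxon rank-sum test, disease vs control.
    A gene with zero variance in both groups and equal means gets P = 1 by
    convention. P-values are clamped to ``[P_FLOOR, 1]`` so the downstream
    inverse-normal transform stays finite.
    """
    disease = ds.values.loc[:, ds.groups[ds.groups == "disease"].index].to_numpy(float)
    control = ds.values.loc[:, ds.groups[ds.groups == "control"].index].to_numpy(float)
    if disease.shape[1] < 2 or control.shape[1] < 2:
        raise ValidationError(f"{ds.cell_type}: need >=2 samples per group")
    if method == "welch_t":
        res = stats.ttest_ind(disease, control, axis=1, equal_var=False)
        pvals = np.asarray(res.pvalue, dtype=float)
    elif method == "wilcoxon":
        res = stats.mannwhitneyu(disease, control, axis=1, alternative="two-sided")
        pvals = np.asarray(res.pvalue, dtype=float)
    else:
        raise ValueError(f"unknown method {method!r}")
    pvals = np.where(np.isnan(pvals), 1.0, pvals)  # constant genes
    pvals = np.clip(pvals, P_FLOOR, 1.0)
    return dict(zip(ds.values.index.astype(str), pvals))
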