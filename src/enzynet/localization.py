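"""Subcellular localization of enzymes via GO cellular-component backtracking.

Each enzyme's proteins carry GO cellular-component annotations; every
annotated term is backtracked through the ontology's is_a/part_of
hierarchy, and the enzyme is assigned to each of the six anchor
compartments (cytoplasm, mitochondria, Golgi, extracellular, nucleus,
endoplasmic reticulum) found among the term's ancestors. Enzymes whose
annotations reach no anchor land in the "uncertain" bucket and are
screened out of the compartment subnetworks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .io import Annotation, GeneEnzymeMap
from .network import EnzymeNetwork

__all__ = [
    "DEFAULT_COMPARTMENTS",
    "CompartmentScheme",
    "CompartmentPartition",
    "backtrack_term",
    "partition_enzymes",
    "compartment_subnetwork",
    "write_partition",
]

logger = logging.getLogger(__name__)

#: Canonical GO cellular-component ids for the six compartments.
DEFAULT_COMPARTMENTS: tuple[tuple[str, str], ...] = (
    ("cytoplasm", "GO:0005737"),
    ("mitochondria", "GO:0005739"),
    ("golgi", "GO:0005794"),
    ("extracellular", "GO:0005576"),
    ("nucleus", "GO:0005634"),
    ("endoplasmic_reticulum", "GO:0005783"),
)


@dataclass(frozen=True)
class CompartmentScheme:
    """Ordered (label, anchor GO term) pairs defining the compartments."""

    anchors: tuple[tuple[str, str], ...] = DEFAULT_COMPARTMENTS

    def __post_init__(self) -> None:
        labels = [label for label, _ in self.anchors]
        if len(set(labels)) != len(labels):
            raise ValueError("compartment labels must be unique")

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.anchors]

    @property
    def anchor_to_label(self) -> dict[str, str]:
        return {term: label for label, term in self.anchors}

    def validate_against(self, dag: nx.DiGraph) -> None:
        missing = [term for _, term in self.anchors if term not in dag]
        if missing:
            raise KeyError(f"anchor term(s) not in ontology: {missing}")


@dataclass
class CompartmentPartition:
    """Enzyme -> compartment labels, with an explicit uncertain bucket.

    Every enzyme of the partitioned network appears either with >=1
    compartment or in ``uncertain``, never both.
    """

    compartments: dict[str, set[str]]
    uncertain: set[str] = field(default_factory=set)

    def members(self, label: str) -> set[str]:
        return {e for e, labels in self.compartments.items() if label in labels}


def backtrack_term(term: str, dag: nx.DiGraph, scheme: CompartmentScheme) -> set[str]:
    """Compartment labels whose anchor is the term itself or an ancestor.

    The ontology graph points child -> parent, so ancestors are the
    graph-descendants of ``term``.
    """
    if term not in dag:
        raise KeyError(f"term {term!r} not in ontology")
    ancestors = nx.descendants(dag, term) | {term}
    anchor_to_label = scheme.anchor_to_label
    return {anchor_to_label[t] for t in ancestors if t in anchor_to_label}


def partition_enzymes(
    net: EnzymeNetwork,
    annotations: list[Annotation],
    gene_map: GeneEnzymeMap,
    dag: nx.DiGraph,
    scheme: CompartmentScheme = CompartmentScheme(),
    exclude_evidence_codes: frozenset[str] = frozenset(),
) -> CompartmentPartition:
    """Assign every network enzyme to compartments (or "uncertain").

    An enzyme's compartment set is the union of :func:`backtrack_term`
    over all cellular-component terms annotated to any of its mapped
    genes/proteins. Multi-compartment membership is allowed. Annotations
    to terms absent from the ontology (e.g. filtered obsoletes) are
    skipped.
    """
    scheme.validate_against(dag)
    by_object: dict[str, list[Annotation]] = {}
    for a in annotations:
        if a.aspect == "C" and a.evidence not in exclude_evidence_codes:
            by_object.setdefault(a.object_id, []).append(a)

    term_cache: dict[str, set[str]] = {}
    compartments: dict[str, set[str]] = {}
    uncertain: set[str] = set()
    for enzyme in sorted(net.enzymes):
        genes = gene_map.genes_of(enzyme)
        if not genes:
            logger.info("enzyme %s has no mapped genes; classified uncertain", enzyme)
            uncertain.add(enzyme)
            continue
        labels: set[str] = set()
        for gene in genes:
            for a in by_object.get(gene, ()):
                if a.term_id not in dag:
                    continue
                if a.term_id not in term_cache:
                    term_cache[a.term_id] = backtrack_term(a.term_id, dag, scheme)
                labels |= term_cache[a.term_id]
        if labels:
            compartments[enzyme] = labels
        else:
            uncertain.add(enzyme)
    return CompartmentPartition(compartments=compartments, uncertain=uncertain)


def compartment_subnetwork(
    net: EnzymeNetwork,
    part: CompartmentPartition,
    label: str,
    scheme: CompartmentScheme = CompartmentScheme(),
) -> EnzymeNetwork:
    """Induced subgraph on the enzymes localized to ``label``.

    Uncertain enzymes are never included; an enzyme localized to several
    compartments appears in each subnetwork. A label outside the scheme is
    a lookup error (an empty subnetwork for a scheme label is not).
    """
    if label not in scheme.labels:
        raise KeyError(f"unknown compartment label {label!r}")
    members = part.members(label)
    sub = net.graph.subgraph(members).copy()
    return EnzymeNetwork(graph=sub, label=f"{net.label}:{label}", compartment=label)


def write_partition(part: CompartmentPartition, path: str | Path) -> None:
    """Two-column TSV: enzyme, ';'-joined compartments or 'uncertain'."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("enzyme\tcompartments\n")
        rows = [(e, ";".join(sorted(labels))) for e, labels in part.compartments.items()]
        rows += [(e, "uncertain") for e in part.uncertain]
        for enzyme, labels in sorted(rows):
            handle.write(f"{enzyme}\t{labels}\n")
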