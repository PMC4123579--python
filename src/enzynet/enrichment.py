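"""Hypergeometric term enrichment with BH-FDR, and function-class labelling.

Module gene sets are tested term-by-term against a background universe
(by default all genes mapped to enzymes of the network under analysis)
with the upper-tail hypergeometric test; P-values are adjusted by
Benjamini-Hochberg within each module (one FDR family per module).
Significant terms are then classified into four function classes —
programmed cell death, CHD pathogenesis, lipid metabolism, and basic
metabolism — by an editable scheme of term ids and name keywords.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "FunctionClassScheme",
    "hypergeom_enrich",
    "bh_fdr",
    "classify_terms",
    "load_function_classes",
    "write_enrichment",
]

FUNCTION_CLASS_LABELS = ("basic_metabolic", "lipid", "chd", "death")


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's enrichment in one module's gene set."""

    term_id: str
    term_name: str
    hits: int
    module_size: int
    term_size: int
    universe_size: int
    p: float
    fdr: float
    function_class: str = "unclassified"


@dataclass(frozen=True)
class FunctionClassScheme:
    """Ordered class -> (term ids, name keywords) classification scheme.

    Classes are tried in order; within a class pass, explicit term-id
    membership takes precedence over keyword matching against the term
    name (case-insensitive substring).
    """

    classes: tuple[tuple[str, frozenset[str], tuple[str, ...]], ...]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Mapping[str, Sequence[str]]]) -> "FunctionClassScheme":
        entries = []
        for label, spec in mapping.items():
            if label not in FUNCTION_CLASS_LABELS:
                raise ValueError(
                    f"unknown function class {label!r}; expected one of {FUNCTION_CLASS_LABELS}"
                )
            entries.append(
                (
                    label,
                    frozenset(spec.get("term_ids", ()) or ()),
                    tuple(k.lower() for k in (spec.get("keywords", ()) or ())),
                )
            )
        if not entries:
            raise ValueError("function-class scheme is empty")
        return cls(classes=tuple(entries))

    def classify(self, term_id: str, term_name: str) -> str:
        name = term_name.lower()
        for label, term_ids, _ in self.classes:
            if term_id in term_ids:
                return label
        for label, _, keywords in self.classes:
            if any(k in name for k in keywords):
                return label
        return "unclassified"


def load_function_classes(path: str | Path | None = None) -> FunctionClassScheme:
    """Load the classification scheme from YAML (bundled default if None)."""
    if path is None:
        text = (
            importlib_resources.files("enzynet.resources")
            .joinpath("function_classes.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    return FunctionClassScheme.from_mapping(yaml.safe_load(text))


def bh_fdr(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return []
    if np.any(arr <= 0.0) or np.any(arr > 1.0):
        raise ValueError("P-values must lie in (0, 1]")
    return list(multipletests(arr, method="fdr_bh")[1])


def hypergeom_enrich(
    module_genes: set[str],
    term_to_genes: Mapping[str, set[str]],
    universe: set[str],
    term_names: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of every term with >= 1 hit.

    Term gene sets are intersected with the universe before testing; the
    module must be a subset of the universe. BH-FDR is computed across
    all tested (>=1 hit) terms of this module.
    """
    if not universe:
        raise ValueError("empty enrichment universe")
    if not module_genes <= universe:
        raise ValueError("module genes must be a subset of the universe")
    names = term_names or {}
    M, N = len(universe), len(module_genes)
    tested: list[tuple[str, int, int]] = []
    for term in sorted(term_to_genes):
        term_set = set(term_to_genes[term]) & universe
        hits = len(term_set & module_genes)
        if hits >= 1:
            tested.append((term, hits, len(term_set)))
    if not tested:
        return []
    pvals = [stats.hypergeom.sf(hits - 1, M, n, N) for _, hits, n in tested]
    fdrs = bh_fdr([min(p, 1.0) for p in pvals])
    return [
        EnrichmentResult(
            term_id=term,
            term_name=names.get(term, ""),
            hits=hits,
            module_size=N,
            term_size=n,
            universe_size=M,
            p=float(min(p, 1.0)),
            fdr=float(fdr),
        )
        for (term, hits, n), p, fdr in zip(tested, pvals, fdrs)
    ]


def classify_terms(
    results: Sequence[EnrichmentResult], scheme: FunctionClassScheme
) -> list[EnrichmentResult]:
    """Attach a function class to each enrichment result."""
    return [
        replace(r, function_class=scheme.classify(r.term_id, r.term_name))
        for r in results
    ]


def class_counts(
    results: Sequence[EnrichmentResult], fdr_alpha: float = 0.05
) -> dict[str, int]:
    """Significant-term count per function class (FDR < alpha)."""
    counts = {label: 0 for label in FUNCTION_CLASS_LABELS}
    counts["unclassified"] = 0
    for r in results:
        if r.fdr < fdr_alpha:
            counts[r.function_class] += 1
    return counts


def write_enrichment(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(
            "term_id\tterm_name\thits\tmodule_size\tterm_size\tuniverse_size\tp\tfdr\tclass\n"
        )
        for r in results:
            handle.write(
                f"{r.term_id}\t{r.term_name}\t{r.hits}\t{r.module_size}\t{r.term_size}\t"
                f"{r.universe_size}\t{r.p:.6g}\t{r.fdr:.6g}\t{r.function_class}\n"
            )
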