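"""Gene-neighborhood extraction and functional-category ratios.

The five nearest annotated genes on each side of a focal gene (by gene rank
on the scaffold, not bp distance) are collected and assigned to one of three
broad biological-process categories — metabolism, signaling/cell function,
genetic information processing — or "unknown", by a first-match keyword
table over the free-text product annotation. Inside-vs-outside category
ratios then contrast the neighborhoods of homologs within clusters against
those elsewhere in the genome.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .io_formats import GeneFeature, GenomeAnnotation

__all__ = [
    "NeighborSet",
    "CategoryAssignment",
    "CATEGORIES",
    "DEFAULT_CATEGORY_RULES",
    "nearest_neighbors",
    "assign_categories",
    "inside_outside_ratio",
]

CATEGORIES = (
    "metabolism",
    "signaling_cell_function",
    "genetic_information_processing",
    "unknown",
)

# Ordered first-match-wins keyword rules (keyword, category, subcategory).
# Transport/defense outranks metabolism so that e.g. "ABC transporter
# permease" is not caught by a broader enzymatic keyword.
DEFAULT_CATEGORY_RULES: tuple[tuple[str, str, str], ...] = (
    ("abc transporter", "signaling_cell_function", "defense-transport"),
    ("permease", "signaling_cell_function", "defense-transport"),
    ("efflux", "signaling_cell_function", "defense-transport"),
    ("transporter", "signaling_cell_function", "defense-transport"),
    ("antiporter", "signaling_cell_function", "defense-transport"),
    ("two-component", "signaling_cell_function", "signaling"),
    ("histidine kinase", "signaling_cell_function", "signaling"),
    ("kinase", "signaling_cell_function", "signaling"),
    ("sigma factor", "signaling_cell_function", "regulation"),
    ("regulator", "signaling_cell_function", "regulation"),
    ("cell wall", "signaling_cell_function", "cell-envelope"),
    ("cell division", "signaling_cell_function", "cell-cycle"),
    ("glycosylase", "genetic_information_processing", "dna-repair"),
    ("dna repair", "genetic_information_processing", "dna-repair"),
    ("excinuclease", "genetic_information_processing", "dna-repair"),
    ("helicase", "genetic_information_processing", "replication"),
    ("polymerase", "genetic_information_processing", "replication"),
    ("topoisomerase", "genetic_information_processing", "replication"),
    ("recombinase", "genetic_information_processing", "recombination"),
    ("ribosom", "genetic_information_processing", "translation"),
    ("trna", "genetic_information_processing", "translation"),
    ("transcription", "genetic_information_processing", "transcription"),
    ("nuclease", "genetic_information_processing", "dna-repair"),
    ("polyketide synthase", "metabolism", "secondary-metabolism"),
    ("nonribosomal peptide", "metabolism", "secondary-metabolism"),
    ("terpene", "metabolism", "secondary-metabolism"),
    ("cytochrome p450", "metabolism", "oxidation"),
    ("synthase", "metabolism", "biosynthesis"),
    ("synthetase", "metabolism", "biosynthesis"),
    ("dehydrogenase", "metabolism", "oxidation-reduction"),
    ("reductase", "metabolism", "oxidation-reduction"),
    ("oxidase", "metabolism", "oxidation-reduction"),
    ("oxidoreductase", "metabolism", "oxidation-reduction"),
    ("acetyltransferase", "metabolism", "transfer"),
    ("methyltransferase", "metabolism", "transfer"),
    ("transferase", "metabolism", "transfer"),
    ("hydrolase", "metabolism", "hydrolysis"),
    ("isomerase", "metabolism", "isomerization"),
)


@dataclass
class NeighborSet:
    focal_gene_id: str
    upstream: list[GeneFeature] = field(default_factory=list)  # increasing distance
    downstream: list[GeneFeature] = field(default_factory=list)

    @property
    def all_neighbors(self) -> list[GeneFeature]:
        return list(self.upstream) + list(self.downstream)


@dataclass
class CategoryAssignment:
    gene_id: str
    category: str
    subcategory: str = ""


def nearest_neighbors(
    focal: GeneFeature | str, annotation: GenomeAnnotation, k: int = 5
) -> NeighborSet:
    """Up to ``k`` genes on each side of the focal gene by genomic rank on
    its scaffold; fewer are returned near scaffold ends. Upstream neighbors
    (lower coordinates) and downstream neighbors are each ordered by
    increasing distance from the focal gene."""
    if isinstance(focal, str):
        focal = annotation.get(focal)
    ladder = annotation.genes_on(focal.scaffold_id)
    try:
        idx = next(i for i, g in enumerate(ladder) if g.gene_id == focal.gene_id)
    except StopIteration:
        raise ValueError(f"focal gene {focal.gene_id!r} absent from annotation")
    upstream = ladder[max(0, idx - k) : idx][::-1]
    downstream = ladder[idx + 1 : idx + 1 + k]
    return NeighborSet(focal.gene_id, upstream, downstream)


def assign_categories(
    neighbors: Sequence[GeneFeature] | NeighborSet,
    rules: Sequence[tuple[str, str, str]] = DEFAULT_CATEGORY_RULES,
    multi: bool = False,
) -> list[CategoryAssignment]:
    """Assign each neighbor to a functional category by keyword lookup.

    First matching rule wins; no match (or empty annotation) -> unknown.
    With ``multi`` a gene matching several rules contributes one assignment
    per distinct category (the replicate-every-term convention); the default
    single-assignment mode conserves counts.
    """
    genes = neighbors.all_neighbors if isinstance(neighbors, NeighborSet) else neighbors
    out: list[CategoryAssignment] = []
    for g in genes:
        text = g.annotation.lower()
        matched: list[tuple[str, str]] = []
        for keyword, category, subcategory in rules:
            if keyword in text:
                if not multi:
                    matched = [(category, subcategory)]
                    break
                if category not in {m[0] for m in matched}:
                    matched.append((category, subcategory))
        if not matched:
            matched = [("unknown", "")]
        out.extend(CategoryAssignment(g.gene_id, c, s) for c, s in matched)
    return out


def inside_outside_ratio(
    assignments_inside: Sequence[CategoryAssignment],
    assignments_outside: Sequence[CategoryAssignment],
) -> dict[str, tuple[int, int, Optional[float]]]:
    """Per-category (count_inside, count_outside, inside/outside ratio).

    Categories absent from both sides are omitted; a category with zero
    outside count has an undefined ratio, reported as None.
    """
    if not assignments_inside or not assignments_outside:
        raise ValueError("both assignment lists must be nonempty")
    ci = Counter(a.category for a in assignments_inside)
    co = Counter(a.category for a in assignments_outside)
    out: dict[str, tuple[int, int, Optional[float]]] = {}
    for cat in CATEGORIES:
        i, o = ci.get(cat, 0), co.get(cat, 0)
        if i == 0 and o == 0:
            continue
        out[cat] = (i, o, (i / o) if o else None)
    return out
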