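"""Gene-to-cluster proximity: signed distances, nearest-BGC search, the
within-5-genes-or-2-kb membership rule, and distance-distribution comparison.

Distance is the gap between the closest interval boundaries, 0 for any
overlap (touching half-open intervals also have gap 0). The sign places the
gene relative to the cluster in scaffold coordinates: positive when the gene
lies on the lower-coordinate (5′) side of the cluster, negative on the
higher-coordinate (3′) side. Only clusters on the gene's own scaffold and
strictly closer than 2 Mbp qualify as "nearest".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io_formats import BgcInterval, GeneFeature, GenomeAnnotation

__all__ = [
    "ProximityResult",
    "DistanceSummary",
    "signed_distance",
    "count_intervening_genes",
    "is_inside",
    "nearest_bgc",
    "distance_summary",
    "compare_distance_distributions",
    "DEFAULT_MAX_DISTANCE",
    "DEFAULT_INSIDE_BP",
    "DEFAULT_INSIDE_GENES",
    "DEFAULT_BIN_EDGES",
]

DEFAULT_MAX_DISTANCE = 2_000_000  # strictly-less-than cap, same scaffold only
DEFAULT_INSIDE_BP = 2_000
DEFAULT_INSIDE_GENES = 5
# landmark thresholds: inside / 2 kb rule / 20 kb depletion / display range
DEFAULT_BIN_EDGES = (0, 2_000, 20_000, 100_000)


@dataclass
class ProximityResult:
    gene_id: str
    genome_id: str
    scaffold_id: str
    nearest_bgc_id: Optional[str]
    signed_distance: Optional[int]
    intervening_genes: Optional[int]
    inside: bool
    subfamily: str = ""


@dataclass
class DistanceSummary:
    subfamily: str
    n: int
    n_unassigned: int = 0
    mean_abs: Optional[float] = None
    median_abs: Optional[float] = None
    q1_abs: Optional[float] = None
    q3_abs: Optional[float] = None
    mean_signed: Optional[float] = None
    median_signed: Optional[float] = None
    q1_signed: Optional[float] = None
    q3_signed: Optional[float] = None


def signed_distance(gene: GeneFeature, bgc: BgcInterval) -> int:
    """Boundary gap between gene and cluster; 0 for any overlap.

    Positive: gene on the 5′ (lower-coordinate) side of the cluster.
    Negative: gene on the 3′ (higher-coordinate) side.
    """
    if gene.scaffold_id != bgc.scaffold_id:
        raise ValueError(
            f"gene {gene.gene_id} on {gene.scaffold_id} vs BGC {bgc.bgc_id} "
            f"on {bgc.scaffold_id}: different scaffolds"
        )
    if gene.start < bgc.end and bgc.start < gene.end:
        return 0
    if gene.end <= bgc.start:
        return bgc.start - gene.end
    return -(gene.start - bgc.end)


def count_intervening_genes(
    gene: GeneFeature, bgc: BgcInterval, annotation: GenomeAnnotation
) -> int:
    """Annotated genes lying strictly between the facing boundaries of gene
    and cluster (any strand; a gene counts when its whole interval fits in
    the gap)."""
    d = signed_distance(gene, bgc)
    if d == 0:
        return 0
    lo, hi = (gene.end, bgc.start) if d > 0 else (bgc.end, gene.start)
    return sum(
        1
        for g in annotation.genes_on(gene.scaffold_id)
        if g.gene_id != gene.gene_id and g.start >= lo and g.end <= hi
    )


def is_inside(
    distance: int,
    intervening_genes: int,
    inside_bp: int = DEFAULT_INSIDE_BP,
    inside_genes: int = DEFAULT_INSIDE_GENES,
) -> bool:
    """Cluster-membership rule: within the cluster (distance 0), or within
    2 kb, or within 5 genes of the cluster boundary — a disjunction of
    sufficient conditions."""
    return (
        distance == 0
        or abs(distance) <= inside_bp
        or intervening_genes <= inside_genes
    )


def nearest_bgc(
    gene: GeneFeature,
    bgcs: Sequence[BgcInterval],
    annotation: GenomeAnnotation,
    max_distance: int = DEFAULT_MAX_DISTANCE,
    inside_bp: int = DEFAULT_INSIDE_BP,
    inside_genes: int = DEFAULT_INSIDE_GENES,
    subfamily: str = "",
) -> ProximityResult:
    """Nearest same-scaffold cluster strictly within ``max_distance``.

    Ties on |distance| break toward the 5′ side (positive sign), then
    lexicographic bgc_id. No qualifying cluster -> nearest_bgc_id None,
    inside False.
    """
    candidates = []
    for b in bgcs:
        if b.scaffold_id != gene.scaffold_id:
            continue
        d = signed_distance(gene, b)
        if abs(d) < max_distance:
            candidates.append((abs(d), 0 if d >= 0 else 1, b.bgc_id, d, b))
    if not candidates:
        return ProximityResult(
            gene.gene_id, gene.genome_id, gene.scaffold_id,
            None, None, None, False, subfamily,
        )
    candidates.sort(key=lambda c: c[:3])
    _, _, _, d, best = candidates[0]
    m = count_intervening_genes(gene, best, annotation)
    return ProximityResult(
        gene.gene_id,
        gene.genome_id,
        gene.scaffold_id,
        best.bgc_id,
        d,
        m,
        is_inside(d, m, inside_bp, inside_genes),
        subfamily,
    )


def distance_summary(
    results: Sequence[ProximityResult], subfamily: str
) -> DistanceSummary:
    """n, mean, median and quartiles of signed and absolute distances for one
    subfamily; genes without a qualifying cluster are excluded from the
    statistics and counted in ``n_unassigned``."""
    pool = [r for r in results if r.subfamily == subfamily]
    if not pool:
        raise ValueError(f"no results for subfamily {subfamily!r}")
    assigned = [r.signed_distance for r in pool if r.nearest_bgc_id is not None]
    n_unassigned = len(pool) - len(assigned)
    if not assigned:
        return DistanceSummary(subfamily, 0, n_unassigned)
    signed = np.asarray(assigned, dtype=float)
    absd = np.abs(signed)
    return DistanceSummary(
        subfamily=subfamily,
        n=len(assigned),
        n_unassigned=n_unassigned,
        mean_abs=float(absd.mean()),
        median_abs=float(np.median(absd)),
        q1_abs=float(np.percentile(absd, 25)),
        q3_abs=float(np.percentile(absd, 75)),
        mean_signed=float(signed.mean()),
        median_signed=float(np.median(signed)),
        q1_signed=float(np.percentile(signed, 25)),
        q3_signed=float(np.percentile(signed, 75)),
    )


def compare_distance_distributions(
    a: Sequence[float],
    b: Sequence[float],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    absolute: bool = True,
) -> tuple[float, int, float]:
    """Chi-square comparison of two distance samples on shared bins.

    With the default landmark edges (0, 2 kb, 20 kb, 100 kb) distances are
    binned on their absolute value into {exactly 0, (0,2k], (2k,20k],
    (20k,100k], (100k,∞)}; the outer bin is open-ended. Both samples form a
    2×k contingency table; all-zero columns are dropped and the classical
    (uncorrected) Pearson chi-square statistic and upper-tail P are returned
    as (statistic, dof, P).
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    xa = np.abs(np.asarray(a, dtype=float)) if absolute else np.asarray(a, dtype=float)
    xb = np.abs(np.asarray(b, dtype=float)) if absolute else np.asarray(b, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    # right-closed bins; values at/below the first edge form their own bin
    counts_a = np.bincount(np.digitize(xa, edges, right=True), minlength=len(edges) + 1)
    counts_b = np.bincount(np.digitize(xb, edges, right=True), minlength=len(edges) + 1)
    table = np.vstack([counts_a, counts_b])
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        raise ValueError("fewer than 2 non-empty bins: chi-square test undefined")
    if np.array_equal(table[0], table[1]):
        return 0.0, table.shape[1] - 1, 1.0
    stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(dof), float(p)
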