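"""Per-genome copy-number census, frequency spectra, YQL/AZL coincidence,
and pairwise one-way ANOVA of copy-number variance between subfamilies."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .motif_classify import SUBFAMILIES, UNCLASSIFIED, SubfamilyCall

__all__ = [
    "GenomeCensus",
    "CoincidenceTable",
    "census",
    "copy_number_frequency",
    "coincidence",
    "anova_pairwise",
]


@dataclass
class GenomeCensus:
    genome_id: str
    counts: dict[str, int] = field(default_factory=dict)

    def count(self, subfamily: str) -> int:
        return self.counts.get(subfamily, 0)


@dataclass
class CoincidenceTable:
    """Cross-tabulation of per-genome YQL and AZL copy numbers.

    ``cells`` maps (yql_count, azl_count) to the number of genomes; the
    three totals partition the genome set.
    """

    cells: dict[tuple[int, int], int]
    both: int
    either_only: int
    neither: int

    @property
    def n_genomes(self) -> int:
        return sum(self.cells.values())


def census(
    calls: Sequence[SubfamilyCall],
    genome_ids: Optional[Sequence[str]] = None,
) -> list[GenomeCensus]:
    """One census per genome, counting classified calls only.

    ``genome_ids`` optionally fixes the full genome set so that genomes with
    zero classified homologs still appear (needed for coincidence totals).
    The grand total over all censuses equals the number of classified calls.
    """
    per_genome: dict[str, Counter] = {}
    for c in calls:
        if not c.genome_id:
            raise ValueError(f"call {c.protein_id} lacks a genome_id")
        per_genome.setdefault(c.genome_id, Counter())
        if c.subfamily != UNCLASSIFIED:
            per_genome[c.genome_id][c.subfamily] += 1
    ids = list(genome_ids) if genome_ids is not None else sorted(per_genome)
    return [GenomeCensus(gid, dict(per_genome.get(gid, Counter()))) for gid in ids]


def copy_number_frequency(
    censuses: Sequence[GenomeCensus],
    subfamily: str,
    include_zero_genomes: bool = False,
    top_bin: int = 5,
) -> dict[object, float]:
    """Percent of genomes by copy number (1, 2, 3, 4, "5+").

    The denominator is genomes carrying at least one copy of the subfamily
    (the per-clade reading of the copy-number spectrum); with
    ``include_zero_genomes`` all genomes count and a 0 bin is added.
    Returns an empty dict when the subfamily is absent everywhere.
    """
    counts = [c.count(subfamily) for c in censuses]
    if not include_zero_genomes:
        counts = [c for c in counts if c >= 1]
    if not counts or sum(counts) == 0:
        return {}
    denom = len(counts)
    tally: Counter = Counter()
    for c in counts:
        tally[f"{top_bin}+" if c >= top_bin else c] += 1
    keys = ([0] if include_zero_genomes else []) + list(range(1, top_bin)) + [f"{top_bin}+"]
    return {k: 100.0 * tally[k] / denom for k in keys if tally[k] > 0}


def coincidence(
    censuses: Sequence[GenomeCensus], a: str = "YQL", b: str = "AZL"
) -> CoincidenceTable:
    """YQL/AZL co-occurrence table: genomes with both, with exactly one, or
    with neither subfamily. Cells partition the genome set."""
    cells: Counter = Counter()
    both = either = neither = 0
    for c in censuses:
        ya, az = c.count(a), c.count(b)
        cells[(ya, az)] += 1
        if ya > 0 and az > 0:
            both += 1
        elif ya > 0 or az > 0:
            either += 1
        else:
            neither += 1
    return CoincidenceTable(dict(cells), both, either, neither)


def anova_pairwise(
    counts_a: Sequence[int], counts_b: Sequence[int]
) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA on two groups of per-genome copy
    counts; returns (F, P). With two groups F equals the square of the pooled
    two-sample t statistic."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var() == 0 and b.var() == 0 and a.mean() == b.mean():
        raise ValueError("degenerate ANOVA: zero variance and equal means")
    f, p = stats.f_oneway(a, b)
    return float(f), float(p)
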