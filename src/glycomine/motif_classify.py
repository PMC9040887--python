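"""Catalytic-motif classification of HTH_42 glycosylase candidates.

The HTH_42 superfamily splits into three subfamilies distinguished by the
residue classes at the catalytic position of the central winged-helix
surface:

* **YQL** (YcaQ-like):  Q-Φ-D
* **AZL** (AlkZ-like):  (Q|H)-Φ-Q, with variants QΦQ and HΦQ
* **AZL2**:             H-Φ-(S|T)-(D|E)

where Φ is an aliphatic residue (default ``{A, V, L, I, M}``). The three
patterns are mutually exclusive because their final-class constraints
({D}, {Q}, {S,T}) are disjoint.

Candidate windows are located by global pairwise alignment of each query to
a reference anchor whose catalytic position is known, because motif-like
trigrams occur frequently by chance in unrelated sequence. A regex-style
scan of the raw sequence is retained as an explicit anchor-free fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import BlastHit

__all__ = [
    "AA20",
    "DEFAULT_ALIPHATIC",
    "MotifPattern",
    "SubfamilyCall",
    "ReferenceAnchor",
    "default_patterns",
    "classify_motif",
    "scan_motif",
    "find_motif_occurrences",
    "filter_hits",
    "locate_catalytic_window",
    "classify_proteome",
    "motif_frequency_matrix",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
DEFAULT_ALIPHATIC = frozenset("AVLIM")

SUBFAMILIES = ("YQL", "AZL", "AZL2")
UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class MotifPattern:
    """Ordered per-position residue-class constraints for one subfamily."""

    name: str
    positions: tuple[frozenset, ...]

    def __len__(self) -> int:
        return len(self.positions)

    def matches(self, window: str) -> bool:
        if len(window) != len(self.positions):
            return False
        return all(res in allowed for res, allowed in zip(window, self.positions))


def default_patterns(aliphatic: frozenset = DEFAULT_ALIPHATIC) -> dict[str, MotifPattern]:
    phi = frozenset(aliphatic)
    return {
        "YQL": MotifPattern("YQL", (frozenset("Q"), phi, frozenset("D"))),
        "AZL": MotifPattern("AZL", (frozenset("QH"), phi, frozenset("Q"))),
        "AZL2": MotifPattern(
            "AZL2", (frozenset("H"), phi, frozenset("ST"), frozenset("DE"))
        ),
    }


@dataclass
class SubfamilyCall:
    """Classification of one protein: subfamily label plus its motif window."""

    protein_id: str
    subfamily: str
    window: str = ""
    window_start: int = -1
    alignment_reference: str = ""
    azl_variant: Optional[str] = None
    genome_id: str = ""


@dataclass(frozen=True)
class ReferenceAnchor:
    """A reference protein whose catalytic window position is known."""

    name: str
    sequence: str
    window_start: int
    window_length: int = 3


# ---------------------------------------------------------------------------
# hit filtering
# ---------------------------------------------------------------------------


def filter_hits(
    hits: Sequence[BlastHit],
    evalue_max: float = 1e-4,
    identity_min: float = 25.0,
    coverage_min: float = 0.75,
) -> list[BlastHit]:
    """Apply the homology-search cutoffs: e-value <= 1e-4, identity >= 25%,
    and coverage strictly greater than 75% of the subject/profile length.
    Input order is preserved."""
    if min(evalue_max, identity_min, coverage_min) <= 0:
        raise ValueError("thresholds must be positive")
    return [
        h
        for h in hits
        if h.evalue <= evalue_max
        and h.percent_identity >= identity_min
        and h.coverage > coverage_min
    ]


# ---------------------------------------------------------------------------
# window classification
# ---------------------------------------------------------------------------


def _check_window(window: str) -> None:
    if len(window) not in (3, 4):
        raise ValueError(f"window must be 3 or 4 residues, got {len(window)}")
    bad = [c for c in window if c not in AA20]
    if bad:
        raise ValueError(f"non-amino-acid characters in window: {bad}")


def classify_motif(
    window: str, aliphatic: frozenset = DEFAULT_ALIPHATIC
) -> tuple[str, Optional[str]]:
    """Classify a 3- or 4-residue catalytic window.

    Returns ``(subfamily, azl_variant)``; 3-residue windows are tested
    against YQL then AZL, 4-residue windows against AZL2. AZL calls carry
    the QΦQ/HΦQ variant from their first position.
    """
    _check_window(window)
    patterns = default_patterns(aliphatic)
    if len(window) == 3:
        if patterns["YQL"].matches(window):
            return "YQL", None
        if patterns["AZL"].matches(window):
            return "AZL", ("QΦQ" if window[0] == "Q" else "HΦQ")
    else:
        if patterns["AZL2"].matches(window):
            return "AZL2", None
    return UNCLASSIFIED, None


def find_motif_occurrences(
    sequence: str, aliphatic: frozenset = DEFAULT_ALIPHATIC
) -> list[tuple[int, str, str]]:
    """All (position, subfamily, window) motif occurrences in a raw sequence."""
    patterns = default_patterns(aliphatic)
    out: list[tuple[int, str, str]] = []
    n = len(sequence)
    for i in range(n - 2):
        tri = sequence[i : i + 3]
        if patterns["YQL"].matches(tri):
            out.append((i, "YQL", tri))
        elif patterns["AZL"].matches(tri):
            out.append((i, "AZL", tri))
        if i + 4 <= n:
            quad = sequence[i : i + 4]
            if patterns["AZL2"].matches(quad):
                out.append((i, "AZL2", quad))
    return out


def scan_motif(
    sequence: str, aliphatic: frozenset = DEFAULT_ALIPHATIC
) -> tuple[str, Optional[str], str, int]:
    """Anchor-free fallback: return the first motif occurrence by position.

    Returns (subfamily, azl_variant, window, window_start); UNCLASSIFIED when
    the sequence contains no motif.
    """
    occ = find_motif_occurrences(sequence, aliphatic)
    if not occ:
        return UNCLASSIFIED, None, "", -1
    pos, name, window = occ[0]
    variant = None
    if name == "AZL":
        variant = "QΦQ" if window[0] == "Q" else "HΦQ"
    return name, variant, window, pos


# ---------------------------------------------------------------------------
# alignment-anchored window location
# ---------------------------------------------------------------------------


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _align_and_map(
    query: str, reference: str, ref_start: int, window_length: int
) -> tuple[Optional[int], Optional[str], float]:
    """Align reference vs query; map the reference catalytic columns to the
    query. Returns (window_start, window, score); (None, None, score) when any
    catalytic column aligns to a gap in the query."""
    aligner = _make_aligner()
    alignment = aligner.align(reference, query)[0]
    ref_blocks, query_blocks = alignment.aligned
    mapped: list[int] = []
    for col in range(ref_start, ref_start + window_length):
        qpos = None
        for (rs, re), (qs, _qe) in zip(ref_blocks, query_blocks):
            if rs <= col < re:
                qpos = qs + (col - rs)
                break
        if qpos is None:
            return None, None, alignment.score
        mapped.append(qpos)
    window = "".join(query[i] for i in mapped)
    return mapped[0], window, alignment.score


def locate_catalytic_window(
    query: str,
    reference: str,
    reference_window_start: int,
    window_length: int = 3,
) -> Optional[tuple[int, str]]:
    """Locate a query's catalytic window by global alignment to a reference.

    Returns (window_start in query, window string) or None when a catalytic
    column aligns to a gap in the query. Inserted query residues within the
    window are not part of the returned window (it holds exactly the residues
    aligned to the reference's catalytic columns).
    """
    if not query or not reference:
        raise ValueError("empty sequence")
    if not (0 <= reference_window_start
            and reference_window_start + window_length <= len(reference)):
        raise ValueError("reference window out of bounds")
    start, window, _score = _align_and_map(
        query, reference, reference_window_start, window_length
    )
    if start is None:
        return None
    return start, window


# ---------------------------------------------------------------------------
# proteome classification
# ---------------------------------------------------------------------------


def _classify_against_anchor(
    seq: str, anchor: ReferenceAnchor, aliphatic: frozenset
) -> tuple[SubfamilyCall, float]:
    """Best call for one protein under one anchor (3-mer first, then 4-mer)."""
    start, window, score = _align_and_map(
        seq, anchor.sequence, anchor.window_start, 3
    )
    if window is not None:
        subfamily, variant = classify_motif(window, aliphatic)
        if subfamily != UNCLASSIFIED:
            return (
                SubfamilyCall("", subfamily, window, start, anchor.name, variant),
                score,
            )
    if anchor.window_start + 4 <= len(anchor.sequence):
        start4, window4, score4 = _align_and_map(
            seq, anchor.sequence, anchor.window_start, 4
        )
        if window4 is not None:
            subfamily, variant = classify_motif(window4, aliphatic)
            if subfamily != UNCLASSIFIED:
                return (
                    SubfamilyCall("", subfamily, window4, start4, anchor.name, variant),
                    score4,
                )
    fallback = SubfamilyCall("", UNCLASSIFIED, window or "", -1 if start is None else start,
                             anchor.name, None)
    return fallback, score


def classify_proteome(
    proteins: Mapping[str, str] | Iterable[tuple[str, str]],
    anchors: Sequence[ReferenceAnchor],
    aliphatic: frozenset = DEFAULT_ALIPHATIC,
    genome_map: Optional[Mapping[str, str]] = None,
    use_regex_fallback: bool = False,
) -> tuple[list[SubfamilyCall], pd.DataFrame]:
    """Classify every protein of a set and summarize subfamily composition.

    Each protein is aligned to every anchor; a classified call beats
    UNCLASSIFIED, otherwise the higher alignment score wins and ties break
    toward the first-listed anchor (convention: list the AZL anchor first).
    With ``use_regex_fallback`` proteins left UNCLASSIFIED by alignment are
    re-tried with a raw motif scan.

    Returns the calls plus a summary table (subfamily, count, percent);
    percents are over all input proteins and sum to 100.
    """
    if not anchors:
        raise ValueError("at least one reference anchor required")
    if isinstance(proteins, Mapping):
        items = list(proteins.items())
    else:
        items = list(proteins)
    seen: set[str] = set()
    dups = sorted({pid for pid, _ in items if pid in seen or seen.add(pid)})
    if dups:
        raise ValueError(f"duplicate protein ids: {dups}")

    calls: list[SubfamilyCall] = []
    for pid, seq in items:
        best: Optional[SubfamilyCall] = None
        best_key: tuple = ()
        for rank, anchor in enumerate(anchors):
            call, score = _classify_against_anchor(seq, anchor, aliphatic)
            key = (call.subfamily != UNCLASSIFIED, score, -rank)
            if best is None or key > best_key:
                best, best_key = call, key
        assert best is not None
        if best.subfamily == UNCLASSIFIED and use_regex_fallback:
            subfamily, variant, window, pos = scan_motif(seq, aliphatic)
            if subfamily != UNCLASSIFIED:
                best = SubfamilyCall("", subfamily, window, pos, "regex-scan", variant)
        best.protein_id = pid
        if genome_map:
            best.genome_id = genome_map.get(pid, "")
        calls.append(best)

    n = len(calls)
    rows = []
    for label in (*SUBFAMILIES, UNCLASSIFIED):
        count = sum(1 for c in calls if c.subfamily == label)
        rows.append(
            {"subfamily": label, "count": count, "percent": 100.0 * count / n if n else 0.0}
        )
    return calls, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# position frequency matrix (the data behind a sequence logo)
# ---------------------------------------------------------------------------


def motif_frequency_matrix(calls: Sequence[SubfamilyCall]) -> pd.DataFrame:
    """Per-column residue probabilities over the calls' motif windows.

    Rows are the 20 amino acids, columns the window positions; every column
    sums to 1. All windows must share one length.
    """
    windows = [c.window for c in calls if c.window]
    if not windows:
        raise ValueError("no windows to tabulate")
    lengths = {len(w) for w in windows}
    if len(lengths) != 1:
        raise ValueError(f"mixed window lengths: {sorted(lengths)}")
    width = lengths.pop()
    pfm = pd.DataFrame(0.0, index=list(AA20), columns=range(width))
    for w in windows:
        for j, res in enumerate(w):
            pfm.loc[res, j] += 1.0
    return pfm / len(windows)
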