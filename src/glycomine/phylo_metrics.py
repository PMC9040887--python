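"""Clade-level conservation metrics on externally inferred trees/alignments.

Two summaries contrast subfamily divergence: the mean root-to-tip path
length of a clade's leaves on a rooted tree (a proxy for substitution rate),
and the mean pairwise percent identity/similarity within a clade's aligned
sequences. "Similarity" counts substitution-matrix-positive residue pairs
(BLOSUM62 by default); columns gapped in either member of a pair are
excluded from that pair's denominator unless ``all_columns`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
from Bio import SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "SimilaritySummary",
    "load_tree",
    "midpoint_root",
    "mean_root_to_tip",
    "read_alignment_fasta",
    "pairwise_similarity",
]

_GAPS = {"-", "."}


@dataclass
class SimilaritySummary:
    clade: str
    mean_identity: float  # percent
    mean_similarity: float  # percent
    n_pairs: int
    matrix: str = "BLOSUM62"


def load_tree(source) -> dendropy.Tree:
    """Load a newick tree from a path or string."""
    if isinstance(source, dendropy.Tree):
        return source
    text = str(source)
    try:
        is_file = Path(text).exists()
    except OSError:  # e.g. a newick string longer than a legal filename
        is_file = False
    if is_file:
        return dendropy.Tree.get(path=text, schema="newick")
    return dendropy.Tree.get(data=text, schema="newick")


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Midpoint-root a tree in place (and return it)."""
    tree.reroot_at_midpoint(update_bipartitions=True)
    return tree


def mean_root_to_tip(
    tree, clade: Mapping[str, str], label: str
) -> float:
    """Arithmetic mean, over the leaves carrying ``label``, of the summed
    branch lengths from root to leaf.

    The tree must be rooted (bifurcating at the seed node) with every branch
    length present; an unrooted (basal trifurcation) tree raises with an
    instruction to midpoint-root first via :func:`midpoint_root`.
    """
    tree = load_tree(tree)
    root = tree.seed_node
    if len(root.child_nodes()) > 2:
        raise ValueError(
            "tree appears unrooted (basal multifurcation); midpoint-root it "
            "first, e.g. glycomine.phylo_metrics.midpoint_root(tree)"
        )
    totals = []
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label if leaf.taxon else None
        if name is None or clade.get(name) != label:
            continue
        depth = 0.0
        node = leaf
        while node is not root:
            if node.edge.length is None:
                raise ValueError(f"missing branch length above leaf {name!r}")
            depth += node.edge.length
            node = node.parent_node
        totals.append(depth)
    if not totals:
        raise ValueError(f"no leaves labeled {label!r}")
    return sum(totals) / len(totals)


def read_alignment_fasta(path) -> dict[str, str]:
    """Read an aligned FASTA into a name -> aligned-sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def pairwise_similarity(
    alignment: Mapping[str, str] | str | Path,
    members: Sequence[str],
    clade: str = "",
    matrix_name: str = "BLOSUM62",
    all_columns: bool = False,
) -> SimilaritySummary:
    """Mean pairwise percent identity and similarity over a clade's members.

    For each unordered pair, identity is the fraction of columns where both
    residues are present and identical; similarity additionally counts
    positive-scoring substitutions under the named matrix. By default the
    per-pair denominator is the both-non-gap column count; ``all_columns``
    switches to the full alignment length.
    """
    if not isinstance(alignment, Mapping):
        alignment = read_alignment_fasta(alignment)
    missing = [m for m in members if m not in alignment]
    if missing:
        raise ValueError(f"members absent from alignment: {missing}")
    if len(members) < 2:
        raise ValueError("need at least 2 members")
    lengths = {len(alignment[m]) for m in members}
    if len(lengths) != 1:
        raise ValueError(f"unequal aligned lengths: {sorted(lengths)}")
    matrix = substitution_matrices.load(matrix_name)

    ident_vals, sim_vals = [], []
    for a, b in combinations(members, 2):
        sa, sb = alignment[a], alignment[b]
        n_both = n_ident = n_sim = 0
        for ra, rb in zip(sa, sb):
            gapped = ra in _GAPS or rb in _GAPS
            if gapped and not all_columns:
                continue
            if not gapped:
                n_both += 1
                if ra == rb:
                    n_ident += 1
                    n_sim += 1
                elif matrix[ra, rb] > 0:
                    n_sim += 1
        denom = len(sa) if all_columns else n_both
        if denom == 0:
            raise ValueError(f"pair ({a}, {b}) shares no aligned columns")
        ident_vals.append(100.0 * n_ident / denom)
        sim_vals.append(100.0 * n_sim / denom)

    n_pairs = len(ident_vals)
    return SimilaritySummary(
        clade=clade,
        mean_identity=sum(ident_vals) / n_pairs,
        mean_similarity=sum(sim_vals) / n_pairs,
        n_pairs=n_pairs,
        matrix=matrix_name,
    )
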