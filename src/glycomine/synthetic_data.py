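"""Synthetic genomes, proteomes and assay data with exact known ground truth.

Every pipeline stage is testable offline against a manifest: multi-scaffold
genome annotations carry planted subfamily genes at exactly specified
boundary gaps and gene ranks from their biosynthetic gene clusters;
proteomes carry planted catalytic motifs at known offsets (derived from the
reference anchors by point mutation, so alignment-based window location is
meaningful); kinetic and dose-response series are drawn from the fitted
functional forms with optional Gaussian noise.

Randomness uses one global seed expanded into per-entity child seeds by a
fixed counter scheme (``default_rng([seed, genome_index, entity_index])``),
so adding entities never reshuffles existing ones and outputs are
byte-identical for a fixed configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    BgcInterval,
    GeneFeature,
    GenomeAnnotation,
    write_bgc_intervals,
    write_gene_features,
    write_table,
)
from .motif_classify import (
    AA20,
    DEFAULT_ALIPHATIC,
    ReferenceAnchor,
    find_motif_occurrences,
)
from .bgc_proximity import is_inside

__all__ = [
    "ConfigError",
    "PlantSpec",
    "GenomePlan",
    "SimulationConfig",
    "TruthGene",
    "SyntheticTruth",
    "make_reference_anchors",
    "generate_motif_protein",
    "generate_genome_set",
    "default_paper_plan",
    "ExponentialBlock",
    "LagHillBlock",
    "SurvivalBlock",
    "AssayConfig",
    "default_assay_config",
    "generate_assay_data",
    "generate_growth_curve",
]

_AA = np.array(list(AA20))


class ConfigError(ValueError):
    """An infeasible simulation configuration, raised before any file is written."""


# ---------------------------------------------------------------------------
# proteins
# ---------------------------------------------------------------------------

_MAX_SCRUB_ROUNDS = 500
_FLANK_KEEP = 4  # residues either side of the catalytic window left unmutated


def _random_residues(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(_AA, size=n))


def _sample_window(subfamily: str, rng: np.random.Generator,
                   aliphatic: frozenset) -> str:
    phi = rng.choice(sorted(aliphatic))
    if subfamily == "YQL":
        return "Q" + phi + "D"
    if subfamily == "AZL":
        return rng.choice(["Q", "H"]) + phi + "Q"
    if subfamily == "AZL2":
        return "H" + phi + rng.choice(["S", "T"]) + rng.choice(["D", "E"])
    raise ValueError(f"unknown subfamily {subfamily!r}")


def _scrub_accidental_motifs(
    seq: list[str],
    window_start: int,
    window_length: int,
    rng: np.random.Generator,
    aliphatic: frozenset,
) -> None:
    """Resample residues until no motif occurs outside the planted window.

    A match is forbidden unless it lies entirely within the planted window;
    the first residue of a forbidden match outside the window is resampled.
    Bounded retries; exhaustion raises (impossible exclusion).
    """
    w_lo, w_hi = window_start, window_start + window_length
    for _round in range(_MAX_SCRUB_ROUNDS):
        text = "".join(seq)
        offending = [
            (pos, len(win))
            for pos, _name, win in find_motif_occurrences(text, aliphatic)
            if not (w_lo <= pos and pos + len(win) <= w_hi)
        ]
        if not offending:
            return
        for pos, wl in offending:
            target = pos if pos < w_lo or pos >= w_hi else pos + wl - 1
            seq[target] = str(rng.choice(_AA))
    raise ConfigError("could not exclude accidental motifs (sequence too constrained)")


def generate_motif_protein(
    subfamily: str,
    length: int,
    window_offset: int,
    seed,
    anchor: Optional[ReferenceAnchor] = None,
    mutation_rate: float = 0.25,
    aliphatic: frozenset = DEFAULT_ALIPHATIC,
) -> str:
    """Generate a protein with the subfamily motif planted at ``window_offset``.

    With an ``anchor`` the protein is a homolog: the anchor sequence is point
    mutated at the given rate (the catalytic window and a few flanking
    residues stay conserved) and padded/trimmed so the window lands at the
    requested offset. Without an anchor the background is random. Either way
    no motif occurs anywhere outside the planted window; subfamily
    ``UNCLASSIFIED`` produces a sequence containing no motif at all.
    """
    rng = np.random.default_rng(seed)
    wl = 0 if subfamily == "UNCLASSIFIED" else (4 if subfamily == "AZL2" else 3)
    if length < max(wl, 3):
        raise ConfigError(f"length {length} too small for a {wl}-residue window")
    if subfamily == "UNCLASSIFIED":
        seq = _random_residues(rng, length)
        _scrub_accidental_motifs(seq, 0, 0, rng, aliphatic)
        return "".join(seq)

    if not (0 <= window_offset and window_offset + wl <= length):
        raise ConfigError(
            f"window [{window_offset}, {window_offset + wl}) does not fit in length {length}"
        )
    window = _sample_window(subfamily, rng, aliphatic)

    if anchor is None:
        seq = _random_residues(rng, length)
    else:
        core = list(anchor.sequence)
        aws = anchor.window_start
        # mutate outside the conserved catalytic surround
        keep_lo, keep_hi = aws - _FLANK_KEEP, aws + wl + _FLANK_KEEP
        for i in range(len(core)):
            if keep_lo <= i < keep_hi:
                continue
            if rng.random() < mutation_rate:
                core[i] = str(rng.choice(_AA))
        core[aws : aws + wl] = list(window)  # may extend a 3-mer site to 4
        prefix_len = window_offset - aws
        if prefix_len >= 0:
            seq = _random_residues(rng, prefix_len) + core
        else:
            seq = core[-prefix_len:]
        if len(seq) < length:
            seq = seq + _random_residues(rng, length - len(seq))
        elif len(seq) > length:
            tail_floor = window_offset + wl + _FLANK_KEEP
            if length < tail_floor:
                raise ConfigError(
                    f"length {length} cannot hold the window plus conserved flank"
                )
            seq = seq[:length]
    seq[window_offset : window_offset + wl] = list(window)
    _scrub_accidental_motifs(seq, window_offset, wl, rng, aliphatic)
    return "".join(seq)


def make_reference_anchors(seed: int = 1123) -> dict[str, ReferenceAnchor]:
    """Synthetic stand-ins for the AlkZ (AZL) and YcaQ (YQL) reference
    proteins: fixed sequences with the catalytic window at a known offset
    (AZL anchor Q-Φ-Q at residue 40, mirroring the AlkZ Q41/Q43 numbering;
    YQL anchor Q-Φ-D at residue 60)."""
    out: dict[str, ReferenceAnchor] = {}
    for i, (role, length, ws) in enumerate([("AZL", 360, 40), ("YQL", 430, 60)]):
        rng = np.random.default_rng([seed, i])
        seq = _random_residues(rng, length)
        window = _sample_window(role, rng, DEFAULT_ALIPHATIC)
        seq[ws : ws + 3] = list(window)
        _scrub_accidental_motifs(seq, ws, 3, rng, DEFAULT_ALIPHATIC)
        out[role] = ReferenceAnchor(
            name=f"{role}_anchor_synthetic", sequence="".join(seq),
            window_start=ws, window_length=3,
        )
    return out


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantSpec:
    """Where one subfamily gene is planted relative to its own cluster."""

    subfamily: str
    placement: str = "inside"  # "inside" | "flank"
    side: str = "+"  # '+': gene on the 5'/lower side; '-': 3'/higher side
    gap_bp: int = 0
    n_intervening: int = 0


@dataclass
class GenomePlan:
    genome_id: str
    planted: list[PlantSpec] = field(default_factory=list)
    n_decoy_bgcs: int = 1
    background_scaffold_genes: int = 12


@dataclass
class SimulationConfig:
    plans: list[GenomePlan]
    seed: int
    gene_length: tuple[int, int] = (300, 1200)
    gene_spacing: tuple[int, int] = (60, 300)
    bgc_size: tuple[int, int] = (20_000, 40_000)
    bgc_internal_genes: tuple[int, int] = (3, 6)
    unit_margin: int = 300_000
    protein_length: tuple[int, int] = (320, 400)
    mutation_rate: float = 0.25


@dataclass
class TruthGene:
    genome_id: str
    scaffold_id: str
    gene_id: str
    subfamily: str
    start: int
    end: int
    signed_distance: Optional[int]
    nearest_bgc_id: Optional[str]
    intervening_genes: int
    inside: bool
    window: str
    window_start: int


@dataclass
class SyntheticTruth:
    """Manifest tying every generated entity to its planted parameters."""

    genome_ids: list[str]
    annotations: dict[str, GenomeAnnotation]
    bgcs: dict[str, list[BgcInterval]]
    proteins: dict[str, str]
    protein_genomes: dict[str, str]
    genes: list[TruthGene]
    anchors: dict[str, ReferenceAnchor]
    census: dict[str, dict[str, int]]


_BIOSYNTH_PRODUCTS = (
    "polyketide synthase",
    "nonribosomal peptide synthetase",
    "terpene cyclase",
    "cytochrome P450 monooxygenase",
    "ABC transporter permease",
    "O-methyltransferase",
    "DrrA-like ABC transporter ATP-binding protein",
)

_GENERAL_PRODUCTS = (
    "hypothetical protein",
    "hypothetical protein",
    "N-acetyltransferase",
    "two-component system response regulator",
    "sensor histidine kinase",
    "MFS transporter",
    "alcohol dehydrogenase",
    "DNA polymerase III subunit",
    "50S ribosomal protein",
    "aldo/keto reductase",
    "serine/threonine protein kinase",
    "alpha/beta fold hydrolase",
)

_PLANT_PRODUCT = "HTH_42 family DNA glycosylase"

_MIN_INTERVENING_GENE = 60
_INTERVENING_PAD = 30


def _validate_config(config: SimulationConfig) -> None:
    seen_ids: set[str] = set()
    for plan in config.plans:
        if plan.genome_id in seen_ids:
            raise ConfigError(f"duplicate genome_id {plan.genome_id!r}")
        seen_ids.add(plan.genome_id)
        for spec in plan.planted:
            if spec.placement not in ("inside", "flank"):
                raise ConfigError(f"bad placement {spec.placement!r}")
            if spec.placement == "flank":
                if spec.gap_bp <= 0:
                    raise ConfigError("flank placement requires a positive gap")
                if spec.n_intervening > 0:
                    seg = spec.gap_bp // (spec.n_intervening + 1)
                    if seg - 2 * _INTERVENING_PAD < _MIN_INTERVENING_GENE:
                        raise ConfigError(
                            f"{plan.genome_id}: {spec.n_intervening} intervening "
                            f"genes cannot fit in a {spec.gap_bp} bp gap"
                        )
            if spec.side not in ("+", "-"):
                raise ConfigError(f"bad side {spec.side!r}")


@dataclass
class _DraftGene:
    scaffold_id: str
    start: int
    end: int
    strand: str
    product: str
    plant_index: Optional[int] = None  # index into plan.planted


def _layout_bgc_internal(
    rng: np.random.Generator,
    scaffold: str,
    bgc_start: int,
    bgc_end: int,
    n_internal: int,
    planted_slot: Optional[tuple[int, int]] = None,  # (plant_index, gene_length)
) -> list[_DraftGene]:
    """Evenly slotted genes inside a cluster; one slot may hold the planted gene."""
    n_slots = n_internal + (1 if planted_slot else 0)
    width = (bgc_end - bgc_start) // n_slots
    slot_of_plant = int(rng.integers(n_slots)) if planted_slot else -1
    genes = []
    for s in range(n_slots):
        lo = bgc_start + s * width
        if s == slot_of_plant:
            plant_index, length = planted_slot  # type: ignore[misc]
            start = lo + 200
            genes.append(_DraftGene(scaffold, start, start + length,
                                    str(rng.choice(["+", "-"])), _PLANT_PRODUCT,
                                    plant_index))
        else:
            length = int(min(800, width - 400))
            start = lo + 200
            genes.append(_DraftGene(scaffold, start, start + length,
                                    str(rng.choice(["+", "-"])),
                                    str(rng.choice(_BIOSYNTH_PRODUCTS))))
    return genes


def _layout_intervening(
    rng: np.random.Generator, scaffold: str, lo: int, hi: int, m: int
) -> list[_DraftGene]:
    """m genes strictly inside the open gap (lo, hi), evenly partitioned."""
    if m == 0:
        return []
    seg = (hi - lo) // (m + 1)
    length = max(_MIN_INTERVENING_GENE, min(600, seg - 2 * _INTERVENING_PAD))
    genes = []
    for i in range(1, m + 1):
        center = lo + i * seg
        start = max(lo + 1, center - length // 2)
        end = min(hi - 1, start + length)
        genes.append(_DraftGene(scaffold, start, end, str(rng.choice(["+", "-"])),
                                str(rng.choice(_GENERAL_PRODUCTS))))
    return genes


def _build_genome(
    plan: GenomePlan, config: SimulationConfig, genome_index: int,
    anchors: dict[str, ReferenceAnchor],
):
    """Lay out one genome; returns (annotation, bgcs, truth genes, proteins)."""
    rng = np.random.default_rng([config.seed, genome_index])
    gid = plan.genome_id
    drafts: list[_DraftGene] = []
    bgcs: list[BgcInterval] = []
    scaffold = f"{gid}_s1"
    cursor = 10_000
    n_bgc = 0

    plant_meta: dict[int, dict] = {}  # plant_index -> truth fields
    for j, spec in enumerate(plan.planted):
        gene_len = int(rng.integers(*config.gene_length))
        bgc_len = int(rng.integers(*config.bgc_size))
        n_internal = int(rng.integers(*config.bgc_internal_genes))
        n_bgc += 1
        bgc_id = f"{gid}_bgc{n_bgc:02d}"
        if spec.placement == "inside":
            b_lo, b_hi = cursor, cursor + bgc_len
            drafts += _layout_bgc_internal(rng, scaffold, b_lo, b_hi, n_internal,
                                           planted_slot=(j, gene_len))
            d, m = 0, 0
            unit_end = b_hi
        elif spec.side == "-":
            b_lo, b_hi = cursor, cursor + bgc_len
            drafts += _layout_bgc_internal(rng, scaffold, b_lo, b_hi, n_internal)
            drafts += _layout_intervening(rng, scaffold, b_hi, b_hi + spec.gap_bp,
                                          spec.n_intervening)
            g_lo = b_hi + spec.gap_bp
            drafts.append(_DraftGene(scaffold, g_lo, g_lo + gene_len,
                                     str(rng.choice(["+", "-"])), _PLANT_PRODUCT, j))
            d, m = -spec.gap_bp, spec.n_intervening
            unit_end = g_lo + gene_len
        else:  # side '+': gene on the lower-coordinate (5') flank
            g_lo = cursor
            drafts.append(_DraftGene(scaffold, g_lo, g_lo + gene_len,
                                     str(rng.choice(["+", "-"])), _PLANT_PRODUCT, j))
            gap_lo = g_lo + gene_len
            drafts += _layout_intervening(rng, scaffold, gap_lo,
                                          gap_lo + spec.gap_bp, spec.n_intervening)
            b_lo = gap_lo + spec.gap_bp
            b_hi = b_lo + bgc_len
            drafts += _layout_bgc_internal(rng, scaffold, b_lo, b_hi, n_internal)
            d, m = spec.gap_bp, spec.n_intervening
            unit_end = b_hi
        bgcs.append(BgcInterval(bgc_id, gid, scaffold, b_lo, b_hi,
                                predicted_type=str(rng.choice(
                                    ["T1PKS", "NRPS", "terpene", "PKS-NRPS hybrid"]))))
        plant_meta[j] = {"signed_distance": d, "intervening": m, "bgc_id": bgc_id}
        cursor = unit_end + config.unit_margin + int(rng.integers(0, 50_000))

    for _ in range(plan.n_decoy_bgcs):
        bgc_len = int(rng.integers(*config.bgc_size))
        n_internal = int(rng.integers(*config.bgc_internal_genes))
        n_bgc += 1
        drafts += _layout_bgc_internal(rng, scaffold, cursor, cursor + bgc_len,
                                       n_internal)
        bgcs.append(BgcInterval(f"{gid}_bgc{n_bgc:02d}", gid, scaffold,
                                cursor, cursor + bgc_len,
                                predicted_type=str(rng.choice(
                                    ["T2PKS", "lanthipeptide", "siderophore"]))))
        cursor = cursor + bgc_len + config.unit_margin

    scaffolds = {scaffold: cursor + 20_000}

    bg_scaffold = f"{gid}_s2"
    pos = 5_000
    for _ in range(plan.background_scaffold_genes):
        length = int(rng.integers(*config.gene_length))
        drafts.append(_DraftGene(bg_scaffold, pos, pos + length,
                                 str(rng.choice(["+", "-"])),
                                 str(rng.choice(_GENERAL_PRODUCTS))))
        pos += length + int(rng.integers(*config.gene_spacing))
    scaffolds[bg_scaffold] = pos + 5_000

    # stable ids by genomic order on each scaffold
    drafts.sort(key=lambda g: (g.scaffold_id, g.start))
    genes: list[GeneFeature] = []
    truth: list[TruthGene] = []
    proteins: dict[str, str] = {}
    ordinal: dict[str, int] = {}
    for draft in drafts:
        ordinal[draft.scaffold_id] = ordinal.get(draft.scaffold_id, 0) + 1
        gene_id = f"{draft.scaffold_id}_{ordinal[draft.scaffold_id]:04d}"
        genes.append(GeneFeature(gene_id, gid, draft.scaffold_id, draft.start,
                                 draft.end, draft.strand, draft.product))
        if draft.plant_index is None:
            continue
        j = draft.plant_index
        spec = plan.planted[j]
        meta = plant_meta[j]
        prot_rng = np.random.default_rng([config.seed, genome_index, j])
        length = int(prot_rng.integers(*config.protein_length))
        anchor = None
        if spec.subfamily in ("AZL", "AZL2"):
            anchor = anchors["AZL"]
        elif spec.subfamily == "YQL":
            anchor = anchors["YQL"]
        if anchor is not None:
            offset = anchor.window_start + int(prot_rng.integers(0, 21))
        else:
            offset = int(prot_rng.integers(10, 40))
        seq = generate_motif_protein(
            spec.subfamily, length, offset, [config.seed, genome_index, j, 7],
            anchor=anchor, mutation_rate=config.mutation_rate,
        )
        wl = 4 if spec.subfamily == "AZL2" else (0 if spec.subfamily == "UNCLASSIFIED" else 3)
        proteins[gene_id] = seq
        truth.append(TruthGene(
            genome_id=gid, scaffold_id=draft.scaffold_id, gene_id=gene_id,
            subfamily=spec.subfamily, start=draft.start, end=draft.end,
            signed_distance=meta["signed_distance"], nearest_bgc_id=meta["bgc_id"],
            intervening_genes=meta["intervening"],
            inside=is_inside(meta["signed_distance"], meta["intervening"]),
            window=seq[offset : offset + wl], window_start=offset if wl else -1,
        ))
    annotation = GenomeAnnotation(gid, scaffolds, genes)
    return annotation, bgcs, truth, proteins


def generate_genome_set(
    config: SimulationConfig, out_dir: Optional[str | Path] = None
) -> SyntheticTruth:
    """Generate the full synthetic genome/proteome set described by ``config``.

    Returns the ground-truth manifest; with ``out_dir`` additionally writes
    ``genomes/<id>.gff3``, ``bgcs/<id>.bed``, ``proteins.fasta``,
    ``references.fasta``/``references.tsv`` and the truth tables. Outputs are
    byte-identical for a fixed config and seed.
    """
    _validate_config(config)
    anchors = make_reference_anchors()
    annotations: dict[str, GenomeAnnotation] = {}
    bgcs: dict[str, list[BgcInterval]] = {}
    proteins: dict[str, str] = {}
    protein_genomes: dict[str, str] = {}
    genes: list[TruthGene] = []
    census: dict[str, dict[str, int]] = {}

    for gi, plan in enumerate(config.plans):
        annotation, genome_bgcs, truth, prot = _build_genome(plan, config, gi, anchors)
        gid = plan.genome_id
        annotations[gid] = annotation
        bgcs[gid] = genome_bgcs
        proteins.update(prot)
        protein_genomes.update({pid: gid for pid in prot})
        genes.extend(truth)
        counts: dict[str, int] = {}
        for tg in truth:
            if tg.subfamily != "UNCLASSIFIED":
                counts[tg.subfamily] = counts.get(tg.subfamily, 0) + 1
        census[gid] = counts

    truth_obj = SyntheticTruth(
        genome_ids=[p.genome_id for p in config.plans],
        annotations=annotations, bgcs=bgcs, proteins=proteins,
        protein_genomes=protein_genomes, genes=genes, anchors=anchors,
        census=census,
    )
    if out_dir is not None:
        _write_outputs(truth_obj, Path(out_dir))
    return truth_obj


def _write_outputs(truth: SyntheticTruth, out_dir: Path) -> None:
    (out_dir / "genomes").mkdir(parents=True, exist_ok=True)
    (out_dir / "bgcs").mkdir(parents=True, exist_ok=True)
    for gid in truth.genome_ids:
        write_gene_features(truth.annotations[gid], out_dir / "genomes" / f"{gid}.gff3")
        write_bgc_intervals(truth.bgcs[gid], out_dir / "bgcs" / f"{gid}.bed")
    with open(out_dir / "proteins.fasta", "w") as fh:
        for pid in sorted(truth.proteins):
            fh.write(f">{pid} genome={truth.protein_genomes[pid]}\n")
            fh.write(truth.proteins[pid] + "\n")
    with open(out_dir / "references.fasta", "w") as fh:
        for role in ("AZL", "YQL"):  # AZL first: the tie-break anchor order
            anchor = truth.anchors[role]
            fh.write(f">{anchor.name} role={role}\n{anchor.sequence}\n")
    ref_rows = [
        {"name": truth.anchors[role].name, "role": role,
         "window_start": truth.anchors[role].window_start,
         "window_length": truth.anchors[role].window_length}
        for role in ("AZL", "YQL")
    ]
    write_table(pd.DataFrame(ref_rows), out_dir / "references.tsv")
    gene_rows = [
        {
            "genome_id": g.genome_id, "scaffold_id": g.scaffold_id,
            "gene_id": g.gene_id, "subfamily": g.subfamily,
            "start": g.start, "end": g.end,
            "signed_distance": g.signed_distance,
            "nearest_bgc_id": g.nearest_bgc_id,
            "intervening_genes": g.intervening_genes, "inside": g.inside,
            "window": g.window, "window_start": g.window_start,
        }
        for g in truth.genes
    ]
    write_table(pd.DataFrame(gene_rows), out_dir / "truth_genes.tsv")
    census_rows = [
        {"genome_id": gid,
         "YQL": truth.census[gid].get("YQL", 0),
         "AZL": truth.census[gid].get("AZL", 0),
         "AZL2": truth.census[gid].get("AZL2", 0)}
        for gid in truth.genome_ids
    ]
    write_table(pd.DataFrame(census_rows), out_dir / "truth_census.tsv")


# ---------------------------------------------------------------------------
# the study-structure default plan
# ---------------------------------------------------------------------------


def default_paper_plan(n_genomes: int = 100, seed: int = 0) -> list[GenomePlan]:
    """Planting plan mirroring the study's headline structure.

    Across 100 genomes (scaled proportionally otherwise): 98 YQL copies
    (88 genomes x1, 5 x2; all >20 kb from any cluster with >=6 intervening
    genes, mean gap 25 kb), 86 AZL copies (13x1/16x2/8x3/3x4/1x5; half inside
    clusters, a quarter within 2 kb, a quarter 4-11 kb out, with the planted
    mean |distance| exactly 2.3 kb), and 16 AZL2 copies (14x1, 1x2; placed
    like YQL). The classified mix is 49% / 43% / 8%.
    """
    if n_genomes < 1:
        raise ConfigError("need at least one genome")
    scale = n_genomes / 100.0
    rng = np.random.default_rng([seed, 999])
    ids = [f"G{i + 1:03d}" for i in range(n_genomes)]

    def scaled(spectrum: list[tuple[int, int]]) -> list[int]:
        # spectrum entries (copies, n_genomes at 100-genome scale)
        out: list[int] = []
        for copies, n in spectrum:
            out += [copies] * max(1 if n else 0, round(n * scale))
        return out

    yql_copies = scaled([(1, 88), (2, 5)])
    azl_copies = scaled([(1, 13), (2, 16), (3, 8), (4, 3), (5, 1)])
    azl2_copies = scaled([(1, 14), (2, 1)])

    n_azl = sum(azl_copies)
    n_inside = n_azl // 2
    n_near = (n_azl - n_inside) // 2
    n_out = n_azl - n_inside - n_near
    near_gaps = rng.integers(500, 2001, size=n_near)
    # outside gaps adjusted so the planted mean |distance| is exactly 2.3 kb
    target_total = 2300 * n_azl
    out_target = target_total - int(near_gaps.sum())
    out_gaps = rng.integers(4000, 11001, size=n_out).astype(float)
    out_gaps = np.round(out_gaps * out_target / out_gaps.sum()).astype(int)
    out_gaps = np.clip(out_gaps, 4000, None)
    out_gaps[-1] += out_target - int(out_gaps.sum())

    azl_specs = (
        [PlantSpec("AZL", "inside")] * n_inside
        + [PlantSpec("AZL", "flank", str(rng.choice(["+", "-"])), int(g), 0)
           for g in near_gaps]
        + [PlantSpec("AZL", "flank", str(rng.choice(["+", "-"])), int(g),
                     int(rng.integers(6, 10)))
           for g in out_gaps]
    )
    azl_specs = [azl_specs[i] for i in rng.permutation(len(azl_specs))]

    def far_specs(subfamily: str, n: int) -> list[PlantSpec]:
        gaps = rng.integers(20_500, 29_501, size=n)
        gaps = gaps - (int(gaps.mean()) - 25_000)  # center the mean at 25 kb
        return [
            PlantSpec(subfamily, "flank", str(rng.choice(["+", "-"])), int(g),
                      int(rng.integers(6, 10)))
            for g in gaps
        ]

    yql_specs = far_specs("YQL", sum(yql_copies))
    azl2_specs = far_specs("AZL2", sum(azl2_copies))

    plans = [GenomePlan(gid) for gid in ids]
    for copies_list, specs in (
        (yql_copies, yql_specs), (azl_copies, azl_specs), (azl2_copies, azl2_specs)
    ):
        carriers = rng.choice(n_genomes, size=min(len(copies_list), n_genomes),
                              replace=False)
        queue = list(specs)
        for gi, copies in zip(carriers, copies_list):
            for _ in range(copies):
                if queue:
                    plans[gi].planted.append(queue.pop())
    return plans


# ---------------------------------------------------------------------------
# assay data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExponentialBlock:
    label: str
    k: float  # min^-1
    amplitude: float = 1.0


@dataclass(frozen=True)
class LagHillBlock:
    label: str
    min_lag: float  # h
    max_lag: float
    ic50: float  # uM
    hill: float


@dataclass(frozen=True)
class SurvivalBlock:
    label: str
    ic50: float  # uM
    hill: float
    max_survival: float = 100.0
    min_survival: float = 0.0


@dataclass
class AssayConfig:
    exponential: list[ExponentialBlock] = field(default_factory=list)
    lag: list[LagHillBlock] = field(default_factory=list)
    survival: list[SurvivalBlock] = field(default_factory=list)
    time_grid: tuple[float, ...] = (0.08, 0.17, 0.33, 0.67, 1, 2, 4, 8, 15, 30, 60)
    doses: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 25.0, 50.0, 100.0)
    sigma: float = 0.0  # Gaussian noise, as a fraction of each response's scale


def default_assay_config(sigma: float = 0.0) -> AssayConfig:
    """Assay blocks at the study's measured parameter values: glycosylase
    rates 7.8 / 0.8 / 0.04 min^-1 (wild type / Q43A / Q41A), growth-lag
    IC50s 5.9 / 3.9 uM (glycosylase-expressing / vector), survival IC50s
    48.1 / 11.1 uM."""
    return AssayConfig(
        exponential=[
            ExponentialBlock("wildtype", 7.8),
            ExponentialBlock("Q41A", 0.04),
            ExponentialBlock("Q43A", 0.8),
        ],
        lag=[
            LagHillBlock("glycosylase", 1.5, 18.0, 5.9, 1.5),
            LagHillBlock("vector", 1.5, 18.0, 3.9, 1.5),
        ],
        survival=[
            SurvivalBlock("vector", 11.1, 1.8),
            SurvivalBlock("glycosylase", 48.1, 1.8),
        ],
        sigma=sigma,
    )


def generate_assay_data(
    config: AssayConfig, seed, out_dir: Optional[str | Path] = None
) -> dict[str, dict[str, np.ndarray]]:
    """Draw time courses and dose-response series from the model forms.

    Noise is Gaussian, independent per point, with standard deviation
    ``sigma`` times the response scale (amplitude for time courses, the
    min-to-max span for Hill curves); sigma 0 gives noiseless data. Returns
    ``{kind: {label: (x, y)}}`` and optionally writes one CSV per series.
    """
    if config.sigma < 0:
        raise ConfigError("sigma must be non-negative")
    from .kinetics import hill_lag, hill_survival

    out: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {
        "timecourse": {}, "lag": {}, "survival": {},
    }
    t = np.asarray(config.time_grid, dtype=float)
    doses = np.asarray(config.doses, dtype=float)
    for i, block in enumerate(config.exponential):
        rng = np.random.default_rng([*np.atleast_1d(seed), 1, i])
        y = block.amplitude * (1 - np.exp(-block.k * t))
        y = y + rng.normal(0, config.sigma * block.amplitude, size=t.shape)
        out["timecourse"][block.label] = (t, y)
    for i, block in enumerate(config.lag):
        rng = np.random.default_rng([*np.atleast_1d(seed), 2, i])
        y = hill_lag(doses, block.min_lag, block.max_lag, block.ic50, block.hill)
        y = y + rng.normal(0, config.sigma * (block.max_lag - block.min_lag),
                           size=doses.shape)
        out["lag"][block.label] = (doses, y)
    for i, block in enumerate(config.survival):
        rng = np.random.default_rng([*np.atleast_1d(seed), 3, i])
        y = hill_survival(doses, block.min_survival, block.max_survival,
                          block.ic50, block.hill)
        y = y + rng.normal(
            0, config.sigma * (block.max_survival - block.min_survival),
            size=doses.shape)
        out["survival"][block.label] = (doses, y)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        headers = {"timecourse": ("time_min", "fraction_product"),
                   "lag": ("dose_uM", "lag_h"),
                   "survival": ("dose_uM", "percent_survival")}
        for kind, series in out.items():
            for label, (x, y) in series.items():
                df = pd.DataFrame({headers[kind][0]: x, headers[kind][1]: y})
                df.to_csv(out_dir / f"{kind}_{label}.csv", index=False)
    return out


def generate_growth_curve(
    t: Sequence[float],
    lag: float,
    rate: float = 0.9,
    baseline: float = 0.01,
    cap: float = 1.0,
    sigma: float = 0.0,
    seed=0,
) -> np.ndarray:
    """A lag/exponential/plateau growth curve: flat at ``baseline`` until
    ``lag``, exponential at ``rate`` (per h) afterwards, capped at ``cap``,
    with optional multiplicative Gaussian noise."""
    rng = np.random.default_rng(seed)
    t = np.asarray(t, dtype=float)
    od = np.minimum(baseline * np.exp(rate * np.clip(t - lag, 0, None)), cap)
    if sigma > 0:
        od = od * np.exp(rng.normal(0, sigma, size=t.shape))
    return od
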