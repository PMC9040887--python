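"""Readers, writers and coordinate-bearing record types shared by the pipeline.

All coordinates are held internally as 0-based half-open intervals on named
scaffolds. GFF3 input is interpreted as 1-based inclusive and converted on
read; BED input is already 0-based half-open and passes through unchanged.
The writers are exact inverses of the readers, so any annotation or interval
list round-trips bit-exactly.
"""

from __future__ import annotations

import csv
import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "ParseError",
    "GeneFeature",
    "GenomeAnnotation",
    "BgcInterval",
    "BlastHit",
    "read_gene_features",
    "write_gene_features",
    "read_bgc_intervals",
    "write_bgc_intervals",
    "read_blast_hits",
    "read_table",
    "write_table",
]

_STRANDS = {"+", "-", "?"}


class ParseError(ValueError):
    """A malformed record in an input file, reported with its line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass
class GeneFeature:
    """One annotated gene on a scaffold, 0-based half-open."""

    gene_id: str
    genome_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str = "?"
    annotation: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """All gene features of one genome, sorted by (scaffold, start).

    ``scaffolds`` maps scaffold id to its length in bp, or None when the
    length is unknown (e.g. a gene TSV without sequence-region metadata).
    """

    genome_id: str
    scaffolds: dict[str, Optional[int]]
    genes: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        self.genes = sorted(self.genes, key=lambda g: (g.scaffold_id, g.start, g.end))
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r} in {self.genome_id}")
            seen.add(g.gene_id)
            if g.scaffold_id not in self.scaffolds:
                self.scaffolds[g.scaffold_id] = None
            length = self.scaffolds[g.scaffold_id]
            if length is not None and g.end > length:
                raise ValueError(
                    f"gene {g.gene_id} ends at {g.end} beyond scaffold "
                    f"{g.scaffold_id} length {length}"
                )

    def genes_on(self, scaffold_id: str) -> list[GeneFeature]:
        return [g for g in self.genes if g.scaffold_id == scaffold_id]

    def get(self, gene_id: str) -> GeneFeature:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class BgcInterval:
    """A predicted biosynthetic gene cluster interval (0-based half-open)."""

    bgc_id: str
    genome_id: str
    scaffold_id: str
    start: int
    end: int
    predicted_type: str = ""
    similar_known_cluster: Optional[tuple[str, float]] = None

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"BGC {self.bgc_id}: negative start {self.start}")
        if not self.start < self.end:
            raise ValueError(
                f"BGC {self.bgc_id}: require start < end, got [{self.start}, {self.end})"
            )


@dataclass
class BlastHit:
    """One row of a homology-search hit table with subject coverage."""

    query_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    coverage: float
    bitscore: float

    def __post_init__(self):
        if not 0 <= self.percent_identity <= 100:
            raise ValueError(f"percent_identity out of range: {self.percent_identity}")
        if self.evalue < 0:
            raise ValueError(f"negative e-value: {self.evalue}")
        if not 0 <= self.coverage <= 1:
            raise ValueError(f"coverage out of [0,1]: {self.coverage}")


# ---------------------------------------------------------------------------
# gene features
# ---------------------------------------------------------------------------

# identity priority reflects the mix of annotation styles across assemblies
_ID_PRIORITY = ("locus_tag", "ID", "protein_id")

_GENE_TSV_COLUMNS = ["gene_id", "scaffold_id", "start", "end", "strand", "annotation"]


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gene_features(
    path,
    genome_id: str,
    feature_types: Sequence[str] = ("gene",),
) -> GenomeAnnotation:
    """Read gene features from GFF3 (1-based inclusive) or a gene TSV.

    Coordinates are converted to 0-based half-open. Features without a usable
    identifier (locus_tag, then ID, then protein_id) get a deterministic
    synthetic id ``<scaffold>_gNNNN`` by file order on that scaffold. A file
    that yields zero gene records triggers an explicit warning.
    """
    path = Path(path)
    if path.suffix.lower() in {".tsv", ".txt", ".csv"}:
        return _read_gene_tsv(path, genome_id)

    scaffolds: dict[str, Optional[int]] = {}
    genes: list[GeneFeature] = []
    ordinals: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    try:
                        scaffolds[parts[1]] = int(parts[3])
                    except ValueError:
                        raise ParseError(path, lineno, "bad sequence-region length")
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(path, lineno, f"expected 9 GFF3 columns, got {len(cols)}")
            scaffold, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            if ftype not in feature_types:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(path, lineno, f"non-integer coordinates {start_s!r}/{end_s!r}")
            if start1 < 1 or end1 < start1:
                raise ParseError(path, lineno, f"bad 1-based interval [{start1}, {end1}]")
            attrs = _parse_gff_attributes(attr_s)
            gene_id = next((attrs[k] for k in _ID_PRIORITY if k in attrs), None)
            if gene_id is None:
                ordinals[scaffold] = ordinals.get(scaffold, 0) + 1
                gene_id = f"{scaffold}_g{ordinals[scaffold]:04d}"
            genes.append(
                GeneFeature(
                    gene_id=gene_id,
                    genome_id=genome_id,
                    scaffold_id=scaffold,
                    start=start1 - 1,  # 1-based inclusive -> 0-based half-open
                    end=end1,
                    strand=strand if strand in _STRANDS else "?",
                    annotation=attrs.get("product", attrs.get("Note", "")),
                )
            )
            scaffolds.setdefault(scaffold, None)
    if not genes:
        warnings.warn(f"{path}: no gene records found", stacklevel=2)
    return GenomeAnnotation(genome_id=genome_id, scaffolds=scaffolds, genes=genes)


def _read_gene_tsv(path: Path, genome_id: str) -> GenomeAnnotation:
    genes: list[GeneFeature] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header: Optional[list[str]] = None
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if header is None:
                header = row
                if header[: len(_GENE_TSV_COLUMNS)] != _GENE_TSV_COLUMNS:
                    raise ParseError(path, lineno, f"expected header {_GENE_TSV_COLUMNS}")
                continue
            if len(row) < 5:
                raise ParseError(path, lineno, f"expected >=5 columns, got {len(row)}")
            try:
                start, end = int(row[2]), int(row[3])
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates")
            genes.append(
                GeneFeature(
                    gene_id=row[0],
                    genome_id=genome_id,
                    scaffold_id=row[1],
                    start=start,
                    end=end,
                    strand=row[4] if row[4] in _STRANDS else "?",
                    annotation=row[5] if len(row) > 5 else "",
                )
            )
    if not genes:
        warnings.warn(f"{path}: no gene records found", stacklevel=2)
    return GenomeAnnotation(genome_id=genome_id, scaffolds={}, genes=genes)


def write_gene_features(annotation: GenomeAnnotation, path) -> None:
    """Write a GenomeAnnotation as GFF3 (converting back to 1-based inclusive)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for scaffold_id in sorted(annotation.scaffolds):
            length = annotation.scaffolds[scaffold_id]
            if length is not None:
                fh.write(f"##sequence-region {scaffold_id} 1 {length}\n")
        for g in annotation.genes:
            attrs = f"ID={g.gene_id};locus_tag={g.gene_id}"
            if g.annotation:
                attrs += f";product={g.annotation}"
            fh.write(
                "\t".join(
                    [
                        g.scaffold_id,
                        "glycomine",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand if g.strand != "?" else ".",
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BGC intervals
# ---------------------------------------------------------------------------


def read_bgc_intervals(path, genome_id: str) -> list[BgcInterval]:
    """Read BGC intervals from BED (0-based half-open) or a headered TSV.

    Duplicate (scaffold, start, end) intervals are collapsed with a warning;
    negative coordinates are a parse error. An empty file yields an empty list.
    """
    path = Path(path)
    intervals: list[BgcInterval] = []
    seen: dict[tuple, str] = {}
    n_bgc = 0
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header: Optional[list[str]] = None
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#") or row[0] in {"track", "browser"}:
                continue
            if header is None and len(row) >= 3 and not _is_int(row[1]):
                header = row  # headered TSV dialect
                continue
            if len(row) < 3:
                raise ParseError(path, lineno, f"expected >=3 columns, got {len(row)}")
            if header is not None:
                rec = dict(zip(header, row))
                scaffold = rec.get("scaffold_id", rec.get("scaffold", ""))
                start_s, end_s = rec.get("start", ""), rec.get("end", "")
                bgc_id = rec.get("bgc_id", "")
                ptype = rec.get("predicted_type", "")
                similar = None
                if rec.get("similar_cluster"):
                    similar = (rec["similar_cluster"], float(rec.get("similar_pct", "nan")))
            else:
                scaffold, start_s, end_s = row[0], row[1], row[2]
                bgc_id = row[3] if len(row) > 3 else ""
                ptype = row[4] if len(row) > 4 else ""
                similar = None
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(path, lineno, f"non-integer coordinates {start_s!r}/{end_s!r}")
            if start < 0:
                raise ParseError(path, lineno, f"negative coordinate {start}")
            if not start < end:
                raise ParseError(path, lineno, f"require start < end, got [{start}, {end})")
            key = (scaffold, start, end)
            if key in seen:
                warnings.warn(
                    f"{path}:{lineno}: duplicate interval {key} collapsed", stacklevel=2
                )
                continue
            n_bgc += 1
            if not bgc_id:
                bgc_id = f"bgc{n_bgc:03d}"
            seen[key] = bgc_id
            intervals.append(
                BgcInterval(
                    bgc_id=bgc_id,
                    genome_id=genome_id,
                    scaffold_id=scaffold,
                    start=start,
                    end=end,
                    predicted_type=ptype,
                    similar_known_cluster=similar,
                )
            )
    return intervals


def write_bgc_intervals(bgcs: Iterable[BgcInterval], path) -> None:
    """Write BGC intervals as BED4 (+type in column 5 when present)."""
    with open(path, "w") as fh:
        for b in sorted(bgcs, key=lambda b: (b.scaffold_id, b.start, b.end)):
            cols = [b.scaffold_id, str(b.start), str(b.end), b.bgc_id]
            if b.predicted_type:
                cols.append(b.predicted_type)
            fh.write("\t".join(cols) + "\n")


def _is_int(text: str) -> bool:
    try:
        int(text)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# BLAST tabular hits
# ---------------------------------------------------------------------------

_BLAST_NCOL = 12


def read_blast_hits(path, subject_lengths: Mapping[str, int] | str | Path) -> list[BlastHit]:
    """Read a 12-column tabular homology hit file.

    ``subject_lengths`` maps subject id to residue length (or is a 2-column
    TSV of the same), required to compute subject coverage
    (aligned subject span / subject length).
    """
    if not isinstance(subject_lengths, Mapping):
        lengths: dict[str, int] = {}
        with open(subject_lengths) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                lengths[row[0]] = int(row[1])
        subject_lengths = lengths

    hits: list[BlastHit] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != _BLAST_NCOL:
                raise ParseError(
                    path, lineno, f"expected {_BLAST_NCOL} columns, got {len(row)}"
                )
            query, subject = row[0], row[1]
            try:
                pident = float(row[2])
                sstart, send = int(row[8]), int(row[9])
                evalue = float(row[10])
                bitscore = float(row[11])
            except ValueError:
                raise ParseError(path, lineno, "malformed numeric field")
            if subject not in subject_lengths:
                raise ParseError(path, lineno, f"no length for subject {subject!r}")
            span = abs(send - sstart) + 1  # tabular coordinates are 1-based inclusive
            coverage = min(span / subject_lengths[subject], 1.0)
            hits.append(
                BlastHit(
                    query_id=query,
                    subject_id=subject,
                    percent_identity=pident,
                    evalue=evalue,
                    coverage=coverage,
                    bitscore=bitscore,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# generic TSV output with "#"-prefixed metadata lines
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path, meta: Optional[Mapping[str, object]] = None) -> None:
    """Write a DataFrame as TSV with leading ``# key: value`` metadata lines."""
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`, skipping metadata lines."""
    return pd.read_csv(path, sep="\t", comment="#")


def config_hash(params: Mapping[str, object]) -> str:
    """Stable short hash of a parameter mapping, for output provenance lines."""
    text = ";".join(f"{k}={params[k]}" for k in sorted(params))
    return hashlib.sha256(text.encode()).hexdigest()[:12]
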