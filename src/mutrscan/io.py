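"""Data model and file IO for genomes, annotations, segments, expression and PWMs.

Internal coordinates are 0-based half-open everywhere; conversion to and from
1-based closed coordinates happens only at the GFF3 file boundary.  Strand is
mandatory on every feature and segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord

KNOWN_CLASSES = ("ORF", "snoRNA", "rRNA", "tRNA", "SUT", "CUT", "MUT")
BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# sample design vocabulary
STRAIN_A = "MATa"
STRAIN_AALPHA = "MATa/alpha"
STRAIN_ALPHAALPHA = "MATalpha/alpha"
MEDIA = ("YPD", "YPA", "SPII", "sync")
SPII_HOURS = tuple(range(1, 13))
#: condition axis used for segment/ORF correlation: YPD, YPA and SPII 1-12 h
#: of the sporulating diploid, replicates averaged first -> 14 values.
CONDITIONS = ("YPD", "YPA") + tuple(f"SPII_{h:02d}h" for h in SPII_HOURS)


class AnnotationError(ValueError):
    """Malformed annotation, segment or matrix input."""


@dataclass(frozen=True)
class GeneFeature:
    """A strand-aware annotated feature.

    For protein-coding genes ``tss`` and ``terminator`` default to the
    ORF-proximal 5' and 3' boundaries; explicit UTR annotation may override
    them.  On the + strand the TSS is the smaller coordinate, on the - strand
    the larger one.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    tss: int = -1
    terminator: int = -1
    feature_class: str = "ORF"

    def __post_init__(self):
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: strand must be + or -")
        if not 0 <= self.start < self.end:
            raise AnnotationError(f"{self.gene_id}: invalid interval [{self.start},{self.end})")
        if self.tss < 0:
            object.__setattr__(self, "tss", self.start if self.strand == "+" else self.end)
        if self.terminator < 0:
            object.__setattr__(self, "terminator", self.end if self.strand == "+" else self.start)
        if self.strand == "+" and self.tss > self.terminator:
            raise AnnotationError(f"{self.gene_id}: + strand requires tss <= terminator")
        if self.strand == "-" and self.tss < self.terminator:
            raise AnnotationError(f"{self.gene_id}: - strand requires tss >= terminator")

    @property
    def is_orf(self) -> bool:
        return self.feature_class == "ORF"


@dataclass(frozen=True)
class Segment:
    """A contiguous expression segment from a prior segmentation step."""

    segment_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise AnnotationError(f"{self.segment_id}: strand must be + or -")
        if not 0 <= self.start < self.end:
            raise AnnotationError(
                f"{self.segment_id}: invalid interval [{self.start},{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PwmRecord:
    """Per-position nucleotide observation counts, columns ordered A,C,G,T."""

    identifier: str
    counts: np.ndarray  # shape (L, 4)

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise AnnotationError(f"{self.identifier}: counts must be (L, 4)")
        if (counts < 0).any():
            raise AnnotationError(f"{self.identifier}: negative counts")
        if (counts.sum(axis=1) <= 0).any():
            raise AnnotationError(f"{self.identifier}: empty count column")


@dataclass
class ExpressionMatrix:
    """Log2-normalized expression for segments and genes across the sample set.

    ``values`` is indexed by row id with one column per sample id; ``samples``
    is indexed by sample id with columns strain/medium/timepoint/replicate.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        missing = set(self.values.columns) ^ set(self.samples.index)
        if missing:
            raise AnnotationError(
                "matrix columns and sample sheet ids disagree: " + ", ".join(sorted(missing))
            )
        if "replicate" not in self.samples.columns:
            self.samples = self.samples.assign(replicate=1)
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise AnnotationError("expression values must all be finite")
        bad_strain = set(self.samples["strain"]) - {STRAIN_A, STRAIN_AALPHA, STRAIN_ALPHAALPHA}
        if bad_strain:
            raise AnnotationError(f"unknown strain labels: {sorted(bad_strain)}")
        bad_medium = set(self.samples["medium"]) - set(MEDIA)
        if bad_medium:
            raise AnnotationError(f"unknown medium labels: {sorted(bad_medium)}")
        desc = list(
            zip(self.samples["strain"], self.samples["medium"],
                self.samples["timepoint"].fillna(-1.0), self.samples["replicate"])
        )
        if len(set(desc)) != len(desc):
            raise AnnotationError("sample descriptors (strain, medium, timepoint, replicate) not unique")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    def row(self, row_id: str) -> pd.Series:
        if row_id not in self.values.index:
            raise KeyError(f"row id {row_id!r} not in expression matrix")
        return self.values.loc[row_id]

    def sample_ids(self, strain: str | None = None, medium: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        if strain is not None:
            mask &= self.samples["strain"] == strain
        if medium is not None:
            mask &= self.samples["medium"] == medium
        return list(self.samples.index[mask])

    def nonsporulation_sample_ids(self) -> list[str]:
        """All mitotic and starvation samples: everything except the sporulating
        diploid's SPII time course."""
        spii = (self.samples["strain"] == STRAIN_AALPHA) & (self.samples["medium"] == "SPII")
        return list(self.samples.index[~spii])

    def spii_profile(self, row_id: str) -> pd.Series:
        """SPII 1-12 h profile of the sporulating diploid, replicates averaged,
        indexed by integer hour."""
        row = self.row(row_id)
        meta = self.samples
        out = {}
        for h in SPII_HOURS:
            ids = meta.index[
                (meta["strain"] == STRAIN_AALPHA)
                & (meta["medium"] == "SPII")
                & (meta["timepoint"] == float(h))
            ]
            if len(ids) == 0:
                raise AnnotationError(f"missing SPII {h} h sample for {STRAIN_AALPHA}")
            out[h] = float(row[ids].mean())
        return pd.Series(out)

    def condition_values(self, row_id: str) -> np.ndarray:
        """The 14 condition values (YPD, YPA, SPII 1-12 h of the sporulating
        diploid; replicates averaged) used for the correlation test."""
        row = self.row(row_id)
        meta = self.samples
        vals = []
        for medium in ("YPD", "YPA"):
            ids = meta.index[(meta["strain"] == STRAIN_AALPHA) & (meta["medium"] == medium)]
            if len(ids) == 0:
                raise AnnotationError(f"missing {medium} sample for {STRAIN_AALPHA}")
            vals.append(float(row[ids].mean()))
        spii = self.spii_profile(row_id)
        vals.extend(float(v) for v in spii.values)
        return np.asarray(vals)


def standard_sample_sheet(replicates: int = 1) -> pd.DataFrame:
    """The study's 45-sample design (times ``replicates``): a synchronized
    haploid MATa mitotic time course (0-135 min, every 5 min), the sporulating
    diploid in YPD, YPA and SPII 1-12 h, and the sporulation-deficient
    MATalpha/alpha diploid in YPA and SPII 8 and 10 h."""
    rows = []
    for rep in range(1, replicates + 1):
        suf = "" if replicates == 1 else f"_r{rep}"
        for minute in range(0, 140, 5):
            rows.append((f"mito_{minute:03d}min{suf}", STRAIN_A, "sync", float(minute), rep))
        rows.append((f"YPD{suf}", STRAIN_AALPHA, "YPD", np.nan, rep))
        rows.append((f"YPA{suf}", STRAIN_AALPHA, "YPA", np.nan, rep))
        for h in SPII_HOURS:
            rows.append((f"SPII_{h:02d}h{suf}", STRAIN_AALPHA, "SPII", float(h), rep))
        rows.append((f"aa_YPA{suf}", STRAIN_ALPHAALPHA, "YPA", np.nan, rep))
        for h in (8, 10):
            rows.append((f"aa_SPII_{h:02d}h{suf}", STRAIN_ALPHAALPHA, "SPII", float(h), rep))
    sheet = pd.DataFrame(rows, columns=["id", "strain", "medium", "timepoint", "replicate"])
    return sheet.set_index("id")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 (gene / ncRNA dialect with a class= attribute)


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for chunk in text.strip().split(";"):
        if chunk and "=" in chunk:
            key, val = chunk.split("=", 1)
            out[key.strip()] = val.strip()
    return out


def read_annotation(path: str | Path) -> list[GeneFeature]:
    """Read gene/ncRNA features from GFF3 (1-based closed) into 0-based
    half-open :class:`GeneFeature` records.  Unknown classes parse as
    ``other``; malformed lines fail naming the line number."""
    features = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            chrom, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise AnnotationError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if strand not in "+-":
                raise AnnotationError(f"{path}: line {lineno}: strand must be + or -")
            attributes = _parse_gff_attributes(attrs)
            gene_id = attributes.get("ID")
            if gene_id is None:
                raise AnnotationError(f"{path}: line {lineno}: missing ID attribute")
            cls = attributes.get("class", "ORF" if ftype == "gene" else "other")
            if cls not in KNOWN_CLASSES:
                cls = "other"
            features.append(
                GeneFeature(
                    gene_id=gene_id, chrom=chrom, strand=strand,
                    start=start_i - 1, end=end_i, feature_class=cls,
                )
            )
    return features


def write_annotation(features: Iterable[GeneFeature], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for f in features:
            ftype = "gene" if f.is_orf else "ncRNA"
            attrs = f"ID={f.gene_id};class={f.feature_class}"
            handle.write(
                f"{f.chrom}\tmutrscan\t{ftype}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# BED6 segments


def read_segments(path: str | Path) -> list[Segment]:
    """Read segments from BED6 (already half-open) or from GFF3."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        feats = read_annotation(path)
        return [
            Segment(f.gene_id, f.chrom, f.strand, f.start, f.end) for f in feats
        ]
    segments = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AnnotationError(f"{path}: line {lineno}: BED6 requires 6 columns")
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise AnnotationError(f"{path}: line {lineno}: non-integer coordinate") from exc
            segments.append(Segment(name, chrom, strand, start_i, end_i))
    return segments


def write_segments(segments: Iterable[Segment], path: str | Path) -> None:
    with open(path, "w") as handle:
        for s in segments:
            handle.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.segment_id}\t0\t{s.strand}\n")


def write_mutr_bed(calls: Iterable, path: str | Path) -> None:
    """Write mUTR calls as BED6: name = gene|side|timing, score =
    round(1000 * (1 - adjusted P)) clamped to [0, 1000]."""
    with open(path, "w") as handle:
        for call in calls:
            seg = call.segment
            timing = call.timing.timing_class if call.timing is not None else "NA"
            name = f"{call.gene.gene_id}|{call.side}|{timing}"
            score = int(round(1000 * (1 - call.correlation.p_adjusted)))
            score = max(0, min(1000, score))
            handle.write(
                f"{seg.chrom}\t{seg.start}\t{seg.end}\t{name}\t{score}\t{seg.strand}\n"
            )


# ---------------------------------------------------------------------------
# Expression TSV


def read_expression(matrix_path: str | Path, samplesheet_path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if values.isna().any().any():
        bad = values.index[values.isna().any(axis=1)]
        raise AnnotationError(
            f"{matrix_path}: non-finite/missing values in rows {list(bad[:5])}"
        )
    samples = pd.read_csv(samplesheet_path, sep="\t", index_col=0)
    required = {"strain", "medium", "timepoint"}
    if not required <= set(samples.columns):
        raise AnnotationError(f"{samplesheet_path}: sample sheet needs columns {sorted(required)}")
    return ExpressionMatrix(values=values, samples=samples)


def write_expression(expr: ExpressionMatrix, matrix_path: str | Path,
                     samplesheet_path: str | Path) -> None:
    out = expr.values.copy()
    out.index.name = "id"
    out.to_csv(matrix_path, sep="\t", float_format="%.4f")
    sheet = expr.samples.copy()
    sheet.index.name = "id"
    sheet.to_csv(samplesheet_path, sep="\t")


# ---------------------------------------------------------------------------
# TRANSFAC matrix format


def read_transfac(path: str | Path) -> list[PwmRecord]:
    """Parse TRANSFAC matrix blocks (ID / P0 header / numbered count rows /
    ``//`` terminator).  The P0 header may permute the base order; columns are
    re-ordered to A,C,G,T."""
    records = []
    identifier = None
    order: list[int] | None = None
    rows: list[list[float]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            tag = line.split()[0]
            if tag == "//":
                if identifier is None and not rows:
                    continue
                if identifier is None or not rows:
                    raise AnnotationError(f"{path}: line {lineno}: incomplete TRANSFAC block")
                counts = np.zeros((len(rows), 4))
                for i, row in enumerate(rows):
                    for j, v in zip(order, row):  # type: ignore[arg-type]
                        counts[i, j] = v
                records.append(PwmRecord(identifier, counts))
                identifier, order, rows = None, None, []
            elif tag in ("ID", "AC", "NA"):
                if identifier is None or tag == "ID":
                    identifier = line.split(maxsplit=1)[1].strip()
            elif tag in ("P0", "PO"):
                letters = line.split()[1:5]
                if sorted(letters) != list("ACGT"):
                    raise AnnotationError(f"{path}: line {lineno}: P0 header must list A,C,G,T")
                order = [BASE_INDEX[b] for b in letters]
            elif tag[:2].isdigit():
                if order is None:
                    raise AnnotationError(f"{path}: line {lineno}: count row before P0 header")
                cells = line.split()[1:5]
                try:
                    rows.append([float(c) for c in cells])
                except ValueError as exc:
                    raise AnnotationError(f"{path}: line {lineno}: non-numeric count cell") from exc
                if len(cells) != 4:
                    raise AnnotationError(f"{path}: line {lineno}: expected 4 count cells")
    if identifier is not None or rows:
        raise AnnotationError(f"{path}: missing // terminator at end of file")
    return records


def write_transfac(records: Iterable[PwmRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f"ID {rec.identifier}\nP0      A      C      G      T\n")
            for i, row in enumerate(rec.counts, start=1):
                cells = "".join(f"{v:7g}" for v in row)
                handle.write(f"{i:02d}{cells}\n")
            handle.write("//\n")


# ---------------------------------------------------------------------------
# Upstream windows


def upstream_window(genome: Mapping[str, str], chrom: str, strand: str,
                    anchor: int, width: int = 100) -> str:
    """Sequence of up to ``width`` bases immediately upstream of ``anchor``.

    On the + strand this is ``[anchor - width, anchor)`` on the forward
    strand; on the - strand the reverse complement of ``[anchor, anchor +
    width)``.  Windows are truncated (never padded) at chromosome edges.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    seq = genome[chrom]
    if not 0 <= anchor <= len(seq):
        raise ValueError(f"anchor {anchor} outside chromosome {chrom} (length {len(seq)})")
    if strand == "+":
        return seq[max(0, anchor - width):anchor]
    if strand == "-":
        return reverse_complement(seq[anchor:min(len(seq), anchor + width)])
    raise ValueError("strand must be + or -")
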