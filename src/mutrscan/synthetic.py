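"""Synthetic miniature datasets with the statistical structure the caller assumes.

The generator emits a small random genome, an annotation of non-overlapping
ORFs plus non-coding decoy features, an expression-segment set, a log2
expression matrix over the study's 45-sample design (a synchronized MATa
mitotic time course 0-135 min every 5 min; the sporulating diploid in YPD,
YPA and SPII 1-12 h; the sporulation-deficient MATalpha/alpha diploid in YPA
and SPII 8/10 h) and a ground-truth table.

Planted 5'/3' UTR-extension segments satisfy every selection criterion by
construction: sporulation-only expression with an early/middle/late peak,
<100 bp from the cognate ORF's TSS/terminator, and no expression correlation
with the (constitutively expressed) ORF.  Decoy segments each violate
exactly one criterion: expressed in mitosis, placed >= 100 bp away, or
correlated with an ORF whose own profile carries the same sporulation bump.
Segments overlapping annotated non-coding features test the annotation
filter.  URS1 occurrences (the classical consensus TAGCCGCCGA, or a
single-substitution variant) are planted on either strand in the 100-bp
window upstream of each 5'-mUTR's distal end at a controlled rate, and in
the 100-bp window upstream of every gene's mitotic TSS at a background rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .io import (ExpressionMatrix, GeneFeature, Segment, SPII_HOURS,
                 STRAIN_AALPHA, standard_sample_sheet, write_annotation,
                 write_expression, write_fasta, write_segments)
from .pwm import URS1_CONSENSUS

TIMING_CLASSES = ("early", "middle", "late")
TIMING_PEAK_HOURS = {"early": (1, 4), "middle": (5, 8), "late": (9, 12)}
DECOY_KINDS = ("decoy_mitotic", "decoy_far", "decoy_correlated")

# slot layout per gene (bp)
_UPSTREAM_MARGIN = 1100
_DOWNSTREAM_MARGIN = 700
_ORF_MIN, _ORF_MAX = 300, 600
_MIN_SLOT = _UPSTREAM_MARGIN + _ORF_MIN + _DOWNSTREAM_MARGIN

# observed meiotic UTR length scale: log-normal around the published medians
_LEN_5P = dict(median=241.0, sigma=0.45, lo=56, hi=900)
_LEN_3P = dict(median=173.0, sigma=0.45, lo=57, hi=600)

_URS1_WINDOW = 100
_EXACT_PLANT_FRACTION = 0.75


class PackingError(ValueError):
    """Too many genes for the requested chromosome length."""


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 50_000
    n_genes: int = 40
    n_planted_5p_mutrs: int = 10
    n_planted_3p_mutrs: int = 6
    n_decoy_segments: int = 9
    timing_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    urs1_plant_rate_target: float = 0.66
    urs1_plant_rate_background: float = 0.10
    background_level: float = 4.0
    expressed_level: float = 9.0
    noise_sd: float = 0.25
    background_threshold_tau: float = 6.0
    replicates: int = 1

    def __post_init__(self):
        counts = (self.n_chromosomes, self.chrom_length, self.n_genes,
                  self.n_planted_5p_mutrs, self.n_planted_3p_mutrs,
                  self.n_decoy_segments)
        if any(c < 0 for c in counts) or self.n_chromosomes == 0 or self.chrom_length <= 0:
            raise ValueError("counts must be non-negative, chromosomes/length positive")
        for rate in (self.urs1_plant_rate_target, self.urs1_plant_rate_background):
            if not 0 <= rate <= 1:
                raise ValueError("plant rates must lie in [0, 1]")
        if not math.isclose(sum(self.timing_mix), 1.0, abs_tol=1e-9):
            raise ValueError("timing_mix must sum to 1")
        if not (self.expressed_level > self.background_threshold_tau > self.background_level):
            raise ValueError("need expressed_level > tau > background_level")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        roles = self.n_planted_5p_mutrs + self.n_planted_3p_mutrs + self.n_decoy_segments
        if roles > self.n_genes:
            raise ValueError(
                f"need n_genes >= planted + decoy segments ({roles}), got {self.n_genes}"
            )
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class SyntheticGenome:
    config: SimConfig
    sequences: dict[str, str]
    genes: list[GeneFeature]
    segments: list[Segment]
    truth: pd.DataFrame       # one row per segment
    promoters: pd.DataFrame   # one row per ORF gene: mitotic-promoter URS1 truth


TRUTH_COLUMNS = ["segment_id", "gene_id", "side", "timing", "kind",
                 "peak_spii_hour", "urs1_planted", "urs1_position", "urs1_strand",
                 "urs1_exact"]
PROMOTER_COLUMNS = ["gene_id", "chrom", "window_start", "window_end", "strand",
                    "urs1_planted", "urs1_position", "urs1_strand", "urs1_exact"]


def _draw_length(rng: np.random.Generator, spec: dict) -> int:
    val = rng.lognormal(mean=math.log(spec["median"]), sigma=spec["sigma"])
    return int(np.clip(round(val), spec["lo"], spec["hi"]))


def _plant_motif(chrom_seq: np.ndarray, occupied: list[tuple[int, int]],
                 window_start: int, window_end: int,
                 rng: np.random.Generator) -> tuple[int, str, bool] | None:
    """Write the URS1 consensus (or a 1-substitution variant) on a random
    strand at a random collision-free position inside the window; returns
    (genomic start, strand, exact?) or None if no free position was found."""
    L = len(URS1_CONSENSUS)
    if window_end - window_start < L:
        return None
    motif = URS1_CONSENSUS
    exact = bool(rng.random() < _EXACT_PLANT_FRACTION)
    if not exact:
        pos = int(rng.integers(L))
        base = motif[pos]
        alt = str(rng.choice([b for b in "ACGT" if b != base]))
        motif = motif[:pos] + alt + motif[pos + 1:]
    strand = "+" if rng.random() < 0.5 else "-"
    written = motif if strand == "+" else reverse_complement(motif)
    for _ in range(20):
        start = int(rng.integers(window_start, window_end - L + 1))
        if all(start + L <= a or start >= b for a, b in occupied):
            chrom_seq[start:start + L] = np.frombuffer(written.encode(), dtype=np.uint8)
            occupied.append((start, start + L))
            return start, strand, exact
    return None


def generate_genome(cfg: SimConfig) -> SyntheticGenome:
    """Deterministically generate genome, annotation, segments and truth."""
    rng = np.random.default_rng([cfg.seed, 0])
    genes_per_chrom = math.ceil(cfg.n_genes / cfg.n_chromosomes) if cfg.n_genes else 0
    if genes_per_chrom:
        slot = cfg.chrom_length // genes_per_chrom
        if slot < _MIN_SLOT:
            raise PackingError(
                f"{genes_per_chrom} genes per {cfg.chrom_length} bp chromosome leaves "
                f"{slot} bp per gene; at least {_MIN_SLOT} bp is required"
            )
    sequences = {
        f"chr{i + 1}": rng.integers(0, 4, size=cfg.chrom_length)
        for i in range(cfg.n_chromosomes)
    }
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq_arrays = {c: base_codes[v].copy() for c, v in sequences.items()}

    genes: list[GeneFeature] = []
    for i in range(cfg.n_genes):
        chrom = f"chr{i // genes_per_chrom + 1}"
        slot_start = (i % genes_per_chrom) * slot
        strand = "+" if rng.random() < 0.5 else "-"
        orf_len = int(rng.integers(_ORF_MIN, min(_ORF_MAX, slot - _UPSTREAM_MARGIN
                                                 - _DOWNSTREAM_MARGIN) + 1))
        if strand == "+":
            orf_start = slot_start + _UPSTREAM_MARGIN
            orf_end = orf_start + orf_len
        else:
            orf_end = slot_start + slot - _UPSTREAM_MARGIN
            orf_start = orf_end - orf_len
        genes.append(GeneFeature(f"gene_{i + 1:03d}", chrom, strand, orf_start, orf_end))

    # role assignment: shuffled so planted genes are scattered along chromosomes
    order = rng.permutation(cfg.n_genes)
    n5, n3, nd = cfg.n_planted_5p_mutrs, cfg.n_planted_3p_mutrs, cfg.n_decoy_segments
    idx_5p = order[:n5]
    idx_3p = order[n5:n5 + n3]
    idx_decoy = order[n5 + n3:n5 + n3 + nd]
    idx_background = order[n5 + n3 + nd:]

    segments: list[Segment] = []
    truth_rows: list[dict] = []

    def _upstream_segment(gene: GeneFeature, length: int, gap: int, seg_id: str) -> Segment:
        if gene.strand == "+":
            end = gene.tss - gap
            return Segment(seg_id, gene.chrom, "+", end - length, end)
        start = gene.tss + gap
        return Segment(seg_id, gene.chrom, "-", start, start + length)

    def _downstream_segment(gene: GeneFeature, length: int, gap: int, seg_id: str) -> Segment:
        if gene.strand == "+":
            start = gene.terminator + gap
            return Segment(seg_id, gene.chrom, "+", start, start + length)
        end = gene.terminator - gap
        return Segment(seg_id, gene.chrom, "-", end - length, end)

    def _draw_timing() -> tuple[str, int]:
        timing = str(rng.choice(TIMING_CLASSES, p=cfg.timing_mix))
        lo, hi = TIMING_PEAK_HOURS[timing]
        return timing, int(rng.integers(lo, hi + 1))

    for k, gi in enumerate(idx_5p):
        gene = genes[gi]
        seg = _upstream_segment(gene, _draw_length(rng, _LEN_5P),
                                int(rng.integers(0, 51)), f"seg_5p_{k + 1:03d}")
        timing, peak = _draw_timing()
        segments.append(seg)
        truth_rows.append(dict(segment_id=seg.segment_id, gene_id=gene.gene_id,
                               side="5p", timing=timing, kind="mutr",
                               peak_spii_hour=peak))
    for k, gi in enumerate(idx_3p):
        gene = genes[gi]
        seg = _downstream_segment(gene, _draw_length(rng, _LEN_3P),
                                  int(rng.integers(0, 51)), f"seg_3p_{k + 1:03d}")
        timing, peak = _draw_timing()
        segments.append(seg)
        truth_rows.append(dict(segment_id=seg.segment_id, gene_id=gene.gene_id,
                               side="3p", timing=timing, kind="mutr",
                               peak_spii_hour=peak))
    for k, gi in enumerate(idx_decoy):
        gene = genes[gi]
        kind = DECOY_KINDS[k % len(DECOY_KINDS)]
        gap = int(rng.integers(120, 251)) if kind == "decoy_far" else int(rng.integers(0, 51))
        length = _draw_length(rng, dict(_LEN_5P, hi=700))
        seg = _upstream_segment(gene, length, gap, f"seg_decoy_{k + 1:03d}")
        timing, peak = _draw_timing()
        if kind == "decoy_mitotic":
            timing, peak = "none", -1
        segments.append(seg)
        truth_rows.append(dict(segment_id=seg.segment_id, gene_id=gene.gene_id,
                               side="none", timing=timing, kind=kind,
                               peak_spii_hour=peak))

    # non-coding decoy features and segments that exactly overlap them
    nc_classes = ("snoRNA", "tRNA", "SUT", "CUT", "MUT")
    n_ncrna = min(len(nc_classes), len(idx_background))
    for k in range(n_ncrna):
        gene = genes[idx_background[k]]
        nc_len = int(rng.integers(80, 151))
        if gene.strand == "+":
            start = gene.terminator + 20
            nc = GeneFeature(f"nc_{k + 1:03d}", gene.chrom, "+", start, start + nc_len,
                             feature_class=nc_classes[k])
        else:
            end = gene.terminator - 20
            nc = GeneFeature(f"nc_{k + 1:03d}", gene.chrom, "-", end - nc_len, end,
                             feature_class=nc_classes[k])
        genes.append(nc)
        seg = Segment(f"seg_nc_{k + 1:03d}", nc.chrom, nc.strand, nc.start, nc.end)
        timing, peak = _draw_timing()
        segments.append(seg)
        truth_rows.append(dict(segment_id=seg.segment_id, gene_id=nc.gene_id,
                               side="none", timing=timing, kind="annotated",
                               peak_spii_hour=peak))

    # URS1 planting
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in seq_arrays}
    seg_by_id = {s.segment_id: s for s in segments}
    target_gene_ids = {genes[gi].gene_id for gi in idx_5p}
    for row in truth_rows:
        row.update(urs1_planted=False, urs1_position=-1, urs1_strand=".", urs1_exact=False)
        if row["side"] != "5p":
            continue
        if rng.random() >= cfg.urs1_plant_rate_target:
            continue
        seg = seg_by_id[row["segment_id"]]
        if seg.strand == "+":
            win = (seg.start - _URS1_WINDOW, seg.start)
        else:
            win = (seg.end, seg.end + _URS1_WINDOW)
        planted = _plant_motif(seq_arrays[seg.chrom], occupied[seg.chrom],
                               win[0], win[1], rng)
        if planted is not None:
            pos, strand, exact = planted
            row.update(urs1_planted=True, urs1_position=pos, urs1_strand=strand,
                       urs1_exact=exact)

    promoter_rows = []
    for gene in genes:
        if not gene.is_orf:
            continue
        if gene.strand == "+":
            win = (gene.tss - _URS1_WINDOW, gene.tss)
        else:
            win = (gene.tss, gene.tss + _URS1_WINDOW)
        rec = dict(gene_id=gene.gene_id, chrom=gene.chrom, window_start=win[0],
                   window_end=win[1], strand=gene.strand, urs1_planted=False,
                   urs1_position=-1, urs1_strand=".", urs1_exact=False)
        if rng.random() < cfg.urs1_plant_rate_background:
            planted = _plant_motif(seq_arrays[gene.chrom], occupied[gene.chrom],
                                   win[0], win[1], rng)
            if planted is not None:
                pos, strand, exact = planted
                rec.update(urs1_planted=True, urs1_position=pos, urs1_strand=strand,
                           urs1_exact=exact)
        promoter_rows.append(rec)

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    promoters = pd.DataFrame(promoter_rows, columns=PROMOTER_COLUMNS)
    final_sequences = {c: arr.tobytes().decode() for c, arr in seq_arrays.items()}
    return SyntheticGenome(config=cfg, sequences=final_sequences, genes=genes,
                           segments=segments, truth=truth, promoters=promoters)


def _sporulation_bump(peak_hour: int, amplitude: float, width: float = 1.5) -> np.ndarray:
    hours = np.asarray(SPII_HOURS, dtype=float)
    return amplitude * np.exp(-((hours - peak_hour) ** 2) / (2 * width**2))


def generate_expression(cfg: SimConfig, genome: SyntheticGenome) -> ExpressionMatrix:
    """Expression matrix over the 45-sample design (times ``replicates``).

    ORF rows are expressed in every sample; planted mUTR rows (and decoys
    carrying a meiotic profile) sit at background everywhere except the
    sporulating diploid's SPII samples, where a Gaussian-shaped bump peaks at
    the truth table's peak hour.  Mitotic decoys are constitutively
    expressed; correlated decoys share their bump with the cognate ORF.
    Noise is additive Gaussian on the log2 scale.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    sheet = standard_sample_sheet(cfg.replicates)
    sample_ids = list(sheet.index)
    spii_mask = ((sheet["strain"] == STRAIN_AALPHA) & (sheet["medium"] == "SPII")).to_numpy()
    spii_hours = sheet["timepoint"].to_numpy()
    amplitude = cfg.expressed_level - cfg.background_level

    bad_timing = set(genome.truth["timing"]) - set(TIMING_CLASSES) - {"none"}
    if bad_timing:
        raise ValueError(f"unknown timing labels in truth table: {sorted(bad_timing)}")
    gene_ids = [g.gene_id for g in genome.genes if g.is_orf]
    known_genes = set(gene_ids) | {g.gene_id for g in genome.genes}
    unknown = set(genome.truth["gene_id"]) - known_genes
    if unknown:
        raise ValueError(f"truth table references unknown genes: {sorted(unknown)}")

    def _bump_vector(peak: int) -> np.ndarray:
        per_hour = dict(zip(SPII_HOURS, _sporulation_bump(peak, amplitude)))
        out = np.zeros(len(sample_ids))
        for j, (is_spii, h) in enumerate(zip(spii_mask, spii_hours)):
            if is_spii:
                out[j] = per_hour[int(h)]
        return out

    correlated_bumps: dict[str, np.ndarray] = {}
    rows = {}
    for rec in genome.truth.itertuples():
        base = np.full(len(sample_ids), cfg.background_level)
        if rec.kind == "decoy_mitotic":
            base[:] = cfg.expressed_level
        else:
            bump = _bump_vector(int(rec.peak_spii_hour))
            base += bump
            if rec.kind == "decoy_correlated":
                correlated_bumps[rec.gene_id] = 0.8 * bump
        rows[rec.segment_id] = base

    for gene_id in gene_ids:
        base = np.full(len(sample_ids), cfg.expressed_level)
        if gene_id in correlated_bumps:
            base += correlated_bumps[gene_id]
        rows[gene_id] = base

    values = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    if cfg.noise_sd > 0:
        values += rng.normal(0.0, cfg.noise_sd, size=values.shape)
    values.index.name = "id"
    return ExpressionMatrix(values=values, samples=sheet)


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    """TSV with header; round-trips losslessly via :func:`read_truth`."""
    if truth is None:
        raise ValueError("truth table is required")
    out = truth if len(truth) else pd.DataFrame(columns=TRUTH_COLUMNS)
    out.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t", dtype={"segment_id": str, "gene_id": str})
    if len(truth) == 0:
        return pd.DataFrame(columns=list(truth.columns))
    return truth


def generate_dataset(cfg: SimConfig) -> tuple[SyntheticGenome, ExpressionMatrix]:
    genome = generate_genome(cfg)
    return genome, generate_expression(cfg, genome)


def write_dataset(genome: SyntheticGenome, expr: ExpressionMatrix,
                  outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.gff3",
        "segments": outdir / "segments.bed",
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
        "promoters": outdir / "promoters.tsv",
    }
    write_fasta(genome.sequences, paths["genome"])
    write_annotation(genome.genes, paths["annotation"])
    write_segments(genome.segments, paths["segments"])
    write_expression(expr, paths["expression"], paths["samples"])
    write_truth(genome.truth, paths["truth"])
    genome.promoters.to_csv(paths["promoters"], sep="\t", index=False)
    return paths
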