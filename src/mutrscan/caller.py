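"""The mUTR annotation procedure.

Starting from expression segments produced by a prior segmentation step, the
caller (1) discards segments overlapping, on the same strand, anything
already annotated (ORFs, snoRNAs, rRNAs, tRNAs, SUTs, CUTs, MUTs); (2) keeps
segments whose expression rises above background only in sporulating cells;
(3) assigns each survivor to the nearest same-strand ORF less than 100 bp
from its TSS (5' candidates) or terminator (3' candidates), requiring the
ORF itself to be expressed during fermentation or respiration; (4) computes
the Pearson correlation between segment and ORF over the 14 averaged
condition values (YPD, YPA, SPII 1-12 h), whose t statistic has 12 degrees
of freedom; and (5) after Benjamini-Hochberg adjustment over all candidates
jointly, selects segments with NO significant correlation (adjusted P >
0.05) as distinct meiotic isoform extensions.

Note the deliberate logic of step 5: a significant correlation means the
segment co-varies with its ORF and is likely the same transcript, so the
procedure keeps the non-significant ones.  Low power therefore favours
selection; degenerate (zero-variance) profiles are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import (AnnotationError, ExpressionMatrix, GeneFeature, Segment,
                 STRAIN_AALPHA)

CORRELATION_N = 14
CORRELATION_DF = CORRELATION_N - 2


@dataclass(frozen=True)
class CallerConfig:
    tau: float = 6.0                      # log2 background threshold
    max_gap: int = 100                    # bp; candidacy requires gap < max_gap
    min_spii_timepoints_above_tau: int = 2
    alpha: float = 0.05                   # adjusted-P selection threshold
    require_orf_expressed_in: str = "either"   # YPD | YPA | either

    def __post_init__(self):
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.require_orf_expressed_in not in ("YPD", "YPA", "either"):
            raise ValueError("require_orf_expressed_in must be YPD, YPA or either")


@dataclass(frozen=True)
class CorrelationResult:
    cc: float
    n: int
    df: int
    t_stat: float
    p_raw: float
    p_adjusted: float = float("nan")
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class MutrCall:
    segment: Segment
    gene: GeneFeature
    side: str                 # 5p | 3p
    gap: int
    correlation: CorrelationResult
    timing: object | None = None   # TimingCall, filled by isoform statistics

    @property
    def segment_id(self) -> str:
        return self.segment.segment_id

    @property
    def gene_id(self) -> str:
        return self.gene.gene_id


def _overlaps(seg: Segment, feat: GeneFeature) -> bool:
    return (seg.chrom == feat.chrom and seg.strand == feat.strand
            and max(seg.start, feat.start) < min(seg.end, feat.end))


def filter_unannotated(segments: Sequence[Segment],
                       annotation: Sequence[GeneFeature]) -> list[Segment]:
    """Retain segments with no same-strand overlap with any annotated known-class
    feature.  Any overlap excludes; opposite-strand overlap does not."""
    by_loc: dict[tuple[str, str], list[GeneFeature]] = {}
    for feat in annotation:
        by_loc.setdefault((feat.chrom, feat.strand), []).append(feat)
    kept = []
    for seg in segments:
        feats = by_loc.get((seg.chrom, seg.strand), ())
        if not any(_overlaps(seg, f) for f in feats):
            kept.append(seg)
    return kept


def sporulation_specific(expr: ExpressionMatrix, row_id: str, cfg: CallerConfig) -> bool:
    """True iff the row exceeds tau in at least ``min_spii_timepoints_above_tau``
    SPII timepoints of the sporulating diploid and never (strictly) exceeds tau
    in any mitotic or starvation sample."""
    row = expr.row(row_id)
    nonspor = expr.nonsporulation_sample_ids()
    if not nonspor:
        raise AnnotationError("expression matrix has no mitotic/starvation samples")
    spii = expr.spii_profile(row_id)
    n_above = int((spii > cfg.tau).sum())
    if n_above < cfg.min_spii_timepoints_above_tau:
        return False
    return bool((row[nonspor] <= cfg.tau).all())


def _candidate(seg: Segment, gene: GeneFeature) -> tuple[str, int] | None:
    """(side, gap) of the segment relative to one gene, or None.

    The gap counts bases strictly between the segment boundary and the
    anchor (TSS for 5', terminator for 3').  A segment abutting or
    overlapping the anchor has gap 0 provided it does not extend past the
    opposite ORF boundary.
    """
    if seg.chrom != gene.chrom or seg.strand != gene.strand:
        return None
    candidates = []
    if gene.strand == "+":
        if seg.end <= gene.tss:
            candidates.append(("5p", gene.tss - seg.end))
        elif seg.start < gene.tss and seg.end <= gene.end:
            candidates.append(("5p", 0))
        if seg.start >= gene.terminator:
            candidates.append(("3p", seg.start - gene.terminator))
        elif seg.end > gene.terminator and seg.start >= gene.start:
            candidates.append(("3p", 0))
    else:
        if seg.start >= gene.tss:
            candidates.append(("5p", seg.start - gene.tss))
        elif seg.end > gene.tss and seg.start >= gene.start:
            candidates.append(("5p", 0))
        if seg.end <= gene.terminator:
            candidates.append(("3p", gene.terminator - seg.end))
        elif seg.start < gene.terminator and seg.end <= gene.end:
            candidates.append(("3p", 0))
    if not candidates:
        return None
    # a tiny ORF could qualify a segment on both sides: take the smaller gap,
    # 5' first on ties ("5p" < "3p" is false lexicographically, so order explicitly)
    candidates.sort(key=lambda c: (c[1], 0 if c[0] == "5p" else 1))
    return candidates[0]


def assign_to_gene(seg: Segment, genes: Sequence[GeneFeature],
                   cfg: CallerConfig) -> tuple[str, str, int] | None:
    """Assign a segment to the qualifying ORF with the smallest gap
    (< max_gap); ties break on lexicographic gene id.  Returns
    (gene_id, side, gap) or None."""
    best: tuple[int, str, str] | None = None
    for gene in genes:
        if not gene.is_orf:
            continue
        cand = _candidate(seg, gene)
        if cand is None:
            continue
        side, gap = cand
        if gap >= cfg.max_gap:
            continue
        key = (gap, gene.gene_id, side)
        if best is None or key < (best[0], best[1], best[2]):
            best = key
    if best is None:
        return None
    gap, gene_id, side = best
    return gene_id, side, gap


def correlate(segment_values: np.ndarray, orf_values: np.ndarray) -> CorrelationResult:
    """Pearson correlation over the 14 paired condition values with the
    t-distribution (df = 12) two-sided P.

    Zero-variance rows make the coefficient undefined; they are treated as
    cc = 0 with P = 1 and flagged."""
    x = np.asarray(segment_values, dtype=float)
    y = np.asarray(orf_values, dtype=float)
    if x.shape != (CORRELATION_N,) or y.shape != (CORRELATION_N,):
        raise AnnotationError(
            f"correlation requires exactly {CORRELATION_N} condition values per row"
        )
    flags: tuple[str, ...] = ()
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(cc=0.0, n=CORRELATION_N, df=CORRELATION_DF,
                                 t_stat=0.0, p_raw=1.0, flags=("degenerate_variance",))
    cc = float(np.corrcoef(x, y)[0, 1])
    cc = max(-1.0, min(1.0, cc))
    if abs(cc) == 1.0:
        t = float("inf") if cc > 0 else float("-inf")
        p = 0.0
    else:
        t = cc * np.sqrt(CORRELATION_DF / (1.0 - cc * cc))
        p = float(2.0 * sps.t.sf(abs(t), CORRELATION_DF))
    return CorrelationResult(cc=cc, n=CORRELATION_N, df=CORRELATION_DF,
                             t_stat=float(t), p_raw=min(1.0, p), flags=flags)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values, input order preserved,
    capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p values must lie in [0, 1]")
    return sps.false_discovery_control(p, method="bh")


def _orf_expressed(expr: ExpressionMatrix, gene_id: str, cfg: CallerConfig) -> bool:
    row = expr.row(gene_id)
    means = {}
    for medium in ("YPD", "YPA"):
        ids = expr.sample_ids(strain=STRAIN_AALPHA, medium=medium)
        if not ids:
            raise AnnotationError(f"missing {medium} samples")
        means[medium] = float(row[ids].mean())
    if cfg.require_orf_expressed_in == "either":
        return means["YPD"] > cfg.tau or means["YPA"] > cfg.tau
    return means[cfg.require_orf_expressed_in] > cfg.tau


def call_mutrs(segments: Sequence[Segment], annotation: Sequence[GeneFeature],
               expr: ExpressionMatrix, cfg: CallerConfig = CallerConfig(),
               ) -> tuple[list[MutrCall], pd.DataFrame]:
    """Run the full annotation procedure; returns the selected calls and a
    per-candidate report (one row per segment that reached the correlation
    stage, whether or not it was selected)."""
    genes_by_id = {g.gene_id: g for g in annotation if g.is_orf}
    unannotated = filter_unannotated(segments, annotation)
    candidates = []
    for seg in sorted(unannotated, key=lambda s: s.segment_id):
        if seg.segment_id not in expr.values.index:
            raise AnnotationError(f"segment {seg.segment_id} missing from expression matrix")
        if not sporulation_specific(expr, seg.segment_id, cfg):
            continue
        assigned = assign_to_gene(seg, annotation, cfg)
        if assigned is None:
            continue
        gene_id, side, gap = assigned
        if gene_id not in expr.values.index:
            raise AnnotationError(f"gene {gene_id} missing from expression matrix")
        if not _orf_expressed(expr, gene_id, cfg):
            continue
        corr = correlate(expr.condition_values(seg.segment_id),
                         expr.condition_values(gene_id))
        candidates.append((seg, genes_by_id[gene_id], side, gap, corr))

    if candidates:
        adjusted = bh_adjust([c[4].p_raw for c in candidates])
    else:
        adjusted = np.empty(0)

    calls, report_rows = [], []
    for (seg, gene, side, gap, corr), p_adj in zip(candidates, adjusted):
        corr = replace(corr, p_adjusted=float(p_adj))
        selected = corr.p_adjusted > cfg.alpha
        if selected:
            calls.append(MutrCall(segment=seg, gene=gene, side=side, gap=gap,
                                  correlation=corr))
        report_rows.append({
            "segment_id": seg.segment_id, "gene_id": gene.gene_id, "side": side,
            "gap": gap, "cc": corr.cc, "t": corr.t_stat, "p_raw": corr.p_raw,
            "p_adjusted": corr.p_adjusted, "selected": selected,
            "flags": ";".join(corr.flags),
        })
    report = pd.DataFrame(
        report_rows,
        columns=["segment_id", "gene_id", "side", "gap", "cc", "t",
                 "p_raw", "p_adjusted", "selected", "flags"],
    )
    return calls, report
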