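"""End-to-end orchestration: simulate -> call -> windows -> scan -> enrich -> stats.

Every stage writes a self-describing text artifact so any downstream stage
can be resumed independently; a JSON run summary records the seed, stage
counts and headline statistics.  Runs are deterministic given the config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import pandas as pd

from . import __version__
from .caller import CallerConfig, MutrCall, call_mutrs
from .enrichment import fisher_enrichment, motif_percent, permutation_enrichment
from .io import (ExpressionMatrix, read_annotation, read_expression, read_fasta,
                 read_segments, upstream_window, write_fasta, write_mutr_bed)
from .pwm import DEFAULT_MIN_CSS, DEFAULT_MIN_MSS, Pwm, scan, urs1_pwm
from .stats import (MITOTIC_3P_MEDIAN_BP, MITOTIC_5P_MEDIAN_BP, TimingBoundaries,
                    classify_timing, length_summary)
from .synthetic import SimConfig, generate_dataset, write_dataset


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    outdir: str = "mutrscan_run"
    seed: int = 0
    simulate: bool = True
    sim: SimConfig | None = None
    # used when simulate is False:
    genome_path: str | None = None
    annotation_path: str | None = None
    segments_path: str | None = None
    expression_path: str | None = None
    samples_path: str | None = None
    caller: CallerConfig = field(default_factory=CallerConfig)
    min_css: float = DEFAULT_MIN_CSS
    min_mss: float = DEFAULT_MIN_MSS
    window_width: int = 100
    enrichment_method: str = "permutation"   # permutation | fisher | both
    n_perm: int = 999
    timing: TimingBoundaries = field(default_factory=TimingBoundaries)

    def __post_init__(self):
        if self.simulate and self.sim is None:
            self.sim = SimConfig(seed=self.seed)


def meiotic_tss_anchor(call: MutrCall) -> tuple[str, str, int]:
    """(chrom, strand, anchor) of the distal 5' end of a 5'-mUTR call — the
    meiotic TSS whose 100-bp upstream window is the motif-search target."""
    seg = call.segment
    anchor = seg.start if seg.strand == "+" else seg.end
    return seg.chrom, seg.strand, anchor


def run_all(cfg: RunConfig, pwm: Pwm | None = None) -> dict:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if pwm is None:
        pwm = urs1_pwm()
    summary: dict = {"version": __version__, "seed": cfg.seed, "stages": {}}

    # ---- inputs -----------------------------------------------------------
    if cfg.simulate:
        genome_sim, expr = generate_dataset(cfg.sim)
        write_dataset(genome_sim, expr, outdir / "sim")
        genome = genome_sim.sequences
        annotation = genome_sim.genes
        segments = genome_sim.segments
    else:
        paths = {name: getattr(cfg, f"{name}_path") for name in
                 ("genome", "annotation", "segments", "expression", "samples")}
        missing = [p for p in paths.values() if p is None or not Path(p).exists()]
        if missing:
            raise PipelineError("inputs", f"missing input path(s): {missing}")
        genome = read_fasta(paths["genome"])
        annotation = read_annotation(paths["annotation"])
        segments = read_segments(paths["segments"])
        expr = read_expression(paths["expression"], paths["samples"])
    summary["stages"]["inputs"] = {"n_segments": len(segments),
                                   "n_features": len(annotation),
                                   "n_samples": expr.values.shape[1]}

    # ---- mUTR calling -----------------------------------------------------
    try:
        calls, report = call_mutrs(segments, annotation, expr, cfg.caller)
    except Exception as exc:
        raise PipelineError("call-mutrs", str(exc)) from exc
    timed_calls = []
    for call in calls:
        timing = classify_timing(expr.spii_profile(call.segment_id),
                                 segment_id=call.segment_id, boundaries=cfg.timing)
        timed_calls.append(replace(call, timing=timing))
    calls = timed_calls
    report.to_csv(outdir / "mutr_report.tsv", sep="\t", index=False)
    write_mutr_bed(calls, outdir / "mutr_calls.bed")
    calls_5p = [c for c in calls if c.side == "5p"]
    calls_3p = [c for c in calls if c.side == "3p"]
    summary["stages"]["call_mutrs"] = {"n_candidates": len(report),
                                       "n_called": len(calls),
                                       "n_5p": len(calls_5p), "n_3p": len(calls_3p)}

    # ---- upstream windows -------------------------------------------------
    targets: dict[str, str] = {}
    for call in calls_5p:
        chrom, strand, anchor = meiotic_tss_anchor(call)
        targets[call.segment_id] = upstream_window(genome, chrom, strand, anchor,
                                                   cfg.window_width)
    background: dict[str, str] = {}
    for call in calls_5p:
        gene = call.gene
        background[gene.gene_id] = upstream_window(genome, gene.chrom, gene.strand,
                                                   gene.tss, cfg.window_width)
    write_fasta(targets, outdir / "target_windows.fa")
    write_fasta(background, outdir / "background_windows.fa")
    summary["stages"]["windows"] = {"n_target": len(targets),
                                    "n_background": len(background)}

    # ---- motif scan -------------------------------------------------------
    hit_rows = []
    targets_with_hit = 0
    for seq_id, seq in targets.items():
        hits = scan(pwm, seq, sequence_id=seq_id, min_css=cfg.min_css,
                    min_mss=cfg.min_mss)
        targets_with_hit += bool(hits)
        for h in hits:
            hit_rows.append({"seq_id": h.sequence_id, "offset": h.offset,
                             "strand": h.strand, "word": h.word,
                             "mss": round(h.mss, 4), "css": round(h.css, 4)})
    bg_with_hit = sum(
        bool(scan(pwm, seq, sequence_id=k, min_css=cfg.min_css, min_mss=cfg.min_mss))
        for k, seq in background.items()
    )
    pd.DataFrame(hit_rows, columns=["seq_id", "offset", "strand", "word", "mss", "css"]
                 ).to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
    pct = motif_percent(targets_with_hit, len(targets)) if targets else None
    summary["stages"]["scan"] = {"n_hits": len(hit_rows),
                                 "targets_with_hit": targets_with_hit,
                                 "background_with_hit": bg_with_hit,
                                 "percent_targets_with_hit": pct}

    # ---- enrichment -------------------------------------------------------
    enrich_rows = []
    if targets and background:
        if cfg.enrichment_method in ("permutation", "both"):
            res = permutation_enrichment(pwm, list(targets.values()),
                                         list(background.values()),
                                         n_perm=cfg.n_perm, seed=cfg.seed)
            enrich_rows.append(res)
        if cfg.enrichment_method in ("fisher", "both"):
            res = fisher_enrichment(targets_with_hit, len(targets),
                                    bg_with_hit, len(background),
                                    motif_id=pwm.identifier)
            enrich_rows.append(res)
    pd.DataFrame([{
        "motif_id": r.motif_id, "method": r.method,
        "statistic": r.statistic_observed, "p_value": r.p_value,
        "target_n": r.target_n, "background_n": r.background_n,
        "flags": ";".join(r.flags),
    } for r in enrich_rows]).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    summary["stages"]["enrichment"] = {r.method: r.p_value for r in enrich_rows}

    # ---- statistics -------------------------------------------------------
    stats_block = {}
    for side, side_calls, ref in (("5p", calls_5p, MITOTIC_5P_MEDIAN_BP),
                                  ("3p", calls_3p, MITOTIC_3P_MEDIAN_BP)):
        if not side_calls:
            continue
        summ = length_summary([c.segment.length for c in side_calls], side, ref)
        stats_block[side] = {"n": summ.n, "median_bp": summ.median_bp,
                             "min_bp": summ.min_bp, "max_bp": summ.max_bp,
                             "fold_change": summ.fold_change,
                             "wilcoxon_p": summ.wilcoxon_p}
    timing_rows = [{"segment_id": c.segment_id, "gene_id": c.gene_id,
                    "side": c.side, "timing": c.timing.timing_class,
                    "peak_spii_hour": c.timing.peak_spii_hour,
                    "score": round(c.timing.score, 4)} for c in calls]
    pd.DataFrame(timing_rows, columns=["segment_id", "gene_id", "side", "timing",
                                       "peak_spii_hour", "score"]
                 ).to_csv(outdir / "timing.tsv", sep="\t", index=False)
    summary["stages"]["stats"] = stats_block

    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
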