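import filecmp

import numpy as np
import pandas as pd
import pytest

from mutrscan import (CallerConfig, SimConfig, URS1_CONSENSUS, generate_dataset,
                      generate_expression, generate_genome, read_truth,
                      write_dataset, write_truth)
from mutrscan.caller import assign_to_gene, filter_unannotated, sporulation_specific
from mutrscan.io import reverse_complement
from mutrscan.synthetic import PackingError


class TestGenerateGenome:
    def test_degenerate_no_genes(self):
        cfg = SimConfig(seed=0, n_genes=0, n_planted_5p_mutrs=0,
                        n_planted_3p_mutrs=0, n_decoy_segments=0)
        genome = generate_genome(cfg)
        assert genome.genes == [] and genome.segments == []
        assert all(len(s) == cfg.chrom_length for s in genome.sequences.values())

    def test_infeasible_packing_fails(self):
        with pytest.raises(PackingError):
            generate_genome(SimConfig(seed=0, chrom_length=5000, n_genes=40))

    def test_deterministic_and_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=7)
        for d in ("a", "b"):
            genome, expr = generate_dataset(cfg)
            write_dataset(genome, expr, tmp_path / d)
        for name in ("genome.fa", "annotation.gff3", "segments.bed",
                     "expression.tsv", "samples.tsv", "truth.tsv", "promoters.tsv"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False), name

    def test_full_plant_rate_recoverable_by_string_search(self):
        cfg = SimConfig(seed=1, urs1_plant_rate_target=1.0)
        genome = generate_genome(cfg)
        planted = genome.truth[genome.truth["side"] == "5p"]
        assert planted["urs1_planted"].all()
        seg_by_id = {s.segment_id: s for s in genome.segments}
        for row in planted.itertuples():
            seg = seg_by_id[row.segment_id]
            seq = genome.sequences[seg.chrom]
            word = seq[row.urs1_position:row.urs1_position + len(URS1_CONSENSUS)]
            on_motif_strand = word if row.urs1_strand == "+" else reverse_complement(word)
            if row.urs1_exact:
                assert on_motif_strand == URS1_CONSENSUS
            else:
                mismatches = sum(a != b for a, b in zip(on_motif_strand, URS1_CONSENSUS))
                assert mismatches == 1
            # position lies inside the 100-bp window upstream of the segment's 5' end
            if seg.strand == "+":
                assert seg.start - 100 <= row.urs1_position < seg.start
            else:
                assert seg.end <= row.urs1_position < seg.end + 100

    def test_background_promoter_planting(self):
        genome = generate_genome(SimConfig(seed=3, urs1_plant_rate_background=1.0))
        planted = genome.promoters[genome.promoters["urs1_planted"]]
        # collisions with target windows may skip a handful of plants
        assert len(planted) >= 0.9 * len(genome.promoters)
        for row in planted.itertuples():
            assert row.window_start <= row.urs1_position
            assert row.urs1_position + len(URS1_CONSENSUS) <= row.window_end


class TestGenerateExpression:
    def test_matrix_dimensions(self, genome, expr):
        n_orfs = sum(g.is_orf for g in genome.genes)
        assert expr.values.shape == (len(genome.truth) + n_orfs, 45)

    def test_zero_noise_orfs_exactly_at_expressed_level(self):
        cfg = SimConfig(seed=2, noise_sd=0.0)
        genome, expr = generate_dataset(cfg)
        for gene in genome.genes:
            if gene.is_orf and gene.gene_id not in set(
                    genome.truth.loc[genome.truth["kind"] == "decoy_correlated",
                                     "gene_id"]):
                assert (expr.row(gene.gene_id) == cfg.expressed_level).all()

    def test_early_mutr_peaks_in_spii_1_to_4(self, genome, expr):
        cfg = genome.config
        early = genome.truth[(genome.truth["kind"] == "mutr")
                             & (genome.truth["timing"] == "early")]
        assert len(early) > 0
        for seg_id in early["segment_id"]:
            spii = expr.spii_profile(seg_id)
            assert spii.loc[1:4].max() > cfg.background_threshold_tau
            nonspor = expr.row(seg_id)[expr.nonsporulation_sample_ids()]
            assert (nonspor <= cfg.background_threshold_tau).all()

    def test_unknown_timing_label_fails(self, genome):
        broken = genome.truth.copy()
        broken.loc[broken.index[0], "timing"] = "sometime"
        import dataclasses

        from mutrscan.synthetic import SyntheticGenome
        bad = SyntheticGenome(config=genome.config, sequences=genome.sequences,
                              genes=genome.genes, segments=genome.segments,
                              truth=broken, promoters=genome.promoters)
        with pytest.raises(ValueError, match="timing"):
            generate_expression(genome.config, bad)


class TestTruthConsistency:
    """Planted mUTRs satisfy every selection criterion by construction;
    every decoy fails at least one, checked against the caller's own
    criteria functions."""

    def test_planted_pass_and_decoys_fail(self, genome, expr):
        from mutrscan.caller import bh_adjust, correlate
        cfg = CallerConfig(tau=genome.config.background_threshold_tau)
        unannotated_ids = {s.segment_id
                           for s in filter_unannotated(genome.segments, genome.genes)}
        seg_by_id = {s.segment_id: s for s in genome.segments}
        checks_by_id: dict[str, dict] = {}
        raw_p: dict[str, float] = {}
        for row in genome.truth.itertuples():
            seg = seg_by_id[row.segment_id]
            assigned = assign_to_gene(seg, genome.genes, cfg)
            checks_by_id[row.segment_id] = dict(
                annotation=seg.segment_id in unannotated_ids,
                sporulation=sporulation_specific(expr, seg.segment_id, cfg),
                assignment=assigned is not None,
                assigned=assigned,
            )
            if assigned is not None:
                corr = correlate(expr.condition_values(seg.segment_id),
                                 expr.condition_values(assigned[0]))
                raw_p[row.segment_id] = corr.p_raw
        # the correlation criterion is judged after joint BH adjustment,
        # exactly as in the full procedure
        ids = sorted(raw_p)
        adjusted = dict(zip(ids, bh_adjust([raw_p[i] for i in ids])))
        for row in genome.truth.itertuples():
            checks = checks_by_id[row.segment_id]
            passes_corr = (bool(adjusted.get(row.segment_id, 0.0) > cfg.alpha)
                           if checks["assignment"] else None)
            if row.kind == "mutr":
                assert checks["annotation"] and checks["sporulation"]
                assert checks["assigned"] == (row.gene_id, row.side, checks["assigned"][2])
                assert checks["assigned"][2] < cfg.max_gap
                assert passes_corr, (row.segment_id, adjusted.get(row.segment_id))
            elif row.kind == "annotated":
                assert not checks["annotation"]
            elif row.kind == "decoy_mitotic":
                assert not checks["sporulation"]
            elif row.kind == "decoy_far":
                assert not checks["assignment"]
            elif row.kind == "decoy_correlated":
                assert passes_corr is False

    def test_truth_round_trip(self, tmp_path, genome):
        path = tmp_path / "truth.tsv"
        write_truth(genome.truth, path)
        back = read_truth(path)
        assert len(back) == len(genome.truth)
        pd.testing.assert_frame_equal(back, genome.truth.reset_index(drop=True),
                                      check_dtype=False)

    def test_empty_truth_is_header_only(self, tmp_path):
        path = tmp_path / "truth.tsv"
        write_truth(pd.DataFrame(), path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("segment_id")


class TestSimConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(urs1_plant_rate_target=1.5),
        dict(timing_mix=(0.5, 0.5, 0.5)),
        dict(background_level=7.0),          # violates expressed > tau > background
        dict(n_genes=3),                      # fewer genes than planted segments
        dict(noise_sd=-1.0),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(seed=0, **kwargs)
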