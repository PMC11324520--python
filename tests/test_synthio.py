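"""The synthetic-experiment generator: determinism, truth consistency and rates."""

import numpy as np
import pytest

from tribescope import synthio
from tribescope.synthio import InvalidConfigError, SimulationConfig


class TestConfig:
    def test_probability_bounds_enforced(self):
        with pytest.raises(InvalidConfigError, match="snp_density"):
            SimulationConfig(snp_density=1.5).validate()

    def test_rate_ordering_enforced(self):
        with pytest.raises(InvalidConfigError, match="exceed"):
            SimulationConfig(editing_rate_target=0.01,
                             editing_rate_background=0.05).validate()

    def test_utr_range_too_small_for_adenosines(self):
        with pytest.raises(InvalidConfigError, match="adenosines"):
            SimulationConfig(utr_length_range=(5, 8), read_length=4).validate()


class TestReference:
    def test_deterministic_under_seed(self):
        config = SimulationConfig(n_genes=5, n_target_genes=1, seed=1)
        ref1, ann1, truth1 = synthio.gen_reference_and_annotation(config)
        ref2, ann2, truth2 = synthio.gen_reference_and_annotation(config)
        assert ref1 == ref2
        assert truth1.edited_sites == truth2.edited_sites
        assert truth1.snp_sites == truth2.snp_sites
        assert [r.intervals for r in ann1] == [r.intervals for r in ann2]

    def test_excluded_biotype_fraction_exact(self):
        config = SimulationConfig(n_genes=100, n_target_genes=10,
                                  excluded_biotype_fraction=0.2, seed=2)
        _, ann, truth = synthio.gen_reference_and_annotation(config)
        from tribescope.targets import DEFAULT_EXCLUDED_BIOTYPES

        excluded = [r for r in ann if r.biotype in DEFAULT_EXCLUDED_BIOTYPES]
        assert len(excluded) == 20
        assert not truth.target_genes & {r.gene_id for r in excluded}

    def test_planted_sites_are_strand_aware_adenosines(self, small_experiment):
        config, reference, annotation, truth = small_experiment
        strands = {r.gene_id: r.strand for r in annotation}
        for site in truth.edited_sites:
            base = reference[site.contig][site.position - 1]
            assert base == ("A" if strands[site.gene_id] == "+" else "T")

    def test_every_utr_has_ten_sense_adenosines(self, small_experiment):
        config, reference, annotation, truth = small_experiment
        for rec in annotation:
            (start, end), = rec.intervals
            utr = reference[rec.contig][start:end]
            sense = utr.count("A") if rec.strand == "+" else utr.count("T")
            assert sense >= 10


class TestBulkAlignments:
    def test_zero_editing_leaves_only_snp_and_error_mismatches(self):
        config = SimulationConfig(n_genes=10, n_target_genes=2, seed=4)
        reference, annotation, truth = synthio.gen_reference_and_annotation(config)
        aln = synthio.gen_bulk_alignments(config, reference, annotation, truth, "control")
        truth_pos = {(s.contig, s.position) for s in truth.edited_sites}
        snp_pos = {(c, p) for c, p, _, _ in truth.snp_sites}
        mismatch_at_truth = 0
        total_truth_cover = 0
        for read in aln.reads:
            ref = reference[read.contig]
            for off, base in enumerate(read.seq):
                pos = (read.contig, read.start0 + off + 1)
                if pos in truth_pos:
                    total_truth_cover += 1
                    if base != ref[read.start0 + off]:
                        mismatch_at_truth += 1
        # at planted sites the control condition shows only the error rate
        assert mismatch_at_truth / max(total_truth_cover, 1) < 5 * config.seq_error_rate

    def test_planted_rate_recovered_within_binomial_error(self):
        """Observed G fraction at planted target sites matches the configured rate."""
        config = SimulationConfig(n_genes=20, n_target_genes=20, depth_mean=50.0,
                                  editing_rate_target=0.5, seq_error_rate=0.0,
                                  snp_density=0.0, excluded_biotype_fraction=0.0, seed=5)
        reference, annotation, truth = synthio.gen_reference_and_annotation(config)
        aln = synthio.gen_bulk_alignments(config, reference, annotation, truth, "agoTRIBE")
        strands = {r.gene_id: r.strand for r in annotation}
        edited = covered = 0
        truth_sites = {(s.contig, s.position): s for s in truth.edited_sites}
        for read in aln.reads:
            for off, base in enumerate(read.seq):
                site = truth_sites.get((read.contig, read.start0 + off + 1))
                if site is None:
                    continue
                covered += 1
                alt = "G" if strands[site.gene_id] == "+" else "C"
                edited += base == alt
        phat = edited / covered
        sigma = np.sqrt(0.5 * 0.5 / covered)
        assert abs(phat - 0.5) < 3 * sigma

    def test_low_quality_fraction_controls_phred_split(self, small_sam):
        import pysam

        sam, _ = small_sam
        lo = hi = 0
        with pysam.AlignmentFile(str(sam)) as f:
            for read in f:
                quals = np.asarray(read.query_qualities)
                lo += int((quals < 31).sum())
                hi += int((quals >= 31).sum())
        frac = lo / (lo + hi)
        assert abs(frac - 0.1) < 0.02

    def test_sam_written_coordinate_sorted(self, small_sam):
        import pysam

        sam, _ = small_sam
        with pysam.AlignmentFile(str(sam)) as f:
            assert f.header["HD"]["SO"] == "coordinate"
            last = (-1, -1)
            for read in f:
                key = (read.reference_id, read.reference_start)
                assert key >= last
                last = key


class TestExpressionCounts:
    def test_null_effect_means_equal(self):
        config = SimulationConfig(n_genes=300, n_target_genes=50,
                                  derepression_log2fc=0.0, seed=6)
        reference, annotation, truth = synthio.gen_reference_and_annotation(config)
        t6b = synthio.gen_expression_counts(config, annotation, truth, "T6B")
        ctrl = synthio.gen_expression_counts(config, annotation, truth, "control")
        t6b_cpm = t6b / t6b.sum() * 1e6
        ctrl_cpm = ctrl / ctrl.sum() * 1e6
        targets = sorted(truth.target_genes)
        lfc = np.log2(t6b_cpm.loc[targets].mean(axis=1) / ctrl_cpm.loc[targets].mean(axis=1))
        assert abs(lfc.median()) < 0.1

    def test_counts_nonnegative_integral(self, small_experiment):
        config, reference, annotation, truth = small_experiment
        counts = synthio.gen_expression_counts(config, annotation, truth, "control")
        assert (counts.to_numpy() >= 0).all()
        assert np.issubdtype(counts.to_numpy().dtype, np.integer)

    def test_background_median_log2fc_near_zero_with_planted_targets(self):
        config = SimulationConfig(n_genes=2000, n_target_genes=100, seed=7)
        reference, annotation, truth = synthio.gen_reference_and_annotation(config)
        t6b = synthio.gen_expression_counts(config, annotation, truth, "T6B")
        ctrl = synthio.gen_expression_counts(config, annotation, truth, "control")
        cpm = lambda m: m / m.sum() * 1e6
        bg = sorted(set(annotation.genes()) - truth.target_genes)
        lfc = np.log2(cpm(t6b).loc[bg].mean(axis=1) / cpm(ctrl).loc[bg].mean(axis=1))
        assert abs(lfc.median()) < 0.03


class TestSingleCells:
    def test_zero_transfection_no_linker_reads(self):
        config = SimulationConfig(n_genes=30, n_target_genes=5, n_cells=20,
                                  transfected_fraction=0.0, seed=8)
        reference, annotation, truth = synthio.gen_reference_and_annotation(config)
        sc = synthio.gen_single_cells(config, reference, annotation, truth)
        assert (sc.metadata["linker_raw"] == 0).all()

    def test_exactly_the_flagged_cells_have_elevated_editing(self):
        config = SimulationConfig(n_genes=50, n_target_genes=10, n_cells=100,
                                  transfected_fraction=0.8, seed=9)
        reference, annotation, truth = synthio.gen_reference_and_annotation(config)
        sc = synthio.gen_single_cells(config, reference, annotation, truth)
        meta = sc.metadata
        assert meta["transfected"].sum() == 80
        # transfected cells separate cleanly in total editing
        assert meta.loc[meta["transfected"], "editing_events"].min() > \
               meta.loc[~meta["transfected"], "editing_events"].max()

    def test_phase_specific_editing_recovered_after_spikein_normalization(self):
        """End-to-end: a gene edited only in S shows the highest spike-in
        normalized pseudobulk editing in S."""
        config = SimulationConfig(n_genes=40, n_target_genes=5, n_cells=90,
                                  transfected_fraction=1.0, seed=10)
        reference, annotation, truth = synthio.gen_reference_and_annotation(config)
        gene = sorted(set(annotation.genes()) - truth.target_genes)[0]
        config = synthio.replace(config, phase_edited_genes=((gene, "S"),))
        sc = synthio.gen_single_cells(config, reference, annotation, truth)
        meta = sc.metadata.set_index("cell_id")
        import pandas as pd

        from tribescope.singlecell import pseudobulk_spikein_normalize

        pooled = sc.editing.loc[[gene]].T.groupby(meta["phase_truth"]).sum().T
        spike = meta.groupby("phase_truth")["spike_reads"].sum().to_dict()
        cells = meta.groupby("phase_truth").size().to_dict()
        norm = pseudobulk_spikein_normalize(pooled.astype(float), spike, cells)
        assert norm.loc[gene].idxmax() == "S"
        assert norm.loc[gene, "S"] > 2 * max(norm.loc[gene, "G1"], norm.loc[gene, "G2M"])

    def test_cell_sam_contains_linker_and_spikein_contigs(self, tmp_path):
        config = SimulationConfig(n_genes=10, n_target_genes=2, n_cells=4,
                                  transfected_fraction=1.0, seed=12)
        reference, annotation, truth = synthio.gen_reference_and_annotation(config)
        sc = synthio.gen_single_cells(config, reference, annotation, truth)
        cell = sc.metadata["cell_id"].iloc[0]
        path = tmp_path / "cell.sam"
        sc.write_cell_sam(cell, path, reference, annotation)
        from tribescope.singlecell import count_contig_reads, count_linker_reads

        aligned_linker = count_contig_reads(path, contig="linker")
        assert aligned_linker == sc.metadata.set_index("cell_id").at[cell, "linker_raw"]
        # scan-based counting of the raw copies agrees with the alignment path
        scanned = count_linker_reads(sc.linker_reads[cell], truth.linker_seq)
        assert scanned == aligned_linker
        spikes = count_contig_reads(path, prefix="ERCC-")
        assert spikes == sc.metadata.set_index("cell_id").at[cell, "spike_reads"]
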