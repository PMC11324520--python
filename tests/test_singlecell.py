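"""Linker counting, cell QC, module scores, phase assignment and spike-in
normalization."""

import numpy as np
import pandas as pd
import pytest

from tribescope._util import revcomp
from tribescope.singlecell import (QcThresholds, assign_phase, count_linker_reads, cpm,
                                   differential_targeting, module_score,
                                   pseudobulk_spikein_normalize, qc_filter_cells,
                                   spikein_scaling_factors)

LINKER = "ACGTACGGTTCAGGCAATCC"


class TestLinkerCounting:
    def test_exact_substring_counts(self):
        read = "TTTT" + LINKER + "GGGG"
        assert count_linker_reads([read], LINKER) == 1

    def test_two_mismatches_everywhere_rejected(self):
        corrupt = LINKER[:5] + "TA" + LINKER[7:]  # 2 mismatches at the only offset
        assert count_linker_reads([corrupt], LINKER, max_mismatches=1) == 0
        assert count_linker_reads([corrupt], LINKER, max_mismatches=2) == 1

    def test_reverse_complement_detected(self):
        assert count_linker_reads([revcomp(LINKER)], LINKER) == 1

    def test_brute_force_hamming_oracle(self, rng):
        def oracle(read, linker, k):
            for target in (linker, revcomp(linker)):
                short, long_ = (read, target) if len(read) <= len(target) else (target, read)
                for off in range(len(long_) - len(short) + 1):
                    mm = sum(a != b for a, b in zip(short, long_[off:off + len(short)]))
                    if mm <= k:
                        return True
            return False

        reads = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(150)]
        # spike in some near-matches
        reads += [LINKER[:15] + "T" + LINKER[16:], "C" * 5 + LINKER + "A" * 3]
        got = count_linker_reads(reads, LINKER, 1)
        expected = sum(oracle(r, LINKER, 1) for r in reads)
        assert got == expected

    def test_symmetric_under_read_revcomp(self, rng):
        reads = ["".join(rng.choice(list("ACGT"), 25)) for _ in range(60)] + [LINKER]
        assert count_linker_reads(reads, LINKER) == \
               count_linker_reads([revcomp(r) for r in reads], LINKER)

    def test_empty_linker_rejected(self):
        with pytest.raises(ValueError):
            count_linker_reads(["ACGT"], "")


def make_cells(rows):
    return pd.DataFrame(rows, columns=["cell_id", "detected_genes", "dedup_reads",
                                       "total_reads", "linker_raw", "editing_events"])


class TestQcFilter:
    thresholds = QcThresholds(min_genes=9000, min_dedup_reads=150_000,
                              linker_log10_min=-4.5, min_editing=1000)

    def test_gene_count_boundary_strict(self):
        cells = make_cells([("low", 8999, 200_000, 10_000, 100, 5000),
                            ("ok", 9000, 200_000, 10_000, 100, 5000)])
        out = qc_filter_cells(cells, self.thresholds, mode="hek")
        assert list(out["cell_id"]) == ["ok"]

    def test_low_linker_but_high_editing_retained(self):
        # log10 norm linker -5.0 yet 1,500 editing events: exclusion needs BOTH
        cells = make_cells([("edited", 9500, 200_000, 100_000, 0, 1500),
                            ("unedited", 9500, 200_000, 100_000, 0, 999)])
        out = qc_filter_cells(cells, self.thresholds, mode="hek")
        assert list(out["cell_id"]) == ["edited"]

    def test_truth_table_on_boundary_fixture(self):
        """20 cells spanning every threshold boundary match a hand-derived truth table."""
        genes = [8999, 9000]
        reads = [149_999, 150_000]
        # normalized linker = (raw+1)/total; total 100_000 -> raw 0 gives 1e-5 (log10 -5),
        # raw 3 gives 4e-5 (log10 ~ -4.4)
        linker = [0, 3]
        editing = [999, 1001]
        rows = []
        i = 0
        for g in genes:
            for r in reads:
                for ln in linker:
                    for e in editing:
                        if i >= 20:
                            break
                        rows.append((f"c{i:02d}", g, r, 100_000, ln, e))
                        i += 1
        cells = make_cells(rows[:20])
        out = qc_filter_cells(cells, self.thresholds, mode="hek")
        expected = []
        for cid, g, r, total, ln, e in rows[:20]:
            qc = g >= 9000 and r >= 150_000
            low_linker = np.log10((ln + 1) / total) < -4.5
            keep = qc and not (low_linker and e < 1000)
            if keep:
                expected.append(cid)
        assert list(out["cell_id"]) == expected
        assert len(expected) > 0

    def test_k562_mode_single_linker_read_suffices(self):
        thr = QcThresholds(min_genes=0, min_dedup_reads=0)
        cells = make_cells([("pos", 100, 100, 1000, 1, 0), ("neg", 100, 100, 1000, 0, 0)])
        out = qc_filter_cells(cells, thr, mode="k562")
        assert list(out["cell_id"]) == ["pos"]

    def test_monotone_tightening_never_admits(self, rng):
        cells = make_cells([(f"c{i}", int(rng.integers(5000, 12000)),
                             int(rng.integers(50_000, 250_000)), 100_000,
                             int(rng.integers(0, 10)), int(rng.integers(0, 3000)))
                            for i in range(50)])
        base = set(qc_filter_cells(cells, self.thresholds)["cell_id"])
        tighter = QcThresholds(min_genes=10_000, min_dedup_reads=200_000,
                               linker_log10_min=-4.0, min_editing=2000)
        assert set(qc_filter_cells(cells, tighter)["cell_id"]) <= base


class TestModuleScore:
    def _matrix(self, rng, n_genes=400, n_cells=60):
        mu = rng.lognormal(np.log(50), 0.6, n_genes)
        data = rng.poisson(mu[:, None], (n_genes, n_cells))
        return pd.DataFrame(data, index=[f"g{i:03d}" for i in range(n_genes)],
                            columns=[f"c{j:02d}" for j in range(n_cells)])

    def test_null_set_scores_near_zero(self, rng):
        expr = cpm(self._matrix(rng))
        gene_set = list(expr.index[::40])
        scores = module_score(expr, gene_set, seed=0)
        assert abs(scores.mean()) < 0.2 * expr.to_numpy().mean()

    def test_planted_upregulation_separates_cells(self, rng):
        matrix = self._matrix(rng)
        gene_set = list(matrix.index[:20])
        matrix.iloc[:20, :30] *= 3  # first half of cells upregulated
        scores = module_score(cpm(matrix), gene_set, seed=0)
        assert scores.iloc[:30].min() > scores.iloc[30:].max()

    def test_deterministic_and_local(self, rng):
        matrix = self._matrix(rng)
        gene_set = list(matrix.index[5:15])
        s1 = module_score(cpm(matrix), gene_set, seed=42)
        s2 = module_score(cpm(matrix), gene_set, seed=42)
        pd.testing.assert_series_equal(s1, s2)

    def test_missing_genes_error(self, rng):
        expr = cpm(self._matrix(rng))
        with pytest.raises(ValueError, match="ghost"):
            module_score(expr, ["ghost1", "ghost2"], seed=0)

    def test_agrees_with_scanpy_reference(self, rng):
        """Cross-check against the field-standard score_genes implementation."""
        import scanpy as sc
        from anndata import AnnData

        matrix = self._matrix(rng, n_genes=300, n_cells=50)
        gene_set = list(matrix.index[10:30])
        matrix.iloc[10:30, :25] *= 2
        expr = cpm(matrix)
        ours = module_score(expr, gene_set, seed=0)
        adata = AnnData(expr.T.to_numpy().astype(np.float32))
        adata.var_names = expr.index
        adata.obs_names = expr.columns
        sc.tl.score_genes(adata, gene_set, ctrl_size=100, n_bins=24, random_state=0)
        theirs = adata.obs["score"].to_numpy()
        r = np.corrcoef(ours.to_numpy(), theirs)[0, 1]
        assert r > 0.95


class TestAssignPhase:
    def scores(self, rows):
        return pd.DataFrame(rows, columns=["s_score", "g2m_score"],
                            index=[f"c{i}" for i in range(len(rows))])

    def test_argmax_rule(self):
        out = assign_phase(self.scores([(10, -5), (-1, -2), (2, 8)]))
        assert list(out["phase"]) == ["S", "G1", "G2M"]

    def test_both_high_forced_to_g1_under_custom_rule(self):
        scores = self.scores([(60, 70), (60, 10)])
        default = assign_phase(scores, rule="argmax")
        custom = assign_phase(scores, rule="both-high-g1")
        assert list(default["phase"]) == ["G2M", "S"]
        assert list(custom["phase"]) == ["G1", "S"]

    def test_substages_split_evenly_extra_to_early(self):
        rows = [(float(i), -1.0) for i in range(1, 6)]  # five S cells
        out = assign_phase(self.scores(rows))
        assert (out["phase"] == "S").all()
        assert (out["substage"] == "early").sum() == 3
        assert (out["substage"] == "late").sum() == 2


class TestSpikeNormalization:
    def test_factor_algebra(self):
        factors = spikein_scaling_factors({"A": 100.0}, {"A": 20})
        assert factors["A"] == 5.0

    def test_double_spike_halves_values(self):
        values = pd.DataFrame({"A": [100.0, 10.0], "B": [100.0, 10.0]}, index=["g1", "g2"])
        norm = pseudobulk_spikein_normalize(values, {"A": 500.0, "B": 1000.0},
                                            {"A": 10, "B": 10})
        assert np.allclose(norm["B"], norm["A"] / 2)

    def test_zero_spike_rejected(self):
        with pytest.raises(ValueError, match="spike"):
            spikein_scaling_factors({"A": 0.0}, {"A": 5})


class TestDifferentialTargeting:
    def test_identical_counts_null(self):
        editing = pd.DataFrame({"G1": [10, 7], "S": [10, 7], "G2M": [10, 7]},
                               index=["g1", "g2"])
        res = differential_targeting(editing, {"G1": 1000, "S": 1000, "G2M": 1000})
        assert np.allclose(res["max_min_fold"], 1.0)
        assert (res["p_adj"] > 0.9).all()

    def test_planted_stage_specific_gene_ranks_first(self, rng):
        n = 200
        editing = pd.DataFrame({
            "G1": rng.poisson(5, n), "S": rng.poisson(5, n), "G2M": rng.poisson(5, n)},
            index=[f"g{i:03d}" for i in range(n)])
        editing.loc["g000"] = [5, 80, 5]  # S-specific targeting
        res = differential_targeting(editing, {"G1": 5000, "S": 5000, "G2M": 5000})
        assert res["p_adj"].idxmin() == "g000"

    def test_bh_adjustment_matches_step_up_oracle(self):
        """BH adjusted values equal the hand-computed step-up on a 10-p fixture."""
        ps = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.216])
        n = len(ps)
        ranks = np.arange(1, n + 1)
        stepup = np.minimum(np.minimum.accumulate((ps * n / ranks)[::-1])[::-1], 1.0)
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(ps, method="fdr_bh")[1]
        assert np.allclose(adj, stepup)
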