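"""Prioritization core: candidate resolution, regions, thresholds, scanning."""

from __future__ import annotations

import math
import random

import numpy as np
import pandas as pd
import pytest

from genescout.gene_db import GeneModel, build_gene_store
from genescout.gwas_io import ColumnMap, GwasIndex, GwasRecord, load_gwas
from genescout.prioritize import (
    GeneRegion,
    SignificanceThreshold,
    ThresholdMethod,
    compute_threshold,
    define_regions,
    resolve_candidates,
    scan_gwas,
)


@pytest.fixture()
def toy_store(tmp_path):
    models = [
        GeneModel("G1", "chr1", "+", 50_000, 60_000, "NM_1"),
        GeneModel("G2", "chr1", "+", 5_000, 8_000, "NM_2"),
        GeneModel("G3", "chr2", "-", 100_000, 120_000, "NM_3"),
        GeneModel("GX", "chrX", "+", 10_000, 20_000, "NM_4"),
    ]
    return build_gene_store(models, tmp_path / "genes.db")


class TestResolveCandidates:
    def test_duplicates_collapse_in_first_occurrence_order(self, toy_store):
        result = resolve_candidates(["G1", "G1", "G2"], toy_store)
        assert [m.gene_symbol for m in result.resolved] == ["G1", "G2"]
        assert result.duplicates == ["G1"]
        assert result.n == 2

    def test_unmapped_symbol_filtered(self, toy_store):
        result = resolve_candidates(["G1", "NOPE"], toy_store)
        assert result.filtered == {"NOPE": "unmapped"}

    def test_gonosomal_gene_filtered_by_default(self, toy_store):
        result = resolve_candidates(["G1", "GX"], toy_store)
        assert result.filtered == {"GX": "gonosomal"}
        kept = resolve_candidates(["G1", "GX"], toy_store, exclude_gonosomes=False)
        assert kept.filtered == {} and kept.n == 2

    def test_nothing_resolved_raises(self, toy_store):
        with pytest.raises(ValueError, match="no candidate genes"):
            resolve_candidates(["NOPE"], toy_store)


class TestDefineRegions:
    def test_default_flank_is_10kb(self, toy_store):
        result = resolve_candidates(["G1"], toy_store)
        (region,) = define_regions(result)
        assert (region.region_start, region.region_end) == (40_000, 70_000)
        assert region.flank_bp == 10_000

    def test_start_clipped_at_zero(self, toy_store):
        result = resolve_candidates(["G2"], toy_store)
        (region,) = define_regions(result, flank_bp=10_000)
        assert (region.region_start, region.region_end) == (0, 18_000)

    def test_negative_flank_rejected(self, toy_store):
        with pytest.raises(ValueError):
            define_regions(resolve_candidates(["G1"], toy_store), flank_bp=-1)


def region(symbol="G1", chrom="1", start=0, end=100_000, m=None):
    return GeneRegion(symbol, chrom, start, end, m_g=m)


class TestComputeThreshold:
    def test_genomewide_significance_worked_example(self):
        threshold = compute_threshold(
            [region(m=1_000_000)], method="bonferroni_listwise", alpha=0.05
        )
        assert threshold.M == 1_000_000
        assert math.isclose(threshold.value, 5e-8, rel_tol=1e-12)

    def test_listwise_sums_without_deduplication(self):
        threshold = compute_threshold(
            [region("G1", m=10), region("G2", m=40)], method="bonferroni_listwise"
        )
        assert threshold.M == 50
        assert threshold.value == pytest.approx(1e-3)

    def test_per_gene_mode_excludes_zero_count_genes(self, caplog):
        with caplog.at_level("WARNING"):
            threshold = compute_threshold(
                [region("G1", m=10), region("G2", m=0)], method="bonferroni_per_gene"
            )
        assert threshold.per_gene == {"G1": pytest.approx(0.005)}
        assert threshold.threshold_for("G2") is None
        assert any("G2" in m for m in caplog.messages)

    def test_listwise_zero_total_raises(self):
        with pytest.raises(ValueError, match="zero independent"):
            compute_threshold([region(m=0)], method="bonferroni_listwise")

    def test_listwise_threshold_decreases_with_more_genes(self):
        small = compute_threshold([region("G1", m=10)], method="bonferroni_listwise")
        large = compute_threshold(
            [region("G1", m=10), region("G2", m=5)], method="bonferroni_listwise"
        )
        assert large.value < small.value

    def test_fixed_mode(self):
        threshold = compute_threshold([region(m=1)], method="fixed", fixed_value=1e-6)
        assert threshold.value == 1e-6
        with pytest.raises(ValueError):
            compute_threshold([region(m=1)], method="fixed", fixed_value=2.0)

    def test_fdr_mode_benjamini_hochberg(self):
        # 10 region SNPs with known p-values: BH at q=0.25 passes the
        # smallest two (0.01 <= 0.025, 0.04 <= 0.05; 0.20 > 0.075)
        pvalues = np.array([0.01, 0.04, 0.20, 0.30, 0.45, 0.55, 0.65, 0.75, 0.85, 0.95])
        positions = np.arange(1, 11) * 10
        index = GwasIndex({"1": (positions, pvalues)})
        threshold = compute_threshold(
            [region(start=0, end=200)], method="fdr", fdr_q=0.25, summary=index
        )
        # strict-inequality threshold sits just above the largest passing p
        assert 0.04 < threshold.value < 0.0400001
        empty = compute_threshold(
            [region(start=0, end=200)], method="fdr", fdr_q=0.001, summary=index
        )
        assert 0.0 < empty.value < 1e-300  # below any representable p: no hits

    def test_empty_region_list_raises(self):
        with pytest.raises(ValueError):
            compute_threshold([], method="fixed", fixed_value=0.5)


def make_table(rows, columns=("SNP", "CHR", "POS", "P")):
    return load_gwas(pd.DataFrame(rows, columns=list(columns)), ColumnMap())


class TestScanGwas:
    def fixed(self, value):
        return SignificanceThreshold(method=ThresholdMethod.FIXED, value=value)

    def test_threshold_boundary_is_exclusive(self):
        table = make_table([["rs1", "1", 500, 1e-4], ["rs2", "1", 600, 0.99e-4]])
        hits = scan_gwas(table, [region(start=0, end=1000)], self.fixed(1e-4))
        assert list(hits.frame["snp_id"]) == ["rs2"]

    def test_snp_outside_regions_absent(self):
        table = make_table([["rs1", "1", 5_000, 1e-10]])
        hits = scan_gwas(table, [region(start=0, end=1000)], self.fixed(1e-4))
        assert hits.frame.empty and hits.x == 0

    def test_region_boundaries_half_open(self):
        # 0-based region [100, 200): 1-based hits are positions 101..200
        table = make_table(
            [["rs_a", "1", 100, 1e-9], ["rs_b", "1", 101, 1e-9],
             ["rs_c", "1", 200, 1e-9], ["rs_d", "1", 201, 1e-9]]
        )
        hits = scan_gwas(table, [region(start=100, end=200)], self.fixed(1e-4))
        assert list(hits.frame["snp_id"]) == ["rs_b", "rs_c"]

    def test_overlapping_regions_emit_one_row_per_gene(self):
        table = make_table([["rs1", "1", 500, 1e-9]])
        regions = [region("G1", start=0, end=1000), region("G2", start=400, end=2000)]
        hits = scan_gwas(table, regions, self.fixed(1e-4))
        assert len(hits.frame) == 2
        assert hits.significant_genes == {"G1", "G2"}
        assert hits.x == 2

    def test_scan_is_order_independent(self):
        rng = random.Random(5)
        rows = [[f"rs{i}", "1", 10 * i + 1, rng.random() * 1e-3] for i in range(200)]
        regions = [region("G1", start=0, end=900), region("G2", start=800, end=1700)]
        table_a = make_table(rows)
        shuffled = rows[:]
        rng.shuffle(shuffled)
        table_b = make_table(shuffled)
        hits_a = scan_gwas(table_a, regions, self.fixed(5e-4))
        hits_b = scan_gwas(table_b, regions, self.fixed(5e-4))
        pd.testing.assert_frame_equal(hits_a.frame, hits_b.frame)

    def test_passthrough_columns_preserved(self):
        table = make_table(
            [["rs1", "1", 500, 1e-9, 0.42, "note"]],
            columns=("SNP", "CHR", "POS", "P", "BETA", "COMMENT"),
        )
        hits = scan_gwas(table, [region(start=0, end=1000)], self.fixed(1e-4))
        assert hits.frame.loc[0, "BETA"] == 0.42
        assert hits.frame.loc[0, "COMMENT"] == "note"
        assert hits.frame.loc[0, "applied_threshold"] == 1e-4

    def test_per_gene_thresholds_applied_per_region(self):
        table = make_table([["rs1", "1", 500, 1e-5]])
        regions = [region("G1", start=0, end=1000), region("G2", start=0, end=1000)]
        threshold = SignificanceThreshold(
            method=ThresholdMethod.BONFERRONI_PER_GENE,
            per_gene={"G1": 1e-4, "G2": 1e-6},
        )
        hits = scan_gwas(table, regions, threshold)
        assert hits.significant_genes == {"G1"}

    def test_no_regions_raises(self):
        with pytest.raises(ValueError):
            scan_gwas(make_table([["rs1", "1", 5, 0.5]]), [], self.fixed(0.5))


class TestGwasLoading:
    def test_zero_pvalues_clamped_and_counted(self):
        table = make_table([["rs1", "1", 100, 0.0], ["rs2", "1", 200, 0.5]])
        assert table.n_clamped == 1
        assert table.frame["p_value"].min() > 0.0

    def test_unparseable_rows_skipped_and_counted(self):
        table = make_table(
            [["rs1", "1", "abc", 0.5], ["rs2", "1", 200, "xyz"], ["rs3", "1", 300, 0.5]]
        )
        assert table.n_skipped == 2
        assert list(table.frame["snp_id"]) == ["rs3"]

    def test_column_mapping_by_index(self, tmp_path):
        path = tmp_path / "gwas.tsv"
        path.write_text("a\tb\tc\td\nrs1\t1\t100\t0.5\n")
        table = load_gwas(path, ColumnMap(snp_id=1, chromosome=2, position=3, p_value=4))
        assert table.frame.loc[0, "snp_id"] == "rs1"

    def test_gzip_input(self, tmp_path):
        import gzip

        path = tmp_path / "gwas.tsv.gz"
        with gzip.open(path, "wt") as handle:
            handle.write("SNP\tCHR\tPOS\tP\nrs1\t1\t100\t0.25\n")
        table = load_gwas(path)
        assert table.frame.loc[0, "p_value"] == 0.25


def test_planted_signal_always_hits_under_genomewide_bonferroni(small_world):
    """A p = 1e-15 signal beats any Bonferroni threshold with M <= 1e6."""
    from genescout.prioritize import resolve_candidates

    candidates = resolve_candidates(
        [m.gene_symbol for m in small_world.models[:10]], small_world.store
    )
    regions = define_regions(candidates)
    for r in regions:
        r.m_g = 100_000  # inflate to the genome-wide scale: M = 1e6
    threshold = compute_threshold(regions, method="bonferroni_listwise")
    hits = scan_gwas(small_world.table, regions, threshold)
    assert "GENE00003" in hits.significant_genes
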