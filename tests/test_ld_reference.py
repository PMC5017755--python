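"""LD reference: MAF, pairwise r², windowed pruning, region counts."""

from __future__ import annotations

import numpy as np
import pytest

from genescout.ld_reference import (
    GenotypePanel,
    PrunedSnpStore,
    PruningConfig,
    allele_frequency,
    build_snp_store,
    prune_chromosome,
    r2,
    read_dosage_tsv,
    read_vcf_panel,
)
from genescout.synthetic import SyntheticConfig, generate_ld_panel, write_vcf

NAN = float("nan")


def greedy_prune_oracle(dosages, positions, config):
    """Independent brute-force replay of the documented pruning rule.

    Plain-python reimplementation: MAF filter, sliding window in SNP
    counts, repeated removal of the lower-MAF member of the worst pair
    (later position on ties), union of removals over windows.
    """

    def maf(col):
        vals = [v for v in col if not np.isnan(v)]
        f = sum(vals) / (2 * len(vals))
        return min(f, 1 - f)

    def pearson_r2(a, b):
        pairs = [(x, y) for x, y in zip(a, b) if not (np.isnan(x) or np.isnan(y))]
        xs, ys = zip(*pairs)
        mx, my = sum(xs) / len(xs), sum(ys) / len(ys)
        sxx = sum((x - mx) ** 2 for x in xs)
        syy = sum((y - my) ** 2 for y in ys)
        sxy = sum((x - mx) * (y - my) for x, y in pairs)
        if sxx == 0 or syy == 0:
            return 0.0
        return min(sxy * sxy / (sxx * syy), 1.0)

    n_total = dosages.shape[1]
    mafs = [maf(dosages[:, j]) for j in range(n_total)]
    kept = [j for j in range(n_total) if mafs[j] >= config.maf_min]
    removed = set()
    ws = 0
    while True:
        window = [j for j in kept[ws : ws + config.window_size] if j not in removed]
        while len(window) >= 2:
            best = None
            for a_idx in range(len(window)):
                for b_idx in range(a_idx + 1, len(window)):
                    value = pearson_r2(
                        dosages[:, window[a_idx]], dosages[:, window[b_idx]]
                    )
                    if best is None or value > best[0]:
                        best = (value, a_idx, b_idx)
            if best is None or best[0] <= config.r2_threshold:
                break
            _, a_idx, b_idx = best
            a, b = window[a_idx], window[b_idx]
            if mafs[a] < mafs[b]:
                drop = a
            elif mafs[b] < mafs[a]:
                drop = b
            else:
                drop = b if positions[b] > positions[a] else a
            removed.add(drop)
            window.remove(drop)
        if ws + config.window_size >= len(kept):
            break
        ws += config.step
    return [j for j in kept if j not in removed]


def make_panel(dosages, positions=None, chromosome="1"):
    dosages = np.asarray(dosages, dtype=float)
    n = dosages.shape[1]
    if positions is None:
        positions = np.arange(1, n + 1) * 100
    return GenotypePanel(
        ancestry_label="EUR",
        chromosome=chromosome,
        positions=np.asarray(positions),
        snp_ids=[f"rs{i}" for i in range(n)],
        dosages=dosages,
    )


class TestAlleleFrequency:
    def test_examples(self):
        assert allele_frequency([0, 0, 0, 0]) == 0.0
        assert allele_frequency([1, 1, 1, 1]) == 0.5
        assert allele_frequency([2, 1, 0, NAN]) == pytest.approx(0.5)
        assert allele_frequency([2, 2, 2, 2]) == 0.0  # folded to minor allele

    def test_all_missing_raises(self):
        with pytest.raises(ValueError, match="missing"):
            allele_frequency([NAN, NAN])


class TestR2:
    def test_identical_and_anticorrelated(self):
        assert r2([0, 1, 2, 0], [0, 1, 2, 0]) == pytest.approx(1.0)
        assert r2([0, 0, 1, 1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_against_pearson_formula(self):
        a = np.array([0.0, 1.0, 2.0, 0.0])
        b = np.array([0.0, 1.0, 1.0, 1.0])
        expected = (np.corrcoef(a, b)[0, 1]) ** 2
        assert r2(a, b) == pytest.approx(expected, rel=1e-12)

    def test_constant_vector_gives_zero(self):
        assert r2([1, 1, 1, 1], [0, 1, 2, 0]) == 0.0

    def test_pairwise_complete_subset(self):
        # dropping the NaN pair leaves perfectly correlated vectors
        assert r2([0, 1, 2, NAN], [0, 1, 2, 5]) == pytest.approx(1.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            r2([0, 1], [0, 1, 2])


class TestPruneChromosome:
    def test_duplicate_columns_keep_one(self):
        col = np.array([0, 1, 2, 0, 1, 2, 1, 0])
        dosages = np.column_stack([col, col, np.array([2, 0, 1, 1, 0, 2, 0, 1])])
        retained = prune_chromosome(make_panel(dosages), PruningConfig(window_size=3, step=1))
        assert len(retained) == 2
        assert retained[-1] == 2

    def test_uncorrelated_columns_all_retained(self):
        rng = np.random.default_rng(0)
        # orthogonal-ish independent columns, threshold high enough
        dosages = rng.binomial(2, 0.5, size=(200, 6)).astype(float)
        retained = prune_chromosome(
            make_panel(dosages), PruningConfig(window_size=6, step=2, r2_threshold=0.5)
        )
        assert len(retained) == 6

    def test_ten_snp_fixture_matches_oracle(self):
        rng = np.random.default_rng(42)
        base = rng.binomial(1, 0.4, size=(30, 10)).astype(float)
        # inject correlation: columns 3,4 copy column 2 with few flips
        base[:, 3] = base[:, 2]
        base[:, 4] = base[:, 2]
        base[::7, 4] = 1 - base[::7, 4]
        dosages = base + rng.binomial(1, 0.4, size=(30, 10))
        config = PruningConfig(window_size=5, step=2, r2_threshold=0.2)
        panel = make_panel(dosages)
        retained = prune_chromosome(panel, config)
        expected = greedy_prune_oracle(dosages, panel.positions, config)
        assert list(retained) == expected

    def test_maf_filter_runs_first(self):
        polymorphic = np.zeros(50)
        polymorphic[:25] = 1.0  # MAF 0.25
        dosages = np.column_stack([np.zeros(50), polymorphic])
        retained = prune_chromosome(make_panel(dosages), PruningConfig())
        assert list(retained) == [1]  # monomorphic column fails the MAF floor

    def test_empty_after_maf_filter_warns(self, caplog):
        dosages = np.zeros((20, 3))
        with caplog.at_level("WARNING"):
            retained = prune_chromosome(make_panel(dosages), PruningConfig())
        assert retained.size == 0
        assert any("MAF" in m for m in caplog.messages)

    def test_threshold_monotonicity(self):
        """Raising the r² ceiling never shrinks the retained set."""
        rng = np.random.default_rng(3)
        for trial in range(8):
            dosages = rng.binomial(2, rng.uniform(0.2, 0.5), size=(40, 30)).astype(float)
            dosages[:, 1::3] = dosages[:, ::3]  # heavy correlation
            panel = make_panel(dosages)
            previous = -1
            for threshold in (0.1, 0.3, 0.6, 0.9, 1.0):
                config = PruningConfig(window_size=10, step=3, r2_threshold=threshold)
                count = prune_chromosome(panel, config).size
                assert count >= previous
                previous = count

    def test_retained_set_guarantee(self):
        """No retained pair that shared a window exceeds the threshold.

        Replays the window schedule over the MAF-surviving SNP order:
        retained SNPs inside the same scheduled window were necessarily
        both present when that window was processed.
        """
        rng = np.random.default_rng(11)
        dosages = rng.binomial(2, 0.3, size=(60, 80)).astype(float)
        dosages[:, 40:60] = dosages[:, 20:40]
        config = PruningConfig(window_size=15, step=4, r2_threshold=0.2)
        panel = make_panel(dosages)
        retained = set(prune_chromosome(panel, config).tolist())
        mafs = [allele_frequency(dosages[:, j]) for j in range(dosages.shape[1])]
        kept = [j for j in range(dosages.shape[1]) if mafs[j] >= config.maf_min]
        ws = 0
        while True:
            window = [j for j in kept[ws : ws + config.window_size] if j in retained]
            for i, a in enumerate(window):
                for b in window[i + 1 :]:
                    assert r2(dosages[:, a], dosages[:, b]) <= config.r2_threshold + 1e-12
            if ws + config.window_size >= len(kept):
                break
            ws += config.step


class TestSnpStore:
    @pytest.fixture()
    def store(self, tmp_path):
        store = PrunedSnpStore.create(tmp_path / "snps.db")
        store.add_panel("EUR", "1", np.array([100, 200, 300, 450]), ["a", "b", "c", "d"])
        store.add_panel("EUR", "2", np.array([10, 20]), ["e", "f"])
        return store

    def test_boundary_handling(self, store):
        # [150, 450): positions 200 and 300 inside, boundary 450 excluded
        assert store.count_independent("EUR", "1", 150, 450) == 2
        assert store.count_independent("EUR", "1", 150, 451) == 3

    def test_empty_region_and_whole_chromosome(self, store):
        assert store.count_independent("EUR", "1", 500, 900) == 0
        assert store.count_independent("EUR", "1", 0, 10**9) == 4
        assert store.count_independent("EUR", "chr1", 0, 10**9) == 4  # prefix normalized

    def test_additivity_over_disjoint_intervals(self, store):
        total = store.count_independent("EUR", "1", 0, 10**9)
        split = store.count_independent("EUR", "1", 0, 250) + store.count_independent(
            "EUR", "1", 250, 10**9
        )
        assert split == total

    def test_unknown_ancestry_lists_available(self, store):
        with pytest.raises(ValueError, match="EUR"):
            store.count_independent("AFR", "1", 0, 100)

    def test_missing_chromosome_counts_zero(self, store):
        assert store.count_independent("EUR", "99", 0, 100) == 0


def test_vcf_round_trip(tmp_path):
    config = SyntheticConfig(
        seed=4, n_genes=5, n_chromosomes=1, chrom_length_bp=100_000,
        n_snps_per_chrom=120, n_samples=15, intergenic_gap_range=(2_000, 3_000),
        flank_bp=500,
    )
    panel = generate_ld_panel(config, 1)
    panel.dosages[0, 0] = np.nan  # exercise missing genotypes
    write_vcf([panel], tmp_path / "panel.vcf")
    (loaded,) = read_vcf_panel(tmp_path / "panel.vcf", "EUR")
    assert np.array_equal(loaded.positions, panel.positions)
    assert loaded.snp_ids == panel.snp_ids
    assert np.array_equal(loaded.dosages, panel.dosages, equal_nan=True)


def test_dosage_tsv_round_trip(tmp_path):
    path = tmp_path / "dosage.tsv"
    path.write_text("rs1:100\trs2:250\n0\t2\n1\t1\n2\t0\n")
    panel = read_dosage_tsv(path, "EUR", "1")
    assert list(panel.positions) == [100, 250]
    assert panel.snp_ids == ["rs1", "rs2"]
    assert panel.dosages.shape == (3, 2)


def test_build_snp_store_persists_pruned_positions(tmp_path):
    col = np.array([0, 1, 2, 0, 1, 2, 1, 0, 2, 1], dtype=float)
    dosages = np.column_stack([col, col, 2 - col])
    panel = make_panel(dosages)
    store = build_snp_store([panel], tmp_path / "snps.db", PruningConfig(window_size=3, step=1))
    # three mutually |r|=1 columns: exactly one survives
    assert store.chromosome_total("EUR", "1") == 1
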