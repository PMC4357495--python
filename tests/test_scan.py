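import numpy as np
import pandas as pd
import pytest

from snpig.infotheory import DegeneratePhenotypeError, interaction_gain
from snpig.scan import (
    PAIR_FORMS,
    ScanConfig,
    SnpAnnotation,
    allpairs_ig_values,
    classify_pair,
    distance_stratified_summary,
    filter_pairs,
    ld_r2,
    map_snps_to_genes,
    pair_count,
    scan_all_pairs,
)
from snpig.simulate import hwe_genotype_probs


class TestGeneMapping:
    def test_containment_and_boundaries(self):
        anns = [
            SnpAnnotation("rs1", "22", 150),
            SnpAnnotation("rs2", "22", 99),
            SnpAnnotation("rs3", "22", 100),
            SnpAnnotation("rs4", "22", 200),
        ]
        mapped, summary = map_snps_to_genes(anns, [("22", 100, 200, "GENE1")])
        assert [a.gene_id for a in mapped] == ["GENE1", None, "GENE1", "GENE1"]
        assert summary == {"n_snps": 4, "n_on_gene": 3, "n_between_gene": 1, "n_genes": 1}

    def test_counts_match_hand_enumeration(self):
        # 20 SNPs at positions 10, 20, ..., 200; three genes
        anns = [SnpAnnotation(f"rs{i}", "1", 10 * i) for i in range(1, 21)]
        genes = [("1", 15, 45, "GA"), ("1", 100, 130, "GB"), ("1", 500, 600, "GC")]
        mapped, summary = map_snps_to_genes(anns, genes)
        # GA covers 20,30,40; GB covers 100,110,120,130; GC covers none
        assert summary["n_on_gene"] == 7
        assert summary["n_between_gene"] == 13
        assert summary["n_genes"] == 2

    def test_chromosome_mismatch_warns_and_leaves_intergenic(self):
        anns = [SnpAnnotation("rs1", "22", 150)]
        with pytest.warns(UserWarning, match="chromosome"):
            mapped, _ = map_snps_to_genes(anns, [("21", 100, 200, "G")])
        assert mapped[0].gene_id is None


class TestClassifyPair:
    def test_five_forms(self):
        on_g1 = SnpAnnotation("a", "22", 10, "G1")
        on_g1b = SnpAnnotation("b", "22", 20, "G1")
        on_g2 = SnpAnnotation("c", "22", 30, "G2")
        inter1 = SnpAnnotation("d", "22", 40, None)
        inter2 = SnpAnnotation("e", "22", 50, None)
        other_chrom = SnpAnnotation("f", "21", 10, "G3")
        assert classify_pair(on_g1, on_g1b) == "within-gene"
        assert classify_pair(on_g1, on_g2) == "gene-gene"
        assert classify_pair(inter1, inter2) == "intergenic-intergenic"
        assert classify_pair(on_g1, inter1) == "gene-intergenic"
        assert classify_pair(on_g1, other_chrom) == "cross-chromosome"
        # cross-chromosome takes precedence over gene-based forms
        assert classify_pair(on_g2, other_chrom) == "cross-chromosome"
        assert set(PAIR_FORMS) >= {
            classify_pair(a, b)
            for a, b in [(on_g1, on_g1b), (on_g1, on_g2), (inter1, inter2),
                         (on_g1, inter1), (on_g1, other_chrom)]
        }


class TestLdR2:
    def test_identical_and_flipped_vectors(self, rng):
        x = rng.integers(0, 3, 200)
        assert ld_r2(x, x) == pytest.approx(1.0)
        assert ld_r2(x, 2 - x) == pytest.approx(1.0)

    def test_independent_snps_have_tiny_r2(self):
        rng = np.random.default_rng(3)
        p = hwe_genotype_probs(0.3)
        x = rng.choice(3, 10_000, p=p)
        y = rng.choice(3, 10_000, p=p)
        assert ld_r2(x, y) < 0.01

    def test_monomorphic_is_nan(self):
        assert np.isnan(ld_r2(np.zeros(10, dtype=int), np.arange(10) % 3))


class TestScanAllPairs:
    def test_pair_counts(self):
        assert pair_count(2) == 1
        assert pair_count(200) == 19_900

    def test_two_snp_scan(self, rng):
        geno = rng.integers(0, 3, (40, 2)).astype(np.int8)
        ph = np.array([0, 1] * 20, dtype=np.int8)
        rec = scan_all_pairs(geno, ph)
        assert len(rec) == 1

    def test_matches_per_pair_oracle(self, small_dataset):
        rec = scan_all_pairs(small_dataset.genotypes, small_dataset.phenotype)
        assert len(rec) == pair_count(30)
        idx = {f"x{j + 1}": j for j in range(30)}
        sampled = rec.iloc[::37]  # spot-check a spread of pairs
        for row in sampled.itertuples():
            i, j = idx[row.snp_a], idx[row.snp_b]
            res = interaction_gain(
                small_dataset.genotypes[:, i],
                small_dataset.genotypes[:, j],
                small_dataset.phenotype,
            )
            assert row.ig == pytest.approx(res.ig, abs=1e-9)
            assert row.mi_xy == pytest.approx(res.mi_xy, abs=1e-9)
            assert row.cmi == pytest.approx(res.cmi_xy_given_p, abs=1e-9)

    @pytest.mark.parametrize("workers", [2, 4])
    def test_worker_count_independence(self, small_dataset, workers):
        base = scan_all_pairs(
            small_dataset.genotypes, small_dataset.phenotype,
            config=ScanConfig(n_workers=1, chunk_size=7),
        )
        other = scan_all_pairs(
            small_dataset.genotypes, small_dataset.phenotype,
            config=ScanConfig(n_workers=workers, chunk_size=7),
        )
        pd.testing.assert_frame_equal(base, other)

    def test_chunk_size_independence(self, small_dataset):
        a = scan_all_pairs(small_dataset.genotypes, small_dataset.phenotype,
                           config=ScanConfig(chunk_size=5))
        b = scan_all_pairs(small_dataset.genotypes, small_dataset.phenotype,
                           config=ScanConfig(chunk_size=1000))
        pd.testing.assert_frame_equal(a, b)

    def test_column_reordering_invariance(self, small_dataset):
        rng = np.random.default_rng(0)
        perm = rng.permutation(30)
        ids = [f"x{j + 1}" for j in range(30)]
        a = scan_all_pairs(small_dataset.genotypes, small_dataset.phenotype,
                           snp_ids=ids)
        b = scan_all_pairs(small_dataset.genotypes[:, perm], small_dataset.phenotype,
                           snp_ids=[ids[j] for j in perm])
        key = ["snp_a", "snp_b"]
        a = a.sort_values(key).reset_index(drop=True)
        b = b.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(a[key + ["ig", "r2"]], b[key + ["ig", "r2"]])

    def test_canonical_id_ordering(self, small_dataset):
        rec = scan_all_pairs(small_dataset.genotypes, small_dataset.phenotype)
        assert (rec["snp_a"] < rec["snp_b"]).all()

    def test_single_class_phenotype_rejected(self, rng):
        geno = rng.integers(0, 3, (10, 3)).astype(np.int8)
        with pytest.raises(DegeneratePhenotypeError):
            scan_all_pairs(geno, np.zeros(10, dtype=np.int8))

    def test_missing_genotypes_use_pairwise_deletion(self, rng):
        geno = rng.integers(0, 3, (120, 4)).astype(np.int8)
        ph = np.array([0, 1] * 60, dtype=np.int8)
        geno_miss = geno.copy()
        geno_miss[5:25, 1] = -1
        rec = scan_all_pairs(geno_miss, ph)
        # pair (x1, x2): drop rows missing at either SNP, recompute directly
        keep = geno_miss[:, 1] >= 0
        expected = interaction_gain(geno[keep, 0], geno[keep, 1], ph[keep]).ig
        row = rec[(rec["snp_a"] == "x1") & (rec["snp_b"] == "x2")].iloc[0]
        assert row.ig == pytest.approx(expected, abs=1e-9)
        # pairs not involving x2 are unaffected
        row34 = rec[(rec["snp_a"] == "x3") & (rec["snp_b"] == "x4")].iloc[0]
        assert row34.ig == pytest.approx(
            interaction_gain(geno[:, 2], geno[:, 3], ph).ig, abs=1e-9
        )

    def test_lean_kernel_agrees_with_full_scan(self, small_dataset):
        rec = scan_all_pairs(small_dataset.genotypes, small_dataset.phenotype)
        _, _, ig = allpairs_ig_values(small_dataset.genotypes, small_dataset.phenotype)
        assert np.allclose(rec["ig"].to_numpy(), ig, atol=1e-12)


class TestFilterPairs:
    def _records(self, igs, r2s):
        return pd.DataFrame(
            {
                "snp_a": [f"a{i}" for i in range(len(igs))],
                "snp_b": [f"b{i}" for i in range(len(igs))],
                "ig": igs,
                "r2": r2s,
            }
        )

    def test_all_zero_ig_removed(self):
        rec = self._records([0.0] * 5, [0.1] * 5)
        out = filter_pairs(rec, ScanConfig(alpha=0.1))
        assert len(out.records) == 0
        assert out.n_removed_alpha == 5

    def test_ld_rule_removes_high_r2(self):
        rec = self._records([0.2, 0.2], [0.9, 0.5])
        out = filter_pairs(rec, ScanConfig(alpha=0.1, r2_cutoff=0.8))
        assert list(out.records["r2"]) == [0.5]
        assert out.n_removed_ld == 1

    def test_nan_r2_is_retained(self):
        rec = self._records([0.3], [np.nan])
        out = filter_pairs(rec, ScanConfig(alpha=0.1))
        assert len(out.records) == 1

    def test_matches_hand_filter_and_is_idempotent(self, rng):
        igs = rng.uniform(0, 0.3, 100)
        r2s = rng.uniform(0, 1, 100)
        rec = self._records(igs, r2s)
        cfg = ScanConfig(alpha=0.1, r2_cutoff=0.8)
        out = filter_pairs(rec, cfg)
        expected = {(f"a{i}", f"b{i}") for i in range(100)
                    if igs[i] > 0.1 and r2s[i] <= 0.8}
        got = set(zip(out.records["snp_a"], out.records["snp_b"]))
        assert got == expected
        again = filter_pairs(out.records, cfg)
        pd.testing.assert_frame_equal(again.records, out.records)
        assert again.n_removed_alpha == again.n_removed_ld == 0


class TestDistanceSummary:
    def test_single_record(self):
        rec = pd.DataFrame(
            {"snp_a": ["a"], "snp_b": ["b"], "ig": [0.5],
             "form": ["within-gene"], "distance_bp": [10.0]}
        )
        out = distance_stratified_summary(rec)
        assert len(out) == 1
        assert out.iloc[0].n_pairs == 1
        assert out.iloc[0].max_ig == 0.5

    def test_distance_bins_ordered_with_decreasing_max_ig(self):
        rec = pd.DataFrame(
            {"snp_a": ["a", "c"], "snp_b": ["b", "d"], "ig": [0.5, 0.01],
             "form": ["gene-gene"] * 2, "distance_bp": [10.0, 1e6]}
        )
        out = distance_stratified_summary(rec).sort_values("bin_lo_bp")
        assert out.iloc[0].max_ig > out.iloc[-1].max_ig

    def test_cross_chromosome_records_excluded(self):
        rec = pd.DataFrame(
            {"snp_a": ["a"], "snp_b": ["b"], "ig": [0.5],
             "form": ["cross-chromosome"], "distance_bp": [np.nan]}
        )
        assert distance_stratified_summary(rec).empty

    def test_no_distance_trend_on_ld_free_data(self, small_dataset):
        from scipy import stats

        rec = scan_all_pairs(small_dataset.genotypes, small_dataset.phenotype)
        same = rec[rec["distance_bp"].notna()]
        # drop the planted pair; null SNPs carry no distance signal
        null = same[~((same["snp_a"] == "x1") & (same["snp_b"] == "x30"))]
        res = stats.linregress(null["distance_bp"], null["ig"])
        ci = 2.6 * res.stderr
        assert res.slope - ci <= 0 <= res.slope + ci
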