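"""VCF / population-map I/O, the exact HWE test, and SNP filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from popsweep import (
    MISSING,
    filter_variants,
    hwe_exact_test,
    read_population_map,
    read_vcf,
    write_population_map,
    write_vcf,
)
from popsweep.genotypes import PopulationMap
from popsweep.simulate import CohortDesign, simulate_structured_cohort

from conftest import make_matrix
from oracles import hwe_exact_enumeration

VCF_SMALL = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=100>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsA\tsB
chr1\t5\t.\tA\tT\t.\t.\t.\tGT\t0/0\t0/1
chr1\t17\t.\tC\tG\t.\t.\t.\tGT\t1/1\t./.
chr1\t40\t.\tG\tA\t.\t.\t.\tGT\t0/1\t1/1
"""


class TestReadVcf:
    def test_direct_transcription(self, tmp_path):
        p = tmp_path / "s.vcf"
        p.write_text(VCF_SMALL)
        gm = read_vcf(p)
        assert gm.samples == ["sA", "sB"]
        assert gm.pos.tolist() == [5, 17, 40]
        assert gm.gt.tolist() == [[0, 2, 1], [1, MISSING, 2]]
        assert gm.chrom_lengths == {"chr1": 100}
        assert not gm.is_phased  # unphased separators

    def test_missing_genotype_policy(self, tmp_path):
        p = tmp_path / "s.vcf"
        p.write_text(VCF_SMALL)
        with pytest.raises(ValueError, match="missing genotype"):
            read_vcf(p, missing_policy="error")

    @pytest.mark.parametrize(
        "gt_field,message",
        [("0/x", "malformed GT"), ("0/1/1", "non-diploid"), ("1", "non-diploid")],
    )
    def test_bad_gt_names_line(self, tmp_path, gt_field, message):
        body = VCF_SMALL.replace("0/1\t1/1", f"{gt_field}\t1/1")
        p = tmp_path / "bad.vcf"
        p.write_text(body)
        with pytest.raises(ValueError, match=f"line 7.*{message}|{message}.*line 7"):
            read_vcf(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "e.vcf"
        p.write_text("##fileformat=VCFv4.2\n")
        with pytest.raises(ValueError):
            read_vcf(p)

    def test_round_trip_identity(self, tmp_path):
        design = CohortDesign(n_snps=300, chrom_length=100_000, seed=5)
        gm, _, _ = simulate_structured_cohort(design)
        path = tmp_path / "c.vcf"
        write_vcf(gm, path)
        back = read_vcf(path)
        assert back.samples == gm.samples
        assert np.array_equal(back.pos, gm.pos)
        assert np.array_equal(back.gt, gm.gt)
        assert list(back.ref) == list(gm.ref)
        assert list(back.alt) == list(gm.alt)
        assert back.chrom_lengths == gm.chrom_lengths

    def test_phase_retained_round_trip(self, tmp_path):
        from popsweep import simulate_linked_haplotypes

        gm = simulate_linked_haplotypes(5, chrom_length=50_000, snp_density=1e-3, seed=2)
        path = tmp_path / "p.vcf"
        write_vcf(gm, path)
        back = read_vcf(path)
        assert back.is_phased
        assert np.array_equal(back.haplotypes, gm.haplotypes)


class TestPopulationMap:
    def test_three_line_tsv(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("sample\tpopulation\tregion\na\tP1\tR1\nb\tP1\tR1\nc\tP2\tR2\n")
        pmap = read_population_map(p)
        assert pmap.samples == ["a", "b", "c"]
        assert pmap.populations == ["P1", "P2"]

    def test_duplicate_sample_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("sample\tpopulation\tregion\na\tP1\tR1\na\tP2\tR2\n")
        with pytest.raises(ValueError, match="duplicated"):
            read_population_map(p)

    def test_study_design_shape(self, tmp_path):
        """The 8-subpopulation / 3-region collection design round-trips."""
        recs = []
        for region, k in {"Yumin": 3, "Tuoli": 4, "Tacheng": 1}.items():
            for i in range(k):
                pop = f"{region} {i + 1}"
                recs += [(f"{pop}-s{j}", pop, region) for j in range(2)]
        pmap = PopulationMap.from_records(recs)
        assert len(pmap.populations) == 8
        assert pmap.regions == ["Yumin", "Tuoli", "Tacheng"]
        path = tmp_path / "design.tsv"
        write_population_map(pmap, path)
        assert read_population_map(path).populations == pmap.populations

    def test_unmapped_samples_listed(self, small_cohort):
        gm, pmap, _ = small_cohort
        short = PopulationMap(pmap.table.iloc[:-3])
        with pytest.raises(ValueError, match="missing from population map"):
            short.require_samples(gm)


class TestHweExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(5, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 7) == 1.0

    def test_label_symmetry(self):
        assert hwe_exact_test(10, 21, 15) == pytest.approx(
            hwe_exact_test(15, 21, 10), abs=1e-14
        )

    def test_enumeration_oracle_frozen_value(self):
        # exact enumeration over het counts {1, 3, ..} given 41 ref / 51 alt
        assert hwe_exact_test(10, 21, 15) == pytest.approx(
            0.7645478050337627, abs=1e-12
        )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)

    @given(
        st.integers(min_value=0, max_value=25),
        st.integers(min_value=0, max_value=25),
        st.integers(min_value=0, max_value=25),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration(self, a, b, c):
        if a + b + c == 0:
            return
        assert hwe_exact_test(a, b, c) == pytest.approx(
            hwe_exact_enumeration(a, b, c), abs=1e-12
        )


class TestFilterVariants:
    def test_monomorphic_all_attributed_to_maf(self):
        gm = make_matrix(np.zeros((6, 4), dtype=np.int8))
        out, report = filter_variants(gm)
        assert out.n_variants == 0
        assert report.removed == {
            "non_biallelic": 0,
            "missingness": 0,
            "maf": 4,
            "hwe": 0,
        }

    def test_toy_fixture_attribution(self):
        """Six hand-built variants: one fails each rule, two survive."""
        n = 30
        rng = np.random.default_rng(0)
        good = rng.binomial(1, 0.5, n) + rng.binomial(1, 0.5, n)
        gt = np.zeros((n, 6), dtype=np.int8)
        gt[:, 0] = good  # triallelic (alt edited below)
        gt[:, 1] = good
        gt[:5, 1] = MISSING  # 5/30 ≈ 17% missing
        gt[:, 2] = 0
        gt[0, 2] = 1  # MAF 1/60 < 0.05
        gt[:, 3] = 1  # all heterozygous: extreme HWE departure
        gt[:, 4] = good
        gt[:, 5] = rng.binomial(1, 0.4, n) + rng.binomial(1, 0.4, n)
        gm = make_matrix(gt)
        gm.alt[0] = "T,G"
        out, report = filter_variants(gm)
        assert report.removed == {
            "non_biallelic": 1,
            "missingness": 1,
            "maf": 1,
            "hwe": 1,
        }
        assert out.n_variants == 2
        assert report.retained_count == 2

    def test_retained_satisfy_all_bounds(self, small_cohort):
        gm, _, _ = small_cohort
        out, _ = filter_variants(gm)
        called = out.gt != MISSING
        n = called.sum(axis=0)
        p = (out.gt * called).sum(axis=0) / (2 * n)
        maf = np.minimum(p, 1 - p)
        assert (maf > 0.05).all()
        assert ((1 - n / out.n_samples) <= 0.10).all()
        for j in range(out.n_variants):
            col = out.gt[:, j]
            pval = hwe_exact_test(
                int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
            )
            assert pval >= 0.001

    def test_idempotent(self, small_cohort):
        gm, _, _ = small_cohort
        once, _ = filter_variants(gm)
        twice, report = filter_variants(once)
        assert twice.n_variants == once.n_variants
        assert sum(report.removed.values()) == 0

    def test_keep_departures_flag_inverts_hwe(self):
        gt = np.ones((30, 1), dtype=np.int8)  # all het: HWE p << 0.001
        gm = make_matrix(gt)
        removed_default, _ = filter_variants(gm)
        kept_inverted, _ = filter_variants(gm, hwe_keep_departures=True)
        assert removed_default.n_variants == 0
        assert kept_inverted.n_variants == 1

    def test_threshold_bounds_checked(self, small_cohort):
        gm, _, _ = small_cohort
        with pytest.raises(ValueError):
            filter_variants(gm, maf_min=1.5)
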