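"""Synthetic-cohort and linked-haplotype generators."""

import numpy as np
import pytest

from popsweep import (
    CohortDesign,
    inject_sweep_signal,
    make_junction_scenario,
    pairwise_fst,
    read_population_map,
    read_vcf,
    simulate_linked_haplotypes,
    simulate_structured_cohort,
    write_cohort,
)
from popsweep.differentiation import fst_site_components, fst_windowed


class TestStructuredCohort:
    def test_deterministic_given_seed(self):
        d = CohortDesign(n_snps=500, chrom_length=500_000, seed=42)
        gm1, pmap1, _ = simulate_structured_cohort(d)
        gm2, pmap2, _ = simulate_structured_cohort(d)
        assert np.array_equal(gm1.gt, gm2.gt)
        assert np.array_equal(gm1.pos, gm2.pos)
        assert pmap1.table.equals(pmap2.table)

    def test_design_shape_matches_defaults(self):
        gm, pmap, truth = simulate_structured_cohort(
            CohortDesign(n_snps=100, chrom_length=100_000, seed=0)
        )
        assert len(pmap.populations) == 8
        assert pmap.regions == ["Yumin", "Tuoli", "Tacheng"]
        sizes = pmap.table.groupby("population", sort=False)["sample"].count()
        assert sizes.between(15, 18).all()
        assert set(truth.population_frequencies) == set(pmap.populations)

    def test_panmixia_limit(self):
        d = CohortDesign(
            f_region=1e-4, f_local=1e-4, n_snps=10_000,
            samples_per_population=15, seed=2,
        )
        gm, pmap, _ = simulate_structured_cohort(d)
        mat = pairwise_fst(gm, pmap, level="region")
        off = mat.values[np.triu_indices(3, 1)]
        assert np.all(np.abs(off) < 0.02)

    def test_estimator_recovery(self):
        d = CohortDesign(n_snps=20_000, samples_per_population=15, seed=8)
        gm, pmap, _ = simulate_structured_cohort(d)
        mat = pairwise_fst(gm, pmap, level="region")
        off = mat.values[np.triu_indices(3, 1)]
        assert abs(np.mean(off) - 0.30) <= 0.03

    def test_fst_monotone_in_generating_f(self):
        estimates = []
        for f in (0.05, 0.1, 0.2, 0.3):
            d = CohortDesign(
                regions={"R1": 1, "R2": 1}, samples_per_population=15,
                f_region=f, f_local=0.01, n_snps=5_000, seed=77,
            )
            gm, pmap, _ = simulate_structured_cohort(d)
            a, b = pmap.populations
            estimates.append(pairwise_fst(gm, pmap).loc[a, b])
        assert estimates == sorted(estimates)

    def test_within_population_hwe_holds(self):
        """Without injection, within-population genotypes are HWE-distributed."""
        from popsweep import hwe_exact_test

        d = CohortDesign(regions={"R": 1}, samples_per_population=30,
                         n_snps=2_000, seed=5)
        gm, pmap, _ = simulate_structured_cohort(d)
        pvals = []
        for j in range(gm.n_variants):
            col = gm.gt[:, j]
            pvals.append(hwe_exact_test(
                int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
            ))
        # rejection rate near the nominal level (exact test is conservative)
        rate = np.mean(np.array(pvals) < 0.05)
        assert rate < 0.07

    def test_invalid_f_rejected(self):
        with pytest.raises(ValueError):
            CohortDesign(f_region=0.0)
        with pytest.raises(ValueError):
            CohortDesign(f_local=1.0)


@pytest.fixture(scope="module")
def cohort():
    d = CohortDesign(n_snps=4_000, chrom_length=4_000_000,
                     samples_per_population=15, seed=19)
    return simulate_structured_cohort(d)


class TestInjectSweep:
    def test_strength_zero_is_identity(self, cohort):
        gm, pmap, truth = cohort
        out, _ = inject_sweep_signal(
            gm, truth, pmap, [("chr1", 1_000_000, 1_100_000)], "Tuoli", 0.0
        )
        assert np.array_equal(out.gt, gm.gt)

    def test_locality(self, cohort):
        gm, pmap, truth = cohort
        win = [("chr1", 1_000_000, 1_100_000)]
        out, _ = inject_sweep_signal(gm, truth, pmap, win, "Tuoli", 0.9, seed=1)
        inside = (gm.pos - 1 >= 1_000_000) & (gm.pos - 1 < 1_100_000)
        assert np.array_equal(out.gt[:, ~inside], gm.gt[:, ~inside])
        non_target = [s for s in gm.samples
                      if s not in pmap.samples_in("Tuoli")]
        idx = gm.sample_indices(non_target)
        assert np.array_equal(out.gt[idx], gm.gt[idx])

    def test_injected_windows_elevate_fst(self, cohort):
        gm, pmap, truth = cohort
        win = [("chr1", 1_000_000, 1_100_000), ("chr1", 2_500_000, 2_600_000)]
        out, new_truth = inject_sweep_signal(gm, pmap=pmap, truth=truth,
                                             windows=win, target_pop="Tuoli",
                                             strength=0.9, seed=3)
        comp = fst_site_components(
            out, pmap.samples_in("Tuoli"), pmap.samples_in("Yumin")
        )
        tr = fst_windowed(comp, window=100_000, step=100_000, min_snps=1)
        injected = np.isin(tr.start, [1_000_000, 2_500_000])
        assert np.nanmin(tr.value[injected]) > np.nanmedian(tr.value[~injected])
        assert len(new_truth.sweep_windows) == 2

    def test_overlapping_windows_rejected(self, cohort):
        gm, pmap, truth = cohort
        with pytest.raises(ValueError, match="overlap"):
            inject_sweep_signal(
                gm, truth, pmap,
                [("chr1", 0, 200_000), ("chr1", 100_000, 300_000)],
                "Tuoli", 0.5,
            )


class TestLinkedHaplotypes:
    def test_deterministic(self):
        a = simulate_linked_haplotypes(10, chrom_length=200_000, seed=3)
        b = simulate_linked_haplotypes(10, chrom_length=200_000, seed=3)
        assert np.array_equal(a.haplotypes, b.haplotypes)

    def test_no_recombination_gives_founder_mosaic_of_one_block(self):
        gm = simulate_linked_haplotypes(
            12, chrom_length=100_000, snp_density=1e-3,
            founder_count=5, recomb_rate=0.0, seed=6,
        )
        # every haplotype is a single founder copy -> at most 5 distinct rows
        flat = gm.haplotypes.transpose(0, 2, 1).reshape(-1, gm.n_variants)
        distinct = {tuple(h) for h in flat}
        assert len(distinct) <= 5

    def test_r2_decays_with_distance(self):
        from popsweep.junction import _hap_r2_matrix

        gm = simulate_linked_haplotypes(
            40, chrom_length=500_000, snp_density=1e-3,
            founder_count=8, recomb_rate=1e-5, seed=11,
        )
        hap = gm.haplotypes.transpose(0, 2, 1).reshape(-1, gm.n_variants)
        r2 = _hap_r2_matrix(hap, hap)
        dist = np.abs(gm.pos[None, :] - gm.pos[:, None])
        near = np.nanmean(r2[(dist > 0) & (dist < 10_000)])
        far = np.nanmean(r2[(dist > 200_000) & (dist < 300_000)])
        assert near > far


class TestJunctionScenarioGeneration:
    def test_observed_matrix_is_column_permutation(self):
        haps = simulate_linked_haplotypes(15, chrom_length=400_000,
                                          snp_density=5e-4, seed=2)
        obs, scen, truth = make_junction_scenario(haps, 200_000, 100_000,
                                                  "alternative")
        cols_a = {tuple(haps.gt[:, j]) for j in range(haps.n_variants)}
        cols_b = {tuple(obs.gt[:, j]) for j in range(obs.n_variants)}
        assert cols_a == cols_b
        assert truth.junction["true_mode"] == "alternative"

    def test_breakpoint_near_end_rejected(self):
        haps = simulate_linked_haplotypes(10, chrom_length=400_000,
                                          snp_density=5e-4, seed=2)
        with pytest.raises(ValueError, match="closer than flank"):
            make_junction_scenario(haps, 50_000, 100_000, "current")


class TestWriteCohort:
    def test_round_trip(self, tmp_path, small_cohort):
        gm, pmap, truth = small_cohort
        paths = write_cohort(gm, pmap, tmp_path / "cohort", truth)
        back = read_vcf(paths["vcf"])
        assert np.array_equal(back.gt, gm.gt)
        assert np.array_equal(back.pos, gm.pos)
        pm = read_population_map(paths["popmap"])
        assert pm.table.equals(pmap.table)
        assert paths["truth"].exists()

    def test_empty_cohort_rejected(self, tmp_path):
        import pandas as pd
        from popsweep import GenotypeMatrix, PopulationMap

        gm = GenotypeMatrix(
            samples=[], chrom=np.array([], dtype=object),
            pos=np.array([], dtype=np.int64), ref=np.array([], dtype=object),
            alt=np.array([], dtype=object), gt=np.zeros((0, 0), dtype=np.int8),
        )
        pmap = PopulationMap(pd.DataFrame(columns=["sample", "population", "region"]))
        with pytest.raises(ValueError, match="empty"):
            write_cohort(gm, pmap, tmp_path)

    def test_vcf_header_well_formed(self, tmp_path, small_cohort):
        gm, pmap, _ = small_cohort
        paths = write_cohort(gm, pmap, tmp_path / "c")
        lines = paths["vcf"].read_text().splitlines()
        assert lines[0] == "##fileformat=VCFv4.2"
        header = [l for l in lines if l.startswith("#CHROM")]
        assert len(header) == 1
        assert header[0].split("\t")[:9] == [
            "#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT",
        ]
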