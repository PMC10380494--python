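"""Per-population diversity indices and windowed nucleotide diversity.

Indices per biallelic locus with within-population alt frequency ``p``
(q = 1 - p) over the ``n`` non-missing diploid samples:

* observed heterozygosity  Ho = fraction of heterozygous genotypes;
* expected heterozygosity  He = 1 - p^2 - q^2 = 2pq;
* Nei's unbiased gene diversity  (2n / (2n - 1)) * He;
* Shannon-Wiener index  -(p ln p + q ln q) (natural log; 0 when fixed);
* observed allele number = count of alleles segregating (1 or 2).

Reports are means over usable loci.  Windowed pi divides the summed
per-site unbiased heterozygosity by the window *span* in bp, i.e. pi per
site, the sliding-window convention; with full calls and phase this equals
the mean pairwise per-site difference between haplotypes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, PopulationMap
from .windows import WindowTrack, assign_window_sums, make_windows


def locus_allele_stats(gm: GenotypeMatrix, samples: list[str]) -> dict[str, np.ndarray]:
    """Per-locus allele/genotype tallies over a sample subset.

    Returns arrays keyed ``p_alt``, ``n_alleles``, ``n_hom_ref``, ``n_het``,
    ``n_hom_alt``, ``n`` (non-missing diploids) and a boolean ``usable``
    mask that is False where every genotype is missing.
    """
    if not samples:
        raise ValueError("sample subset is empty")
    gt = gm.gt[gm.sample_indices(samples)]
    called = gt != MISSING
    n = called.sum(axis=0)
    n_het = (gt == 1).sum(axis=0)
    n_hom_ref = (gt == 0).sum(axis=0)
    n_hom_alt = (gt == 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(n > 0, (gt * called).sum(axis=0) / (2 * n), np.nan)
    n_alleles = np.where(
        n == 0, 0, 1 + ((p_alt > 0) & (p_alt < 1)).astype(int)
    )
    return {
        "p_alt": p_alt,
        "n_alleles": n_alleles,
        "n_hom_ref": n_hom_ref,
        "n_het": n_het,
        "n_hom_alt": n_hom_alt,
        "n": n,
        "usable": n > 0,
    }


def _per_locus_indices(stats: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    p = stats["p_alt"]
    q = 1 - p
    n = stats["n"]
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n > 0, stats["n_het"] / n, np.nan)
        he = 2 * p * q
        nei = np.where(n > 0, 2 * n / np.maximum(2 * n - 1, 1) * he, np.nan)
        shannon = -(
            np.where(p > 0, p * np.log(p), 0.0) + np.where(q > 0, q * np.log(q), 0.0)
        )
    return {"Ho": ho, "He": he, "Nei": nei, "Shannon": shannon}


def population_diversity(gm: GenotypeMatrix, pmap: PopulationMap) -> pd.DataFrame:
    """Mean diversity indices per population.

    Loci that are monomorphic within a population still contribute (indices
    0, allele number 1); loci with no called genotype in the population are
    excluded from that population's means.
    """
    pmap.require_samples(gm)
    rows = []
    for pop, samples in pmap.groups("population").items():
        samples = [s for s in samples if s in gm.samples]
        if len(samples) < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 samples")
        st = locus_allele_stats(gm, samples)
        idx = _per_locus_indices(st)
        use = st["usable"]
        rows.append(
            {
                "population": pop,
                "region": pmap.region_of(pop),
                "n_samples": len(samples),
                "n_loci": int(use.sum()),
                "Ho": float(np.nanmean(idx["Ho"][use])),
                "He": float(np.nanmean(idx["He"][use])),
                "Nei": float(np.nanmean(idx["Nei"][use])),
                "Shannon": float(np.nanmean(idx["Shannon"][use])),
                "allele_number": float(np.mean(st["n_alleles"][use])),
            }
        )
    return pd.DataFrame(rows)


def windowed_pi(
    gm: GenotypeMatrix,
    pmap: PopulationMap,
    population: str,
    window: int = 100_000,
    step: int = 10_000,
    min_snps: int = 10,
) -> WindowTrack:
    """Sliding-window nucleotide diversity for a population or region.

    Per window, pi = sum over SNPs of (2n/(2n-1)) * 2 p (1-p), divided by
    the window span in bp; windows with fewer than ``min_snps`` usable SNPs
    get an undefined (NaN) value.
    """
    if not (window >= step > 0):
        raise ValueError("require window >= step > 0")
    samples = pmap.samples_in(population)  # KeyError on unknown label
    samples = [s for s in samples if s in gm.samples]
    if len(samples) < 2:
        raise ValueError(f"label {population!r} has fewer than 2 usable samples")
    st = locus_allele_stats(gm, samples)
    p, n = st["p_alt"], st["n"]
    with np.errstate(invalid="ignore"):
        per_site = np.where(
            n > 1, 2 * p * (1 - p) * (2 * n) / np.maximum(2 * n - 1, 1), np.nan
        )
    lengths = {c: gm.chrom_length(c) for c in dict.fromkeys(gm.chrom.tolist())}
    grid = make_windows(lengths, window, step)
    sums = assign_window_sums(gm.chrom, gm.pos, {"pi": per_site}, grid)
    g_chrom, g_start, g_end, g_partial = grid
    span = (g_end - g_start).astype(float)
    n_snps = sums["n_sites"].astype(int)
    value = np.where(n_snps >= min_snps, sums["pi"] / span, np.nan)
    return WindowTrack(
        chrom=g_chrom,
        start=g_start,
        end=g_end,
        n_snps=n_snps,
        value=value,
        partial=g_partial,
        metadata={
            "statistic": "pi",
            "population": population,
            "window": window,
            "step": step,
            "min_snps": min_snps,
        },
    )
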