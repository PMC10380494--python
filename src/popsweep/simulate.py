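"""Seeded synthetic cohorts emulating a multi-region re-sequencing design.

Two deliberately decoupled generators:

* :func:`simulate_structured_cohort` draws allele frequencies under a
  hierarchical Balding-Nichols model — ancestral frequency, a Beta draw
  per region with variance ``F_region * p * (1 - p)``, a Beta draw per
  subpopulation around the region value with ``F_local`` — and genotypes
  each diploid binomially (Hardy-Weinberg within subpopulations).  Sites
  are independent, so expected Fst is available in closed form but the
  cohort carries no LD.
* :func:`simulate_linked_haplotypes` builds phased samples as recombinant
  mosaics of a small founder haplotype pool, giving r^2 that decays with
  distance at a scale of roughly 1 / recomb_rate bp — the substrate for
  the junction-validation procedure.

The default design mirrors a three-region, eight-subpopulation collection
(3 + 4 + 1 subpopulations, 15-18 diploids each) with strong between-region
(F = 0.30) and mild within-region (F = 0.07) differentiation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genotypes import GenotypeMatrix, PopulationMap
from .junction import JunctionScenario
from .variantio import write_population_map, write_vcf

_DEFAULT_REGIONS: dict[str, int] = {"Yumin": 3, "Tuoli": 4, "Tacheng": 1}


@dataclass
class CohortDesign:
    """Parameters of the hierarchical Balding-Nichols cohort.

    ``regions`` maps region name -> number of subpopulations; sample sizes
    cycle through 15-18 unless ``samples_per_population`` pins them.
    """

    regions: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_REGIONS))
    samples_per_population: int | None = None
    f_region: float = 0.30
    f_local: float = 0.07
    n_snps: int = 20_000
    chrom: str = "chr1"
    chrom_length: int = 20_000_000
    maf_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, f in (("f_region", self.f_region), ("f_local", self.f_local)):
            if not 0 < f < 1:
                raise ValueError(f"{name} must be in (0, 1), got {f}")
        if self.samples_per_population is not None and self.samples_per_population < 2:
            raise ValueError("sample sizes must be >= 2")

    def population_sizes(self) -> dict[str, tuple[str, int]]:
        """Ordered mapping population -> (region, n_samples)."""
        out: dict[str, tuple[str, int]] = {}
        k = 0
        for region, n_pops in self.regions.items():
            for i in range(n_pops):
                n = (
                    self.samples_per_population
                    if self.samples_per_population is not None
                    else 15 + k % 4
                )
                out[f"{region} {i + 1}"] = (region, n)
                k += 1
        return out


@dataclass
class TruthRecord:
    """Generating parameters and injected signals, for recovery tests."""

    design: dict = field(default_factory=dict)
    population_frequencies: dict[str, np.ndarray] = field(default_factory=dict)
    sweep_windows: list[dict] = field(default_factory=list)
    junction: dict = field(default_factory=dict)


def _bn_draw(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Balding-Nichols Beta draw around p; fixed frequencies pass through."""
    p = np.asarray(p, dtype=float)
    out = p.copy()
    interior = (p > 0) & (p < 1)
    a = p[interior] * (1 - f) / f
    b = (1 - p[interior]) * (1 - f) / f
    out[interior] = rng.beta(a, b)
    return out


def simulate_structured_cohort(
    design: CohortDesign,
) -> tuple[GenotypeMatrix, PopulationMap, TruthRecord]:
    """Draw a structured diploid cohort; deterministic given the design seed."""
    rng = np.random.default_rng(design.seed)
    lo, hi = design.maf_range
    p_anc = rng.uniform(lo, hi, design.n_snps)
    pos = np.sort(
        rng.choice(np.arange(1, design.chrom_length + 1), design.n_snps, replace=False)
    )
    pops = design.population_sizes()
    pop_freqs: dict[str, np.ndarray] = {}
    region_freqs: dict[str, np.ndarray] = {}
    samples: list[str] = []
    records: list[tuple[str, str, str]] = []
    gt_blocks: list[np.ndarray] = []
    for pop, (region, n) in pops.items():
        if region not in region_freqs:
            region_freqs[region] = _bn_draw(rng, p_anc, design.f_region)
        p_pop = _bn_draw(rng, region_freqs[region], design.f_local)
        pop_freqs[pop] = p_pop
        gt_blocks.append(rng.binomial(2, p_pop, size=(n, design.n_snps)).astype(np.int8))
        tag = pop.replace(" ", "")
        for i in range(n):
            sid = f"{tag}_s{i + 1:02d}"
            samples.append(sid)
            records.append((sid, pop, region))
    gm = GenotypeMatrix(
        samples=samples,
        chrom=np.array([design.chrom] * design.n_snps, dtype=object),
        pos=pos,
        ref=np.array(["A"] * design.n_snps, dtype=object),
        alt=np.array(["T"] * design.n_snps, dtype=object),
        gt=np.vstack(gt_blocks),
        chrom_lengths={design.chrom: design.chrom_length},
    )
    pmap = PopulationMap.from_records(records)
    truth = TruthRecord(
        design={
            "regions": dict(design.regions),
            "f_region": design.f_region,
            "f_local": design.f_local,
            "n_snps": design.n_snps,
            "chrom": design.chrom,
            "chrom_length": design.chrom_length,
            "seed": design.seed,
        },
        population_frequencies=pop_freqs,
    )
    return gm, pmap, truth


def inject_sweep_signal(
    gm: GenotypeMatrix,
    truth: TruthRecord,
    pmap: PopulationMap,
    windows: list[tuple[str, int, int]],
    target_pop: str,
    strength: float,
    seed: int = 0,
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Push the target group's allele frequencies toward fixation in windows.

    Within each (chrom, start, end) window (0-based half-open), each SNP's
    frequency in the target population/region moves a fraction ``strength``
    of the way toward its nearer fixed state, and the target samples'
    genotypes there are redrawn binomially.  This raises Fst against other
    groups and lowers pi in the target — the signature the sweep scan
    looks for.  ``strength = 0`` leaves the matrix untouched.
    """
    if not 0 <= strength <= 1:
        raise ValueError("strength must be in [0, 1]")
    for i, (c1, s1, e1) in enumerate(windows):
        for c2, s2, e2 in windows[i + 1 :]:
            if c1 == c2 and s1 < e2 and s2 < e1:
                raise ValueError("injected windows overlap")
    new_truth = TruthRecord(
        design=dict(truth.design),
        population_frequencies=dict(truth.population_frequencies),
        sweep_windows=list(truth.sweep_windows),
        junction=dict(truth.junction),
    )
    for chrom, start, end in windows:
        new_truth.sweep_windows.append(
            {"chrom": chrom, "start": int(start), "end": int(end),
             "target": target_pop, "strength": float(strength)}
        )
    if strength == 0:
        return gm, new_truth
    rng = np.random.default_rng(seed)
    target_samples = pmap.samples_in(target_pop)
    rows = gm.sample_indices([s for s in target_samples if s in gm.samples])
    gt = gm.gt.copy()
    for chrom, start, end in windows:
        in_w = (gm.chrom == chrom) & (gm.pos - 1 >= start) & (gm.pos - 1 < end)
        cols = np.flatnonzero(in_w)
        if cols.size == 0:
            continue
        sub = gt[np.ix_(rows, cols)].astype(float)
        p = sub.mean(axis=0) / 2
        shifted = np.where(p >= 0.5, p + strength * (1 - p), p * (1 - strength))
        gt[np.ix_(rows, cols)] = rng.binomial(
            2, shifted, size=(rows.size, cols.size)
        ).astype(np.int8)
    out = GenotypeMatrix(
        samples=list(gm.samples),
        chrom=gm.chrom,
        pos=gm.pos,
        ref=gm.ref,
        alt=gm.alt,
        gt=gt,
        chrom_lengths=dict(gm.chrom_lengths),
    )
    return out, new_truth


def simulate_linked_haplotypes(
    n_samples: int,
    chrom_length: int = 2_000_000,
    snp_density: float = 5e-4,
    founder_count: int = 8,
    recomb_rate: float = 1e-5,
    seed: int = 0,
    chrom: str = "chr1",
) -> GenotypeMatrix:
    """Phased samples as recombinant mosaics of a founder haplotype pool.

    Each haplotype starts from a random founder and switches to a fresh
    founder at Poisson(``recomb_rate`` per bp) breakpoints, so the chance
    two sites share a founder decays exponentially with distance at scale
    ~1/recomb_rate; with ``recomb_rate = 0`` every haplotype is a single
    founder copy and LD equals the founder-pool LD at all distances.
    """
    if founder_count < 2:
        raise ValueError("founder_count must be >= 2")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    n_snps = max(2, int(round(chrom_length * snp_density)))
    pos = np.sort(rng.choice(np.arange(1, chrom_length + 1), n_snps, replace=False))
    founder_freq = rng.uniform(0.1, 0.9, n_snps)
    founders = (rng.random((founder_count, n_snps)) < founder_freq).astype(np.int8)
    hap = np.empty((n_samples, n_snps, 2), dtype=np.int8)
    for i in range(n_samples):
        for h in range(2):
            if recomb_rate > 0:
                n_breaks = rng.poisson(recomb_rate * chrom_length)
                breaks = np.sort(rng.integers(1, chrom_length + 1, n_breaks))
            else:
                breaks = np.array([], dtype=np.int64)
            seg = np.searchsorted(breaks, pos, side="left")
            founder_ids = rng.integers(0, founder_count, breaks.size + 1)
            hap[i, :, h] = founders[founder_ids[seg], np.arange(n_snps)]
    gt = hap.sum(axis=2).astype(np.int8)
    return GenotypeMatrix(
        samples=[f"s{i + 1:03d}" for i in range(n_samples)],
        chrom=np.array([chrom] * n_snps, dtype=object),
        pos=pos,
        ref=np.array(["A"] * n_snps, dtype=object),
        alt=np.array(["T"] * n_snps, dtype=object),
        gt=gt,
        haplotypes=hap,
        chrom_lengths={chrom: chrom_length},
    )


def make_junction_scenario(
    haps: GenotypeMatrix,
    breakpoint: int,
    flank: int = 500_000,
    true_mode: str = "current",
) -> tuple[GenotypeMatrix, JunctionScenario, TruthRecord]:
    """Derive the observed assembly and candidate modes from true haplotypes.

    ``haps`` is the genotype matrix on the *true* chromosome.  With
    ``true_mode="alternative"`` the observed assembly has the B-side contig
    reversed (i.e. the assembly under test is wrong), so the validator
    should prefer re-reversing it.  The genotype columns are a permutation
    of the input's in either case.
    """
    if true_mode not in ("current", "alternative"):
        raise ValueError(f"unknown true_mode {true_mode!r}")
    chroms = dict.fromkeys(haps.chrom.tolist())
    if len(chroms) != 1:
        raise ValueError("junction scenarios require a single-chromosome matrix")
    chrom = next(iter(chroms))
    length = haps.chrom_length(chrom)
    if not (flank <= breakpoint <= length - flank):
        raise ValueError(
            f"breakpoint {breakpoint} closer than flank {flank} to a chromosome end"
        )
    scenario = JunctionScenario(chrom=chrom, breakpoint=breakpoint, flank=flank,
                                b_end=length)
    if true_mode == "current":
        observed = haps
    else:
        pos = haps.pos.copy()
        b_side = pos > breakpoint
        pos[b_side] = breakpoint + (length - pos[b_side]) + 1
        order = np.argsort(pos, kind="stable")
        observed = GenotypeMatrix(
            samples=list(haps.samples),
            chrom=haps.chrom[order],
            pos=pos[order],
            ref=haps.ref[order],
            alt=haps.alt[order],
            gt=haps.gt[:, order],
            haplotypes=None if haps.haplotypes is None else haps.haplotypes[:, order, :],
            chrom_lengths=dict(haps.chrom_lengths),
        )
    truth = TruthRecord(junction={"chrom": chrom, "breakpoint": int(breakpoint),
                                  "flank": int(flank), "true_mode": true_mode})
    return observed, scenario, truth


def write_cohort(
    gm: GenotypeMatrix,
    pmap: PopulationMap,
    outdir: str | Path,
    truth: TruthRecord | None = None,
) -> dict[str, Path]:
    """Write cohort VCF + population map (+ truth JSON) into ``outdir``."""
    if gm.n_samples == 0 or gm.n_variants == 0:
        raise ValueError("refusing to write an empty cohort")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "popmap": outdir / "populations.tsv",
    }
    write_vcf(gm, paths["vcf"])
    write_population_map(pmap, paths["popmap"])
    if truth is not None:
        paths["truth"] = outdir / "truth.json"
        payload = {
            "design": truth.design,
            "sweep_windows": truth.sweep_windows,
            "junction": truth.junction,
        }
        paths["truth"].write_text(json.dumps(payload, indent=2) + "\n")
    return paths
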