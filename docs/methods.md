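# Methods

This note documents the statistical models, estimators and numerical
conventions implemented in `popsweep`, the choices made where several
defensible options existed, and what the synthetic cohorts do and do not
establish about behavior on real data.

## Genotype model and coordinates

Diploid genotypes are alt-allele dosage codes {0, 1, 2} with −1 for
uncalled; phased haplotype pairs are kept when the source supplies them
and their per-entry sum is validated against the codes. Variant
positions are 1-based (VCF convention); every window output uses 0-based
half-open intervals (BED convention), so a variant at position p lies in
windows with start ≤ p−1 < end. Windows tile each chromosome from 0 with
a fixed step; terminal windows shorter than the nominal size are emitted
but flagged partial and excluded from all quantile computations.

## SNP filtering

Four rules in fixed order — non-biallelic, missingness > 10 %, pooled
MAF ≤ 5 % (retention requires strictly > 0.05), exact Hardy–Weinberg
p < 0.001 — with each removed variant attributed to the first rule it
fails, so filter reports are deterministic and their counts add up to
the input count. MAF and HWE use genotypes pooled over the whole cohort
because the filters describe a single merged call set.

The HWE test is the standard (not mid-p) two-sided exact conditional
test on the heterozygote count given the allele counts. It is computed
in log-space with `lgamma`, normalised over the support, and compares
conditional probabilities with a 1 + 1e−12 relative tolerance so that
tables tied with the observed one are always included; the test is
exactly symmetric under swapping the homozygote classes and returns 1
when an allele is absent. An exhaustive sweep against an exact-rational
enumeration oracle over every table with ≤ 30 individuals bounds the
absolute error at < 1e−12.

Removing (rather than keeping) p < 0.001 variants follows universal
quality-control practice; the inverse behavior is available via
`hwe_keep_departures=True` for matching pipelines that phrase the rule
the other way.

**A consequence worth knowing:** in a strongly structured cohort the
pooled genotype counts show a Wahlund heterozygote deficit precisely at
the most differentiated SNPs, so the pooled HWE rule preferentially
removes high-F_ST sites and attenuates downstream differentiation
estimates (in the default simulated cohort it removes roughly a quarter
of the SNPs, and region-level F_ST drops from ≈ 0.32 to ≈ 0.16–0.20).
Estimator-recovery checks therefore run on unfiltered simulated
genotypes; the pipeline applies the filters as a real analysis would.

## Diversity indices

Per biallelic locus with within-group alt frequency p (q = 1−p) over n
non-missing diploids: H_o = heterozygote fraction; H_e = 2pq; Nei's
unbiased gene diversity (2n/(2n−1))·2pq; Shannon–Wiener −(p ln p +
q ln q) with 0·ln 0 = 0; allele number = segregating alleles (1 or 2).
Reports are unweighted means over loci with at least one called
genotype in the group; loci monomorphic in the group contribute zeros
(allele number 1). Groups need ≥ 2 samples.

## Windowed π

π per window is Σ over SNPs of (2n/(2n−1))·2p̂(1−p̂), divided by the
window span in bp — per-site nucleotide diversity against the full
window, the sliding-window convention. On fully called data this equals
the mean per-site pairwise difference over all 2n haplotypes (an
algebraic identity: the unbiased per-SNP heterozygosity is exactly the
pairwise mismatch fraction), which the tests verify against a
brute-force pairwise oracle. Windows with fewer than `min_snps`
(default 10) SNPs are undefined (NaN); the default guards the π-ratio
against near-zero denominators.

## F_ST

Estimator: the 1984 Weir–Cockerham variance components for r sampled
groups, computed per site from group sizes, allele frequencies and
observed heterozygosities — the default of the standard population-
genomics tools. Sites with < 2 called genotypes in a group, or
monomorphic across the pooled pair, are flagged unusable. Multi-site
values (windows, genome-wide, matrix entries) are ratios of sums,
Σa/Σ(a+b+c), never means of per-site ratios, which are unstable in
low-diversity windows; a constructed two-SNP fixture in the tests pins
the difference. Negative estimates are reported as computed.

The hierarchical simulator gives closed-form expectations to recover:
with regional differentiation F_region = 0.30 and subpopulation
differentiation F_local = 0.07 around regional frequencies, region-level
pairwise θ̂ recovers ≈ 0.30 and within-region subpopulation pairs
recover ≈ 0.07. Two caveats are properties of the estimator, not bugs:
(i) a two-group comparison of populations drawn from *different* regions
estimates the total divergence F_region + (1−F_region)·F_local ≈ 0.35,
not F_region; (ii) region-level comparisons carry a small upward bias
(≈ +0.01 to +0.03) because within-region substructure is unmodeled by
the two-group formulation — largest when a "region" holds a single
subpopulation. Acceptance checks therefore evaluate the mean of the
between-region entries, which sits within ±0.03 of the generating value
across seeds. An independent Hudson-estimator transcription cross-checks
the implementation within 0.03 on balanced designs.

## Sweep scan

The joint rule on a shared window grid: F_ST threshold is the empirical
(1−q) quantile (linear interpolation) of usable windows (default
q = 0.05); the log2 π-ratio track log2((π_A+ε)/(π_B+ε)) gets two tails
of q/2 each, one per population (a single-tail mode with q per tail is
available). Selection is ≥ for F_ST — matching how such cutoffs are
reported ("F_ST ≥ threshold") — and strictly > (<) for the ratio tails,
which makes tie behavior exact: constant tracks flag everything by F_ST
and nothing by ratio, so the intersection is empty. A high ratio means
A is the more diverse side, so the candidate is called selected-in-B,
and vice versa. The pseudocount ε = 1e−8 per site is negligible against
typical per-site π (~1e−3) and only guards the log at zero-π windows.
Candidate counts are window counts; per-SNP reporting is out of scope.

## Junction validation

The two connection modes of a two-contig join are "current" (B-side
contig as assembled) and "alternative" (B-side reversed: position p maps
to breakpoint + (b_end − p) + 1). Each mode is scored by the unweighted
mean r² over all SNP pairs with one member in each flank (default
500 kb) and inter-SNP distance at most the flank length; the mode with
the higher mean wins, with relative differences below 1e−6 declared
undecided. r² is the composite (squared Pearson correlation of dosage
codes) by default and the haplotype-frequency D²/(p_i q_i p_j q_j) form
when phase is available; both are invariant to sample order and allele
relabeling. Monomorphic sites are excluded. Pairwise scoring is
vectorized via block correlation matrices when no genotypes are missing,
with a per-pair pairwise-complete fallback otherwise.

Discrimination between modes depends on cohort size: the composite-r²
background for unlinked pairs is of order 1/(2N), so small cohorts can
bury the cross-junction signal in noise. Validation scenarios use a
130-sample cohort at ~1 SNP/kb — the scale of a population
re-sequencing study — where the true mode is recovered in 100/100
seeded trials; a 30-sample variant of the same scenario recovers only
~90/100, which is the expected noise-floor effect, not an
implementation failure.

## Synthetic cohorts

`simulate_structured_cohort` draws ancestral frequencies uniform on
[0.05, 0.95] (keeping most sites past the MAF filter), regional
frequencies Beta(p(1−F_R)/F_R, (1−p)(1−F_R)/F_R), subpopulation
frequencies with F_local around them (frequencies that hit 0 or 1 pass
through unchanged), and binomial genotypes — Hardy–Weinberg within
subpopulations, no LD between sites, no missingness. Defaults mirror a
three-region collection: 3 + 4 + 1 subpopulations, sample sizes cycling
15–18, F_region = 0.30, F_local = 0.07, 20 000 SNPs on a 20-Mb
chromosome. `inject_sweep_signal` moves the target group's frequencies a
fraction `strength` toward the nearer fixed state inside chosen windows
and redraws that group's genotypes there; strength 0.8 emulates
near-fixation sweeps.

`simulate_linked_haplotypes` decouples the LD concern: phased samples
are mosaics of a small founder pool (default 8) with founder switches at
Poisson breakpoints, giving r² that decays from the founder-pool level
(~1/founder count) to the sampling floor at scale ≈ 1/recomb_rate
(default 1e−5 /bp → 100 kb).

What passing tests show — estimator correctness, threshold exactness,
parameter recovery, mode identifiability — and what they do not: the
frequency cohort has no LD, missingness, allele-frequency spectrum
realism or linked selection, so recall numbers and filter pass rates on
real resequencing data will differ. The generators are pure functions of
(parameters, seed).

## Pipeline

Stage order is fixed (simulate/load → filter → diversity → F_ST → sweep
→ optional junction); every run writes a JSON manifest with all
parameters, the seed and the stage list, numeric TSV output uses a fixed
%.6g format, and reruns with the same config and seed are byte-identical.
Unknown config keys are rejected by name. A stage failure aborts the run
with the failing stage named and a partial manifest on disk.

## Problem sizes

Default analysis sizes used throughout the tests and the acceptance
script — 20 000 SNPs on 20 Mb for recovery checks, 100 windows for the
constructed sweep fixture, 200 non-overlapping windows for recall, 100
junction scenarios of 2 Mb at 1 SNP/kb, exhaustive HWE tables to n = 30 —
were chosen so each check runs in seconds while leaving the measured
quantities' sampling error an order of magnitude below the tolerances
they are compared at.
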