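"""VCF / population-map I/O and SNP quality filtering.

The reader handles the GT-only subset of VCF 4.2 that re-sequencing SNP
matrices use: diploid genotypes, ``./.`` missing calls, ``|`` phase
separators (phase is retained only when every call in the file is phased).
Multi-allelic records are loaded and *flagged* — :func:`filter_variants`
removes them attributably rather than the reader dropping them silently.

Filtering follows the usual merged-cohort regime: biallelic SNPs with
pooled minor-allele frequency above a floor, per-variant missingness below
a cap, and an exact Hardy-Weinberg test on pooled genotype counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, PopulationMap

_RULES = ("non_biallelic", "missingness", "maf", "hwe")


@dataclass
class FilterReport:
    """Attribution of removed variants to the first filter rule they fail."""

    input_count: int
    removed: dict[str, int]
    retained_count: int
    thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.input_count != self.retained_count + sum(self.removed.values()):
            raise ValueError("filter report counts do not add up")

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.input_count)]
        rows += [(f"removed_{r}", self.removed.get(r, 0)) for r in _RULES]
        rows.append(("retained", self.retained_count))
        return pd.DataFrame(rows, columns=["category", "count"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _parse_gt(token: str, line_no: int) -> tuple[int, int, bool]:
    """Parse one GT call -> (allele1, allele2, phased); -1 encodes '.'."""
    call = token.split(":", 1)[0]
    phased = "|" in call
    parts = call.replace("|", "/").split("/")
    if len(parts) != 2:
        raise ValueError(
            f"line {line_no}: non-diploid GT field {call!r} (expected 2 alleles)"
        )
    alleles = []
    for p in parts:
        if p == ".":
            alleles.append(-1)
        else:
            try:
                alleles.append(int(p))
            except ValueError:
                raise ValueError(f"line {line_no}: malformed GT field {call!r}") from None
    return alleles[0], alleles[1], phased


def read_vcf(path: str | Path, missing_policy: str = "allow") -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path
        Uncompressed VCF 4.x file with diploid GT as the first FORMAT field.
    missing_policy
        ``"allow"`` maps ``./.`` to the MISSING code; ``"error"`` rejects any
        uncalled genotype.
    """
    if missing_policy not in ("allow", "error"):
        raise ValueError("missing_policy must be 'allow' or 'error'")
    path = Path(path)
    samples: list[str] = []
    chrom_lengths: dict[str, int] = {}
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    gt_rows: list[np.ndarray] = []
    hap_rows: list[np.ndarray] = []
    all_phased = True
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                if line.startswith("##contig="):
                    body = line[len("##contig=<") :].rstrip(">")
                    fields = dict(
                        kv.split("=", 1) for kv in body.split(",") if "=" in kv
                    )
                    if "ID" in fields and "length" in fields:
                        chrom_lengths[fields["ID"]] = int(fields["length"])
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10:
                    raise ValueError(f"line {line_no}: VCF has no sample columns")
                samples = cols[9:]
                continue
            if not samples:
                raise ValueError(f"line {line_no}: data line before #CHROM header")
            cols = line.split("\t")
            if len(cols) != 9 + len(samples):
                raise ValueError(
                    f"line {line_no}: expected {9 + len(samples)} columns, "
                    f"got {len(cols)}"
                )
            chroms.append(cols[0])
            poss.append(int(cols[1]))
            refs.append(cols[3])
            alts.append(cols[4])
            codes = np.empty(len(samples), dtype=np.int8)
            haps = np.empty((len(samples), 2), dtype=np.int8)
            for i, token in enumerate(cols[9:]):
                a1, a2, phased = _parse_gt(token, line_no)
                if a1 < 0 or a2 < 0:
                    if missing_policy == "error":
                        raise ValueError(f"line {line_no}: missing genotype for "
                                         f"sample {samples[i]!r}")
                    codes[i] = MISSING
                    haps[i] = (MISSING, MISSING)
                    continue
                codes[i] = (a1 > 0) + (a2 > 0)  # non-ref dosage, multiallelic-safe
                haps[i] = (a1, a2)
                if not phased:
                    all_phased = False
            gt_rows.append(codes)
            hap_rows.append(haps)
    if not samples or not gt_rows:
        raise ValueError(f"{path}: empty VCF (no samples or no data lines)")
    gt = np.stack(gt_rows, axis=1)
    haplotypes = None
    if all_phased:
        hap = np.stack(hap_rows, axis=1)
        if not (hap[gt != MISSING] > 1).any():
            haplotypes = hap
    return GenotypeMatrix(
        samples=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        gt=gt,
        haplotypes=haplotypes,
        chrom_lengths=chrom_lengths,
    )


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a GT-only VCF 4.2; phased separators when the matrix is phased."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popsweep\n")
        for chrom in dict.fromkeys(gm.chrom.tolist()):
            length = gm.chrom_lengths.get(chrom, int(gm.pos[gm.chrom == chrom].max()))
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        sep = "|" if gm.is_phased else "/"
        for j in range(gm.n_variants):
            calls = []
            for i in range(gm.n_samples):
                code = gm.gt[i, j]
                if code == MISSING:
                    calls.append(f".{sep}.")
                elif gm.is_phased:
                    a, b = gm.haplotypes[i, j]
                    calls.append(f"{a}{sep}{b}")
                else:
                    a = 0 if code == 0 else (1 if code == 2 else 0)
                    b = 0 if code == 0 else 1
                    calls.append(f"{a}{sep}{b}")
            fh.write(
                f"{gm.chrom[j]}\t{gm.pos[j]}\t.\t{gm.ref[j]}\t{gm.alt[j]}"
                f"\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# Population map
# ---------------------------------------------------------------------------


def read_population_map(path: str | Path) -> PopulationMap:
    """Read a sample/population/region TSV into a :class:`PopulationMap`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return PopulationMap(df)


def write_population_map(pmap: PopulationMap, path: str | Path) -> None:
    pmap.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test on the heterozygote count.

    Conditions on the observed allele counts and sums, over every possible
    heterozygote count of matching parity, the conditional probabilities
    that are at most that of the observed table.  Symmetric under swapping
    the homozygote classes; returns 1.0 when one allele is absent.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError(f"counts must be nonnegative integers, got {counts}")
    n = sum(counts)
    if n == 0:
        raise ValueError("at least one genotyped individual required")
    n_a = 2 * n_hom_ref + n_het  # ref allele count
    n_b = 2 * n - n_a
    if n_a == 0 or n_b == 0:
        return 1.0

    rare = min(n_a, n_b)
    lg = math.lgamma

    def log_prob(het: int) -> float:
        hom_rare = (rare - het) // 2
        hom_common = n - hom_rare - het
        return (
            lg(n + 1)
            - lg(hom_rare + 1)
            - lg(het + 1)
            - lg(hom_common + 1)
            + het * math.log(2.0)
            + lg(n_a + 1)
            + lg(n_b + 1)
            - lg(2 * n + 1)
        )

    hets = range(rare % 2, rare + 1, 2)
    logs = np.array([log_prob(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[(n_het - rare % 2) // 2]
    # tolerance absorbs float noise in "<=" comparisons between equal tables
    p = probs[probs <= p_obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Variant filtering
# ---------------------------------------------------------------------------


def filter_variants(
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    missing_max: float = 0.10,
    hwe_alpha: float = 0.001,
    biallelic_only: bool = True,
    hwe_keep_departures: bool = False,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the merged-cohort SNP filters.

    Rules are applied in a fixed order — non-biallelic, missingness, pooled
    MAF (strictly greater than ``maf_min``), Hardy-Weinberg exact test on
    pooled genotype counts — and each removed variant is attributed to the
    first rule it fails, so the report is deterministic.

    ``hwe_keep_departures=True`` inverts the HWE rule (keep only p <
    ``hwe_alpha``); the default removes extreme departures, the standard
    quality-control reading.
    """
    for name, value in (
        ("maf_min", maf_min),
        ("missing_max", missing_max),
        ("hwe_alpha", hwe_alpha),
    ):
        if not 0 <= value <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {value}")

    gt = gm.gt
    called = gt != MISSING
    n_called = called.sum(axis=0)
    miss_frac = 1.0 - n_called / gm.n_samples

    with np.errstate(invalid="ignore"):
        p_alt = np.where(n_called > 0, (gt * called).sum(axis=0) / (2 * n_called), np.nan)
    maf = np.minimum(p_alt, 1 - p_alt)

    fail_bi = ~gm.is_biallelic() if biallelic_only else np.zeros(gm.n_variants, bool)
    fail_miss = (miss_frac > missing_max) | (n_called == 0)
    fail_maf = ~(maf > maf_min)  # NaN fails too

    removed = dict.fromkeys(_RULES, 0)
    reason = np.full(gm.n_variants, "", dtype=object)
    reason[fail_maf] = "maf"
    reason[fail_miss] = "missingness"
    reason[fail_bi] = "non_biallelic"
    # HWE only evaluated on variants surviving the earlier rules
    survivors = np.flatnonzero(reason == "")
    for j in survivors:
        col = gt[:, j]
        n_het = int((col == 1).sum())
        n_hom_ref = int((col == 0).sum())
        n_hom_alt = int((col == 2).sum())
        p = hwe_exact_test(n_hom_ref, n_het, n_hom_alt)
        extreme = p < hwe_alpha
        if extreme != hwe_keep_departures:
            reason[j] = "hwe"
    # attribution: each variant charged to its first failing rule
    order = {"non_biallelic": 0, "missingness": 1, "maf": 2, "hwe": 3}
    final = np.full(gm.n_variants, "", dtype=object)
    for rule in sorted(order, key=order.get):
        if rule == "non_biallelic":
            mask = fail_bi
        elif rule == "missingness":
            mask = fail_miss
        elif rule == "maf":
            mask = fail_maf
        else:
            mask = reason == "hwe"
        final[(final == "") & mask] = rule
    keep = final == ""
    for rule in _RULES:
        removed[rule] = int((final == rule).sum())
    report = FilterReport(
        input_count=gm.n_variants,
        removed=removed,
        retained_count=int(keep.sum()),
        thresholds={
            "maf_min": maf_min,
            "missing_max": missing_max,
            "hwe_alpha": hwe_alpha,
        },
    )
    return gm.take_variants(keep), report
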