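"""In-memory genotype containers.

A :class:`GenotypeMatrix` holds diploid genotypes as alt-allele dosage codes
(0, 1, 2) with :data:`MISSING` = -1 for uncalled genotypes, one column per
variant, one row per sample.  When the source provides phase (the simulator,
or a fully phased VCF) the haplotype pair is retained alongside the codes.

A :class:`PopulationMap` assigns each sample to a subpopulation and each
subpopulation to a geographic region, mirroring the two-level sampling
design of a multi-region re-sequencing cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel genotype code for an uncalled ("./.") genotype.
MISSING: int = -1


@dataclass
class GenotypeMatrix:
    """Samples x variants diploid genotype matrix.

    Parameters
    ----------
    samples
        Sample identifiers, one per row of ``gt``.
    chrom, pos, ref, alt
        Per-variant chromosome, 1-based position (VCF convention), and
        alleles.  Multi-allelic records carry a comma-joined ``alt``.
    gt
        ``(n_samples, n_variants)`` int8 array of alt-allele counts in
        {0, 1, 2} or :data:`MISSING`.
    haplotypes
        Optional ``(n_samples, n_variants, 2)`` int8 array of phased allele
        calls; its per-entry sum must equal ``gt`` wherever non-missing.
    chrom_lengths
        Optional chromosome lengths in bp (from VCF contig headers or the
        simulator); required by windowed analyses.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    gt: np.ndarray
    haplotypes: np.ndarray | None = None
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        if self.gt.shape != (len(self.samples), self.pos.size):
            raise ValueError(
                f"gt shape {self.gt.shape} does not match "
                f"{len(self.samples)} samples x {self.pos.size} variants"
            )
        self.validate()

    # -- consistency ------------------------------------------------------

    def validate(self) -> None:
        """Check container invariants; raise ``ValueError`` on violation."""
        valid = {0, 1, 2, MISSING}
        codes = set(np.unique(self.gt).tolist())
        if not codes <= valid:
            raise ValueError(f"invalid genotype codes: {sorted(codes - valid)}")
        for c in dict.fromkeys(self.chrom.tolist()):
            p = self.pos[self.chrom == c]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        if self.haplotypes is not None:
            hap = np.asarray(self.haplotypes, dtype=np.int8)
            if hap.shape != self.gt.shape + (2,):
                raise ValueError("haplotypes shape mismatch")
            called = self.gt != MISSING
            if not np.array_equal(hap[called].sum(axis=-1), self.gt[called]):
                raise ValueError("haplotype pair sums disagree with genotype codes")
            self.haplotypes = hap
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")

    # -- basic views ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return int(self.pos.size)

    @property
    def is_phased(self) -> bool:
        return self.haplotypes is not None

    def is_biallelic(self) -> np.ndarray:
        """Boolean mask of variants with exactly one alt allele."""
        return np.array(["," not in a for a in self.alt], dtype=bool)

    def sample_indices(self, ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in genotype matrix: {missing}")
        return np.array([lookup[s] for s in ids], dtype=np.intp)

    def take_samples(self, ids: list[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(ids)
        return GenotypeMatrix(
            samples=list(ids),
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            gt=self.gt[idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[idx],
            chrom_lengths=dict(self.chrom_lengths),
        )

    def take_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            samples=list(self.samples),
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            gt=self.gt[:, mask],
            haplotypes=None
            if self.haplotypes is None
            else self.haplotypes[:, mask, :],
            chrom_lengths=dict(self.chrom_lengths),
        )

    def chrom_length(self, chrom: str) -> int:
        """Length of ``chrom`` in bp, falling back to the last variant."""
        if chrom in self.chrom_lengths:
            return int(self.chrom_lengths[chrom])
        sel = self.chrom == chrom
        if not sel.any():
            raise KeyError(f"unknown chromosome {chrom!r}")
        return int(self.pos[sel].max())


@dataclass
class PopulationMap:
    """Sample -> subpopulation -> region assignment."""

    table: pd.DataFrame  # columns: sample, population, region

    def __post_init__(self) -> None:
        required = ["sample", "population", "region"]
        if list(self.table.columns[:3]) != required:
            raise ValueError(f"population map needs columns {required}")
        dup = self.table["sample"][self.table["sample"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicated sample ids: {sorted(set(dup))}")
        multi = (
            self.table.groupby("population")["region"].nunique().loc[lambda s: s > 1]
        )
        if len(multi):
            raise ValueError(
                f"populations mapped to multiple regions: {list(multi.index)}"
            )

    @classmethod
    def from_records(cls, records: list[tuple[str, str, str]]) -> "PopulationMap":
        return cls(pd.DataFrame(records, columns=["sample", "population", "region"]))

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.table["population"]))

    @property
    def regions(self) -> list[str]:
        return list(dict.fromkeys(self.table["region"]))

    def samples_in(self, label: str) -> list[str]:
        """Samples belonging to a population or (if no such population) a region."""
        t = self.table
        if (t["population"] == label).any():
            return list(t.loc[t["population"] == label, "sample"])
        if (t["region"] == label).any():
            return list(t.loc[t["region"] == label, "sample"])
        raise KeyError(f"unknown population/region label {label!r}")

    def region_of(self, population: str) -> str:
        t = self.table
        sel = t["population"] == population
        if not sel.any():
            raise KeyError(f"unknown population {population!r}")
        return str(t.loc[sel, "region"].iloc[0])

    def groups(self, level: str) -> dict[str, list[str]]:
        """Mapping of group label -> sample ids at ``level`` ('population'|'region')."""
        if level not in ("population", "region"):
            raise ValueError("level must be 'population' or 'region'")
        out: dict[str, list[str]] = {}
        for _, row in self.table.iterrows():
            out.setdefault(str(row[level]), []).append(str(row["sample"]))
        return out

    def require_samples(self, gm: GenotypeMatrix) -> None:
        """Error (listing offenders) unless every matrix sample is mapped."""
        known = set(self.samples)
        offenders = [s for s in gm.samples if s not in known]
        if offenders:
            raise ValueError(f"samples missing from population map: {offenders}")
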