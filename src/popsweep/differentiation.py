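"""Weir-Cockerham Fst: per-site variance components and windowed/global ratios.

The estimator follows the 1984 variance-components formulation for ``r``
sampled groups: per site, an among-group component ``a`` and within-group
components ``b`` (among individuals) and ``c`` (within individuals) are
built from group sample sizes, allele frequencies and observed
heterozygosities; theta-hat = a / (a + b + c).  Multi-site estimates are
ratios of sums (sum a over sum a+b+c), the standard aggregation, which is
stable in low-diversity windows where per-site ratios explode.  Negative
estimates are reported as computed, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, PopulationMap
from .windows import WindowTrack, assign_window_sums, make_windows


@dataclass
class FstComponents:
    """Per-SNP Weir-Cockerham components for one group comparison."""

    chrom: np.ndarray
    pos: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    usable: np.ndarray
    labels: tuple[str, ...] = ("A", "B")
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def theta_per_site(self) -> np.ndarray:
        denom = self.a + self.b + self.c
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.usable & (denom != 0), self.a / denom, np.nan)

    def theta_overall(self) -> float:
        u = self.usable
        denom = (self.a[u] + self.b[u] + self.c[u]).sum()
        return float(self.a[u].sum() / denom)


def _group_stats(gm: GenotypeMatrix, samples: list[str]):
    gt = gm.gt[gm.sample_indices(samples)]
    called = gt != MISSING
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        p = np.where(n > 0, (gt * called).sum(axis=0) / (2 * n), np.nan)
        h = np.where(n > 0, (gt == 1).sum(axis=0) / n, np.nan)
    return n, p, h


def _wc_components(
    ns: np.ndarray, ps: np.ndarray, hs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) a, b, c for r groups; inputs are (r, L) arrays."""
    r = ns.shape[0]
    nsum = ns.sum(axis=0)
    nbar = nsum / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (nsum - (ns**2).sum(axis=0) / nsum) / (r - 1)
        pbar = (ns * ps).sum(axis=0) / nsum
        s2 = (ns * (ps - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (ns * hs).sum(axis=0) / nsum
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    return a, b, c


def fst_site_components(
    gm: GenotypeMatrix, popA: list[str], popB: list[str]
) -> FstComponents:
    """Per-SNP two-group Weir-Cockerham components.

    Sites with fewer than 2 non-missing genotypes in either group, or
    monomorphic across both groups, are flagged unusable rather than
    contributing degenerate components.
    """
    overlap = set(popA) & set(popB)
    if overlap:
        raise ValueError(f"sample subsets overlap: {sorted(overlap)}")
    nA, pA, hA = _group_stats(gm, popA)
    nB, pB, hB = _group_stats(gm, popB)
    ns = np.stack([nA, nB])
    ps = np.stack([pA, pB])
    hs = np.stack([hA, hB])
    a, b, c = _wc_components(ns, ps, hs)
    with np.errstate(invalid="ignore"):
        pooled = (ns * ps).sum(axis=0) / ns.sum(axis=0)
    usable = (
        (nA >= 2)
        & (nB >= 2)
        & np.isfinite(a)
        & np.isfinite(b)
        & np.isfinite(c)
        & (pooled > 0)
        & (pooled < 1)
    )
    return FstComponents(
        chrom=gm.chrom,
        pos=gm.pos,
        a=a,
        b=b,
        c=c,
        usable=usable,
        labels=("A", "B"),
        chrom_lengths={c_: gm.chrom_length(c_) for c_ in dict.fromkeys(gm.chrom.tolist())},
    )


def fst_windowed(
    components: FstComponents,
    window: int = 100_000,
    step: int = 10_000,
    min_snps: int = 10,
) -> WindowTrack:
    """Windowed Fst as the ratio of summed components within each window."""
    if not (window >= step > 0):
        raise ValueError("require window >= step > 0")
    u = components.usable
    grid = make_windows(components.chrom_lengths, window, step)
    a = np.where(u, components.a, np.nan)
    denom = np.where(u, components.a + components.b + components.c, np.nan)
    # count only usable SNPs per window
    sums = assign_window_sums(
        components.chrom[u],
        components.pos[u],
        {"a": a[u], "denom": denom[u]},
        grid,
    )
    g_chrom, g_start, g_end, g_partial = grid
    n_snps = sums["n_sites"].astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        value = np.where(
            (n_snps >= min_snps) & (sums["denom"] != 0),
            sums["a"] / sums["denom"],
            np.nan,
        )
    return WindowTrack(
        chrom=g_chrom,
        start=g_start,
        end=g_end,
        n_snps=n_snps,
        value=value,
        partial=g_partial,
        metadata={
            "statistic": "fst",
            "labels": components.labels,
            "window": window,
            "step": step,
            "min_snps": min_snps,
        },
    )


def pairwise_fst(
    gm: GenotypeMatrix, pmap: PopulationMap, level: str = "population"
) -> pd.DataFrame:
    """Genome-wide ratio-of-sums Fst between every pair of groups.

    ``level`` selects subpopulations or regions as the grouping unit.
    Returns a symmetric labeled matrix with zero diagonal.
    """
    groups = pmap.groups(level)
    groups = {g: [s for s in ss if s in gm.samples] for g, ss in groups.items()}
    if len(groups) < 2:
        raise ValueError(f"need at least 2 groups at level {level!r}")
    for g, ss in groups.items():
        if len(ss) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    labels = list(groups)
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, gi in enumerate(labels):
        for gj in labels[i + 1 :]:
            comp = fst_site_components(gm, groups[gi], groups[gj])
            comp.labels = (gi, gj)
            theta = comp.theta_overall()
            mat.loc[gi, gj] = theta
            mat.loc[gj, gi] = theta
    return mat
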