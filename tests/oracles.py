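"""Independent brute-force oracles used to pin expected values.

Deliberately naive implementations, written separately from the package
code paths they check: exact-fraction Hardy-Weinberg enumeration, mean
pairwise haplotype differences for pi, a scalar transcription of the 1984
Weir-Cockerham variance components, the Hudson two-population Fst, a
sorting-based quantile, and a cumulative-scan Nxx.
"""

from __future__ import annotations

from fractions import Fraction
from math import factorial

import numpy as np


def hwe_exact_enumeration(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact-rational enumeration over heterozygote counts given allele counts."""
    n = n_hom_ref + n_het + n_hom_alt
    n_a = 2 * n_hom_ref + n_het
    n_b = 2 * n - n_a
    if n_a == 0 or n_b == 0:
        return 1.0

    def prob(het: int) -> Fraction:
        hom_a = (n_a - het) // 2
        hom_b = n - hom_a - het
        if hom_a < 0 or hom_b < 0 or (n_a - het) % 2:
            return Fraction(0)
        return Fraction(
            factorial(n) * 2**het * factorial(n_a) * factorial(n_b),
            factorial(hom_a) * factorial(het) * factorial(hom_b) * factorial(2 * n),
        )

    rare = min(n_a, n_b)
    hets = range(rare % 2, rare + 1, 2)
    p_obs = prob(n_het)
    total = sum(prob(h) for h in hets)
    tail = sum(prob(h) for h in hets if prob(h) <= p_obs)
    return float(tail / total)


def pi_mean_pairwise(haplotypes: np.ndarray, span: int) -> float:
    """Mean per-site difference over all haplotype pairs, divided by span.

    ``haplotypes``: (n_haplotypes, n_sites) 0/1 array of one window.
    """
    h = np.asarray(haplotypes)
    n = h.shape[0]
    total = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int(np.sum(h[i] != h[j]))
            pairs += 1
    return total / pairs / span


def wc_theta_scalar(counts_a, counts_b) -> tuple[float, float, float]:
    """Two-group Weir-Cockerham components at one site, scalar transcription.

    ``counts_x``: (n_hom_ref, n_het, n_hom_alt) genotype counts per group.
    Returns (a, b, c).
    """
    groups = []
    for c0, c1, c2 in (counts_a, counts_b):
        n = c0 + c1 + c2
        p = (2 * c2 + c1) / (2 * n)  # alt frequency
        h = c1 / n
        groups.append((n, p, h))
    r = 2
    n1, p1, h1 = groups[0]
    n2, p2, h2 = groups[1]
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def hudson_fst(p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray) -> float:
    """Hudson-estimator Fst, ratio of sums over sites, from sample frequencies."""
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    n1, n2 = np.asarray(n1, float), np.asarray(n2, float)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum() / den.sum())


def quantile_sorted(values, q: float) -> float:
    """Linear-interpolation empirical quantile via an explicit sort."""
    v = sorted(float(x) for x in values)
    if not v:
        raise ValueError("empty")
    h = (len(v) - 1) * q
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def nxx_cumulative_scan(lengths, x: float, total=None) -> int:
    """First-reach Nxx by explicit cumulative scan of descending lengths."""
    total = sum(lengths) if total is None else total
    cum = 0
    for length in sorted(lengths, reverse=True):
        cum += length
        if cum >= x / 100 * total:
            return length
    raise ValueError("x% of total not reachable")


def ld_r2_hand_tally(hap_i: np.ndarray, hap_j: np.ndarray) -> float:
    """Haplotype r^2 from explicit 2x2 haplotype counts."""
    hap_i = np.asarray(hap_i).ravel()
    hap_j = np.asarray(hap_j).ravel()
    n = hap_i.size
    n11 = int(np.sum((hap_i == 1) & (hap_j == 1)))
    pi = hap_i.mean()
    pj = hap_j.mean()
    d = n11 / n - pi * pj
    return d * d / (pi * (1 - pi) * pj * (1 - pj))
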