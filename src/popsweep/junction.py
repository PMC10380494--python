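"""Linkage-disequilibrium validation of an assembly contig junction.

A chromosome assembled from two contigs has two possible connection modes
at the join: the contig as placed ("current") or reversed ("alternative").
If the assembly is correct, SNP pairs physically close across the junction
show the higher LD; reversing the second contig moves its far end next to
the junction and the cross-junction LD collapses toward background.  The
validator scores both modes by mean r^2 over cross-junction SNP pairs
within a distance cap and keeps the better-supported mode.

r^2 is the genotype-composite measure (squared Pearson correlation of
dosage codes) by default, or the classical D^2/(p q p q) haplotype measure
when phase is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class JunctionScenario:
    """A two-contig join: breakpoint, flank and the two candidate modes.

    The first contig ("A side") covers positions <= ``breakpoint``; the
    second ("B side") covers (breakpoint, b_end].  Mode "current" keeps
    B-side coordinates; mode "alternative" reverses the B-side contig so
    position p maps to breakpoint + (b_end - p) + 1.
    """

    chrom: str
    breakpoint: int
    flank: int = 500_000
    b_end: int | None = None

    modes = ("current", "alternative")

    def resolve_b_end(self, gm: GenotypeMatrix) -> int:
        return int(self.b_end if self.b_end is not None else gm.chrom_length(self.chrom))

    def remap_positions(self, gm: GenotypeMatrix, mode: str) -> np.ndarray:
        """Variant positions on ``chrom`` under the given connection mode."""
        if mode not in self.modes:
            raise ValueError(f"unknown mode {mode!r}")
        sel = gm.chrom == self.chrom
        pos = gm.pos[sel].astype(np.int64)
        if mode == "alternative":
            b_end = self.resolve_b_end(gm)
            b_side = pos > self.breakpoint
            pos = pos.copy()
            pos[b_side] = self.breakpoint + (b_end - pos[b_side]) + 1
        return pos


@dataclass
class JunctionDecision:
    scores: dict[str, float]
    pair_counts: dict[str, int]
    chosen: str  # "current" | "alternative" | "undecided"
    score_ratio: float


def _usable_biallelic(gm: GenotypeMatrix, i: int) -> None:
    col = gm.gt[:, i]
    called = col != MISSING
    if called.sum() < 2:
        raise ValueError(f"site {i} has fewer than 2 called genotypes")
    vals = np.unique(col[called])
    if vals.size == 1 and vals[0] in (0, 2):
        raise ValueError(f"site {i} is monomorphic; r^2 undefined")


def ld_r2(gm: GenotypeMatrix, site_i: int, site_j: int, method: str = "auto") -> float:
    """Pairwise LD between two sites as r^2 in [0, 1].

    ``method="haplotype"`` uses phased haplotype frequencies,
    D^2 / (p_i q_i p_j q_j); ``"genotype"`` the squared Pearson correlation
    of dosage codes (composite LD); ``"auto"`` picks haplotype when phase
    is available.
    """
    if method == "auto":
        method = "haplotype" if gm.is_phased else "genotype"
    if method not in ("haplotype", "genotype"):
        raise ValueError(f"unknown LD method {method!r}")
    _usable_biallelic(gm, site_i)
    _usable_biallelic(gm, site_j)
    gi, gj = gm.gt[:, site_i], gm.gt[:, site_j]
    both = (gi != MISSING) & (gj != MISSING)
    if both.sum() < 2:
        raise ValueError("fewer than 2 samples called at both sites")
    if method == "haplotype":
        if not gm.is_phased:
            raise ValueError("haplotype method requires phased genotypes")
        hi = gm.haplotypes[both, site_i, :].ravel().astype(float)
        hj = gm.haplotypes[both, site_j, :].ravel().astype(float)
        pi, pj = hi.mean(), hj.mean()
        if pi in (0.0, 1.0) or pj in (0.0, 1.0):
            raise ValueError("monomorphic site in the paired subset; r^2 undefined")
        d = (hi * hj).mean() - pi * pj
        return float(d * d / (pi * (1 - pi) * pj * (1 - pj)))
    x, y = gi[both].astype(float), gj[both].astype(float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("monomorphic site in the paired subset; r^2 undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(min(r * r, 1.0))


def _r2_matrix(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    """Composite r^2 between every column of ``ga`` and of ``gb``.

    Assumes no missing genotypes (the simulator's output); monomorphic
    columns yield NaN and are excluded from averaging upstream.
    """
    ga = ga.astype(float)
    gb = gb.astype(float)
    ga = ga - ga.mean(axis=0)
    gb = gb - gb.mean(axis=0)
    sa = np.sqrt((ga**2).sum(axis=0))
    sb = np.sqrt((gb**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ga.T @ gb) / np.outer(sa, sb)
    return np.minimum(r * r, 1.0)


def _hap_r2_matrix(ha: np.ndarray, hb: np.ndarray) -> np.ndarray:
    """Haplotype-frequency r^2 between columns of two phased allele blocks.

    ``ha``/``hb`` are (2N, sites) haplotype matrices over the same samples.
    """
    ha = ha.astype(float)
    hb = hb.astype(float)
    pa = ha.mean(axis=0)
    pb = hb.mean(axis=0)
    p_ab = (ha.T @ hb) / ha.shape[0]
    d = p_ab - np.outer(pa, pb)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = d * d / np.outer(pa * (1 - pa), pb * (1 - pb))
    return r2


def junction_ld_score(
    gm: GenotypeMatrix,
    scenario: JunctionScenario,
    mode: str,
    max_pair_distance: int | None = None,
    method: str = "auto",
) -> tuple[float, int]:
    """Mean cross-junction r^2 under one connection mode.

    Pairs one SNP from the A-side flank with one from the B-side flank
    (positions under the mode's remapping), keeps pairs separated by at
    most ``max_pair_distance`` bp (default: the flank length), and averages
    their r^2.  Monomorphic sites are excluded.
    """
    if method == "auto":
        method = "haplotype" if gm.is_phased else "genotype"
    if max_pair_distance is None:
        max_pair_distance = scenario.flank
    sel = np.flatnonzero(gm.chrom == scenario.chrom)
    if sel.size == 0:
        raise ValueError(f"no variants on {scenario.chrom!r}")
    pos = scenario.remap_positions(gm, mode)
    bp, fl = scenario.breakpoint, scenario.flank
    a_idx = sel[(pos > bp - fl) & (pos <= bp)]
    b_idx = sel[(pos > bp) & (pos <= bp + fl)]
    b_pos = pos[(pos > bp) & (pos <= bp + fl)]
    a_pos = pos[(pos > bp - fl) & (pos <= bp)]
    if a_idx.size == 0 or b_idx.size == 0:
        raise ValueError("no SNPs in one of the junction flanks")
    has_missing = (gm.gt[:, np.concatenate([a_idx, b_idx])] == MISSING).any()
    if method == "haplotype" and gm.is_phased and not has_missing:
        hap = gm.haplotypes
        ha = hap[:, a_idx, :].transpose(0, 2, 1).reshape(-1, a_idx.size)
        hb = hap[:, b_idx, :].transpose(0, 2, 1).reshape(-1, b_idx.size)
        r2 = _hap_r2_matrix(ha, hb)
    elif not has_missing:
        r2 = _r2_matrix(gm.gt[:, a_idx], gm.gt[:, b_idx])
    else:  # per-pair fallback honouring pairwise-complete samples
        r2 = np.full((a_idx.size, b_idx.size), np.nan)
        for ii, i in enumerate(a_idx):
            for jj, j in enumerate(b_idx):
                try:
                    r2[ii, jj] = ld_r2(gm, int(i), int(j), method=method)
                except ValueError:
                    pass
    dist = np.abs(b_pos[None, :] - a_pos[:, None])
    ok = (dist <= max_pair_distance) & np.isfinite(r2)
    n_pairs = int(ok.sum())
    if n_pairs == 0:
        raise ValueError("no usable cross-junction SNP pairs")
    return float(r2[ok].mean()), n_pairs


def validate_junction(
    gm: GenotypeMatrix,
    scenario: JunctionScenario,
    max_pair_distance: int | None = None,
    method: str = "auto",
    tol: float = 1e-6,
) -> JunctionDecision:
    """Score both connection modes and keep the better-supported one.

    Modes whose mean LD differ by a relative margin below ``tol`` give an
    "undecided" call.
    """
    scores: dict[str, float] = {}
    counts: dict[str, int] = {}
    for mode in scenario.modes:
        s, n = junction_ld_score(gm, scenario, mode, max_pair_distance, method)
        scores[mode] = s
        counts[mode] = n
    s_cur, s_alt = scores["current"], scores["alternative"]
    denom = max(abs(s_cur), abs(s_alt), 1e-300)
    if abs(s_cur - s_alt) / denom < tol:
        chosen = "undecided"
    else:
        chosen = "current" if s_cur > s_alt else "alternative"
    ratio = s_cur / s_alt if s_alt != 0 else float("inf")
    return JunctionDecision(
        scores=scores, pair_counts=counts, chosen=chosen, score_ratio=float(ratio)
    )
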