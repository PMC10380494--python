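"""Joint Fst / pi-ratio selective-sweep scan.

Candidate windows are the intersection of the upper tail of windowed Fst
(value >= the empirical (1-q) quantile) with the tails of the windowed
log2 pi-ratio between the two groups (strictly beyond the q/2 and 1-q/2
quantiles by default, one tail per group).  The group with the *lower*
diversity in a flagged window is called the selected one: a high ratio
log2(piA/piB) marks selection in B, a low ratio selection in A.

Quantiles are linear-interpolation order statistics of the usable
(full-size, defined-value) windows; the >= / strict-> asymmetry makes tie
behavior reproducible: a constant track flags every window by Fst but
none by ratio, so the intersection is empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .windows import WindowTrack


def pi_ratio_track(
    piA: WindowTrack, piB: WindowTrack, pseudocount: float = 1e-8
) -> WindowTrack:
    """Windowed log2((piA + eps) / (piB + eps)); NaN where either is undefined.

    ``pseudocount`` is a per-site diversity floor guarding against zero-pi
    windows; it is negligible against typical per-site pi (~1e-3).
    """
    if not piA.same_grid(piB):
        raise ValueError("pi tracks are on different window grids")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    with np.errstate(invalid="ignore"):
        value = np.log2((piA.value + pseudocount) / (piB.value + pseudocount))
    return WindowTrack(
        chrom=piA.chrom,
        start=piA.start,
        end=piA.end,
        n_snps=np.minimum(piA.n_snps, piB.n_snps),
        value=value,
        partial=piA.partial | piB.partial,
        metadata={
            "statistic": "log2_pi_ratio",
            "population_a": piA.metadata.get("population", "A"),
            "population_b": piB.metadata.get("population", "B"),
            "pseudocount": pseudocount,
            "window": piA.metadata.get("window"),
            "step": piA.metadata.get("step"),
        },
    )


@dataclass
class SweepResult:
    """Thresholds and candidate windows of a joint Fst / pi-ratio scan."""

    fst_threshold: float
    ratio_low: float
    ratio_high: float
    q: float
    tails: str
    pop_a: str
    pop_b: str
    candidates: pd.DataFrame  # chrom, start, end, fst, ratio, selected_in
    n_usable: int
    metadata: dict = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        c = self.candidates["selected_in"].value_counts().to_dict()
        return {self.pop_a: c.get(self.pop_a, 0), self.pop_b: c.get(self.pop_b, 0)}

    def summary(self) -> dict:
        return {
            "fst_threshold": self.fst_threshold,
            "ratio_low": self.ratio_low,
            "ratio_high": self.ratio_high,
            "q": self.q,
            "tails": self.tails,
            "pop_a": self.pop_a,
            "pop_b": self.pop_b,
            "n_usable_windows": self.n_usable,
            "n_candidates": int(len(self.candidates)),
            "counts": self.counts,
        }


def sweep_scan(
    fst: WindowTrack, ratio: WindowTrack, q: float = 0.05, tails: str = "split"
) -> SweepResult:
    """Intersect top-q Fst windows with the pi-ratio tails.

    ``tails="split"`` puts q/2 in each ratio tail (one per group, matching
    the two shaded diversity tails of a joint scan figure);
    ``tails="full"`` puts q in each tail.
    """
    if not fst.same_grid(ratio):
        raise ValueError("fst and ratio tracks are on different window grids")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if tails not in ("split", "full"):
        raise ValueError("tails must be 'split' or 'full'")
    use = fst.usable & ratio.usable
    n_usable = int(use.sum())
    if n_usable < 20:
        raise ValueError(f"only {n_usable} usable windows; need at least 20")
    fst_vals = fst.value[use]
    ratio_vals = ratio.value[use]
    tail_q = q / 2 if tails == "split" else q
    fst_thr = float(np.quantile(fst_vals, 1 - q, method="linear"))
    lo = float(np.quantile(ratio_vals, tail_q, method="linear"))
    hi = float(np.quantile(ratio_vals, 1 - tail_q, method="linear"))
    pop_a = str(ratio.metadata.get("population_a", "A"))
    pop_b = str(ratio.metadata.get("population_b", "B"))
    flag = use & (fst.value >= fst_thr) & ((ratio.value > hi) | (ratio.value < lo))
    idx = np.flatnonzero(flag)
    selected_in = np.where(ratio.value[idx] > hi, pop_b, pop_a)
    candidates = pd.DataFrame(
        {
            "chrom": fst.chrom[idx],
            "start": fst.start[idx],
            "end": fst.end[idx],
            "fst": fst.value[idx],
            "ratio": ratio.value[idx],
            "selected_in": selected_in,
        }
    )
    return SweepResult(
        fst_threshold=fst_thr,
        ratio_low=lo,
        ratio_high=hi,
        q=q,
        tails=tails,
        pop_a=pop_a,
        pop_b=pop_b,
        candidates=candidates,
        n_usable=n_usable,
        metadata={"window": fst.metadata.get("window"), "step": fst.metadata.get("step")},
    )


def count_selected(result: SweepResult, direction: str) -> int:
    """Number of candidate windows whose selected group is ``direction``."""
    if direction not in (result.pop_a, result.pop_b):
        raise KeyError(
            f"unknown direction {direction!r}; expected "
            f"{result.pop_a!r} or {result.pop_b!r}"
        )
    return result.counts[direction]
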