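"""Sliding-window track container.

Windows use 0-based half-open coordinates (BED convention); variant
positions remain 1-based internally, so a variant at position ``p`` falls
in windows with ``start <= p - 1 < end``.  Terminal windows shorter than
the nominal window size are emitted but flagged partial, and downstream
quantile computations exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class WindowTrack:
    """Per-window statistic values on a fixed chrom/start/step grid."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    n_snps: np.ndarray
    value: np.ndarray  # NaN where below min_snps ("MISSING")
    partial: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.n_snps = np.asarray(self.n_snps, dtype=np.int64)
        self.value = np.asarray(self.value, dtype=float)
        self.partial = np.asarray(self.partial, dtype=bool)
        n = self.start.size
        for name in ("chrom", "end", "n_snps", "value", "partial"):
            if getattr(self, name).size != n:
                raise ValueError(f"window track field {name} has wrong length")
        if np.any(self.end <= self.start):
            raise ValueError("windows must satisfy end > start")

    def __len__(self) -> int:
        return int(self.start.size)

    @property
    def usable(self) -> np.ndarray:
        """Full-size windows with a defined value."""
        return np.isfinite(self.value) & ~self.partial

    def same_grid(self, other: "WindowTrack") -> bool:
        return (
            len(self) == len(other)
            and bool(np.all(self.chrom == other.chrom))
            and bool(np.all(self.start == other.start))
            and bool(np.all(self.end == other.end))
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "n_snps": self.n_snps,
                "value": self.value,
                "partial": self.partial,
            }
        )

    def to_bed(self, path) -> None:
        """Write as BED4+ TSV; undefined values as 'NA'."""
        df = self.to_frame()
        df["value"] = [
            "NA" if not np.isfinite(v) else format(v, ".6g") for v in df["value"]
        ]
        df.to_csv(path, sep="\t", index=False, header=True)


def make_windows(
    chrom_lengths: dict[str, int], window: int, step: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Tile each chromosome with [start, start+window) windows every ``step`` bp.

    Returns (chrom, start, end, partial) arrays; the terminal windows that
    would extend past the chromosome end are clipped and flagged partial.
    """
    if not (window >= step > 0):
        raise ValueError("require window >= step > 0")
    chroms, starts, ends, partials = [], [], [], []
    for chrom, length in chrom_lengths.items():
        length = int(length)
        start = 0
        while start < length:
            end = min(start + window, length)
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
            partials.append(end - start < window)
            start += step
    return (
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        np.array(partials, dtype=bool),
    )


def assign_window_sums(
    chrom: np.ndarray,
    pos: np.ndarray,
    per_site: dict[str, np.ndarray],
    grid: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
) -> dict[str, np.ndarray]:
    """Sum per-site quantities into each grid window (overlapping windows count
    a site once each).  Returns per-window sums plus an ``n_sites`` count."""
    g_chrom, g_start, g_end, _ = grid
    out = {k: np.zeros(g_start.size) for k in per_site}
    out["n_sites"] = np.zeros(g_start.size)
    pos0 = pos - 1  # 0-based site coordinate
    for c in dict.fromkeys(g_chrom.tolist()):
        wsel = np.flatnonzero(g_chrom == c)
        ssel = np.flatnonzero(chrom == c)
        if ssel.size == 0:
            continue
        p = pos0[ssel]  # sorted within chrom by container invariant
        lo = np.searchsorted(p, g_start[wsel], side="left")
        hi = np.searchsorted(p, g_end[wsel], side="left")
        out["n_sites"][wsel] = hi - lo
        for k, v in per_site.items():
            cs = np.concatenate([[0.0], np.nancumsum(v[ssel])])
            out[k][wsel] = cs[hi] - cs[lo]
    return out
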