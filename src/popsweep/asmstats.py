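"""Assembly and annotation summary arithmetic.

Small, exact utilities over length lists and count tables: Nxx contiguity
statistics ("first-reach" convention: sort descending, report the length
at which the cumulative sum first reaches x% of the total), the
chromosome anchoring ratio, the BUSCO completeness percentage, and
labeled composition percentages (repeat classes, annotation databases).
Rounding follows the usual reporting style: one decimal for anchoring and
BUSCO, two for compositions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path


@dataclass
class LengthSet:
    """Named sequence lengths (e.g. contigs, scaffolds or chromosomes)."""

    names: list[str]
    lengths: list[int]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if any(length <= 0 for length in self.lengths):
            raise ValueError("sequence lengths must be positive")

    @classmethod
    def from_fai(cls, path: str | Path) -> "LengthSet":
        """Read names and lengths from a samtools .fai index (first two columns)."""
        names, lengths = [], []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            fields = line.split("\t")
            names.append(fields[0])
            lengths.append(int(fields[1]))
        return cls(names, lengths)

    @property
    def total(self) -> int:
        return sum(self.lengths)


def nxx(lengths: LengthSet, x: float, total_override: int | None = None) -> int:
    """Nxx statistic: smallest length whose descending cumulative sum covers x%.

    ``total_override`` computes the statistic against an externally known
    assembly total (e.g. scaffold N50 of a full assembly from its
    chromosome-scale subset).
    """
    if not lengths.lengths:
        raise ValueError("empty length set")
    if not 0 < x < 100:
        raise ValueError("x must be in (0, 100)")
    total = total_override if total_override is not None else lengths.total
    target = x / 100 * total
    if target > sum(lengths.lengths):
        raise ValueError(
            f"{x}% of total ({target:.0f} bp) exceeds the summed lengths "
            f"({sum(lengths.lengths)} bp)"
        )
    cum = 0
    for length in sorted(lengths.lengths, reverse=True):
        cum += length
        if cum >= target:
            return length
    raise AssertionError("unreachable")


def anchoring_ratio(chrom_lengths: LengthSet, assembly_total: int) -> float:
    """Percent of the assembly placed into chromosome-scale sequences (1 dp)."""
    if assembly_total <= 0:
        raise ValueError("assembly total must be positive")
    placed = chrom_lengths.total
    if placed > assembly_total:
        raise ValueError(
            f"chromosome lengths ({placed}) exceed assembly total ({assembly_total})"
        )
    return round(100 * placed / assembly_total, 1)


def busco_summary(counts: dict[str, int]) -> float:
    """BUSCO completeness: 100 * complete / total, one decimal.

    ``counts`` uses the BUSCO letters: ``C`` (complete; or ``S`` + ``D``),
    and ``total``.  If ``S``, ``D`` and ``C`` are all given but disagree, a
    warning is raised and ``C`` is used.
    """
    total = counts.get("total", 0)
    if total <= 0:
        raise ValueError("total BUSCO group count must be positive")
    if "C" in counts:
        complete = counts["C"]
        if "S" in counts and "D" in counts and counts["S"] + counts["D"] != complete:
            warnings.warn(
                f"S + D = {counts['S'] + counts['D']} disagrees with C = {complete};"
                " using C",
                stacklevel=2,
            )
    elif "S" in counts and "D" in counts:
        complete = counts["S"] + counts["D"]
    else:
        raise ValueError("need either C or both S and D counts")
    if complete < 0 or complete > total:
        raise ValueError("complete count outside [0, total]")
    return round(100 * complete / total, 1)


def composition_percentages(
    parts: dict[str, float | dict[str, float]], denominator: float
) -> dict[str, float]:
    """Percent of ``denominator`` per labeled part, two decimals.

    A part given as a sub-dictionary is summed first (subtotal lines such
    as an LTR class built from its families), and the subtotal percentage
    is reported under the outer label.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    out: dict[str, float] = {}
    for label, value in parts.items():
        total = sum(value.values()) if isinstance(value, dict) else value
        if total < 0:
            raise ValueError(f"negative part {label!r}")
        out[label] = round(100 * total / denominator, 2)
    return out
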