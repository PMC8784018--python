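"""Sørensen–Dice agreement between predicted and known inversion intervals.

    DSC = 2 |P ∩ T| / (|P| + |T|)

Interval endpoints are first rounded to the nearest 0.1 Mb; lengths are
then continuous (not 0.1 Mb unit counts). Percentages are reported with
one decimal, rounding half up.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence, Tuple

from .errors import InputError


@dataclass(frozen=True)
class GenomicInterval:
    """An inversion interval in Mb coordinates."""

    chrom: str
    start_mb: float
    end_mb: float

    def __post_init__(self) -> None:
        if self.start_mb > self.end_mb:
            raise InputError(
                f"interval start {self.start_mb} exceeds end {self.end_mb} on {self.chrom}"
            )
        if self.start_mb < 0:
            raise InputError(f"negative coordinate {self.start_mb} on {self.chrom}")

    @classmethod
    def from_bp(cls, chrom: str, start_bp: float, end_bp: float) -> "GenomicInterval":
        return cls(chrom, start_bp / 1e6, end_bp / 1e6)


def _round_tenth(x: float) -> float:
    """Round to the nearest 0.1 Mb (half away from zero)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def dice_overlap(P: GenomicInterval, T: GenomicInterval) -> float:
    """Sørensen–Dice coefficient of two intervals after 0.1 Mb endpoint rounding."""
    if P.chrom != T.chrom:
        raise InputError(f"chromosome mismatch: {P.chrom!r} vs {T.chrom!r}")
    s1, e1 = _round_tenth(P.start_mb), _round_tenth(P.end_mb)
    s2, e2 = _round_tenth(T.start_mb), _round_tenth(T.end_mb)
    inter = max(0.0, min(e1, e2) - max(s1, s2))
    total = (e1 - s1) + (e2 - s2)
    if total == 0.0:
        return 1.0 if (s1, e1) == (s2, e2) else 0.0
    return 2.0 * inter / total


def average_overlap(pairs: Iterable[Tuple[GenomicInterval, GenomicInterval]]) -> float:
    """Arithmetic mean DSC over (predicted, known) interval pairs."""
    values = [dice_overlap(P, T) for P, T in pairs]
    if not values:
        raise InputError("no interval pairs supplied")
    return sum(values) / len(values)


def as_percent(dsc: float) -> float:
    """DSC as a percentage with one decimal, rounding half up (0.887 -> 88.7)."""
    return float(Decimal(repr(dsc * 100.0)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def union_interval(intervals: Sequence[GenomicInterval]) -> GenomicInterval:
    """Merge intervals on one chromosome into their spanning interval.

    Convenience for comparing against callers that report an inversion's
    two breakpoint regions separately.
    """
    if not intervals:
        raise InputError("no intervals supplied")
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise InputError(f"intervals span multiple chromosomes: {sorted(chroms)}")
    return GenomicInterval(
        intervals[0].chrom,
        min(iv.start_mb for iv in intervals),
        max(iv.end_mb for iv in intervals),
    )
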