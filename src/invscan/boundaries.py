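"""Automated inversion localization from the per-SNP association scan.

The algorithm looks for the change points between the inversion-linked
block of significant SNPs and the background:

1. Each SNP is flagged significant if its scan p-value is below the
   Bonferroni-corrected threshold ``snp_alpha / num_snps`` (strict ``<``).
2. The chromosome is tiled from coordinate 0 with non-overlapping windows
   (default 10 kb). Each window's significant-SNP fraction is tested with
   a one-sided exact binomial tail P[X >= n_significant], where X ~
   Binomial(n_snps, p0) and p0 is the chromosome-wide fraction of
   significant SNPs. Windows with no SNPs, or no significant SNPs, get
   p = 1.0.
3. A window is significant if its p-value is below ``window_alpha /
   num_windows`` (strict ``<``), where num_windows counts every tiled
   window — empty windows carry p = 1.0 and are members of the tested
   family. The inversion ends are the centers of the left-most and
   right-most significant windows; no significant window means no call.

One call per chromosome per scan: a single contiguous inversion is assumed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.stats import binom

from .assoc import AssociationRecord
from .errors import InputError, ParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BoundaryConfig:
    """Family error levels and window width for boundary calling."""

    snp_alpha: float = 0.01
    window_alpha: float = 0.0001
    window_size: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 < self.snp_alpha < 1.0 or not 0.0 < self.window_alpha < 1.0:
            raise ParameterError("snp_alpha and window_alpha must lie in (0, 1)")
        if self.window_size < 1:
            raise ParameterError(f"window_size must be >= 1, got {self.window_size}")


@dataclass(frozen=True)
class WindowResult:
    """Binomial enrichment result for one half-open window [start, end)."""

    index: int
    start: int
    end: int
    n_snps: int
    n_significant: int
    pvalue: float
    significant: bool = False


@dataclass(frozen=True)
class InversionCall:
    """Predicted inversion interval; endpoints are significant-window centers."""

    chrom: str
    start_bp: float
    end_bp: float
    n_significant_windows: int


def flag_significant_snps(
    records: Sequence[AssociationRecord], snp_alpha: float = 0.01
) -> np.ndarray:
    """Bonferroni flags: p < snp_alpha / num_snps (strict)."""
    if not records:
        raise InputError("no association records")
    if not 0.0 < snp_alpha < 1.0:
        raise ParameterError(f"snp_alpha must lie in (0, 1), got {snp_alpha}")
    threshold = snp_alpha / len(records)
    return np.array([r.pvalue < threshold for r in records], dtype=bool)


def test_windows(
    positions: Sequence[int],
    flags: Sequence[bool],
    config: BoundaryConfig = BoundaryConfig(),
    chrom_extent: Optional[int] = None,
) -> List[WindowResult]:
    """Exact binomial enrichment test of significant SNPs in tiled windows."""
    positions = np.asarray(positions, dtype=np.int64)
    flags = np.asarray(flags, dtype=bool)
    if positions.shape != flags.shape:
        raise InputError("positions and flags must align")
    if positions.size == 0:
        raise InputError("no SNP positions supplied")
    if np.any(np.diff(positions) < 0):
        raise InputError("positions must be sorted ascending")
    w = config.window_size
    if chrom_extent is None:
        chrom_extent = int(math.ceil(positions.max() / w) * w)
    elif chrom_extent < positions.max():
        raise InputError("chrom_extent is smaller than the largest SNP position")
    num_windows = int(math.ceil(chrom_extent / w))
    idx = positions // w
    n_snps = np.bincount(idx, minlength=num_windows)
    n_sig = np.bincount(idx, weights=flags.astype(float), minlength=num_windows).astype(int)
    p0 = flags.sum() / flags.size
    pvals = np.ones(num_windows)
    if p0 == 0.0:
        logger.warning(
            "no SNP passed the per-SNP Bonferroni threshold; "
            "all window p-values are 1.0"
        )
    else:
        testable = (n_snps > 0) & (n_sig > 0)
        # exact upper tail P[X >= n_sig], X ~ Binomial(n_snps, p0)
        pvals[testable] = binom.sf(n_sig[testable] - 1, n_snps[testable], p0)
    window_threshold = config.window_alpha / num_windows
    return [
        WindowResult(
            i,
            i * w,
            (i + 1) * w,
            int(n_snps[i]),
            int(n_sig[i]),
            float(pvals[i]),
            significant=bool(pvals[i] < window_threshold),
        )
        for i in range(num_windows)
    ]


def call_boundaries(
    window_results: Sequence[WindowResult],
    config: BoundaryConfig = BoundaryConfig(),
    chrom: str = "",
) -> Optional[InversionCall]:
    """Call the inversion interval from the extreme significant windows.

    Returns ``None`` when no window passes the Bonferroni-corrected window
    threshold ("no inversion").
    """
    if not window_results:
        raise InputError("no window results")
    num_windows = len(window_results)
    threshold = config.window_alpha / num_windows
    sig = [wr for wr in window_results if wr.pvalue < threshold]
    if not sig:
        return None
    w = config.window_size
    left, right = sig[0], sig[-1]
    return InversionCall(
        chrom=chrom,
        start_bp=left.start + w / 2.0,
        end_bp=right.start + w / 2.0,
        n_significant_windows=len(sig),
    )


def localize(
    records: Sequence[AssociationRecord],
    config: BoundaryConfig = BoundaryConfig(),
    chrom_extent: Optional[int] = None,
) -> Optional[InversionCall]:
    """Convenience wrapper: flag SNPs, test windows, call boundaries."""
    order = np.argsort([r.pos for r in records], kind="mergesort")
    records = [records[i] for i in order]
    flags = flag_significant_snps(records, config.snp_alpha)
    windows = test_windows([r.pos for r in records], flags, config, chrom_extent)
    chrom = records[0].chrom if records else ""
    return call_boundaries(windows, config, chrom=chrom)
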