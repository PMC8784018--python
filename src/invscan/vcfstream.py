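"""Streaming access to biallelic SNP records in VCF files.

The reader never materializes the whole file: records are parsed (via
cyvcf2/htslib) and handed downstream in fixed-size batches, so peak memory
is bounded by one batch regardless of how many variants the file holds.
Only biallelic SNPs are yielded; multi-allelic records, indels and other
non-SNP variants are skipped and counted.

Genotype calls are collapsed to four classes. Phased ("|") and unphased
("/") separators are treated identically — only the genotype class matters
downstream — and any call with a missing haplotype ("./.", "0/.", ...)
maps to :data:`Genotype.UNKNOWN`.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterator, Optional, Sequence

import numpy as np
from cyvcf2 import VCF

from .errors import InputError, VcfFormatError

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


class Genotype(IntEnum):
    """Diploid genotype class of one sample at one biallelic site."""

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    UNKNOWN = 3


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNP.

    ``genotypes`` holds one :class:`Genotype` code per sample (int8 array,
    file sample order), ``pos`` is the 1-based coordinate.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VcfFormatError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise VcfFormatError(f"ref and alt alleles are identical at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class StreamConfig:
    """Batching parameters for :func:`stream_variants`.

    The default batch size of 10,000 records bounds memory while amortizing
    per-batch overhead; it is a knob, not a tuned constant.
    """

    batch_size: int = 10_000
    allowed_chromosomes: Optional[frozenset] = None

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise InputError(f"batch_size must be >= 1, got {self.batch_size}")


@dataclass
class StreamStats:
    """Bookkeeping for one pass over a VCF: yielded + skipped = data lines."""

    n_yielded: int = 0
    n_skipped: int = 0
    skip_reasons: Counter = field(default_factory=Counter)


def _open(vcf_source: str) -> VCF:
    try:
        return VCF(str(vcf_source), gts012=False)
    except Exception as exc:  # htslib raises bare OSError/Exception
        raise VcfFormatError(f"cannot open VCF {vcf_source!r}: {exc}") from exc


def read_samples(vcf_source: str) -> list:
    """Return the sample identifiers from the ``#CHROM`` header line, in file order.

    The length of this list defines ``n`` for every downstream matrix.
    """
    vcf = _open(vcf_source)
    try:
        samples = list(vcf.samples)
    finally:
        vcf.close()
    if not samples:
        raise InputError(f"VCF {vcf_source!r} has no sample columns")
    return samples


def _classify(variant, n_samples: int, record_index: int) -> np.ndarray:
    """Collapse per-sample allele pairs to Genotype codes (int8, length n)."""
    if "GT" not in variant.FORMAT:
        raise VcfFormatError(
            f"record #{record_index} ({variant.CHROM}:{variant.POS}) has no GT field"
        )
    arr = variant.genotype.array()
    if arr.shape[0] != n_samples:
        raise VcfFormatError(
            f"record #{record_index} has {arr.shape[0]} genotype columns, expected {n_samples}"
        )
    alleles = arr[:, :-1]  # last column is the phasing flag
    missing = (alleles < 0).any(axis=1)
    dosage = np.where(missing, 0, alleles.sum(axis=1))
    codes = np.empty(n_samples, dtype=np.int8)
    codes[dosage == 0] = Genotype.HOM_REF
    codes[dosage == 1] = Genotype.HET
    codes[dosage >= 2] = Genotype.HOM_ALT
    codes[missing] = Genotype.UNKNOWN
    return codes


def _skip_reason(variant) -> Optional[str]:
    alts = variant.ALT
    if len(alts) != 1:
        return "multiallelic" if len(alts) > 1 else "no_alt"
    ref, alt = variant.REF, alts[0]
    if len(ref) != 1 or len(alt) != 1 or ref.upper() not in _BASES or alt.upper() not in _BASES:
        return "not_snp"
    return None


class VariantStream:
    """Iterator over batches of :class:`VariantRecord`, with skip statistics.

    One-pass: iterate once, then consult :attr:`stats`.
    """

    def __init__(self, vcf_source: str, config: StreamConfig = StreamConfig()):
        self.source = str(vcf_source)
        self.config = config
        self.samples = read_samples(vcf_source)
        self.stats = StreamStats()

    def __iter__(self) -> Iterator[list]:
        vcf = _open(self.source)
        n = len(self.samples)
        allowed = self.config.allowed_chromosomes
        batch: list = []
        index = 0
        try:
            for variant in vcf:
                index += 1
                if allowed is not None and variant.CHROM not in allowed:
                    self.stats.n_skipped += 1
                    self.stats.skip_reasons["chromosome"] += 1
                    continue
                reason = _skip_reason(variant)
                if reason is not None:
                    self.stats.n_skipped += 1
                    self.stats.skip_reasons[reason] += 1
                    continue
                codes = _classify(variant, n, index)
                batch.append(
                    VariantRecord(
                        chrom=variant.CHROM,
                        pos=int(variant.POS),
                        ref=variant.REF.upper(),
                        alt=variant.ALT[0].upper(),
                        genotypes=codes,
                    )
                )
                self.stats.n_yielded += 1
                if len(batch) == self.config.batch_size:
                    yield batch
                    batch = []
        except VcfFormatError:
            raise
        except Exception as exc:
            raise VcfFormatError(
                f"malformed VCF data near record #{index} in {self.source!r}: {exc}"
            ) from exc
        finally:
            vcf.close()
        if batch:
            yield batch
        logger.info(
            "streamed %s: %d biallelic SNPs yielded, %d records skipped (%s)",
            self.source,
            self.stats.n_yielded,
            self.stats.n_skipped,
            dict(self.stats.skip_reasons) or "none",
        )


def stream_variants(vcf_source: str, config: StreamConfig = StreamConfig()) -> VariantStream:
    """Open ``vcf_source`` for batched streaming of biallelic SNP records."""
    return VariantStream(vcf_source, config)


def iter_records(stream) -> Iterator[VariantRecord]:
    """Flatten an iterable of batches into individual records."""
    for batch in stream:
        yield from batch
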