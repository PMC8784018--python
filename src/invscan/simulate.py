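"""Synthetic VCFs with a planted polymorphic inversion.

The generator emulates the defining signature of a large polymorphic
inversion — a block of SNPs in complete linkage with the inversion
orientation — without coalescent realism:

* each sample draws an inversion genotype from Hardy–Weinberg proportions
  at the inverted-orientation frequency;
* ``l`` inversion-linked SNPs at uniform-random positions inside the
  inversion interval copy the sample's inversion genotype (ref/alt
  polarity randomized per site, optional per-site/per-sample "leakage"
  redraws emulating imperfect linkage);
* ``m`` background SNPs at uniform-random positions outside the interval
  draw an alt-allele frequency from Uniform(0.05, 0.95) and genotypes
  from Hardy–Weinberg, resampled until the site is variable;
* genotypes are masked to "./." with probability ``missing_rate``.

Linked and background SNPs have equal density when ``l/m`` matches the
ratio of inversion span to remaining chromosome; recombination suppression
makes essentially every SNP inside a real high-frequency inversion
orientation-informative, so no unlinked SNPs are placed inside the
interval. Output is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np

from .errors import InputError

_GT_STRINGS = np.array(["0/0", "0/1", "1/1", "./."])
_BASES = np.array(list("ACGT"))
MISSING = 3


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated chromosome.

    Defaults describe a 10 Mb chromosome carrying a 2 Mb inversion at
    frequency 0.3, genotyped in 100 samples, with 2,000 inversion-linked
    and 8,000 background SNPs (equal SNP density inside and outside the
    inversion, ~1 SNP/kb).
    """

    n_samples: int = 100
    chrom: str = "sim1"
    chrom_length_bp: int = 10_000_000
    inversion_start_bp: int = 2_000_000
    inversion_end_bp: int = 4_000_000
    inversion_freq: float = 0.3
    l: int = 2_000
    m: int = 8_000
    missing_rate: float = 0.0
    leakage: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise InputError("n_samples must be >= 1")
        if self.l + self.m == 0:
            raise InputError("at least one SNP is required (l + m = 0)")
        if self.l < 0 or self.m < 0:
            raise InputError("l and m must be non-negative")
        if not (0 <= self.inversion_start_bp < self.inversion_end_bp <= self.chrom_length_bp):
            raise InputError("inversion interval must lie within the chromosome")
        if not 0.0 < self.inversion_freq < 1.0:
            raise InputError("inversion_freq must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0 or not 0.0 <= self.leakage < 1.0:
            raise InputError("missing_rate and leakage must lie in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated VCF."""

    chrom: str
    inversion_start_bp: int
    inversion_end_bp: int
    inversion_freq: float
    sample_ids: List[str]
    inversion_genotypes: List[int]  # inverted-allele dosage 0/1/2 per sample
    positions: List[int] = field(repr=False, default_factory=list)
    is_linked: List[bool] = field(repr=False, default_factory=list)
    seed: int = 0

    def to_json(self, path: str) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))

    @classmethod
    def from_json(cls, path: str) -> "SimTruth":
        return cls(**json.loads(Path(path).read_text()))


def _distinct_positions(rng: np.random.Generator, size: int, count: int) -> np.ndarray:
    """Draw ``count`` distinct indices in [0, size); collisions are re-drawn."""
    if count > size:
        raise InputError(f"cannot place {count} distinct SNPs in {size} bp")
    chosen = np.unique(rng.integers(0, size, count))
    while chosen.size < count:
        extra = rng.integers(0, size, count - chosen.size)
        chosen = np.unique(np.concatenate([chosen, extra]))
    return chosen


def _hw_dosage(rng: np.random.Generator, freq, shape) -> np.ndarray:
    """Hardy–Weinberg diploid dosage draws at allele frequency ``freq``."""
    return rng.binomial(2, freq, size=shape).astype(np.int8)


def simulate_inversion_vcf(
    config: SimConfig,
    out_vcf: str,
    out_truth: Optional[str] = None,
) -> SimTruth:
    """Write a VCF with a planted inversion; return (and optionally write) truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]

    inv_gt = _hw_dosage(rng, config.inversion_freq, n)

    span = config.inversion_end_bp - config.inversion_start_bp
    linked_pos = config.inversion_start_bp + 1 + _distinct_positions(rng, span, config.l)

    outside = config.chrom_length_bp - span
    raw = 1 + _distinct_positions(rng, outside, config.m)
    bg_pos = np.where(raw <= config.inversion_start_bp, raw, raw + span)

    # linked SNPs copy the inversion genotype, with per-site polarity flips
    linked = np.tile(inv_gt, (config.l, 1))
    flip = rng.random(config.l) < 0.5
    linked[flip] = 2 - linked[flip]
    if config.leakage > 0 and config.l > 0:
        leak = rng.random((config.l, n)) < config.leakage
        linked[leak] = _hw_dosage(rng, config.inversion_freq, int(leak.sum()))

    # background SNPs are unlinked Hardy-Weinberg draws, resampled if fixed
    bg = np.empty((config.m, n), dtype=np.int8)
    if config.m > 0:
        freqs = rng.uniform(0.05, 0.95, config.m)
        bg[:] = _hw_dosage(rng, freqs[:, None], (config.m, n))
        while True:
            mono = (bg == bg[:, :1]).all(axis=1)
            if not mono.any():
                break
            freqs[mono] = rng.uniform(0.05, 0.95, int(mono.sum()))
            bg[mono] = _hw_dosage(rng, freqs[mono][:, None], (int(mono.sum()), n))

    positions = np.concatenate([linked_pos, bg_pos])
    genotypes = np.concatenate([linked, bg], axis=0) if config.m else linked
    is_linked = np.concatenate(
        [np.ones(config.l, dtype=bool), np.zeros(config.m, dtype=bool)]
    )
    order = np.argsort(positions, kind="mergesort")
    positions, genotypes, is_linked = positions[order], genotypes[order], is_linked[order]

    if config.missing_rate > 0:
        mask = rng.random(genotypes.shape) < config.missing_rate
        genotypes = np.where(mask, MISSING, genotypes)

    ref_idx = rng.integers(0, 4, positions.size)
    alt_idx = (ref_idx + rng.integers(1, 4, positions.size)) % 4

    _write_vcf(out_vcf, config, sample_ids, positions, genotypes, ref_idx, alt_idx)

    truth = SimTruth(
        chrom=config.chrom,
        inversion_start_bp=config.inversion_start_bp,
        inversion_end_bp=config.inversion_end_bp,
        inversion_freq=config.inversion_freq,
        sample_ids=sample_ids,
        inversion_genotypes=[int(g) for g in inv_gt],
        positions=[int(p) for p in positions],
        is_linked=[bool(b) for b in is_linked],
        seed=config.seed,
    )
    if out_truth is not None:
        truth.to_json(out_truth)
    return truth


def _write_vcf(path, config, sample_ids, positions, genotypes, ref_idx, alt_idx) -> None:
    gt_col = _GT_STRINGS[genotypes]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={config.chrom},length={config.chrom_length_bp}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        for i, pos in enumerate(positions):
            fh.write(
                f"{config.chrom}\t{pos}\t.\t{_BASES[ref_idx[i]]}\t{_BASES[alt_idx[i]]}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gt_col[i]) + "\n"
            )
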