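"""Streaming single-SNP association scan against a principal component.

For every SNP the selected PC coordinates are split into groups by genotype
class (HOM_REF / HET / HOM_ALT, UNKNOWN samples excluded) and a one-way
ANOVA F-test p-value is computed. The scan consumes the variant stream
batch-by-batch, so memory stays bounded by one batch; within a batch the
group sums are accumulated with matrix products, which is algebraically
identical to the per-SNP textbook F computation (and is cross-checked
against ``scipy.stats.f_oneway`` in the test suite).

Degenerate SNPs — fewer than two non-empty genotype groups, or no residual
degrees of freedom — receive p = 1.0 rather than being dropped, so the SNP
count used for Bonferroni correction downstream equals the number of
scanned SNPs. A SNP with zero within-group variance but distinct group
means is a perfect separation: p = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .decomp import PCScores
from .errors import InputError
from .vcfstream import Genotype

logger = logging.getLogger(__name__)

#: p-values are clamped to this floor before the -log10 transform
PVALUE_FLOOR = 1e-300


@dataclass(frozen=True)
class AssociationRecord:
    """Per-SNP association result (p-value of the PC-genotype ANOVA)."""

    chrom: str
    pos: int
    pvalue: float
    neglog10p: float


def neglog10(pvalue: float) -> float:
    return float(-np.log10(max(pvalue, PVALUE_FLOOR)))


def snp_pc_scan(
    variant_batches: Iterable, scores: PCScores, component_index: int = 0
) -> List[AssociationRecord]:
    """One-way ANOVA of the chosen PC coordinate against each SNP's genotypes."""
    if not 0 <= component_index < scores.c:
        raise InputError(
            f"component_index {component_index} out of range for {scores.c} components"
        )
    y = np.asarray(scores.coords[:, component_index], dtype=np.float64)
    n_samples = y.shape[0]
    records: List[AssociationRecord] = []
    n_degenerate = 0
    for batch in variant_batches:
        codes = np.array([rec.genotypes for rec in batch], dtype=np.int8)
        if codes.shape[1] != n_samples:
            raise InputError(
                f"stream has {codes.shape[1]} samples per record, PC scores have {n_samples}"
            )
        pvals, degen = _batch_anova(codes, y)
        n_degenerate += int(degen.sum())
        for rec, p in zip(batch, pvals):
            records.append(AssociationRecord(rec.chrom, rec.pos, float(p), neglog10(float(p))))
    if n_degenerate:
        logger.warning("%d degenerate SNPs assigned p = 1.0", n_degenerate)
    return records


def _batch_anova(codes: np.ndarray, y: np.ndarray):
    """Vectorized one-way ANOVA over a (batch x samples) genotype-code array.

    Returns (p-values, degenerate flags). Group sums per genotype class are
    accumulated via boolean-mask matrix products; F and its p-value follow
    the usual between/within mean-square ratio with (G-1, N-G) df.
    """
    b = codes.shape[0]
    y2 = y * y
    ng = np.empty((3, b))
    sg = np.empty((3, b))
    qg = np.empty((3, b))
    for g in range(3):
        mask = codes == g
        ng[g] = mask.sum(axis=1)
        sg[g] = mask @ y
        qg[g] = mask @ y2
    N = ng.sum(axis=0)
    G = (ng > 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_sq = np.where(ng > 0, sg**2 / np.where(ng > 0, ng, 1), 0.0)
        ss_between = mean_sq.sum(axis=0) - np.where(N > 0, sg.sum(axis=0) ** 2 / np.where(N > 0, N, 1), 0.0)
        ss_within = qg.sum(axis=0) - mean_sq.sum(axis=0)
    df_between = G - 1.0
    df_within = N - G
    degenerate = (G < 2) | (df_within < 1)
    pvals = np.ones(b)
    ok = ~degenerate
    ssb = np.clip(ss_between[ok], 0.0, None)  # guard tiny negative rounding
    ssw = np.clip(ss_within[ok], 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df_between[ok]) / (ssw / df_within[ok])
    # zero within-group variance: perfect separation (F = inf, p = 0) if the
    # group means differ, no evidence at all (p = 1) if they do not
    F = np.where(ssw > 0, F, np.where(ssb > 1e-12, np.inf, 0.0))
    pvals[ok] = f_dist.sf(F, df_between[ok], df_within[ok])
    return pvals, degenerate


def write_manhattan(
    records: Iterable[AssociationRecord],
    out_path: str,
    plot_path: Optional[str] = None,
) -> pd.DataFrame:
    """Write the Manhattan table (TSV sorted by position), optionally a plot."""
    records = list(records)
    if not records:
        raise InputError("no association records to write")
    df = pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "pvalue": [r.pvalue for r in records],
            "neglog10p": [r.neglog10p for r in records],
        }
    ).sort_values("pos", kind="mergesort", ignore_index=True)
    df.to_csv(out_path, sep="\t", index=False)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(10, 3))
        ax.scatter(df["pos"] / 1e6, df["neglog10p"], s=2, color="tab:blue")
        ax.set_xlabel("position (Mb)")
        ax.set_ylabel(r"$-\log_{10} p$")
        ax.set_title(f"{df['chrom'].iloc[0]} PC-SNP association")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return df


def read_manhattan(path: str) -> List[AssociationRecord]:
    """Read a Manhattan TSV back into association records."""
    df = pd.read_csv(path, sep="\t")
    return [
        AssociationRecord(str(row.chrom), int(row.pos), float(row.pvalue), float(row.neglog10p))
        for row in df.itertuples()
    ]
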