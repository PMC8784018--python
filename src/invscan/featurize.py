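"""Feature-matrix construction from a variant stream.

Two encoders are provided:

* **categorical** — the full ``n x 3v`` one-hot matrix: each site occupies
  three consecutive columns (HOM_REF, HOM_ALT, HET); a called genotype sets
  exactly one of them to 1, an UNKNOWN genotype leaves all three at 0.
  Storage is O(n*v); this is the exact reference encoding.

* **hashed** — the ``n x k`` feature-hashed allele-count matrix. Each site
  allele is named by the string ``"chromosome_position_allele"`` and mapped
  to a column by ``abs(hash(s)) % k`` with a seedable, platform-stable
  32-bit MurmurHash3. Entries accumulate allele copy counts: a homozygote
  adds 2 to its allele's column, a heterozygote adds 1 to each of the two
  allele columns, an UNKNOWN genotype changes nothing. Sign alternation is
  deliberately not applied. Storage is O(n*k), independent of v, and the
  matrix is updated batch-by-batch so the stream is never materialized.

Row sums are conserved: hashed rows sum to twice the sample's number of
called genotypes, categorical rows to the number of called genotypes —
handy invariants for verifying a build.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.utils.murmurhash import murmurhash3_32

from .errors import InputError, ParameterError
from .vcfstream import Genotype, VariantRecord

CATEGORICAL = "categorical"
HASHED = "hashed"

#: column offset of each genotype class within a categorical 3-column site group
_CAT_OFFSET = {Genotype.HOM_REF: 0, Genotype.HOM_ALT: 1, Genotype.HET: 2}


@dataclass
class FeatureMatrix:
    """Dense n-samples x k-columns matrix plus its provenance."""

    values: np.ndarray
    sample_ids: Sequence[str]
    encoder: str
    k: int
    hash_seed: Optional[int]
    n_variants_consumed: int


def allele_key(chrom: str, pos: int, allele: str) -> str:
    """Feature-name string for one site allele, ``"chromosome_position_allele"``."""
    return f"{chrom}_{pos}_{allele}"


def hash_column(key: str, k: int, hash_seed: int = 0) -> int:
    """Map an allele-key string to a column index in ``[0, k)``.

    Uses MurmurHash3 x86_32 interpreted as a signed 32-bit integer; ``abs``
    is taken in Python's arbitrary-precision arithmetic so the INT32_MIN
    case is well defined. Deterministic across runs and platforms for a
    fixed seed.
    """
    if k <= 0:
        raise ParameterError(f"number of hashed dimensions must be >= 1, got {k}")
    h = int(murmurhash3_32(key, seed=hash_seed, positive=False))
    return abs(h) % k


def build_categorical_matrix(variant_batches: Iterable, n: int) -> FeatureMatrix:
    """Build the full one-hot matrix (k = 3v) from a stream of record batches."""
    blocks = []
    sample_ids = _stream_samples(variant_batches, n)
    v = 0
    for batch in variant_batches:
        block = np.zeros((n, 3 * len(batch)), dtype=np.float64)
        for j, rec in enumerate(batch):
            for gt, offset in _CAT_OFFSET.items():
                block[rec.genotypes == gt, 3 * j + offset] = 1.0
        blocks.append(block)
        v += len(batch)
    if v == 0:
        raise InputError("variant stream yielded no biallelic SNPs")
    values = np.hstack(blocks)
    return FeatureMatrix(values, sample_ids, CATEGORICAL, 3 * v, None, v)


def build_hashed_matrix(
    variant_batches: Iterable, n: int, k: int, hash_seed: int = 0
) -> FeatureMatrix:
    """Build the n x k hashed allele-count matrix in a single streaming pass."""
    if k <= 0:
        raise ParameterError(f"number of hashed dimensions must be >= 1, got {k}")
    sample_ids = _stream_samples(variant_batches, n)
    X = np.zeros((n, k), dtype=np.float64)
    v = 0
    for batch in variant_batches:
        for rec in batch:
            _accumulate(X, rec, k, hash_seed)
        v += len(batch)
    if v == 0:
        raise InputError("variant stream yielded no biallelic SNPs")
    return FeatureMatrix(X, sample_ids, HASHED, k, hash_seed, v)


def _accumulate(X: np.ndarray, rec: VariantRecord, k: int, hash_seed: int) -> None:
    col_ref = hash_column(allele_key(rec.chrom, rec.pos, rec.ref), k, hash_seed)
    col_alt = hash_column(allele_key(rec.chrom, rec.pos, rec.alt), k, hash_seed)
    gts = rec.genotypes
    X[gts == Genotype.HOM_REF, col_ref] += 2.0
    X[gts == Genotype.HOM_ALT, col_alt] += 2.0
    het = gts == Genotype.HET
    X[het, col_ref] += 1.0
    X[het, col_alt] += 1.0


def bucket_projection_oracle(
    variant_records: Sequence[VariantRecord], n: int, k: int, hash_seed: int = 0
) -> FeatureMatrix:
    """Reference construction of the hashed matrix for small inputs.

    Builds the exact n x 2v allele-copy-count matrix (one column per site
    allele), then sums the columns whose allele keys hash to the same
    bucket. Must agree entry-for-entry with :func:`build_hashed_matrix`;
    it exists to be compared against the streaming path, not to replace it.
    """
    if k <= 0:
        raise ParameterError(f"number of hashed dimensions must be >= 1, got {k}")
    records = list(variant_records)
    if not records:
        raise InputError("no variant records supplied")
    counts = np.zeros((n, 2 * len(records)), dtype=np.float64)
    buckets = np.empty(2 * len(records), dtype=np.int64)
    for j, rec in enumerate(records):
        gts = rec.genotypes
        counts[gts == Genotype.HOM_REF, 2 * j] = 2.0
        counts[gts == Genotype.HOM_ALT, 2 * j + 1] = 2.0
        het = gts == Genotype.HET
        counts[het, 2 * j] = 1.0
        counts[het, 2 * j + 1] = 1.0
        buckets[2 * j] = hash_column(allele_key(rec.chrom, rec.pos, rec.ref), k, hash_seed)
        buckets[2 * j + 1] = hash_column(allele_key(rec.chrom, rec.pos, rec.alt), k, hash_seed)
    X = np.zeros((n, k), dtype=np.float64)
    np.add.at(X.T, buckets, counts.T)
    return FeatureMatrix(X, [f"S{i}" for i in range(n)], HASHED, k, hash_seed, len(records))


def _stream_samples(variant_batches, n: int) -> Sequence[str]:
    ids = getattr(variant_batches, "samples", None)
    if ids is not None:
        if len(ids) != n:
            raise InputError(f"stream has {len(ids)} samples but n={n} was requested")
        return list(ids)
    return [f"S{i}" for i in range(n)]


def save_matrix(matrix: FeatureMatrix, path: str) -> None:
    """Persist a matrix as ``<path>.npy`` plus a JSON provenance sidecar."""
    base = Path(path)
    np.save(base.with_suffix(".npy"), matrix.values)
    meta = {
        "sample_ids": list(matrix.sample_ids),
        "encoder": matrix.encoder,
        "k": matrix.k,
        "hash_seed": matrix.hash_seed,
        "n_variants_consumed": matrix.n_variants_consumed,
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_matrix(path: str) -> FeatureMatrix:
    base = Path(path)
    values = np.load(base.with_suffix(".npy"))
    meta = json.loads(base.with_suffix(".json").read_text())
    return FeatureMatrix(
        values,
        meta["sample_ids"],
        meta["encoder"],
        meta["k"],
        meta["hash_seed"],
        meta["n_variants_consumed"],
    )
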