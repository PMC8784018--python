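"""Feature matrices: categorical one-hot, hashed allele counts, hash oracle."""

import numpy as np
import pytest

from invscan import (
    FeatureMatrix,
    Genotype,
    InputError,
    ParameterError,
    allele_key,
    bucket_projection_oracle,
    build_categorical_matrix,
    build_hashed_matrix,
    hash_column,
    load_matrix,
    save_matrix,
)
from invscan.vcfstream import VariantRecord

from conftest import make_records


def rec(codes, pos=100, chrom="2L", ref="A", alt="T"):
    return VariantRecord(chrom, pos, ref, alt, np.array(codes, dtype=np.int8))


# --- independent MurmurHash3 x86_32 oracle (bit-twiddling reimplementation) ---

def _murmur3_32(data: bytes, seed: int) -> int:
    """Reference MurmurHash3 x86_32, returning the unsigned 32-bit digest."""
    c1, c2 = 0xCC9E2D51, 0x1B873593
    h = seed & 0xFFFFFFFF
    length = len(data)
    rounded = length - (length % 4)
    for i in range(0, rounded, 4):
        k = int.from_bytes(data[i : i + 4], "little")
        k = (k * c1) & 0xFFFFFFFF
        k = ((k << 15) | (k >> 17)) & 0xFFFFFFFF
        k = (k * c2) & 0xFFFFFFFF
        h ^= k
        h = ((h << 13) | (h >> 19)) & 0xFFFFFFFF
        h = (h * 5 + 0xE6546B64) & 0xFFFFFFFF
    k = 0
    tail = data[rounded:]
    if len(tail) >= 3:
        k ^= tail[2] << 16
    if len(tail) >= 2:
        k ^= tail[1] << 8
    if len(tail) >= 1:
        k ^= tail[0]
        k = (k * c1) & 0xFFFFFFFF
        k = ((k << 15) | (k >> 17)) & 0xFFFFFFFF
        k = (k * c2) & 0xFFFFFFFF
        h ^= k
    h ^= length
    h ^= h >> 16
    h = (h * 0x85EBCA6B) & 0xFFFFFFFF
    h ^= h >> 13
    h = (h * 0xC2B2AE35) & 0xFFFFFFFF
    h ^= h >> 16
    return h


@pytest.mark.parametrize(
    "data,seed,expected",
    [
        (b"", 0, 0x00000000),
        (b"", 1, 0x514E28B7),
        (b"aaaa", 0x9747B28C, 0x5A97808A),
        (b"Hello, world!", 0x9747B28C, 0x24884CBA),
    ],
)
def test_murmur_oracle_matches_published_vectors(data, seed, expected):
    """The test oracle itself agrees with the published MurmurHash3 vectors."""
    assert _murmur3_32(data, seed) == expected


class TestHashColumn:
    def test_modulo_one(self):
        assert hash_column("2L_1_A", 1, 0) == 0

    def test_deterministic(self):
        a = hash_column("2R_9897_A", 1000, 42)
        assert a == hash_column("2R_9897_A", 1000, 42)

    @pytest.mark.parametrize("key", ["2L_34534_T", "2R_9897_A", "X_1_G"])
    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_against_independent_hash(self, key, seed):
        """abs(signed 32-bit murmur) % k, with abs taken in wide arithmetic."""
        unsigned = _murmur3_32(key.encode(), seed)
        signed = unsigned - (1 << 32) if unsigned >= (1 << 31) else unsigned
        assert hash_column(key, 1000, seed) == abs(signed) % 1000

    def test_invalid_k(self):
        with pytest.raises(ParameterError):
            hash_column("2L_1_A", 0, 0)


class TestCategoricalMatrix:
    def test_single_genotype_encodings(self):
        G = Genotype
        for code, expected in [
            (G.HOM_ALT, [0, 1, 0]),
            (G.HOM_REF, [1, 0, 0]),
            (G.HET, [0, 0, 1]),
            (G.UNKNOWN, [0, 0, 0]),
        ]:
            fm = build_categorical_matrix([[rec([code])]], 1)
            assert fm.values.tolist() == [expected]
            assert fm.k == 3

    def test_all_het_block(self):
        batches = [[rec([1, 1], pos=p) for p in (10, 20, 30)]]
        fm = build_categorical_matrix(batches, 2)
        assert fm.values.tolist() == [[0, 0, 1] * 3] * 2
        assert fm.values.sum(axis=1).tolist() == [3, 3]

    def test_site_group_row_sums_are_binary(self, rng):
        records = make_records(rng, n=7, v=20)
        fm = build_categorical_matrix([records], 7)
        groups = fm.values.reshape(7, 20, 3).sum(axis=2)
        assert set(np.unique(groups)) <= {0.0, 1.0}
        called = np.array([(r.genotypes != Genotype.UNKNOWN) for r in records]).T
        assert np.array_equal(fm.values.sum(axis=1), called.sum(axis=1))

    def test_empty_stream_is_error(self):
        with pytest.raises(InputError):
            build_categorical_matrix([], 3)


class TestHashedMatrix:
    def test_het_increments_two_buckets(self):
        fm = build_hashed_matrix([[rec([Genotype.HET], pos=7)]], 1, 64, 0)
        ci = hash_column(allele_key("2L", 7, "A"), 64, 0)
        cj = hash_column(allele_key("2L", 7, "T"), 64, 0)
        assert ci != cj  # chosen fixture has no collision
        assert fm.values[0, ci] == 1 and fm.values[0, cj] == 1
        assert fm.values.sum() == 2

    def test_hom_ref_adds_two_copies(self):
        fm = build_hashed_matrix([[rec([Genotype.HOM_REF], pos=7)]], 1, 64, 0)
        ci = hash_column(allele_key("2L", 7, "A"), 64, 0)
        assert fm.values[0, ci] == 2
        assert fm.values.sum() == 2

    def test_unknown_changes_nothing(self):
        fm = build_hashed_matrix([[rec([Genotype.UNKNOWN])]], 1, 16, 0)
        assert fm.values.sum() == 0

    def test_k_one_collapses_to_copy_count(self, rng):
        records = make_records(rng, n=6, v=30)
        fm = build_hashed_matrix([records], 6, 1, 0)
        called = np.array([(r.genotypes != Genotype.UNKNOWN) for r in records]).sum(axis=0)
        assert fm.values[:, 0].tolist() == (2 * called).tolist()

    def test_row_sum_conservation(self, rng):
        records = make_records(rng, n=10, v=50, unknown_rate=0.3)
        fm = build_hashed_matrix([records], 10, 37, 5)
        called = np.array([(r.genotypes != Genotype.UNKNOWN) for r in records]).sum(axis=0)
        assert np.array_equal(fm.values.sum(axis=1), 2.0 * called)

    def test_batch_size_invariance(self, rng):
        records = make_records(rng, n=8, v=40)
        whole = build_hashed_matrix([records], 8, 19, 1)
        chunked = build_hashed_matrix(
            [records[i : i + 7] for i in range(0, 40, 7)], 8, 19, 1
        )
        assert np.array_equal(whole.values, chunked.values)
        assert whole.n_variants_consumed == chunked.n_variants_consumed == 40

    def test_invalid_k(self, rng):
        with pytest.raises(ParameterError):
            build_hashed_matrix([make_records(rng, 2, 3)], 2, 0, 0)


class TestBucketProjectionOracle:
    def test_forced_collision_sums_columns(self):
        r = rec([Genotype.HET, Genotype.HOM_ALT], pos=5)
        k = 2
        direct = build_hashed_matrix([[r]], 2, k, 0)
        oracle = bucket_projection_oracle([r], 2, k, 0)
        assert np.array_equal(direct.values, oracle.values)
        assert direct.values.sum() == 4  # total allele copies conserved

    @pytest.mark.parametrize("seed", range(10))
    def test_streaming_equals_oracle_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 21))
        v = int(rng.integers(5, 201))
        k = int(rng.integers(1, 33))
        records = make_records(rng, n=n, v=v)
        streaming = build_hashed_matrix([records], n, k, seed)
        oracle = bucket_projection_oracle(records, n, k, seed)
        assert np.array_equal(streaming.values, oracle.values)


def test_total_mass_conservation(rng):
    records = make_records(rng, n=12, v=60, unknown_rate=0.2)
    fm = build_hashed_matrix([records], 12, 23, 0)
    n_called = sum((r.genotypes != Genotype.UNKNOWN).sum() for r in records)
    assert fm.values.sum() == 2.0 * n_called


def test_save_load_round_trip(tmp_path, rng):
    fm = build_hashed_matrix([make_records(rng, 4, 10)], 4, 8, 3)
    save_matrix(fm, str(tmp_path / "m"))
    back = load_matrix(str(tmp_path / "m"))
    assert np.array_equal(back.values, fm.values)
    assert back.encoder == "hashed" and back.k == 8 and back.hash_seed == 3
    assert back.n_variants_consumed == 10
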