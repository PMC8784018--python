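"""Shared fixtures: hand-written VCF text and random variant records."""

import numpy as np
import pytest

from invscan.vcfstream import Genotype, VariantRecord

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=2L,length=1000000>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf(path, data_lines, samples=("S1", "S2", "S3")):
    """Write a VCF with the standard test header and the given data lines."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for line in data_lines:
            fh.write(line + "\n")
    return str(path)


def gt_line(pos, gts, ref="A", alt="T", chrom="2L"):
    return f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts)


def make_records(rng, n, v, chrom="2L", unknown_rate=0.1):
    """Random biallelic SNP records with distinct sorted positions."""
    positions = np.sort(rng.choice(np.arange(1, 50 * v + 1), size=v, replace=False))
    bases = np.array(list("ACGT"))
    records = []
    for pos in positions:
        codes = rng.integers(0, 3, n).astype(np.int8)
        codes[rng.random(n) < unknown_rate] = Genotype.UNKNOWN
        ref, alt = rng.choice(4, 2, replace=False)
        records.append(
            VariantRecord(chrom, int(pos), str(bases[ref]), str(bases[alt]), codes)
        )
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
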