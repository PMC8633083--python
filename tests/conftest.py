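import numpy as np
import pytest

from sweepgf import GridSpec


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(thetas=(0.3, 0.5, 0.7), tas=(0.1, 0.5, 1.0),
                    ss=(0.005, 0.05), Ne=1e4, r=1e-7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240601)


TOY_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1,length=100000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4
"""


def _vcf_line(pos, ref, alt, info, gts):
    return (f"chr1\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\tGT\t"
            + "\t".join(gts) + "\n")


@pytest.fixture(scope="session")
def toy_vcf(tmp_path_factory):
    """Hand-built VCF: 4 samples (8 haplotypes), anchor at 10000, l=1000.

    Haplotype order is S1a,S1b,S2a,S2b,S3a,S3b,S4a,S4b (indices 0..7).
    Known truth for each variant's derived-allele carrier set is encoded
    in the test module.
    """
    lines = [
        # right block 1 (10001..11000)
        _vcf_line(10100, "A", "G", "AA=A",
                  ["0|1", "0|0", "0|0", "0|0"]),           # carriers {1}
        _vcf_line(10500, "C", "T", "AA=T",
                  ["0|0", "1|1", "0|0", "0|1"]),           # AA=ALT: derived
                                                           # = REF: {0,1,4,5,6}
        _vcf_line(10800, "G", "A", "AA=G",
                  ["1|1", "0|0", "1|0", "0|0"]),           # carriers {0,1,4}
        # right block 2 (11001..12000)
        _vcf_line(11500, "T", "C", "AA=T",
                  ["0|0", "0|1", "1|0", "0|0"]),           # carriers {3,4}
        # left block 1 (9001..10000)
        _vcf_line(9999, "A", "C", "AA=A",
                  ["1|0", "0|0", "0|0", "0|0"]),           # carriers {0}
        # dropped sites
        _vcf_line(10000, "A", "G", "AA=A",
                  ["0|1", "0|0", "0|0", "0|0"]),           # at anchor
        _vcf_line(10200, "A", "G,T", "AA=A",
                  ["0|1", "0|2", "0|0", "0|0"]),           # multiallelic
        _vcf_line(10300, "A", "G", ".",
                  ["0|1", "0|0", "0|0", "0|0"]),           # no AA
        _vcf_line(10400, "A", "G", "AA=T",
                  ["0|1", "0|0", "0|0", "0|0"]),           # AA mismatch
        _vcf_line(10600, "A", "G", "AA=A",
                  ["0|1", ".|.", "0|0", "0|0"]),           # missing genotype
        _vcf_line(50000, "A", "G", "AA=A",
                  ["0|1", "0|0", "0|0", "0|0"]),           # outside span
    ]
    path = tmp_path_factory.mktemp("vcf") / "toy.vcf"
    path.write_text(TOY_VCF_HEADER + "".join(lines))
    return path
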