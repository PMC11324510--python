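import numpy as np
import pysam
import pytest

from editscope.refmodel import GenomeSlice, TranscriptModel, WindowInterval, revcomp

# Toy single-exon coding sequence: M V R Ter
TOY_CDS = "ATGGTGCGATAA"


@pytest.fixture
def toy_plus():
    """Plus-strand toy: single exon [0,12), CDS [0,12)."""
    genome = GenomeSlice("toy", TOY_CDS)
    tx = TranscriptModel("toyTx", "toy", "+", [(0, 12)], 0, 12)
    return genome, tx


@pytest.fixture
def toy_minus():
    """Minus-strand toy locus encoding the same protein."""
    genome = GenomeSlice("toy", revcomp(TOY_CDS))
    tx = TranscriptModel("toyTx", "toy", "-", [(0, 12)], 0, 12)
    return genome, tx


@pytest.fixture
def toy_multi_exon():
    """Plus-strand, two exons with UTRs: exon1 [5,14), exon2 [20,32);
    CDS spans [8,29): 9 + 9 spliced bases... built explicitly below."""
    # transcript = utr5(3) + cds(15) + utr3(3); cds = ATG GTG CGA AAA TAA
    cds = "ATGGTGCGAAAATAA"
    utr5, utr3 = "TTT", "CCC"
    exon1_t = utr5 + cds[:6]      # 9 transcript bases
    exon2_t = cds[6:] + utr3      # 12 transcript bases
    seq = "AAAAA" + exon1_t + "GGGGGG" + exon2_t + "AAAAA"
    exons = [(5, 14), (20, 32)]
    cds_start = 8                  # after 3 utr bases in exon1
    cds_end = 29                   # before 3 utr bases in exon2
    genome = GenomeSlice("toy", seq)
    tx = TranscriptModel("toyTx2", "toy", "+", exons, cds_start, cds_end)
    return genome, tx


@pytest.fixture
def chr17_minus_locus():
    """Minus-strand mini locus whose plus-strand window reads CACTCG.

    Transcript codons 6 and 7 are CGA GTG (R, V); replacing the plus-strand
    window CACTCG with CATTCG converts codon 7 from Val to Met, the classic
    CBE missense call on a minus-strand gene.
    """
    codons = ["ATG"] + ["AAA"] * 4 + ["CGA", "GTG"] + ["AAA"] * 3 + ["TAA"]
    cds_t = "".join(codons)                      # transcript strand, 33 nt
    start = 7674927
    genome = GenomeSlice("chr17", revcomp(cds_t), start=start)
    tx = TranscriptModel(
        "mini17Tx", "chr17", "-", [(start, start + 33)], start, start + 33
    )
    win = WindowInterval("chr17", 7674939, 7674945)
    assert genome.fetch_window(win) == "CACTCG"
    return genome, tx, win


@pytest.fixture
def sam_header():
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "toy", "LN": 10000}]}
    )


def make_read(
    header,
    name="r1",
    seq="A" * 30,
    cigar="30M",
    start=100,
    flag=0,
    chrom_id=0,
):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    a.flag = flag
    a.reference_id = chrom_id
    a.reference_start = start
    a.mapping_quality = 60
    a.cigarstring = cigar
    return a


@pytest.fixture
def read_factory(sam_header):
    def factory(**kwargs):
        return make_read(sam_header, **kwargs)

    return factory
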