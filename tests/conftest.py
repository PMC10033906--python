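import numpy as np
import pysam
import pytest

from cissplice import GenomeSequence, GenomicInterval, TranscriptModel, parse_gtf

# Toy transcriptome (1-based GTF coordinates):
#   TX1 (+, gene GA): exons 101-200, 301-400, 501-600
#       0-based exons [100,200) [300,400) [500,600); introns [200,300) [400,500)
#   TX2 (-, gene GB): exons 1101-1200, 1301-1400
#       0-based intron [1200,1300); donor at 1300, acceptor at 1200
#   TX3 (+, gene GC): single exon 2001-2100
TOY_GTF = [
    'chr1\tt\texon\t101\t200\t.\t+\t.\tgene_id "GA"; transcript_id "TX1"; gene_name "ALPHA";',
    'chr1\tt\texon\t301\t400\t.\t+\t.\tgene_id "GA"; transcript_id "TX1"; gene_name "ALPHA";',
    'chr1\tt\texon\t501\t600\t.\t+\t.\tgene_id "GA"; transcript_id "TX1"; gene_name "ALPHA";',
    'chr1\tt\texon\t1101\t1200\t.\t-\t.\tgene_id "GB"; transcript_id "TX2"; gene_name "BETA";',
    'chr1\tt\texon\t1301\t1400\t.\t-\t.\tgene_id "GB"; transcript_id "TX2"; gene_name "BETA";',
    'chr1\tt\texon\t2001\t2100\t.\t+\t.\tgene_id "GC"; transcript_id "TX3"; gene_name "GAMMA";',
]


@pytest.fixture(scope="session")
def toy_index():
    return parse_gtf(TOY_GTF)


@pytest.fixture(scope="session")
def toy_index_single():
    return parse_gtf(TOY_GTF, include_single_exon=True)


@pytest.fixture(scope="session")
def toy_genome():
    rng = np.random.default_rng(7)
    seq = list(rng.choice(list("ACGT"), size=3000))
    # canonical motifs for TX1 introns (+): GT..AG
    for start, end in ((200, 300), (400, 500)):
        seq[start:start + 2] = "GT"
        seq[end - 2:end] = "AG"
    # TX2 intron (-): forward strand CT..AC reads GT-AG after revcomp
    seq[1200:1202] = "CT"
    seq[1298:1300] = "AC"
    return GenomeSequence.from_dict({"chr1": "".join(seq)})


@pytest.fixture(scope="session")
def sam_header():
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": "chr1", "LN": 10_000_000}, {"SN": "chr2", "LN": 10_000_000}],
        }
    )


def make_read(
    header,
    cigar,
    pos,
    contig="chr1",
    name="read",
    flag=0,
    tags=(),
):
    """Build an in-memory alignment record."""
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.flag = flag
    a.reference_id = header.get_tid(contig)
    a.reference_start = pos
    a.mapping_quality = 60
    a.cigarstring = cigar
    for tag, value in tags:
        a.set_tag(tag, value)
    return a


def random_transcripts(rng, n, contig="chr1", max_exons=6):
    """Randomized non-overlapping-exon transcript models for fuzz tests."""
    models = []
    cursor = int(rng.integers(0, 500))
    for i in range(n):
        n_exons = int(rng.integers(1, max_exons + 1))
        # overlap genes occasionally by rewinding the cursor
        if i and rng.random() < 0.3:
            cursor = max(0, cursor - int(rng.integers(0, 800)))
        exons = []
        pos = cursor
        strand = "+" if rng.random() < 0.5 else "-"
        for e in range(n_exons):
            length = int(rng.integers(30, 200))
            exons.append(GenomicInterval(contig, pos, pos + length, strand))
            pos += length
            if e < n_exons - 1:
                pos += int(rng.integers(70, 400))
        cursor = pos + int(rng.integers(1, 500))
        models.append(
            TranscriptModel(
                transcript_id=f"T{i:04d}",
                gene_id=f"G{i:04d}",
                gene_name=f"N{i:04d}",
                strand=strand,
                exons=tuple(exons),
            )
        )
    return models
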