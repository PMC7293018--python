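import pytest

from tssbind.core import GenomicInterval, TranscriptModel
from tssbind.simulate import GenomeConfig, generate_genome


def make_transcript(gene_id="gene_1", transcript_id="tx_1", chrom="chr1",
                    start=1000, strand="+"):
    """Fixed toy anatomy: 200 nt 5'UTR, CDS exons of 300/400, one 800 nt
    intron between them; total body 1700 nt."""
    if strand == "+":
        utr5 = [GenomicInterval(chrom, start, start + 200, "+")]
        cds = [GenomicInterval(chrom, start + 200, start + 500, "+"),
               GenomicInterval(chrom, start + 1300, start + 1700, "+")]
        introns = [GenomicInterval(chrom, start + 500, start + 1300, "+")]
        iv = GenomicInterval(chrom, start, start + 1700, "+")
    else:
        end = start + 1700
        utr5 = [GenomicInterval(chrom, end - 200, end, "-")]
        cds = [GenomicInterval(chrom, end - 500, end - 200, "-"),
               GenomicInterval(chrom, start, start + 400, "-")]
        introns = [GenomicInterval(chrom, start + 400, end - 500, "-")]
        iv = GenomicInterval(chrom, start, end, "-")
    return TranscriptModel(gene_id, transcript_id, iv, utr5, cds, introns)


@pytest.fixture(scope="session")
def small_genome():
    """A 2 x 500 kb genome with 120 genes, most with CGI promoters."""
    cfg = GenomeConfig(n_chroms=2, chrom_length=500_000, n_genes=120,
                       cgi_fraction=0.7, seed=11)
    return generate_genome(cfg)
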