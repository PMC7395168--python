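import numpy as np
import pytest

from pumpkinpop.datamodel import GenotypeMatrix, MarkerRecord

# shorthand call codes used throughout the suite
R, H, A, M = 0, 1, 2, -1


def make_matrix(rows, accession_ids=None, marker_ids=None):
    """Build a GenotypeMatrix from a list of call-code rows."""
    arr = np.array(rows, dtype=np.int8)
    n, m = arr.shape
    return GenotypeMatrix(
        accession_ids or [f"acc{i}" for i in range(n)],
        marker_ids or [f"m{j}" for j in range(m)],
        arr,
    )


def make_markers(n, chromosome="chr01", spacing=1000, pic=None):
    return [
        MarkerRecord(
            marker_id=f"m{j}",
            chromosome=chromosome,
            position=(j + 1) * spacing,
            ref_allele="A",
            alt_allele="G",
            pic=pic[j] if pic is not None else None,
        )
        for j in range(n)
    ]


@pytest.fixture
def toy_vcf(tmp_path):
    """3-sample VCF with 2 SNPs, one './.' call."""
    text = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=chr01>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
        "chr01\t100\tsnp1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        "chr01\t200\tsnp2\tC\tT\t.\tPASS\t.\tGT\t0/0\t./.\t0/1\n"
    )
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    return path
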