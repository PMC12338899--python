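import numpy as np
import pandas as pd
import pytest

from founder_enrich.io_formats import MISSING, GenotypeMatrix, Pedigree


FIXTURE_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
1\t100\t.\tA\tG\t.\t.\t.\tGT:DP:AD\t0/1:20:10,10\t0/0:15:15,0
1\t200\t.\tC\tT\t.\t.\t.\tGT:DP:AD\t1/1:30:0,30\t./.:.:.,.
1\t300\t.\tG\tA\t.\t.\t.\tGT:DP:AD\t0/0:12:12,0\t0/1:9:8,1
"""


@pytest.fixture
def fixture_vcf(tmp_path):
    path = tmp_path / "fixture.vcf"
    path.write_text(FIXTURE_VCF)
    return path


@pytest.fixture
def small_gm():
    """3 samples x 4 variants with depth/AD fields and one missing call."""
    variants = pd.DataFrame(
        {
            "chrom": ["1", "1", "1", "2"],
            "pos": [100, 200, 300, 50],
            "ref": ["A", "C", "G", "T"],
            "alt": ["G", "T", "A", "C"],
        }
    )
    dosage = np.array(
        [[0, 1, 2, 0], [1, MISSING, 0, 2], [2, 0, 1, 1]], dtype=np.int8
    )
    depth = np.full((3, 4), 30, dtype=np.int32)
    ad_alt = np.where(dosage == 1, 15, np.where(dosage == 2, 30, 0)).astype(np.int32)
    ad_ref = (depth - ad_alt).astype(np.int32)
    return GenotypeMatrix(
        samples=["S1", "S2", "S3"],
        variants=variants,
        dosage=dosage,
        depth=depth,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
    )


@pytest.fixture
def trio_pedigree():
    table = pd.DataFrame(
        [
            ("F1", "dad", "0", "0", 1, 1),
            ("F1", "mom", "0", "0", 2, 1),
            ("F1", "kid", "dad", "mom", 1, 2),
        ],
        columns=["fid", "iid", "father", "mother", "sex", "phenotype"],
    )
    return Pedigree(table)
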