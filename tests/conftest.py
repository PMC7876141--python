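import numpy as np
import pytest

from svgex.io_formats import GeneAnnotation, SSVRecord, TumorMeta
from svgex.synthetic_cohort import CohortParams, generate_cohort

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position">
##INFO=<ID=MATEID,Number=.,Type=String,Description="Mate breakend id">
##FILTER=<ID=MinQual,Description="Low quality">
##contig=<ID=chr1,length=249250621>
##contig=<ID=chr2,length=243199373>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


@pytest.fixture
def write_vcf(tmp_path):
    """Write VCF body lines under a minimal SV header; returns the path."""

    def _write(lines, name="test.vcf"):
        path = tmp_path / name
        path.write_text(VCF_HEADER + "".join(line + "\n" for line in lines))
        return path

    return _write


def make_gene(gene_id="G1", chrom="chr1", start=1_000_000, end=1_050_000, strand="+"):
    return GeneAnnotation(gene_id, chrom, start, end, strand)


def make_ssv(ssv_id="S1", svclass="deletion", chrom1="chr1", pos1=100, orient1="positive",
             chrom2=None, pos2=200, orient2="negative", tumor_id="T1"):
    return SSVRecord(ssv_id, svclass, chrom1, pos1, orient1,
                     chrom2 or chrom1, pos2, orient2, tumor_id)


@pytest.fixture(scope="session")
def small_cohort():
    """Small planted cohort shared by unit tests (fast to generate)."""
    params = CohortParams(
        seed=42, n_tumors=60, n_types=3, n_genes=120,
        planted_cis_genes=5, cis_carriers=10,
        planted_fusions=4, planted_burden_driver=True,
        burden_expr_genes=2, n_pairs=10,
    )
    return generate_cohort(params)


@pytest.fixture
def simple_meta():
    return [
        TumorMeta(f"T{i}", f"P{i}", "typeA" if i % 2 else "typeB", "initial")
        for i in range(1, 7)
    ]
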