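import numpy as np
import pytest

from gqscore.core import DropThreshold, ScoredSNP, band_assignment, classify_outlier
from gqscore.io import SummaryStatRecord
from gqscore.ld import GenotypePanel, PanelVariant


@pytest.fixture
def default_thr() -> DropThreshold:
    return DropThreshold()


def make_scored(var_id: str, r2: float, p_obs: float, index_logp: float,
                thr: DropThreshold = DropThreshold()) -> ScoredSNP:
    """Build a fully-consistent ScoredSNP from raw (r², p_obs, index) inputs."""
    p_hat = r2 * index_logp
    e = p_obs - p_hat
    s = e / p_hat
    loss = max(0.0, -s)
    outlier = classify_outlier(r2, loss, thr)
    return ScoredSNP(
        var_id=var_id, r2=r2, p_obs=p_obs, p_hat=p_hat, e=e, s=s, loss=loss,
        band=band_assignment(s), is_outlier=outlier,
        perp_dist=thr.distance(r2, loss) if outlier else 0.0,
    )


def make_records(rows):
    """rows: iterable of (chrom, pos, var_id, p) or full-field tuples."""
    return [
        SummaryStatRecord(chrom=str(c), pos=int(b), var_id=v, p_value=p)
        for c, b, v, p in rows
    ]


def make_panel(dosage_rows, chrom="1", start=100, spacing=10) -> GenotypePanel:
    """Panel from a list of per-variant dosage lists (-1 = missing)."""
    dosages = np.array(dosage_rows, dtype=np.int8)
    variants = [
        PanelVariant(chrom, start + i * spacing, f"v{i}", "A", "G")
        for i in range(dosages.shape[0])
    ]
    samples = [f"s{j}" for j in range(dosages.shape[1])]
    return GenotypePanel(variants, dosages, samples)


@pytest.fixture
def toy_sumstats(tmp_path):
    path = tmp_path / "toy.tsv"
    path.write_text(
        "CHR SNP BP A1 A2 P\n"
        "1 rs1 1000 A G 1e-9\n"
        "1 rs2 2000 C T 0.5\n"
        "2 rs3 3000 G A 0.01\n"
    )
    return path


TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4
1\t100\trsA\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/1
1\t200\trsB\tC\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/1
1\t300\trsC\tG\tA\t.\tPASS\t.\tGT\t./1\t0/0\t0/1\t1/1
1\t400\trsD\tA\tC,T\t.\tPASS\t.\tGT\t0/1\t0/2\t1/2\t0/0
1\t500\trsE\tT\tG\t.\tPASS\t.\tGT\t0/0\t0/0\t0/1\t0/0
"""


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path
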