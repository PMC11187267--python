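import numpy as np
import pytest

from mrmediate.harmonization import HarmonizedInstrument
from mrmediate.summary_data import SummaryDataset, VariantAssociation


def make_inst(rsid, beta_exp, beta_out, se_out, se_exp=0.01):
    return HarmonizedInstrument(
        rsid=rsid, beta_exp=beta_exp, se_exp=se_exp, beta_out=beta_out, se_out=se_out
    )


def make_variant(rsid="rs1", ea="A", oa="G", beta=0.1, se=0.01, pval=1e-9, n=100000,
                 eaf=0.3, chrom=None, pos=None):
    return VariantAssociation(rsid, ea, oa, beta, se, pval, n, eaf, chrom, pos)


@pytest.fixture
def three_snp_instruments():
    """Three instruments whose Wald ratios are (0.5, 0.6, 0.4), each with ratio SE 0.1."""
    return [
        make_inst("rs1", 0.10, 0.05, 0.010),
        make_inst("rs2", 0.20, 0.12, 0.020),
        make_inst("rs3", 0.15, 0.06, 0.015),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240606)


def random_instruments(rng, k, theta=0.4, noise=0.0):
    """Small instrument sets with exposure effects well away from zero."""
    bx = rng.uniform(0.05, 0.3, k)
    sy = rng.uniform(0.005, 0.03, k)
    by = theta * bx + noise * rng.standard_normal(k) * sy
    sx = rng.uniform(0.002, 0.01, k)
    return [
        make_inst(f"rs{j}", float(bx[j]), float(by[j]), float(sy[j]), float(sx[j]))
        for j in range(k)
    ]


def dataset_from_variants(variants, trait_name="trait", trait_type="binary"):
    return SummaryDataset(trait_name, trait_type, variants)
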