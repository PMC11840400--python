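import numpy as np
import pytest

from mrglyc.summary_io import AssociationRecord, HarmonizedSet, Variant


def make_variant(vid="rs1", ea="A", oa="G", eaf=0.3, chrom="1", pos=100):
    return Variant(id=vid, chrom=chrom, pos=pos, effect_allele=ea,
                   other_allele=oa, eaf=eaf)


def make_record(vid="rs1", beta=0.1, se=0.02, pval=0.5, n=1000, ea="A", oa="G", eaf=0.3):
    return AssociationRecord(variant=make_variant(vid, ea, oa, eaf),
                             beta=beta, se=se, pval=pval, n=n)


def make_hset(gamma, sigma_gamma, Gamma, sigma_Gamma):
    """Harmonized set straight from effect vectors (shared dummy variants)."""
    exp, out = [], []
    for j, (g, sg, G, sG) in enumerate(zip(gamma, sigma_gamma, Gamma, sigma_Gamma)):
        v = make_variant(f"rs{j + 1}")
        exp.append(AssociationRecord(variant=v, beta=g, se=sg, pval=0.5, n=1000))
        out.append(AssociationRecord(variant=v, beta=G, se=sG, pval=0.5, n=1000))
    return HarmonizedSet(exposure_records=exp, outcome_records=out)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hset_factory():
    return make_hset


@pytest.fixture
def record_factory():
    return make_record
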