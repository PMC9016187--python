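import numpy as np
import pytest

from mrkit import (GwasSummaryTable, HarmonizedInstrument,
                   VariantAssociation, f_statistic, per_snp_r2)


def make_variant(snp_id="rs1", ea="A", oa="G", beta=0.1, se=0.01,
                 pval=None, n=50_000, eaf=0.3, chrom="1", pos=1_000_000):
    """Association with a p-value consistent with (beta, se) by default."""
    if pval is None:
        from scipy import stats
        pval = max(float(2 * stats.norm.sf(abs(beta / se))), 1e-300)
    return VariantAssociation(snp_id=snp_id, effect_allele=ea,
                              other_allele=oa, beta=beta, se=se, pval=pval,
                              n=n, eaf=eaf, chrom=chrom, pos=pos)


def make_instrument(snp_id="rs1", beta_exp=0.3, beta_out=0.03,
                    se_exp=0.02, se_out=0.02, n_exp=50_000, n_out=50_000,
                    ea="A", oa="G", eaf=0.3):
    return HarmonizedInstrument(
        snp_id=snp_id, effect_allele=ea, other_allele=oa,
        beta_exp=beta_exp, se_exp=se_exp, pval_exp=1e-20, n_exp=n_exp,
        beta_out=beta_out, se_out=se_out, pval_out=0.01, n_out=n_out,
        eaf_exp=eaf, eaf_out=eaf,
        r2_exp=per_snp_r2(beta_exp, se_exp, n_exp),
        r2_out=per_snp_r2(beta_out, se_out, n_out),
        f_stat=f_statistic(beta_exp, se_exp),
    )


def random_instruments(rng, j, slope=0.1, intercept=0.0, noise=0.005):
    """Small random instrument set: beta_out = a + b*beta_exp + noise."""
    insts = []
    for k in range(j):
        be = rng.uniform(0.1, 0.5)
        se_o = rng.uniform(0.005, 0.03)
        bo = intercept + slope * be + noise * rng.standard_normal()
        insts.append(make_instrument(
            snp_id=f"rs{k + 1:04d}", beta_exp=be, beta_out=bo,
            se_exp=rng.uniform(0.005, 0.03), se_out=se_o))
    return insts


@pytest.fixture
def rng():
    return np.random.default_rng(20220405)


def table_from(variants, label="trait"):
    return GwasSummaryTable(label, tuple(variants))
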