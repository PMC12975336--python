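import numpy as np
import pytest

from drugmr.ld import LDMatrix, InstrumentSet, condition_psd
from drugmr.sumstats import AssociationRecord, SummaryDataset, Variant


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_variant(pos, ea="A", oa="G", chrom="1", eaf=0.3, rsid=None):
    return Variant(chrom, pos, rsid or f"{chrom}:{pos}", ea, oa, eaf)


def make_record(pos, beta, se, pvalue=None, n=10_000, chrom="1",
                ea="A", oa="G", eaf=0.3, trait_id="trait"):
    import warnings

    import scipy.stats as st
    if pvalue is None:
        pvalue = max(2 * st.norm.sf(abs(beta) / se), 1e-320)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # fixtures may pair arbitrary beta/p
        return AssociationRecord(
            variant=make_variant(pos, ea, oa, chrom, eaf),
            beta=beta, se=se, pvalue=pvalue, n=n, trait_id=trait_id,
        )


def make_dataset(records, trait_id="trait", trait_type="quantitative"):
    return SummaryDataset.from_records(records, trait_id, trait_type)


def make_iset(beta_x, se_x, beta_y, se_y, r=None, chrom="1"):
    """InstrumentSet on synthetic variants with the given LD matrix."""
    beta_y = np.asarray(beta_y, dtype=float)
    m = beta_y.size
    variants = [make_variant(1000 + i, chrom=chrom) for i in range(m)]
    if r is None:
        r = np.eye(m)
    ld = LDMatrix(variants, condition_psd(np.asarray(r, dtype=float)))
    return InstrumentSet(
        variants=variants,
        beta_x=np.asarray(beta_x, dtype=float),
        se_x=np.asarray(se_x, dtype=float),
        beta_y=beta_y,
        se_y=np.asarray(se_y, dtype=float),
        ld=ld,
    )


@pytest.fixture
def iset_factory():
    return make_iset
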