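import pytest

from gynotrace import Genotype, SVCallset, SVRecord, SVType


def make_rec(
    sample="S1",
    chrom="A1",
    pos=1000,
    end=None,
    svtype=SVType.DEL,
    svlen=None,
    qual=40.0,
    support=10,
    precise=True,
    gt=Genotype.HET,
    strands=None,
    record_id=None,
):
    """Record builder with passing-by-default QC fields."""
    if end is None:
        end = pos if svtype is SVType.INS else pos + 99
    if svlen is None:
        if svtype is SVType.INS:
            svlen = 100
        elif svtype is SVType.DEL:
            svlen = -(end - pos + 1)
        else:
            svlen = end - pos + 1
    return SVRecord(
        sample_id=sample,
        chrom=chrom,
        pos=pos,
        end=end,
        svtype=svtype,
        svlen=svlen,
        qual=qual,
        support=support,
        precise=precise,
        gt=gt,
        strands=strands,
        record_id=record_id,
    )


def make_callset(records, sample=None):
    sample = sample or records[0].sample_id
    return SVCallset(sample, list(records))


@pytest.fixture
def rec():
    return make_rec


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """Small deterministic cohort with all noise channels off."""
    from gynotrace import SimConfig, simulate_cohort

    return simulate_cohort(SimConfig(seed=11).zero_noise())
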