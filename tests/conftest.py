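import numpy as np
import pytest

from svsoma.model import Callset, SampleMeta, SVRecord
from svsoma.simulate import SimConfig, simulate_cohort, simulate_reference


def make_sv(svtype="DEL", chrom="chr1", pos=10_000, end=None, svlen=None,
            support=10, sample_id="S1", record_id=None, seq=None,
            chrom2=None, pos2=None):
    """Terse SVRecord factory for tests."""
    if svtype in ("DEL", "DUP", "INV"):
        if end is None:
            end = pos + (svlen if svlen is not None else 1000)
        if svlen is None:
            svlen = end - pos
    elif svtype == "INS":
        if svlen is None:
            svlen = len(seq) if seq else 100
    else:  # TRA
        svlen = 0
        chrom2 = chrom2 or "chr2"
        pos2 = pos2 or 50_000
    if record_id is None:
        make_sv._n = getattr(make_sv, "_n", 0) + 1
        record_id = f"sv{make_sv._n}"
    return SVRecord(record_id=record_id, sample_id=sample_id, chrom=chrom,
                    pos=pos, end=end, svtype=svtype, svlen=svlen,
                    support=support, seq=seq, chrom2=chrom2, pos2=pos2)


def make_meta(sample_id="S1", patient_id="P1", role="tumor",
              mean_depth=20.0, msi_status="MSS", stage="II"):
    return SampleMeta(sample_id=sample_id, patient_id=patient_id, role=role,
                      mean_depth=mean_depth, msi_status=msi_status,
                      stage=stage)


def make_callset(records, **meta_kwargs):
    return Callset(sample=make_meta(**meta_kwargs), records=list(records))


def random_records(rng, n, sample_id="S1", chroms=("chr1", "chr2"),
                   span=2_000_000):
    """Random ingest-valid records of all five SV types."""
    records = []
    for i in range(n):
        svtype = ["DEL", "INS", "DUP", "INV", "TRA"][int(rng.integers(5))]
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(1_000, span))
        support = int(rng.integers(2, 40))
        if svtype == "TRA":
            records.append(make_sv("TRA", chrom=chrom, pos=pos,
                                   chrom2=chroms[int(rng.integers(len(chroms)))],
                                   pos2=int(rng.integers(1_000, span)),
                                   support=support, sample_id=sample_id,
                                   record_id=f"{sample_id}_r{i}"))
        else:
            svlen = int(rng.integers(50, 50_000))
            seq = None
            if svtype == "INS" and rng.random() < 0.5:
                seq = "".join("ACGT"[b] for b in rng.integers(0, 4, svlen))
            records.append(make_sv(svtype, chrom=chrom, pos=pos, svlen=svlen,
                                   support=support, sample_id=sample_id,
                                   record_id=f"{sample_id}_r{i}", seq=seq))
    return records


SMALL_SIM = SimConfig(
    seed=11, n_chromosomes=2, chrom_length=1_500_000, str_region_count=60,
    mobile_element_copies={"LINE": 8, "SINE": 10, "LTR": 6},
    genes_per_chromosome=3, n_patients=4,
    germline_counts={"DEL": 20, "INS": 20, "DUP": 5, "INV": 5, "TRA": 4},
    somatic_counts={"DEL": 8, "INS": 6, "DUP": 2, "INV": 2, "TRA": 2},
    span_len_range=(3_000, 80_000))


@pytest.fixture(scope="session")
def small_reference():
    return simulate_reference(SMALL_SIM)


@pytest.fixture(scope="session")
def small_cohort(small_reference):
    return simulate_cohort(small_reference, SMALL_SIM)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
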