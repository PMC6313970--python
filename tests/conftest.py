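import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from xenovar import CandidateVariant

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_candidate(**overrides) -> CandidateVariant:
    """A comfortably-passing SNP candidate; override fields to probe rules."""
    fields = dict(
        contig="chrT_h", pos=500, ref="A", alt="G", vtype="SNP",
        DP=200, FDP=200, FAO=60, RO=140, alt_fwd=30, alt_rev=30,
        STB=0.5, HRUN=1, QUAL=150.0, GQ=90.0,
        mapq_ref_mean=59.0, mapq_alt_mean=59.0,
        readlen_ref_mean=100.0, readlen_alt_mean=100.0,
        mmqs_ref_mean=20.0, mmqs_alt_mean=30.0,
    )
    fields.update(overrides)
    return CandidateVariant(**fields)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180101)
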