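import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gutclpb import FamilySpec, make_orf_population, make_reference

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference():
    return make_reference(seed=11, length=400, motif="RWGKPV", motif_position=200)


@pytest.fixture(scope="session")
def planted_population(reference):
    """Three families with 0/1/3 planted motif mismatches, flank identity 0.9."""
    specs = [
        FamilySpec("f1", n_orfs=40, motif_mismatches=0, flank_identity=0.9),
        FamilySpec("f2", n_orfs=30, motif_mismatches=1, flank_identity=0.9),
        FamilySpec("f3", n_orfs=10, motif_mismatches=3, flank_identity=0.9),
    ]
    records, taxonomy, truth = make_orf_population(reference, specs, flank_span=30, seed=7)
    return records, taxonomy, truth
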