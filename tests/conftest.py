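import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oligostate import helixmodel, seqmotif, synthgen

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_alignment() -> seqmotif.PositionMap:
    return seqmotif.load_reference_alignment()


@pytest.fixture(scope="session")
def hs_sequence(reference_alignment) -> seqmotif.OrthologSequence:
    return reference_alignment.sequences()["hs"].ungapped()


@pytest.fixture(scope="session")
def hs_dimer(hs_sequence) -> helixmodel.BundleModel:
    return helixmodel.assemble_dimer(hs_sequence)


@pytest.fixture(scope="session")
def parallel_tetramer(hs_dimer) -> helixmodel.BundleModel:
    return helixmodel.assemble_tetramer(hs_dimer, "parallel")


@pytest.fixture(scope="session")
def antiparallel_tetramer(hs_dimer) -> helixmodel.BundleModel:
    return helixmodel.assemble_tetramer(hs_dimer, "antiparallel")


#: crosslink efficiency ordering measured on the human zipper by
#: non-reducing SDS-PAGE after diamide treatment: T274C ~ Y277C (highest)
#: > S262C ~ R281C (intermediate) > S266C ~ S270C (lowest); ranks are
#: 1-based with ties averaged
MEASURED_XLINK_RANKS = {274: 1.5, 277: 1.5, 262: 3.5, 281: 3.5, 266: 5.5, 270: 5.5}
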