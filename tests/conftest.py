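import pytest
from hypothesis import HealthCheck, settings

from morna import (
    GenomicInterval,
    MatureMir,
    PriMirLocus,
    QuantParams,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def plus_locus() -> PriMirLocus:
    """A plus-strand pri-miR with both arms at the worked-example coordinates."""
    return PriMirLocus(
        "mir-x",
        GenomicInterval("chr1", 990, 1090, "+"),
        mature_5p=MatureMir("mir-x-5p", "5p", GenomicInterval("chr1", 1000, 1022, "+")),
        mature_3p=MatureMir("mir-x-3p", "3p", GenomicInterval("chr1", 1060, 1082, "+")),
    )


@pytest.fixture
def default_params() -> QuantParams:
    return QuantParams()
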