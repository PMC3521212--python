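import pytest
from hypothesis import settings

from tcomplex.types import PhaseLabel, PhaseLabelTable

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

# The Cdc28 cluster with its published phase labels: one static kinase and
# nine cyclin partners peaking across the cycle.
CDC28_LABELS = {
    "Ybr160w": "Static",
    "Ygr108w": "M",
    "Ypr119w": "G2",
    "Ydl155w": "S",
    "Ylr210w": "S",
    "Ypr120c": "G1",
    "Ygr109c": "G1",
    "Ymr199w": "G1/S",
    "Ypl256c": "G1",
    "Yal040c": "M",
}


@pytest.fixture
def cdc28_labels() -> PhaseLabelTable:
    return PhaseLabelTable(
        {p: PhaseLabel.parse(s) for p, s in CDC28_LABELS.items()}
    )


@pytest.fixture
def cdc28_members() -> frozenset:
    return frozenset(CDC28_LABELS)
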