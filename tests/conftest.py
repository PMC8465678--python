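import numpy as np
import pytest

from mdlinker.io_formats import MeshEntry, SequenceRecord
from mdlinker.node_features import FeatureTable


@pytest.fixture
def toy_mesh() -> list[MeshEntry]:
    """A small two-branch hierarchy with named and anonymous positions."""
    return [
        MeshEntry("root disease", ("C01",)),
        MeshEntry("mid disease", ("C01.1",)),
        MeshEntry("leaf a", ("C01.1.1",)),
        MeshEntry("leaf b", ("C01.1.2",)),
        MeshEntry("other branch", ("C02.5",)),  # C02 itself is anonymous
    ]


@pytest.fixture
def toy_sequences() -> list[SequenceRecord]:
    return [
        SequenceRecord("mir-a", "ACGUACGUACGU"),
        SequenceRecord("mir-b", "ACGUACGUACGA"),
        SequenceRecord("mir-c", "GGGGGGGGCCCC"),
    ]


def random_features(labels: list[str], ne: int, seed: int) -> FeatureTable:
    rng = np.random.default_rng(seed)
    return FeatureTable(tuple(labels), rng.normal(0, 0.1, (len(labels), ne)))
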