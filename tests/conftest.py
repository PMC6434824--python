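import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from boolrepair import parse_model, parse_timeseries


@pytest.fixture
def table2_model():
    """Three inputs driving d via (!a & b) | (!a & !c)."""
    return parse_model("d = (!a & b) | (!a & !c)\n")


@pytest.fixture
def and_gate_model():
    """Inputs b, c driving d via b & c."""
    return parse_model("d = b & c\n")


@pytest.fixture
def steady_conflict_series():
    """Single-column steady observation b=1, c=0, d=1 (d unexplainable by b&c)."""
    return parse_timeseries("comp\t0\nb\t1\nc\t0\nd\t1\n", experiment="e1")


@pytest.fixture
def cycle4_model():
    """Four components, four positive edges, one feedback cycle."""
    return parse_model("b = c & d\nc = a\na = b\nd = b\n")
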