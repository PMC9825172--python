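import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from coilscape.core import ExpressionMatrix, SampleSeries, TranscriptionUnit


@pytest.fixture
def samples4():
    return SampleSeries(("s1", "s2", "s3", "s4"), (-2.0, -1.0, 1.0, 2.0))


@pytest.fixture
def small_matrix(samples4):
    values = np.array(
        [
            [1.0, 1.0, 4.0, 4.0],
            [2.0, 2.0, 2.0, 2.0],
            [8.0, 8.0, 2.0, 2.0],
        ]
    )
    return ExpressionMatrix(["gA", "gB", "gC"], samples4, values, unit="TPM")


@pytest.fixture
def toy_tu():
    def make(tu_id="TU1", strand="+", tss=50, genes=("gA", "gB"),
             replicon="chr", replicon_class="chromosome"):
        return TranscriptionUnit(tu_id, replicon, replicon_class, strand, tss,
                                 tuple(genes))

    return make
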