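import pytest

from hknot import RnaSequence, TuningParams

#: 22-nt pseudoknotted sequence used in the worked decoration example.
WORKED_SEQ = "UCAAAUGGACAUAGCAUAACAU"
WORKED_FINAL = "((..[[[))..((...)).]]]"


@pytest.fixture
def worked_seq() -> RnaSequence:
    return RnaSequence(WORKED_SEQ)


@pytest.fixture
def default_params() -> TuningParams:
    return TuningParams()
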