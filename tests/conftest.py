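import warnings

import pytest

from ssuintrons import reference

warnings.filterwarnings("ignore", message=".*end_gap_score.*")


@pytest.fixture(scope="session")
def ref():
    return reference.load_reference()


@pytest.fixture(scope="session")
def canonical():
    return sorted(reference.CANONICAL_LOCI)
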