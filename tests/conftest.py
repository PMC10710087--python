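import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from linamp.params import default_parameters


@pytest.fixture(scope="session")
def defaults():
    """Packaged default circuit calibration."""
    return default_parameters()
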