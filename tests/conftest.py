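import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from mtdrift.synthetic import SynthEffectConfig, gen_effect_tables


@pytest.fixture(scope="session")
def effect_table():
    """Default synthetic deletion-collection effect table (seeded)."""
    return gen_effect_tables(SynthEffectConfig())
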