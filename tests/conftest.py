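import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from kdsd.kg import build_kg
from kdsd.synth import SynthConfig, generate_records, generate_world


@pytest.fixture(scope="session")
def small_cfg():
    return SynthConfig(n_syndromes=5, n_symptom_vocab=20, n_chief_vocab=10,
                       n_nature_labels=4, n_location_labels=4,
                       symptoms_per_syndrome=4, chiefs_per_syndrome=2,
                       n_records=120, seed=3)


@pytest.fixture(scope="session")
def small_world(small_cfg):
    return generate_world(small_cfg)


@pytest.fixture(scope="session")
def small_records(small_world, small_cfg):
    return generate_records(small_world, small_cfg)


@pytest.fixture(scope="session")
def small_kg(small_records, small_world):
    return build_kg(small_records, small_world.nature_lexicon,
                    small_world.location_lexicon,
                    chief_lexicon=small_world.chief_lexicon)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
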