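import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from httguard.io_formats import SeqRecord

BASES = "ACGT"


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_seq(rng, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def random_seq_factory(rng):
    def make(n: int) -> str:
        return random_seq(rng, n)

    return make


def mutate_subs(rng, seq: str, n_subs: int) -> str:
    """Mutate exactly n_subs distinct positions to a different base."""
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    chars = list(seq)
    for p in positions:
        alts = [b for b in BASES if b != chars[p]]
        chars[p] = alts[int(rng.integers(0, 3))]
    return "".join(chars)


@pytest.fixture
def toy_scenario():
    """Small HTT scenario shared by unit tests (cheap to build)."""
    from httguard.simfixtures import ScenarioConfig, build_scenario

    cfg = ScenarioConfig(
        seed=7,
        scenario="HTT",
        genome_length=15000,
        n_copies_donor=6,
        n_copies_recipient=6,
        te_length=900,
        paired_coverage=4,
        long_read_coverage=2,
        long_read_mean=2500,
    )
    return build_scenario(cfg)
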