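import random

import pytest

from symbiocomp import CommunitySpec, ScoringScheme, generate_community


@pytest.fixture(scope="session")
def scoring():
    return ScoringScheme()


@pytest.fixture(scope="session")
def small_community():
    """One deterministic 10+10 community shared by cheap tests."""
    spec = CommunitySpec(n_host=10, n_symbiont=10, seed=42)
    return generate_community(spec)


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))
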