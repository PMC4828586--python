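from __future__ import annotations

import random

import pytest
from hypothesis import HealthCheck, settings

from cnvburden.model import CnvCall

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20_22)


def random_call(rng: random.Random, sample_id: str = "S", chrom: str = "22") -> CnvCall:
    start = rng.randrange(1, 50_000_000)
    length = rng.randrange(10_000, 2_000_000)
    return CnvCall(
        sample_id=sample_id,
        chrom=chrom,
        start=start,
        end=start + length - 1,
        copy_number=rng.choice([0, 1, 2, 3, 4]),
        num_snps=rng.randrange(10, 800),
    )
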