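import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from replikit.synth import (  # noqa: E402
    FusionEvent,
    MatePairLibrarySpec,
    RepeatElement,
    RepeatPlacement,
    RepliconSpec,
    apply_fusion,
    generate_genome,
)

# small-library settings used by most fixtures: short inserts let the
# chromosome stay small and the tests fast while preserving every structural
# property of the long-insert protocol
SMALL_LIB = dict(insert_min=400, insert_max=1200, read_length=100)


@pytest.fixture(scope="session")
def small_specs():
    return [
        RepliconSpec("chr", 20_000, 1.0, is_chromosome=True),
        RepliconSpec("pA", 8_000, 2.0),
        RepliconSpec("pX", 5_000, 2.0),
    ]


@pytest.fixture(scope="session")
def shared_repeat():
    return RepeatElement(
        "tnp1",
        (
            RepeatPlacement("chr", 9_001, 10_000),
            RepeatPlacement("pA", 3_001, 4_000),
        ),
    )


@pytest.fixture(scope="session")
def wt_genome(small_specs, shared_repeat):
    return generate_genome(small_specs, [shared_repeat], seed=11)


@pytest.fixture(scope="session")
def fused_genome(wt_genome, shared_repeat):
    event = FusionEvent(
        donor="pA", acceptor="chr",
        donor_repeat=shared_repeat.placements[1],
        acceptor_repeat=shared_repeat.placements[0],
        crossover_offset=444,
    )
    return apply_fusion(wt_genome, event)


@pytest.fixture(scope="session")
def plain_genome():
    """Repeat-free two-replicon genome for unambiguous-mapping tests."""
    specs = [
        RepliconSpec("chr", 20_000, 1.0, is_chromosome=True),
        RepliconSpec("pA", 6_000, 3.0),
    ]
    return generate_genome(specs, [], seed=5)


def small_lib(**kw) -> MatePairLibrarySpec:
    args = dict(SMALL_LIB)
    args.update(kw)
    return MatePairLibrarySpec(**args)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
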