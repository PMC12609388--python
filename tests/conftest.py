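import numpy as np
import pytest
from hypothesis import settings

from virafall import GeneratorConfig, SkeletonSequence, generate_sequences
from virafall.core import Convention

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# desk-scale generator settings shared across tests: 10 fps keeps the
# slowest motif inside an 80-frame clip while all kinematic contrasts
# (descent-duration bands, floor persistence) survive the down-sampling
DESK_FPS = 10.0
DESK_FRAMES = 80


def desk_config(**overrides) -> GeneratorConfig:
    base = dict(
        n_sequences=40,
        fall_fraction=0.5,
        domain="fast_fall",
        frame_len=DESK_FRAMES,
        fps=DESK_FPS,
        noise_sd=0.01,
        seed=0,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fast_sequences():
    return generate_sequences(desk_config(n_sequences=40, seed=11))


@pytest.fixture()
def one_sequence(fast_sequences):
    return fast_sequences[0].copy()


def random_sequence(rng, t=30, convention=Convention.COCO17, label=0):
    v = convention.num_joints
    return SkeletonSequence(
        coords=rng.normal(size=(t, v, 3)),
        label=label,
        convention=convention,
        source_id=f"rand-{rng.integers(1 << 30)}",
    )
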