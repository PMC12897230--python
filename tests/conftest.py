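from __future__ import annotations

import numpy as np
import pytest

from foveoct import DenoiserConfig, PhantomSpec, add_speckle, generate_phantom, train_self_supervised

# Desk-scale phantom for denoiser work: a 16-slice miniature retina at the
# denoiser's native working resolution.


def small_phantom_spec(seed: int, depth: int = 16, **overrides) -> PhantomSpec:
    fields = dict(
        D=depth,
        H=64,
        W=64,
        pit_slice=depth // 2,
        retina_top_row=22,
        retina_bottom_row=48,
        pit_depth_px=7.0,
        pit_halfwidth_px=4.0,
        pit_axial_sigma_slices=2.0,
        bottom_wobble_px=3.0,
        seed=seed,
    )
    fields.update(overrides)
    return PhantomSpec(**fields)


def speckled_small_phantom(seed: int, depth: int = 16, **overrides):
    stack, pit = generate_phantom(small_phantom_spec(seed, depth, **overrides))
    return add_speckle(stack, "multiplicative_gamma", L=4.0, seed=10_000 + seed), pit


@pytest.fixture(scope="session")
def desk_denoiser():
    """Denoiser trained once per session under the default desk conditions:

    default config (16x64x64 input, patch (2,4,4), embed 48, 2x2 blocks),
    8 speckled phantoms, 5 epochs, fixed seed.  Shared by the training-
    convergence, inference and restoration-benefit tests.
    """
    volumes = [speckled_small_phantom(seed)[0] for seed in range(8)]
    config = DenoiserConfig(seed=0, epochs=5)
    model, report = train_self_supervised(volumes, config)
    return model, report


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
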