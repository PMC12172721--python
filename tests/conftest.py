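"""Shared fixtures: small seeded synthetic cohorts and atlases.

Session scope keeps the expensive cohort simulations to one run each.
"""

import dataclasses

import numpy as np
import pytest

import volmatch as vm
from volmatch.preprocess import normalize_stack

DESK_GRID = (32, 38, 32)
TINY_GRID = (14, 16, 14)


@pytest.fixture(scope="session")
def tiny_atlas():
    """4-region atlas on a very small grid for fast unit tests."""
    return vm.build_atlas(TINY_GRID, 4, seed=0)


@pytest.fixture(scope="session")
def desk_atlas():
    """17-region atlas at the desk-scale grid."""
    return vm.build_atlas(DESK_GRID, 17, seed=0)


@pytest.fixture(scope="session")
def ship600(desk_atlas):
    """Default-effects large-cohort profile at n=600, with normalized stack."""
    cohort = vm.simulate_cohort(vm.SHIP_PROFILE, seed=1, n=600,
                                atlas=desk_atlas)
    frame = cohort.frame()
    norm = normalize_stack(cohort.images, desk_atlas.mask)
    return cohort, frame, norm


@pytest.fixture(scope="session")
def tiny_cohort(tiny_atlas):
    """n=120 cohort on the tiny grid with one strongly planted region."""
    effects = vm.default_effects(tiny_atlas, vm.SHIP_PROFILE, seed=2)
    effects.sex_effect[:] = 0.0
    effects.sex_effect[1] = 0.3
    cohort = vm.simulate_cohort(vm.SHIP_PROFILE, seed=3, n=120,
                                atlas=tiny_atlas, effects=effects)
    frame = cohort.frame()
    norm = normalize_stack(cohort.images, tiny_atlas.mask)
    return cohort, frame, norm
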