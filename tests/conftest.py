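import numpy as np
import pytest

from motifthread.fixtures import (FixtureSpec, make_planted_potential,
                                  make_toy_complex)
from motifthread.structio import curate_complex


@pytest.fixture
def toy_spec():
    return FixtureSpec(seed=1, duplex_length=9, contact_positions=(2, 3, 4),
                       planted_kmer="ACG")


@pytest.fixture
def toy_complex(toy_spec):
    return make_toy_complex(toy_spec)


@pytest.fixture
def toy_curated(toy_complex):
    return curate_complex(toy_complex)


@pytest.fixture
def planted_potential(toy_spec):
    pot, kmer = make_planted_potential(toy_spec)
    return pot


def brute_force_min_distance(coords_a, coords_b):
    """O(n*m) oracle for the closest approach between two atom sets."""
    best = np.inf
    for a in coords_a:
        for b in coords_b:
            best = min(best, float(np.linalg.norm(a - b)))
    return best


def random_rigid_transform(rng):
    """A uniformly random proper rotation plus a random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    trans = rng.uniform(-20, 20, size=3)
    return rot, trans
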