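import numpy as np
import pytest

from confland import synthgen


@pytest.fixture(scope="session")
def generator():
    """3-macrostate / 12-microstate metastable generator, timescales 80 and 15 steps."""
    return synthgen.make_generator(3, 12, [80.0, 15.0], seed=7)


@pytest.fixture(scope="session")
def traj_set(generator):
    """Medium trajectory swarm: 50 trajectories x 2000 steps in 10 seed groups."""
    return synthgen.sample_trajectories(generator, 50, 2000, n_groups=10, seed=11)


@pytest.fixture(scope="session")
def bead_ensemble():
    """Bead chain with two base contacts and one perturbed contact, 10+10 frames."""
    return synthgen.make_bead_chain_ensemble(
        12,
        base_contacts={(0, 5), (2, 9)},
        perturbed_contacts={(1, 8)},
        n_frames_base=10,
        n_frames_perturbed=10,
        seed=3,
    )


@pytest.fixture(scope="session")
def micro_truth(generator):
    """Exact microstate chain implied by the generator (disjoint emissions)."""
    T = synthgen.micro_transition_matrix(generator)
    pi = synthgen.micro_stationary_distribution(generator)
    return T, pi


def permuted_max_error(A, B):
    """min over label permutations of max|A[p][:,p] - B| for small matrices."""
    from itertools import permutations

    n = A.shape[0]
    return min(
        np.max(np.abs(A[np.ix_(p, p)] - B)) for p in permutations(range(n))
    )
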