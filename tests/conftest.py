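import numpy as np
import pytest

from fmtunmix import (
    OpticalProperties,
    TimeCourse,
    simulate_dynamic_measurements,
)


@pytest.fixture(scope="session")
def muscle_optics():
    # muscle-like soft tissue at NIR wavelengths
    return OpticalProperties(mu_a_x=0.02, mu_s_prime_x=1.0,
                             mu_a_m=0.02, mu_s_prime_m=1.0)


@pytest.fixture(scope="session")
def absorbing_optics():
    # liver-like, strongly absorbing: keeps distant inclusions optically
    # well separated on a small phantom
    return OpticalProperties(mu_a_x=0.16, mu_s_prime_x=0.578,
                             mu_a_m=0.124, mu_s_prime_m=0.542)


@pytest.fixture
def three_pixel_stack():
    """Hand-solvable instance: frames mix s1=(2,0,1), s2=(0,2,1) with
    convex weights; the sum-normalized affine hull is the segment
    {(1+t, 1-t, 1)/3 : t in [-1, 1]} with the sources at its endpoints."""
    S = np.array([[2.0, 0.0, 1.0], [0.0, 2.0, 1.0]])
    W = np.array([[0.5, 0.5], [0.8, 0.2], [0.2, 0.8]])
    courses = [TimeCourse(times=np.array([1.0, 2.0, 3.0]), values=W[:, p])
               for p in range(2)]
    stack = simulate_dynamic_measurements(S, courses)
    return stack, S, W


def nse_per_source(comparison, truth):
    """Per-source normalized squared errors of a MatchedComparison."""
    from fmtunmix import max_normalize
    out = []
    for err, j in zip(comparison.per_source_errors, comparison.permutation):
        out.append(err / np.sum(max_normalize(truth[j]) ** 2))
    return out
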