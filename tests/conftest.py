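import numpy as np
import pytest

from icdc import enm, fixtures, response


@pytest.fixture(scope="session")
def square():
    """Planar unit square; pseudo-inversion needs threshold null-space mode."""
    return fixtures.make_square()


@pytest.fixture(scope="session")
def ring6():
    return fixtures.make_ring(6)


@pytest.fixture(scope="session")
def dumbbell():
    """The canonical compact dumbbell: 18 residues, linker at 0-based indices 8, 9."""
    return fixtures.make_dumbbell(8, seed=0)


@pytest.fixture(scope="session")
def dumbbell_kernel(dumbbell):
    return enm.invert_kernel(enm.build_hessian(dumbbell))


@pytest.fixture(scope="session")
def dumbbell_responses(dumbbell_kernel):
    return response.scan_responses(dumbbell_kernel)


def square_hessian_oracle(coords, cutoff, gamma):
    """Independent brute-force Hessian assembly straight from the definition."""
    n = len(coords)
    h = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            v = coords[j] - coords[i]
            d2 = float(v @ v)
            if d2 > cutoff**2:
                continue
            block = -(gamma / d2) * np.outer(v, v)
            h[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
            h[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
    return h
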