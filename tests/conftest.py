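import numpy as np
import pytest

from retipath import default_field


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def field3():
    return default_field(3)


@pytest.fixture
def field5():
    return default_field(5)


def brute_force_valid_convolve(plane, kernel):
    """Independent oracle: nested-loop valid-region correlation,
    accumulated left-to-right in row-major kernel order."""
    plane = np.asarray(plane, dtype=float)
    s = kernel.shape[0]
    h, w = plane.shape
    out = np.zeros((h - s + 1, w - s + 1))
    for oy in range(h - s + 1):
        for ox in range(w - s + 1):
            acc = 0.0
            for ky in range(s):
                for kx in range(s):
                    acc += kernel[ky, kx] * plane[oy + ky, ox + kx]
            out[oy, ox] = acc
    return out
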