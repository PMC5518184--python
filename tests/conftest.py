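import numpy as np
import pytest

from aposematrix import synthetic, visual


@pytest.fixture(scope="session")
def sensors():
    return synthetic.default_sensor_sets()


@pytest.fixture(scope="session")
def receptors(sensors):
    return sensors[0]


@pytest.fixture(scope="session")
def camera(sensors):
    return sensors[1]


@pytest.fixture(scope="session")
def illuminant():
    return synthetic.d65_like_illuminant()


@pytest.fixture(scope="session")
def noise(receptors):
    return visual.noise_ratios(receptors)


def rnl_quadratic_oracle(qa, qb, omega):
    """Independent receptor-noise distance: Delta S^2 = df' A df with
    A = W - W 1 (1' W 1)^-1 1' W and W = diag(1/omega^2).

    This is the generic quadratic form of the receptor-noise-limited
    model (inverse-noise weighting with the achromatic direction
    projected out); it is kept separate from the closed-form production
    implementation on purpose.
    """
    qa = np.asarray(qa, float)
    qb = np.asarray(qb, float)
    w = 1.0 / np.asarray(omega, float) ** 2
    A = np.diag(w) - np.outer(w, w) / w.sum()
    df = np.log(qa) - np.log(qb)
    return float(np.sqrt(df @ A @ df))


@pytest.fixture(scope="session")
def rnl_oracle():
    return rnl_quadratic_oracle
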