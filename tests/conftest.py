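import numpy as np
import pytest

from fgskinetics.plasma import PlasmaInput


@pytest.fixture(scope="session")
def peptide_plasma():
    return PlasmaInput(A=0.02, alpha=0.3, B=2e-3, beta=6e-4)


@pytest.fixture(scope="session")
def affibody_plasma():
    return PlasmaInput(A=0.6, alpha=0.2, B=0.4, beta=5e-3)


@pytest.fixture(scope="session")
def quasi_constant_plasma():
    # effectively constant unit input over a few hundred minutes
    return PlasmaInput(A=1.0, alpha=1e-9, B=0.0, beta=1e-9)


@pytest.fixture
def minute_grid():
    return np.arange(0.0, 60.0 + 1e-9, 0.25)


def rk4_two_compartment(K1, k2, k3, k4, plasma, t_end, h=1e-3):
    """Independent fixed-step 4th-order Runge-Kutta oracle for the targeted
    two-compartment model; returns (times, free, bound) on the step grid."""
    n = int(round(t_end / h))
    times = np.linspace(0.0, n * h, n + 1)
    cf = np.zeros(n + 1)
    cb = np.zeros(n + 1)

    def f(ti, y):
        cp = plasma.scale * (
            plasma.A * np.exp(-plasma.alpha * ti) + plasma.B * np.exp(-plasma.beta * ti)
        )
        return np.array(
            [K1 * cp - (k2 + k3) * y[0] + k4 * y[1], k3 * y[0] - k4 * y[1]]
        )

    y = np.zeros(2)
    for i in range(n):
        ti = times[i]
        k_1 = f(ti, y)
        k_2 = f(ti + h / 2, y + h / 2 * k_1)
        k_3 = f(ti + h / 2, y + h / 2 * k_2)
        k_4 = f(ti + h, y + h * k_3)
        y = y + h / 6 * (k_1 + 2 * k_2 + 2 * k_3 + k_4)
        cf[i + 1], cb[i + 1] = y
    return times, cf, cb
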