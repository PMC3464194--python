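import numpy as np
import pytest

from rewardctl.plants import (
    FilteredPointSpec,
    PlanarArmSpec,
    PointMassSpec,
    object_iiia,
    object_iiib,
)


@pytest.fixture(scope="session")
def point_mass():
    return PointMassSpec()


@pytest.fixture(scope="session")
def filtered_point():
    return FilteredPointSpec()


@pytest.fixture(scope="session")
def arm_a():
    return object_iiia()


@pytest.fixture(scope="session")
def arm_b():
    return object_iiib()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def discrete_qp_effort(A, B, x0, xstar, T, gamma, N=1500):
    """Independent oracle: discounted minimum-effort connection by direct
    discretisation (ZOH) and equality-constrained least squares."""
    from scipy.linalg import expm

    n = A.shape[0]
    m = B.shape[1]
    h = T / N
    C = np.zeros((n + m, n + m))
    C[:n, :n] = A * h
    C[:n, n:] = B * h
    F = expm(C)
    Ad, Bd = F[:n, :n], F[:n, n:]
    cols = []
    P = np.eye(n)
    for _ in range(N):
        cols.append(P @ Bd)
        P = P @ Ad
    E = np.hstack(list(reversed(cols)))          # (n, N*m)
    w = np.repeat(np.exp(-np.arange(N) * h / gamma) * h, m)
    d = np.asarray(xstar) - P @ np.asarray(x0)
    M2 = (E / w[None, :]) @ E.T
    lam = np.linalg.solve(M2, d)
    u = (E / w[None, :]).T @ lam
    return float(np.sum(w * u * u))
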