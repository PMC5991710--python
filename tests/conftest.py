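import numpy as np
import pytest

from sizespectra import (ModelParams, build_grid, build_operators,
                         initial_state, run)


@pytest.fixture(scope="session")
def basic_grid():
    """Reference 50-class grid: egg mass 1 mg, ratio 1.5, 37 imaginary steps."""
    return build_grid(m2=0.001, delta=1.5, k=50, s=37)


@pytest.fixture(scope="session")
def basic_ops(basic_grid):
    return build_operators(basic_grid, ModelParams())


@pytest.fixture(scope="session")
def basic_run(basic_grid, basic_ops):
    """The 40-year reference integration, shared across tests (deterministic)."""
    return run(initial_state(basic_grid, 0.01), basic_ops, years=40.0,
               record_interval=1.0)


@pytest.fixture()
def toy_grid():
    """3-class doubling grid with masses (0.5, 1, 2) g."""
    return build_grid(m2=1.0, delta=2.0, k=3, s=0)


def brute_force_increments(n, grid, params, S, h=None, dt=None):
    """Index-by-index reimplementation of the four process increments.

    Pure double loops over predator-prey pairs and classes, no matrix
    algebra; serves as the independent oracle for the dynamics module.
    ``S`` is passed explicitly so prescribed toy kernels can be used.
    """
    dt = params.dt if dt is None else dt
    k = grid.k
    m = list(grid.m)
    m_up = m[1:] + [grid.m_kplus1]
    h = [0.0] * k if h is None else list(h)
    e, alpha = params.e, params.alpha

    # predation: P[i][j] prey eaten, per step
    P = [[0.0] * k for _ in range(k)]
    for i in range(k):
        for j in range(k):
            P[i][j] = n[j] * params.gamma * m[i] ** params.p * S[i][j] * n[i] * dt
    removal = [sum(P[i][j] for i in range(k)) for j in range(k)]
    G = [e * sum(m[j] * P[i][j] for j in range(k)) / (m_up[i] - m[i]) for i in range(k)]
    dnG = [0.0] * k
    for i in range(k):
        dnG[i] -= G[i]
        if i + 1 < k:
            dnG[i + 1] += G[i]
    dnG[0] += G[k - 1] * grid.m_kplus1 / m[0]          # carrion from class k+1
    egesta = sum((1 - e) * m[j] * P[i][j] for i in range(k) for j in range(k))
    dnE = [0.0] * k
    dnE[0] = egesta / m[0]
    dnP = [-removal[i] + dnG[i] + dnE[i] for i in range(k)]

    # reproduction: rate F_i = c*m_i**r for classes >= 3 (index >= 2)
    F = [params.c * m[i] ** params.r if i >= 2 else 0.0 for i in range(k)]
    dnR = [0.0] * k
    for i in range(k):
        flux = F[i] * n[i] * dt                        # egg biomass, g per step
        dnR[1] += alpha * flux / m[1]                  # eggs into class 2
        dnR[0] += (1 - alpha) * flux / m[0]            # semen recycled
        B = F[i] * n[i] / (m[i] - (m[i - 1] if i > 0 else 0.0)) * dt
        dnR[i] -= B
        if i > 0:
            dnR[i - 1] += B

    # metabolism: rate W_i = v*m_i**q for consumers (index >= 1)
    W = [params.v * m[i] ** params.q if i >= 1 else 0.0 for i in range(k)]
    dnQ = [0.0] * k
    for i in range(k):
        flux = W[i] * n[i] * dt
        dnQ[0] += flux / m[0]
        L = W[i] * n[i] / (m[i] - (m[i - 1] if i > 0 else 0.0)) * dt
        dnQ[i] -= L
        if i > 0:
            dnQ[i - 1] += L

    # non-predation + fishing mortality, carrion/catch recycled
    z0, z = params.z0, params.z
    dnU = [0.0] * k
    for i in range(k):
        rate = (n[i] * z0 * m[i] ** (-z) if i >= 1 else 0.0) + h[i]
        loss = rate * n[i] * dt
        dnU[i] -= loss
        dnU[0] += loss * m[i] / m[0]
    return (np.array(dnP), np.array(dnR), np.array(dnQ), np.array(dnU))
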