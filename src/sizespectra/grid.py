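"""Logarithmic body-mass grid, model parameters and community state.

The community is discretized into ``k`` size classes whose body masses form a
geometric series with ratio ``delta``: class 1 holds the background resources,
classes 2..k the consumers, with class 2 pinned to the egg mass ``m2``.  Below
class 1 an *imaginary* resource range (classes ``-s..0``) extends the prey-size
axis so that small consumers see a full spectrum of prey inside the feeding
kernel; imaginary classes carry no abundance.  One extra imaginary class
``k+1`` above the grid receives individuals growing out of the top class, whose
biomass is recycled as carrion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SizeGrid",
    "ModelParams",
    "CommunityState",
    "build_grid",
    "initial_state",
]


@dataclass(frozen=True)
class SizeGrid:
    """Discretized body-mass axis.

    Attributes
    ----------
    k : int
        Number of real size classes (resources + consumers).
    delta : float
        Mass ratio of successive size classes, ``m_{i+1} = m_i * delta``.
    m : ndarray of shape (k,)
        Body masses of the real classes in grams.
    s : int
        Number of imaginary resource steps below class 0 (imaginary classes
        are indexed ``-s..0``, i.e. ``s + 1`` masses).
    m_imag : ndarray of shape (s + 1,)
        Masses of the imaginary resource classes, ``m_x = m_1 * delta**(x-1)``.
    m_kplus1 : float
        Mass of the imaginary class above the grid, ``m_k * delta``.
    """

    k: int
    delta: float
    m: np.ndarray
    s: int
    m_imag: np.ndarray
    m_kplus1: float

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError(f"need at least 3 size classes, got k={self.k}")
        if not self.delta > 1:
            raise ValueError(f"mass ratio delta must exceed 1, got {self.delta}")
        m = np.asarray(self.m, dtype=float)
        if m.shape != (self.k,) or not np.all(m > 0) or not np.all(np.diff(m) > 0):
            raise ValueError("masses must be k strictly positive increasing values")
        ratios = m[1:] / m[:-1]
        if not np.allclose(ratios, self.delta, rtol=1e-12, atol=0):
            raise ValueError("masses do not form a geometric series with ratio delta")
        if not np.isclose(self.m_imag[-1] * self.delta, m[0], rtol=1e-12):
            raise ValueError("imaginary class 0 must sit one delta-step below class 1")
        if not np.isclose(self.m_kplus1, m[-1] * self.delta, rtol=1e-12):
            raise ValueError("m_kplus1 must equal m_k * delta")


@dataclass(frozen=True)
class ModelParams:
    """Rate coefficients and exponents of the community model.

    Defaults are the reference parameterization: allometric searching rate
    ``gamma * m**p`` (m^3 yr^-1), lognormal feeding kernel of width ``sigma``
    around the preferred predator-prey mass ratio ``upsilon * m**tau``,
    metabolic rate ``v * m**q`` (yr^-1 scale), density-dependent non-predation
    mortality ``n_i * (mu0/ks) * m**(f-d)`` built from the allometric natural
    mortality ``mu0 * m**-d`` and carrying capacity ``ks * m**-f``,
    reproduction rate ``c * m**r`` split between eggs (female share ``alpha``,
    into class 2) and recycled semen, assimilation efficiency ``e``,
    catchability ``q0``, and Euler time step ``dt`` in years.
    """

    gamma: float = 600.0
    p: float = 0.75
    upsilon: float = 100.0
    tau: float = 0.0
    sigma: float = 1.3
    v: float = 2.4
    q: float = 0.75
    mu0: float = 0.6
    d: float = 0.25
    ks: float = 0.0015
    f: float = 1.15
    c: float = 10.0
    r: float = 0.75
    alpha: float = 0.5
    e: float = 0.6
    q0: float = 0.1
    dt: float = 0.001

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError(f"sex ratio alpha must lie in [0, 1], got {self.alpha}")
        if not 0 < self.e <= 1:
            raise ValueError(f"assimilation efficiency must lie in (0, 1], got {self.e}")
        if not self.dt > 0:
            raise ValueError(f"time step dt must be positive, got {self.dt}")
        if self.sigma <= 0:
            raise ValueError(f"kernel width sigma must be positive, got {self.sigma}")
        if self.upsilon <= 0:
            raise ValueError(f"PPMR factor upsilon must be positive, got {self.upsilon}")
        if self.gamma <= 0:
            raise ValueError(f"searching factor gamma must be positive, got {self.gamma}")
        for name in ("v", "c", "mu0", "ks", "q0"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be non-negative")

    @property
    def z0(self) -> float:
        """Density-dependent mortality factor mu0 / ks."""
        return self.mu0 / self.ks

    @property
    def z(self) -> float:
        """Density-dependent mortality exponent d - f."""
        return self.d - self.f

    def with_(self, **overrides: float) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **overrides)


@dataclass
class CommunityState:
    """Abundance vector (individuals per m^3 per class) at model time t (years)."""

    n: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        if self.n.ndim != 1:
            raise ValueError("abundance must be a 1-D vector")
        if np.any(self.n < 0):
            raise ValueError("abundances must be non-negative")

    def copy(self) -> "CommunityState":
        return CommunityState(self.n.copy(), self.t)


def build_grid(m2: float, delta: float, k: int, s: int) -> SizeGrid:
    """Construct the geometric size grid from the egg mass of class 2.

    Class 2 has mass ``m2``; class 1 (resources) has mass ``m2/delta``; real
    class ``i`` has mass ``m2 * delta**(i-2)``.  Imaginary resource classes
    ``x = -s..0`` have masses ``m_1 * delta**(x-1)``.

    Parameters
    ----------
    m2 : float
        Egg mass (mass of size class 2) in grams; must be positive.
    delta : float
        Mass ratio of successive classes; must exceed 1.
    k : int
        Number of real size classes; at least 3.
    s : int
        Number of imaginary steps below class 0 (``s >= 0``).
    """
    if m2 <= 0:
        raise ValueError(f"egg mass m2 must be positive, got {m2}")
    if delta <= 1:
        raise ValueError(f"mass ratio delta must exceed 1, got {delta}")
    if k < 3:
        raise ValueError(f"need at least 3 size classes, got k={k}")
    if s < 0:
        raise ValueError(f"imaginary class count s must be non-negative, got {s}")
    m = m2 * delta ** np.arange(-1.0, k - 1)
    x = np.arange(-s, 1, dtype=float)
    m_imag = m[0] * delta ** (x - 1)
    return SizeGrid(k=k, delta=delta, m=m, s=s, m_imag=m_imag,
                    m_kplus1=m[-1] * delta)


def initial_state(grid: SizeGrid, a0: float = 0.01) -> CommunityState:
    """Equal-biomass initial condition ``n_i = a0 / m_i`` at t = 0.

    Every class starts with biomass ``a0`` g/m^3, so the initial spectrum is an
    exact power law of slope -1 with total biomass ``a0 * k``.
    """
    if a0 <= 0:
        raise ValueError(f"abundance scale a0 must be positive, got {a0}")
    return CommunityState(a0 / grid.m, t=0.0)
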