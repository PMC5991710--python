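"""Static matrices of the size-structured community model.

All operators are assembled once from a :class:`~sizespectra.grid.SizeGrid`
and :class:`~sizespectra.grid.ModelParams` and treated as immutable; the only
state-dependent diagonals (prey/predator numbers ``N`` and the
density-dependent mortality ``ND``) are rebuilt each step by the dynamics
module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .grid import ModelParams, SizeGrid

__all__ = [
    "OperatorSet",
    "FishingScenario",
    "size_preference",
    "search_matrix",
    "transfer_matrices",
    "mass_difference_matrices",
    "reproduction_matrix",
    "metabolic_matrix",
    "fishing_matrix",
    "build_operators",
]

UNBALANCED_THRESHOLD_G = 1.0e4
BALANCED_THRESHOLD_G = 10.0
BALANCED_EXPONENT = -0.25


@dataclass(frozen=True)
class FishingScenario:
    """Fishing pattern applied through the mortality matrix H.

    ``unbalanced``: constant mortality ``q0*F0`` on classes heavier than
    10^4 g.  ``balanced``: mortality ``q0*F0*m**-0.25`` (proportional to
    natural productivity) on classes heavier than 10 g.  ``none``: H = 0.
    """

    pattern: Literal["none", "unbalanced", "balanced"] = "none"
    F0: float = 0.0
    threshold_mass: float | None = None

    def __post_init__(self) -> None:
        if self.pattern not in ("none", "unbalanced", "balanced"):
            raise ValueError(f"unknown fishing pattern {self.pattern!r}")
        if self.F0 < 0:
            raise ValueError(f"fishing intensity F0 must be non-negative, got {self.F0}")

    @property
    def threshold(self) -> float:
        if self.threshold_mass is not None:
            return self.threshold_mass
        return UNBALANCED_THRESHOLD_G if self.pattern == "unbalanced" else BALANCED_THRESHOLD_G


@dataclass(frozen=True)
class OperatorSet:
    """All static matrices, plus precomposed products used by the stepper.

    S is the strictly lower-triangular feeding-kernel matrix; V the diagonal
    of allometric search rates; Tg/Tc/T1/T2 the transfer matrices for growth,
    carrion recycling, recycling into class 1 and egg deposition into class 2;
    dMplus_inv/dMminus_inv the inverse mass-difference diagonals; R and Q the
    diagonal reproduction and metabolic rate matrices; H the diagonal fishing
    mortality.
    """

    grid: SizeGrid
    params: ModelParams
    scenario: FishingScenario
    S: np.ndarray
    V: np.ndarray
    M: np.ndarray
    M1_inv: np.ndarray
    M2_inv: np.ndarray
    E: np.ndarray
    A: np.ndarray
    R: np.ndarray
    Q: np.ndarray
    Tg: np.ndarray
    Tc: np.ndarray
    T1: np.ndarray
    T2: np.ndarray
    dMplus_inv: np.ndarray
    dMminus_inv: np.ndarray
    H: np.ndarray
    # precomposed pieces (derived, kept for the inner Euler loop)
    gain_P: np.ndarray          # (Tg+Tc)·dM+⁻¹·E + T1·M1⁻¹·(I−E)
    repro_map: np.ndarray       # (T1·M1⁻¹·(I−A) + T2·M2⁻¹·A + Tgᵀ·dM−⁻¹)·R
    metab_map: np.ndarray       # (T1·M1⁻¹ + Tgᵀ·dM−⁻¹)·Q
    v_diag: np.ndarray          # diag of V
    r_diag: np.ndarray          # diag of R
    q_diag: np.ndarray          # diag of Q
    h_diag: np.ndarray          # diag of H
    nd_coeff: np.ndarray        # z0·m**(-z) with zero first entry
    dplus_diag: np.ndarray      # diag of dMplus_inv
    dminus_diag: np.ndarray     # diag of dMminus_inv


def size_preference(grid: SizeGrid, upsilon: float, tau: float,
                    sigma: float) -> np.ndarray:
    """Lognormal size-selectivity matrix ``phi_{i,j}`` (strictly lower triangular).

    For a predator of mass ``m_i`` the preferred predator-prey mass ratio is
    ``beta_i = upsilon * m_i**tau`` and the preference for prey of mass ``m_j``
    is ``exp(-(ln(beta_i*m_j/m_i))**2 / (2*sigma**2))`` — an unnormalized
    lognormal of width ``sigma`` peaking at ``m_i/beta_i``.  Column 1
    aggregates the real resource class and all imaginary resource classes
    ``x = -s..0``, so small consumers see prey below the grid.
    """
    if sigma <= 0:
        raise ValueError(f"kernel width sigma must be positive, got {sigma}")
    if upsilon <= 0:
        raise ValueError(f"PPMR factor upsilon must be positive, got {upsilon}")
    m = grid.m
    k = grid.k
    beta = upsilon * m ** tau
    S = np.zeros((k, k))
    # columns j >= 2 (0-based j >= 1): plain kernel evaluation
    log_ratio = np.log(beta[:, None] * m[None, :] / m[:, None])
    kernel = np.exp(-log_ratio ** 2 / (2.0 * sigma ** 2))
    ii, jj = np.tril_indices(k, -1)
    S[ii, jj] = kernel[ii, jj]
    # column 1 (0-based 0): sum over imaginary classes -s..0 plus real class 1
    prey_masses = np.concatenate([grid.m_imag, m[:1]])
    lr = np.log(beta[:, None] * prey_masses[None, :] / m[:, None])
    col1 = np.exp(-lr ** 2 / (2.0 * sigma ** 2)).sum(axis=1)
    S[1:, 0] = col1[1:]
    return S


def search_matrix(grid: SizeGrid, gamma: float, p: float) -> np.ndarray:
    """Diagonal of allometric search rates ``gamma * m_i**p`` (m^3/yr)."""
    if gamma <= 0:
        raise ValueError(f"searching factor gamma must be positive, got {gamma}")
    return np.diag(gamma * grid.m ** p)


def transfer_matrices(grid: SizeGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Growth (Tg), carrion (Tc), class-1 (T1) and class-2 (T2) transfer matrices.

    Tg moves growing individuals one class up (-1 diagonal, +1 subdiagonal);
    Tc recycles the biomass of individuals growing out of class k as
    ``m_{k+1}/m_1`` resources; T1 funnels any per-class quantity into class 1;
    T2 funnels into class 2 (egg deposition).
    """
    k = grid.k
    Tg = -np.eye(k) + np.diag(np.ones(k - 1), -1)
    Tc = np.zeros((k, k))
    Tc[0, k - 1] = grid.m_kplus1 / grid.m[0]
    T1 = np.zeros((k, k))
    T1[0, :] = 1.0
    T2 = np.zeros((k, k))
    T2[1, :] = 1.0
    return Tg, Tc, T1, T2


def mass_difference_matrices(grid: SizeGrid) -> tuple[np.ndarray, np.ndarray]:
    """Inverse mass-difference diagonals for growth and down-transfer.

    ``dMplus_inv[i] = 1/(m_{i+1} - m_i)`` with ``m_{k+1} = m_k*delta``;
    ``dMminus_inv[i] = 1/(m_i - m_{i-1})`` with the mass below class 1 taken
    as zero, so the first entry is ``1/m_1``.
    """
    m = grid.m
    m_ext_up = np.append(m[1:], grid.m_kplus1)
    dMplus_inv = np.diag(1.0 / (m_ext_up - m))
    m_ext_down = np.concatenate([[0.0], m[:-1]])
    dMminus_inv = np.diag(1.0 / (m - m_ext_down))
    return dMplus_inv, dMminus_inv


def reproduction_matrix(grid: SizeGrid, c: float, r: float) -> np.ndarray:
    """Diagonal reproduction rates ``c * m_i**r`` for classes >= 3, else 0.

    Resources (class 1) and the egg class (class 2) do not reproduce.
    """
    if c < 0:
        raise ValueError(f"reproduction factor c must be non-negative, got {c}")
    rates = c * grid.m ** r
    rates[:2] = 0.0
    return np.diag(rates)


def metabolic_matrix(grid: SizeGrid, v: float, q: float) -> np.ndarray:
    """Diagonal metabolic rates ``v * m_i**q`` for consumers (classes >= 2).

    Resource metabolites recycle within class 1, so entry 1 is zero.
    """
    if v < 0:
        raise ValueError(f"metabolic factor v must be non-negative, got {v}")
    rates = v * grid.m ** q
    rates[0] = 0.0
    return np.diag(rates)


def fishing_matrix(grid: SizeGrid, scenario: FishingScenario, q0: float) -> np.ndarray:
    """Diagonal fishing mortality rates ``h_i`` (1/yr) for the scenario."""
    h = np.zeros(grid.k)
    if scenario.pattern == "unbalanced":
        fished = grid.m > scenario.threshold
        h[fished] = q0 * scenario.F0
    elif scenario.pattern == "balanced":
        fished = grid.m > scenario.threshold
        h[fished] = q0 * scenario.F0 * grid.m[fished] ** BALANCED_EXPONENT
    return np.diag(h)


def build_operators(grid: SizeGrid, params: ModelParams,
                    scenario: FishingScenario | None = None) -> OperatorSet:
    """Assemble every static matrix of the model for one run."""
    scenario = scenario or FishingScenario()
    k = grid.k
    S = size_preference(grid, params.upsilon, params.tau, params.sigma)
    V = search_matrix(grid, params.gamma, params.p)
    M = np.diag(grid.m)
    M1_inv = np.eye(k) / grid.m[0]
    M2_inv = np.eye(k) / grid.m[1]
    E = np.eye(k) * params.e
    A = np.eye(k) * params.alpha
    R = reproduction_matrix(grid, params.c, params.r)
    Q = metabolic_matrix(grid, params.v, params.q)
    Tg, Tc, T1, T2 = transfer_matrices(grid)
    dMplus_inv, dMminus_inv = mass_difference_matrices(grid)
    H = fishing_matrix(grid, scenario, params.q0)

    I = np.eye(k)
    gain_P = (Tg + Tc) @ dMplus_inv @ E + T1 @ M1_inv @ (I - E)
    repro_map = (T1 @ M1_inv @ (I - A) + T2 @ M2_inv @ A + Tg.T @ dMminus_inv) @ R
    metab_map = (T1 @ M1_inv + Tg.T @ dMminus_inv) @ Q
    nd_coeff = params.z0 * grid.m ** (-params.z)
    nd_coeff[0] = 0.0

    return OperatorSet(
        grid=grid, params=params, scenario=scenario,
        S=S, V=V, M=M, M1_inv=M1_inv, M2_inv=M2_inv, E=E, A=A, R=R, Q=Q,
        Tg=Tg, Tc=Tc, T1=T1, T2=T2,
        dMplus_inv=dMplus_inv, dMminus_inv=dMminus_inv, H=H,
        gain_P=gain_P, repro_map=repro_map, metab_map=metab_map,
        v_diag=np.diag(V).copy(), r_diag=np.diag(R).copy(),
        q_diag=np.diag(Q).copy(), h_diag=np.diag(H).copy(),
        nd_coeff=nd_coeff,
        dplus_diag=np.diag(dMplus_inv).copy(),
        dminus_diag=np.diag(dMminus_inv).copy(),
    )
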