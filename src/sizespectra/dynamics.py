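"""Forward-Euler integration of the size-structured community model.

Each step adds four independent increments to the abundance vector —
predator-prey interaction, reproduction, metabolism, and non-predation plus
fishing mortality — every one of which conserves community biomass exactly
(all egesta, carrion, metabolites, semen and catches are recycled as resources
in class 1).  The update is explicit Euler; instead of adaptive stepping, each
step validates that no per-capita transfer probability exceeds one, turning a
too-large time step into a diagnosable error rather than silent instability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import CommunityState
from .operators import OperatorSet

__all__ = [
    "IntegrationError",
    "StepSizeError",
    "ProcessIncrements",
    "Trajectory",
    "predation_increment",
    "reproduction_increment",
    "metabolism_increment",
    "mortality_increment",
    "process_increments",
    "step",
    "run",
    "is_steady",
]


class IntegrationError(RuntimeError):
    """The Euler update produced an invalid state (e.g. negative abundance)."""


class StepSizeError(IntegrationError):
    """A per-capita transfer probability exceeded one within a single step."""

    def __init__(self, process: str, class_index: int, t: float, dt: float):
        self.process = process
        self.class_index = class_index
        self.t = t
        self.dt = dt
        super().__init__(
            f"{process}: per-capita transfer probability exceeds 1 in size class "
            f"{class_index} at t={t:.6g} yr with dt={dt:g} yr; reduce dt"
        )


@dataclass
class ProcessIncrements:
    """The four per-step abundance changes with their diagnostic sub-terms.

    Sub-terms follow the flux bookkeeping of the model graph: prey removal,
    growth with carrion recycling, egesta recycling (predation); eggs/semen
    and parental down-transfer (reproduction); metabolite recycling and
    down-transfer (metabolism); density-dependent death and fishing with their
    recycled carrion/catch (mortality).
    """

    dnP: np.ndarray
    dnR: np.ndarray
    dnQ: np.ndarray
    dnU: np.ndarray
    dnP_predation: np.ndarray = None
    dnG: np.ndarray = None
    dnE: np.ndarray = None
    dnF: np.ndarray = None
    dnB: np.ndarray = None
    dnW: np.ndarray = None
    dnL: np.ndarray = None
    dnD_loss: np.ndarray = None
    dnD_recycle: np.ndarray = None
    dnY_remove: np.ndarray = None
    dnY_recycle: np.ndarray = None

    @property
    def total(self) -> np.ndarray:
        return self.dnP + self.dnR + self.dnQ + self.dnU


@dataclass
class Trajectory:
    """Recorded abundance vectors of one integration."""

    times: np.ndarray
    states: np.ndarray          # shape (n_records, k)
    biomass_series: np.ndarray  # total biomass g/m^3 at each record

    @property
    def final(self) -> CommunityState:
        return CommunityState(self.states[-1].copy(), float(self.times[-1]))


def _check_probability(prob: np.ndarray, process: str, t: float, dt: float) -> None:
    if np.any(prob > 1.0 + 1e-12):
        cls = int(np.argmax(prob)) + 1
        raise StepSizeError(process, cls, t, dt)


def predation_increment(state: CommunityState, ops: OperatorSet,
                        dt: float | None = None,
                        check: bool = True) -> np.ndarray:
    """Abundance change from predation: removal, growth + carrion, egesta.

    The state-dependent diagonal N plays two roles: prey numbers in the
    removal term and predator numbers in the assimilation term.
    """
    dt = ops.params.dt if dt is None else dt
    n, m = state.n, ops.grid.m
    removal = n * (ops.S.T @ (ops.v_diag * n))
    intake = n * ops.v_diag * (ops.S @ (m * n))       # biomass eaten per class, g/yr
    if check:
        # stability condition: the fraction of a class growing up per step
        # cannot exceed one (removal overshoot is caught by the negativity
        # guard in step(), since recycling inflows may compensate)
        growth = ops.dplus_diag * ops.params.e * intake
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(n > 0, growth * dt / np.where(n > 0, n, 1.0), 0.0)
        _check_probability(frac, "predation growth", state.t, dt)
    return (-removal + ops.gain_P @ intake) * dt


def reproduction_increment(state: CommunityState, ops: OperatorSet,
                           dt: float | None = None,
                           check: bool = True) -> np.ndarray:
    """Abundance change from reproduction: eggs, semen, parental down-transfer."""
    dt = ops.params.dt if dt is None else dt
    if check:
        b_rate = ops.r_diag * ops.dminus_diag
        _check_probability(b_rate * dt, "reproduction down-transfer", state.t, dt)
    return (ops.repro_map @ state.n) * dt


def metabolism_increment(state: CommunityState, ops: OperatorSet,
                         dt: float | None = None,
                         check: bool = True) -> np.ndarray:
    """Abundance change from metabolism: metabolite recycling and down-transfer."""
    dt = ops.params.dt if dt is None else dt
    if check:
        l_rate = ops.q_diag * ops.dminus_diag
        _check_probability(l_rate * dt, "metabolic down-transfer", state.t, dt)
    return (ops.metab_map @ state.n) * dt


def mortality_increment(state: CommunityState, ops: OperatorSet,
                        dt: float | None = None,
                        check: bool = True) -> np.ndarray:
    """Abundance change from density-dependent natural mortality and fishing.

    The per-capita non-predation rate is ``n_i * (mu0/ks) * m_i**(f-d)``,
    i.e. mortality rises with the ratio of abundance to the carrying capacity
    ``ks * m**-f``.  Dead biomass and catches are recycled to class 1.
    """
    dt = ops.params.dt if dt is None else dt
    n, m = state.n, ops.grid.m
    nd = ops.nd_coeff * n  # per-capita rate, 1/yr
    total_rate = nd + ops.h_diag
    if check:
        _check_probability(total_rate * dt, "mortality", state.t, dt)
    loss = total_rate * n
    recycled = np.zeros_like(n)
    recycled[0] = np.sum(loss * m) / m[0]
    return (-loss + recycled) * dt


def process_increments(state: CommunityState, ops: OperatorSet,
                       dt: float | None = None) -> ProcessIncrements:
    """All four increments with every diagnostic sub-term, via explicit fluxes."""
    dt = ops.params.dt if dt is None else dt
    n, m = state.n, ops.grid.m
    k = ops.grid.k
    removal = n * (ops.S.T @ (ops.v_diag * n)) * dt
    intake = n * ops.v_diag * (ops.S @ (m * n)) * dt   # g per step
    G = ops.dplus_diag * ops.params.e * intake
    dnG = (ops.Tg + ops.Tc) @ G
    dnE = ops.T1 @ ((1.0 - np.diag(ops.E)) * intake) / m[0]
    dnP = -removal + dnG + dnE

    F_flux = ops.r_diag * n * dt                       # g per step
    alpha = np.diag(ops.A)
    dnF = ops.T1 @ ((1.0 - alpha) * F_flux) / m[0] + ops.T2 @ (alpha * F_flux) / m[1]
    dnB = ops.Tg.T @ (ops.dminus_diag * F_flux)
    dnR = dnF + dnB

    W_flux = ops.q_diag * n * dt
    dnW = ops.T1 @ W_flux / m[0]
    dnL = ops.Tg.T @ (ops.dminus_diag * W_flux)
    dnQ = dnW + dnL

    nd = ops.nd_coeff * n
    dnD_loss = nd * n * dt
    dnY_remove = ops.h_diag * n * dt
    dnD_recycle = np.zeros(k)
    dnD_recycle[0] = np.sum(dnD_loss * m) / m[0]
    dnY_recycle = np.zeros(k)
    dnY_recycle[0] = np.sum(dnY_remove * m) / m[0]
    dnU = -dnD_loss + dnD_recycle - dnY_remove + dnY_recycle

    return ProcessIncrements(
        dnP=dnP, dnR=dnR, dnQ=dnQ, dnU=dnU,
        dnP_predation=removal, dnG=dnG, dnE=dnE,
        dnF=dnF, dnB=dnB, dnW=dnW, dnL=dnL,
        dnD_loss=dnD_loss, dnD_recycle=dnD_recycle,
        dnY_remove=dnY_remove, dnY_recycle=dnY_recycle,
    )


def step(state: CommunityState, ops: OperatorSet,
         constant_resource_level: float | None = None,
         check: bool = True) -> CommunityState:
    """One explicit Euler step n(t+dt) = n(t) + dnP + dnR + dnQ + dnU.

    In constant-resource mode the resource class is pinned back to
    ``constant_resource_level`` after the update.  Negative resulting
    abundances abort the run rather than being clamped, since clamping would
    silently break mass balance.
    """
    dt = ops.params.dt
    dn = (predation_increment(state, ops, dt, check)
          + reproduction_increment(state, ops, dt, check)
          + metabolism_increment(state, ops, dt, check)
          + mortality_increment(state, ops, dt, check))
    n_new = state.n + dn
    if np.any(n_new < 0):
        cls = int(np.argmin(n_new)) + 1
        raise IntegrationError(
            f"negative abundance in size class {cls} at t={state.t + dt:.6g} yr; "
            f"reduce dt (currently {dt:g} yr)"
        )
    if constant_resource_level is not None:
        n_new[0] = constant_resource_level
    out = CommunityState.__new__(CommunityState)
    out.n = n_new
    out.t = state.t + dt
    return out


def run(state: CommunityState, ops: OperatorSet, years: float,
        record_interval: float = 1.0,
        constant_resource: bool = False) -> Trajectory:
    """Integrate for ``years`` model years, recording at ``record_interval``.

    The recorded series always includes the initial and final states.  With
    ``constant_resource=True`` the resource abundance n_1 is held at its
    initial value, breaking mass balance deliberately.
    """
    dt = ops.params.dt
    if years <= 0:
        raise ValueError(f"run length must be positive, got {years} years")
    if record_interval < dt:
        raise ValueError("record_interval must be at least one time step")
    n_steps = int(round(years / dt))
    rec_every = max(1, int(round(record_interval / dt)))
    resource_level = float(state.n[0]) if constant_resource else None

    times = [state.t]
    states = [state.n.copy()]
    current = state.copy()
    for i in range(1, n_steps + 1):
        try:
            current = step(current, ops, resource_level)
        except IntegrationError as err:
            raise IntegrationError(f"at step {i} ({current.t + dt:.6g} yr): {err}") from err
        if i % rec_every == 0 or i == n_steps:
            times.append(current.t)
            states.append(current.n.copy())
    states_arr = np.array(states)
    biomass = states_arr @ ops.grid.m
    return Trajectory(times=np.array(times), states=states_arr,
                      biomass_series=biomass)


def is_steady(traj: Trajectory, tol: float = 1e-6) -> bool:
    """True if the per-year relative change between the last two records is < tol."""
    if len(traj.times) < 2:
        raise ValueError("need at least two recorded states")
    n0, n1 = traj.states[-2], traj.states[-1]
    span = traj.times[-1] - traj.times[-2]
    eps = np.finfo(float).eps * np.max(np.abs(n1))
    rate = np.max(np.abs(n1 - n0) / (n1 + eps)) / span
    return bool(rate < tol)
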