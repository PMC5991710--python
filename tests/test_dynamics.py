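import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sizespectra import (CommunityState, FishingScenario, IntegrationError,
                         ModelParams, StepSizeError, build_grid,
                         build_operators, initial_state, is_steady,
                         metabolism_increment, mortality_increment,
                         predation_increment, process_increments,
                         reproduction_increment, run, step)
from conftest import brute_force_increments


def toy_ops(c=0.0, v=0.0, e=0.5, alpha=0.5, gamma=1.0, mu0=0.0, dt=1.0, **kw):
    grid = build_grid(m2=1.0, delta=2.0, k=3, s=0)
    params = ModelParams(c=c, v=v, e=e, alpha=alpha, gamma=gamma, p=kw.pop("p", 0.0),
                         mu0=mu0, dt=dt, **kw)
    return grid, build_operators(grid, params)


def with_kernel(ops, S):
    """Operator set with a prescribed toy selectivity matrix."""
    return dataclasses.replace(ops, S=np.asarray(S, dtype=float))


class TestPredationIncrement:
    def test_toy_hand_bookkeeping(self):
        """Prescribed kernel on the doubling grid, flux-by-flux arithmetic."""
        grid, ops = toy_ops(e=0.5)
        ops = with_kernel(ops, [[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        state = CommunityState(np.array([2.0, 1.0, 0.5]))
        dnP = predation_increment(state, ops, dt=1.0, check=False)
        # removal: class1 loses n1*phi21*n2 = 2, class2 loses n2*phi32*n3 = 0.5
        # G2 = e*m1*P21/(m3-m2) = 0.5, G3 = e*m2*P32/(m4-m3) = 0.125
        # class1 gains carrion G3*m4/m1 = 1 and egesta (1-e)*1.5/m1 = 1.5
        assert np.allclose(dnP, [0.5, -1.0, 0.375], rtol=1e-12)
        assert grid.m @ dnP == pytest.approx(0.0, abs=1e-15)

    def test_full_assimilation_means_no_egesta(self):
        grid, ops = toy_ops(e=1.0)
        ops = with_kernel(ops, [[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        state = CommunityState(np.array([2.0, 1.0, 0.5]))
        dnP = predation_increment(state, ops, dt=1.0, check=False)
        _, _, _, _ = state, ops, grid, dnP
        # egesta term (I-E)=0: class 1 change is -removal + carrion only
        # G2 = 1.0, G3 = 0.25, carrion = 0.25*8/0.5... (m4/m1 = 8)
        assert dnP[0] == pytest.approx(-2.0 + 0.25 * 4.0 / 0.5, rel=1e-12)

    def test_growth_overshoot_raises_step_size_error(self):
        grid, ops = toy_ops(e=1.0, gamma=100.0)
        ops = with_kernel(ops, [[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        state = CommunityState(np.array([2.0, 1.0, 0.5]))
        with pytest.raises(StepSizeError) as exc:
            predation_increment(state, ops, dt=1.0)
        assert exc.value.class_index in (2, 3)


class TestReproductionIncrement:
    def test_toy_hand_bookkeeping(self):
        grid, ops = toy_ops(c=1.0, r=0.0, alpha=0.5)
        state = CommunityState(np.array([0.0, 0.0, 1.0]))
        dnR = reproduction_increment(state, ops, dt=1.0, check=False)
        # eggs 0.5/m2 into class 2, semen 0.5/m1 into class 1, B3 = 1 drops
        assert np.allclose(dnR, [1.0, 1.5, -1.0], rtol=1e-12)

    def test_all_female_output_is_eggs(self):
        grid, ops = toy_ops(c=1.0, r=0.0, alpha=1.0)
        state = CommunityState(np.array([0.0, 0.0, 1.0]))
        dnR = reproduction_increment(state, ops, dt=1.0, check=False)
        assert dnR[0] == pytest.approx(0.0)   # nothing recycled as semen
        assert dnR[1] == pytest.approx(1.0 + 1.0)  # eggs + down-transfer

    def test_down_transfer_overshoot_raises(self):
        grid, ops = toy_ops(c=10.0, r=0.0)
        state = CommunityState(np.array([0.0, 0.0, 1.0]))
        with pytest.raises(StepSizeError):
            reproduction_increment(state, ops, dt=1.0)


class TestMetabolismIncrement:
    def test_toy_hand_bookkeeping(self):
        grid, ops = toy_ops(v=1.0, q=0.0)
        state = CommunityState(np.array([0.0, 1.0, 0.0]))
        dnQ = metabolism_increment(state, ops, dt=1.0, check=False)
        # W2 = 1 g recycled as 2 resources; L2 = 2 individuals drop a class
        assert np.allclose(dnQ, [4.0, -2.0, 0.0], rtol=1e-12)

    def test_zero_metabolism(self):
        grid, ops = toy_ops(v=0.0)
        state = CommunityState(np.array([1.0, 1.0, 1.0]))
        assert np.allclose(metabolism_increment(state, ops, dt=1.0), 0.0)


class TestMortalityIncrement:
    def test_per_capita_rate_value(self):
        """n=0.01 at 1 g with z0=400, z=-0.9 gives a 4/yr per-capita rate."""
        p = ModelParams()
        assert 0.01 * p.z0 * 1.0 ** (-p.z) == pytest.approx(4.0)

    def test_vanishes_without_mortality_sources(self):
        grid, ops = toy_ops(mu0=0.0)
        state = CommunityState(np.array([1.0, 2.0, 3.0]))
        assert np.allclose(mortality_increment(state, ops, dt=1.0), 0.0)

    def test_fishing_and_natural_mortality_recycled(self):
        grid = build_grid(m2=1.0, delta=2.0, k=3, s=0)
        params = ModelParams(mu0=0.15, dt=0.001)  # z0 = 100
        sc = FishingScenario("unbalanced", F0=5.0, threshold_mass=1.5)
        ops = build_operators(grid, params, sc)
        state = CommunityState(np.array([1.0, 0.001, 0.001]))
        dnU = mortality_increment(state, ops, dt=0.001)
        assert grid.m @ dnU == pytest.approx(0.0, abs=1e-15)
        assert dnU[2] < 0  # fished class loses individuals


@st.composite
def random_states(draw, k=5):
    vals = draw(st.lists(st.floats(0.0, 10.0, allow_nan=False), min_size=k, max_size=k))
    return np.array(vals)


class TestConservationProperties:
    """Each process conserves community biomass exactly, by construction."""

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(n=random_states())
    def test_each_increment_conserves_biomass(self, n):
        grid = build_grid(m2=0.01, delta=2.0, k=5, s=3)
        ops = build_operators(grid, ModelParams(dt=1e-6),
                              FishingScenario("balanced", F0=5.0, threshold_mass=0.01))
        state = CommunityState(n)
        m = grid.m
        scale = max(float(np.abs(n).sum()), 1.0)
        for inc in (predation_increment, reproduction_increment,
                    metabolism_increment, mortality_increment):
            dn = inc(state, ops, check=False)
            assert abs(m @ dn) <= 1e-10 * max(np.abs(m * dn).sum(), scale * 1e-12)

    def test_zero_state_is_fixed_point(self):
        grid, ops = toy_ops(c=1.0, v=1.0, mu0=0.6, dt=0.01)
        state = CommunityState(np.zeros(3))
        out = step(state, ops)
        assert np.all(out.n == 0) and out.t == pytest.approx(0.01)


class TestBruteForceOracle:
    """Matrix-algebra increments equal an index-loop reimplementation."""

    @pytest.mark.parametrize("k,s,delta", [(3, 0, 2.0), (4, 2, 1.7), (5, 3, 2.0)])
    def test_matrix_equals_loops(self, k, s, delta):
        grid = build_grid(m2=0.01, delta=delta, k=k, s=s)
        params = ModelParams(dt=1e-5)
        sc = FishingScenario("unbalanced", F0=3.0, threshold_mass=float(grid.m[k // 2]))
        ops = build_operators(grid, params, sc)
        rng = np.random.default_rng(12345)
        for _ in range(5):
            n = rng.uniform(0.0, 5.0, size=k)
            state = CommunityState(n)
            expected = brute_force_increments(n, grid, params, ops.S,
                                              h=np.diag(ops.H))
            got = (predation_increment(state, ops, check=False),
                   reproduction_increment(state, ops, check=False),
                   metabolism_increment(state, ops, check=False),
                   mortality_increment(state, ops, check=False))
            for name, e, g in zip("PRQU", expected, got):
                scale = max(np.abs(e).max(), 1e-30)
                assert np.allclose(g, e, rtol=1e-12, atol=1e-12 * scale), name

    def test_detailed_increments_match_fast_path(self, basic_grid, basic_ops):
        state = initial_state(basic_grid, 0.01)
        inc = process_increments(state, basic_ops)
        assert np.allclose(inc.dnP, predation_increment(state, basic_ops), rtol=1e-12)
        assert np.allclose(inc.dnR, reproduction_increment(state, basic_ops), rtol=1e-12)
        assert np.allclose(inc.dnQ, metabolism_increment(state, basic_ops), rtol=1e-12)
        assert np.allclose(inc.dnU, mortality_increment(state, basic_ops), rtol=1e-12)


class TestStepAndRun:
    def test_step_is_sum_of_increments(self, basic_grid, basic_ops):
        state = initial_state(basic_grid, 0.01)
        total = (predation_increment(state, basic_ops)
                 + reproduction_increment(state, basic_ops)
                 + metabolism_increment(state, basic_ops)
                 + mortality_increment(state, basic_ops))
        out = step(state, basic_ops)
        assert np.allclose(out.n, state.n + total, rtol=1e-12)
        assert out.t == pytest.approx(0.001)

    def test_step_conserves_total_biomass(self, basic_grid, basic_ops):
        state = initial_state(basic_grid, 0.01)
        out = step(state, basic_ops)
        assert out.n @ basic_grid.m == pytest.approx(0.5, rel=1e-10)

    def test_negative_abundance_aborts(self):
        # c=100 raises the class-3 down-transfer rate beyond 1/dt
        grid = build_grid(m2=0.001, delta=1.5, k=50, s=37)
        ops = build_operators(grid, ModelParams(c=100.0, dt=0.001))
        with pytest.raises(IntegrationError):
            run(initial_state(grid, 0.01), ops, years=1.0)

    def test_constant_resource_pins_class_one(self, basic_grid):
        ops = build_operators(basic_grid, ModelParams())
        state = initial_state(basic_grid, 0.01)
        traj = run(state, ops, years=0.05, record_interval=0.01,
                   constant_resource=True)
        assert np.allclose(traj.states[:, 0], state.n[0])

    def test_run_length_validation(self, basic_ops, basic_grid):
        state = initial_state(basic_grid, 0.01)
        with pytest.raises(ValueError):
            run(state, basic_ops, years=0.0)
        with pytest.raises(ValueError):
            run(state, basic_ops, years=1.0, record_interval=1e-6)


class TestSteadyState:
    def test_identical_records_are_steady(self, basic_grid):
        from sizespectra import Trajectory
        n = initial_state(basic_grid, 0.01).n
        traj = Trajectory(times=np.array([0.0, 1.0]),
                          states=np.vstack([n, n]),
                          biomass_series=np.array([0.5, 0.5]))
        assert is_steady(traj, tol=1e-12)

    def test_transient_is_not_steady(self, basic_run):
        head = basic_run
        from sizespectra import Trajectory
        early = Trajectory(times=head.times[:2], states=head.states[:2],
                           biomass_series=head.biomass_series[:2])
        assert not is_steady(early, tol=1e-6)

    def test_reference_run_is_steady_at_40_years(self, basic_run):
        assert is_steady(basic_run, tol=1e-4)

    def test_steady_state_independent_of_initial_shape(self, basic_grid, basic_ops,
                                                       basic_run):
        """A non-power-law start with the same biomass reaches the same spectrum."""
        rng = np.random.default_rng(7)
        n0 = rng.uniform(0.5, 2.0, basic_grid.k) / basic_grid.m
        n0 *= 0.5 / (n0 @ basic_grid.m)
        traj = run(CommunityState(n0), basic_ops, years=40.0)
        assert np.allclose(traj.states[-1], basic_run.states[-1], rtol=1e-5)
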