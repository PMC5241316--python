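"""Cell-dynamics unit tests: Euler integration, outputs, accumulators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hebbnet import (
    ModelParams,
    NetworkState,
    build_architecture,
    excitatory_output,
    inhibitory_output,
    membrane_step,
    net_input,
    step_network,
)
from hebbnet.network import update_lowpass
from hebbnet.params import ConnectomeParams


class TestMembrane:
    def test_leaky_decay_single_step(self, params):
        V = np.array([1.0])
        membrane_step(V, np.zeros(1), params.tau_exc, params)
        assert V[0] == pytest.approx(0.6)

    def test_decay_matches_closed_form_geometric(self, params):
        V = np.array([1.0])
        for _ in range(20):
            membrane_step(V, np.zeros(1), params.tau_exc, params)
        assert V[0] == pytest.approx((1 - 1 / params.tau_exc) ** 20, rel=1e-12)

    def test_zero_is_fixed_point(self, params):
        V = np.zeros(3)
        membrane_step(V, np.zeros(3), params.tau_exc, params)
        assert np.all(V == 0.0)

    def test_converges_to_rescaled_constant_input(self, params):
        # constant drive c/k1 -> V converges to c
        c = 0.42
        V = np.zeros(1)
        vin = np.array([c / params.k1])
        for _ in range(int(100 * params.tau_exc)):
            membrane_step(V, vin, params.tau_exc, params)
        assert V[0] == pytest.approx(c, rel=1e-6)


class TestOutputs:
    @pytest.mark.parametrize(
        "V, omega, expected",
        [
            (0.19, 0.0, 1.0),  # just above threshold
            (0.18, 0.0, 0.0),  # boundary: strict inequality
            (0.25, 0.01, 0.0),  # 0.25 - 7*0.01 = 0.18, not > 0.18
            (0.26, 0.01, 1.0),
        ],
    )
    def test_spike_threshold_with_adaptation(self, params, V, omega, expected):
        out = excitatory_output(np.array([V]), np.array([omega]), params)
        assert out[0] == expected

    @pytest.mark.parametrize("V, expected", [(-0.3, 0.0), (0.0, 0.0), (0.42, 0.42)])
    def test_inhibitory_rectified_linear(self, V, expected):
        assert inhibitory_output(np.array([V]))[0] == expected


class TestAccumulators:
    def test_zero_spike_train_stays_zero(self, params):
        w = np.zeros(4)
        for _ in range(50):
            update_lowpass(w, np.zeros(4), params.tau_adapt)
        assert np.all(w == 0.0)

    def test_constant_firing_saturates_monotonically_below_one(self, params):
        w = np.zeros(1)
        prev = 0.0
        ones = np.ones(1)
        for _ in range(400):
            update_lowpass(w, ones, params.tau_adapt)
            assert prev <= w[0] <= 1.0
            assert w[0] > 0.0
            prev = w[0]
        assert w[0] == pytest.approx(1.0, abs=1e-15)

    def test_single_spike_decay_factor(self, params):
        w = np.zeros(1)
        update_lowpass(w, np.ones(1), params.tau_adapt)
        peak = w[0]
        zeros = np.zeros(1)
        for n in range(1, 6):
            update_lowpass(w, zeros, params.tau_adapt)
            assert w[0] == pytest.approx(peak * (1 - 1 / params.tau_adapt) ** n)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=200))
    def test_lowpass_of_binary_signal_stays_in_unit_interval(self, spikes):
        for tau in (1.0, 2.5, 10.0, 30.0):
            w = np.zeros(1)
            for s in spikes:
                update_lowpass(w, np.array([float(s)]), tau)
                assert 0.0 <= w[0] <= 1.0


class TestGlobalInhibition:
    def test_sustained_spiking_converges_to_area_count(self, tiny_connectome, params):
        state = NetworkState.zeros(tiny_connectome)
        spikes = np.zeros(tiny_connectome.n_exc)
        spikes[tiny_connectome.area_slice("A1")] = 0.0
        # 10 cells of A1 spiking each step -> omega_G -> 10 for A1 only
        spikes[:10] = 1.0
        from hebbnet.network import update_global_inhibition

        for _ in range(600):
            update_global_inhibition(state.omega_G, spikes, None, params, tiny_connectome)
        assert state.omega_G[0] == pytest.approx(10.0, rel=1e-9)
        assert state.omega_G[1] == 0.0

    def test_area_locality_within_one_step(self, tiny_connectome, params):
        from hebbnet.network import update_global_inhibition

        base = NetworkState.zeros(tiny_connectome)
        pert = NetworkState.zeros(tiny_connectome)
        spikes = np.zeros(tiny_connectome.n_exc)
        spikes_pert = spikes.copy()
        spikes_pert[tiny_connectome.area_slice("A1")] += 1.0  # perturb area A1 only
        update_global_inhibition(base.omega_G, spikes, None, params, tiny_connectome)
        update_global_inhibition(pert.omega_G, spikes_pert, None, params, tiny_connectome)
        assert pert.omega_G[0] != base.omega_G[0]
        assert pert.omega_G[1] == base.omega_G[1]

    def test_burst_then_silence_decays_exponentially(self, tiny_connectome, params):
        from hebbnet.network import update_global_inhibition

        state = NetworkState.zeros(tiny_connectome)
        spikes = np.zeros(tiny_connectome.n_exc)
        spikes[:5] = 1.0
        update_global_inhibition(state.omega_G, spikes, None, params, tiny_connectome)
        peak = state.omega_G[0]
        none = np.zeros(tiny_connectome.n_exc)
        for n in range(1, 5):
            update_global_inhibition(state.omega_G, none, None, params, tiny_connectome)
            assert state.omega_G[0] == pytest.approx(peak * (1 - 1 / params.tau_glob) ** n)


class TestNetInput:
    def test_zero_activity_gives_zero_input(self, tiny_connectome, params):
        state = NetworkState.zeros(tiny_connectome)
        vin_e, vin_i = net_input(state, tiny_connectome, None, params)
        assert np.all(vin_e == 0.0) and np.all(vin_i == 0.0)

    def test_single_spike_single_weight(self, tiny_connectome, params):
        W = tiny_connectome.W_ee
        # pick an existing synapse and isolate it
        post = np.flatnonzero(np.diff(W.indptr))[0]
        pre = W.indices[W.indptr[post]]
        W.data[:] = 0.0
        W.data[W.indptr[post]] = 0.1
        state = NetworkState.zeros(tiny_connectome)
        state.phi_e[pre] = 1.0
        vin_e, _ = net_input(state, tiny_connectome, None, params)
        assert vin_e[post] == pytest.approx(0.1)
        assert np.count_nonzero(vin_e) == 1

    def test_matches_naive_double_loop_on_toy_net(self, tiny_connectome, params):
        rng = np.random.default_rng(3)
        state = NetworkState.zeros(tiny_connectome)
        state.phi_e = (rng.random(tiny_connectome.n_exc) < 0.3).astype(float)
        state.phi_i = rng.random(tiny_connectome.n_exc) * 0.2
        state.omega_G = rng.random(tiny_connectome.n_areas)
        vin_e, vin_i = net_input(state, tiny_connectome, None, params)
        Wd = tiny_connectome.W_ee.toarray()
        Wi = tiny_connectome.W_ie.toarray()
        n = tiny_connectome.n_exc
        expect_e = np.zeros(n)
        expect_i = np.zeros(n)
        for x in range(n):
            for y in range(n):
                expect_e[x] += Wd[x, y] * state.phi_e[y]
                expect_i[x] += Wi[x, y] * state.phi_e[y]
            expect_e[x] += tiny_connectome.i2e[x] * state.phi_i[x]
            expect_e[x] -= params.kG * state.omega_G[tiny_connectome.area_index[x]]
        np.testing.assert_allclose(vin_e, expect_e, rtol=1e-12, atol=1e-14)
        np.testing.assert_allclose(vin_i, expect_i, rtol=1e-12, atol=1e-14)

    def test_dimension_mismatch_raises(self, tiny_connectome, params):
        other = build_architecture(
            ConnectomeParams(grid=4, n_exc=3, n_inh=3), rng=0, areas=["A1"], edges=[]
        )
        state = NetworkState.zeros(other)
        with pytest.raises(ValueError, match="cells"):
            net_input(state, tiny_connectome, None, params)


def _scalar_reference_step(state, conn, stim, params, noise):
    """Naive per-cell Python implementation of one synchronous step."""
    n = conn.n_exc
    Wd = conn.W_ee.toarray()
    Wi = conn.W_ie.toarray()
    phi_e = np.array(
        [1.0 if state.V_e[x] - params.alpha * state.omega[x] > params.thresh else 0.0
         for x in range(n)]
    )
    phi_i = np.array([max(state.V_i[x], 0.0) for x in range(n)])
    V_e = state.V_e.copy()
    V_i = state.V_i.copy()
    for x in range(n):
        vin = sum(Wd[x, y] * phi_e[y] for y in range(n))
        vin += conn.i2e[x] * phi_i[x]
        vin -= params.kG * state.omega_G[conn.area_index[x]]
        if stim is not None:
            vin += stim[x]
        vin += params.k2 * noise[x]
        V_e[x] = state.V_e[x] + (-state.V_e[x] + params.k1 * vin) / params.tau_exc
        vin_i = sum(Wi[x, y] * phi_e[y] for y in range(n))
        V_i[x] = state.V_i[x] + (-state.V_i[x] + params.k1 * vin_i) / params.tau_inh
    omega = state.omega + (-state.omega + phi_e) / params.tau_adapt
    omega_E = state.omega_E + (-state.omega_E + phi_e) / params.tau_favg
    npa = conn.cells_per_area
    sums = np.array([phi_e[a * npa : (a + 1) * npa].sum() for a in range(conn.n_areas)])
    omega_G = state.omega_G + (-state.omega_G + sums) / params.tau_glob
    return V_e, V_i, omega, omega_E, omega_G, phi_e, phi_i


class TestStepNetwork:
    def test_matches_scalar_reference(self, params):
        conn = build_architecture(
            ConnectomeParams(grid=4, n_exc=3, n_inh=3, p0=0.6), rng=11,
            areas=["A1", "PB"], edges=[("A1", "PB")],
        )
        assert conn.n_exc <= 50
        rng = np.random.default_rng(5)
        state = NetworkState.zeros(conn)
        state.V_e = rng.normal(0, 0.3, conn.n_exc)
        state.V_i = rng.normal(0, 0.1, conn.n_exc)
        state.omega = rng.random(conn.n_exc) * 0.05
        stim = np.zeros(conn.n_exc)
        stim[:3] = 30.0
        for _ in range(12):
            noise = rng.random(conn.n_exc) - 0.5
            expected = _scalar_reference_step(state, conn, stim, params, noise)
            step_network(state, conn, stim, params, noise=noise)
            for got, want in zip(
                (state.V_e, state.V_i, state.omega, state.omega_E, state.omega_G,
                 state.phi_e, state.phi_i),
                expected,
            ):
                np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-14)

    def test_zero_network_stays_zero(self, tiny_connectome, params):
        tiny_connectome.W_ee.data[:] = 0.0
        state = NetworkState.zeros(tiny_connectome)
        for _ in range(20):
            step_network(state, tiny_connectome, None, params, rng=None)
        for arr in (state.V_e, state.V_i, state.omega, state.omega_E, state.omega_G):
            assert np.all(arr == 0.0)

    def test_fixed_seed_reproduces_trajectory(self, tiny_connectome, params):
        runs = []
        for _ in range(2):
            state = NetworkState.zeros(tiny_connectome)
            rng = np.random.default_rng(99)
            traj = []
            for _ in range(30):
                step_network(state, tiny_connectome, None, params, rng=rng)
                traj.append(state.V_e.copy())
            runs.append(np.array(traj))
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_subthreshold_state_decays_toward_zero_without_input(self, tiny_connectome, params):
        state = NetworkState.zeros(tiny_connectome)
        state.V_e += 0.1  # below threshold: no spikes, pure decay
        prev = np.abs(state.V_e).max()
        for _ in range(40):
            step_network(state, tiny_connectome, None, params, rng=None)
            cur = np.abs(state.V_e).max()
            assert cur < prev or cur == 0.0
            prev = cur
        assert prev < 1e-6

    def test_no_spikes_when_potentials_at_or_below_threshold(self, tiny_connectome, params):
        state = NetworkState.zeros(tiny_connectome)
        state.V_e += params.thresh  # exactly at threshold: strict inequality
        step_network(state, tiny_connectome, None, params, rng=None)
        assert state.phi_e.sum() == 0.0

    def test_nonfinite_state_raises_with_step_index(self, tiny_connectome, params):
        from hebbnet.network import NumericalError

        state = NetworkState.zeros(tiny_connectome)
        state.V_e[0] = np.nan
        with pytest.raises(NumericalError, match="step"):
            step_network(state, tiny_connectome, None, params, rng=None)
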