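"""Discrete-time synchronous update of all cell state variables.

Excitatory cells are leaky integrate-and-fire units with spike-rate
adaptation; their twin inhibitory cells are graded-response (rectified
linear) units.  All low-pass dynamics are integrated with the Euler scheme
at step size ``dt`` (0.5 ms), with time constants expressed in steps:

* membrane:        tau * dV/dt = -V + k1 * (V_In + k2 * eta)
* net input:       V_In(x)     = -kG * omega_G(A_x) + sum_y w_xy * phi(y)
* spiking:         phi(e) = 1  iff  V(e) - alpha * omega(e) > thresh
* adaptation:      tau_ADAPT * d omega / dt   = -omega + phi(e)
* rate estimate:   tau_Favg  * d omega_E / dt = -omega_E + phi(e)
* global inhib.:   tau_GLOB  * d omega_G / dt = -omega_G + sum_{e in A} phi(e)

eta is uniform white noise on [-0.5, 0.5], drawn independently per
excitatory cell per step; inhibitory cells receive no noise (k2 = 0) and no
global-inhibition term.  All cells update synchronously from the outputs of
the previous step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import Connectome
from .params import ModelParams

__all__ = [
    "NetworkState",
    "net_input",
    "membrane_step",
    "excitatory_output",
    "inhibitory_output",
    "update_lowpass",
    "update_adaptation",
    "update_rate_estimate",
    "update_global_inhibition",
    "step_network",
]


class NumericalError(RuntimeError):
    """Raised when a state variable becomes non-finite."""


@dataclass
class NetworkState:
    """Per-cell state of the network at one time step.

    ``V_e``/``V_i`` are membrane potentials of the excitatory/inhibitory
    banks; ``omega`` is adaptation, ``omega_E`` the low-passed firing-rate
    estimate, ``omega_G`` the per-area global-inhibition accumulator.
    ``phi_e``/``phi_i`` are the outputs computed from the current potentials
    (binary spikes and rectified graded output respectively).
    """

    V_e: np.ndarray
    V_i: np.ndarray
    omega: np.ndarray
    omega_E: np.ndarray
    omega_G: np.ndarray
    phi_e: np.ndarray
    phi_i: np.ndarray
    t: int = 0

    @classmethod
    def zeros(cls, connectome: Connectome) -> "NetworkState":
        n = connectome.n_exc
        return cls(
            V_e=np.zeros(n),
            V_i=np.zeros(n),
            omega=np.zeros(n),
            omega_E=np.zeros(n),
            omega_G=np.zeros(connectome.n_areas),
            phi_e=np.zeros(n),
            phi_i=np.zeros(n),
            t=0,
        )

    def reset(self) -> None:
        """Global network reset: all state variables back to 0."""
        for arr in (self.V_e, self.V_i, self.omega, self.omega_E,
                    self.omega_G, self.phi_e, self.phi_i):
            arr.fill(0.0)
        self.t = 0

    def check_finite(self) -> None:
        if not (np.isfinite(self.V_e).all() and np.isfinite(self.V_i).all()):
            raise NumericalError(f"non-finite membrane potential at step {self.t}")


def excitatory_output(V: np.ndarray, omega: np.ndarray, params: ModelParams) -> np.ndarray:
    """Binary spike output: 1 iff V - alpha*omega strictly exceeds thresh."""
    return (V - params.alpha * omega > params.thresh).astype(np.float64)


def inhibitory_output(V: np.ndarray) -> np.ndarray:
    """Graded rectified-linear output: 0 below 0, V otherwise."""
    return np.maximum(V, 0.0)


def net_input(
    state: NetworkState,
    connectome: Connectome,
    ext_input: np.ndarray | None,
    params: ModelParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Net input V_In to every cell from the current outputs.

    Excitatory cells receive recurrent/projection input ``W_ee @ phi_e``,
    inhibition from their twin (negative weight times the graded output), the
    subtractive area-wide term ``-kG * omega_G`` and any external stimulus
    drive.  Inhibitory cells pool excitatory spikes from their 5x5
    neighbourhood and receive neither global inhibition nor stimulus.
    """
    if connectome.W_ee.shape[0] != state.V_e.shape[0]:
        raise ValueError(
            f"connectome has {connectome.W_ee.shape[0]} excitatory cells, "
            f"state has {state.V_e.shape[0]}"
        )
    vin_e = connectome.W_ee @ state.phi_e
    vin_e += connectome.i2e * state.phi_i
    vin_e -= params.kG * state.omega_G[connectome.area_index]
    if ext_input is not None:
        vin_e = vin_e + ext_input
    vin_i = connectome.W_ie @ state.phi_e
    return vin_e, vin_i


def membrane_step(
    V: np.ndarray,
    vin: np.ndarray,
    tau: float,
    params: ModelParams,
    noise: np.ndarray | None = None,
) -> np.ndarray:
    """One Euler step of the membrane equation (in place).

    ``noise`` is the per-cell uniform draw on [-0.5, 0.5]; pass None for the
    inhibitory bank (k2 = 0).
    """
    drive = vin if noise is None else vin + params.k2 * noise
    V += (-V + params.k1 * drive) / tau
    return V


def update_lowpass(acc: np.ndarray, signal: np.ndarray, tau: float) -> np.ndarray:
    """Euler low-pass: acc += (-acc + signal)/tau (in place).

    For a {0,1} signal and tau >= 1 the accumulator stays in [0, 1].
    """
    acc += (-acc + signal) / tau
    return acc


def update_adaptation(omega: np.ndarray, phi_e: np.ndarray, params: ModelParams) -> np.ndarray:
    return update_lowpass(omega, phi_e, params.tau_adapt)


def update_rate_estimate(omega_E: np.ndarray, phi_e: np.ndarray, params: ModelParams) -> np.ndarray:
    return update_lowpass(omega_E, phi_e, params.tau_favg)


def update_global_inhibition(
    omega_G: np.ndarray,
    phi_e: np.ndarray,
    area_spike_sum: np.ndarray | None,
    params: ModelParams,
    connectome: Connectome | None = None,
) -> np.ndarray:
    """Per-area Euler low-pass of the total excitatory spike count."""
    if area_spike_sum is None:
        assert connectome is not None
        npa = connectome.cells_per_area
        area_spike_sum = phi_e.reshape(connectome.n_areas, npa).sum(axis=1)
    return update_lowpass(omega_G, area_spike_sum, params.tau_glob)


def step_network(
    state: NetworkState,
    connectome: Connectome,
    stimulus: np.ndarray | None,
    params: ModelParams,
    rng: np.random.Generator | None = None,
    noise: np.ndarray | None = None,
    check: bool = True,
) -> NetworkState:
    """Advance the network one synchronous 0.5 ms step (in place).

    Outputs are computed from the current potentials; net inputs from those
    outputs; then potentials and all accumulators are updated.  ``noise``
    may be supplied pre-drawn (one uniform [-0.5, 0.5] value per excitatory
    cell); otherwise it is drawn from ``rng``.
    """
    state.phi_e = excitatory_output(state.V_e, state.omega, params)
    state.phi_i = inhibitory_output(state.V_i)
    vin_e, vin_i = net_input(state, connectome, stimulus, params)
    if noise is None:
        if rng is None:
            noise = None
        else:
            noise = rng.random(state.V_e.shape[0]) - 0.5
    membrane_step(state.V_e, vin_e, params.tau_exc, params, noise)
    membrane_step(state.V_i, vin_i, params.tau_inh, params, None)
    update_adaptation(state.omega, state.phi_e, params)
    update_rate_estimate(state.omega_E, state.phi_e, params)
    update_global_inhibition(state.omega_G, state.phi_e, None, params, connectome)
    state.t += 1
    if check:
        state.check_finite()
    return state
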