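"""Spike-gated Hebbian learning on excitatory-to-excitatory synapses.

The rule discretizes the Artola-Broecher-Singer plasticity characteristic
into two fixed efficacy changes, +Delta (LTP) and -Delta (LTD), selected by
the presynaptic firing-rate estimate omega_E and the postsynaptic membrane
potential V:

* LTP:                +Delta  if omega_E(pre) >= theta_pre and V(post) >= theta_plus
* homosynaptic LTD:   -Delta  if omega_E(pre) >= theta_pre and theta_minus <= V(post) < theta_plus
* heterosynaptic LTD: -Delta  if omega_E(pre) <  theta_pre and V(post) >= theta_plus
* otherwise:           0

The whole rule applies only in steps where the pre- or the postsynaptic cell
fires (inclusive OR); without a gating spike the weight is untouched.
Weights are clipped to [0, w_max] after every update.  Inhibitory loops and
the global-inhibition pathway are never plastic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import Connectome
from .params import ModelParams

__all__ = ["SynapseUpdateContext", "hebbian_delta", "apply_plasticity"]


@dataclass
class SynapseUpdateContext:
    """Inputs to the learning rule for a single synapse at one step."""

    w: float
    omega_E_pre: float
    V_post: float
    spike_pre: bool
    spike_post: bool


def hebbian_delta(ctx: SynapseUpdateContext, params: ModelParams) -> float:
    """Weight change for one synapse: +Delta, -Delta or 0 (scalar reference)."""
    if not (ctx.spike_pre or ctx.spike_post):
        return 0.0
    active = ctx.omega_E_pre >= params.theta_pre
    if active and ctx.V_post >= params.theta_plus:
        return params.delta  # LTP
    if active and params.theta_minus <= ctx.V_post < params.theta_plus:
        return -params.delta  # homosynaptic LTD
    if not active and ctx.V_post >= params.theta_plus:
        return -params.delta  # heterosynaptic LTD
    return 0.0


def apply_plasticity(
    connectome: Connectome,
    phi_e: np.ndarray,
    V_e: np.ndarray,
    omega_E: np.ndarray,
    params: ModelParams,
) -> int:
    """Apply the learning rule to every excitatory-to-excitatory synapse.

    All quantities are the time-t values: the spikes ``phi_e`` computed from
    the potentials ``V_e``, and the rate estimates ``omega_E`` valid at the
    same step.  Updates ``connectome.W_ee.data`` in place and returns the
    number of synapses whose weight changed.
    """
    W = connectome.W_ee
    pre = W.indices
    post = connectome.post_of
    spiking = phi_e > 0.0
    gate = spiking[pre] | spiking[post]
    idx = np.flatnonzero(gate)
    if idx.size == 0:
        return 0
    vpost = V_e[post[idx]]
    active = omega_E[pre[idx]] >= params.theta_pre
    high = vpost >= params.theta_plus
    ltp = active & high
    ltd = (active & ~high & (vpost >= params.theta_minus)) | (~active & high)
    dw = params.delta * (ltp.astype(np.float64) - ltd.astype(np.float64))
    changed = int(np.count_nonzero(dw))
    if changed:
        W.data[idx] = np.clip(W.data[idx] + dw, 0.0, params.w_max)
    return changed
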