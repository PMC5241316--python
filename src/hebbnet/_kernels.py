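"""Numba inner loop for trial simulation.

The vectorized numpy implementation in :mod:`network` defines the
semantics (and is what the oracle tests exercise); this kernel runs the
same synchronous update as a single compiled loop so that training and
testing schedules with millions of steps stay fast.  Noise is pre-drawn by
the caller, so the kernel is bit-deterministic given its inputs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_steps_kernel"]


@njit(cache=True, nogil=True)
def run_steps_kernel(
    n_steps: int,
    V_e: np.ndarray,
    V_i: np.ndarray,
    omega: np.ndarray,
    omega_E: np.ndarray,
    omega_G: np.ndarray,
    phi_e: np.ndarray,
    phi_i: np.ndarray,
    ee_data: np.ndarray,
    ee_indices: np.ndarray,
    ee_indptr: np.ndarray,
    csc_data: np.ndarray,  # CSC copy (pre -> post) for the frozen-weight path
    csc_indices: np.ndarray,
    csc_indptr: np.ndarray,
    grid: int,
    n_inh: int,  # inhibitory pooling box side; weights e2i_total/count
    e2i_total: float,
    i2e: np.ndarray,
    n_areas: int,
    drive: np.ndarray,  # length n, or length 0 for no stimulus
    noise: np.ndarray,  # (n_steps, n), or (0, 0) for no noise
    serp_out: np.ndarray,  # (n_areas, >=offset+n_steps), or (0, 0)
    spikes_out: np.ndarray,
    out_offset: int,
    plastic: bool,
    # model constants
    tau_e: float,
    tau_i: float,
    k1: float,
    k2: float,
    kG: float,
    thresh: float,
    alpha: float,
    tau_a: float,
    tau_f: float,
    tau_g: float,
    theta_pre: float,
    theta_plus: float,
    theta_minus: float,
    delta: float,
    w_max: float,
) -> int:
    """Advance the network ``n_steps`` steps in place; returns -1 on a
    non-finite potential (the offending step index is recoverable from the
    return value as ``-(step+2)``)."""
    n = V_e.shape[0]
    npa = n // n_areas
    have_drive = drive.shape[0] == n
    have_noise = noise.shape[0] == n_steps
    record = serp_out.shape[0] == n_areas
    use_csc = (not plastic) and csc_data.shape[0] == ee_data.shape[0]

    vin_e = np.empty(n)
    vin_i = np.empty(n)
    area_spikes = np.empty(n_areas)
    prefix = np.zeros((grid + 1) * (grid + 1))

    for step in range(n_steps):
        # outputs at time t
        for x in range(n):
            phi_e[x] = 1.0 if V_e[x] - alpha * omega[x] > thresh else 0.0
            phi_i[x] = V_i[x] if V_i[x] > 0.0 else 0.0

        if record:
            for a in range(n_areas):
                s = 0.0
                c = 0.0
                for x in range(a * npa, (a + 1) * npa):
                    s += V_e[x]
                    c += phi_e[x]
                serp_out[a, out_offset + step] = s
                spikes_out[a, out_offset + step] = c

        if plastic:
            for post in range(n):
                vp = V_e[post]
                post_spike = phi_e[post] > 0.0
                for k in range(ee_indptr[post], ee_indptr[post + 1]):
                    pre = ee_indices[k]
                    if not (post_spike or phi_e[pre] > 0.0):
                        continue
                    active = omega_E[pre] >= theta_pre
                    if active and vp >= theta_plus:
                        w = ee_data[k] + delta
                    elif active and vp >= theta_minus:
                        w = ee_data[k] - delta
                    elif (not active) and vp >= theta_plus:
                        w = ee_data[k] - delta
                    else:
                        continue
                    if w < 0.0:
                        w = 0.0
                    elif w > w_max:
                        w = w_max
                    ee_data[k] = w

        # net inputs from time-t outputs
        for a in range(n_areas):
            c = 0.0
            for x in range(a * npa, (a + 1) * npa):
                c += phi_e[x]
            area_spikes[a] = c
        if use_csc:
            # scatter outgoing weights of spiking cells only
            for x in range(n):
                vin_e[x] = 0.0
            for pre in range(n):
                if phi_e[pre] > 0.0:
                    for k in range(csc_indptr[pre], csc_indptr[pre + 1]):
                        vin_e[csc_indices[k]] += csc_data[k]
            for x in range(n):
                s = vin_e[x]
                s += i2e[x] * phi_i[x]
                s -= kG * omega_G[x // npa]
                if have_drive:
                    s += drive[x]
                if have_noise:
                    s += k2 * noise[step, x]
                vin_e[x] = s
        else:
            for x in range(n):
                s = 0.0
                for k in range(ee_indptr[x], ee_indptr[x + 1]):
                    if phi_e[ee_indices[k]] > 0.0:
                        s += ee_data[k]
                s += i2e[x] * phi_i[x]
                s -= kG * omega_G[x // npa]
                if have_drive:
                    s += drive[x]
                if have_noise:
                    s += k2 * noise[step, x]
                vin_e[x] = s

        # inhibitory pooled drive: clipped n_inh x n_inh box mean of spikes,
        # scaled by e2i_total (identical weights to the explicit loop matrix)
        half = n_inh // 2
        for a in range(n_areas):
            base = a * npa
            # 2D prefix sums of phi over the area grid
            for r in range(grid):
                acc = 0.0
                for c in range(grid):
                    acc += phi_e[base + r * grid + c]
                    prefix[(r + 1) * (grid + 1) + (c + 1)] = (
                        prefix[r * (grid + 1) + (c + 1)] + acc
                    )
            for r in range(grid):
                r0 = r - half if r - half > 0 else 0
                r1 = r + half + 1 if r + half + 1 < grid else grid
                for c in range(grid):
                    c0 = c - half if c - half > 0 else 0
                    c1 = c + half + 1 if c + half + 1 < grid else grid
                    box = (
                        prefix[r1 * (grid + 1) + c1]
                        - prefix[r0 * (grid + 1) + c1]
                        - prefix[r1 * (grid + 1) + c0]
                        + prefix[r0 * (grid + 1) + c0]
                    )
                    count = (r1 - r0) * (c1 - c0)
                    vin_i[base + r * grid + c] = e2i_total * box / count

        # state updates
        for x in range(n):
            V_e[x] += (-V_e[x] + k1 * vin_e[x]) / tau_e
            V_i[x] += (-V_i[x] + k1 * vin_i[x]) / tau_i
            omega[x] += (-omega[x] + phi_e[x]) / tau_a
            omega_E[x] += (-omega_E[x] + phi_e[x]) / tau_f
        for a in range(n_areas):
            omega_G[a] += (-omega_G[a] + area_spikes[a]) / tau_g
        if not np.isfinite(V_e[0]):
            return -(step + 2)
    return 0
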