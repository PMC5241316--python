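"""Single-cell dynamics: leaky integration, spiking, adaptation.

Builds no network -- just exercises the cell equations to show the membrane
time constant, the strict spiking threshold and the adaptation penalty.
"""

import numpy as np

from hebbnet import ModelParams, excitatory_output, membrane_step

params = ModelParams()

# Leaky decay: V relaxes to 0 with factor (1 - 1/tau) per step.
V = np.array([1.0])
print("decay from V=1 with tau=2.5 steps:")
for step in range(1, 6):
    membrane_step(V, np.zeros(1), params.tau_exc, params)
    print(f"  step {step}: V = {V[0]:.4f}   (closed form {(1 - 1/params.tau_exc)**step:.4f})")

# Threshold is strict and adaptation raises it by alpha * omega.
for V0, omega in [(0.19, 0.0), (0.18, 0.0), (0.25, 0.01)]:
    spike = excitatory_output(np.array([V0]), np.array([omega]), params)[0]
    print(f"V={V0:.2f}, omega={omega:.2f} -> spike={int(spike)} "
          f"(effective threshold {params.thresh + params.alpha*omega:.2f})")

# A constantly driven cell settles into an adaptation-limited firing rate:
# it spikes until alpha*omega catches up with the suprathreshold drive.
V = np.array([0.0])
omega = np.array([0.0])
drive = np.array([250.0])  # suprathreshold: k1 * 250 = 2.5
spikes = 0
for _ in range(400):
    phi = excitatory_output(V, omega, params)
    spikes += int(phi[0])
    membrane_step(V, drive, params.tau_exc, params)
    omega += (-omega + phi) / params.tau_adapt
rate = spikes / 400
print(f"\ndriven cell: {rate:.2f} spikes/step over 400 steps "
      f"(adaptation-limited; (V-thresh)/alpha = {(2.5 - params.thresh)/params.alpha:.2f})")
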