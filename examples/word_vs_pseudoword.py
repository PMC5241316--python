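"""The headline contrast: band-limited responses, words vs pseudowords.

Trains and tests two replicate miniature networks (a few minutes), then
compares the 20-40 Hz responses during stimulation: total power (all
stimulus-driven oscillation), its split into evoked (phase-locked) and
induced (non-phase-locked) parts, and the frequency at which the word
response most exceeds the pseudoword response.
"""

import time

import numpy as np

from hebbnet import run_experiment
from hebbnet.experiment import miniature_config

t0 = time.time()
res = run_experiment(miniature_config(), master_seed=3, n_instances=2, n_perm=200)
print(f"2 instances trained, tested and analyzed in {time.time() - t0:.0f} s\n")

ind_w, ind_p = res.stim_band_power()
tot_w, tot_p = res.total_band_contrast()
for i in range(2):
    print(f"instance {i}: 20-40 Hz power in the stimulus window")
    print(f"   total:   word {tot_w[i]:.3g}   pseudoword {tot_p[i]:.3g}")
    print(f"   induced: word {ind_w[i]:.3g}   pseudoword {ind_p[i]:.3g}")
print(f"\nword response most exceeds pseudoword response at "
      f"{res.peak_frequency():.0f} Hz")
print(f"peak S-ERP amplitudes, paired t = {res.peak_t:.2f}")
print("\nAt this reduced scale the word response is strongly stimulus-locked "
      "(its rhythm counts as evoked power), while pseudoword responses vary "
      "from trial to trial (counted as induced); the induced contrast can "
      "therefore favour pseudowords even when the word rhythm is stronger. "
      "docs/methods.md discusses this scale effect.")
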