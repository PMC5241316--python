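"""Train a reduced-scale network and watch cell assemblies form.

Runs the learning schedule on a 6-area, 11x11 miniature architecture (a few
minutes on one CPU), then reports weight growth and the per-area footprint
of each word's cell assembly.
"""

import time

import numpy as np

from hebbnet import identify_cell_assemblies
from hebbnet.experiment import miniature_config, run_instance

cfg = miniature_config()
print("training", cfg.protocol.n_words, "words x",
      cfg.protocol.trials_per_pattern, "trials (takes a few minutes)...")
t0 = time.time()
inst = run_instance(cfg, seed=7)
print(f"done in {time.time() - t0:.0f} s")

w = inst.connectome.W_ee.data
print(f"weights after training: median {np.median(w):.3f}, "
      f"90th pct {np.quantile(w, 0.9):.2f}, at ceiling ({cfg.model.w_max}): "
      f"{(w >= cfg.model.w_max).mean():.1%}")
print("mean weight over training:",
      " -> ".join(f"{m:.4f}" for m in inst.log.mean_weight[:: max(1, len(inst.log.mean_weight)//5)]))

areas = inst.connectome.areas
for gamma in (5.0, 2.0):
    assemblies = identify_cell_assemblies(
        inst.connectome, inst.stimuli, cfg.model, cfg.protocol, gamma=gamma
    )
    print(f"\ncell-assembly membership per area (noise-free response rate "
          f"> {gamma:g}x the network mean):")
    for i, ca in enumerate(assemblies[:4]):
        per_area = {a: int(ca[inst.connectome.area_slice(a)].sum()) for a in areas}
        print(f"  word {i} ({inst.stimuli.categories[i]}): total {int(ca.sum())}  {per_area}")
print("\nat the strict threshold only the strongly driven A1 input cells "
      "qualify; relaxing it exposes the downstream cells recruited into "
      "each word's circuit")
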