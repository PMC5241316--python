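# hebbnet

A spiking neural-network model of how the cortex learns spoken words, and
an analysis toolbox for the oscillatory responses the model generates.

The network spans twelve cortical areas of the left hemisphere — six
perisylvian "language" areas (A1 … M1_i) and six extrasylvian "semantic"
areas (V1 … M1_L) — each a 25×25 sheet of leaky integrate-and-fire cells
with adaptation, paired with graded inhibitory cells, connected by sparse
topographic projections along known cortico-cortical pathways.  Learning a
word means repeatedly co-stimulating its auditory pattern (A1), its
articulatory pattern (M1_i) and a semantic grounding pattern (V1 for
object words, M1_L for action words) while a spike-gated Hebbian rule
(discretized Artola–Bröcher–Singer LTP/LTD) shapes the
excitatory-to-excitatory weights:

    Δw(j,i) = +Δ   if ω_E(i) ≥ θ_pre and V(j) ≥ θ+            (LTP)
              −Δ   if ω_E(i) ≥ θ_pre and θ− ≤ V(j) < θ+       (homosynaptic LTD)
              −Δ   if ω_E(i) <  θ_pre and V(j) ≥ θ+           (heterosynaptic LTD)

applied only at steps with a pre- or postsynaptic spike.  Training makes
distributed cell assemblies emerge — strongly interconnected cell sets
spanning several areas that act as memory circuits for the learned words.
The analysis side mirrors a standard electrophysiology pipeline: per-area
"simulated ERPs" (summed membrane potentials), six-cycle Morlet wavelet
time-frequency maps split into total / evoked / induced power, across-trial
wavelet coherence between areas, cluster-based permutation statistics and
peak-amplitude tests for word-vs-pseudoword contrasts.  Pseudowords are
novel auditory patterns recombined from 5×5 sub-squares of the trained
words' patterns — familiar parts, unfamiliar wholes.

Intended users: computational neuroscientists studying cell-assembly
accounts of language and memory, and anyone needing a compact, fully
deterministic testbed for oscillatory EEG/MEG-style analyses with known
ground truth.

## A worked example

```bash
python examples/membrane_and_spiking.py
```

prints the single-cell behaviour that everything else builds on:

```
decay from V=1 with tau=2.5 steps:
  step 1: V = 0.6000   (closed form 0.6000)
  step 2: V = 0.3600   (closed form 0.3600)
  step 3: V = 0.2160   (closed form 0.2160)
  step 4: V = 0.1296   (closed form 0.1296)
  step 5: V = 0.0778   (closed form 0.0778)
V=0.19, omega=0.00 -> spike=1 (effective threshold 0.18)
V=0.18, omega=0.00 -> spike=0 (effective threshold 0.18)
V=0.25, omega=0.01 -> spike=0 (effective threshold 0.25)

driven cell: 0.34 spikes/step over 400 steps (adaptation-limited; (V-thresh)/alpha = 0.33)
```

The membrane relaxes geometrically with factor (1 − 1/τ) per 0.5 ms step;
spiking requires the potential to *strictly* exceed 0.18 after subtracting
the adaptation penalty α·ω; and a constantly driven cell settles at the
firing rate where adaptation exactly cancels the suprathreshold drive.

The other examples scale up from there, each printing what it computes and
what the numbers mean:

* `examples/build_architecture.py` — the 12-area, 15,000-cell default
  architecture and its 22 between-area pathways;
* `examples/wavelet_analysis.py` — the total/evoked/induced decomposition
  on synthetic trials with known ground truth;
* `examples/train_miniature.py` — assembly formation in the reduced
  six-area network (a few minutes);
* `examples/word_vs_pseudoword.py` — the word/pseudoword band-power
  contrast over two replicate networks;
* `examples/coherence_dissociation.py` — category-specific long-range
  coherence (M1_i↔V1 vs M1_i↔M1_L).

A thin CLI wraps the same pipeline for shell use:

```bash
hebbnet dry-run                      # schedule sizes, no simulation
hebbnet pipeline --scale miniature --seed 1 --out run1
```

The pipeline is staged (build → train → test → analyze), writes a JSON
manifest with seeds and content hashes, and resumes from intact artifacts.

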