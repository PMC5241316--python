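# Methods

## The model

`hebbnet` simulates a network of twelve cortical areas relevant for spoken
language and its grounding in perception and action: six perisylvian areas
(primary auditory A1, auditory belt AB, parabelt PB, inferior prefrontal
PF_i, inferior premotor PM_i, inferior primary motor M1_i) and six
extrasylvian areas (primary visual V1, temporo-occipital TO, anterior
temporal AT, dorsolateral prefrontal PF_L, dorsolateral premotor PM_L,
dorsolateral primary motor M1_L).  Each area is a 25×25 grid of excitatory
cells paired one-to-one with a 25×25 grid of inhibitory cells — 15,000
cells in total.

### Cell dynamics

Excitatory cells are discrete-time leaky integrate-and-fire units with
spike-rate adaptation; inhibitory cells are graded (rectified-linear)
units.  All low-pass dynamics are integrated with the Euler scheme at
Δt = 0.5 ms, with time constants given in steps:

* membrane: τ · dV/dt = −V + k1 · (V_In + k2 · η), with τ = 2.5 steps
  (excitatory) or 5 steps (inhibitory), k1 = 0.01, and η uniform white
  noise on [−0.5, 0.5] drawn per excitatory cell per step (k2 = 0 for
  inhibitory cells);
* net input: V_In(x) = −kG · ω_G(A_x) + Σ_y w_xy · φ(y) plus any external
  stimulus; inhibitory weights carry a negative sign; the global-inhibition
  term applies to excitatory cells only;
* spiking: φ(e) = 1 iff V(e) − α·ω(e) > thresh, with thresh = 0.18 and
  α = 7 (strict inequality);
* adaptation ω, rate estimate ω_E: Euler low-passes of the spike train with
  τ_ADAPT = 10 and τ_Favg = 30 steps (both bounded in [0, 1]);
* global inhibition ω_G: per-area Euler low-pass (τ_GLOB = 12 steps) of the
  area's total spike count, fed back subtractively with gain kG to every
  excitatory cell of that area.

The noise amplitude and global-inhibition gain switch jointly with the
simulation mode: k2 = 5·(24/Δt) and kG = 0.75 during learning,
k2 = 50·(24/Δt) and kG = 0.60 during testing.  The strong testing noise
models spontaneous baseline firing; regulation of total activity is left to
global inhibition.

### Connectivity

Excitatory projections within and between areas are sparse, random and
topographic: a source cell links to a target at grid offset d within a
19×19 square with probability p0 · exp(−|d|²/2σ²) (clipped to zero outside
the square; neighbourhoods clip at area borders, no wrap-around).  Initial
weights are i.i.d. uniform on [0, 0.1].  The 22 between-area edges follow
the known cortico-cortical pathways: next-neighbour chains within each
sub-system, cross-links between the four multimodal hub areas (AT, PB,
PF_i, PF_L), within-modality "jumping" links, and long-distance links
between the auditory/articulatory and visual/motor systems.  Primary areas
are never directly connected.  Each inhibitory cell pools the excitatory
spikes of its 5×5 neighbourhood (fixed weights summing to `e2i_total`,
default 1, i.e. the local mean rate) and inhibits only its twin excitatory
cell (fixed weight `i2e_weight`, default −1); these local loops are
non-plastic.

p0 and σ are not constrained by the architecture description; the defaults
are p0 = 0.28 and σ = n/4, which produce sparse patchy maps, and both are
configuration values.

### Plasticity

Excitatory-to-excitatory synapses follow a discretized
Artola–Bröcher–Singer rule with fixed increments ±Δ (Δ = 0.0008): LTP when
the presynaptic rate estimate ω_E ≥ θ_pre = 0.05 and postsynaptic potential
V ≥ θ+ = 0.15; homosynaptic LTD when ω_E ≥ θ_pre and θ− = 0.14 ≤ V < θ+;
heterosynaptic LTD when ω_E < θ_pre and V ≥ θ+.  The rule applies only at
steps with a pre- or postsynaptic spike (inclusive OR), and is evaluated on
the time-t values from which that step's spikes were computed.  Weights are
clipped to [0, w_max]; the rule itself is unbounded above, so w_max is a
configuration value (default 0.225 at full scale).  Plasticity is active
during learning and frozen during testing.

## Protocols

**Word learning.**  Each "word" is a triplet of 19-cell binary patterns
(~3% of an area): an auditory pattern in A1 and an articulatory pattern in
M1_i always, plus a grounding pattern in V1 (object words) or M1_L (action
words).  Training presents each word's triplet simultaneously to its
primary areas for `t_on` steps followed by `isi` noise-only steps (defaults
16 and 30 steps — the precursor procedure's exact timing is not
recoverable, so both are configuration values), in one long randomly
ordered schedule: 3000 trials per word, 36,000 trials at full scale.
Stimulation adds a constant suprathreshold drive (default amplitude brings
an isolated cell to threshold within a few steps) to the pattern cells
inside the k1-rescaled net input.

**Pseudowords.**  The A1 grid is tiled into 5×5 sub-squares (25 tiles at
full scale).  Each pseudoword takes, at every tile position, the content of
that tile from one source word, preserving spatial position; with 12 words
the composition is two tiles per word plus one uniformly drawn extra (the
25-tile grid cannot hold exactly two from each of 12 words; the remainder
rule is the minimal resolution and is flagged in code).  Pseudowords are
therefore made entirely of familiar parts in familiar positions but match
no trained whole.

**Testing.**  Plasticity frozen, testing noise/inhibition mode.  Each trial:
global reset of all state variables to 0, 1.5 s of noise-driven baseline,
0.5 s of A1-only stimulation (words present only their auditory component),
1 s of noise — 6000 steps in total, 10 trials per stimulus, 240 trials at
full scale.  Each trial draws its noise from a seed stream derived from
(run seed, stimulus, trial), so recordings are independent of trial order.
During every step the per-area sum of excitatory membrane potentials (the
simulated event-related potential, S-ERP) and per-area spike counts are
recorded.

## Analysis

Single-trial S-ERPs are convolved with a six-cycle complex Morlet wavelet
(σ_t = c/2πf with c = 6; kernel truncated at ±m·σ_t with m = 3; unit-energy
normalization A = σ_t^−1/2 π^−1/4) on a 4–100 Hz, 1 Hz grid; coefficients
are computed at the native 2 kHz rate and reduced to 10 ms bins (power by
within-bin averaging of |X|², complex coefficients by bin-centre sampling).
Bins whose wavelet support extends past the epoch edge are flagged invalid
rather than zero-padded.  Total power is the across-trial average of
single-trial power; evoked power is the power of the across-trial average
S-ERP; induced power is total minus evoked.  Baseline correction subtracts
the per-frequency mean over −500 to −100 ms; it is applied to each reported
map.  Between-area synchrony is the across-trial magnitude-squared
coherence of the complex coefficients, |⟨X_s·conj(X_t)⟩|² /
(⟨|X_s|²⟩⟨|X_t|²⟩), with M1_i as seed and V1 or M1_L as target, per word
category.

Condition contrasts use two-tailed cluster-based permutation statistics on
the 20–40 Hz band-averaged induced power: a dependent-samples t per
(area, time-bin), thresholded at the two-tailed α = 0.05 critical value;
clusters form by adjacency in time within each area (areas are separate
strips unless an explicit area-adjacency list is supplied — the
architecture graph can be passed in, but no canonical area adjacency is
defined for this statistic); cluster mass is the summed t; the null
distribution of the maximum |mass| comes from within-pair condition swaps —
exhaustively enumerated when 2^n_pairs permutations suffice, otherwise
Monte-Carlo with the +1 correction.  A paired t-test on per-instance peak
S-ERP amplitudes (50–500 ms post-onset, averaged over trials and areas)
probes amplitude differences separately from phase consistency.

## Reduced-scale study conditions

The full 12-area, 15,000-cell network trained for 36,000 trials is
impractical for routine runs, so replicate experiments use a six-area
miniature: the two perisylvian primaries (A1, M1_i) around the auditory hub
PB, the two extrasylvian grounding primaries (V1, M1_L) around the
multimodal hub AT, and the PB–AT hub link; 11×11 grids; 8 words (4 object,
4 action) of 19 cells; 500 training trials per word.  The scale-down keeps
every printed cell constant except one, and calibrates the free constants:

* **Testing noise.**  The net-input equation balances per-cell noise
  against terms that sum over populations (recurrent input, global
  inhibition).  At 121 cells per area those sums shrink roughly fivefold
  while the per-cell noise does not, and the unscaled testing noise
  saturates the network (≈0.27 spikes/cell/step; membrane noise SD ≈ 3.5
  against a threshold of 0.18), erasing all stimulus specificity.  The
  miniature preset therefore scales k2 (testing) by the population ratio
  121/625.  The learning-phase k2 is kept at its printed value: it is set
  against the fixed plasticity thresholds θ± and supplies the postsynaptic
  depolarization that bootstraps cross-area LTP — scaling it down
  demonstrably prevents assembly formation.
* **Word count.**  Pseudoword recombination needs enough source words that
  any single word contributes only a small fraction of a pseudoword.  With
  four words every pseudoword necessarily contains a quarter of each word's
  pattern and ignites the corresponding assemblies almost as well as the
  words themselves; eight words restore ≈1/8 dilution (full scale: 1/12).
* **Coupling.**  w_max = 8 and p0 = 0.6 raise per-synapse and convergence
  gains so that trained assemblies can reverberate despite the smaller
  population sums; pattern size stays at 19 cells, preserving absolute
  convergence onto downstream cells.  The stimulus amplitude is 500 (in
  V_In units; k1·500 = 5 on the membrane scale).

With these conditions the trained miniature shows the core circuit
phenomena noise-free: word-selective ignition spreading from A1 through PB
into M1_i and the hub, periodic population bursts at ≈25–40 ms intervals
during word stimulation, and weaker, more irregular pseudoword responses
with spectral peaks below 20 Hz.

## What the reduced scale does and does not reproduce

The full-scale findings this package targets are (i) stronger *induced*
(non-phase-locked) 20–40 Hz power for words than pseudowords, (ii) a word
oscillation peaking at 25–30 Hz, and (iii) a category-specific double
dissociation of M1_i↔V1 / M1_i↔M1_L coherence.  At the 121-cell scale the
induced-power contrast does not reproduce — in replicate runs it is
consistently absent or inverted — for an identifiable dynamical reason:
the reduced network's word response is nearly deterministic given the
stimulus (the same assembly ignites on the same schedule every trial), so
its oscillation is phase-locked and counted as *evoked* power, while
pseudoword competition produces trial-to-trial variability that is counted
as *induced*.  In a large network the per-cell noise is strong relative to
per-synapse coupling, the ignition rhythm's phase diffuses across trials,
and the same oscillation lands in the induced component.  No setting of the
free constants (weight ceiling, connection density, drive amplitude,
local-loop gain, training length between 500 and 6000 trials per word, or
population-scaled noise/inhibition) was found that combines strong word
rhythms with sufficient phase diffusion inside the reduced network's
dynamic range; the corresponding acceptance tests are left failing rather
than redefined.  The three-synapse grounding route (A1→PB→AT→V1/M1_L)
that the coherence dissociation requires likewise consolidates unreliably
at this scale: each instance acquires a connectivity-driven preference for
one extrasylvian branch that is independent of word category.  The
peak-frequency summary is reported as the frequency at which the word
response most exceeds the pseudoword response (the ratio of total-power
spectra), because the sign-indefinite reduced-scale induced maps have no
meaningful maximum; its value varies across replicate sets.

Passing tests at miniature scale therefore demonstrate the model mechanics
(cell equations, plasticity, selective assembly formation, the analysis
chain) rather than the full-scale spectral findings, and the synthetic
stimuli exercise exactly the structure the protocols define — random sparse
patterns with no phonological or semantic structure beyond their grounding
assignment.

## Numerical choices

* Synchronous update: all outputs are computed from the previous step's
  potentials; plasticity is evaluated once per step on time-t values.
* Membrane potentials are not clipped; only the outputs are nonlinear.
* All state variables are zero at network creation and after each testing
  reset (including adaptation, rate estimates and global inhibition).
* The trial loops run in a compiled kernel that reproduces the vectorized
  reference implementation to machine precision (the testing phase uses a
  pre-transposed weight copy and an integral-image form of the inhibitory
  pooling; both are exact reformulations).
* Determinism: a single master seed is split via `SeedSequence` into
  per-stage and per-trial streams; every artifact records its seed, and
  runs are bit-reproducible at every scale.
* Degenerate inputs: the paired t-test reports a signed infinity with a
  warning when the difference has zero variance; coherence is defined as 0
  at bins with zero power; cluster p-values are 1 when no bin crosses the
  threshold.
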