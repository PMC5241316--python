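"""Training schedule, testing protocol and raw recording.

Learning: each word's full sensorimotor pattern triplet is presented to the
primary areas for a short on-period followed by a noise-only inter-trial
interval, with the spike-gated Hebbian rule active at every step; all words
are interleaved in one long randomly ordered schedule (3000 trials per word,
36,000 trials in total at full scale).

Testing: plasticity is frozen and each trial starts from a global network
reset (all state variables 0), followed by 1.5 s of noise-driven baseline,
0.5 s of auditory stimulation (the word's or pseudoword's A1 pattern only)
and 1 s of noise; the trial is 3 s = 6000 steps.  During every trial the
per-area sum of excitatory membrane potentials (the simulated event-related
potential, S-ERP) and the per-area spike count are recorded at each step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .connectome import Connectome
from .network import NetworkState, NumericalError, excitatory_output
from .params import ModelParams, ProtocolParams
from .stimuli import AUDITORY, StimulusSet, stimulus_drive

__all__ = [
    "TrialRecording",
    "TrainingLog",
    "make_schedule",
    "run_training",
    "run_testing",
    "identify_cell_assemblies",
    "serp_array",
    "save_recordings",
    "load_recordings",
]


@dataclass
class TrialRecording:
    """One testing trial: per-area S-ERP and spike-count traces plus metadata."""

    serp: np.ndarray  # (n_areas, n_steps) sum of excitatory potentials
    spikes: np.ndarray  # (n_areas, n_steps) total spikes per step
    stimulus_id: int
    condition: str  # 'word' | 'pseudoword'
    category: str | None  # 'object' | 'action' | None
    trial_index: int
    seed: int | None = None


@dataclass
class TrainingLog:
    """Schedule and periodic weight summaries of one training run."""

    schedule: np.ndarray
    mean_weight: list[float] = field(default_factory=list)
    snapshot_every: int = 200
    seed: int | None = None


def make_schedule(
    n_patterns: int, trials_per_pattern: int, rng: np.random.Generator
) -> np.ndarray:
    """Randomly ordered schedule with each pattern exactly trials_per_pattern times."""
    schedule = np.repeat(np.arange(n_patterns), trials_per_pattern)
    rng.shuffle(schedule)
    return schedule


def _run_steps(
    state: NetworkState,
    connectome: Connectome,
    drive: np.ndarray | None,
    params: ModelParams,
    n_steps: int,
    rng: np.random.Generator | None,
    plastic: bool = False,
    serp_out: np.ndarray | None = None,
    spikes_out: np.ndarray | None = None,
    out_offset: int = 0,
    csc: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> None:
    """Advance ``n_steps`` with a fixed drive; optionally learn and record.

    The learning rule is evaluated on the time-t values (the potentials and
    rate estimates from which the step's spikes were computed).  Recording,
    when requested, stores the time-t S-ERP and spike counts.  The update
    semantics are those of :func:`hebbnet.network.step_network`; the loop
    itself runs in a compiled kernel.
    """
    from ._kernels import run_steps_kernel

    n = state.V_e.shape[0]
    noise_block = (
        np.empty((0, 0)) if rng is None else rng.random((n_steps, n)) - 0.5
    )
    W_ee = connectome.W_ee
    if csc is None:
        empty = np.empty(0)
        csc = (empty, np.empty(0, dtype=W_ee.indices.dtype), np.empty(0, dtype=W_ee.indptr.dtype))
    status = run_steps_kernel(
        n_steps,
        state.V_e, state.V_i, state.omega, state.omega_E, state.omega_G,
        state.phi_e, state.phi_i,
        W_ee.data, W_ee.indices, W_ee.indptr,
        csc[0], csc[1], csc[2],
        connectome.grid, connectome.params.n_inh, connectome.params.e2i_total,
        connectome.i2e, connectome.n_areas,
        drive if drive is not None else np.empty(0),
        noise_block,
        serp_out if serp_out is not None else np.empty((0, 0)),
        spikes_out if spikes_out is not None else np.empty((0, 0)),
        out_offset,
        plastic,
        params.tau_exc, params.tau_inh, params.k1, params.k2, params.kG,
        params.thresh, params.alpha,
        params.tau_adapt, params.tau_favg, params.tau_glob,
        params.theta_pre, params.theta_plus, params.theta_minus,
        params.delta, params.w_max,
    )
    if status < 0:
        raise NumericalError(f"non-finite activity at step {state.t - status - 2}")
    state.t += n_steps


def run_training(
    connectome: Connectome,
    stimuli: StimulusSet,
    params: ModelParams,
    protocol: ProtocolParams,
    rng: np.random.Generator | int | None,
    seed: int | None = None,
) -> TrainingLog:
    """Train the network on the word set (weights updated in place).

    Runs ``trials_per_pattern * n_words`` randomly ordered learning trials.
    Each trial presents one word's full pattern triplet to the primary areas
    for ``t_on`` steps, then ``isi`` noise-only steps; the network state is
    carried across trials (no reset during learning).
    """
    if params.mode != "learning":
        params = params.with_mode("learning")
    if isinstance(rng, (int, np.integer)) or rng is None:
        seed = rng if seed is None else seed
        rng = np.random.default_rng(rng)
    schedule = make_schedule(stimuli.n_words, protocol.trials_per_pattern, rng)
    log = TrainingLog(schedule=schedule, seed=seed)
    drives = [
        stimulus_drive(connectome, w, protocol.stim_amplitude) for w in stimuli.words
    ]
    state = NetworkState.zeros(connectome)
    for i, word in enumerate(schedule):
        _run_steps(state, connectome, drives[word], params, protocol.t_on, rng, plastic=True)
        _run_steps(state, connectome, None, params, protocol.isi, rng, plastic=True)
        if (i + 1) % log.snapshot_every == 0 or i + 1 == len(schedule):
            log.mean_weight.append(float(connectome.W_ee.data.mean()))
    return log


def run_testing(
    connectome: Connectome,
    stimuli: StimulusSet,
    params: ModelParams,
    protocol: ProtocolParams,
    rng: np.random.Generator | int | None,
    seed: int | None = None,
) -> list[TrialRecording]:
    """Record the trained network's responses to words and pseudowords.

    Every stimulus (each word's A1 pattern and each pseudoword) is presented
    for ``test_trials_per_stimulus`` independent trials.  Each trial:
    global reset, baseline noise, A1 stimulation, post-stimulus noise.
    Plasticity is frozen throughout.  Each trial draws its noise from its own
    seed stream derived from (seed, stimulus, trial), so a trial's recording
    does not depend on the trials run before it.
    """
    if params.mode != "testing":
        params = params.with_mode("testing")
    if isinstance(rng, (int, np.integer)):
        seed = int(rng) if seed is None else seed
    elif rng is None and seed is None:
        seed = 0
    elif seed is None:
        # a generator was passed: derive a base seed from it
        seed = int(rng.integers(2**31))
    items: list[tuple[int, str, str | None, np.ndarray]] = []
    for i in range(stimuli.n_words):
        items.append((i, "word", stimuli.categories[i], stimuli.word_a1(i)))
    for i, pw in enumerate(stimuli.pseudowords):
        items.append((i, "pseudoword", None, pw))

    n_areas = connectome.n_areas
    steps = protocol.trial_steps
    state = NetworkState.zeros(connectome)
    W_csc = connectome.W_ee.tocsc()
    csc = (W_csc.data, W_csc.indices, W_csc.indptr)
    recordings: list[TrialRecording] = []
    for item_idx, (stim_id, condition, category, cells) in enumerate(items):
        drive = stimulus_drive(connectome, {AUDITORY: cells}, protocol.stim_amplitude)
        for trial in range(protocol.test_trials_per_stimulus):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, item_idx, trial])
            )
            state.reset()
            serp = np.empty((n_areas, steps))
            spikes = np.empty((n_areas, steps))
            _run_steps(state, connectome, None, params, protocol.baseline_steps,
                       rng, serp_out=serp, spikes_out=spikes, out_offset=0, csc=csc)
            _run_steps(state, connectome, drive, params, protocol.stim_steps,
                       rng, serp_out=serp, spikes_out=spikes,
                       out_offset=protocol.baseline_steps, csc=csc)
            _run_steps(state, connectome, None, params, protocol.post_steps,
                       rng, serp_out=serp, spikes_out=spikes,
                       out_offset=protocol.baseline_steps + protocol.stim_steps, csc=csc)
            recordings.append(
                TrialRecording(
                    serp=serp, spikes=spikes, stimulus_id=stim_id,
                    condition=condition, category=category,
                    trial_index=trial, seed=seed,
                )
            )
    return recordings


def identify_cell_assemblies(
    connectome: Connectome,
    stimuli: StimulusSet,
    params: ModelParams,
    protocol: ProtocolParams,
    gamma: float = 5.0,
    steps: int = 500,
) -> list[np.ndarray]:
    """Estimate each word's cell assembly from noise-free responses.

    Presents each word's A1 pattern with noise switched off, averages the
    firing-rate estimate omega_E over the second half of the presentation,
    and takes as assembly members all excitatory cells whose average exceeds
    ``gamma`` times the network-wide mean.  Sets may overlap.
    """
    if params.mode != "testing":
        params = params.with_mode("testing")
    assemblies: list[np.ndarray] = []
    state = NetworkState.zeros(connectome)
    settle = steps // 2
    for i in range(stimuli.n_words):
        drive = stimulus_drive(
            connectome, {AUDITORY: stimuli.word_a1(i)}, protocol.stim_amplitude
        )
        state.reset()
        _run_steps(state, connectome, drive, params, settle, rng=None)
        acc = np.zeros(connectome.n_exc)
        for _ in range(steps - settle):
            _run_steps(state, connectome, drive, params, 1, rng=None)
            acc += state.omega_E
        acc /= max(steps - settle, 1)
        mean = acc.mean()
        if mean <= 0:
            assemblies.append(np.zeros(connectome.n_exc, dtype=bool))
        else:
            assemblies.append(acc > gamma * mean)
    return assemblies


def serp_array(
    recordings: list[TrialRecording],
    condition: str | None = None,
    category: str | None = None,
    area: str | None = None,
    areas: list[str] | None = None,
) -> np.ndarray:
    """Stack selected trials' S-ERPs: (n_trials, n_areas, n_steps) or
    (n_trials, n_steps) when a single area is requested."""
    sel = [
        r for r in recordings
        if (condition is None or r.condition == condition)
        and (category is None or r.category == category)
    ]
    if not sel:
        raise ValueError("no trials match the requested condition/category")
    arr = np.stack([r.serp for r in sel])
    if area is not None:
        if areas is None:
            raise ValueError("area selection requires the connectome area list")
        arr = arr[:, areas.index(area), :]
    return arr


def save_recordings(path: str | Path, recordings: list[TrialRecording], areas: list[str]) -> None:
    """Write a recording list to a portable .npz container."""
    np.savez_compressed(
        path,
        serp=np.stack([r.serp for r in recordings]),
        spikes=np.stack([r.spikes for r in recordings]).astype(np.int16),
        stimulus_id=np.array([r.stimulus_id for r in recordings]),
        condition=np.array([r.condition for r in recordings]),
        category=np.array([r.category or "" for r in recordings]),
        trial_index=np.array([r.trial_index for r in recordings]),
        seed=np.array([-1 if r.seed is None else r.seed for r in recordings]),
        areas=np.array(areas),
    )


def load_recordings(path: str | Path) -> tuple[list[TrialRecording], list[str]]:
    with np.load(path, allow_pickle=False) as f:
        recordings = [
            TrialRecording(
                serp=f["serp"][i].astype(np.float64),
                spikes=f["spikes"][i].astype(np.float64),
                stimulus_id=int(f["stimulus_id"][i]),
                condition=str(f["condition"][i]),
                category=str(f["category"][i]) or None,
                trial_index=int(f["trial_index"][i]),
                seed=None if int(f["seed"][i]) < 0 else int(f["seed"][i]),
            )
            for i in range(f["serp"].shape[0])
        ]
        areas = [str(a) for a in f["areas"]]
    return recordings, areas
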