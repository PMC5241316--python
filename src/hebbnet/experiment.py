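"""End-to-end word/pseudoword experiments over replicate network instances.

One *instance* is an independently initialized network trained on its own
word set and then tested on words and derived pseudowords.  The experiment
level aggregates instances: induced 20-40 Hz power contrasts (word vs
pseudoword) assessed with the cluster permutation test, peak-amplitude
paired t, peak oscillation frequency, and the category-specific coherence
double dissociation between the articulatory seed area (M1_i) and the two
grounding areas (V1, M1_L).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import Connectome, build_architecture
from .params import Config
from .protocols import (
    TrainingLog,
    TrialRecording,
    run_testing,
    run_training,
    serp_array,
)
from .spectral import (
    ClusterTestResult,
    band_average,
    baseline_correct,
    cluster_permutation_test,
    evoked_induced_split,
    morlet_tfr,
    peak_amplitude_test,
    peak_serp_amplitude,
    wavelet_coherence,
)
from .stimuli import ARTICULATORY, MOTOR, VISUAL, make_pseudowords, make_word_patterns

__all__ = [
    "MINIATURE_AREAS",
    "MINIATURE_EDGES",
    "miniature_config",
    "derive_seeds",
    "InstanceResult",
    "run_instance",
    "InstanceAnalysis",
    "analyze_instance",
    "ExperimentResult",
    "run_experiment",
]

# Reduced-scale architecture used for fast replicate experiments: the two
# perisylvian primaries (A1, M1_i) around the auditory hub PB, the two
# extrasylvian grounding primaries (V1, M1_L) around the multimodal hub AT,
# and the hub-hub cross link.  Preserves the topology that matters: primary
# areas are never directly connected, and A1 reaches V1/M1_L only through
# the hubs.
MINIATURE_AREAS = ["V1", "AT", "M1_L", "A1", "PB", "M1_i"]
MINIATURE_EDGES = [
    ("A1", "PB"), ("PB", "M1_i"),
    ("V1", "AT"), ("AT", "M1_L"),
    ("PB", "AT"),
]


def miniature_config() -> Config:
    """Reduced-scale study conditions: 6 areas, 11x11 grids, 4+4 stimuli.

    The cell equations and their printed constants are unchanged; what
    scales are the free coupling constants the full-scale description leaves
    open.  A 121-cell area supplies roughly one fifth of the synaptic
    convergence of a 625-cell area, and the per-area inhibition pools
    one fifth as many cells, so per-synapse and per-loop gains must rise for
    assembly reverberation to survive the (unchanged, strong) membrane
    noise: the weight ceiling is 15, the local inhibitory loop pools raw
    spike counts (e2i_total=25) with a strong return weight, the peak
    connection probability is 0.6, and training runs 2000 trials per pattern
    (the learning increment Delta is fixed, so weight growth is
    trial-limited).  Patterns keep the full-scale 19 active cells, giving
    the same absolute convergence onto downstream cells.
    """
    cfg = Config()
    cfg.areas = list(MINIATURE_AREAS)
    cfg.edges = list(MINIATURE_EDGES)
    cfg.connectome.grid = 11
    cfg.connectome.n_exc = 9
    cfg.connectome.n_inh = 5
    cfg.connectome.p0 = 0.6
    cfg.model.w_max = 8.0
    # Testing-phase noise scales with the area population (121/625 of full
    # scale) so that spontaneous drive occupies the same relative dynamic
    # range as at full scale instead of saturating the small network; the
    # learning-phase noise is set against the fixed plasticity thresholds
    # and is therefore kept at its full-scale per-cell value.
    cfg.model.k2_testing = 50.0 * 48.0 * (121.0 / 625.0)
    cfg.protocol.n_words = 8
    cfg.protocol.cells_per_pattern = 19
    cfg.protocol.stim_amplitude = 500.0
    cfg.protocol.trials_per_pattern = 500
    cfg.validate()
    return cfg


def derive_seeds(master_seed: int, n: int, stream: str = "instance") -> list[int]:
    """Derive n reproducible per-stream seeds (< 2^31) from one master seed."""
    stream_key = int.from_bytes(stream.encode()[:4].ljust(4, b"\0"), "big") % 2**31
    ss = np.random.SeedSequence([master_seed, stream_key])
    return [int(s) for s in ss.generate_state(n) % np.uint32(2**31)]


@dataclass
class InstanceResult:
    """One trained + tested network instance."""

    connectome: Connectome
    stimuli: object
    log: TrainingLog
    recordings: list[TrialRecording]
    seed: int


def run_instance(config: Config, seed: int, train: bool = True) -> InstanceResult:
    """Build, train and test one network instance from a single seed.

    Stage seeds (build / stimuli / training / testing) are derived from
    ``seed`` so each stage is reproducible in isolation.  ``train=False``
    skips training (used for untrained null controls).
    """
    build_seed, stim_seed, train_seed, test_seed = (
        np.random.SeedSequence(seed).generate_state(4) % np.uint32(2**31)
    )
    conn = build_architecture(
        config.connectome, int(build_seed), areas=config.areas, edges=config.edges
    )
    conn.seed = int(build_seed)
    stim_rng = np.random.default_rng(int(stim_seed))
    stimuli = make_word_patterns(
        stim_rng,
        n_words=config.protocol.n_words,
        cells_per_pattern=config.protocol.cells_per_pattern,
        grid=config.connectome.grid,
    )
    make_pseudowords(stimuli, stim_rng, subsquare=config.protocol.subsquare)
    if train:
        log = run_training(
            conn, stimuli, config.model.with_mode("learning"), config.protocol,
            int(train_seed), seed=int(train_seed),
        )
    else:
        log = TrainingLog(schedule=np.empty(0, dtype=int), seed=None)
    recordings = run_testing(
        conn, stimuli, config.model.with_mode("testing"), config.protocol,
        int(test_seed), seed=int(test_seed),
    )
    return InstanceResult(
        connectome=conn, stimuli=stimuli, log=log, recordings=recordings, seed=seed
    )


def run_null_instance(config: Config, seed: int) -> InstanceResult:
    """Zero-weight untrained control: stimuli and noise only.

    All excitatory-to-excitatory weights are set to zero before testing, so
    any word/pseudoword response difference can come only from the stimulus
    patterns themselves, not from learned structure.
    """
    build_seed, stim_seed, _, test_seed = (
        np.random.SeedSequence(seed).generate_state(4) % np.uint32(2**31)
    )
    conn = build_architecture(
        config.connectome, int(build_seed), areas=config.areas, edges=config.edges
    )
    conn.W_ee.data[:] = 0.0
    stim_rng = np.random.default_rng(int(stim_seed))
    stimuli = make_word_patterns(
        stim_rng, n_words=config.protocol.n_words,
        cells_per_pattern=config.protocol.cells_per_pattern,
        grid=config.connectome.grid,
    )
    make_pseudowords(stimuli, stim_rng, subsquare=config.protocol.subsquare)
    recordings = run_testing(
        conn, stimuli, config.model.with_mode("testing"), config.protocol,
        int(test_seed), seed=int(test_seed),
    )
    log = TrainingLog(schedule=np.empty(0, dtype=int), seed=None)
    return InstanceResult(
        connectome=conn, stimuli=stimuli, log=log, recordings=recordings, seed=seed
    )


@dataclass
class InstanceAnalysis:
    """Spectral summaries of one instance's testing recordings."""

    freqs: np.ndarray
    times: np.ndarray  # s relative to stimulus onset
    induced_word: np.ndarray  # (n_areas, n_freqs, n_bins)
    induced_pseudo: np.ndarray
    band_word: np.ndarray  # (n_areas, n_bins) 20-40 Hz average
    band_pseudo: np.ndarray
    peak_word: float
    peak_pseudo: float
    coherence: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    # keys: (category, target_area) -> (n_freqs, n_bins)
    total_word: np.ndarray | None = None  # (n_areas, n_freqs, n_bins), uncorrected
    total_pseudo: np.ndarray | None = None


def analyze_instance(
    result: InstanceResult,
    config: Config,
    band: tuple[float, float] = (20.0, 40.0),
    with_coherence: bool = True,
) -> InstanceAnalysis:
    """Induced power maps, band averages, peaks and coherence for one instance."""
    areas = result.connectome.areas
    sfreq = config.model.sampling_rate
    onset = config.protocol.baseline_steps
    onset_s = onset / sfreq

    induced = {}
    totals = {}
    for condition in ("word", "pseudoword"):
        serp = serp_array(result.recordings, condition=condition)  # (tr, areas, steps)
        per_area = []
        per_area_total = []
        for ai in range(len(areas)):
            # uncorrected maps; the induced map is baseline-corrected below,
            # the total map is kept raw (non-negative) for ratio spectra
            tot, _, ind = evoked_induced_split(
                serp[:, ai, :], sfreq, onset_s, baseline_window=None
            )
            per_area.append(baseline_correct(ind.power, ind.times))
            per_area_total.append(tot.power)
        induced[condition] = np.stack(per_area)
        totals[condition] = np.stack(per_area_total)
        freqs, times = ind.freqs, ind.times

    band_word = band_average(induced["word"], freqs, band)
    band_pseudo = band_average(induced["pseudoword"], freqs, band)

    peak_word = peak_serp_amplitude(
        serp_array(result.recordings, condition="word"), sfreq, onset
    )
    peak_pseudo = peak_serp_amplitude(
        serp_array(result.recordings, condition="pseudoword"), sfreq, onset
    )

    coherence: dict[tuple[str, str], np.ndarray] = {}
    if with_coherence:
        for category in ("object", "action"):
            serp = serp_array(result.recordings, condition="word", category=category)
            coeffs = {}
            for area in (ARTICULATORY, VISUAL, MOTOR):
                if area not in areas:
                    continue
                tfr = morlet_tfr(serp[:, areas.index(area), :], sfreq)
                coeffs[area] = tfr.coeffs
            for target in (VISUAL, MOTOR):
                if ARTICULATORY in coeffs and target in coeffs:
                    cm = wavelet_coherence(
                        coeffs[ARTICULATORY], coeffs[target], freqs=freqs,
                        times=times, seed_area=ARTICULATORY, target_area=target,
                        condition=category,
                    )
                    coherence[(category, target)] = cm.coherence

    return InstanceAnalysis(
        freqs=freqs, times=times,
        induced_word=induced["word"], induced_pseudo=induced["pseudoword"],
        band_word=band_word, band_pseudo=band_pseudo,
        peak_word=peak_word, peak_pseudo=peak_pseudo,
        coherence=coherence,
        total_word=totals["word"], total_pseudo=totals["pseudoword"],
    )


@dataclass
class ExperimentResult:
    """Aggregate word/pseudoword contrast over replicate instances."""

    config: Config
    seeds: list[int]
    analyses: list[InstanceAnalysis]
    cluster: ClusterTestResult
    peak_t: float
    peak_p: float

    # -- summary quantities --------------------------------------------------

    def stim_window_mask(self, window: tuple[float, float] = (0.0, 0.5)) -> np.ndarray:
        t = self.analyses[0].times
        return (t >= window[0]) & (t <= window[1])

    def stim_band_power(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-instance mean induced band power in the stimulus window
        (averaged over areas), for words and pseudowords."""
        mask = self.stim_window_mask()
        word = np.array([a.band_word[:, mask].mean() for a in self.analyses])
        pseudo = np.array([a.band_pseudo[:, mask].mean() for a in self.analyses])
        return word, pseudo

    def word_advantage_fraction(self) -> float:
        """Fraction of instances with word > pseudoword induced band power."""
        word, pseudo = self.stim_band_power()
        return float(np.mean(word > pseudo))

    def positive_cluster_in_window(self, window: tuple[float, float] = (0.0, 0.5)) -> bool:
        """Is there a positive (word > pseudoword) cluster overlapping the
        stimulus window?"""
        t = self.analyses[0].times
        for cl in self.cluster.clusters:
            if cl.mass <= 0:
                continue
            lo, hi = cl.time_extent
            if t[hi] >= window[0] and t[lo] <= window[1]:
                return True
        return False

    def peak_frequency(self) -> float:
        """Frequency (Hz) at which the word response most exceeds the
        pseudoword response.

        Computed as the argmax of the word/pseudoword ratio of across-
        instance average total-power spectra in the stimulus window.  The
        ratio removes the broadband spectral skirt of the sustained
        stimulus response that otherwise dominates both conditions equally,
        leaving the word-specific oscillatory enhancement.
        """
        mask = self.stim_window_mask()
        word = np.mean([a.total_word for a in self.analyses], axis=0)
        pseudo = np.mean([a.total_pseudo for a in self.analyses], axis=0)
        w_spec = word[:, :, mask].mean(axis=(0, 2))
        p_spec = pseudo[:, :, mask].mean(axis=(0, 2))
        ratio = np.where(p_spec > 0, w_spec / p_spec, 0.0)
        return float(self.analyses[0].freqs[int(np.argmax(ratio))])

    def total_band_contrast(self, band: tuple[float, float] = (20.0, 40.0)) -> tuple[np.ndarray, np.ndarray]:
        """Per-instance stimulus-window band-averaged *total* power for words
        and pseudowords (areas averaged)."""
        mask = self.stim_window_mask()
        freqs = self.analyses[0].freqs
        fsel = (freqs >= band[0]) & (freqs <= band[1])
        word = np.array(
            [a.total_word[:, fsel][:, :, mask].mean() for a in self.analyses]
        )
        pseudo = np.array(
            [a.total_pseudo[:, fsel][:, :, mask].mean() for a in self.analyses]
        )
        return word, pseudo

    def coherence_dissociation(self) -> dict[str, np.ndarray]:
        """Per-instance stimulus-window 20-40 Hz coherence per category/target.

        Returns arrays 'object_V1', 'object_M1_L', 'action_V1', 'action_M1_L'.
        """
        mask = self.stim_window_mask()
        freqs = self.analyses[0].freqs
        fmask = (freqs >= 20) & (freqs <= 40)
        out: dict[str, list[float]] = {}
        for a in self.analyses:
            for (category, target), coh in a.coherence.items():
                out.setdefault(f"{category}_{target}", []).append(
                    float(coh[np.ix_(fmask, mask)].mean())
                )
        return {k: np.array(v) for k, v in out.items()}


def run_experiment(
    config: Config,
    master_seed: int,
    n_instances: int = 5,
    train: bool = True,
    with_coherence: bool = True,
    n_perm: int = 1000,
) -> ExperimentResult:
    """Run replicate instances and aggregate the word/pseudoword contrast.

    The cluster permutation test is applied across instances (paired by
    instance) to the 20-40 Hz band-averaged induced power over all areas and
    time bins of the epoch.
    """
    seeds = derive_seeds(master_seed, n_instances)
    analyses = []
    for seed in seeds:
        inst = run_instance(config, seed, train=train)
        analyses.append(analyze_instance(inst, config, with_coherence=with_coherence))
        del inst
    band_word = np.stack([a.band_word for a in analyses])  # (inst, areas, bins)
    band_pseudo = np.stack([a.band_pseudo for a in analyses])
    cluster = cluster_permutation_test(
        band_word, band_pseudo, n_perm=n_perm,
        rng=derive_seeds(master_seed, 1, stream="permutation")[0],
    )
    peak_t, peak_p = peak_amplitude_test(
        np.array([a.peak_word for a in analyses]),
        np.array([a.peak_pseudo for a in analyses]),
    )
    return ExperimentResult(
        config=config, seeds=seeds, analyses=analyses,
        cluster=cluster, peak_t=peak_t, peak_p=peak_p,
    )
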