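"""Time-frequency, coherence and statistical analysis of S-ERP recordings.

Single-trial traces are convolved with a six-cycle complex Morlet wavelet
(sigma_t = c / (2 pi f), kernel truncated at +/- m sigma_t, unit-energy
normalization A = sigma_t^(-1/2) pi^(-1/4)) on a 4-100 Hz, 1 Hz grid, and
the coefficients are reduced to 10 ms output bins.  Total power is the
across-trial average of single-trial power; evoked power is the power of
the across-trial average signal (phase-locked part); induced power is their
difference.  Baseline correction subtracts the mean over a pre-stimulus
window per frequency.  Across-trial coherence of the complex coefficients
quantifies between-area synchrony.  Condition contrasts are assessed with
two-tailed cluster-based permutation statistics (dependent-samples t as the
thresholding statistic, cluster mass = summed t, null built by within-pair
condition swaps), and with a paired t-test on peak S-ERP amplitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.fft
import scipy.stats

__all__ = [
    "morlet_kernel",
    "MorletTFR",
    "morlet_tfr",
    "TFRMap",
    "evoked_induced_split",
    "baseline_correct",
    "band_average",
    "CoherenceMap",
    "wavelet_coherence",
    "Cluster",
    "ClusterTestResult",
    "cluster_permutation_test",
    "peak_serp_amplitude",
    "peak_amplitude_test",
]

DEFAULT_FREQS = np.arange(4.0, 101.0)  # 4..100 Hz inclusive, 1 Hz steps


def morlet_kernel(
    freq: float, sfreq: float, c: float = 6.0, m: float = 3.0
) -> np.ndarray:
    """Complex Morlet wavelet at one frequency, truncated at +/- m sigma_t.

    sigma_t = c / (2 pi f); amplitude A = sigma_t^(-1/2) pi^(-1/4) gives the
    kernel unit energy.
    """
    sigma_t = c / (2.0 * np.pi * freq)
    half = int(np.floor(m * sigma_t * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    A = sigma_t ** (-0.5) * np.pi ** (-0.25)
    return A * np.exp(-(t**2) / (2.0 * sigma_t**2)) * np.exp(2j * np.pi * freq * t)


@dataclass
class MorletTFR:
    """Binned wavelet decomposition of a set of single trials.

    ``power`` averages |coefficient|^2 within each output bin per trial;
    ``coeffs`` holds the complex coefficient at each bin centre (used for
    coherence).  ``valid`` flags bins whose wavelet support lies entirely
    inside the epoch; edge bins are flagged invalid rather than zero-padded.
    """

    freqs: np.ndarray  # (n_freqs,)
    times: np.ndarray  # (n_bins,) bin-centre times, s relative to epoch start
    power: np.ndarray  # (n_trials, n_freqs, n_bins)
    coeffs: np.ndarray  # (n_trials, n_freqs, n_bins) complex
    valid: np.ndarray  # (n_freqs, n_bins) bool


def morlet_tfr(
    trials: np.ndarray,
    sfreq: float,
    freqs: np.ndarray | None = None,
    c: float = 6.0,
    m: float = 3.0,
    bin_s: float = 0.010,
) -> MorletTFR:
    """Morlet time-frequency decomposition of single-trial traces.

    ``trials`` has shape (n_trials, n_times) (a single trace is promoted).
    Coefficients are computed at the native sampling rate by FFT convolution
    and then reduced to ``bin_s`` bins: power by averaging |X|^2 within the
    bin, complex coefficients by sampling the bin centre.
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=np.float64))
    n_trials, n_times = trials.shape
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, dtype=np.float64)
    fmin = freqs.min()
    support = 2.0 * m * (c / (2.0 * np.pi * fmin))
    epoch = n_times / sfreq
    if epoch < support:
        raise ValueError(
            f"epoch ({epoch:.3f} s) shorter than the wavelet support at "
            f"{fmin:g} Hz; need at least {support:.3f} s"
        )

    bin_len = max(int(round(bin_s * sfreq)), 1)
    n_bins = n_times // bin_len
    centers = np.arange(n_bins) * bin_len + bin_len // 2
    times = centers / sfreq

    max_half = int(np.floor(m * (c / (2.0 * np.pi * fmin)) * sfreq))
    nfft = scipy.fft.next_fast_len(n_times + 2 * max_half + 1)
    sig_f = scipy.fft.fft(trials, nfft, axis=-1)

    power = np.empty((n_trials, len(freqs), n_bins))
    coeffs = np.empty((n_trials, len(freqs), n_bins), dtype=np.complex128)
    valid = np.empty((len(freqs), n_bins), dtype=bool)
    for fi, f in enumerate(freqs):
        kern = morlet_kernel(f, sfreq, c, m)
        half = len(kern) // 2
        kern_f = scipy.fft.fft(kern, nfft)
        conv = scipy.fft.ifft(sig_f * kern_f, axis=-1)
        x = conv[:, half : half + n_times]  # 'same' alignment
        p = np.abs(x) ** 2
        usable = n_bins * bin_len
        power[:, fi] = p[:, :usable].reshape(n_trials, n_bins, bin_len).mean(axis=-1)
        coeffs[:, fi] = x[:, centers]
        valid[fi] = (centers >= half) & (centers < n_times - half)
    return MorletTFR(freqs=freqs, times=times, power=power, coeffs=coeffs, valid=valid)


@dataclass
class TFRMap:
    """A trial-averaged time-frequency power map (one kind, possibly many areas)."""

    power: np.ndarray  # (..., n_freqs, n_bins)
    freqs: np.ndarray
    times: np.ndarray  # s relative to stimulus onset
    kind: str  # 'total' | 'evoked' | 'induced'
    valid: np.ndarray | None = None
    baseline_window: tuple[float, float] | None = None


def baseline_correct(
    power: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float] = (-0.5, -0.1),
) -> np.ndarray:
    """Subtract the mean over the baseline window, per frequency row."""
    mask = (times >= window[0]) & (times <= window[1])
    if not mask.any():
        raise ValueError(f"baseline window {window} outside epoch [{times[0]}, {times[-1]}]")
    return power - power[..., mask].mean(axis=-1, keepdims=True)


def evoked_induced_split(
    trials: np.ndarray,
    sfreq: float,
    onset_s: float,
    freqs: np.ndarray | None = None,
    c: float = 6.0,
    m: float = 3.0,
    bin_s: float = 0.010,
    baseline_window: tuple[float, float] | None = (-0.5, -0.1),
) -> tuple[TFRMap, TFRMap, TFRMap]:
    """Total / evoked / induced power of one condition's trials.

    Evoked power is the wavelet power of the across-trial average S-ERP;
    induced power is the across-trial mean single-trial power minus the
    evoked power.  Each returned map is baseline-corrected (window given in
    seconds relative to stimulus onset); pass ``baseline_window=None`` to
    skip correction.  Requires at least two trials.
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=np.float64))
    if trials.shape[0] < 2:
        raise ValueError("induced power is undefined for fewer than 2 trials")
    tfr = morlet_tfr(trials, sfreq, freqs, c, m, bin_s)
    total = tfr.power.mean(axis=0)
    evoked = morlet_tfr(trials.mean(axis=0), sfreq, freqs, c, m, bin_s).power[0]
    induced = total - evoked
    times = tfr.times - onset_s
    maps = []
    for kind, p in (("total", total), ("evoked", evoked), ("induced", induced)):
        if baseline_window is not None:
            p = baseline_correct(p, times, baseline_window)
        maps.append(
            TFRMap(power=p, freqs=tfr.freqs, times=times, kind=kind,
                   valid=tfr.valid, baseline_window=baseline_window)
        )
    return tuple(maps)


def band_average(
    power: np.ndarray, freqs: np.ndarray, band: tuple[float, float] = (20.0, 40.0)
) -> np.ndarray:
    """Average power over a frequency band (inclusive), collapsing that axis."""
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency of {freqs}")
    return power[..., mask, :].mean(axis=-2)


@dataclass
class CoherenceMap:
    """Across-trial coherence of complex wavelet coefficients between two areas."""

    coherence: np.ndarray  # (n_freqs, n_bins) in [0, 1]
    freqs: np.ndarray
    times: np.ndarray
    seed_area: str = ""
    target_area: str = ""
    condition: str = ""


def wavelet_coherence(
    coeffs_seed: np.ndarray,
    coeffs_target: np.ndarray,
    freqs: np.ndarray | None = None,
    times: np.ndarray | None = None,
    **labels: str,
) -> CoherenceMap:
    """Magnitude-squared coherence across trials, per (frequency, time) bin.

    coh = |<X_seed conj(X_target)>|^2 / (<|X_seed|^2> <|X_target|^2>), the
    expectation taken across trials.  Inputs are (n_trials, n_freqs, n_bins)
    complex coefficient arrays from :func:`morlet_tfr`.
    """
    if coeffs_seed.shape != coeffs_target.shape:
        raise ValueError(
            f"trial-count/shape mismatch: {coeffs_seed.shape} vs {coeffs_target.shape}"
        )
    cross = (coeffs_seed * np.conj(coeffs_target)).mean(axis=0)
    p_seed = (np.abs(coeffs_seed) ** 2).mean(axis=0)
    p_target = (np.abs(coeffs_target) ** 2).mean(axis=0)
    denom = p_seed * p_target
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(denom > 0, np.abs(cross) ** 2 / denom, 0.0)
    n_freqs, n_bins = coh.shape
    return CoherenceMap(
        coherence=coh,
        freqs=np.arange(n_freqs, dtype=float) if freqs is None else freqs,
        times=np.arange(n_bins, dtype=float) if times is None else times,
        **labels,
    )


# ---------------------------------------------------------------------------
# cluster-based permutation statistics
# ---------------------------------------------------------------------------


@dataclass
class Cluster:
    """A contiguous suprathreshold region of the (area, time) grid."""

    mass: float  # sum of t values (signed)
    bins: list[tuple[int, int]]  # (area, time-bin) members
    p: float = 1.0

    @property
    def time_extent(self) -> tuple[int, int]:
        ts = [b[1] for b in self.bins]
        return min(ts), max(ts)

    @property
    def areas(self) -> list[int]:
        return sorted({b[0] for b in self.bins})


@dataclass
class ClusterTestResult:
    t_map: np.ndarray  # (n_areas, n_bins) dependent-samples t
    threshold: float
    clusters: list[Cluster]  # sorted by |mass|, largest first
    p_min: float
    n_perm: int
    exhaustive: bool


def _find_clusters(
    t_map: np.ndarray, threshold: float, adjacency: list[tuple[int, int]] | None
) -> list[Cluster]:
    """Group suprathreshold bins into clusters, separately per sign.

    Adjacency is along time within each area; with an area ``adjacency``
    edge list, simultaneous bins of connected areas also join.
    """
    n_areas, n_bins = t_map.shape
    clusters: list[Cluster] = []
    for sign in (1.0, -1.0):
        supra = sign * t_map > threshold
        if not supra.any():
            continue
        # union-find over suprathreshold bins
        idx_map = {tuple(b): i for i, b in enumerate(np.argwhere(supra))}
        parent = list(range(len(idx_map)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i: int, j: int) -> None:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri

        for (a, t), i in idx_map.items():
            if (a, t + 1) in idx_map:
                union(i, idx_map[(a, t + 1)])
        if adjacency:
            for a, b in adjacency:
                for t in range(n_bins):
                    if (a, t) in idx_map and (b, t) in idx_map:
                        union(idx_map[(a, t)], idx_map[(b, t)])
        groups: dict[int, list[tuple[int, int]]] = {}
        for bin_at, i in idx_map.items():
            groups.setdefault(find(i), []).append(bin_at)
        for members in groups.values():
            mass = float(sum(t_map[a, t] for a, t in members))
            clusters.append(Cluster(mass=mass, bins=sorted(members)))
    clusters.sort(key=lambda cl: abs(cl.mass), reverse=True)
    return clusters


def _paired_t(diff: np.ndarray) -> np.ndarray:
    """Dependent-samples t over the first (pair) axis; 0 where variance is 0."""
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), np.where(mean != 0, np.inf, 0.0))
    return np.sign(mean) * np.abs(t)


def cluster_permutation_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    adjacency: list[tuple[int, int]] | None = None,
    rng: np.random.Generator | int | None = None,
) -> ClusterTestResult:
    """Two-tailed cluster-based permutation test on paired observations.

    ``cond_a``/``cond_b`` have shape (n_pairs, n_areas, n_bins): one
    band-averaged power map per pair (e.g. per network instance) and
    condition.  Bins are thresholded at the two-tailed dependent-samples t
    critical value for ``alpha``; clusters form by time adjacency within
    each area (plus simultaneous bins of ``adjacency``-connected areas if
    given); cluster mass is the summed t.  The null distribution of the
    maximum |mass| is built by swapping conditions within pairs — all
    2^n_pairs sign patterns when that is <= n_perm (exact test), otherwise
    ``n_perm`` random patterns with the +1 Monte-Carlo correction.
    """
    cond_a = np.asarray(cond_a, dtype=np.float64)
    cond_b = np.asarray(cond_b, dtype=np.float64)
    if cond_a.shape != cond_b.shape:
        raise ValueError(f"condition shapes differ: {cond_a.shape} vs {cond_b.shape}")
    if cond_a.ndim == 2:  # single-area input -> add area axis
        cond_a = cond_a[:, None, :]
        cond_b = cond_b[:, None, :]
    n_pairs = cond_a.shape[0]
    if n_pairs < 2:
        raise ValueError("need at least 2 pairs")
    diff = cond_a - cond_b
    df = n_pairs - 1
    threshold = float(scipy.stats.t.ppf(1.0 - alpha / 2.0, df))
    t_map = _paired_t(diff)
    clusters = _find_clusters(t_map, threshold, adjacency)
    if not clusters:
        return ClusterTestResult(
            t_map=t_map, threshold=threshold, clusters=[], p_min=1.0,
            n_perm=n_perm, exhaustive=False,
        )

    exhaustive = 2**n_pairs <= n_perm
    if exhaustive:
        signs_iter = (
            np.array([1.0 if (k >> i) & 1 else -1.0 for i in range(n_pairs)])
            for k in range(2**n_pairs)
        )
        total = 2**n_pairs
    else:
        if isinstance(rng, (int, np.integer)) or rng is None:
            rng = np.random.default_rng(rng)
        signs_iter = (
            rng.choice([-1.0, 1.0], size=n_pairs) for _ in range(n_perm)
        )
        total = n_perm

    null_max = np.empty(total)
    for k, signs in enumerate(signs_iter):
        perm_t = _paired_t(diff * signs[:, None, None])
        perm_clusters = _find_clusters(perm_t, threshold, adjacency)
        null_max[k] = max((abs(c.mass) for c in perm_clusters), default=0.0)

    for cl in clusters:
        exceed = int(np.sum(null_max >= abs(cl.mass)))
        cl.p = exceed / total if exhaustive else (exceed + 1) / (total + 1)
    p_min = min(cl.p for cl in clusters)
    return ClusterTestResult(
        t_map=t_map, threshold=threshold, clusters=clusters,
        p_min=p_min, n_perm=total, exhaustive=exhaustive,
    )


# ---------------------------------------------------------------------------
# peak-amplitude analysis
# ---------------------------------------------------------------------------


def peak_serp_amplitude(
    serp: np.ndarray,
    sfreq: float,
    onset_step: int,
    window_s: tuple[float, float] = (0.05, 0.5),
) -> float:
    """Mean peak S-ERP in a post-onset window, across trials and areas.

    ``serp`` has shape (n_trials, n_areas, n_steps); the per-trial, per-area
    peak within the window is averaged over trials and areas.
    """
    lo = onset_step + int(round(window_s[0] * sfreq))
    hi = onset_step + int(round(window_s[1] * sfreq))
    return float(serp[..., lo:hi].max(axis=-1).mean())


def peak_amplitude_test(
    word_values: np.ndarray, pseudo_values: np.ndarray
) -> tuple[float, float]:
    """Paired t-test of per-instance peak amplitudes, word vs pseudoword.

    Returns (t, p).  A zero-variance nonzero difference is degenerate and
    reported as signed infinity with a warning.
    """
    word_values = np.asarray(word_values, dtype=np.float64)
    pseudo_values = np.asarray(pseudo_values, dtype=np.float64)
    if word_values.shape != pseudo_values.shape:
        raise ValueError("conditions have different numbers of instances")
    diff = word_values - pseudo_values
    if diff.std(ddof=1) == 0.0:
        if np.allclose(diff, 0.0):
            return 0.0, 1.0
        warnings.warn("zero-variance nonzero difference: degenerate paired t", stacklevel=2)
        return float(np.sign(diff.mean()) * np.inf), 0.0
    t, p = scipy.stats.ttest_rel(word_values, pseudo_values)
    return float(t), float(p)
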