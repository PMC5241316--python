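"""Staged, resumable simulation pipeline with reproducibility metadata.

The pipeline runs build -> train -> test -> analyze, serializing each
stage's artifact to a portable array container and recording content hashes
in a JSON run manifest.  A later invocation with the same output directory
resumes from the first stage whose artifact is missing; artifacts whose
hashes no longer match the manifest are refused rather than silently
reused.  All randomness derives from one master seed split into per-stage
streams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__ as _version
from .connectome import Connectome, build_architecture
from .experiment import miniature_config
from .params import Config
from .protocols import (
    load_recordings,
    run_testing,
    run_training,
    save_recordings,
    serp_array,
)
from .spectral import band_average, evoked_induced_split, peak_serp_amplitude
from .stimuli import StimulusSet, make_pseudowords, make_word_patterns

__all__ = [
    "RunManifest",
    "full_config",
    "stage_seeds",
    "save_stimuli",
    "load_stimuli",
    "run_pipeline",
    "dry_run_summary",
]

STAGES = ("build", "train", "test", "analyze")
ARTIFACTS = {
    "build": "connectome.npz",
    "train": "connectome_trained.npz",
    "test": "recordings.npz",
    "analyze": "results.tsv",
}


def full_config() -> Config:
    """The default full-scale study conditions (12 areas, 25x25 grids)."""
    return Config()


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Split a master seed into one reproducible stream per stage."""
    state = np.random.SeedSequence(master_seed).generate_state(4) % np.uint32(2**31)
    return dict(zip(("build", "stimuli", "train", "test"), (int(s) for s in state)))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, seeds, artifact hashes, timings."""

    config: dict
    master_seed: int
    seeds: dict[str, int]
    version: str = _version
    hashes: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        return cls(**json.loads(path.read_text()))


def save_stimuli(path: str | Path, stimuli: StimulusSet) -> None:
    arrays: dict[str, np.ndarray] = {"grid": np.int64(stimuli.grid)}
    arrays["categories"] = np.array(stimuli.categories)
    for i, word in enumerate(stimuli.words):
        for area, cells in word.items():
            arrays[f"word{i}_{area}"] = cells
    for i, pw in enumerate(stimuli.pseudowords):
        arrays[f"pseudo{i}"] = pw
    np.savez_compressed(path, **arrays)


def load_stimuli(path: str | Path) -> StimulusSet:
    with np.load(path, allow_pickle=False) as f:
        categories = [str(c) for c in f["categories"]]
        words = []
        for i in range(len(categories)):
            prefix = f"word{i}_"
            words.append(
                {k[len(prefix):]: f[k] for k in f.files if k.startswith(prefix)}
            )
        pseudos = []
        for i in range(len(categories)):
            key = f"pseudo{i}"
            if key in f.files:
                pseudos.append(f[key])
        return StimulusSet(
            grid=int(f["grid"]), words=words, categories=categories, pseudowords=pseudos
        )


def analysis_settings(config: Config) -> tuple[np.ndarray, tuple[float, float]]:
    """Frequency axis and baseline window compatible with the trial length.

    The standard axis is 4-100 Hz with a -500..-100 ms baseline; short test
    epochs raise the lowest frequency so the wavelet support (2 m sigma_t)
    fits, and shrink the baseline window into the available pre-stimulus
    period.
    """
    sfreq = config.model.sampling_rate
    epoch_s = config.protocol.trial_steps / sfreq
    c, m = 6.0, 3.0
    fmin = max(4.0, np.ceil(2.0 * m * c / (2.0 * np.pi * epoch_s * 0.95)))
    freqs = np.arange(fmin, 101.0)
    base_s = config.protocol.baseline_steps / sfreq
    if base_s >= 0.6:
        window = (-0.5, -0.1)
    else:
        window = (-0.85 * base_s, -0.1 * base_s)
    return freqs, window


def dry_run_summary(config: Config) -> dict[str, int]:
    """Schedule sizes of a run under this config, without simulating."""
    p = config.protocol
    n_stimuli = 2 * p.n_words  # words + pseudowords
    n_test_trials = n_stimuli * p.test_trials_per_stimulus
    return {
        "areas": len(config.areas) if config.areas else 12,
        "cells_total": 2 * (len(config.areas) if config.areas else 12) * config.connectome.grid**2,
        "training_trials": p.n_words * p.trials_per_pattern,
        "testing_trials": n_test_trials,
        "steps_per_testing_trial": p.trial_steps,
        "total_testing_steps": n_test_trials * p.trial_steps,
    }


def _check_artifact(outdir: Path, manifest: RunManifest, stage: str) -> bool:
    """True if the stage artifact exists and matches the manifest hash."""
    path = outdir / ARTIFACTS[stage]
    if not path.exists():
        return False
    recorded = manifest.hashes.get(stage)
    if recorded is None:
        return False
    actual = _sha256(path)
    if actual != recorded:
        raise RuntimeError(
            f"artifact {path} does not match the manifest hash for stage "
            f"{stage!r} ({actual[:12]} != {recorded[:12]}); delete it (and all "
            f"later artifacts) to recompute, or restore the original file"
        )
    return True


def run_pipeline(
    config: Config,
    master_seed: int,
    outdir: str | Path,
    verbose: bool = True,
) -> RunManifest:
    """Run (or resume) build -> train -> test -> analyze into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    seeds = stage_seeds(master_seed)
    config_snapshot = {
        "model": dataclasses.asdict(config.model),
        "connectome": dataclasses.asdict(config.connectome),
        "protocol": dataclasses.asdict(config.protocol),
        "areas": config.areas,
        "edges": [list(e) for e in config.edges] if config.edges else None,
    }
    if manifest_path.exists():
        manifest = RunManifest.load(manifest_path)
        if manifest.master_seed != master_seed or manifest.config != config_snapshot:
            raise RuntimeError(
                f"{manifest_path} was produced with a different seed or config; "
                "use a fresh output directory"
            )
    else:
        manifest = RunManifest(config=config_snapshot, master_seed=master_seed, seeds=seeds)

    def log(msg: str) -> None:
        if verbose:
            print(msg, flush=True)

    def finish(stage: str, t0: float) -> None:
        manifest.hashes[stage] = _sha256(outdir / ARTIFACTS[stage])
        manifest.timings[stage] = time.time() - t0
        manifest.save(manifest_path)

    # build ------------------------------------------------------------------
    if not _check_artifact(outdir, manifest, "build"):
        t0 = time.time()
        log("build: constructing architecture")
        conn = build_architecture(
            config.connectome, seeds["build"], areas=config.areas, edges=config.edges
        )
        conn.seed = seeds["build"]
        conn.save(outdir / ARTIFACTS["build"])
        finish("build", t0)

    # train ------------------------------------------------------------------
    if not _check_artifact(outdir, manifest, "train"):
        t0 = time.time()
        log("train: running learning schedule")
        conn = Connectome.load(outdir / ARTIFACTS["build"])
        rng = np.random.default_rng(seeds["stimuli"])
        stimuli = make_word_patterns(
            rng, config.protocol.n_words, config.protocol.cells_per_pattern,
            config.connectome.grid,
        )
        make_pseudowords(stimuli, rng, config.protocol.subsquare)
        save_stimuli(outdir / "stimuli.npz", stimuli)
        run_training(
            conn, stimuli, config.model.with_mode("learning"), config.protocol,
            seeds["train"], seed=seeds["train"],
        )
        conn.save(outdir / ARTIFACTS["train"])
        finish("train", t0)

    # test -------------------------------------------------------------------
    if not _check_artifact(outdir, manifest, "test"):
        t0 = time.time()
        log("test: recording responses")
        conn = Connectome.load(outdir / ARTIFACTS["train"])
        stimuli = load_stimuli(outdir / "stimuli.npz")
        recordings = run_testing(
            conn, stimuli, config.model.with_mode("testing"), config.protocol,
            seeds["test"], seed=seeds["test"],
        )
        save_recordings(outdir / ARTIFACTS["test"], recordings, conn.areas)
        finish("test", t0)

    # analyze ----------------------------------------------------------------
    if not _check_artifact(outdir, manifest, "analyze"):
        t0 = time.time()
        log("analyze: time-frequency decomposition")
        recordings, areas = load_recordings(outdir / ARTIFACTS["test"])
        sfreq = config.model.sampling_rate
        onset = config.protocol.baseline_steps
        freqs, baseline_window = analysis_settings(config)
        band_lims = (max(20.0, freqs[0]), min(40.0, freqs[-1]))
        stim_end = min(0.5, config.protocol.stim_steps / sfreq)
        rows = []
        for condition in ("word", "pseudoword"):
            serp = serp_array(recordings, condition=condition)
            band_by_area = []
            for ai, area in enumerate(areas):
                _, _, induced = evoked_induced_split(
                    serp[:, ai, :], sfreq, onset / sfreq,
                    freqs=freqs, baseline_window=baseline_window,
                )
                band = band_average(induced.power, induced.freqs, band=band_lims)
                stim = (induced.times >= 0) & (induced.times <= stim_end)
                band_by_area.append(band[stim].mean())
                rows.append((condition, area, band[stim].mean()))
            peak = peak_serp_amplitude(serp, sfreq, onset)
            rows.append((condition, "ALL", float(np.mean(band_by_area))))
            rows.append((condition, "PEAK_SERP", peak))
        with open(outdir / ARTIFACTS["analyze"], "w") as f:
            f.write("condition\tarea\tvalue\n")
            for cond, area, value in rows:
                f.write(f"{cond}\t{area}\t{value:.6g}\n")
        finish("analyze", t0)

    return manifest
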