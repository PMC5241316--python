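"""Model constants and configuration handling.

All scalar constants of the cell equations live in :class:`ModelParams`.
Time constants are expressed in simulation steps (one step = ``dt`` ms), so
Euler updates use ``1/tau`` directly.  The network runs in one of two modes,
``learning`` or ``testing``, which jointly switch the noise amplitude ``k2``
and the global-inhibition strength ``kG``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "ModelParams",
    "ConnectomeParams",
    "ProtocolParams",
    "Config",
    "load_config",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-range values in a config file."""


@dataclass
class ModelParams:
    """Scalar constants of the membrane, output, adaptation and learning rules.

    Defaults are the values used in all simulations.  ``k2`` scales with the
    integration step so that the noise drive is invariant to ``dt``.
    """

    dt: float = 0.5  # integration step, ms
    tau_exc: float = 2.5  # membrane time constant, excitatory cells (steps)
    tau_inh: float = 5.0  # membrane time constant, inhibitory cells (steps)
    k1: float = 0.01  # total input rescaling factor
    k2_learning: float | None = None  # noise amplitude, learning (5 * 24/dt)
    k2_testing: float | None = None  # noise amplitude, testing (50 * 24/dt)
    kG_learning: float = 0.75  # global inhibition strength, learning
    kG_testing: float = 0.60  # global inhibition strength, testing
    thresh: float = 0.18  # spiking threshold
    alpha: float = 7.0  # adaptation strength
    tau_adapt: float = 10.0  # adaptation time constant (steps)
    tau_favg: float = 30.0  # firing-rate-estimate time constant (steps)
    tau_glob: float = 12.0  # global-inhibition time constant (steps)
    theta_plus: float = 0.15  # postsynaptic LTP threshold
    theta_minus: float = 0.14  # postsynaptic LTD threshold
    theta_pre: float = 0.05  # presynaptic rate threshold
    delta: float = 0.0008  # learning increment
    w_max: float = 0.225  # hard upper bound on excitatory weights
    mode: str = "testing"  # 'learning' or 'testing'

    def __post_init__(self) -> None:
        if self.k2_learning is None:
            self.k2_learning = 5.0 * (24.0 / self.dt)
        if self.k2_testing is None:
            self.k2_testing = 50.0 * (24.0 / self.dt)
        self.validate()

    def validate(self) -> None:
        for name in ("dt", "tau_exc", "tau_inh", "tau_adapt", "tau_favg", "tau_glob"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.delta <= 0:
            raise ConfigError(f"delta must be > 0, got {self.delta}")
        if not self.theta_minus < self.theta_plus:
            raise ConfigError(
                f"theta_minus ({self.theta_minus}) must be < theta_plus ({self.theta_plus})"
            )
        if self.mode not in ("learning", "testing"):
            raise ConfigError(f"mode must be 'learning' or 'testing', got {self.mode!r}")
        if self.w_max <= 0:
            raise ConfigError(f"w_max must be > 0, got {self.w_max}")

    # -- mode-dependent constants -------------------------------------------

    @property
    def k2(self) -> float:
        """Noise amplitude for the active mode (inhibitory cells have k2 = 0)."""
        return self.k2_learning if self.mode == "learning" else self.k2_testing

    @property
    def kG(self) -> float:
        """Global-inhibition strength for the active mode."""
        return self.kG_learning if self.mode == "learning" else self.kG_testing

    @property
    def sampling_rate(self) -> float:
        """Samples per second of all recorded traces (1000 / dt_ms)."""
        return 1000.0 / self.dt

    def with_mode(self, mode: str) -> "ModelParams":
        return dataclasses.replace(self, mode=mode)


@dataclass
class ConnectomeParams:
    """Geometry and connectivity constants of the area graph."""

    grid: int = 25  # side of the square cell grid per area (25x25 default)
    n_exc: int = 19  # excitatory projection neighbourhood (n x n square)
    n_inh: int = 5  # excitatory->inhibitory fan-in neighbourhood
    p0: float = 0.28  # peak (zero-distance) connection probability
    sigma_factor: float = 0.25  # Gaussian falloff sigma = sigma_factor * n
    w_init_max: float = 0.1  # initial weights ~ U[0, w_init_max]
    i2e_weight: float = -1.0  # fixed inhibitory->twin-excitatory weight
    e2i_total: float = 1.0  # summed excitatory->inhibitory fan-in weight

    def validate(self) -> None:
        if self.grid < 1:
            raise ConfigError("grid must be >= 1")
        for name in ("n_exc", "n_inh"):
            n = getattr(self, name)
            if n < 1 or n % 2 == 0:
                raise ConfigError(f"{name} must be odd and >= 1, got {n}")
        if not 0.0 <= self.p0 <= 1.0:
            raise ConfigError(f"p0 must be in [0, 1], got {self.p0}")
        if self.sigma_factor <= 0:
            raise ConfigError("sigma_factor must be > 0")
        if self.i2e_weight > 0:
            raise ConfigError("i2e_weight must be <= 0 (inhibitory)")


@dataclass
class ProtocolParams:
    """Timing and size constants of the training and testing protocols."""

    n_words: int = 12
    cells_per_pattern: int = 19
    trials_per_pattern: int = 3000  # learning presentations per word
    t_on: int = 16  # learning-trial stimulus-on period (steps)
    isi: int = 30  # learning inter-trial interval, noise only (steps)
    stim_amplitude: float = 225.0  # external drive to pattern cells (V_In units)
    baseline_steps: int = 3000  # testing: pre-stimulus noise period (1.5 s)
    stim_steps: int = 1000  # testing: stimulus-on period (0.5 s)
    post_steps: int = 2000  # testing: post-stimulus noise period (1.0 s)
    test_trials_per_stimulus: int = 10
    subsquare: int = 5  # pseudoword recombination tile side

    @property
    def trial_steps(self) -> int:
        return self.baseline_steps + self.stim_steps + self.post_steps

    def validate(self) -> None:
        if self.n_words < 1:
            raise ConfigError("n_words must be >= 1")
        if self.cells_per_pattern < 1:
            raise ConfigError("cells_per_pattern must be >= 1")
        for name in (
            "trials_per_pattern",
            "t_on",
            "isi",
            "baseline_steps",
            "stim_steps",
            "post_steps",
            "test_trials_per_stimulus",
            "subsquare",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.stim_amplitude < 0:
            raise ConfigError("stim_amplitude must be >= 0")


@dataclass
class Config:
    """Bundle of all parameter groups plus the area list."""

    model: ModelParams = field(default_factory=ModelParams)
    connectome: ConnectomeParams = field(default_factory=ConnectomeParams)
    protocol: ProtocolParams = field(default_factory=ProtocolParams)
    areas: list[str] | None = None  # None -> default 12-area architecture
    edges: list[tuple[str, str]] | None = None  # None -> default edge list

    def validate(self) -> None:
        self.model.validate()
        self.connectome.validate()
        self.protocol.validate()


_SECTIONS = {"model": ModelParams, "connectome": ConnectomeParams, "protocol": ProtocolParams}


def load_config(path: str | Path | None = None) -> Config:
    """Load a YAML config; missing keys fall back to the defaults.

    The file holds up to three mappings (``model``, ``connectome``,
    ``protocol``) whose keys mirror the parameter field names, plus optional
    ``areas`` / ``edges`` lists.  An empty or absent file yields the full
    defaults.  Unknown keys or invalid values raise :class:`ConfigError`
    naming the offending key.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config root must be a mapping, got {type(loaded).__name__}")
        raw = loaded

    cfg_kwargs: dict = {}
    for section, cls in _SECTIONS.items():
        sect = raw.pop(section, {}) or {}
        if not isinstance(sect, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(sect) - valid
        if unknown:
            raise ConfigError(f"unknown key(s) in section {section!r}: {sorted(unknown)}")
        try:
            cfg_kwargs[section] = cls(**sect)
        except TypeError as exc:  # pragma: no cover - defensive
            raise ConfigError(str(exc)) from exc

    areas = raw.pop("areas", None)
    edges = raw.pop("edges", None)
    if edges is not None:
        edges = [tuple(e) for e in edges]
    if raw:
        raise ConfigError(f"unknown top-level key(s): {sorted(raw)}")

    cfg = Config(areas=areas, edges=edges, **cfg_kwargs)
    cfg.validate()
    return cfg
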