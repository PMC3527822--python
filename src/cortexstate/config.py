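"""Simulation and pipeline configuration.

The defaults encode the study conditions the analysis is calibrated against:
two cortical states (synchronized / desynchronized) alternating with mean
epoch durations of order minutes, four extracellular cell classes
(superficial / deep pyramidal cells and fast-spiking interneurons) with
class-specific baseline rates, state-modulation gains, burstiness and
waveform shapes, and a laminar probe spanning ~1.6 mm of cortex.

Two presets are provided:

``anesthetized()``
    Urethane-like conditions: epoch means 167 s (synchronized) / 165 s
    (desynchronized); class baseline rates 0.9 / 3.0 / 5.8 / 5.1 Hz for
    sPC / dPC / sFS / dFS.

``unanesthetized()``
    Drug-free head-restrained conditions: epoch means 197 / 423 s; class
    baseline rates 2.2 / 4.5 / 7.5 / 13.5 Hz.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field

import yaml

CELL_CLASSES = ("sPC", "dPC", "sFS", "dFS")

#: assumed pia-to-white-matter cortical thickness, micrometers
CORTICAL_THICKNESS_UM = 1600.0

#: epochs shorter than this are never generated (left truncation of the
#: exponential epoch-duration law); avoids un-analyzable slivers
EPOCH_FLOOR_S = 10.0


class ConfigError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


@dataclass
class WaveformShape:
    """Target features of a mean extracellular spike waveform.

    trough_to_peak_ms : time from the negative trough to the following
        positive peak. Narrow (~0.35 ms) for FS cells, wide (~0.7 ms) for PCs.
    half_width_ms : width of the trough at half its baseline-to-trough depth.
    asymmetry : (a_R - a_L) / (a_R + a_L) of the two baseline-to-peak
        amplitudes flanking the trough, in [-1, 1]; higher for FS cells.
    """

    trough_to_peak_ms: float = 0.70
    half_width_ms: float = 0.30
    asymmetry: float = 0.10


@dataclass
class ClassParams:
    """Generator parameters for one cell class.

    baseline_rate_hz is the synchronized-state average rate (spikes are
    concentrated in up phases, so the within-up rate is baseline / up
    fraction).  desync_gain is the design ratio FR_d / FR_s.  rate_spread
    is the log-normal sigma of per-unit baselines around the class value
    (median preserved); gain_rate_exponent makes the per-unit gain scale as
    (unit_baseline / class_baseline) ** exponent, which produces
    higher-baseline units being more enhanced by desynchronization.
    burst_prob is the probability that a spike initiates a doublet whose
    extra spike trails by an exponential lag of mean burst_isi_ms.
    """

    n_units: int = 10
    baseline_rate_hz: float = 3.0
    desync_gain: float = 1.0
    burst_prob: float = 0.0
    burst_isi_ms: float = 4.0
    depth_range_um: tuple[float, float] = (800.0, 1100.0)
    waveform: WaveformShape = field(default_factory=WaveformShape)
    rate_spread: float = 0.0
    gain_rate_exponent: float = 0.0


@dataclass
class LfpParams:
    """Amplitudes (arbitrary μV-like units) of the two LFP components.

    The slow component is sign-locked to up/down phases during synchronized
    epochs (fundamental ≈ 1 / (up mean + down mean) Hz) and absent during
    desynchronized epochs; broadband Gaussian noise is present throughout.
    """

    sync_osc_amp: float = 100.0
    noise_amp: float = 10.0
    smooth_ms: float = 50.0


@dataclass
class StimParams:
    """Optional stimulation schedule (evoked-desynchronization mode).

    Each event is a pulse train of ``duration_s`` that switches the cortex
    into the desynchronized state for ``desync_s`` seconds after its offset.
    """

    n_events: int = 0
    first_onset_s: float = 30.0
    period_s: float = 30.0
    duration_s: float = 1.0
    desync_s: float = 6.0


def _default_classes() -> dict[str, ClassParams]:
    pc_wf = WaveformShape(0.70, 0.30, 0.10)
    fs_wf = WaveformShape(0.35, 0.18, 0.40)
    return {
        "sPC": ClassParams(10, 0.9, 1.0, 0.15, 4.0, (100.0, 500.0),
                           dataclasses.replace(pc_wf)),
        "dPC": ClassParams(20, 3.0, 1.0, 0.15, 4.0, (800.0, 1100.0),
                           dataclasses.replace(pc_wf)),
        "sFS": ClassParams(5, 5.8, 1.0, 0.05, 4.0, (100.0, 500.0),
                           dataclasses.replace(fs_wf)),
        "dFS": ClassParams(8, 5.1, 1.0, 0.05, 4.0, (800.0, 1100.0),
                           dataclasses.replace(fs_wf)),
    }


@dataclass
class SimulationConfig:
    """Full parameterization of one synthetic laminar recording."""

    duration_s: float = 600.0
    n_channels: int = 16
    channel_spacing_um: float = 100.0
    lfp_fs: float = 500.0
    wf_fs: float = 20000.0
    wf_n_samples: int = 61
    state_mean_durations: dict[str, float] = field(
        default_factory=lambda: {"synchronized": 167.0, "desynchronized": 165.0})
    updown_mean_durations: dict[str, float] = field(
        default_factory=lambda: {"up": 0.5, "down": 0.5})
    updown_bin_s: float = 0.01
    class_params: dict[str, ClassParams] = field(default_factory=_default_classes)
    lfp_params: LfpParams = field(default_factory=LfpParams)
    stim: StimParams = field(default_factory=StimParams)
    spatial_decay_um: float = 50.0
    waveform_noise: float = 0.0
    iso_distance_median: float = 45.0
    iso_distance_spread: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        if self.n_channels < 1 or self.channel_spacing_um <= 0:
            raise ConfigError("channel layout invalid")
        if self.lfp_fs <= 0 or self.wf_fs <= 0:
            raise ConfigError("sampling rates must be positive")
        for state in ("synchronized", "desynchronized"):
            m = self.state_mean_durations.get(state)
            if m is None or (not math.isinf(m) and m <= 0):
                raise ConfigError(f"state mean duration for {state!r} must be "
                                  "positive (math.inf = one-state mode)")
        if math.isinf(self.state_mean_durations["synchronized"]):
            raise ConfigError("synchronized mean duration cannot be infinite")
        for phase in ("up", "down"):
            if self.updown_mean_durations.get(phase, 0) <= 0:
                raise ConfigError(f"up/down mean duration for {phase!r} must be positive")
        if self.updown_bin_s <= 0:
            raise ConfigError("updown_bin_s must be positive")
        for name, cp in self.class_params.items():
            if cp.n_units < 0:
                raise ConfigError(f"{name}: n_units must be >= 0")
            if cp.baseline_rate_hz <= 0:
                raise ConfigError(f"{name}: baseline_rate_hz must be positive")
            if cp.desync_gain < 0:
                raise ConfigError(f"{name}: desync_gain must be >= 0")
            if not 0.0 <= cp.burst_prob <= 1.0:
                raise ConfigError(f"{name}: burst_prob must be in [0, 1]")
            if cp.burst_isi_ms <= 0:
                raise ConfigError(f"{name}: burst_isi_ms must be positive")
            lo, hi = cp.depth_range_um
            if not (0.0 <= lo <= hi <= CORTICAL_THICKNESS_UM):
                raise ConfigError(
                    f"{name}: depth range must lie within [0, {CORTICAL_THICKNESS_UM}] um")
            if not -1.0 <= cp.waveform.asymmetry <= 1.0:
                raise ConfigError(f"{name}: waveform asymmetry must be in [-1, 1]")
            if cp.waveform.trough_to_peak_ms <= 0 or cp.waveform.half_width_ms <= 0:
                raise ConfigError(f"{name}: waveform times must be positive")
        if self.lfp_params.sync_osc_amp < 0 or self.lfp_params.noise_amp < 0:
            raise ConfigError("LFP amplitudes must be >= 0")

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "class_params" in d:
            cps = {}
            for name, cp in d["class_params"].items():
                cp = dict(cp)
                if isinstance(cp.get("waveform"), dict):
                    cp["waveform"] = WaveformShape(**cp["waveform"])
                if "depth_range_um" in cp:
                    cp["depth_range_um"] = tuple(cp["depth_range_um"])
                cps[name] = ClassParams(**cp)
            d["class_params"] = cps
        if isinstance(d.get("lfp_params"), dict):
            d["lfp_params"] = LfpParams(**d["lfp_params"])
        if isinstance(d.get("stim"), dict):
            d["stim"] = StimParams(**d["stim"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def anesthetized(**overrides) -> SimulationConfig:
    """Urethane-anesthesia preset (short, balanced state epochs)."""
    cfg = SimulationConfig(**overrides)
    return cfg


def unanesthetized(**overrides) -> SimulationConfig:
    """Drug-free preset: longer desynchronized epochs, higher baselines."""
    cfg = SimulationConfig(**overrides)
    cfg.state_mean_durations = {"synchronized": 197.0, "desynchronized": 423.0}
    for name, rate in zip(CELL_CLASSES, (2.2, 4.5, 7.5, 13.5)):
        cfg.class_params[name].baseline_rate_hz = rate
    return cfg


def invivo_like(**overrides) -> SimulationConfig:
    """Directional preset for the qualitative population pattern.

    Superficial PCs and FS cells of both layers are suppressed by
    desynchronization (gain < 1); deep PCs have per-unit gains that increase
    with baseline rate, giving a mixed enhanced/suppressed population and a
    positive baseline-rate-vs-modulation correlation among PCs but not FSs.
    """
    cfg = unanesthetized(**overrides)
    cfg.class_params["sPC"].n_units = 30
    cfg.class_params["dPC"].n_units = 60
    cfg.class_params["sFS"].n_units = 8
    cfg.class_params["dFS"].n_units = 15
    cfg.class_params["sPC"].desync_gain = 0.45
    cfg.class_params["sFS"].desync_gain = 0.55
    cfg.class_params["dFS"].desync_gain = 0.55
    cfg.class_params["dPC"].desync_gain = 0.95
    cfg.class_params["dPC"].rate_spread = 0.8
    cfg.class_params["dPC"].gain_rate_exponent = 0.35
    return cfg


PRESETS = {
    "anesthetized": anesthetized,
    "unanesthetized": unanesthetized,
    "invivo_like": invivo_like,
}
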