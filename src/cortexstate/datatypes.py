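"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SYNCHRONIZED = "synchronized"
DESYNCHRONIZED = "desynchronized"
NA = "n/a"


@dataclass
class Recording:
    """Multi-channel LFP matrix with probe geometry.

    lfp : array, shape (n_frames, n_channels), μV
    fs : sampling rate, Hz
    channel_depths_um : depth of each recording site below the pia,
        strictly increasing
    stim_times_s : optional stimulation onset timestamps
    """

    lfp: np.ndarray
    fs: float
    channel_depths_um: np.ndarray
    stim_times_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lfp = np.asarray(self.lfp)
        self.channel_depths_um = np.asarray(self.channel_depths_um, dtype=float)
        if self.lfp.ndim != 2:
            raise ValueError("lfp must be 2-D (n_frames, n_channels)")
        if self.lfp.shape[1] != self.channel_depths_um.size:
            raise ValueError("channel_depths_um length must match lfp columns")
        if self.channel_depths_um.size > 1 and np.any(np.diff(self.channel_depths_um) <= 0):
            raise ValueError("channel depths must be strictly increasing")
        if self.stim_times_s is not None:
            self.stim_times_s = np.asarray(self.stim_times_s, dtype=float)

    @property
    def duration_s(self) -> float:
        return self.lfp.shape[0] / self.fs

    @property
    def n_channels(self) -> int:
        return self.lfp.shape[1]

    def infragranular_channel(self) -> int:
        """Default channel for state evaluation: middle of the deepest third."""
        n = self.n_channels
        return int(n - 1 - (n // 3) // 2) if n >= 3 else n - 1


@dataclass
class UnitTable:
    """Spike-sorted units: timestamps, mean waveforms, quality metrics.

    spikes : DataFrame with columns (unit_id, timestamp_s)
    units : DataFrame indexed by unit_id; must contain isolation_distance,
        may carry ground-truth columns (cell_class, depth_um, ...) when
        synthetic.
    waveforms : unit_id -> (n_channels, n_samples) mean waveform
    """

    spikes: pd.DataFrame
    units: pd.DataFrame
    waveforms: dict[int, np.ndarray] = field(default_factory=dict)
    wf_fs: float = 20000.0

    def spike_times(self, unit_id: int) -> np.ndarray:
        sel = self.spikes.loc[self.spikes["unit_id"] == unit_id, "timestamp_s"]
        return np.sort(sel.to_numpy(dtype=float))

    @property
    def unit_ids(self) -> np.ndarray:
        return self.units.index.to_numpy()


@dataclass
class PowerSeries:
    """Per-1-s-bin low-frequency (0–7 Hz) LFP power."""

    bin_start_s: np.ndarray
    power: np.ndarray
    bin_s: float = 1.0
    band_hz: tuple[float, float] = (0.0, 7.0)

    def __post_init__(self) -> None:
        self.bin_start_s = np.asarray(self.bin_start_s, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    @property
    def log_power(self) -> np.ndarray:
        """log10 power; NaN where power is zero (flagged bins)."""
        with np.errstate(divide="ignore"):
            lp = np.log10(self.power)
        lp[~np.isfinite(lp)] = np.nan
        return lp


@dataclass
class StateSegmentation:
    """Per-1-s-bin cortical-state labels plus derived epoch list."""

    bin_start_s: np.ndarray
    bin_labels: np.ndarray          # SYNCHRONIZED / DESYNCHRONIZED per bin
    epochs: list[tuple[str, float, float]]
    bin_s: float = 1.0
    updown_bin_s: float | None = None
    updown_labels: np.ndarray | None = None   # 'up'/'down'/NA per fine bin
    status: str = "ok"
    warnings: list[str] = field(default_factory=list)

    def epoch_durations(self, state: str, exclude_boundary: bool = False) -> np.ndarray:
        eps = self.epochs
        if exclude_boundary and len(eps) > 2:
            eps = eps[1:-1]
        return np.array([e - s for st, s, e in eps if st == state])

    def state_duration(self, state: str) -> float:
        return float(np.sum(self.bin_labels == state) * self.bin_s)

    def bins_of(self, state: str) -> np.ndarray:
        return np.flatnonzero(self.bin_labels == state)


@dataclass
class StimWindows:
    """2-s windows flanking each stimulation event.

    events : DataFrame with columns (stim_time_s, pre_start_s, pre_end_s,
        post_start_s, post_end_s, effective)
    n_dropped : events discarded for being too close to the recording edges
    """

    events: pd.DataFrame
    n_dropped: int = 0


@dataclass
class GroundTruth:
    """Generator-side truth channel used only by tests and scoring."""

    state_bin_labels: np.ndarray
    state_epochs: list[tuple[str, float, float]]
    updown_labels: np.ndarray
    updown_bin_s: float
    units: pd.DataFrame   # cell_class, depth_um, fr_sync_hz, fr_desync_hz, gain
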