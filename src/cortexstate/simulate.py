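"""Synthetic laminar-recording generator with a ground-truth channel.

The generator emulates the statistical structure the downstream analysis
assumes:

* a two-state alternation (synchronized / desynchronized) whose epoch
  durations are exponential with configurable means, left-truncated at 10 s
  (by memorylessness the realized mean is the configured mean + 10 s);
* up/down phase alternation inside synchronized epochs (exponential phase
  durations, labels at 10 ms resolution);
* per-class inhomogeneous-Poisson spike trains: within synchronized epochs
  all spiking is concentrated in up phases at rate baseline / up-fraction so
  the synchronized-state average recovers the class baseline; during
  desynchronized epochs firing is tonic at baseline x gain.  Each spike
  independently seeds a doublet with probability ``burst_prob`` (extra spike
  at an exponential lag of mean ``burst_isi_ms``);
* parametric biphasic waveform templates hitting the three classification
  features, with Gaussian spatial decay across channels;
* an LFP whose slow component is sign-locked to up/down phases during
  synchronized epochs, plus broadband noise, so 0-7 Hz power separates the
  states.

Everything is driven by one integer seed through named substreams, so a
dataset is bit-reproducible from its configuration.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .config import CELL_CLASSES, EPOCH_FLOOR_S, SimulationConfig, WaveformShape
from .datatypes import (DESYNCHRONIZED, NA, SYNCHRONIZED, GroundTruth,
                        Recording, UnitTable)
from .waveforms import FeatureError, extract_features


class TemplateError(ValueError):
    """Requested waveform features unrealizable by the template family."""


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent child stream of the master seed."""
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def truncated_exp_mean(mean_s: float, floor_s: float = EPOCH_FLOOR_S) -> float:
    """Mean of an exponential left-truncated at ``floor_s`` (memoryless shift)."""
    return floor_s + mean_s


# --------------------------------------------------------------------------
# state sequence

@dataclass
class UpDownPhases:
    """Fine-grained up/down labeling plus the continuous phase intervals."""
    labels: np.ndarray            # 'up' / 'down' / 'n/a' per fine bin
    bin_s: float
    intervals: list[tuple[str, float, float]] = field(default_factory=list)

    def up_fraction(self, sync_duration_s: float) -> float:
        up = sum(e - s for ph, s, e in self.intervals if ph == "up")
        return up / sync_duration_s if sync_duration_s > 0 else float("nan")


def generate_state_sequence(cfg: SimulationConfig,
                            rng: np.random.Generator | None = None
                            ) -> tuple[np.ndarray, list[tuple[str, float, float]]]:
    """Alternating synchronized/desynchronized epochs.

    Returns per-1-s-bin labels and the continuous epoch list (state, start,
    end), clipped to the recording duration.  A stimulation schedule, when
    configured, overrides the spontaneous alternation: the recording is
    synchronized except for a fixed desynchronized window after each pulse
    train.  An infinite desynchronized mean is the one-state flag (the
    recording never leaves the synchronized state).
    """
    rng = rng if rng is not None else substream(cfg.seed, "states")
    T = cfg.duration_s
    epochs: list[tuple[str, float, float]] = []
    if cfg.stim.n_events > 0:
        onsets = stim_times(cfg)
        t = 0.0
        for on in onsets:
            d_start = on + cfg.stim.duration_s
            d_end = min(d_start + cfg.stim.desync_s, T)
            if d_start > t:
                epochs.append((SYNCHRONIZED, t, min(d_start, T)))
            if d_end > d_start and d_start < T:
                epochs.append((DESYNCHRONIZED, d_start, d_end))
            t = d_end
        if t < T:
            epochs.append((SYNCHRONIZED, t, T))
    elif math.isinf(cfg.state_mean_durations[DESYNCHRONIZED]):
        epochs.append((SYNCHRONIZED, 0.0, T))
    else:
        means = cfg.state_mean_durations
        # stationary-ish initial state, weighted by mean epoch durations
        state = SYNCHRONIZED if rng.random() < (
            means[SYNCHRONIZED] / (means[SYNCHRONIZED] + means[DESYNCHRONIZED])
        ) else DESYNCHRONIZED
        t = 0.0
        while t < T:
            dur = EPOCH_FLOOR_S + rng.exponential(means[state])
            end = min(t + dur, T)
            epochs.append((state, t, end))
            t = end
            state = DESYNCHRONIZED if state == SYNCHRONIZED else SYNCHRONIZED
    labels = bin_labels_from_epochs(epochs, T, bin_s=1.0)
    return labels, epochs


def bin_labels_from_epochs(epochs, duration_s: float, bin_s: float = 1.0) -> np.ndarray:
    """Label each bin by the epoch covering its center."""
    n = int(round(duration_s / bin_s))
    centers = (np.arange(n) + 0.5) * bin_s
    starts = np.array([s for _, s, _ in epochs])
    idx = np.clip(np.searchsorted(starts, centers, side="right") - 1, 0, len(epochs) - 1)
    return np.array([epochs[i][0] for i in idx], dtype=object)


def stim_times(cfg: SimulationConfig) -> np.ndarray:
    s = cfg.stim
    return s.first_onset_s + s.period_s * np.arange(s.n_events)


def generate_updown_phases(cfg: SimulationConfig,
                           epochs: list[tuple[str, float, float]],
                           rng: np.random.Generator | None = None) -> UpDownPhases:
    """Alternating up/down phases inside every synchronized epoch.

    Phase durations are exponential with the configured means; labels are
    produced at ``cfg.updown_bin_s`` resolution (desynchronized time is
    'n/a') while the exact continuous boundaries are kept for spike
    placement.
    """
    rng = rng if rng is not None else substream(cfg.seed, "updown")
    mu = cfg.updown_mean_durations
    intervals: list[tuple[str, float, float]] = []
    for state, s, e in epochs:
        if state != SYNCHRONIZED:
            continue
        phase = "up" if rng.random() < mu["up"] / (mu["up"] + mu["down"]) else "down"
        t = s
        while t < e:
            dur = rng.exponential(mu[phase])
            end = min(t + dur, e)
            if end > t:
                intervals.append((phase, t, end))
            t = end
            phase = "down" if phase == "up" else "up"
    n = int(round(cfg.duration_s / cfg.updown_bin_s))
    labels = np.full(n, NA, dtype=object)
    centers = (np.arange(n) + 0.5) * cfg.updown_bin_s
    if intervals:
        starts = np.array([s for _, s, _ in intervals])
        ends = np.array([e for _, _, e in intervals])
        idx = np.searchsorted(starts, centers, side="right") - 1
        ok = (idx >= 0) & (centers < ends[np.clip(idx, 0, None)])
        phases = np.array([ph for ph, _, _ in intervals], dtype=object)
        labels[ok] = phases[idx[ok]]
    return UpDownPhases(labels=labels, bin_s=cfg.updown_bin_s, intervals=intervals)


# --------------------------------------------------------------------------
# spike trains

def _poisson_times(rng, rate_hz: float, start: float, end: float) -> np.ndarray:
    dur = end - start
    if rate_hz <= 0 or dur <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * dur)
    return start + rng.random(n) * dur


def generate_spike_trains(cfg: SimulationConfig,
                          epochs: list[tuple[str, float, float]],
                          updown: UpDownPhases,
                          rng: np.random.Generator | None = None
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-unit spike timestamps plus the realized design-rate table.

    Returns (spikes, units): spikes has columns (unit_id, timestamp_s);
    units is indexed by unit_id with the ground-truth class, depth, per-unit
    baseline/gain and design rates (fr_sync_hz / fr_desync_hz include the
    doublet inflation factor 1 + burst_prob).
    """
    rng = rng if rng is not None else substream(cfg.seed, "spikes")
    sync_T = sum(e - s for st, s, e in epochs if st == SYNCHRONIZED)
    # design up fraction is the configured renewal ratio, not the realized
    # one: a data-adaptive rate would pin every realization's mean rate to
    # baseline exactly and distort the sampling variance the state tests see
    mu = cfg.updown_mean_durations
    up_frac = mu["up"] / (mu["up"] + mu["down"])
    up_iv = [(s, e) for ph, s, e in updown.intervals if ph == "up"]
    desync_iv = [(s, e) for st, s, e in epochs if st == DESYNCHRONIZED]

    unit_rows, spike_frames = [], []
    uid = 0
    for cls in CELL_CLASSES:
        if cls not in cfg.class_params:
            continue
        cp = cfg.class_params[cls]
        for _ in range(cp.n_units):
            depth = rng.uniform(*cp.depth_range_um)
            base = cp.baseline_rate_hz * math.exp(cp.rate_spread * rng.standard_normal()) \
                if cp.rate_spread > 0 else cp.baseline_rate_hz
            gain = cp.desync_gain * (base / cp.baseline_rate_hz) ** cp.gain_rate_exponent
            r_up = base / up_frac if sync_T > 0 else 0.0
            if r_up > 1000.0 / cp.burst_isi_ms:
                warnings.warn(f"unit {uid}: up-phase rate {r_up:.1f} Hz exceeds the "
                              f"refractory-feasible ceiling {1000.0 / cp.burst_isi_ms:.0f} Hz")
            seeds = [_poisson_times(rng, r_up, s, e) for s, e in up_iv]
            seeds += [_poisson_times(rng, base * gain, s, e) for s, e in desync_iv]
            t = np.concatenate(seeds) if seeds else np.empty(0)
            if cp.burst_prob > 0 and t.size:
                mask = rng.random(t.size) < cp.burst_prob
                lags = rng.exponential(cp.burst_isi_ms / 1000.0, int(mask.sum()))
                extra = t[mask] + lags
                t = np.concatenate([t, extra[extra < cfg.duration_s]])
            t.sort()
            iso = cfg.iso_distance_median * math.exp(
                cfg.iso_distance_spread * rng.standard_normal())
            unit_rows.append({
                "unit_id": uid, "cell_class": cls, "depth_um": depth,
                "seed_rate_hz": base, "desync_gain": gain,
                "fr_sync_hz": base * (1 + cp.burst_prob),
                "fr_desync_hz": base * gain * (1 + cp.burst_prob),
                "isolation_distance": iso, "n_spikes": t.size,
            })
            spike_frames.append(pd.DataFrame({"unit_id": uid, "timestamp_s": t}))
            uid += 1
    units = pd.DataFrame(unit_rows).set_index("unit_id") if unit_rows else \
        pd.DataFrame(columns=["cell_class"]).rename_axis("unit_id")
    spikes = pd.concat(spike_frames, ignore_index=True) if spike_frames else \
        pd.DataFrame({"unit_id": pd.Series(dtype=int),
                      "timestamp_s": pd.Series(dtype=float)})
    return spikes, units


# --------------------------------------------------------------------------
# waveform templates

def solve_template(shape: WaveformShape, fs: float, n_samples: int = 61,
                   max_iter: int = 25) -> np.ndarray:
    """Biphasic template (unit trough depth) realizing the three features.

    Sum of three Gaussians — a negative trough flanked by two positive
    peaks — whose positions, widths and amplitudes are refined by fixed
    point iteration against the feature extractor until the re-measured
    trough-to-peak time, half-width and asymmetry match the request to a
    quarter sample / 0.005.  Raises :class:`TemplateError` if the request
    is outside the family (e.g. half-width not smaller than twice the
    trough-to-peak time, |asymmetry| = 1).
    """
    t2p, hw, asym = shape.trough_to_peak_ms, shape.half_width_ms, shape.asymmetry
    if abs(asym) >= 1.0:
        raise TemplateError("asymmetry magnitude must be < 1")
    if hw >= 2.0 * t2p:
        raise TemplateError("half-width must be < 2 x trough-to-peak time")
    dt_ms = 1e3 / fs
    t = np.arange(n_samples) * dt_ms
    trough_ms = 0.4 * n_samples * dt_ms
    if trough_ms + t2p + 3 * dt_ms > t[-1]:
        raise TemplateError("trough-to-peak time does not fit the waveform window")

    sig_n = hw / 2.355          # FWHM of a Gaussian = 2.355 sigma
    pos_r = trough_ms + t2p
    pos_l = trough_ms - max(0.3, 0.8 * sig_n * 2.355)
    sig_p = 0.12
    a_l, a_r = 0.25 * (1 - asym), 0.25 * (1 + asym)

    def build():
        w = (-np.exp(-0.5 * ((t - trough_ms) / sig_n) ** 2)
             + a_l * np.exp(-0.5 * ((t - pos_l) / sig_p) ** 2)
             + a_r * np.exp(-0.5 * ((t - pos_r) / sig_p) ** 2))
        return w

    target_sum = 0.5
    for _ in range(max_iter):
        w = build()
        try:
            f = extract_features(w, fs)
        except FeatureError as err:
            raise TemplateError(f"template family cannot realize request: {err}")
        # measured flanking amplitudes, for the asymmetry correction
        n_base = max(1, int(round(0.2 * w.size)))
        baseline = float(np.mean(w[:n_base]))
        ti = int(np.argmin(w))
        m_l = max(float(np.max(w[:ti])) - baseline, 0.0)
        m_r = max(float(np.max(w[ti + 1:])) - baseline, 0.0)
        err_t2p = t2p - f.trough_to_peak_ms
        err_hw = hw - f.half_width_ms
        d_l = target_sum * (1 - asym) / 2 - m_l
        d_r = target_sum * (1 + asym) / 2 - m_r
        if (abs(err_t2p) < 0.25 * dt_ms and abs(err_hw) < 0.25 * dt_ms
                and abs(asym - f.asymmetry) < 0.005):
            return w
        pos_r += err_t2p
        sig_n *= max(0.2, min(5.0, hw / max(f.half_width_ms, 1e-9)))
        a_l = max(a_l + d_l, 0.0)
        a_r = max(a_r + d_r, 0.0)
    raise TemplateError(
        f"template refinement did not converge for {shape!r}")


def generate_waveform_templates(cfg: SimulationConfig, units: pd.DataFrame,
                                rng: np.random.Generator | None = None,
                                amplitude_uv: float = 100.0
                                ) -> dict[int, np.ndarray]:
    """Per-unit (n_channels, n_samples) mean waveforms.

    The soma channel (nearest the unit's depth) carries the class template;
    amplitude decays across channels as a Gaussian in depth distance
    (sigma = ``cfg.spatial_decay_um``).  Optional per-sample Gaussian noise
    of ``cfg.waveform_noise`` x trough amplitude.
    """
    rng = rng if rng is not None else substream(cfg.seed, "waveforms")
    depths = channel_depths(cfg)
    templates = {cls: solve_template(cfg.class_params[cls].waveform,
                                     cfg.wf_fs, cfg.wf_n_samples)
                 for cls in units["cell_class"].unique()}
    out: dict[int, np.ndarray] = {}
    for uid, row in units.iterrows():
        base = templates[row["cell_class"]] * amplitude_uv
        decay = np.exp(-0.5 * ((depths - row["depth_um"]) / cfg.spatial_decay_um) ** 2)
        W = decay[:, None] * base[None, :]
        if cfg.waveform_noise > 0:
            W = W + rng.standard_normal(W.shape) * cfg.waveform_noise * amplitude_uv
        out[uid] = W.astype(np.float32)
    return out


def channel_depths(cfg: SimulationConfig) -> np.ndarray:
    """Probe geometry: site depths in μm, shallowest first."""
    return cfg.channel_spacing_um * (np.arange(cfg.n_channels) + 1.0)


# --------------------------------------------------------------------------
# LFP

def generate_lfp(cfg: SimulationConfig,
                 epochs: list[tuple[str, float, float]],
                 updown: UpDownPhases,
                 rng: np.random.Generator | None = None) -> Recording:
    """LFP = slow component sign-locked to up/down phases + broadband noise.

    During synchronized epochs the slow component is a rectified-sine
    carrier at the slow-oscillation fundamental (1 / (up mean + down mean))
    whose polarity is locked to the current phase: negative in up phases
    (surface-negative depolarization convention), positive in down phases.
    The polarity envelope is smoothed with a 50 ms Gaussian.  The carrier
    keeps low-frequency power in every synchronized 1-s bin even when a
    single long phase spans the whole bin; desynchronized epochs carry
    broadband noise only.
    """
    rng = rng if rng is not None else substream(cfg.seed, "lfp")
    fs = cfg.lfp_fs
    n = int(round(cfg.duration_s * fs))
    sign = np.zeros(n, dtype=np.float32)
    for ph, s, e in updown.intervals:
        i0, i1 = int(round(s * fs)), int(round(e * fs))
        sign[i0:i1] = -1.0 if ph == "up" else 1.0
    sigma = cfg.lfp_params.smooth_ms / 1000.0 * fs
    if sigma > 0:
        sign = gaussian_filter1d(sign, sigma, mode="nearest")
    mu = cfg.updown_mean_durations
    f0 = 1.0 / (mu["up"] + mu["down"])
    carrier = np.abs(np.sin(np.pi * f0 * np.arange(n) / fs)).astype(np.float32)
    slow = sign * carrier
    amp, noise = cfg.lfp_params.sync_osc_amp, cfg.lfp_params.noise_amp
    lfp = np.empty((n, cfg.n_channels), dtype=np.float32)
    for ch in range(cfg.n_channels):   # channel loop keeps peak memory low
        lfp[:, ch] = amp * slow + noise * rng.standard_normal(n).astype(np.float32)
    stim = stim_times(cfg) if cfg.stim.n_events > 0 else None
    return Recording(lfp=lfp, fs=fs, channel_depths_um=channel_depths(cfg),
                     stim_times_s=stim)


# --------------------------------------------------------------------------
# full dataset

@dataclass
class SimDataset:
    recording: Recording
    unit_table: UnitTable
    truth: GroundTruth
    config: SimulationConfig


def generate_dataset(cfg: SimulationConfig, out_dir=None) -> SimDataset:
    """Generate a complete annotated dataset from one seed.

    The same configuration and seed always produce bit-identical output;
    passing ``out_dir`` also writes the on-disk representation (flat binary
    LFP + sidecar, spike table, waveform container, ground truth, manifest).
    """
    cfg.validate()
    bin_labels, epochs = generate_state_sequence(cfg)
    updown = generate_updown_phases(cfg, epochs)
    spikes, units = generate_spike_trains(cfg, epochs, updown)
    waveforms = generate_waveform_templates(cfg, units)
    recording = generate_lfp(cfg, epochs, updown)
    units.attrs["channel_depths_um"] = channel_depths(cfg)
    unit_table = UnitTable(spikes=spikes, units=units, waveforms=waveforms,
                           wf_fs=cfg.wf_fs)
    truth = GroundTruth(state_bin_labels=bin_labels, state_epochs=epochs,
                        updown_labels=updown.labels, updown_bin_s=updown.bin_s,
                        units=units)
    ds = SimDataset(recording, unit_table, truth, cfg)
    if out_dir is not None:
        from . import io as _io
        _io.write_dataset(ds, out_dir)
    return ds


# --------------------------------------------------------------------------
# doublet / Poisson burst algebra

def expected_burst_fraction(rate_hz: float, window_s: float,
                            up_mean_s: float | None, up_fraction: float,
                            burst_prob: float, burst_isi_s: float) -> float:
    """Expected fraction of ISIs <= window for a generator unit.

    Within the synchronized state, seed spikes are Poisson at
    rate / up_fraction inside up phases of exponential mean ``up_mean_s``;
    an ISI beats the window only if the next seed arrives before both the
    window and the up-phase end (both hazards memoryless).  Doublets add
    one short ISI per burst.  Pass ``up_mean_s=None`` for tonic
    (desynchronized) firing.
    """
    if up_mean_s is None:
        r, h = rate_hz, 0.0
    else:
        r, h = rate_hz / up_fraction, 1.0 / up_mean_s
    q = r / (r + h) * (1.0 - math.exp(-(r + h) * window_s)) if r > 0 else 0.0
    p_lag = 1.0 - math.exp(-window_s / burst_isi_s)
    return (burst_prob * p_lag + q) / (1.0 + burst_prob)


def solve_burst_prob(target_fraction: float, rate_hz: float, window_s: float,
                     up_mean_s: float | None, up_fraction: float,
                     burst_isi_s: float) -> float:
    """Doublet probability whose expected ISI<=window fraction hits target.

    Inverts :func:`expected_burst_fraction`; clamps to 0 when the Poisson
    fraction alone already exceeds the target, raises when the target is
    unreachable even at burst_prob = 1.
    """
    q = expected_burst_fraction(rate_hz, window_s, up_mean_s, up_fraction,
                                0.0, burst_isi_s)
    p_lag = 1.0 - math.exp(-window_s / burst_isi_s)
    if target_fraction >= p_lag:
        raise ValueError("target fraction unreachable: exceeds the doublet lag mass")
    p = (target_fraction - q) / (p_lag - target_fraction)
    if p < 0:
        warnings.warn("Poisson ISI fraction already exceeds target; burst_prob = 0")
        return 0.0
    if p > 1:
        raise ValueError("target fraction unreachable with single-extra-spike doublets")
    return p
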