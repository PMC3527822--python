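"""Cortical-state segmentation from low-frequency LFP power and MUA.

Each 1-s bin of the recording is scored by its total 0–7 Hz spectral power
(Hann-tapered periodogram of the demeaned bin, DC excluded).  The bimodal
log-power distribution is split by deterministic 1-D 2-means (centers
initialized at the data extremes); the low-power cluster is the
desynchronized state.  Labels are median-smoothed and runs shorter than a
minimum epoch length are merged into their neighbours, since the states of
interest persist for minutes.  Up/down phases inside synchronized epochs
are recovered from pooled multi-unit activity (10-ms binned, Gaussian
smoothed, iterated threshold at half the up-phase rate).  Stimulation analyses use 2-s
windows immediately before and after each pulse train, with an
effectiveness check on the drop in low-frequency power.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, median_filter
from sklearn.base import BaseEstimator, ClusterMixin

from .datatypes import (DESYNCHRONIZED, NA, SYNCHRONIZED, PowerSeries,
                        Recording, StateSegmentation, StimWindows)

UP, DOWN = "up", "down"


# --------------------------------------------------------------------------
# spectral power

def compute_low_freq_power(recording: Recording, channel: int | None = None,
                           band_hz: tuple[float, float] = (0.0, 7.0),
                           bin_s: float = 1.0,
                           average_channels: bool = False) -> PowerSeries:
    """Per-bin total spectral power in (0, 7] Hz.

    Each non-overlapping ``bin_s`` window is demeaned, Hann-tapered and
    periodogram-integrated over the band (DC excluded).  ``channel``
    defaults to an infragranular site (deepest third of the probe);
    ``average_channels`` instead averages the band power over all channels.
    """
    from scipy.signal import periodogram

    fs = recording.fs
    if fs <= 2 * band_hz[1]:
        raise ValueError("sampling rate must exceed twice the band upper edge")
    nper = int(round(bin_s * fs))
    n_bins = recording.lfp.shape[0] // nper
    if n_bins < 2:
        raise ValueError("recording must span at least two analysis bins")
    if average_channels:
        cols = range(recording.n_channels)
    else:
        ch = recording.infragranular_channel() if channel is None else int(channel)
        if not 0 <= ch < recording.n_channels:
            raise ValueError(f"channel {ch} out of range")
        cols = [ch]
    total = np.zeros(n_bins)
    for c in cols:
        x = recording.lfp[:n_bins * nper, c].reshape(n_bins, nper).astype(float)
        f, pxx = periodogram(x, fs=fs, window="hann", detrend="constant", axis=1)
        sel = (f > band_hz[0]) & (f <= band_hz[1])
        df = f[1] - f[0]
        total += pxx[:, sel].sum(axis=1) * df
    total /= len(list(cols)) if average_channels else 1.0
    starts = np.arange(n_bins) * bin_s
    return PowerSeries(bin_start_s=starts, power=total, bin_s=bin_s,
                       band_hz=band_hz)


# --------------------------------------------------------------------------
# state classification

def _kmeans_1d(x: np.ndarray, max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic 2-means on a 1-D array, centers seeded at min/max."""
    c = np.array([x.min(), x.max()], dtype=float)
    lab = np.zeros(x.size, dtype=int)
    for _ in range(max_iter):
        lab_new = (x > (c[0] + c[1]) / 2).astype(int)
        if np.array_equal(lab_new, lab) and _ > 0:
            break
        lab = lab_new
        for k in (0, 1):
            if np.any(lab == k):
                c[k] = x[lab == k].mean()
    return lab, c


def _runs(labels: np.ndarray) -> list[tuple[int, int, object]]:
    """Run-length encoding: list of (start, stop_exclusive, value)."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((start, i, labels[start]))
            start = i
    return out


class StateClassifier(ClusterMixin, BaseEstimator):
    """Two-state split of the per-bin log power (sklearn estimator).

    fit(X) takes the log10 band power, shape (n_bins,) or (n_bins, 1).
    The lower-power cluster is labeled desynchronized.  Post-processing:
    ``smooth_bins`` median filter, then runs shorter than ``min_epoch_s``
    merged into their neighbours (shortest first).  Deterministic.

    Attributes: ``labels_`` (synchronized/desynchronized per bin),
    ``cluster_centers_`` (log-power means, [desynchronized, synchronized]),
    ``status_`` ('ok' or 'no state alternation detected', in which case
    bins are labeled by sign against the global median).
    """

    def __init__(self, min_epoch_s: float = 10.0, smooth_bins: int = 5,
                 bin_s: float = 1.0, separation_frac: float = 0.01):
        self.min_epoch_s = min_epoch_s
        self.smooth_bins = smooth_bins
        self.bin_s = bin_s
        self.separation_frac = separation_frac

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).reshape(-1)
        self.warnings_ = []
        finite = np.isfinite(x)
        if not finite.all():
            self.warnings_.append(f"{int((~finite).sum())} zero-power bins "
                                  "imputed with the minimum finite log power")
            x = np.where(finite, x, x[finite].min() if finite.any() else 0.0)
        rng_x = x.max() - x.min()
        lab, centers = _kmeans_1d(x)
        if rng_x == 0 or abs(centers[1] - centers[0]) < self.separation_frac * rng_x:
            self.status_ = "no state alternation detected"
            self.warnings_.append("degenerate unimodal power; labels set by "
                                  "sign against the global median")
            med = np.median(x)
            lab = (x > med).astype(int)
        else:
            self.status_ = "ok"
            if centers[0] > centers[1]:      # ensure cluster 1 = high power
                lab, centers = 1 - lab, centers[::-1]
        if self.smooth_bins > 1:
            lab = median_filter(lab, size=self.smooth_bins, mode="nearest")
        lab = self._merge_short_runs(lab)
        if np.all(lab == lab[0]):
            # post-processing left a single state: nothing to alternate
            self.status_ = "no state alternation detected"
            self.warnings_.append("single-state labeling after smoothing/"
                                  "minimum-epoch merging")
        self.cluster_centers_ = np.sort(np.atleast_1d(centers)).reshape(-1, 1)
        self.labels_ = np.where(lab == 1, SYNCHRONIZED, DESYNCHRONIZED).astype(object)
        return self

    def _merge_short_runs(self, lab: np.ndarray) -> np.ndarray:
        min_bins = int(round(self.min_epoch_s / self.bin_s))
        lab = lab.copy()
        while True:
            runs = _runs(lab)
            if len(runs) <= 1:
                break
            short = [(stop - start, i) for i, (start, stop, _) in enumerate(runs)
                     if stop - start < min_bins]
            if not short:
                break
            _, i = min(short)
            start, stop, val = runs[i]
            lab[start:stop] = 1 - val
        return lab

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def classify_states(ps: PowerSeries, min_epoch_s: float = 10.0,
                    smooth_bins: int = 5) -> StateSegmentation:
    """Classify each 1-s bin as synchronized or desynchronized."""
    clf = StateClassifier(min_epoch_s=min_epoch_s, smooth_bins=smooth_bins,
                          bin_s=ps.bin_s).fit(ps.log_power)
    labels = clf.labels_
    epochs = [(val, ps.bin_start_s[start],
               ps.bin_start_s[stop - 1] + ps.bin_s)
              for start, stop, val in _runs(labels)]
    return StateSegmentation(bin_start_s=ps.bin_start_s, bin_labels=labels,
                             epochs=epochs, bin_s=ps.bin_s,
                             status=clf.status_, warnings=list(clf.warnings_))


# --------------------------------------------------------------------------
# up/down detection from MUA

def detect_updown(unit_table, segmentation: StateSegmentation,
                  bin_ms: float = 10.0, smooth_sigma_ms: float = 30.0,
                  threshold_frac: float = 0.5, min_rate_hz: float = 0.5
                  ) -> np.ndarray:
    """Up/down labels at ``bin_ms`` resolution within synchronized epochs.

    Pooled spike counts are Gaussian-smoothed (sigma 30 ms); bins above
    ``threshold_frac`` (default 50%) of the epoch's mean up-phase rate are
    'up' (threshold iterated twice: first against the epoch mean, then
    against the mean over the provisional up bins).  50% is the unbiased
    boundary for a Gaussian-smoothed step between a silent down phase and
    a constant-rate up phase; lower fractions inflate the up fraction by
    ~0.8 sigma per edge.  Desynchronized time is 'n/a'.  If the pooled
    rate is below ``min_rate_hz`` the epoch is labeled all-down and
    flagged.  The labels are also stored on ``segmentation``.
    """
    n_units = unit_table.units.shape[0]
    if n_units < 5:
        segmentation.warnings.append(
            f"only {n_units} units pooled as MUA (>= 5 recommended)")
    spikes = np.sort(unit_table.spikes["timestamp_s"].to_numpy(dtype=float))
    bin_s = bin_ms / 1000.0
    total_s = segmentation.bin_start_s[-1] + segmentation.bin_s
    n = int(round(total_s / bin_s))
    labels = np.full(n, NA, dtype=object)
    sigma_bins = smooth_sigma_ms / bin_ms
    for state, s, e in segmentation.epochs:
        if state != SYNCHRONIZED:
            continue
        i0, i1 = int(round(s / bin_s)), int(round(e / bin_s))
        edges = np.arange(i0, i1 + 1) * bin_s
        counts, _ = np.histogram(spikes, bins=edges)
        rate = counts / bin_s
        pooled = counts.sum() / max(e - s, bin_s)
        if pooled < min_rate_hz:
            labels[i0:i1] = DOWN
            segmentation.warnings.append(
                f"epoch [{s:.0f},{e:.0f}) s: pooled MUA {pooled:.2f} Hz below "
                f"{min_rate_hz} Hz; up/down labels undefined (all-down)")
            continue
        sm = gaussian_filter1d(rate, sigma_bins, mode="nearest")
        thr = threshold_frac * sm.mean()
        up = sm > thr
        if up.any():                       # second pass against up-phase mean
            thr = threshold_frac * sm[up].mean()
            up = sm > thr
        labels[i0:i1] = np.where(up, UP, DOWN)
    segmentation.updown_labels = labels
    segmentation.updown_bin_s = bin_s
    return labels


# --------------------------------------------------------------------------
# stimulation windows

def build_stim_windows(stim_times_s, stim_duration_s: float = 1.0,
                       ps: PowerSeries | None = None,
                       window_s: float = 2.0,
                       effect_factor: float = 0.5) -> StimWindows:
    """2-s pre/post windows for each stimulation event.

    pre = [t - 2, t), post = [t + stim_duration, t + stim_duration + 2).
    A stimulation is effective when the post-window 0–7 Hz power drops
    below ``effect_factor`` x the pre-window power.  Events whose windows
    leave the recording are dropped (counted in ``n_dropped``).
    """
    times = np.sort(np.asarray(stim_times_s, dtype=float))
    rows, dropped = [], 0
    t_max = None
    if ps is not None:
        t_max = ps.bin_start_s[-1] + ps.bin_s
    for t in times:
        pre = (t - window_s, t)
        post = (t + stim_duration_s, t + stim_duration_s + window_s)
        if pre[0] < 0 or (t_max is not None and post[1] > t_max):
            dropped += 1
            continue
        effective = True
        p_pre = p_post = np.nan
        if ps is not None:
            p_pre = _window_power(ps, *pre)
            p_post = _window_power(ps, *post)
            effective = bool(p_post < effect_factor * p_pre)
        rows.append({"stim_time_s": t, "pre_start_s": pre[0], "pre_end_s": pre[1],
                     "post_start_s": post[0], "post_end_s": post[1],
                     "pre_power": p_pre, "post_power": p_post,
                     "effective": effective})
    cols = ["stim_time_s", "pre_start_s", "pre_end_s", "post_start_s",
            "post_end_s", "pre_power", "post_power", "effective"]
    events = pd.DataFrame(rows, columns=cols)
    return StimWindows(events=events, n_dropped=dropped)


def _window_power(ps: PowerSeries, start: float, end: float) -> float:
    centers = ps.bin_start_s + ps.bin_s / 2
    sel = (centers >= start) & (centers < end)
    return float(ps.power[sel].mean()) if sel.any() else float("nan")
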