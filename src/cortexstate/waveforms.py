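"""Extracellular waveform features, FS/PC classification, depth and layers.

Units are classified from three features of the mean spike waveform on the
soma channel — trough-to-peak time, half-amplitude width of the trough, and
the asymmetry index of the two positive peaks — by 2-means clustering in
z-scored feature space.  Fast-spiking interneurons (FS) form the
narrow-spike cluster; putative pyramidal cells (PC) the wide-spike one.
Unit depth is the depth of the channel with the largest peak-to-trough
amplitude; layers are the fixed depth windows 0–500 μm (superficial, L2/3)
and 800–1100 μm (deep, L5).  Sorting quality is screened with the isolation
distance (squared Mahalanobis radius enclosing as many non-member spikes as
the cluster has members); units below 20 are excluded from analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

PC, FS = "PC", "FS"
SUPERFICIAL, DEEP, UNASSIGNED = "superficial", "deep", "unassigned"

SUPERFICIAL_RANGE_UM = (0.0, 500.0)
DEEP_RANGE_UM = (800.0, 1100.0)
MIN_ISOLATION_DISTANCE = 20.0

# fraction of leading samples used as the baseline estimate
_BASELINE_FRAC = 0.2
# minimum context around the trough, seconds
_MIN_CONTEXT_S = 0.5e-3


class FeatureError(ValueError):
    """Waveform does not admit the three features (unit excluded)."""


@dataclass
class WaveformFeatures:
    trough_to_peak_ms: float
    half_width_ms: float
    asymmetry: float
    flags: list[str] = field(default_factory=list)

    def as_array(self) -> np.ndarray:
        return np.array([self.trough_to_peak_ms, self.half_width_ms, self.asymmetry])


def _half_crossing(x: np.ndarray, level: float, trough: int, direction: int) -> float:
    """Fractional sample index where x crosses `level` moving away from the
    trough in `direction` (+1 right, -1 left); linear interpolation."""
    i = trough
    while 0 <= i + direction < x.size:
        j = i + direction
        if x[j] >= level:
            # crossing between i and j
            frac = (level - x[i]) / (x[j] - x[i])
            return i + direction * frac
        i = j
    raise FeatureError("trough does not recover to half amplitude")


def extract_features(waveform: np.ndarray, fs: float) -> WaveformFeatures:
    """Measure trough-to-peak time, trough half-width and peak asymmetry.

    The waveform must contain a global negative trough with at least 0.5 ms
    of context on each side.  The baseline is the mean of the first 20% of
    samples; positive-peak amplitudes that fall below baseline are clipped
    to zero and flagged.
    """
    w = np.asarray(waveform, dtype=float)
    if w.ndim != 1 or w.size < 8:
        raise FeatureError("waveform must be a 1-D array of >= 8 samples")
    flags: list[str] = []
    n_base = max(1, int(round(_BASELINE_FRAC * w.size)))
    baseline = float(np.mean(w[:n_base]))
    ti = int(np.argmin(w))
    context = int(np.ceil(_MIN_CONTEXT_S * fs))
    if ti < context or ti > w.size - 1 - context:
        raise FeatureError("trough lacks 0.5 ms of context on both sides")
    depth = baseline - w[ti]
    if depth <= 0:
        raise FeatureError("no negative trough relative to baseline")

    # trough-to-peak: global trough -> subsequent positive peak
    post = w[ti + 1:]
    pi = ti + 1 + int(np.argmax(post))
    # a "peak" below 1% of the trough depth is noise, not repolarization
    if w[pi] - baseline <= 0.01 * depth:
        raise FeatureError("no positive peak after the trough")
    trough_to_peak_ms = (pi - ti) / fs * 1e3

    # half-amplitude width with sub-sample interpolation
    level = baseline - depth / 2.0
    left = _half_crossing(w, level, ti, -1)
    right = _half_crossing(w, level, ti, +1)
    half_width_ms = (right - left) / fs * 1e3

    # asymmetry of baseline-to-peak amplitudes flanking the trough
    a_left = float(np.max(w[:ti])) - baseline
    a_right = float(w[pi]) - baseline
    if a_left < 0:
        a_left = 0.0
        flags.append("left_peak_clipped")
    if a_right < 0:   # unreachable given the peak check, kept for safety
        a_right = 0.0
        flags.append("right_peak_clipped")
    total = a_left + a_right
    asymmetry = (a_right - a_left) / total if total > 0 else 0.0
    if total == 0:
        flags.append("no_positive_peaks")
    return WaveformFeatures(trough_to_peak_ms, half_width_ms, asymmetry, flags)


class WaveformClassifier(ClusterMixin, BaseEstimator):
    """2-means FS/PC classifier over z-scored waveform features.

    Parameters
    ----------
    n_restarts : k-means restarts (best inertia kept).
    random_state : seed for the restarts; fixed default keeps the fit
        deterministic.

    Attributes
    ----------
    labels_ : array of "FS"/"PC" per unit. The cluster with the smaller
        mean trough-to-peak time (first feature column) is FS.
    cluster_centers_ : (2, n_features) centers on the original scale,
        row 0 = FS, row 1 = PC.
    status_ : "ok", "degenerate" (identical features) or
        "insufficient_units" (< 4 units; everything labeled PC).
    """

    def __init__(self, n_restarts: int = 50, random_state: int = 0):
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_units, n_features)")
        n = X.shape[0]
        if n < 4:
            warnings.warn("insufficient units for clustering; all labeled PC")
            self.status_ = "insufficient_units"
            self.labels_ = np.array([PC] * n, dtype=object)
            self.cluster_centers_ = np.vstack([X.mean(0), X.mean(0)]) if n else None
            return self
        mu, sd = X.mean(0), X.std(0)
        sd = np.where(sd > 0, sd, 1.0)
        Z = (X - mu) / sd
        if np.allclose(Z, Z[0]):
            warnings.warn("degenerate feature cloud (one cluster); all labeled PC")
            self.status_ = "degenerate"
            self.labels_ = np.array([PC] * n, dtype=object)
            self.cluster_centers_ = np.vstack([X.mean(0), X.mean(0)])
            return self
        km = KMeans(n_clusters=2, n_init=self.n_restarts,
                    random_state=self.random_state).fit(Z)
        centers = km.cluster_centers_ * sd + mu
        fs_cluster = int(np.argmin(centers[:, 0]))   # narrower spikes -> FS
        self.labels_ = np.where(km.labels_ == fs_cluster, FS, PC).astype(object)
        self.cluster_centers_ = centers[[fs_cluster, 1 - fs_cluster]]
        self._scale = (mu, sd)
        self.status_ = "ok"
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if getattr(self, "status_", None) != "ok":
            return np.array([PC] * X.shape[0], dtype=object)
        mu, sd = self._scale
        Z = (X - mu) / sd
        zc = (self.cluster_centers_ - mu) / sd
        d = ((Z[:, None, :] - zc[None]) ** 2).sum(-1)
        return np.where(np.argmin(d, 1) == 0, FS, PC).astype(object)


def classify_units(features: pd.DataFrame, random_state: int = 0) -> pd.Series:
    """FS/PC labels from a (unit x 3-feature) table.

    Columns must start with trough_to_peak_ms (used to orient the clusters).
    """
    cols = ["trough_to_peak_ms", "half_width_ms", "asymmetry"]
    X = features[cols].to_numpy(dtype=float)
    clf = WaveformClassifier(random_state=random_state).fit(X)
    return pd.Series(clf.labels_, index=features.index, name="putative_class")


def estimate_depth(waveforms: np.ndarray, channel_depths_um: np.ndarray
                   ) -> tuple[float, int]:
    """Unit depth = depth of the channel with maximal peak-to-trough span.

    Ties break toward the shallower channel.  Returns (depth_um, channel).
    """
    W = np.asarray(waveforms, dtype=float)
    depths = np.asarray(channel_depths_um, dtype=float)
    if W.ndim != 2 or W.shape[0] != depths.size:
        raise ValueError("waveforms must be (n_channels, n_samples) matching depths")
    if W.shape[0] < 2:
        raise ValueError("depth estimation needs >= 2 channels")
    span = W.max(1) - W.min(1)
    if np.all(span == 0):
        raise FeatureError("all-zero waveforms: depth undefined")
    ch = int(np.argmax(span))   # first occurrence = shallowest on ties
    return float(depths[ch]), ch


def assign_layer(depth_um: float) -> str:
    """Map depth to superficial (0–500 μm), deep (800–1100 μm) or unassigned."""
    if depth_um < 0:
        raise ValueError("depth must be non-negative")
    if SUPERFICIAL_RANGE_UM[0] <= depth_um <= SUPERFICIAL_RANGE_UM[1]:
        return SUPERFICIAL
    if DEEP_RANGE_UM[0] <= depth_um <= DEEP_RANGE_UM[1]:
        return DEEP
    return UNASSIGNED


def isolation_distance(cluster_points: np.ndarray, other_points: np.ndarray,
                       ridge: float = 1e-6) -> float:
    """Isolation distance of a sorted cluster.

    Squared Mahalanobis distance — with respect to the cluster's own
    covariance — from the cluster centroid to the n-th closest non-member
    point, n being the cluster size.  Returns +inf when non-members are
    fewer than members.  A singular covariance is ridge-regularized
    (ridge x trace) with a warning.
    """
    C = np.atleast_2d(np.asarray(cluster_points, dtype=float))
    O = np.atleast_2d(np.asarray(other_points, dtype=float))
    n, d = C.shape
    if n <= d:
        raise ValueError("cluster must have more points than feature dimensions")
    if O.size == 0:
        raise ValueError("other_points must be non-empty")
    if O.shape[0] < n:
        return float("inf")
    cov = np.cov(C, rowvar=False)
    cov = np.atleast_2d(cov)
    try:
        vi = np.linalg.inv(cov)
        if not np.all(np.isfinite(vi)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("singular cluster covariance; ridge-regularized")
        cov = cov + ridge * np.trace(cov) * np.eye(d)
        vi = np.linalg.inv(cov)
    delta = O - C.mean(0)
    d2 = np.einsum("ij,jk,ik->i", delta, vi, delta)
    return float(np.sort(d2)[n - 1])


def label_units(unit_table, random_state: int = 0) -> pd.DataFrame:
    """Full per-unit labeling: features, FS/PC, depth, layer, quality filter.

    Returns a DataFrame indexed by unit_id with columns putative_class,
    depth_um, layer, isolation_distance, included, the three features, and
    an exclusion reason (empty when usable).  Units whose waveform defeats
    feature extraction get reason set and class "n/a".
    """
    ch_depths = unit_table.units.attrs.get("channel_depths_um")
    rows = {}
    for uid in unit_table.unit_ids:
        wf = unit_table.waveforms.get(uid)
        row = {"reason": ""}
        try:
            if wf is None:
                raise FeatureError("no waveform")
            W = np.atleast_2d(np.asarray(wf, dtype=float))
            depth_um, soma = estimate_depth(W, ch_depths)
            feats = extract_features(W[soma], unit_table.wf_fs)
            row.update(trough_to_peak_ms=feats.trough_to_peak_ms,
                       half_width_ms=feats.half_width_ms,
                       asymmetry=feats.asymmetry,
                       depth_um=depth_um, layer=assign_layer(depth_um))
        except FeatureError as err:
            row.update(trough_to_peak_ms=np.nan, half_width_ms=np.nan,
                       asymmetry=np.nan, depth_um=np.nan, layer=UNASSIGNED,
                       reason=str(err))
        rows[uid] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "unit_id"
    iso = unit_table.units["isolation_distance"].reindex(out.index)
    out["isolation_distance"] = iso
    out["included"] = (iso >= MIN_ISOLATION_DISTANCE) & (out["reason"] == "")
    ok = out["reason"] == ""
    out["putative_class"] = "n/a"
    if ok.any():
        out.loc[ok, "putative_class"] = classify_units(out.loc[ok], random_state)
    return out
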