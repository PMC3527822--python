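"""State-dependent firing statistics.

Core quantity: the modulation index MI = (FR_d - FR_s) / (FR_d + FR_s),
where FR_d and FR_s are a unit's firing rates in the desynchronized and
synchronized states.  MI is bounded in [-1, 1]; positive values mean the
unit fires more during desynchronization (enhanced), negative values mean
suppression.  Rates come either from 1-s state bins (spontaneous mode,
unpaired Welch t-test) or from 2-s windows flanking stimulation events
(evoked mode, paired t-test).  Population-level statistics: Wilcoxon
signed-rank of per-class MIs against zero, burst-fraction comparisons
(fraction of inter-spike intervals <= 20 ms per state; Kruskal-Wallis with
post-hoc rank-sum), the semi-log regression of MI on baseline rate, and
layer-resolved MUA modulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (DESYNCHRONIZED, SYNCHRONIZED, StateSegmentation,
                        StimWindows)

ENHANCED, SUPPRESSED, NS = "enhanced", "suppressed", "ns"
SPONTANEOUS, EVOKED = "spontaneous", "evoked"
ALPHA = 0.05
BURST_WINDOWS_MS = (10.0, 15.0, 20.0, 25.0)


def modulation_index(fr_desync: float, fr_sync: float) -> float:
    """(FR_d - FR_s) / (FR_d + FR_s); NaN when both rates are zero."""
    if fr_desync < 0 or fr_sync < 0:
        raise ValueError("firing rates must be non-negative")
    tot = fr_desync + fr_sync
    if tot == 0:
        return float("nan")
    return (fr_desync - fr_sync) / tot


# --------------------------------------------------------------------------
# rates

@dataclass
class StateRates:
    fr_sync: float
    fr_desync: float
    sync_counts: np.ndarray       # per-1-s-bin (spontaneous) or per-event
    desync_counts: np.ndarray
    mode: str = SPONTANEOUS
    flags: list[str] = field(default_factory=list)


def rate_by_state_spontaneous(spike_times: np.ndarray, seg: StateSegmentation,
                              min_bins: int = 30) -> StateRates:
    """FR_s / FR_d from per-1-s-bin spike counts in each state."""
    t = np.asarray(spike_times, dtype=float)
    edges = np.append(seg.bin_start_s, seg.bin_start_s[-1] + seg.bin_s)
    counts, _ = np.histogram(t, bins=edges)
    flags = []
    out = {}
    for state in (SYNCHRONIZED, DESYNCHRONIZED):
        idx = seg.bins_of(state)
        if idx.size == 0:
            flags.append(f"state {state} absent; spontaneous mode unavailable")
            out[state] = (float("nan"), np.empty(0, dtype=int))
        else:
            if idx.size < min_bins:
                flags.append(f"state {state}: only {idx.size} bins (< {min_bins})")
            c = counts[idx]
            out[state] = (float(c.mean() / seg.bin_s), c)
    return StateRates(fr_sync=out[SYNCHRONIZED][0], fr_desync=out[DESYNCHRONIZED][0],
                      sync_counts=out[SYNCHRONIZED][1],
                      desync_counts=out[DESYNCHRONIZED][1],
                      mode=SPONTANEOUS, flags=flags)


def rate_by_state_evoked(spike_times: np.ndarray, windows: StimWindows,
                         min_events: int = 5,
                         effective_only: bool = True) -> StateRates:
    """FR_s / FR_d from 2-s pre/post stimulation windows.

    Pre windows estimate the synchronized rate, post windows the
    desynchronized rate; ineffective stimulations are excluded by default.
    """
    t = np.sort(np.asarray(spike_times, dtype=float))
    ev = windows.events
    if effective_only:
        ev = ev[ev["effective"]]
    flags = []
    if len(ev) == 0:
        return StateRates(float("nan"), float("nan"), np.empty(0), np.empty(0),
                          EVOKED, ["no effective stimulation events; unit skipped"])
    if len(ev) < min_events:
        flags.append(f"only {len(ev)} effective events (< {min_events})")
    pre = np.array([np.searchsorted(t, e) - np.searchsorted(t, s)
                    for s, e in zip(ev["pre_start_s"], ev["pre_end_s"])])
    post = np.array([np.searchsorted(t, e) - np.searchsorted(t, s)
                     for s, e in zip(ev["post_start_s"], ev["post_end_s"])])
    w = float(ev["pre_end_s"].iloc[0] - ev["pre_start_s"].iloc[0])
    return StateRates(fr_sync=float(pre.mean() / w), fr_desync=float(post.mean() / w),
                      sync_counts=pre, desync_counts=post, mode=EVOKED, flags=flags)


# --------------------------------------------------------------------------
# per-cell significance

def per_cell_significance(rates: StateRates, alpha: float = ALPHA
                          ) -> tuple[float, str]:
    """p-value and significance class for one unit's state dependence.

    Spontaneous mode: Welch unpaired t-test between the two states' 1-s bin
    counts.  Evoked mode: paired t-test across events on (post - pre)
    counts.  Zero variance in both samples (or a missing state) yields an
    undefined p and class 'ns'.
    """
    a, b = rates.desync_counts, rates.sync_counts
    if a.size < 2 or b.size < 2:
        return float("nan"), NS
    if np.var(a) == 0 and np.var(b) == 0:
        return float("nan"), NS
    if rates.mode == EVOKED:
        diff = a - b
        if np.var(diff) == 0:
            return float("nan"), NS
        p = float(stats.ttest_rel(a, b).pvalue)
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    if not math.isfinite(p):
        return float("nan"), NS
    if p < alpha:
        if rates.fr_desync > rates.fr_sync:
            return p, ENHANCED
        if rates.fr_desync < rates.fr_sync:
            return p, SUPPRESSED
    return p, NS


def population_signed_rank(mis, exact_n: int = 25) -> tuple[float, float]:
    """Median MI and two-sided Wilcoxon signed-rank p against zero.

    Exact null distribution for n <= 25 (zeros dropped, Wilcoxon
    convention), normal approximation with tie correction above.
    """
    x = np.asarray([m for m in mis if math.isfinite(m)], dtype=float)
    if x.size < 5:
        raise ValueError("need >= 5 defined modulation indices")
    med = float(np.median(x))
    nz = x[x != 0]
    if nz.size == 0:
        return med, 1.0
    method = "exact" if nz.size <= exact_n and np.unique(np.abs(nz)).size == nz.size \
        else "approx"
    p = float(stats.wilcoxon(nz, method=method, zero_method="wilcox").pvalue)
    return med, p


# --------------------------------------------------------------------------
# burst statistics

def state_isis(spike_times: np.ndarray, seg: StateSegmentation, state: str
               ) -> np.ndarray:
    """Inter-spike intervals with both spikes inside one epoch of ``state``.

    ISIs spanning epoch boundaries are discarded so that state transitions
    do not manufacture artificial long intervals.
    """
    t = np.sort(np.asarray(spike_times, dtype=float))
    isis = []
    for st, s, e in seg.epochs:
        if st != state:
            continue
        seg_t = t[(t >= s) & (t < e)]
        if seg_t.size >= 2:
            isis.append(np.diff(seg_t))
    return np.concatenate(isis) if isis else np.empty(0)


def burst_fraction(spike_times: np.ndarray, seg: StateSegmentation,
                   window_ms: float = 20.0) -> dict[str, float]:
    """Fraction of within-state ISIs at or below ``window_ms`` per state.

    NaN for a state with fewer than two spikes (fraction undefined).
    """
    w = window_ms / 1000.0
    out = {}
    for state in (SYNCHRONIZED, DESYNCHRONIZED):
        isis = state_isis(spike_times, seg, state)
        out[state] = float(np.mean(isis <= w)) if isis.size else float("nan")
    return {"window_ms": window_ms, "frac_sync": out[SYNCHRONIZED],
            "frac_desync": out[DESYNCHRONIZED]}


def burst_state_comparison(burst_table: pd.DataFrame, min_units: int = 5
                           ) -> dict:
    """Kruskal-Wallis across class x state groups + per-class rank-sums.

    ``burst_table`` columns: cell_class, frac_sync, frac_desync (one row
    per unit).  Post-hoc two-sided rank-sum per class between states, no
    multiplicity correction (matching conventional reporting; apply your
    own if needed).  Classes with no defined fractions are dropped with a
    warning entry.
    """
    groups, warnings_, posthoc = [], [], {}
    for cls, sub in burst_table.groupby("cell_class"):
        fs = sub["frac_sync"].dropna().to_numpy()
        fd = sub["frac_desync"].dropna().to_numpy()
        if fs.size == 0 or fd.size == 0:
            warnings_.append(f"class {cls}: empty group dropped")
            continue
        if min(fs.size, fd.size) < min_units:
            warnings_.append(f"class {cls}: fewer than {min_units} units per state")
        groups.extend([fs, fd])
        if np.array_equal(np.sort(fs), np.sort(fd)):
            posthoc[cls] = 1.0
        else:
            posthoc[cls] = float(stats.ranksums(fs, fd).pvalue)
    kw_p = float(stats.kruskal(*groups).pvalue) if len(groups) >= 2 else float("nan")
    return {"kruskal_p": kw_p, "posthoc_p": posthoc, "warnings": warnings_}


# --------------------------------------------------------------------------
# population-level relations

def rate_modulation_correlation(fr_sync, mi) -> dict:
    """Pearson r and least-squares line between log10(FR_s) and MI.

    Units with FR_s = 0 (log undefined) or undefined MI are excluded.
    """
    fr = np.asarray(fr_sync, dtype=float)
    m = np.asarray(mi, dtype=float)
    ok = (fr > 0) & np.isfinite(m)
    if ok.sum() < 5:
        raise ValueError("need >= 5 units with positive FR_s and defined MI")
    x = np.log10(fr[ok])
    y = m[ok]
    if np.var(x) == 0 or np.var(y) == 0:
        return {"r": float("nan"), "p": float("nan"),
                "slope": float("nan"), "intercept": float("nan"),
                "n": int(ok.sum())}
    fit = stats.linregress(x, y)
    return {"r": float(fit.rvalue), "p": float(fit.pvalue),
            "slope": float(fit.slope), "intercept": float(fit.intercept),
            "n": int(ok.sum())}


def mua_modulation(unit_tables, segs, depth_windows=None) -> pd.DataFrame:
    """Layer-resolved MUA modulation across recordings.

    For each (recording, depth window): spikes of all units whose depth
    falls in the window are pooled, rates per state computed, and the MI
    taken.  Across recordings, a one-sample t-test of the window's MIs
    against zero (p is NaN for a single recording).  Accepts single
    objects or parallel lists.  Returns one row per depth window with
    columns (window, mean_mi, p, n_recordings).
    """
    from .waveforms import DEEP_RANGE_UM, SUPERFICIAL_RANGE_UM
    if depth_windows is None:
        depth_windows = {"superficial": SUPERFICIAL_RANGE_UM, "deep": DEEP_RANGE_UM}
    if not isinstance(unit_tables, (list, tuple)):
        unit_tables, segs = [unit_tables], [segs]
    per_window: dict[str, list[float]] = {w: [] for w in depth_windows}
    for ut, seg in zip(unit_tables, segs):
        depths = ut.units["depth_um"]
        for name, (lo, hi) in depth_windows.items():
            ids = depths[(depths >= lo) & (depths <= hi)].index
            if len(ids) == 0:
                continue
            t = ut.spikes.loc[ut.spikes["unit_id"].isin(ids), "timestamp_s"]
            r = rate_by_state_spontaneous(t.to_numpy(), seg, min_bins=1)
            mi = modulation_index(r.fr_desync, r.fr_sync)
            if math.isfinite(mi):
                per_window[name].append(mi)
    rows = []
    for name, mis in per_window.items():
        if not mis:
            continue
        p = float(stats.ttest_1samp(mis, 0.0).pvalue) if len(mis) > 1 else float("nan")
        rows.append({"window": name, "mean_mi": float(np.mean(mis)), "p": p,
                     "n_recordings": len(mis)})
    return pd.DataFrame(rows, columns=["window", "mean_mi", "p", "n_recordings"])


# --------------------------------------------------------------------------
# per-unit driver + population summary

def analyze_units(unit_table, seg: StateSegmentation,
                  labels: pd.DataFrame | None = None,
                  mode: str = SPONTANEOUS,
                  windows: StimWindows | None = None,
                  alpha: float = ALPHA,
                  burst_window_ms: float = 20.0,
                  min_bins: int = 30) -> pd.DataFrame:
    """Per-unit modulation table: FR_s, FR_d, MI, p, class, burst fractions.

    ``labels`` (from :func:`cortexstate.waveforms.label_units`) contributes
    putative class / layer / inclusion; when absent all units are analyzed.
    Evoked mode requires ``windows``.
    """
    if mode == EVOKED and windows is None:
        raise ValueError("evoked mode requires stimulation windows")
    rows = []
    for uid in unit_table.unit_ids:
        t = unit_table.spike_times(uid)
        if mode == EVOKED:
            r = rate_by_state_evoked(t, windows)
        else:
            r = rate_by_state_spontaneous(t, seg, min_bins=min_bins)
        mi = modulation_index(r.fr_desync, r.fr_sync) \
            if math.isfinite(r.fr_desync + r.fr_sync) else float("nan")
        p, sig = per_cell_significance(r, alpha=alpha)
        bf = burst_fraction(t, seg, window_ms=burst_window_ms)
        row = {"unit_id": uid, "fr_sync_hz": r.fr_sync, "fr_desync_hz": r.fr_desync,
               "mi": mi, "p_value": p, "sig_class": sig, "mode": mode,
               "burst_frac_sync": bf["frac_sync"],
               "burst_frac_desync": bf["frac_desync"],
               "flags": ";".join(r.flags)}
        rows.append(row)
    out = pd.DataFrame(rows).set_index("unit_id")
    if labels is not None:
        out = out.join(labels[["putative_class", "layer", "depth_um",
                               "isolation_distance", "included"]], how="left")
        out = out[out["included"].fillna(False)]
    return out


def group_key(row) -> str:
    """sPC/dPC/sFS/dFS key from (layer, putative_class); '' if unassigned."""
    layer, cls = row.get("layer"), row.get("putative_class")
    if layer == "superficial" and cls in ("PC", "FS"):
        return "s" + cls
    if layer == "deep" and cls in ("PC", "FS"):
        return "d" + cls
    return ""


def summarize_population(results: pd.DataFrame, alpha: float = ALPHA
                         ) -> pd.DataFrame:
    """Per-class tabulation: n, enhanced:suppressed, median MI, signed-rank p.

    ``results`` must carry either a 'cell_class' column (ground truth) or
    'putative_class' + 'layer' (pipeline output).  Classes with fewer than
    5 defined MIs get a NaN signed-rank p.
    """
    df = results.copy()
    if "cell_class" in df.columns:
        df["group"] = df["cell_class"]
    else:
        df["group"] = df.apply(group_key, axis=1)
    rows = []
    for cls in ("sPC", "dPC", "sFS", "dFS"):
        sub = df[df["group"] == cls]
        n = len(sub)
        n_enh = int((sub["sig_class"] == ENHANCED).sum())
        n_sup = int((sub["sig_class"] == SUPPRESSED).sum())
        mis = sub["mi"].dropna().to_numpy()
        med = float(np.median(mis)) if mis.size else float("nan")
        try:
            _, p = population_signed_rank(mis)
        except ValueError:
            p = float("nan")
        rows.append({"cell_class": cls, "n_units": n, "n_enhanced": n_enh,
                     "n_suppressed": n_sup,
                     "enhanced_suppressed": f"{n_enh}:{n_sup}" if n else "",
                     "median_mi": med, "signed_rank_p": p})
    return pd.DataFrame(rows).set_index("cell_class")
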