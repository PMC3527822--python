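"""End-to-end pipeline: simulate -> segment -> classify -> modulate -> report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from . import modulation, segmentation, simulate, waveforms
from .config import ConfigError, PRESETS, SimulationConfig
from .datatypes import StateSegmentation


@dataclass
class RunConfig:
    """Everything needed for one reproducible end-to-end run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    mode: str = modulation.SPONTANEOUS
    alpha: float = 0.05
    min_epoch_s: float = 10.0
    smooth_bins: int = 5
    burst_window_ms: float = 20.0
    lfp_channel: int | None = None     # None = infragranular default
    out_dir: str | None = None

    def validate(self) -> None:
        self.sim.validate()
        if self.mode not in (modulation.SPONTANEOUS, modulation.EVOKED):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == modulation.EVOKED and self.sim.stim.n_events == 0:
            raise ConfigError("evoked mode requires a stimulation schedule "
                              "(sim.stim.n_events > 0)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("sim"), dict):
            d["sim"] = SimulationConfig.from_dict(d["sim"])
        elif isinstance(d.get("sim"), str):
            d["sim"] = PRESETS[d["sim"]]()
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)      # hash the scientific config, not paths
        payload = json.dumps(d, sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    segmentation: StateSegmentation
    labels: pd.DataFrame
    results: pd.DataFrame
    summary: pd.DataFrame
    correlations: dict
    burst: dict
    mua: pd.DataFrame
    manifest: dict


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute all stages in order; optionally persist outputs + manifest.

    Stage warnings are collected into the manifest; identical config + seed
    reproduce identical manifests (checksums included when writing).
    """
    cfg.validate()
    warnings_log: list[str] = []
    out = Path(cfg.out_dir) if cfg.out_dir else None

    ds = simulate.generate_dataset(cfg.sim, out_dir=out / "data" if out else None)

    ps = segmentation.compute_low_freq_power(ds.recording, channel=cfg.lfp_channel)
    seg = segmentation.classify_states(ps, min_epoch_s=cfg.min_epoch_s,
                                       smooth_bins=cfg.smooth_bins)
    segmentation.detect_updown(ds.unit_table, seg)
    warnings_log += seg.warnings

    labels = waveforms.label_units(ds.unit_table, random_state=cfg.sim.seed)

    windows = None
    if cfg.mode == modulation.EVOKED:
        windows = segmentation.build_stim_windows(
            ds.recording.stim_times_s, cfg.sim.stim.duration_s, ps)
    results = modulation.analyze_units(
        ds.unit_table, seg, labels=labels, mode=cfg.mode, windows=windows,
        alpha=cfg.alpha, burst_window_ms=cfg.burst_window_ms)
    summary = modulation.summarize_population(results, alpha=cfg.alpha)

    groups = results.copy()
    groups["group"] = groups.apply(modulation.group_key, axis=1)
    correlations = {}
    for tag, classes in (("PC", ("sPC", "dPC")), ("FS", ("sFS", "dFS"))):
        sub = groups[groups["group"].isin(classes)]
        try:
            correlations[tag] = modulation.rate_modulation_correlation(
                sub["fr_sync_hz"], sub["mi"])
        except ValueError as err:
            correlations[tag] = {"error": str(err)}
            warnings_log.append(f"correlation {tag}: {err}")

    bt = groups.rename(columns={"burst_frac_sync": "frac_sync",
                                "burst_frac_desync": "frac_desync"})
    bt = bt[bt["group"] != ""].assign(cell_class=lambda d: d["group"])
    burst = modulation.burst_state_comparison(bt)
    warnings_log += burst.pop("warnings", [])

    mua = modulation.mua_modulation(ds.unit_table, seg)

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.sim.seed,
        "warnings": warnings_log,
        "n_units": int(len(ds.unit_table.units)),
        "n_included": int(labels["included"].sum()),
    }
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        _io.write_segmentation(seg, out / "segmentation")
        labels.to_csv(out / "unit_labels.csv")
        results.to_csv(out / "unit_results.csv")
        summary.to_csv(out / "population_summary.csv")
        report = render_report(RunResult(seg, labels, results, summary,
                                         correlations, burst, mua, manifest))
        (out / "report.txt").write_text(report["text"])
        (out / "report.json").write_text(json.dumps(report["json"], indent=1,
                                                    default=_jsonify))
        manifest["files"] = {p.name: _io.file_checksum(p)
                             for p in sorted(out.glob("*.csv"))}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      default=float))
    return RunResult(seg, labels, results, summary, correlations, burst, mua,
                     manifest)


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    return float(x)


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "n/a"
    return f"{x:.6g}"


def render_report(res: RunResult) -> dict:
    """Plain-text and JSON renderings of the population results.

    The text table mirrors the conventional summary layout: one row per
    cell class with its unit count and enhanced:suppressed ratio, followed
    by MI medians, the semi-log rate-vs-MI regression, burst statistics
    and layer-resolved MUA modulation.  Text and JSON carry the same
    numbers (text fixed to 6 significant digits).
    """
    lines = ["Cell-type  N      Enh:Sup  median MI  signed-rank p",
             "-" * 52]
    summary_json = []
    for cls, row in res.summary.iterrows():
        lines.append(f"{cls:<10} {row['n_units']:<6} "
                     f"{row['enhanced_suppressed'] or '-':<8} "
                     f"{_fmt(row['median_mi']):>9}  {_fmt(row['signed_rank_p'])}")
        summary_json.append({"cell_class": cls, **{k: row[k] for k in row.index}})
    lines.append("")
    lines.append("Baseline-rate vs modulation (log10 FR_s vs MI):")
    for tag, c in res.correlations.items():
        if "error" in c:
            lines.append(f"  {tag}: {c['error']}")
        else:
            lines.append(f"  {tag}: r={_fmt(c['r'])} p={_fmt(c['p'])} "
                         f"slope={_fmt(c['slope'])} n={c['n']}")
    lines.append("")
    lines.append(f"Burst fractions: Kruskal-Wallis p={_fmt(res.burst.get('kruskal_p'))}")
    for cls, p in res.burst.get("posthoc_p", {}).items():
        lines.append(f"  {cls}: rank-sum p={_fmt(p)}")
    if len(res.mua):
        lines.append("")
        lines.append("MUA modulation by depth window:")
        for _, row in res.mua.iterrows():
            lines.append(f"  {row['window']}: mean MI={_fmt(row['mean_mi'])} "
                         f"p={_fmt(row['p'])} (n={row['n_recordings']})")
    payload = {
        "summary": summary_json,
        "correlations": res.correlations,
        "burst": res.burst,
        "mua": res.mua.to_dict(orient="records"),
        "warnings": res.manifest.get("warnings", []),
    }
    return {"text": "\n".join(lines) + "\n", "json": payload}
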