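"""Cohort-level orchestration: simulate -> preprocess -> evaluate -> rank.

This module ties the generator, preprocessing chain, window metrics and
channel-ranking statistics into reproducible runs, and owns the run
configuration, the run manifest, and the report files the CLI writes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, DataError, FlatSignalError, ZeroVarianceError
from .metrics import METRIC_NAMES, MetricRecord, average_video, evaluate_window
from .preprocess import PreprocessConfig, preprocess_pair
from .stats import METRIC_DIRECTIONS, rank_channels
from .synthetic import Scene, export_cohort, generate_cohort, load_cohort
from .traces import CHANNELS

log = logging.getLogger("rppgeval")

RECORD_COLUMNS = ("subject", "activity", "channel", "window_index",
                  "dtw", "r", "rmse", "est_bpm", "delta_bpm")


@dataclass
class RunConfig:
    """All knobs of a full run; defaults reproduce the standard protocol
    (10-s windows over 60 s, 0.65-4 Hz order-6 band-pass, 39-240 BPM
    search band, alpha = 0.05)."""

    input_mode: str = "synthetic"          # synthetic | trace-files
    input_dir: str | None = None
    n_subjects: int = 6
    activities: tuple = ("Resting", "Talking", "Rotation", "Gym")
    duration_s: float = 60.0
    camera_fps: float = 30.0
    master_seed: int = 0
    common_fs: float = 60.0
    detrend_method: str = "smoothness_priors"
    detrend_lambda: float = 1000.0
    normalize_scope: str = "per_video"
    window_s: float = 10.0
    total_s: float = 60.0
    welch_segment_s: float = 5.0
    alpha: float = 0.05
    use_true_hr: bool = True               # ground-truth reference when available
    metrics: tuple = METRIC_NAMES
    outdir: str = "rppgeval_out"

    def __post_init__(self) -> None:
        if self.input_mode not in ("synthetic", "trace-files"):
            raise ConfigError(f"unknown input mode {self.input_mode!r}")
        if self.input_mode == "synthetic" and self.n_subjects < 1:
            raise ConfigError("n_subjects must be at least 1")
        if self.input_mode == "trace-files" and not self.input_dir:
            raise ConfigError("trace-files mode requires input_dir")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        unknown = set(self.metrics) - set(METRIC_NAMES)
        if unknown:
            raise ConfigError(f"unknown metrics {sorted(unknown)}")

    def preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(common_fs=self.common_fs,
                                detrend_method=self.detrend_method,
                                detrend_lambda=self.detrend_lambda,
                                window_s=self.window_s, total_s=self.total_s,
                                normalize_scope=self.normalize_scope)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        known = set(cls.__dataclass_fields__)
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        for key in ("activities", "metrics"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        raw.update(overrides)
        return cls(**raw)


def write_manifest(config: RunConfig, outdir: Path,
                   files: list[Path] | None = None) -> Path:
    """JSON manifest: config snapshot, package version, seed, checksums."""
    entry = {
        "package": "rppgeval",
        "version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "master_seed": config.master_seed,
        "config": asdict(config),
        "checksums": {},
    }
    for f in files or []:
        entry["checksums"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    path = outdir / "run_manifest.json"
    path.write_text(json.dumps(entry, indent=2, default=str) + "\n")
    return path


# ---------------------------------------------------------------------------
# Evaluation

@dataclass
class SceneResult:
    records: list[MetricRecord]
    excluded: list[dict] = field(default_factory=list)


def evaluate_scene(scene: Scene, config: RunConfig) -> SceneResult:
    """Preprocess one scene and compute window metrics for all channels.

    Channels or windows that cannot be evaluated (flat signal, zero
    variance) are excluded with a reason code and logged, never silently
    dropped.
    """
    excluded: list[dict] = []
    sub, act = scene.spec.subject_id, scene.spec.activity
    remaining = list(CHANNELS)
    pairs = []
    while remaining:
        try:
            pairs = preprocess_pair(scene.rgb, scene.cppg,
                                    config.preprocess_config(),
                                    subject=sub, activity=act,
                                    channels=tuple(remaining))
            break
        except FlatSignalError as exc:
            log.warning("excluded flat signal: %s", exc)
            if exc.channel == "cppg":   # no ground truth: drop the scene
                excluded.append({"subject": sub, "activity": act,
                                 "channel": "cppg", "window": None,
                                 "reason": "flat_signal"})
                remaining = []
                break
            excluded.append({"subject": sub, "activity": act,
                             "channel": exc.channel, "window": None,
                             "reason": "flat_signal"})
            remaining.remove(exc.channel)
    ref_hr = scene.true_hr_bpm if (config.use_true_hr and
                                   np.isfinite(scene.true_hr_bpm)) else None
    records = []
    for pair in pairs:
        try:
            records.append(evaluate_window(pair, ref_hr_bpm=ref_hr,
                                           metrics=config.metrics))
        except (ZeroVarianceError, DataError) as exc:
            excluded.append({"subject": sub, "activity": act,
                             "channel": pair.channel,
                             "window": pair.window_index,
                             "reason": type(exc).__name__})
            log.warning("excluded window: %s", exc)
    return SceneResult(records=records, excluded=excluded)


def evaluate_cohort(scenes: list[Scene],
                    config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Evaluate all scenes; returns (per-window records, per-video summaries,
    exclusion log)."""
    all_records: list[MetricRecord] = []
    excluded: list[dict] = []
    for scene in scenes:
        res = evaluate_scene(scene, config)
        all_records.extend(res.records)
        excluded.extend(res.excluded)
    if not all_records:
        raise DataError("no valid windows in the whole cohort")
    records_df = pd.DataFrame([{c: getattr(r, c) for c in RECORD_COLUMNS}
                               for r in all_records])
    summaries = []
    for (sub, act, ch), group in records_df.groupby(
            ["subject", "activity", "channel"], sort=True):
        recs = [r for r in all_records
                if (r.subject, r.activity, r.channel) == (sub, act, ch)]
        summaries.append(average_video(recs))
    summary_df = pd.DataFrame(summaries)
    return records_df, summary_df, excluded


# ---------------------------------------------------------------------------
# Reporting

def normalized_overview(summary_df: pd.DataFrame,
                        metrics: tuple = METRIC_NAMES) -> pd.DataFrame:
    """Per-channel overall means scaled to [0, 1] per metric, lower = better.

    Each metric's per-channel means are divided by the maximum across
    channels; Pearson's r is first mapped to 1 - r so that smaller is
    uniformly better.
    """
    rows = []
    for metric in metrics:
        if metric not in summary_df.columns or summary_df[metric].isna().all():
            continue
        means = summary_df.groupby("channel")[metric].mean()
        vals = (1.0 - means) if METRIC_DIRECTIONS[metric] == "higher" else means
        top = vals.max()
        norm = vals / top if top > 0 else vals * 0.0
        for ch in means.index:
            rows.append({"metric": metric, "channel": ch,
                         "mean_value": float(means[ch]),
                         "normalized": float(norm[ch])})
    return pd.DataFrame(rows)


def _ranking_markdown(ranking: pd.DataFrame, overview: pd.DataFrame,
                      alpha: float) -> str:
    lines = ["# Channel comparison report", ""]
    for group, gdf in ranking.groupby("group"):
        lines.append(f"## Group: {group}")
        lines.append("")
        lines.append("| metric | " + " | ".join(CHANNELS) +
                     " | Friedman p | pairwise p (significant at "
                     f"alpha={alpha} marked *) |")
        lines.append("|---" * (len(CHANNELS) + 3) + "|")
        for metric, mdf in gdf.groupby("metric"):
            by_ch = mdf.set_index("channel")
            cells = [f"{by_ch.loc[ch, 'mean_value']:.4g}" if ch in by_ch.index
                     else "-" for ch in CHANNELS]
            head = by_ch.iloc[0]
            pair_cols = [c for c in mdf.columns if c.startswith("p_")]
            cd = head["nemenyi_cd"]
            pair_txt = "; ".join(
                f"{c[2:]}={head[c]:.3g}"
                + ("*" if abs(by_ch.loc[c[2:].split('_vs_')[0], 'mean_rank']
                              - by_ch.loc[c[2:].split('_vs_')[1], 'mean_rank']) > cd
                   else "")
                for c in pair_cols if not pd.isna(head[c]))
            lines.append(f"| {metric} | " + " | ".join(cells) +
                         f" | {head['friedman_p']:.3g} | {pair_txt} |")
        lines.append("")
    lines.append("## Normalized overview (lower = better, max scaled to 1)")
    lines.append("")
    lines.append("| metric | " + " | ".join(CHANNELS) + " |")
    lines.append("|---" * (len(CHANNELS) + 1) + "|")
    for metric, mdf in overview.groupby("metric"):
        by_ch = mdf.set_index("channel")
        cells = [f"{by_ch.loc[ch, 'normalized']:.3f}" if ch in by_ch.index else "-"
                 for ch in CHANNELS]
        lines.append(f"| {metric} | " + " | ".join(cells) + " |")
    lines.append("")
    return "\n".join(lines)


def run_report(summary_df: pd.DataFrame, config: RunConfig,
               groupings: tuple = (None, "activity")) -> dict:
    """Build ranking tables (pooled and per-activity) plus the normalized
    overview; returns {"ranking": DataFrame, "overview": DataFrame,
    "markdown": str}."""
    parts = []
    for grouping in groupings:
        part = rank_channels(summary_df, grouping=grouping,
                             metrics=config.metrics, alpha=config.alpha)
        if not part.empty:
            parts.append(part)
    if not parts:
        raise DataError("no rankable groups in the summaries")
    ranking = pd.concat(parts, ignore_index=True)
    overview = normalized_overview(summary_df, metrics=config.metrics)
    md = _ranking_markdown(ranking, overview, config.alpha)
    return {"ranking": ranking, "overview": overview, "markdown": md}


# ---------------------------------------------------------------------------
# End-to-end convenience

def simulate_to_dir(config: RunConfig, outdir: str | Path) -> list[Scene]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenes = generate_cohort(n_subjects=config.n_subjects,
                             activities=config.activities,
                             master_seed=config.master_seed,
                             duration_s=config.duration_s,
                             camera_fps=config.camera_fps)
    manifest = export_cohort(scenes, outdir)
    files = sorted(outdir.glob("*.csv")) + [manifest]
    write_manifest(config, outdir, files)
    return scenes


def load_input(config: RunConfig) -> list[Scene]:
    if config.input_mode == "trace-files":
        return load_cohort(config.input_dir)
    return generate_cohort(n_subjects=config.n_subjects,
                           activities=config.activities,
                           master_seed=config.master_seed,
                           duration_s=config.duration_s,
                           camera_fps=config.camera_fps)


def run_full(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """simulate/load -> evaluate -> rank; optionally writes all outputs.

    Returns a dict with records, summaries, ranking, overview, markdown and
    the exclusion log.
    """
    scenes = load_input(config)
    records, summaries, excluded = evaluate_cohort(scenes, config)
    report = run_report(summaries, config)
    result = {"scenes": scenes, "records": records, "summaries": summaries,
              "excluded": excluded, **report}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        records_path = outdir / "window_records.csv"
        records.to_csv(records_path, index=False, float_format="%.9g")
        summary_path = outdir / "video_summaries.csv"
        summaries.to_csv(summary_path, index=False, float_format="%.9g")
        ranking_path = outdir / "channel_ranking.csv"
        report["ranking"].to_csv(ranking_path, index=False, float_format="%.9g")
        overview_path = outdir / "normalized_overview.csv"
        report["overview"].to_csv(overview_path, index=False, float_format="%.9g")
        (outdir / "report.md").write_text(report["markdown"])
        if excluded:
            pd.DataFrame(excluded).to_csv(outdir / "exclusions.csv", index=False)
        write_manifest(config, outdir,
                       [records_path, summary_path, ranking_path, overview_path])
    return result
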