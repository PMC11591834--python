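"""End-to-end orchestration: raw recordings to report tables.

Stages: preprocess (filter/resample/epoch/reject/reference) -> per-band PLV
matrices -> thresholded graphs -> graph metrics -> paired statistics. All
stages are deterministic, so rerunning a configuration reproduces the
output files exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import PLVMatrix, instantaneous_phase, plv_matrix
from .io import RawRecording, read_manifest, read_recording
from .metrics import metrics_for_graph
from .montage import Montage, default_montage, load_montage
from .network import DEFAULT_THRESHOLD_GRID, build_graph, sparsity_threshold
from .preprocess import BANDS, preprocess_raw
from .stats import (
    compare_edges,
    compare_global_across_thresholds,
    node_difference_map,
)

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "study_plv_matrices",
           "analyze_study", "load_config"]


class StageError(RuntimeError):
    """Pipeline failure labeled with the stage that raised it."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"[{stage}] {detail}")
        self.stage = stage


@dataclass
class PipelineConfig:
    manifest: str = ""
    montage: str | None = None
    out_dir: str = "plvnet_out"
    bands: tuple[str, ...] = ("delta", "theta", "alpha")
    target_sfreq: float = 250.0
    epoch_length_s: float = 2.0
    reject_limit_uv: float = 100.0
    notch_hz: float = 50.0
    plv_pooling: str = "epoch"
    threshold_mode: str = "grid"  # grid | sparsity
    threshold_grid: tuple[float, ...] = DEFAULT_THRESHOLD_GRID
    sparsity_target: float = 0.20
    distance_mode: str = "one_minus_w"
    edge_method: str = "paired_t"  # paired_t | gated
    tail: str = "two"
    q: float = 0.05
    alpha: float = 0.05
    node_diff_thresholds: dict = field(default_factory=dict)  # (metric, band) -> T
    seed: int = 0


def load_config(path: str | Path) -> PipelineConfig:
    obj = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig()
    for key, value in obj.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown config key {key!r}")
        if isinstance(getattr(cfg, key), tuple) and isinstance(value, list):
            value = tuple(value)
        setattr(cfg, key, value)
    return cfg


def _preprocess_to_plv(
    raw: RawRecording, band_name: str, cfg: PipelineConfig
) -> PLVMatrix:
    ep = preprocess_raw(
        raw,
        band=BANDS[band_name],
        target_sfreq=cfg.target_sfreq,
        epoch_length_s=cfg.epoch_length_s,
        reject_limit_uv=cfg.reject_limit_uv,
        notch_hz=cfg.notch_hz,
    )
    return plv_matrix(instantaneous_phase(ep), pooling=cfg.plv_pooling)


def study_plv_matrices(
    recordings: dict[str, dict[str, RawRecording]],
    cfg: PipelineConfig,
) -> dict[str, dict[str, list[PLVMatrix]]]:
    """Per-band, per-condition lists of PLV matrices, participant-ordered.

    ``recordings`` maps participant id -> condition -> RawRecording.
    """
    out: dict[str, dict[str, list[PLVMatrix]]] = {
        b: {"comfort": [], "fatigue": []} for b in cfg.bands
    }
    for participant in sorted(recordings):
        conds = recordings[participant]
        for condition in ("comfort", "fatigue"):
            if condition not in conds:
                raise StageError(
                    "connectivity", f"{participant} lacks condition {condition!r}"
                )
            raw = conds[condition]
            for band_name in cfg.bands:
                try:
                    m = _preprocess_to_plv(raw, band_name, cfg)
                except Exception as exc:
                    raise StageError(
                        "preprocess",
                        f"{participant}/{condition}/{band_name}: {exc}",
                    ) from exc
                out[band_name][condition].append(m)
    return out


def _thresholds_for(plv: PLVMatrix, cfg: PipelineConfig) -> list[float]:
    if cfg.threshold_mode == "grid":
        return list(cfg.threshold_grid)
    if cfg.threshold_mode == "sparsity":
        return [sparsity_threshold(plv, cfg.sparsity_target)]
    raise StageError("network", f"unknown threshold_mode {cfg.threshold_mode!r}")


def analyze_study(
    plvs: dict[str, dict[str, list[PLVMatrix]]],
    cfg: PipelineConfig,
    montage: Montage | None = None,
) -> dict:
    """Statistics bundle from per-band PLV matrices.

    Returns a dict with keys ``edge_maps`` (band -> EdgeComparisonMap),
    ``metrics`` (long DataFrame), ``threshold_comparison`` (DataFrame),
    ``node_diffs`` ((metric, band) -> NodeDifferenceMap) and
    ``plv_summary`` (DataFrame shaped like a band-wise group PLV table).
    """
    montage = montage or default_montage()
    edge_maps = {}
    metric_frames = []
    summary_rows = []
    for band, by_cond in plvs.items():
        comfort, fatigue = by_cond["comfort"], by_cond["fatigue"]
        try:
            emap = compare_edges(
                comfort, fatigue, q=cfg.q, method=cfg.edge_method, tail=cfg.tail
            )
        except Exception as exc:
            raise StageError("stats", f"edge comparison for {band}: {exc}") from exc
        edge_maps[band] = emap
        summary_rows.append({"band": band, **emap.summary})
        for condition, matrices in by_cond.items():
            for m in matrices:
                for thr in _thresholds_for(m, cfg):
                    g = build_graph(m, thr)
                    table = metrics_for_graph(
                        g, distance_mode=cfg.distance_mode, on_disconnected="nan"
                    )
                    frame = table.to_frame()
                    if cfg.threshold_mode == "sparsity":
                        # adaptive per-participant T: group rows under the
                        # common sparsity target, keep the realized T aside
                        frame["threshold_used"] = thr
                        frame["threshold"] = cfg.sparsity_target
                    metric_frames.append(frame)
    metrics_df = pd.concat(metric_frames, ignore_index=True)

    grid = (
        list(cfg.threshold_grid)
        if cfg.threshold_mode == "grid"
        else [cfg.sparsity_target]
    )
    try:
        thr_cmp = compare_global_across_thresholds(
            metrics_df, grid=grid, q=cfg.alpha, tail=cfg.tail
        )
    except Exception as exc:
        raise StageError("stats", f"threshold comparison: {exc}") from exc

    node_diffs = {}
    labels = next(iter(plvs.values()))["comfort"][0].channel_labels
    if cfg.threshold_mode == "grid" and set(labels) <= set(montage.region_of):
        for band in plvs:
            for metric in ("bc", "ne", "cc"):
                thr = cfg.node_diff_thresholds.get(
                    (metric, band), cfg.threshold_grid[0]
                )
                node_diffs[(metric, band)] = node_difference_map(
                    metrics_df, metric, band, thr, montage,
                    alpha=cfg.alpha, tail=cfg.tail,
                )
    return {
        "edge_maps": edge_maps,
        "metrics": metrics_df,
        "threshold_comparison": thr_cmp,
        "node_diffs": node_diffs,
        "plv_summary": pd.DataFrame(summary_rows),
    }


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the full study pipeline from a manifest; returns the out dir."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"plvnet {__version__}", f"seed {cfg.seed}"]

    try:
        manifest = read_manifest(cfg.manifest)
    except Exception as exc:
        raise StageError("input", f"manifest {cfg.manifest}: {exc}") from exc
    montage = load_montage(cfg.montage) if cfg.montage else default_montage()
    base = Path(cfg.manifest).parent

    recordings: dict[str, dict[str, RawRecording]] = {}
    for _, row in manifest.iterrows():
        path = Path(row["path"])
        if not path.is_absolute():
            path = base / path
        try:
            rec = read_recording(path)
        except Exception as exc:
            raise StageError("input", f"reading {path}: {exc}") from exc
        recordings.setdefault(str(row["participant"]), {})[row["condition"]] = rec
        log.append(f"loaded {row['participant']}/{row['condition']} from {path.name}")

    plvs = study_plv_matrices(recordings, cfg)
    for band, by_cond in plvs.items():
        for condition, mats in by_cond.items():
            for m in mats:
                log.append(
                    f"plv {m.participant}/{condition}/{band}: {m.n_epochs} epochs"
                )

    results = analyze_study(plvs, cfg, montage)

    results["plv_summary"].to_csv(out_dir / "table1_plv_summary.csv", index=False)
    for band, emap in results["edge_maps"].items():
        emap.table.to_csv(out_dir / f"edges_all_{band}.csv", index=False)
        emap.table[emap.table["significant"]].to_csv(
            out_dir / f"edges_significant_{band}.csv", index=False
        )
    thr_cmp = results["threshold_comparison"]
    for band in plvs:
        thr_cmp[thr_cmp["band"] == band].to_csv(
            out_dir / f"table_metrics_by_threshold_{band}.csv", index=False
        )
    for (metric, band), ndm in results["node_diffs"].items():
        ndm.table.to_csv(out_dir / f"node_diff_{metric}_{band}.csv", index=False)
    results["metrics"].to_csv(out_dir / "metrics_long.csv", index=False)

    run_manifest = {
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
            if k != "node_diff_thresholds"
        },
        "n_participants": len(recordings),
        "bands": list(cfg.bands),
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(run_manifest, indent=1))
    (out_dir / "run.log").write_text("\n".join(log) + "\n")
    return out_dir
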