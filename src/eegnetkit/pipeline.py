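"""End-to-end orchestration: config, staged execution, tidy outputs, manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import band_connectivity, compute_hofc, mean_connectivity, save_matrix_csv
from .dynamics import dynamic_entropy, standard_window_lengths
from .graph import compute_graph_metrics
from .montage import BAND_ORDER
from .plotting import export_heatmap
from .preprocess import preprocess_chain
from .recording import EEGRecording, load_csv, load_edf
from .stats import compare_conditions
from .synthetic import CohortSpec, generate_cohort

logger = logging.getLogger(__name__)

_CONFIG_KEYS = {
    "input_dir", "subjects", "duration_s", "sampling_rate", "band_mode",
    "clustering", "state_rule", "windows", "adjust", "seed", "out_dir",
    "line_freq", "heatmaps",
}


@dataclass
class PipelineConfig:
    """Serializable run configuration; unknown keys are rejected on load."""

    out_dir: str
    input_dir: str | None = None     # None -> simulate a cohort
    subjects: int = 4
    duration_s: float = 60.0
    sampling_rate: float = 128.0
    line_freq: float = 50.0
    band_mode: str = "wavelet"       # "wavelet" | "fir"
    clustering: str = "zhang"        # "zhang" | "onnela"
    state_rule: str = "ge-median"
    windows: str = "standard"       # "standard" | comma list of seconds
    adjust: str = "none"             # "none" | "bh"
    seed: int = 0
    heatmaps: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def config_hash(self) -> str:
        # out_dir is where results land, not what they are; exclude it so
        # identical analyses hash identically regardless of destination
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _window_lengths(cfg: PipelineConfig, band: str) -> tuple[float, ...]:
    if cfg.windows == "standard":
        return standard_window_lengths(band)
    return tuple(float(x) for x in cfg.windows.split(","))


def _load_recordings(cfg: PipelineConfig) -> dict[str, dict[str, EEGRecording]]:
    """subject -> condition -> recording, from files named <subject>_<pre|post>.*"""
    in_dir = Path(cfg.input_dir)
    recs: dict[str, dict[str, EEGRecording]] = {}
    for path in sorted(in_dir.glob("*_*.*")):
        if path.suffix not in (".csv", ".edf"):
            continue
        sid, cond = path.stem.rsplit("_", 1)
        if cond not in ("pre", "post"):
            continue
        if path.suffix == ".csv":
            rec = load_csv(path, rate=cfg.sampling_rate, subject_id=sid, condition=cond)
        else:
            rec = load_edf(path, subject_id=sid, condition=cond)
        recs.setdefault(sid, {})[cond] = rec
    if not recs:
        raise FileNotFoundError(f"no <subject>_<pre|post>.csv/.edf recordings in {in_dir}")
    return recs


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute preprocess -> connectivity -> graph metrics -> dynamics -> stats.

    Writes tidy CSVs, optional heatmaps and a manifest into ``cfg.out_dir``;
    returns the manifest dict. Stage failures abort with the stage name and
    the offending subject/band.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    t0 = time.time()

    if cfg.input_dir is None:
        spec = CohortSpec(
            n_subjects=cfg.subjects, duration_s=cfg.duration_s,
            sampling_rate=cfg.sampling_rate, seed=cfg.seed,
        )
        cohort = generate_cohort(spec)
        recordings = cohort.recordings
    else:
        recordings = _load_recordings(cfg)

    metric_rows, dyn_rows, strength_rows = [], [], []
    matrices_dir = out_dir / "matrices"
    matrices_dir.mkdir(exist_ok=True)
    heat_dir = out_dir / "heatmaps"
    if cfg.heatmaps:
        heat_dir.mkdir(exist_ok=True)
    n_matrices = 0

    for sid in sorted(recordings):
        for cond in sorted(recordings[sid]):
            rec = recordings[sid][cond]
            stage = "preprocess"
            try:
                bands = preprocess_chain(
                    rec, line_freq=cfg.line_freq, band_mode=cfg.band_mode
                )
                for band in BAND_ORDER:
                    bs = bands[band]
                    stage = "connectivity"
                    lofc = band_connectivity(bs, order="low")
                    hofc = compute_hofc(lofc)
                    for cm in (lofc, hofc):
                        save_matrix_csv(
                            cm, matrices_dir / f"{sid}_{cond}_{band}_{cm.order}.csv"
                        )
                        n_matrices += 1
                        strength_rows.append({
                            "subject": sid, "condition": cond, "band": band,
                            "order": cm.order, "metric": "mean_connectivity",
                            "scope": "global", "value": mean_connectivity(cm),
                        })
                        if cfg.heatmaps:
                            export_heatmap(
                                cm, heat_dir / f"{sid}_{cond}_{band}_{cm.order}.png"
                            )
                        stage = "graph_metrics"
                        gm = compute_graph_metrics(cm, clustering=cfg.clustering)
                        metric_rows.append({
                            "subject": sid, "condition": cond, "band": band,
                            "order": cm.order, "metric": "global_efficiency",
                            "scope": "global", "value": gm.global_efficiency,
                        })
                        metric_rows.append({
                            "subject": sid, "condition": cond, "band": band,
                            "order": cm.order, "metric": "average_clustering",
                            "scope": "global", "value": gm.average_clustering,
                        })
                        for lobe in gm.lobe_efficiency:
                            metric_rows.append({
                                "subject": sid, "condition": cond, "band": band,
                                "order": cm.order, "metric": "nodal_efficiency",
                                "scope": lobe, "value": gm.lobe_efficiency[lobe],
                            })
                            metric_rows.append({
                                "subject": sid, "condition": cond, "band": band,
                                "order": cm.order, "metric": "nodal_clustering",
                                "scope": lobe, "value": gm.lobe_clustering[lobe],
                            })
                        for ch, ne_v, ncc_v in zip(
                            gm.channel_labels, gm.nodal_efficiency, gm.nodal_clustering
                        ):
                            metric_rows.append({
                                "subject": sid, "condition": cond, "band": band,
                                "order": cm.order, "metric": "nodal_efficiency",
                                "scope": ch, "value": float(ne_v),
                            })
                            metric_rows.append({
                                "subject": sid, "condition": cond, "band": band,
                                "order": cm.order, "metric": "nodal_clustering",
                                "scope": ch, "value": float(ncc_v),
                            })
                    stage = "dynamics"
                    for length_s in _window_lengths(cfg, band):
                        for order in ("low", "high"):
                            try:
                                nse, dist, ss = dynamic_entropy(bs, length_s, order=order)
                            except ValueError:
                                continue  # too few windows at this length
                            dyn_rows.append({
                                "subject": sid, "condition": cond, "band": band,
                                "order": order, "window_length_s": length_s,
                                "n_windows": len(ss), **{f"p{k}": dist.p[k] for k in dist.p},
                                "metric": "state_entropy", "scope": "global",
                                "value": nse,
                            })
            except Exception as exc:
                raise RuntimeError(
                    f"stage {stage!r} failed for subject {sid} ({cond}): {exc}"
                ) from exc
            logger.info("subject %s %s done (%.1fs)", sid, cond, time.time() - t0)

    metrics = pd.DataFrame(metric_rows + strength_rows)
    dynamics = pd.DataFrame(dyn_rows)
    metrics.insert(0, "config_hash", chash)
    dynamics.insert(0, "config_hash", chash)
    metrics.to_csv(out_dir / "metrics.csv", index=False, float_format="%.12g")
    dynamics.to_csv(out_dir / "dynamics.csv", index=False, float_format="%.12g")

    stats_in = pd.concat(
        [metrics, dynamics.assign(scope=lambda d: d["window_length_s"].map(lambda x: f"win{x:g}"))],
        ignore_index=True,
    )
    results = compare_conditions(stats_in, adjust=cfg.adjust)
    results.insert(0, "config_hash", chash)
    results.to_csv(out_dir / "stats.csv", index=False, float_format="%.12g")

    manifest = {
        "package_version": __version__,
        "config": asdict(cfg),
        "config_hash": chash,
        "n_subjects": len(recordings),
        "n_static_matrices": n_matrices,
        "state_rule": cfg.state_rule,
        "clustering_variant": cfg.clustering,
        "outputs": ["metrics.csv", "dynamics.csv", "stats.csv"],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return manifest
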