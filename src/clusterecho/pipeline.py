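"""End-to-end orchestration: simulate -> preprocess -> detect -> compare.

Two run modes mirror the study protocol.  ``experiment`` simulates a normal
stack (individual agents only, the training tunnel) and a sample stack whose
events are clusters with probability ``cluster_frac``; the detector is trained
on the normal stack and classifies the sample stack, and the spectral module
compares the detected groups.  ``control`` runs the identical pipeline with
clusters disabled in both stacks, where the expected outcome is (near) zero
anomalies.

One top-level seed deterministically derives per-stage seeds (stage-name
hashing via CRC32), so a (config, seed) pair reproduces the whole run and any
stage can be re-run in isolation.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detect import LSTMAnomalyDetector, separate
from .io import save_detector, write_datasets, write_frames
from .preprocess import DatasetSplit, ROISpec, build_datasets
from .simulate import (
    AcquisitionSpec,
    EchoSpec,
    SceneSpec,
    simulate_dataset,
)
from .spectra import GroupComparison, compare_groups

__all__ = ["RunConfig", "RunReport", "run", "run_experiment", "run_control",
           "derive_seed", "default_roi", "report_from_artifacts"]

MODES = ("experiment", "control")


def derive_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(base_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def default_roi(acq: AcquisitionSpec, scene: SceneSpec) -> ROISpec:
    """ROI spanning the lateral tunnel span and the 160-sample lumen window."""
    return ROISpec(element_span=scene.element_span(acq), depth_span=scene.tunnel_depth_span)


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one end-to-end run.

    ``n_frames_train`` / ``n_frames_test`` size the two simulated stacks; with
    the default event probability of 0.3 the defaults retain roughly 2,000
    training and 500 testing vectors.  ``mode='control'`` forces
    ``cluster_frac = 0`` in both stacks.
    """

    mode: str = "experiment"
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    scene: SceneSpec = field(default_factory=SceneSpec)
    echo: EchoSpec = field(default_factory=EchoSpec)
    n_frames_train: int = 6700
    n_frames_test: int = 1700
    roi: Optional[ROISpec] = None
    level: Optional[float] = None
    level_multiplier: float = 8.0
    min_pixels: int = 3
    encoder_units: tuple[int, int, int] = (32, 16, 8)
    learning_rate: float = 3e-3
    batch_size: int = 256
    epochs: int = 20
    margin: float = 1.05
    band_frac: float = 0.15
    band_stat: str = "mean"
    seed: int = 0
    output_dir: Optional[str] = None
    save_frames: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.n_frames_train < 1 or self.n_frames_test < 1:
            raise ValueError("both stacks need at least one frame")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "acquisition" in d:
            d["acquisition"] = AcquisitionSpec(**d["acquisition"])
        if "scene" in d:
            sc = dict(d["scene"])
            for key in ("tunnel_depth_span", "tunnel_element_span"):
                if sc.get(key) is not None:
                    sc[key] = tuple(sc[key])
            d["scene"] = SceneSpec(**sc)
        if "echo" in d:
            d["echo"] = EchoSpec(**d["echo"])
        if d.get("roi") is not None:
            r = dict(d["roi"])
            d["roi"] = ROISpec(
                element_span=tuple(r["element_span"]),
                depth_span=tuple(r["depth_span"]),
                center_element=r.get("center_element"),
            )
        if "encoder_units" in d:
            d["encoder_units"] = tuple(d["encoder_units"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [listify(v) for v in obj]
            return obj

        return listify(asdict(self))


@dataclass
class RunReport:
    """Counts, threshold and spectral summary of one run, JSON-serialisable."""

    mode: str
    seed: int
    counts: dict
    threshold: float
    max_train_error: float
    spectral_summary: dict
    config: dict
    version: str = __version__

    def __post_init__(self) -> None:
        c = self.counts
        ok = (
            c["anomalies"] <= c["test_vectors"] <= c["frames_test"]
            and c["train_vectors"] <= c["frames_train"]
        )
        if not ok:
            raise ValueError(f"inconsistent counts: {c}")

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


class StageError(RuntimeError):
    """Wraps a failure with the name of the pipeline stage it occurred in."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def _spectral_groups(split: DatasetSplit, results: pd.DataFrame):
    flags = results["is_anomaly"].to_numpy()
    anomalies, nonanomalies = separate(
        [_Row(bool(f)) for f in flags], split.test
    )
    groups = {"train": split.train, "test_nonanomaly": nonanomalies,
              "test_anomaly": anomalies}
    return {k: v for k, v in groups.items() if len(v) > 0}


class _Row:
    __slots__ = ("is_anomaly",)

    def __init__(self, is_anomaly: bool):
        self.is_anomaly = is_anomaly


def run(cfg: RunConfig) -> RunReport:
    """Execute one full run and (optionally) persist every intermediate."""
    out = Path(cfg.output_dir) if cfg.output_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    acq = cfg.acquisition
    cluster_frac_sample = 0.0 if cfg.mode == "control" else cfg.scene.cluster_frac
    scene_normal = replace(
        cfg.scene,
        n_frames=cfg.n_frames_train,
        cluster_frac=0.0,
        seed=derive_seed(cfg.seed, "simulate/normal"),
    )
    scene_sample = replace(
        cfg.scene,
        n_frames=cfg.n_frames_test,
        cluster_frac=cluster_frac_sample,
        seed=derive_seed(cfg.seed, "simulate/sample"),
    )

    simulate_stage = _stage("simulate")(simulate_dataset)
    frames_n, truth_n = simulate_stage(acq, scene_normal, cfg.echo)
    frames_s, truth_s = simulate_stage(acq, scene_sample, cfg.echo)

    roi = cfg.roi or default_roi(acq, cfg.scene)
    split, retention = _stage("preprocess")(build_datasets)(
        frames_n,
        frames_s,
        roi,
        roi,
        level=cfg.level,
        min_pixels=cfg.min_pixels,
        level_multiplier=cfg.level_multiplier,
    )

    det = LSTMAnomalyDetector(
        encoder_units=cfg.encoder_units,
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        epochs=cfg.epochs,
        margin=cfg.margin,
        seed=derive_seed(cfg.seed, "train"),
    )
    _stage("train")(det.fit)(split.train_matrix)

    errors = _stage("score")(det.score_samples)(split.test_matrix)
    results = pd.DataFrame(
        {
            "frame_index": [v.source_frame for v in split.test],
            "reconstruction_error": errors,
            "threshold": det.threshold_,
            "is_anomaly": errors > det.threshold_,
            "truth_label": [v.truth_label or "" for v in split.test],
        }
    )

    groups = _spectral_groups(split, results)
    spectral_summary: dict = {}
    comparison: Optional[GroupComparison] = None
    if "test_anomaly" in groups and "test_nonanomaly" in groups:
        comparison = _stage("analyze")(compare_groups)(
            groups, acq.fs, acq.f0, band_frac=cfg.band_frac, band_stat=cfg.band_stat
        )
        spectral_summary = {
            "mean_fund_amp": comparison.mean_fund_amp,
            "mean_sub_amp": comparison.mean_sub_amp,
            "auc": comparison.auc,
            "slopes": {g: f.slope for g, f in comparison.fits.items()},
            "r_squared": {g: f.r_squared for g, f in comparison.fits.items()},
            "slope_margin": comparison.slope_margin,
        }
    else:  # control-like outcome: no anomaly group to compare
        from .spectra import group_mean_spectrum

        spectral_summary = {
            "mean_fund_amp": {},
            "mean_sub_amp": {},
            "auc": {},
        }
        for name, vectors in groups.items():
            feats = group_mean_spectrum(vectors, acq.fs, f0=acq.f0, group=name)
            spectral_summary["mean_fund_amp"][name] = feats.fund_amp
            spectral_summary["mean_sub_amp"][name] = feats.sub_amp
            spectral_summary["auc"][name] = feats.auc

    counts = {
        "frames_train": cfg.n_frames_train,
        "frames_test": cfg.n_frames_test,
        "retained_train": len(split.train),
        "retained_test": len(split.test),
        "train_vectors": len(split.train),
        "test_vectors": len(split.test),
        "anomalies": int(results["is_anomaly"].sum()),
    }
    report = RunReport(
        mode=cfg.mode,
        seed=cfg.seed,
        counts=counts,
        threshold=float(det.threshold_),
        max_train_error=float(np.max(det.train_errors_)),
        spectral_summary=spectral_summary,
        config=cfg.to_dict(),
    )

    if out is not None:
        _persist(out, cfg, frames_n, truth_n, frames_s, truth_s, split,
                 retention, det, results, comparison, report)
    return report


def _persist(out, cfg, frames_n, truth_n, frames_s, truth_s, split, retention,
             det, results, comparison, report) -> None:
    truth_n.to_csv(out / "truth_normal.csv", index=False)
    truth_s.to_csv(out / "truth_sample.csv", index=False)
    if cfg.save_frames:
        write_frames(out / "frames_normal.h5", frames_n, truth_n,
                     cfg.acquisition, cfg.scene, cfg.echo)
        write_frames(out / "frames_sample.h5", frames_s, truth_s,
                     cfg.acquisition, cfg.scene, cfg.echo)
    write_datasets(out / "datasets.h5", split, seed=cfg.seed, mode=cfg.mode)
    retention.to_csv(out / "retention.csv", index=False)
    save_detector(out / "model", det)
    results.to_csv(out / "results.csv", index=False)
    if comparison is not None:
        comparison.scatter.to_csv(out / "scatter.csv", index=False)
        comparison.to_frame().to_csv(out / "fits.csv", index=False)
        spec_rows = []
        for g, feats in comparison.mean_spectra.items():
            spec_rows.append(
                pd.DataFrame(
                    {"group": g, "freq_hz": feats.freqs, "magnitude": feats.magnitude}
                )
            )
        pd.concat(spec_rows, ignore_index=True).to_csv(
            out / "mean_spectra.csv", index=False
        )
    (out / "report.json").write_text(report.to_json())


def run_experiment(cfg: RunConfig) -> RunReport:
    """Main experiment: clusters present in the sample stack only."""
    if cfg.mode != "experiment":
        raise ValueError("run_experiment requires cfg.mode == 'experiment'")
    return run(cfg)


def run_control(cfg: RunConfig) -> RunReport:
    """Control experiment: individual agents in both stacks, no clusters."""
    if cfg.mode != "control":
        raise ValueError("run_control requires cfg.mode == 'control'")
    return run(cfg)


def report_from_artifacts(output_dir) -> dict:
    """Recompute the report's counts from the persisted intermediates."""
    out = Path(output_dir)
    report = json.loads((out / "report.json").read_text())
    results = pd.read_csv(out / "results.csv")
    import h5py

    with h5py.File(out / "datasets.h5", "r") as h5:
        n_train = h5["train/values"].shape[0]
        n_test = h5["test/values"].shape[0]
    counts = dict(report["counts"])
    counts.update(
        {
            "retained_train": n_train,
            "retained_test": n_test,
            "train_vectors": n_train,
            "test_vectors": n_test,
            "anomalies": int(results["is_anomaly"].sum()),
        }
    )
    return counts
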