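"""HDF5 / CSV / JSON persistence for frames, datasets and trained detectors."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import h5py
import numpy as np
import pandas as pd

from .detect import LSTMAnomalyDetector, GlobalMinMaxScaler
from ._lstm import LSTMAutoencoder
from .preprocess import DatasetSplit, RFVector
from .simulate import AcquisitionSpec, EchoSpec, FrameTruth, RFFrame, SceneSpec

__all__ = [
    "write_frames",
    "read_frames",
    "write_datasets",
    "read_datasets",
    "save_detector",
    "load_detector",
]

PathLike = Union[str, Path]


def _spec_attrs(group: h5py.Group, name: str, spec) -> None:
    group.attrs[name] = json.dumps(asdict(spec))


def write_frames(
    path: PathLike,
    frames: Sequence[RFFrame],
    truth: pd.DataFrame,
    acq: AcquisitionSpec,
    scene: SceneSpec,
    echo: EchoSpec,
) -> None:
    """One run's frame stack + truth table + spec metadata into an HDF5 file."""
    stack = np.stack([f.samples for f in frames]).astype(np.float32)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("frames", data=stack, compression="gzip", compression_opts=1)
        g = h5.create_group("truth")
        g.create_dataset("frame_index", data=truth["frame_index"].to_numpy(np.int64))
        g.create_dataset(
            "kind", data=np.array(truth["kind"], dtype=h5py.string_dtype())
        )
        g.create_dataset("element", data=truth["element"].to_numpy(np.int64))
        g.create_dataset("depth_sample", data=truth["depth_sample"].to_numpy(np.int64))
        _spec_attrs(h5, "acquisition", acq)
        _spec_attrs(h5, "scene", scene)
        _spec_attrs(h5, "echo", echo)


def read_frames(path: PathLike) -> tuple[list[RFFrame], pd.DataFrame, dict]:
    """Inverse of :func:`write_frames`; truth labels are re-attached."""
    with h5py.File(path, "r") as h5:
        stack = h5["frames"][...]
        truth = pd.DataFrame(
            {
                "frame_index": h5["truth/frame_index"][...],
                "kind": [k.decode() for k in h5["truth/kind"][...]],
                "element": h5["truth/element"][...],
                "depth_sample": h5["truth/depth_sample"][...],
            }
        )
        specs = {k: json.loads(h5.attrs[k]) for k in ("acquisition", "scene", "echo")}
    frames = []
    for i in range(stack.shape[0]):
        row = truth.iloc[i]
        ft = FrameTruth(
            kind=row["kind"],
            element=None if row["element"] < 0 else int(row["element"]),
            depth_sample=None if row["depth_sample"] < 0 else int(row["depth_sample"]),
        )
        frames.append(RFFrame(samples=stack[i], frame_index=int(row["frame_index"]), truth=ft))
    return frames, truth, specs


def _write_vectors(h5: h5py.File, name: str, vectors: Sequence[RFVector]) -> None:
    g = h5.create_group(name)
    g.create_dataset("values", data=np.stack([v.values for v in vectors]))
    g.create_dataset("frame_index", data=np.array([v.source_frame for v in vectors]))
    sd = h5py.string_dtype()
    g.create_dataset(
        "truth_label",
        data=np.array([v.truth_label or "" for v in vectors], dtype=sd),
    )
    g.create_dataset("stack", data=np.array([v.stack for v in vectors], dtype=sd))


def _read_vectors(h5: h5py.File, name: str, group_label: str) -> list[RFVector]:
    g = h5[name]
    values = g["values"][...]
    idx = g["frame_index"][...]
    labels = [t.decode() or None for t in g["truth_label"][...]]
    stacks = [s.decode() for s in g["stack"][...]]
    return [
        RFVector(
            values=values[i],
            source_frame=int(idx[i]),
            group_label=group_label,
            truth_label=labels[i],
            stack=stacks[i],
        )
        for i in range(values.shape[0])
    ]


def write_datasets(path: PathLike, split: DatasetSplit, **attrs) -> None:
    """Training/testing vector matrices (n x 160) with indices and labels."""
    with h5py.File(path, "w") as h5:
        _write_vectors(h5, "train", split.train)
        _write_vectors(h5, "test", split.test)
        for k, v in attrs.items():
            h5.attrs[k] = v


def read_datasets(path: PathLike) -> tuple[DatasetSplit, dict]:
    with h5py.File(path, "r") as h5:
        split = DatasetSplit(
            train=_read_vectors(h5, "train", "train_normal"),
            test=_read_vectors(h5, "test", "test"),
        )
        attrs = dict(h5.attrs)
    return split, attrs


def save_detector(model_dir: PathLike, det: LSTMAnomalyDetector) -> None:
    """Persist a fitted detector: weights, config, scaler, threshold, errors."""
    model_dir = Path(model_dir)
    model_dir.mkdir(parents=True, exist_ok=True)
    weights = det.model_.get_weights()
    np.savez(model_dir / "weights.npz", **{f"w{i}": w for i, w in enumerate(weights)})
    meta = {
        "params": det.get_params(),
        "threshold": det.threshold_,
        "scaler": None
        if det.scaler_ is None
        else {"lo": det.scaler_.lo_, "hi": det.scaler_.hi_},
    }
    (model_dir / "detector.json").write_text(json.dumps(meta, indent=2))
    np.savetxt(model_dir / "train_errors.csv", det.train_errors_, header="train_error")


def load_detector(model_dir: PathLike) -> LSTMAnomalyDetector:
    model_dir = Path(model_dir)
    meta = json.loads((model_dir / "detector.json").read_text())
    det = LSTMAnomalyDetector(**meta["params"])
    det.model_ = LSTMAutoencoder(
        encoder_units=tuple(det.encoder_units),
        learning_rate=det.learning_rate,
        batch_size=det.batch_size,
        epochs=det.epochs,
        seed=det.seed,
    )
    with np.load(model_dir / "weights.npz") as z:
        det.model_.set_weights([z[f"w{i}"] for i in range(len(z.files))])
    if meta["scaler"] is not None:
        det.scaler_ = GlobalMinMaxScaler()
        det.scaler_.lo_ = meta["scaler"]["lo"]
        det.scaler_.hi_ = meta["scaler"]["hi"]
    else:
        det.scaler_ = None
    det.threshold_ = meta["threshold"]
    det.train_errors_ = np.loadtxt(model_dir / "train_errors.csv", ndmin=1)
    return det
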