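"""Synthetic flow-phantom RF data.

Generates labelled stacks of beamformed RF frames emulating a low-concentration
microbubble acquisition in a tissue-mimicking flow phantom: static tunnel-wall
clutter, sparse single-bubble events (individual microbubbles or clustered-
microbubble agents with higher amplitude and elevated subharmonic content), and
additive Gaussian electronic noise.

The echo model is phenomenological, not a bubble-dynamics solver: each event is
a Gaussian-windowed burst with components at the transmit fundamental ``f0``,
the second harmonic ``2 f0`` and the subharmonic ``f0/2``.  Cluster events are
scaled by ``cluster_gain`` and carry a larger subharmonic-to-fundamental ratio,
which is the acoustic signature the downstream anomaly detector is meant to
isolate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionSpec",
    "SceneSpec",
    "EchoSpec",
    "FrameTruth",
    "RFFrame",
    "bubble_echo",
    "wall_clutter",
    "simulate_frame",
    "simulate_dataset",
]

KIND_EMPTY = "empty"
KIND_INDIVIDUAL = "individual"
KIND_CLUSTER = "cluster"

_DTYPE = np.float32


@dataclass(frozen=True)
class AcquisitionSpec:
    """Transducer and digitiser geometry.

    fs : sampling rate [Hz]; f0 : transmit centre (fundamental) frequency [Hz];
    n_elements : lateral element count; n_samples : depth samples per frame;
    frame_rate : frames/s (metadata only).
    """

    fs: float = 11.2e6
    f0: float = 2.8e6
    n_elements: int = 64
    n_samples: int = 512
    frame_rate: float = 100.0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.f0 <= 0 or self.frame_rate <= 0:
            raise ValueError("fs, f0 and frame_rate must be positive")
        if self.fs < 4.0 * self.f0:
            raise ValueError(
                "fs must be >= 4*f0 so the second harmonic stays below Nyquist"
            )
        if self.n_samples < 160:
            raise ValueError("n_samples must be >= 160")
        if self.n_elements < 1:
            raise ValueError("n_elements must be >= 1")

    @property
    def t_axis(self) -> np.ndarray:
        """Fast-time axis [s], one sample per depth sample."""
        return np.arange(self.n_samples) / self.fs


@dataclass(frozen=True)
class SceneSpec:
    """One acquisition run: how many frames, how sparse, how noisy.

    ``tunnel_depth_span`` is the half-open depth-sample interval of the lumen
    (exactly 160 samples, the extraction window); ``tunnel_element_span`` is
    the half-open lateral interval the lumen crosses.  ``event_prob`` is the
    probability a frame contains one bubble event; the low-dilution protocol
    keeps it well below 1 so most frames are empty.  ``cluster_frac`` is the
    fraction of events that are clusters (0 for a pure individual-agent run).
    """

    n_frames: int = 1000
    event_prob: float = 0.3
    cluster_frac: float = 0.25
    tunnel_depth_span: tuple[int, int] = (176, 336)
    tunnel_element_span: Optional[tuple[int, int]] = None
    wall_amplitude: float = 5.0
    noise_sd: float = 0.02
    lateral_sigma: float = 1.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not (0.0 <= self.event_prob <= 1.0):
            raise ValueError("event_prob must lie in [0, 1]")
        if not (0.0 <= self.cluster_frac <= 1.0):
            raise ValueError("cluster_frac must lie in [0, 1]")
        d0, d1 = self.tunnel_depth_span
        if d1 - d0 != 160:
            raise ValueError("tunnel_depth_span must cover exactly 160 samples")
        if d0 < 0:
            raise ValueError("tunnel_depth_span must start at a nonnegative sample")
        if self.noise_sd < 0 or self.wall_amplitude < 0:
            raise ValueError("noise_sd and wall_amplitude must be nonnegative")
        if self.lateral_sigma <= 0:
            raise ValueError("lateral_sigma must be positive")

    def element_span(self, acq: AcquisitionSpec) -> tuple[int, int]:
        """Resolved lateral tunnel span (default: 3 elements on the array centre)."""
        if self.tunnel_element_span is not None:
            e0, e1 = self.tunnel_element_span
        else:
            mid = acq.n_elements // 2
            e0, e1 = max(mid - 2, 0), min(mid + 1, acq.n_elements)
        if not (0 <= e0 < e1 <= acq.n_elements):
            raise ValueError("tunnel_element_span outside the array")
        return e0, e1

    def validate_against(self, acq: AcquisitionSpec) -> None:
        d0, d1 = self.tunnel_depth_span
        if d1 > acq.n_samples:
            raise ValueError("tunnel_depth_span exceeds n_samples")
        self.element_span(acq)


@dataclass(frozen=True)
class EchoSpec:
    """Per-event waveform parameters.

    ``amp_mean`` and ``amp_sd`` parameterise a log-normal peak amplitude:
    amp = amp_mean * exp(amp_sd * N(0,1)), i.e. amp_mean is the median and
    amp_sd the log-scale standard deviation.  ``cluster_gain`` multiplies the
    whole cluster waveform; ``sub_ratio_*`` are subharmonic-to-fundamental
    component ratios; ``harm2_ratio`` the second-harmonic ratio;
    ``pulse_sigma`` the Gaussian envelope width [s].
    """

    amp_mean: float = 1.0
    amp_sd: float = 0.15
    cluster_gain: float = 3.0
    sub_ratio_ind: float = 0.05
    sub_ratio_clu: float = 0.4
    harm2_ratio: float = 0.2
    pulse_sigma: float = 0.7e-6

    def __post_init__(self) -> None:
        if self.cluster_gain <= 1.0:
            raise ValueError("cluster_gain must exceed 1")
        if not (self.sub_ratio_clu > self.sub_ratio_ind >= 0.0):
            raise ValueError("require sub_ratio_clu > sub_ratio_ind >= 0")
        if self.pulse_sigma <= 0:
            raise ValueError("pulse_sigma must be positive")
        if self.amp_mean <= 0 or self.amp_sd < 0:
            raise ValueError("amp_mean must be positive and amp_sd nonnegative")


@dataclass(frozen=True)
class FrameTruth:
    """Ground-truth label for one simulated frame."""

    kind: str = KIND_EMPTY
    element: Optional[int] = None
    depth_sample: Optional[int] = None


@dataclass
class RFFrame:
    """One frame of beamformed RF amplitudes [element, depth sample]."""

    samples: np.ndarray
    frame_index: int
    truth: Optional[FrameTruth] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D [element, depth sample]")


def bubble_echo(
    t_axis: np.ndarray,
    t0: float,
    amp: float,
    echo: EchoSpec,
    acq: AcquisitionSpec,
    is_cluster: bool = False,
) -> np.ndarray:
    """Gaussian-windowed multi-component echo of a single bubble event.

    Returns ``amp * g(t) * [sin(2 pi f0 (t-t0)) + h2 sin(2 pi 2f0 (t-t0))
    + s sin(2 pi (f0/2)(t-t0))]`` with ``g`` a Gaussian envelope of width
    ``pulse_sigma``; cluster events use ``s = sub_ratio_clu`` and are scaled
    by ``cluster_gain``.
    """
    t_axis = np.asarray(t_axis, dtype=float)
    if t_axis.ndim != 1 or t_axis.size < 2:
        raise ValueError("t_axis must be a 1-D array of at least two samples")
    dt = np.diff(t_axis)
    if not np.allclose(dt, 1.0 / acq.fs, rtol=1e-6, atol=1e-6 / acq.fs):
        raise ValueError("t_axis must be uniform at 1/fs")
    if amp < 0:
        raise ValueError("amp must be nonnegative")

    tau = t_axis - t0
    envelope = np.exp(-(tau**2) / (2.0 * echo.pulse_sigma**2))
    s = echo.sub_ratio_clu if is_cluster else echo.sub_ratio_ind
    carrier = (
        np.sin(2.0 * np.pi * acq.f0 * tau)
        + echo.harm2_ratio * np.sin(2.0 * np.pi * 2.0 * acq.f0 * tau)
        + s * np.sin(2.0 * np.pi * 0.5 * acq.f0 * tau)
    )
    wave = amp * envelope * carrier
    if is_cluster:
        wave = echo.cluster_gain * wave
    return wave


def wall_clutter(acq: AcquisitionSpec, scene: SceneSpec) -> np.ndarray:
    """Static tunnel-wall clutter, identical for every frame of a run.

    Two Gaussian-windowed RF reflection bands bracketing the lumen, modulated
    at f0 along depth, with a smooth deterministic per-element gain taper.
    Purely a function of the specs, so background subtraction can remove it
    exactly.
    """
    d0, d1 = scene.tunnel_depth_span
    depth = np.arange(acq.n_samples)
    sigma_w = 8.0  # wall band width [samples]
    margin = 12.0  # wall offset from the lumen edge [samples]
    bands = np.exp(-((depth - (d0 - margin)) ** 2) / (2 * sigma_w**2)) + np.exp(
        -((depth - (d1 + margin)) ** 2) / (2 * sigma_w**2)
    )
    rf = np.sin(2.0 * np.pi * acq.f0 * depth / acq.fs)
    elem_gain = 1.0 + 0.1 * np.sin(
        2.0 * np.pi * np.arange(acq.n_elements) / acq.n_elements
    )
    clutter = scene.wall_amplitude * elem_gain[:, None] * (bands * rf)[None, :]
    return clutter.astype(_DTYPE)


def _draw_amp(echo: EchoSpec, rng: np.random.Generator) -> float:
    return float(echo.amp_mean * np.exp(echo.amp_sd * rng.standard_normal()))


def simulate_frame(
    acq: AcquisitionSpec,
    scene: SceneSpec,
    echo: EchoSpec,
    rng: np.random.Generator,
    force_kind: Optional[str] = None,
    clutter: Optional[np.ndarray] = None,
    frame_index: int = 0,
) -> RFFrame:
    """Simulate one frame: clutter + zero-or-one bubble event + noise.

    The event is a Bernoulli(event_prob) draw (cluster with probability
    cluster_frac) unless ``force_kind`` pins it; it lands on a random element
    inside the lateral tunnel span, at a uniform depth within the lumen, and
    spreads to neighbouring elements with a Gaussian lateral profile.
    """
    scene.validate_against(acq)
    if force_kind not in (None, KIND_EMPTY, KIND_INDIVIDUAL, KIND_CLUSTER):
        raise ValueError(f"unknown force_kind {force_kind!r}")
    if clutter is None:
        clutter = wall_clutter(acq, scene)

    frame = clutter.astype(_DTYPE).copy()

    if force_kind is None:
        has_event = rng.uniform() < scene.event_prob
        kind = KIND_EMPTY
        if has_event:
            kind = KIND_CLUSTER if rng.uniform() < scene.cluster_frac else KIND_INDIVIDUAL
    else:
        kind = force_kind

    truth = FrameTruth()
    if kind != KIND_EMPTY:
        e_lo, e_hi = scene.element_span(acq)
        d_lo, d_hi = scene.tunnel_depth_span
        element = int(rng.integers(e_lo, e_hi))
        depth_pos = rng.uniform(d_lo, d_hi)
        t0 = depth_pos / acq.fs
        amp = _draw_amp(echo, rng)
        wave = bubble_echo(
            acq.t_axis, t0, amp, echo, acq, is_cluster=(kind == KIND_CLUSTER)
        ).astype(_DTYPE)
        reach = 3  # lateral extent of the point-spread [elements]
        for e in range(max(element - reach, 0), min(element + reach + 1, acq.n_elements)):
            gain = np.exp(-((e - element) ** 2) / (2.0 * scene.lateral_sigma**2))
            frame[e, :] += _DTYPE(gain) * wave
        truth = FrameTruth(kind=kind, element=element, depth_sample=int(depth_pos))

    if scene.noise_sd > 0:
        frame += rng.normal(0.0, scene.noise_sd, size=frame.shape).astype(_DTYPE)

    return RFFrame(samples=frame, frame_index=frame_index, truth=truth)


def simulate_dataset(
    acq: AcquisitionSpec,
    scene: SceneSpec,
    echo: EchoSpec,
) -> tuple[list[RFFrame], pd.DataFrame]:
    """Simulate ``scene.n_frames`` frames from one clutter realisation.

    Returns the frame list and a truth table with one row per frame
    (frame_index, kind, element, depth_sample).  Fully determined by the specs
    and ``scene.seed``.
    """
    scene.validate_against(acq)
    rng = np.random.default_rng(scene.seed)
    clutter = wall_clutter(acq, scene)
    frames: list[RFFrame] = []
    rows = []
    for i in range(scene.n_frames):
        fr = simulate_frame(acq, scene, echo, rng, clutter=clutter, frame_index=i)
        frames.append(fr)
        t = fr.truth
        rows.append(
            {
                "frame_index": i,
                "kind": t.kind,
                "element": -1 if t.element is None else t.element,
                "depth_sample": -1 if t.depth_sample is None else t.depth_sample,
            }
        )
    truth = pd.DataFrame(rows, columns=["frame_index", "kind", "element", "depth_sample"])
    return frames, truth


def control_scene(scene: SceneSpec, seed: Optional[int] = None) -> SceneSpec:
    """Copy of ``scene`` with no clusters (negative-control sample)."""
    return replace(scene, cluster_frac=0.0, seed=scene.seed if seed is None else seed)
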