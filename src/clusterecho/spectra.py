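"""Frequency-domain comparison of detected groups.

Magnitude spectra of the 160-sample RF segments (one-sided DFT, no window),
mean band amplitudes around the fundamental f0 and the subharmonic f0/2,
group mean spectra with area under the curve, per-vector
subharmonic-versus-fundamental scatter points, and ordinary least-squares
fits of those scatters.  Spectra are computed on the unnormalized RF values so
amplitudes keep their physical ordering: clustered-agent echoes carry more
energy in both bands, and their scatter shows a steeper subharmonic/
fundamental slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import RFVector, VECTOR_LEN

__all__ = [
    "BandSpec",
    "SpectralFeatures",
    "FitResult",
    "GroupComparison",
    "fundamental_band",
    "subharmonic_band",
    "magnitude_spectrum",
    "band_amplitude",
    "group_mean_spectrum",
    "scatter_points",
    "linear_fit",
    "compare_groups",
]

N_BINS = VECTOR_LEN // 2 + 1

VectorsLike = Union[np.ndarray, Sequence[RFVector], Sequence[np.ndarray]]


@dataclass(frozen=True)
class BandSpec:
    """A frequency band: bins with |freq - center| <= half_width are included."""

    center: float
    half_width: float

    def __post_init__(self) -> None:
        if self.center - self.half_width <= 0:
            raise ValueError("band must lie strictly above 0 Hz")
        if self.half_width < 0:
            raise ValueError("half_width must be nonnegative")

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        return np.abs(np.asarray(freqs) - self.center) <= self.half_width


def fundamental_band(f0: float, frac: float = 0.15) -> BandSpec:
    """Band centred at the transmit fundamental, half-width ``frac * f0``."""
    return BandSpec(center=f0, half_width=frac * f0)


def subharmonic_band(f0: float, frac: float = 0.15) -> BandSpec:
    """Band centred at the subharmonic f0/2, half-width ``frac * f0``."""
    return BandSpec(center=f0 / 2.0, half_width=frac * f0)


@dataclass
class SpectralFeatures:
    """One-sided magnitude spectrum with band summaries for a vector or group."""

    freqs: np.ndarray
    magnitude: np.ndarray
    fund_amp: float
    sub_amp: float
    group: str = ""
    auc: Optional[float] = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.magnitude = np.asarray(self.magnitude, dtype=np.float64)
        if self.freqs.shape != self.magnitude.shape or self.freqs.size != N_BINS:
            raise ValueError(f"freqs and magnitude must both have {N_BINS} bins")
        if self.fund_amp < 0 or self.sub_amp < 0:
            raise ValueError("band amplitudes must be nonnegative")


@dataclass(frozen=True)
class FitResult:
    """Ordinary least-squares line through (fundamental, subharmonic) points."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")


def _to_matrix(vectors: VectorsLike) -> np.ndarray:
    if isinstance(vectors, np.ndarray):
        mat = np.atleast_2d(np.asarray(vectors, dtype=np.float64))
    else:
        rows = [v.values if isinstance(v, RFVector) else np.asarray(v) for v in vectors]
        if len(rows) == 0:
            return np.empty((0, VECTOR_LEN))
        mat = np.stack(rows).astype(np.float64)
    if mat.shape[-1] != VECTOR_LEN:
        raise ValueError(f"vectors must have length {VECTOR_LEN}")
    return mat


def magnitude_spectrum(vector: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided DFT magnitude of a 160-sample segment (no window).

    Returns (freqs, magnitude) on bins ``k * fs / 160`` for k = 0..80.
    """
    vector = np.asarray(vector, dtype=np.float64)
    if vector.shape != (VECTOR_LEN,):
        raise ValueError(f"vector must have length {VECTOR_LEN}")
    if fs <= 0:
        raise ValueError("fs must be positive")
    freqs = np.fft.rfftfreq(VECTOR_LEN, d=1.0 / fs)
    magnitude = np.abs(np.fft.rfft(vector))
    return freqs, magnitude


def band_amplitude(
    freqs: np.ndarray,
    magnitude: np.ndarray,
    band: BandSpec,
    stat: str = "mean",
) -> float:
    """Mean (or max) magnitude over the DFT bins inside the band."""
    freqs = np.asarray(freqs, dtype=np.float64)
    magnitude = np.asarray(magnitude, dtype=np.float64)
    mask = band.mask(freqs)
    if not mask.any():
        raise ValueError(f"band {band} contains no DFT bin")
    if stat == "mean":
        return float(np.mean(magnitude[mask]))
    if stat == "max":
        return float(np.max(magnitude[mask]))
    raise ValueError("stat must be 'mean' or 'max'")


def _spectra_matrix(mat: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    freqs = np.fft.rfftfreq(VECTOR_LEN, d=1.0 / fs)
    return freqs, np.abs(np.fft.rfft(mat, axis=1))


def group_mean_spectrum(
    vectors: VectorsLike,
    fs: float,
    fund_band: Optional[BandSpec] = None,
    sub_band: Optional[BandSpec] = None,
    f0: Optional[float] = None,
    group: str = "",
    band_stat: str = "mean",
) -> SpectralFeatures:
    """Bin-wise mean of the member magnitude spectra of one group.

    Band amplitudes are evaluated on the mean spectrum; ``auc`` is its
    trapezoidal area over frequency.  Bands default to the fundamental and
    subharmonic bands of ``f0`` (required if bands are not given).
    """
    mat = _to_matrix(vectors)
    if mat.shape[0] == 0:
        raise ValueError("group is empty")
    if fund_band is None or sub_band is None:
        if f0 is None:
            raise ValueError("either both bands or f0 must be supplied")
        fund_band = fund_band or fundamental_band(f0)
        sub_band = sub_band or subharmonic_band(f0)
    freqs, mags = _spectra_matrix(mat, fs)
    mean_mag = mags.mean(axis=0)
    return SpectralFeatures(
        freqs=freqs,
        magnitude=mean_mag,
        fund_amp=band_amplitude(freqs, mean_mag, fund_band, stat=band_stat),
        sub_amp=band_amplitude(freqs, mean_mag, sub_band, stat=band_stat),
        group=group,
        auc=float(np.trapezoid(mean_mag, freqs)),
    )


def scatter_points(
    groups: Mapping[str, VectorsLike],
    fs: float,
    fund_band: BandSpec,
    sub_band: BandSpec,
    band_stat: str = "mean",
) -> pd.DataFrame:
    """Per-vector (fund_amp, sub_amp) points for every labelled group."""
    rows = []
    for name, vectors in groups.items():
        mat = _to_matrix(vectors)
        if mat.shape[0] == 0:
            raise ValueError(f"group {name!r} is empty")
        freqs, mags = _spectra_matrix(mat, fs)
        for m in mags:
            rows.append(
                {
                    "group": name,
                    "fund_amp": band_amplitude(freqs, m, fund_band, stat=band_stat),
                    "sub_amp": band_amplitude(freqs, m, sub_band, stat=band_stat),
                }
            )
    return pd.DataFrame(rows, columns=["group", "fund_amp", "sub_amp"])


def linear_fit(x: np.ndarray, y: Optional[np.ndarray] = None) -> FitResult:
    """OLS fit of subharmonic on fundamental amplitude (y on x).

    Accepts either ``(x, y)`` arrays or a single (n, 2) point array.
    """
    if y is None:
        pts = np.asarray(x, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array when y is omitted")
        x, y = pts[:, 0], pts[:, 1]
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct x values for a linear fit")
    res = stats.linregress(x, y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r_squared = 1.0  # constant y is fit exactly by the horizontal line
    else:
        resid = y - (res.slope * x + res.intercept)
        r_squared = float(min(max(1.0 - np.sum(resid**2) / ss_tot, 0.0), 1.0))
    return FitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r_squared,
    )


@dataclass
class GroupComparison:
    """Per-group spectral statistics and the anomaly-slope comparison."""

    mean_spectra: dict[str, SpectralFeatures]
    mean_fund_amp: dict[str, float]
    mean_sub_amp: dict[str, float]
    auc: dict[str, float]
    fits: dict[str, FitResult]
    scatter: pd.DataFrame
    slope_margin: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.mean_spectra:
            fit = self.fits.get(g)
            rows.append(
                {
                    "group": g,
                    "mean_fund_amp": self.mean_fund_amp[g],
                    "mean_sub_amp": self.mean_sub_amp[g],
                    "auc": self.auc[g],
                    "slope": fit.slope if fit else np.nan,
                    "intercept": fit.intercept if fit else np.nan,
                    "r_squared": fit.r_squared if fit else np.nan,
                }
            )
        return pd.DataFrame(rows)


REQUIRED_GROUPS = ("train", "test_anomaly", "test_nonanomaly")


def compare_groups(
    groups: Mapping[str, VectorsLike],
    fs: float,
    f0: float,
    band_frac: float = 0.15,
    band_stat: str = "mean",
) -> GroupComparison:
    """Spectral comparison across labelled groups.

    Requires at least the train, test_anomaly and test_nonanomaly groups (a
    control group is optional).  For each group: per-vector band amplitudes
    (averaged), the mean spectrum with its area under the curve, and the OLS
    fit of subharmonic on fundamental amplitude; ``slope_margin`` records the
    anomaly group's slope minus each other group's slope.
    """
    missing = [g for g in REQUIRED_GROUPS if g not in groups]
    if missing:
        raise ValueError(f"missing required groups: {missing}")
    fund = fundamental_band(f0, band_frac)
    sub = subharmonic_band(f0, band_frac)
    scatter = scatter_points(groups, fs, fund, sub, band_stat=band_stat)
    mean_spectra, fits = {}, {}
    mean_fund, mean_sub, auc = {}, {}, {}
    for name, vectors in groups.items():
        feats = group_mean_spectrum(
            vectors, fs, fund_band=fund, sub_band=sub, group=name, band_stat=band_stat
        )
        mean_spectra[name] = feats
        auc[name] = feats.auc
        pts = scatter[scatter["group"] == name]
        mean_fund[name] = float(pts["fund_amp"].mean())
        mean_sub[name] = float(pts["sub_amp"].mean())
        try:
            fits[name] = linear_fit(pts["fund_amp"].to_numpy(), pts["sub_amp"].to_numpy())
        except ValueError:
            pass  # degenerate group (e.g. a single point): no fit reported
    slope_margin = {}
    if "test_anomaly" in fits:
        for name, fit in fits.items():
            if name != "test_anomaly":
                slope_margin[name] = fits["test_anomaly"].slope - fit.slope
    return GroupComparison(
        mean_spectra=mean_spectra,
        mean_fund_amp=mean_fund,
        mean_sub_amp=mean_sub,
        auc=auc,
        fits=fits,
        scatter=scatter,
        slope_margin=slope_margin,
    )
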