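"""Application pipelines: R-R synchronization profiling and sleep separation.

Pipeline (a): two R-R interval trials (heart-beat intervals resampled on a
uniform 0.25 s grid and high-pass filtered at 0.1 Hz) are paired at a range
of relative time lags; the proposed-scheme multivariate SE computed at each
lag forms a synchronization profile whose minima mark lags at which the two
trials' regularity dynamics coincide, and whose spectrum reveals the
periodicity of that synchronization (e.g. 1/60 Hz for a paced-breathing
protocol alternating every 30 s).

Pipeline (b): a 2-channel recording is cut into fixed-length overlapping
segments with per-time state labels, artifact segments (any sample beyond
±100 µV) are rejected, the multivariate SE is computed per segment, and the
wake vs slow-wave-sleep separation of the per-segment SE distributions is
summarized by the Bhattacharyya distance — once per extension scheme.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline

from .multivariate import MvParams, _as_channels, mv_sample_entropy
from .surrogates import bhattacharyya_distance

__all__ = [
    "RRSeries",
    "LagProfile",
    "LabelledSegments",
    "GaussianSeparation",
    "rr_from_peaks",
    "highpass",
    "lagged_mse_profile",
    "dominant_sync_frequency",
    "segment_overlap",
    "artifact_reject",
    "sleep_separation",
]


@dataclass
class RRSeries:
    """R-R intervals (seconds) resampled on a uniform grid."""

    values: np.ndarray
    dt: float = 0.25
    t_start: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.t_start + self.dt * np.arange(self.values.size)


@dataclass
class LagProfile:
    """Multivariate-SE synchronization profile over signed lags (seconds)."""

    lags: np.ndarray
    mse: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.mse = np.asarray(self.mse, dtype=float)
        steps = np.diff(self.lags)
        if self.lags.size >= 2 and not np.allclose(steps, steps[0]):
            raise ValueError("lag grid must be uniformly spaced")

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0])

    def spectrum(self) -> tuple[np.ndarray, np.ndarray]:
        """(frequency Hz, magnitude) of the mean-removed profile.

        Lags whose entropy is undefined contribute zero after mean removal.
        """
        y = self.mse.copy()
        finite = np.isfinite(y)
        y[~finite] = y[finite].mean()
        y -= y.mean()
        freqs = np.fft.rfftfreq(y.size, d=self.dt)
        mag = np.abs(np.fft.rfft(y))
        return freqs, mag

    def min_lag(self, smooth_seconds: float = 0.0) -> float:
        """Lag (seconds) of the minimum entropy, ignoring undefined lags.

        With ``smooth_seconds > 0`` the profile is first smoothed by a
        centered moving average of half-width ``smooth_seconds``; the
        entropy minimum sits in a basin whose per-step slope is small
        relative to the estimator noise, so a modest smoothing (around 2 s
        for the paced-breathing protocol) locates the vertex far more
        reliably than the raw argmin.  The smoothed search is restricted to
        lags with a full smoothing window.
        """
        if smooth_seconds <= 0:
            return float(self.lags[np.nanargmin(self.mse)])
        half = int(round(smooth_seconds / self.dt))
        w = 2 * half + 1
        if w >= self.mse.size:
            raise ValueError("smoothing window exceeds the lag grid")
        y = self.mse.copy()
        finite = np.isfinite(y)
        y[~finite] = y[finite].mean()
        smoothed = np.convolve(y, np.ones(w) / w, mode="same")
        valid = slice(half, self.mse.size - half)
        return float(self.lags[valid][np.argmin(smoothed[valid])])


@dataclass
class LabelledSegments:
    """Fixed-length 2-channel windows with state labels and artifact flags."""

    segments: np.ndarray  # (n_seg, seg_len, P)
    labels: np.ndarray  # str per segment
    rejected: np.ndarray = field(default=None)
    sample_interval: float = 1.0

    def __post_init__(self) -> None:
        if self.rejected is None:
            self.rejected = np.zeros(len(self.labels), dtype=bool)


@dataclass
class GaussianSeparation:
    """Bhattacharyya separation between two Gaussian-summarized groups."""

    mu_a: float
    sd_a: float
    mu_b: float
    sd_b: float
    distance: float
    n_a: int
    n_b: int


def rr_from_peaks(peak_times, dt: float = 0.25) -> RRSeries:
    """R-R interval series from R-peak times via cubic-spline resampling.

    Successive peak-time differences are attached at the time of the later
    peak and interpolated onto a uniform ``dt`` grid spanning the interval
    times.
    """
    t = np.asarray(peak_times, dtype=float).ravel()
    if t.size < 4:
        raise ValueError("need at least four peak times")
    if np.any(np.diff(t) <= 0):
        raise ValueError("peak times must be strictly increasing")
    rr = np.diff(t)
    rr_times = t[1:]
    spline = CubicSpline(rr_times, rr)
    n_grid = int(np.floor((rr_times[-1] - rr_times[0]) / dt)) + 1
    grid = rr_times[0] + dt * np.arange(n_grid)
    return RRSeries(values=spline(grid), dt=dt, t_start=float(rr_times[0]))


def highpass(x, fs: float, cutoff: float = 0.1, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth high-pass filter (forward-backward)."""
    x = np.asarray(x, dtype=float).ravel()
    if cutoff >= fs / 2.0:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = signal.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def lagged_mse_profile(
    trial1,
    trial2,
    fs: float,
    max_lag: float,
    params: MvParams | None = None,
    min_overlap: float = 0.5,
) -> LagProfile:
    """Proposed-scheme multivariate SE of two trials over a grid of lags.

    At lag L the bivariate series pairs ``trial1[t]`` with ``trial2[t + L]``
    over their overlapping region (truncated, not wrapped); each channel is
    standardized before the entropy computation.  Lags whose overlap is
    shorter than ``min_overlap`` of the trial length are skipped (nan, with
    a warning).  The lag grid has one point per sample interval.
    """
    if params is None:
        params = MvParams(M=(1, 1), tau=(1, 1), r=0.4, scheme="proposed")
    a = np.asarray(trial1, dtype=float).ravel()
    b = np.asarray(trial2, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("trials must have equal length")
    n = a.size
    max_shift = int(round(max_lag * fs))
    shifts = np.arange(-max_shift, max_shift + 1)
    min_n = int(np.ceil(min_overlap * n))
    values = np.full(shifts.size, np.nan)
    for j, s in enumerate(shifts):
        if s >= 0:
            x1, x2 = a[: n - s], b[s:]
        else:
            x1, x2 = a[-s:], b[: n + s]
        if x1.size < min_n:
            warnings.warn(f"lag {s / fs:g} s skipped: overlap too short", stacklevel=2)
            continue
        values[j] = mv_sample_entropy(
            np.column_stack([x1, x2]),
            M=params.M,
            tau=params.tau,
            r=params.r,
            scheme=params.scheme,
        )
    return LagProfile(lags=shifts / fs, mse=values)


def dominant_sync_frequency(profile: LagProfile, prominence: float = 4.0):
    """Frequency (Hz) of the dominant peak of the profile spectrum.

    The zero bin is excluded; returns ``None`` when the peak magnitude is
    below ``prominence`` times the median non-zero-bin magnitude (no clear
    synchronization periodicity).  The default factor of 4 sits well above
    the typical maximum of a structureless profile — for ~10²-bin spectra
    of white noise the largest Rayleigh-distributed magnitude is usually
    only ~2.5-3x the median — while genuine periodicities exceed it by a
    wide margin.
    """
    if profile.lags.size < 16:
        raise ValueError("need at least 16 lag points for spectral analysis")
    freqs, mag = profile.spectrum()
    peak = 1 + int(np.argmax(mag[1:]))
    if mag[peak] < prominence * np.median(mag[1:]):
        return None
    return float(freqs[peak])


def _majority_label(window_labels: np.ndarray) -> str:
    counts = Counter(window_labels.tolist())
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return "other"
    return ranked[0][0]


def segment_overlap(
    X,
    labels,
    fs: float,
    seg_len: float = 2.5,
    overlap: float = 0.5,
) -> LabelledSegments:
    """Cut a labelled multichannel series into fixed overlapping windows.

    ``labels`` is a per-sample annotation track; each window receives the
    majority label within it (an exact tie maps to "other").
    """
    data = _as_channels(X)
    labels = np.asarray(labels)
    if labels.shape[0] != data.shape[0]:
        raise ValueError("labels must have one entry per sample")
    win = seg_len * fs
    if not np.isclose(win, round(win)):
        raise ValueError(
            "segment length must be an integer number of samples; adjust fs or seg_len"
        )
    win = int(round(win))
    hop = int(round(win * (1.0 - overlap)))
    if hop < 1:
        raise ValueError("overlap too large: hop would be < 1 sample")
    n_seg = (data.shape[0] - win) // hop + 1
    if n_seg < 1:
        raise ValueError("series shorter than one segment")
    segs = np.stack([data[j * hop : j * hop + win] for j in range(n_seg)])
    seg_labels = np.array(
        [_majority_label(labels[j * hop : j * hop + win]) for j in range(n_seg)]
    )
    return LabelledSegments(
        segments=segs, labels=seg_labels, sample_interval=1.0 / fs
    )


def artifact_reject(segs: LabelledSegments, thresh: float = 100.0) -> LabelledSegments:
    """Flag segments with any sample beyond ±thresh (µV) in any channel."""
    rejected = np.abs(segs.segments).max(axis=(1, 2)) > thresh
    return LabelledSegments(
        segments=segs.segments,
        labels=segs.labels,
        rejected=rejected,
        sample_interval=segs.sample_interval,
    )


def sleep_separation(
    segs: LabelledSegments,
    params: MvParams | None = None,
    schemes: tuple[str, ...] = ("full", "proposed"),
    label_a: str = "wake",
    label_b: str = "sws",
) -> dict[str, GaussianSeparation]:
    """Bhattacharyya separation of per-segment multivariate SE by state.

    Each non-rejected segment is standardized per channel and its
    multivariate SE computed (default M=[1,1], tau=[1,1], r=0.4) for every
    requested extension scheme; the wake and slow-wave-sleep SE
    distributions are then summarized by mean/SD and their Bhattacharyya
    distance.  Undefined per-segment entropies are dropped.
    """
    if params is None:
        params = MvParams(M=(1, 1), tau=(1, 1), r=0.4)
    keep = ~segs.rejected
    results: dict[str, GaussianSeparation] = {}
    for scheme in schemes:
        groups = {}
        for label in (label_a, label_b):
            mask = keep & (segs.labels == label)
            if mask.sum() < 2:
                raise ValueError(f"fewer than two usable segments labelled {label!r}")
            vals = np.array(
                [
                    mv_sample_entropy(
                        seg, M=params.M, tau=params.tau, r=params.r, scheme=scheme
                    )
                    for seg in segs.segments[mask]
                ]
            )
            vals = vals[np.isfinite(vals)]
            if vals.size < 2:
                raise ValueError(
                    f"fewer than two defined entropies for label {label!r}"
                )
            groups[label] = vals
        a, b = groups[label_a], groups[label_b]
        results[scheme] = GaussianSeparation(
            mu_a=float(a.mean()),
            sd_a=float(a.std(ddof=1)),
            mu_b=float(b.mean()),
            sd_b=float(b.std(ddof=1)),
            distance=bhattacharyya_distance(a.mean(), a.std(ddof=1), b.mean(), b.std(ddof=1)),
            n_a=a.size,
            n_b=b.size,
        )
    return results
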