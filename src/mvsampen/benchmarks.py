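"""Seeded generators for the synthetic benchmark signals.

Four signal families are provided:

* correlated bivariate white Gaussian noise (WGN), for the correlation
  benchmarks and surrogate tests;
* power-law (1/f-family) noise with spectral decay exponent beta
  (0 = white, −1 = pink, −2 = Brownian), synthesized by FFT amplitude
  shaping of Gaussian noise;
* the synchronized-regularity mixing model: two channels generated by
  mutually independent processes whose *within-channel regularity* (white
  vs 1/f content) switches at times governed by a binary mixing parameter —
  shared across channels (synchronized) or drawn independently.  No
  correlation, phase or generalized synchrony exists between the channels
  in either case;
* an alternating-regularity two-trial protocol emulating a paced-breathing
  experiment: blocks of strongly sinusoidally modulated, low-entropy signal
  (a 0.25 Hz oscillation, 15 cycles/min, plus 20% white noise) alternate
  with broadband high-entropy blocks; the second trial starts in the
  opposite block phase and is delayed by a configurable lag.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import standardize
from .multivariate import MultiSeries

__all__ = [
    "MixingModelParams",
    "ProtocolParams",
    "gen_correlated_wgn",
    "gen_power_law_noise",
    "gen_mixing_parameter",
    "gen_regularity_pair",
    "gen_alternating_protocol",
    "gen_sleep_like_recording",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class MixingModelParams:
    """Parameters of the synchronized-regularity mixing model.

    n_samples : series length N (>= 100).
    beta : spectral decay exponent of the noise driving the mixing
        parameter (0 white, −1 pink, −2 Brownian); must be <= 0.
    synchronized : share one mixing sequence across both channels (True)
        or draw two independent ones with the same beta (False).
    seed : RNG seed.
    """

    n_samples: int = 15000
    beta: float = -1.6
    synchronized: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 100:
            raise ValueError("n_samples must be >= 100")
        if self.beta > 0:
            raise ValueError("beta must be <= 0")


@dataclass(frozen=True)
class ProtocolParams:
    """Parameters of the alternating-regularity two-trial protocol.

    duration : trial length in seconds (>= 4 block periods).
    block_period : seconds per regularity block (default 30).
    sample_rate : Hz (default 4, the R-R interval resampling rate).
    lag : delay in seconds applied to the second trial.
    seed : RNG seed.
    """

    duration: float = 300.0
    block_period: float = 30.0
    sample_rate: float = 4.0
    lag: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.block_period <= 0:
            raise ValueError("block_period must be positive")
        if self.duration < 4 * self.block_period:
            raise ValueError("duration must cover at least four block periods")


def gen_correlated_wgn(n: int, rho: float, seed=None) -> MultiSeries:
    """Bivariate WGN with population cross-correlation ``rho``.

    Channels are zero-mean unit-variance Gaussian; the second channel is
    rho·z1 + sqrt(1−rho²)·z2 (the Cholesky factor of [[1, rho], [rho, 1]]).
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    rng = _rng(seed)
    z = rng.standard_normal((int(n), 2))
    x2 = rho * z[:, 0] + np.sqrt(1.0 - rho * rho) * z[:, 1]
    return MultiSeries(np.column_stack([z[:, 0], x2]))


def gen_power_law_noise(n: int, beta: float, seed=None) -> np.ndarray:
    """Gaussian noise with power spectral density ∝ f**beta, standardized.

    Synthesized by shaping the rFFT of complex Gaussian noise with
    amplitude f**(beta/2) and zero DC component, then scaling to zero mean
    and unit population variance.
    """
    n = int(n)
    if n < 16:
        raise ValueError("n must be >= 16")
    if beta > 0:
        raise ValueError("beta must be <= 0")
    rng = _rng(seed)
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (beta / 2.0)
    spec = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n)
    return standardize(x)


def gen_mixing_parameter(n: int, beta: float, seed=None) -> np.ndarray:
    """Binary mixing sequence: 1 where power-law noise is positive, else 0."""
    z = gen_power_law_noise(n, beta, seed)
    return (z > 0).astype(int)


def gen_regularity_pair(params: MixingModelParams) -> MultiSeries:
    """Bivariate signal with (optionally synchronized) regularity dynamics.

    Each channel is sqrt(λ)·v + sqrt(1−λ)·u with v unit-variance WGN and u
    unit-variance 1/f noise, all four component processes mutually
    independent.  With ``synchronized=True`` one mixing sequence λ drives
    both channels, so the white/structured switching happens at the same
    times in each channel; otherwise each channel gets its own λ.  The
    mixed channels are standardized once more for entropy analysis.
    """
    rng = _rng(params.seed)
    n = params.n_samples
    lam1 = gen_mixing_parameter(n, params.beta, rng)
    lam2 = lam1 if params.synchronized else gen_mixing_parameter(n, params.beta, rng)
    channels = []
    for lam in (lam1, lam2):
        v = rng.standard_normal(n)
        u = gen_power_law_noise(n, -1.0, rng)
        x = np.sqrt(lam) * v + np.sqrt(1.0 - lam) * u
        channels.append(standardize(x))
    return MultiSeries(np.column_stack(channels))


def _block_types(n: int, block_len: int, start_low: bool, shift: int) -> np.ndarray:
    """Per-sample block type (True = low-entropy block) with a sample shift."""
    i = np.arange(n) - shift
    phase = np.floor_divide(i, block_len) % 2
    low = phase == 0
    return low if start_low else ~low


def gen_alternating_protocol(params: ProtocolParams):
    """Two single-channel trials with alternating within-trial regularity.

    Trial 1 starts with a low-entropy block (0.25 Hz sinusoid + 20% WGN);
    blocks alternate with high-entropy WGN blocks every ``block_period``
    seconds.  Trial 2 starts in the opposite block phase and its block
    pattern is delayed by ``lag`` seconds.  The trials share no amplitude
    coupling: all noise and the two sinusoid phases are independent.

    Returns ``(trial1, trial2, expected_min_lag)`` where the trials are 1-D
    arrays and ``expected_min_lag = lag + block_period`` is the ground-truth
    lag (seconds) at which a lagged multivariate-SE profile attains its
    minimum.  The regularity patterns coincide at every lag congruent to
    ``lag + block_period`` modulo twice the block period; among those, the
    profile minimum falls at ``lag + block_period`` because that alignment
    maximizes the proportion of paired low-entropy samples in the
    (truncated) overlap when trial 1 starts in a low-entropy block.
    """
    rng = _rng(params.seed)
    fs = params.sample_rate
    n = int(round(params.duration * fs))
    block_len = int(round(params.block_period * fs))
    if not np.isclose(block_len, params.block_period * fs):
        raise ValueError("block_period must be an integer number of samples")
    lag_samples = int(round(params.lag * fs))
    t = np.arange(n) / fs

    def make_trial(start_low: bool, shift: int) -> np.ndarray:
        low = _block_types(n, block_len, start_low, shift)
        sine = np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
        trial = np.where(
            low,
            sine + 0.2 * rng.standard_normal(n),
            rng.standard_normal(n),
        )
        return trial

    trial1 = make_trial(True, 0)
    trial2 = make_trial(False, lag_samples)
    expected = params.lag + params.block_period
    return trial1, trial2, float(expected)


def gen_sleep_like_recording(
    duration: float = 60.0,
    fs: float = 100.0,
    block_seconds: float = 10.0,
    seed=None,
    artifact_segments: int = 2,
):
    """Synthetic labelled 2-channel recording emulating wake/deep-sleep EEG.

    Wake blocks are independent broadband noise in the two channels
    (high entropy, ~20 µV SD); slow-wave-sleep blocks are dominated by a
    1/f-type source shared across channels plus small independent noise
    (low entropy, correlated, ~25 µV SD — comfortably inside the ±100 µV
    artifact threshold).  A few short >100 µV artifact
    bursts are injected so the rejection stage is exercised.  This is a
    synthetic stand-in for expert-annotated polysomnography excerpts: it
    reproduces the regularity/coupling contrast between states, not EEG
    morphology.

    Returns ``(MultiSeries in µV, per-sample label array of 'wake'/'sws')``.
    """
    rng = _rng(seed)
    n = int(round(duration * fs))
    block = int(round(block_seconds * fs))
    labels = np.where(_block_types(n, block, True, 0), "wake", "sws")
    data = np.empty((n, 2))
    wake = labels == "wake"
    n_wake = int(wake.sum())
    data[wake, 0] = 20.0 * rng.standard_normal(n_wake)
    data[wake, 1] = 20.0 * rng.standard_normal(n_wake)
    n_sws = n - n_wake
    shared = gen_power_law_noise(max(n_sws, 16), -1.0, rng)[:n_sws]
    data[~wake, 0] = 25.0 * (0.9 * shared + 0.44 * rng.standard_normal(n_sws))
    data[~wake, 1] = 25.0 * (0.9 * shared + 0.44 * rng.standard_normal(n_sws))
    for _ in range(artifact_segments):
        start = int(rng.integers(0, n - int(0.2 * fs)))
        data[start : start + int(0.2 * fs), int(rng.integers(0, 2))] += 150.0
    series = MultiSeries(data, sample_interval=1.0 / fs, channel_labels=["ch1", "ch2"])
    return series, labels
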