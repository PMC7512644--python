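"""Univariate sample entropy, standardization and multiscale coarse-graining.

Sample entropy (SE) quantifies the regularity of a time series as the
negative log conditional probability that delay-vector patterns similar at
embedding dimension ``m`` (within a Chebyshev-norm tolerance ``r``) remain
similar when the pattern length is increased to ``m + 1``, with self-matches
excluded.  A stochastic series has high SE; a regular one has low SE.

The multiscale extension (MSE) computes SE on coarse-grained versions of the
series — non-overlapping window means at scale factor ``eps`` — revealing
structure across time scales: SE of white noise decays with scale, while SE
of 1/f noise stays roughly constant (high complexity).

Conventions used throughout the package
---------------------------------------
* Standardization divides by the population standard deviation (``ddof=0``).
* Both dimensions ``m`` and ``m + 1`` are evaluated over the same delay-
  vector population ``i = 1 … N − m·tau``, so the match probability at the
  longer dimension can never exceed the one at the shorter dimension and
  SE >= 0 holds structurally.
* ``r`` is expressed in units of the standardized signal and is held fixed
  across scales; coarse-grained series are not re-standardized.
* When no pair matches at either dimension the entropy is undefined; the
  functions return ``nan`` and emit :class:`UndefinedEntropyWarning` rather
  than raising, so multiscale profiles degrade gracefully.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._matching import pair_match_fraction

__all__ = [
    "EntropyParams",
    "ScaleProfile",
    "UndefinedEntropyWarning",
    "standardize",
    "coarse_grain",
    "sample_entropy",
    "multiscale_entropy",
]


class UndefinedEntropyWarning(UserWarning):
    """Raised-as-warning when no template pair matches at some dimension."""


@dataclass(frozen=True)
class EntropyParams:
    """Univariate embedding parameters.

    m : embedding dimension (>= 1)
    tau : time lag in samples (>= 1; unity everywhere in the reference
        experiments)
    r : similarity threshold, in units of the standardized signal
    """

    m: int = 2
    tau: int = 1
    r: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.tau < 1:
            raise ValueError("lag tau must be >= 1")
        if self.r <= 0:
            raise ValueError("threshold r must be positive")


@dataclass
class ScaleProfile:
    """Entropy value per scale factor, optionally with replicate values."""

    scales: np.ndarray
    entropy: np.ndarray
    replicates: list[np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=int)
        self.entropy = np.asarray(self.entropy, dtype=float)
        if self.scales.ndim != 1 or self.scales.size == 0:
            raise ValueError("scales must be a non-empty 1-D sequence")
        if np.any(np.diff(self.scales) <= 0) or self.scales[0] != 1:
            raise ValueError("scales must be strictly increasing from 1")
        if self.entropy.shape != self.scales.shape:
            raise ValueError("entropy must have one value per scale")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"scale": self.scales, "entropy": self.entropy})


def _validate_series(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("series must contain at least two samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return x


def standardize(x) -> np.ndarray:
    """Scale to zero mean and unit population standard deviation."""
    x = _validate_series(x)
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize a zero-variance series")
    return (x - x.mean()) / sd


def coarse_grain(x, scale: int) -> np.ndarray:
    """Non-overlapping window means at the given scale factor.

    Output element j is the mean of samples (j−1)·scale+1 … j·scale;
    trailing samples that do not fill a window are dropped.
    """
    x = _validate_series(x)
    scale = int(scale)
    if scale < 1:
        raise ValueError("scale factor must be >= 1")
    n_out = x.size // scale
    if n_out < 2:
        raise ValueError("coarse-grained series would be shorter than 2 samples")
    if scale == 1:
        return x.copy()
    return x[: n_out * scale].reshape(n_out, scale).mean(axis=1)


def _embed(x: np.ndarray, m: int, tau: int, n_vectors: int) -> np.ndarray:
    idx = np.arange(n_vectors)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def sample_entropy(x, m: int = 2, tau: int = 1, r: float = 0.2) -> float:
    """Sample entropy −ln(Φ_{m+1}/Φ_m) with max-norm matching.

    Operates on the series as given (standardize first if ``r`` is meant as
    a fraction of the standard deviation, as in all reference experiments).
    Returns ``nan`` (with :class:`UndefinedEntropyWarning`) when no pair
    matches at either dimension.
    """
    p = EntropyParams(m=m, tau=tau, r=r)
    x = _validate_series(x)
    n_vectors = x.size - p.m * p.tau
    if n_vectors < 2:
        raise ValueError(
            f"series of length {x.size} too short for m={p.m}, tau={p.tau}"
        )
    phi_m = pair_match_fraction(_embed(x, p.m, p.tau, n_vectors), p.r)
    phi_m1 = pair_match_fraction(_embed(x, p.m + 1, p.tau, n_vectors), p.r)
    if phi_m == 0 or phi_m1 == 0:
        warnings.warn(
            "no matching template pairs; sample entropy undefined",
            UndefinedEntropyWarning,
            stacklevel=2,
        )
        return float("nan")
    return float(-np.log(phi_m1 / phi_m))


def multiscale_entropy(
    x, m: int = 2, tau: int = 1, r: float = 0.2, max_scale: int = 10
) -> ScaleProfile:
    """Multiscale sample entropy of a univariate series.

    The series is standardized once; each scale's value is the sample
    entropy of its coarse-grained version with ``r`` fixed in units of the
    original standard deviation.
    """
    if max_scale < 1:
        raise ValueError("max_scale must be >= 1")
    z = standardize(x)
    if z.size // max_scale - m * tau < 2:
        raise ValueError(
            f"series too short for max_scale={max_scale} with m={m}, tau={tau}"
        )
    scales = np.arange(1, max_scale + 1)
    values = np.array(
        [sample_entropy(coarse_grain(z, s), m=m, tau=tau, r=r) for s in scales]
    )
    return ScaleProfile(scales=scales, entropy=values)
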