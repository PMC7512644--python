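"""Random-alignment surrogates and the separation statistics.

A random-alignment surrogate destroys cross-channel timing while leaving
each channel's own statistics intact: every channel after the first is
circularly rotated by an independent uniform random offset in {1, …, N−1}.
Comparing the multivariate SE of the original signal with the surrogate
distribution isolates cross-channel coupling from within-channel structure.

Two separation statistics are provided: a pooled-variance two-tailed
two-sample t-test applied per scale factor (df = n_a + n_b − 2), and the
Bhattacharyya distance between Gaussian-summarized feature distributions,

    D = 1/4·ln(1/4·(σ_w²/σ_s² + σ_s²/σ_w² + 2)) + 1/4·(μ_s−μ_w)²/(σ_s²+σ_w²).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ScaleProfile
from .multivariate import _as_channels

__all__ = [
    "SurrogateEnsemble",
    "SeparationReport",
    "random_shift_surrogates",
    "scale_separation_ttest",
    "bhattacharyya_distance",
]


@dataclass
class SurrogateEnsemble:
    """Random-alignment surrogates of one multichannel series."""

    surrogates: list[np.ndarray]
    shifts: np.ndarray  # (n_surr, P-1) offsets applied to channels 2…P
    seed: int | None = None


@dataclass
class SeparationReport:
    """Per-scale two-sample t-test results between two replicate groups."""

    scales: np.ndarray
    mean_a: np.ndarray
    sd_a: np.ndarray
    mean_b: np.ndarray
    sd_b: np.ndarray
    t: np.ndarray
    df: np.ndarray
    p: np.ndarray
    alpha: float = 0.05
    significant: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.significant = self.p < self.alpha

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scale": self.scales,
                "mean_a": self.mean_a,
                "sd_a": self.sd_a,
                "mean_b": self.mean_b,
                "sd_b": self.sd_b,
                "t": self.t,
                "df": self.df,
                "p": self.p,
                "significant": self.significant,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def random_shift_surrogates(X, n_surr: int, seed=None) -> SurrogateEnsemble:
    """Circularly rotate channels 2…P by independent random offsets.

    Each surrogate keeps channel 1 untouched and applies an independent
    uniform offset in {1, …, N−1} to every further channel, preserving each
    channel's sample multiset exactly while destroying cross-channel
    alignment.
    """
    data = _as_channels(X)
    n, p = data.shape
    if p < 2:
        raise ValueError("need at least two channels to randomize alignment")
    if n < 10:
        raise ValueError("series too short for meaningful surrogates")
    if n_surr < 1:
        raise ValueError("n_surr must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shifts = rng.integers(1, n, size=(int(n_surr), p - 1))
    surrogates = []
    for row in shifts:
        surr = data.copy()
        for k, offset in enumerate(row, start=1):
            surr[:, k] = np.roll(data[:, k], int(offset))
        surrogates.append(surr)
    return SurrogateEnsemble(surrogates, shifts, None if isinstance(seed, np.random.Generator) else seed)


def _group_matrix(profiles: list[ScaleProfile]) -> tuple[np.ndarray, np.ndarray]:
    scales = profiles[0].scales
    for p in profiles[1:]:
        if not np.array_equal(p.scales, scales):
            raise ValueError("all profiles must share the same scale grid")
    return scales, np.vstack([p.entropy for p in profiles])


def scale_separation_ttest(
    profiles_a: list[ScaleProfile],
    profiles_b: list[ScaleProfile],
    alpha: float = 0.05,
) -> SeparationReport:
    """Pooled-variance two-tailed two-sample t-test at each scale factor.

    Undefined (nan) entropies are dropped per scale with the degrees of
    freedom adjusted; with 20 replicates per group the test has 38 df.
    """
    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise ValueError("need at least two replicate profiles per group")
    scales, mat_a = _group_matrix(profiles_a)
    scales_b, mat_b = _group_matrix(profiles_b)
    if not np.array_equal(scales, scales_b):
        raise ValueError("groups must share the same scale grid")

    out = {k: [] for k in ("mean_a", "sd_a", "mean_b", "sd_b", "t", "df", "p")}
    for j in range(scales.size):
        a = mat_a[:, j][np.isfinite(mat_a[:, j])]
        b = mat_b[:, j][np.isfinite(mat_b[:, j])]
        if a.size < mat_a.shape[0] or b.size < mat_b.shape[0]:
            warnings.warn(
                f"dropped undefined entropies at scale {scales[j]}", stacklevel=2
            )
        if a.size < 2 or b.size < 2:
            raise ValueError(f"fewer than two usable replicates at scale {scales[j]}")
        df = a.size + b.size - 2
        pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
        if pooled == 0:
            if np.isclose(a.mean(), b.mean()):
                warnings.warn(
                    f"zero pooled variance with equal means at scale {scales[j]}",
                    stacklevel=2,
                )
                tval, pval = 0.0, 1.0
            else:
                raise ValueError(
                    f"zero pooled variance with unequal means at scale {scales[j]}"
                )
        else:
            se = np.sqrt(pooled * (1.0 / a.size + 1.0 / b.size))
            tval = (a.mean() - b.mean()) / se
            pval = 2.0 * stats.t.sf(abs(tval), df)
        out["mean_a"].append(a.mean())
        out["sd_a"].append(a.std(ddof=1))
        out["mean_b"].append(b.mean())
        out["sd_b"].append(b.std(ddof=1))
        out["t"].append(tval)
        out["df"].append(df)
        out["p"].append(pval)

    return SeparationReport(
        scales=scales,
        mean_a=np.array(out["mean_a"]),
        sd_a=np.array(out["sd_a"]),
        mean_b=np.array(out["mean_b"]),
        sd_b=np.array(out["sd_b"]),
        t=np.array(out["t"]),
        df=np.array(out["df"], dtype=int),
        p=np.array(out["p"]),
        alpha=alpha,
    )


def bhattacharyya_distance(mu_w: float, sigma_w: float, mu_s: float, sigma_s: float) -> float:
    """Bhattacharyya distance between two Gaussian-summarized distributions."""
    if sigma_w <= 0 or sigma_s <= 0:
        raise ValueError("standard deviations must be positive")
    var_w, var_s = sigma_w**2, sigma_s**2
    term_var = 0.25 * np.log(0.25 * (var_w / var_s + var_s / var_w + 2.0))
    term_mean = 0.25 * (mu_s - mu_w) ** 2 / (var_s + var_w)
    return float(term_var + term_mean)
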