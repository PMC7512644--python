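"""Multivariate sample entropy with three delay-vector extension schemes.

Given a P-channel series, the un-extended multivariate delay vector (DV) at
time i concatenates per-channel embeddings,

    X_M(i) = [x_{1,i}, …, x_{1,i+(m_1−1)τ_1}, …, x_{P,i}, …, x_{P,i+(m_P−1)τ_P}],

and the multivariate SE is −ln(Φ_ext/Φ_unext), where Φ is a max-norm match
fraction and the schemes differ only in how the DVs are *extended* from
total dimension Σm_k to Σm_k + 1 (or + P):

``naive``
    P subspaces, each lengthening one channel by one lagged sample; match
    fractions are computed inside each subspace separately and averaged.
    Blind to cross-channel coupling.
``full``
    The same P subspaces, but distances are taken between *all* DVs across
    all subspaces (the pooled set).  Sensitive to correlation, but compares
    elements of different channels against each other, and interprets
    increasing correlation as *increasing* entropy.
``proposed``
    Every channel is lengthened simultaneously in one aligned vector,

        X^e_M(i) = [x_{1,i}, …, x_{1,i+m_1 τ_1}, …, x_{P,i}, …, x_{P,i+m_P τ_P}],

    so distances are only ever taken between elements of corresponding
    channels.  Correlation and synchronized regularity both *reduce* the
    entropy, consistently.

All schemes evaluate both the un-extended and extended sets over the same
index population i = 1 … N − max_k(m_k·τ_k), so every extended vector
exists and, for the proposed scheme, Φ_ext <= Φ_unext holds structurally
(the extended vector is a coordinate superset under the max norm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, special, stats

from ._matching import pair_match_fraction
from .core import ScaleProfile, UndefinedEntropyWarning, coarse_grain, standardize

__all__ = [
    "MultiSeries",
    "MvParams",
    "DelayVectorSet",
    "SCHEMES",
    "build_delay_vectors",
    "extend_naive",
    "extend_proposed",
    "match_fraction",
    "mv_sample_entropy",
    "mv_multiscale_entropy",
    "analytic_proposed_mse_wgn",
]

SCHEMES = ("naive", "full", "proposed")


@dataclass
class MultiSeries:
    """P-channel real time series with sampling metadata.

    data : (N, P) array, one column per channel, all values finite.
    sample_interval : seconds between samples (default 1).
    channel_labels : optional list of P strings.
    """

    data: np.ndarray
    sample_interval: float = 1.0
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (N, P) array")
        if self.data.shape[0] < 2:
            raise ValueError("need at least two samples per channel")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if self.channel_labels is not None and len(self.channel_labels) != self.data.shape[1]:
            raise ValueError("channel_labels length must equal the channel count")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class MvParams:
    """Multivariate embedding parameters.

    M, tau : per-channel embedding dimensions and lags (default all ones,
        matching the reference experiments).
    r : similarity threshold in standardized units.
    scheme : one of ``naive``, ``full``, ``proposed``.
    """

    M: tuple[int, ...] = (1, 1)
    tau: tuple[int, ...] = (1, 1)
    r: float = 0.15
    scheme: str = "proposed"

    def __post_init__(self) -> None:
        object.__setattr__(self, "M", tuple(int(m) for m in self.M))
        object.__setattr__(self, "tau", tuple(int(t) for t in self.tau))
        if len(self.M) != len(self.tau):
            raise ValueError("M and tau must have equal length")
        if any(m < 1 for m in self.M) or any(t < 1 for t in self.tau):
            raise ValueError("all embedding dimensions and lags must be >= 1")
        if self.r <= 0:
            raise ValueError("threshold r must be positive")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")


@dataclass
class DelayVectorSet:
    """Embedded delay vectors with index bookkeeping.

    vectors : (n, d) array of DVs.
    origins : time index i of each vector (0-based).
    subspace : per-vector extended-channel index for naive/full subspaces,
        or None for un-extended and proposed sets.
    dimension_tag : ``unextended`` or ``extended``.
    """

    vectors: np.ndarray
    origins: np.ndarray
    subspace: np.ndarray | None = None
    dimension_tag: str = "unextended"

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        self.origins = np.asarray(self.origins, dtype=int)
        if self.vectors.shape[0] != self.origins.shape[0]:
            raise ValueError("one origin index per vector required")


def _as_channels(X) -> np.ndarray:
    if isinstance(X, MultiSeries):
        return X.data
    a = np.asarray(X, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise ValueError("expected an (N, P) array or MultiSeries")
    return a


def _resolve_embedding(data: np.ndarray, M, tau):
    p = data.shape[1]
    M = tuple([1] * p) if M is None else tuple(int(m) for m in M)
    tau = tuple([1] * p) if tau is None else tuple(int(t) for t in tau)
    if len(M) != p or len(tau) != p:
        raise ValueError("M and tau must have one entry per channel")
    if any(m < 1 for m in M) or any(t < 1 for t in tau):
        raise ValueError("all embedding dimensions and lags must be >= 1")
    return M, tau


def _n_vectors(n_samples: int, M, tau) -> int:
    span = max(m * t for m, t in zip(M, tau))
    n = n_samples - span
    if n < 2:
        raise ValueError(
            f"series of length {n_samples} too short for embedding M={M}, tau={tau}"
        )
    return n


def _mv_embed(data: np.ndarray, M, tau, extend: tuple[int, ...] | None = None) -> np.ndarray:
    """Concatenated per-channel embeddings over the common index range.

    ``extend`` lists 0-based channel indices whose dimension is m_k + 1;
    the index range is always the one that admits every *fully extended*
    vector, i = 0 … N − max_k(m_k·τ_k) − 1.
    """
    n = _n_vectors(data.shape[0], M, tau)
    extend = extend or ()
    cols = []
    for k in range(data.shape[1]):
        mk = M[k] + (1 if k in extend else 0)
        idx = np.arange(n)[:, None] + tau[k] * np.arange(mk)[None, :]
        cols.append(data[idx, k])
    return np.concatenate(cols, axis=1)


def build_delay_vectors(X, M=None, tau=None) -> DelayVectorSet:
    """Un-extended multivariate delay vectors X_M(i)."""
    data = _as_channels(X)
    M, tau = _resolve_embedding(data, M, tau)
    vectors = _mv_embed(data, M, tau)
    return DelayVectorSet(vectors, np.arange(vectors.shape[0]), None, "unextended")


def extend_naive(X, M=None, tau=None, channel: int = 0) -> DelayVectorSet:
    """Subspace extension: lengthen only ``channel`` (0-based) by one sample."""
    data = _as_channels(X)
    M, tau = _resolve_embedding(data, M, tau)
    if not 0 <= channel < data.shape[1]:
        raise ValueError("channel index out of range")
    vectors = _mv_embed(data, M, tau, extend=(channel,))
    subspace = np.full(vectors.shape[0], channel, dtype=int)
    return DelayVectorSet(vectors, np.arange(vectors.shape[0]), subspace, "extended")


def extend_proposed(X, M=None, tau=None) -> DelayVectorSet:
    """Aligned extension: lengthen every channel simultaneously by one sample."""
    data = _as_channels(X)
    M, tau = _resolve_embedding(data, M, tau)
    vectors = _mv_embed(data, M, tau, extend=tuple(range(data.shape[1])))
    return DelayVectorSet(vectors, np.arange(vectors.shape[0]), None, "extended")


def match_fraction(dvs: DelayVectorSet | np.ndarray, r: float) -> float:
    """Fraction of unordered non-self DV pairs within ``r`` under the max norm.

    For a pooled (full-scheme) set, pass the vertically stacked subspaces:
    cross-subspace pairs — including those sharing an origin index — are
    counted; only literal self-pairs are excluded.
    """
    vectors = dvs.vectors if isinstance(dvs, DelayVectorSet) else np.asarray(dvs)
    return pair_match_fraction(vectors, r)


def _phi_pair(data: np.ndarray, M, tau, r: float, scheme: str) -> tuple[float, float]:
    phi_unext = match_fraction(_mv_embed(data, M, tau), r)
    p = data.shape[1]
    if scheme == "naive":
        phi_ext = float(
            np.mean([match_fraction(_mv_embed(data, M, tau, (k,)), r) for k in range(p)])
        )
    elif scheme == "full":
        pooled = np.vstack([_mv_embed(data, M, tau, (k,)) for k in range(p)])
        phi_ext = match_fraction(pooled, r)
    elif scheme == "proposed":
        phi_ext = match_fraction(_mv_embed(data, M, tau, tuple(range(p))), r)
    else:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    return phi_unext, phi_ext


def mv_sample_entropy(
    X,
    M=None,
    tau=None,
    r: float = 0.15,
    scheme: str = "proposed",
    standardize_channels: bool = True,
) -> float:
    """Multivariate sample entropy −ln(Φ_ext/Φ_unext).

    Channels are standardized internally (zero mean, unit population SD) by
    default, so ``r`` acts as a fraction of each channel's standard
    deviation.  Returns ``nan`` with :class:`UndefinedEntropyWarning` when
    either match fraction is zero.
    """
    if r <= 0:
        raise ValueError("threshold r must be positive")
    data = _as_channels(X)
    M, tau = _resolve_embedding(data, M, tau)
    if standardize_channels:
        data = np.column_stack([standardize(data[:, k]) for k in range(data.shape[1])])
    phi_unext, phi_ext = _phi_pair(data, M, tau, r, scheme)
    if phi_unext == 0 or phi_ext == 0:
        warnings.warn(
            "no matching delay-vector pairs; multivariate sample entropy undefined",
            UndefinedEntropyWarning,
            stacklevel=2,
        )
        return float("nan")
    return float(-np.log(phi_ext / phi_unext))


def mv_multiscale_entropy(
    X,
    M=None,
    tau=None,
    r: float = 0.15,
    scheme: str = "proposed",
    max_scale: int = 5,
) -> ScaleProfile:
    """Multivariate multiscale sample entropy.

    Each channel is standardized once; at every scale factor the channels
    are coarse-grained (non-overlapping window means) and the multivariate
    SE is computed with ``r`` fixed in units of the original per-channel
    standard deviation.
    """
    if max_scale < 1:
        raise ValueError("max_scale must be >= 1")
    data = _as_channels(X)
    M, tau = _resolve_embedding(data, M, tau)
    z = np.column_stack([standardize(data[:, k]) for k in range(data.shape[1])])
    scales = np.arange(1, max_scale + 1)
    values = []
    for s in scales:
        cg = np.column_stack([coarse_grain(z[:, k], s) for k in range(z.shape[1])])
        values.append(
            mv_sample_entropy(cg, M, tau, r=r, scheme=scheme, standardize_channels=False)
        )
    return ScaleProfile(scales=scales, entropy=np.asarray(values))


def analytic_proposed_mse_wgn(rho: float, r: float) -> float:
    """Closed-form proposed-scheme mSE for standardized bivariate WGN.

    For channels that are white in time with cross-correlation ``rho`` and
    M=[1,1], tau=[1,1], the match events of the two extra coordinates in the
    proposed extension are independent of those of the original pair, so the
    extended match probability factorizes as Φ_ext = Φ_unext² and

        mSE = −ln Φ_unext = −ln P(|D1| <= r, |D2| <= r),

    where (D1, D2) are the per-channel sample differences: zero-mean
    bivariate normal with variance 2 and correlation ``rho``.  The rectangle
    probability is evaluated by Gauss quadrature to <= 1e−8 absolute error.

    Special values: rho=0 gives −2·ln erf(r/2); |rho|=1 gives −ln erf(r/2).
    Negative ``rho`` is permitted as a symmetric extension of the model.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    if r <= 0:
        raise ValueError("threshold r must be positive")
    a = r / np.sqrt(2.0)  # rectangle half-width for standardized differences
    if abs(rho) == 1.0:
        return float(-np.log(special.erf(r / 2.0)))
    s = np.sqrt(1.0 - rho * rho)

    def integrand(x: float) -> float:
        lo = (-a - rho * x) / s
        hi = (a - rho * x) / s
        return stats.norm.pdf(x) * (stats.norm.cdf(hi) - stats.norm.cdf(lo))

    prob, _ = integrate.quad(integrand, -a, a, epsabs=1e-10, epsrel=1e-10, limit=200)
    return float(-np.log(prob))
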