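"""Complexity measures for acceleration time series.

Implements coarse-graining, sample entropy, the multiscale-entropy (MSE)
profile with its summary statistics (mean, SD, complexity index), and
permutation entropy from ordinal rank patterns.

Conventions
-----------
* Coarse-graining averages consecutive *non-overlapping* blocks, so the
  series at scale ``tau`` has ``floor(N / tau)`` points.
* Sample entropy uses Chebyshev distance, excludes self-matches, and
  compares the same ``N - m`` templates at lengths ``m`` and ``m + 1``.
* For the MSE profile the tolerance is ``r`` times the SD of the
  *original* (scale-1) series and is held fixed across scales.
* Ordinal patterns are rank vectors; ties are broken by temporal order
  (the earlier sample receives the lower rank).
* Permutation entropy is reported in bits (log base 2).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "MseParams",
    "PeParams",
    "coarse_grain",
    "sample_entropy",
    "mse_profile",
    "complexity_index",
    "mse_mean",
    "mse_sd",
    "ordinal_patterns",
    "ordinal_distribution",
    "permutation_entropy",
]


@dataclass(frozen=True)
class MseParams:
    """Parameters of the multiscale-entropy profile.

    Attributes
    ----------
    m : int
        Template length for sample entropy (>= 1).
    r : float
        Tolerance as a fraction of the scale-1 series SD (> 0).
    tau_max : int
        Largest coarse-graining scale (>= 1).
    """

    m: int = 2
    r: float = 0.15
    tau_max: int = 5

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"template length m must be >= 1, got {self.m}")
        if self.r <= 0:
            raise ValueError(f"tolerance fraction r must be > 0, got {self.r}")
        if self.tau_max < 1:
            raise ValueError(f"tau_max must be >= 1, got {self.tau_max}")


@dataclass(frozen=True)
class PeParams:
    """Parameters of the ordinal-pattern embedding.

    Attributes
    ----------
    order : int
        Embedding dimension (window length, >= 2).
    delay : int
        Embedding delay in samples (>= 1).
    """

    order: int = 3
    delay: int = 1

    def __post_init__(self) -> None:
        if self.order < 2:
            raise ValueError(f"embedding order must be >= 2, got {self.order}")
        if self.delay < 1:
            raise ValueError(f"embedding delay must be >= 1, got {self.delay}")


def _as_series(series) -> np.ndarray:
    x = np.asarray(series, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("series is empty")
    return x


def coarse_grain(series, tau: int) -> np.ndarray:
    """Average consecutive non-overlapping blocks of ``tau`` samples.

    Returns a series of length ``floor(N / tau)``; ``tau=1`` is the
    identity.
    """
    x = _as_series(series)
    tau = int(tau)
    if tau < 1:
        raise ValueError(f"scale tau must be >= 1, got {tau}")
    if tau > x.size:
        raise ValueError(f"scale tau={tau} exceeds series length {x.size}")
    n_blocks = x.size // tau
    return x[: n_blocks * tau].reshape(n_blocks, tau).mean(axis=1)


def sample_entropy(series, m: int = 2, r_absolute: float = 0.2) -> float:
    """Sample entropy of a series under an absolute tolerance.

    Counts template pairs (self-matches excluded) within Chebyshev
    distance ``r_absolute`` at lengths ``m`` and ``m + 1`` and returns
    the negative log of their ratio.

    Returns ``inf`` when no pair matches at length ``m + 1`` and ``nan``
    (flagged missing) when no pair matches even at length ``m``.
    """
    x = _as_series(series)
    m = int(m)
    n = x.size
    if m < 1:
        raise ValueError(f"template length m must be >= 1, got {m}")
    if n <= m + 1:
        raise ValueError(f"series of length {n} too short for m={m} (need > m+1)")
    if r_absolute <= 0:
        raise ValueError(f"tolerance must be > 0, got {r_absolute}")

    n_templates = n - m

    def _match_count(length: int) -> int:
        emb = sliding_window_view(x, length)[:n_templates]
        # pairwise Chebyshev distances; fine for the series sizes used here
        dist = np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=-1)
        iu = np.triu_indices(n_templates, k=1)
        return int(np.count_nonzero(dist[iu] <= r_absolute))

    b = _match_count(m)
    a = _match_count(m + 1)
    if b == 0:
        return math.nan
    if a == 0:
        return math.inf
    return -math.log(a / b)


def mse_profile(series, params: MseParams = MseParams()) -> np.ndarray:
    """Sample entropy of the coarse-grained series at scales 1..tau_max.

    The tolerance is ``params.r`` times the SD of the original series,
    fixed across scales.  A constant series yields an all-zero profile.
    """
    x = _as_series(series)
    if x.size // params.tau_max <= params.m + 1:
        raise ValueError(
            f"series of length {x.size} too short for tau_max={params.tau_max}, "
            f"m={params.m}"
        )
    sd = float(np.std(x))
    if sd == 0.0:
        return np.zeros(params.tau_max)
    r_abs = params.r * sd
    return np.array(
        [
            sample_entropy(coarse_grain(x, tau), params.m, r_abs)
            for tau in range(1, params.tau_max + 1)
        ]
    )


def _check_profile(profile) -> np.ndarray:
    p = np.asarray(profile, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("MSE profile is empty")
    return p


def complexity_index(profile) -> float:
    """Sum of the MSE profile; ``nan`` if any entry is non-finite."""
    p = _check_profile(profile)
    if not np.all(np.isfinite(p)):
        return math.nan
    return float(p.sum())


def mse_mean(profile) -> float:
    p = _check_profile(profile)
    if not np.all(np.isfinite(p)):
        return math.nan
    return float(p.mean())


def mse_sd(profile) -> float:
    p = _check_profile(profile)
    if not np.all(np.isfinite(p)):
        return math.nan
    return float(p.std())


def ordinal_patterns(order: int) -> list[tuple[int, ...]]:
    """All rank patterns of the given order, in lexicographic order."""
    return list(itertools.permutations(range(int(order))))


def _rank_rows(windows: np.ndarray) -> np.ndarray:
    # rank of element i = its position in the sorted window; stable sort
    # gives the earlier of tied samples the lower rank
    order = np.argsort(windows, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(windows.shape[0])[:, None]
    ranks[rows, order] = np.arange(windows.shape[1])[None, :]
    return ranks


def ordinal_distribution(series, params: PeParams = PeParams()) -> np.ndarray:
    """Relative frequency of each rank pattern among embedded windows.

    The embedding slides a window of ``order`` samples spaced ``delay``
    apart, producing ``T - (order - 1) * delay`` vectors.  The returned
    vector is aligned with :func:`ordinal_patterns` and sums to 1.
    """
    x = _as_series(series)
    d, tau = params.order, params.delay
    n_vectors = x.size - (d - 1) * tau
    if n_vectors < 1:
        raise ValueError(
            f"series of length {x.size} too short for order={d}, delay={tau}"
        )
    idx = np.arange(n_vectors)[:, None] + tau * np.arange(d)[None, :]
    ranks = _rank_rows(x[idx])

    patterns = ordinal_patterns(d)
    lookup = {pat: i for i, pat in enumerate(patterns)}
    counts = np.zeros(len(patterns))
    for row in ranks:
        counts[lookup[tuple(row)]] += 1
    return counts / n_vectors


def permutation_entropy(series, params: PeParams = PeParams()) -> float:
    """Shannon entropy (bits) of the ordinal-pattern distribution.

    Bounded by ``[0, log2(order!)]``; 0 for any strictly monotone series.
    """
    p = ordinal_distribution(series, params)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())
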