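"""Gap statistic with block-bootstrap surrogates for choosing k.

The number of clusters is chosen by comparing the log within-cluster
dispersion of the data clustering against its expectation under surrogate
(reference) cohorts.  Surrogates are built by block bootstrap: each 50-day
surrogate concatenates five 10-point segments drawn (with replacement,
uniform start positions) from the scaled input series, preserving short-range
autocorrelation while destroying the cohort's group structure.  Each
reference set is re-clustered with the identical DTW mean-linkage pipeline —
the comparison holds the clustering method fixed.

For k = 1..k_max:

    W_k   = sum_r  D_r / (2 n_r),  D_r = sum of pairwise DTW distances in r
    gap_k = mean_b log W*_kb - log W_k
    s_k   = sd_b(log W*_kb) * sqrt(1 + 1/B)

and the selected k is the smallest with gap_k >= gap_{k+1} - s_{k+1}
(one-standard-error rule; falls back to k_max with a warning when the gap
never stops increasing).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cluster import agglomerate
from .dtw import DtwConfig, dtw_matrix

__all__ = [
    "ReferenceConfig",
    "GapCurve",
    "within_cluster_dispersion",
    "make_reference_series",
    "gap_curve",
    "select_k",
]


@dataclass(frozen=True)
class ReferenceConfig:
    n_reference_sets: int = 100  # B; 100 sets suffice for gap estimation
    block_length: int = 10  # time points per bootstrap segment
    reference_size: int | None = None  # default: number of input series
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reference_sets < 2:
            raise ValueError("need at least two reference sets")
        if self.block_length < 1:
            raise ValueError("block_length must be positive")


@dataclass
class GapCurve:
    k_values: np.ndarray
    W_k: np.ndarray  # within-cluster dispersion of the data clustering
    logW_ref_mean: np.ndarray  # mean over reference sets of log W*
    s_k: np.ndarray  # one-standard-error term, sd * sqrt(1 + 1/B)
    gap_k: np.ndarray  # logW_ref_mean - log(W_k)

    @property
    def ose_criterion_k(self) -> np.ndarray:
        """gap_k - (gap_{k+1} - s_{k+1}) for k < k_max (NaN at k_max)."""
        crit = np.full(self.k_values.size, np.nan)
        crit[:-1] = self.gap_k[:-1] - (self.gap_k[1:] - self.s_k[1:])
        return crit


def within_cluster_dispersion(labels, distance_matrix) -> float:
    """Pooled within-cluster dispersion W = sum_r D_r / (2 n_r).

    ``D_r`` sums the full (ordered-pair) distance matrix over cluster r, so a
    two-point cluster at distance d contributes 2d/(2*2) = d/2.
    """
    labels = np.asarray(labels)
    D = np.asarray(distance_matrix)
    if labels.size != D.shape[0]:
        raise ValueError("labels and distance matrix disagree on n")
    W = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size == 0:
            raise ValueError(f"empty cluster {lab}")
        W += D[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return float(W)


def make_reference_series(
    pool, config: ReferenceConfig, rng: np.random.Generator, n_series: int | None = None
) -> np.ndarray:
    """Block-bootstrap surrogate series from a pool of scaled series.

    Each surrogate concatenates ceil(L / block_length) segments of
    ``block_length`` consecutive values, each taken from a uniformly chosen
    pool series at a uniformly chosen valid start (the last segment is
    truncated if the length does not divide evenly).  Segments never span
    series boundaries.
    """
    pool = np.asarray(pool, dtype=np.float64)
    if pool.ndim != 2 or pool.shape[0] == 0:
        raise ValueError("pool must be a non-empty (n_series, length) array")
    length = pool.shape[1]
    block = config.block_length
    if block > length:
        raise ValueError(f"block_length {block} exceeds series length {length}")
    n_series = n_series if n_series is not None else (
        config.reference_size or pool.shape[0]
    )
    n_starts = length - block + 1
    out = np.empty((n_series, length))
    for s in range(n_series):
        pos = 0
        while pos < length:
            src = rng.integers(pool.shape[0])
            start = rng.integers(n_starts)
            take = min(block, length - pos)
            out[s, pos : pos + take] = pool[src, start : start + take]
            pos += take
    return out


def _dispersion_profile(series_matrix, k_max, dtw_config) -> np.ndarray:
    """W_k for k = 1..k_max from one agglomerative clustering run."""
    D = dtw_matrix(series_matrix, dtw_config)
    model = agglomerate(list(series_matrix), dtw_config)
    return np.array(
        [within_cluster_dispersion(model.cut(k), D) for k in range(1, k_max + 1)]
    )


def gap_curve(
    series,
    k_max: int = 10,
    reference_config: ReferenceConfig | None = None,
    dtw_config: DtwConfig | None = None,
    log_scale: bool = True,
) -> GapCurve:
    """Compute the gap curve for k = 1..k_max.

    Every reference set is pushed through the same DTW + mean-linkage
    clustering as the data.  ``log_scale=False`` compares dispersions on the
    linear scale (sensitivity option).
    """
    reference_config = reference_config or ReferenceConfig()
    dtw_config = dtw_config or DtwConfig()
    X = np.asarray([np.asarray(s, dtype=np.float64) for s in series])
    if X.shape[0] < k_max + 1:
        raise ValueError("need more series than k_max")
    rng = np.random.default_rng(reference_config.rng_seed)

    W_k = _dispersion_profile(X, k_max, dtw_config)
    if W_k[0] <= 0:
        raise ValueError("zero dispersion: input series are all identical")

    tx = np.log if log_scale else (lambda v: v)
    B = reference_config.n_reference_sets
    ref_size = reference_config.reference_size or X.shape[0]
    logW_ref = np.empty((B, k_max))
    for b in range(B):
        surrogate = make_reference_series(X, reference_config, rng, n_series=ref_size)
        logW_ref[b] = tx(_dispersion_profile(surrogate, k_max, dtw_config))

    logW_ref_mean = logW_ref.mean(axis=0)
    s_k = logW_ref.std(axis=0, ddof=1) * np.sqrt(1.0 + 1.0 / B)
    gap = logW_ref_mean - tx(W_k)
    return GapCurve(
        k_values=np.arange(1, k_max + 1),
        W_k=W_k,
        logW_ref_mean=logW_ref_mean,
        s_k=s_k,
        gap_k=gap,
    )


def select_k(curve: GapCurve) -> int:
    """Smallest k whose gap is within one standard error of the next gap.

    Returns the first k with gap_k >= gap_{k+1} - s_{k+1}; if the gap keeps
    increasing through k_max, returns k_max with a warning.
    """
    if curve.k_values.size < 2:
        raise ValueError("gap curve must cover at least k = 1..2")
    crit = curve.ose_criterion_k
    for k, c in zip(curve.k_values[:-1], crit[:-1]):
        if c >= 0:
            return int(k)
    warnings.warn(
        "gap statistic still increasing at k_max; returning k_max", stacklevel=2
    )
    return int(curve.k_values[-1])
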