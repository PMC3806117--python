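"""Phase-space reconstruction: delay embedding, AMI and FNN diagnostics.

A scalar series x(0..N-1) is embedded as time-delay vectors

    X_i = (x_i, x_{i+tau}, ..., x_{i+(m-1) tau}),   i = 0..N-(m-1)tau-1,

with dimension ``m`` and delay ``tau``.  The delay is conventionally chosen
at the first local minimum of the average mutual information (AMI) profile,
and the dimension as the smallest m at which the fraction of false nearest
neighbours (FNN) drops below a threshold.  The pipeline uses the global
choice m = 5, tau = 8 for every 3200-sample part; AMI and FNN are provided
as diagnostics for reproducing that selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "DelayEmbedding",
    "AmiProfile",
    "FnnProfile",
    "delay_embed",
    "average_mutual_information",
    "false_nearest_neighbours",
]

DEFAULT_M = 5
DEFAULT_TAU = 8


@dataclass
class DelayEmbedding:
    """A reconstructed trajectory: points[i, j] = x[i + j * tau]."""

    points: np.ndarray  # shape (N - (m-1)*tau, m)
    m: int
    tau: int
    source_length: int

    def __len__(self) -> int:
        return len(self.points)


def delay_embed(series: np.ndarray, m: int, tau: int) -> DelayEmbedding:
    """Takens time-delay embedding of a scalar series.

    Produces exactly N - (m-1)*tau points of dimension m.  Raises if the
    series is too short to yield at least one point.
    """
    x = np.asarray(series, dtype=float).ravel()
    if m < 1 or tau < 1:
        raise ValueError("m and tau must be >= 1")
    n = len(x)
    min_len = (m - 1) * tau + 1
    if n < min_len:
        raise ValueError(
            f"series of length {n} too short to embed with m={m}, tau={tau}; "
            f"need at least {min_len} samples"
        )
    n_points = n - (m - 1) * tau
    # strided view: column j is x shifted by j*tau
    points = np.empty((n_points, m))
    for j in range(m):
        points[:, j] = x[j * tau : j * tau + n_points]
    return DelayEmbedding(points=points, m=m, tau=tau, source_length=n)


@dataclass
class AmiProfile:
    """Average mutual information (bits) versus lag."""

    lags: np.ndarray
    ami_bits: np.ndarray
    selected_tau: int
    has_local_minimum: bool = True


def _hist_mi_bits(x: np.ndarray, y: np.ndarray, edges: np.ndarray) -> float:
    counts, _, _ = np.histogram2d(x, y, bins=(edges, edges))
    n = counts.sum()
    if n == 0:
        return 0.0
    pxy = counts / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    return float(np.sum(pxy[mask] * np.log2(pxy[mask] / (px @ py)[mask])))


def average_mutual_information(
    series: np.ndarray, max_lag: int = 64, bins: int = 16
) -> AmiProfile:
    """AMI profile over lags 0..max_lag via an equal-width 2-D histogram.

    ``selected_tau`` is the first local minimum, detected over a +/-2-lag
    window (ami[k] below ami[k-1] and not above any neighbour within the
    window) so that bin-level fluctuations of the histogram estimator do
    not trigger spurious early minima; if no local minimum exists within
    the profile the argmin is used instead and a warning logged.
    """
    x = np.asarray(series, dtype=float).ravel()
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if len(x) <= max_lag + 1:
        raise ValueError("series shorter than max_lag + 2")
    lo, hi = x.min(), x.max()
    if hi == lo:
        hi = lo + 1.0  # constant series: all mass in one bin, AMI = 0
    edges = np.linspace(lo, hi, bins + 1)
    lags = np.arange(max_lag + 1)
    ami = np.empty(max_lag + 1)
    for k in lags:
        if k == 0:
            ami[0] = _hist_mi_bits(x, x, edges)
        else:
            ami[k] = _hist_mi_bits(x[:-k], x[k:], edges)
    selected, found = None, False
    window = 2
    for k in range(1, max_lag):
        lo, hi = max(0, k - window), min(len(ami), k + window + 1)
        if ami[k] < ami[k - 1] and ami[k] == ami[lo:hi].min():
            selected, found = k, True
            break
    if selected is None:
        selected = int(np.argmin(ami[1:]) + 1)
        logger.warning(
            "no local AMI minimum within max_lag=%d; falling back to argmin=%d",
            max_lag,
            selected,
        )
    return AmiProfile(lags=lags, ami_bits=ami, selected_tau=selected, has_local_minimum=found)


@dataclass
class FnnProfile:
    """Fraction of false nearest neighbours versus embedding dimension."""

    dimensions: np.ndarray
    fnn_fraction: np.ndarray
    selected_m: int
    converged: bool = True


def false_nearest_neighbours(
    series: np.ndarray,
    tau: int = DEFAULT_TAU,
    max_m: int = 10,
    r_tol: float = 15.0,
    a_tol: float = 2.0,
    threshold: float = 0.01,
) -> FnnProfile:
    """Kennel-style false-nearest-neighbour profile for m = 1..max_m.

    For each m, every point's nearest neighbour at dimension m is re-examined
    at dimension m+1; it is flagged false if the added-coordinate distance
    ratio exceeds ``r_tol`` or the (m+1)-dimensional separation exceeds
    ``a_tol`` standard deviations of the series.  ``selected_m`` is the
    smallest m whose false fraction falls below ``threshold``.
    """
    x = np.asarray(series, dtype=float).ravel()
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if max_m < 2:
        raise ValueError("max_m must be >= 2")
    sigma = float(x.std())
    if sigma == 0:
        raise ValueError("constant series has no neighbour structure")
    dims = np.arange(1, max_m + 1)
    fracs = np.empty(len(dims))
    for idx, m in enumerate(dims):
        # use only points that also exist at dimension m+1
        n_pts = len(x) - m * tau
        if n_pts < 2:
            raise ValueError(
                f"fewer than 2 embeddable points at m={m + 1}, tau={tau} "
                f"(series length {len(x)})"
            )
        emb = delay_embed(x, m, tau).points[:n_pts]
        extra = x[m * tau : m * tau + n_pts]  # coordinate added at m+1
        tree = cKDTree(emb)
        dist, nbr = tree.query(emb, k=2)
        d_m = dist[:, 1]
        j = nbr[:, 1]
        added = np.abs(extra - extra[j])
        d_m1 = np.sqrt(d_m**2 + added**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d_m > 0, added / np.where(d_m > 0, d_m, 1.0), np.inf)
        false = (ratio > r_tol) | (d_m1 / sigma > a_tol)
        # exact duplicates with zero added distance are true neighbours
        false[(d_m == 0) & (added == 0)] = False
        fracs[idx] = false.mean()
    below = np.nonzero(fracs < threshold)[0]
    if below.size:
        selected, converged = int(dims[below[0]]), True
    else:
        selected, converged = int(dims[-1]), False
        logger.warning(
            "FNN fraction never fell below %.3g up to max_m=%d (min %.3f); "
            "series may be stochastic or high-dimensional",
            threshold,
            max_m,
            fracs.min(),
        )
    return FnnProfile(dimensions=dims, fnn_fraction=fracs, selected_m=selected, converged=converged)
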