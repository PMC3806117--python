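"""The two nonlinear features: Shannon entropy and the largest Lyapunov exponent.

Entropy is the Shannon entropy (bits) of a part's amplitude histogram over
the fixed normalized range [-0.5, 0.5].  The largest Lyapunov exponent
(LLE) is estimated by the nearest-neighbour divergence-curve method
(Rosenstein): embed the part, pair each trajectory point with its nearest
neighbour outside a Theiler window, average the log pair separation as the
pairs evolve forward, and fit a line to the early growth — the slope is
lambda_1 in nats per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import FeatureVector, SegmentPart
from .embedding import DEFAULT_M, DEFAULT_TAU, delay_embed

logger = logging.getLogger(__name__)

__all__ = [
    "EntropyEstimate",
    "DivergenceCurve",
    "LleResult",
    "FeatureConfig",
    "shannon_entropy",
    "mean_period",
    "rosenstein_lle",
    "extract_features",
]

DEFAULT_N_BINS = 32
DEFAULT_MAX_STEP = 30
# Fit starts at step 1: the step-0 point is biased low because the neighbour
# was selected to minimise exactly that distance, which turns into a spurious
# slope for signals whose true divergence is at or below the noise floor.
DEFAULT_FIT_RANGE = (1, 6)


@dataclass
class EntropyEstimate:
    """Histogram Shannon entropy of one part, in bits."""

    value: float
    n_bins: int
    probabilities: np.ndarray


def shannon_entropy(
    part: SegmentPart | np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    amplitude_range: tuple[float, float] = (-0.5, 0.5),
) -> EntropyEstimate:
    """H = sum_i p_i log2(1/p_i) over an equal-width amplitude histogram.

    ``p_i`` is the fraction of samples in bin i of ``n_bins`` equal-width
    bins spanning ``amplitude_range``; empty bins contribute nothing.  The
    value is bounded by log2(n_bins) (reached by a uniform histogram) and is
    0 for a constant part.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = part.samples if isinstance(part, SegmentPart) else np.asarray(part, dtype=float)
    counts, _ = np.histogram(x, bins=n_bins, range=amplitude_range)
    n = counts.sum()
    if n == 0:
        raise ValueError("no samples fall inside the amplitude range")
    p = counts / n
    nz = p[p > 0]
    h = float(-(nz * np.log2(nz)).sum())
    return EntropyEstimate(value=h, n_bins=n_bins, probabilities=p)


def mean_period(series: np.ndarray) -> int:
    """Mean period (samples) as the reciprocal of the mean power-spectrum frequency.

    Used as the default Theiler window so that neighbour pairs are separated
    by at least one characteristic oscillation.
    """
    x = np.asarray(series, dtype=float).ravel()
    x = x - x.mean()
    if not np.any(x):
        return 1
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x))  # cycles per sample
    power = spec[1:]
    f = freqs[1:]
    total = power.sum()
    if total == 0:
        return 1
    mean_f = float((f * power).sum() / total)
    if mean_f <= 0:
        return 1
    return max(1, int(round(1.0 / mean_f)))


@dataclass
class DivergenceCurve:
    """Mean log separation of neighbour pairs versus forward step."""

    steps: np.ndarray  # 0..max_step
    y: np.ndarray  # mean ln d_j(i) in nats; NaN where undefined
    pair_counts: np.ndarray  # number of pairs contributing at each step


@dataclass
class LleResult:
    """Largest Lyapunov exponent estimate (nats per sample) with fit diagnostics."""

    lambda1: float
    fit_range: tuple[int, int]
    r_squared: float
    curve: DivergenceCurve
    m: int = DEFAULT_M
    tau: int = DEFAULT_TAU
    theiler: int = 0


def _nearest_neighbours_theiler(points: np.ndarray, theiler: int) -> np.ndarray:
    """Index of each point's nearest neighbour with |i - j| > theiler (-1 if none)."""
    n = len(points)
    tree = cKDTree(points)
    nn = np.full(n, -1, dtype=int)
    unresolved = np.arange(n)
    # start small and grow: even with a wide Theiler window most of the
    # temporally excluded points are spatially distant, so a handful of
    # candidates usually suffices
    k = min(n, 8)
    while unresolved.size:
        dist, idx = tree.query(points[unresolved], k=k)
        if k == 1:
            dist, idx = dist[:, None], idx[:, None]
        sep = np.abs(idx - unresolved[:, None])
        ok = sep > theiler
        has = ok.any(axis=1)
        first = np.argmax(ok, axis=1)
        nn[unresolved[has]] = idx[np.nonzero(has)[0], first[has]]
        unresolved = unresolved[~has]
        if k >= n:
            break
        k = min(n, k * 2)
    return nn


def rosenstein_lle(
    series: SegmentPart | np.ndarray,
    m: int = DEFAULT_M,
    tau: int = DEFAULT_TAU,
    theiler: int | None = None,
    max_step: int = DEFAULT_MAX_STEP,
    fit_range: tuple[int, int] = DEFAULT_FIT_RANGE,
) -> LleResult:
    """Estimate lambda_1 by the nearest-neighbour divergence-curve method.

    The series is delay-embedded (m, tau); each point j is paired with its
    nearest neighbour at temporal separation > ``theiler`` (default: the
    series' mean period); y(i) = <ln d_j(i)> averages the log pair distance
    after i forward steps over all pairs still inside the trajectory with
    d_j(i) > 0; lambda_1 is the least-squares slope of y(i) over
    ``fit_range`` (inclusive), in nats per sample.
    """
    x = series.samples if isinstance(series, SegmentPart) else np.asarray(series, dtype=float)
    emb = delay_embed(x, m, tau)
    pts = emb.points
    n = len(pts)
    if theiler is None:
        theiler = mean_period(x)
    if theiler < 0:
        raise ValueError("theiler must be >= 0")
    nn = _nearest_neighbours_theiler(pts, theiler)
    valid = nn >= 0
    if not valid.any():
        raise ValueError(
            f"no neighbour pair satisfies the Theiler exclusion (window={theiler}, "
            f"{n} trajectory points)"
        )
    j_idx = np.nonzero(valid)[0]
    k_idx = nn[valid]
    steps = np.arange(max_step + 1)
    y = np.full(max_step + 1, np.nan)
    counts = np.zeros(max_step + 1, dtype=int)
    for i in steps:
        inside = (j_idx + i < n) & (k_idx + i < n)
        if not inside.any():
            break
        d = np.linalg.norm(pts[j_idx[inside] + i] - pts[k_idx[inside] + i], axis=1)
        d = d[d > 0]
        if d.size:
            y[i] = float(np.mean(np.log(d)))
            counts[i] = d.size
    lo, hi = int(fit_range[0]), int(fit_range[1])
    if lo < 0 or hi > max_step or hi <= lo:
        raise ValueError(f"fit_range {fit_range} outside the curve's 0..{max_step} steps")
    seg = slice(lo, hi + 1)
    ii = steps[seg]
    yy = y[seg]
    defined = np.isfinite(yy)
    if defined.sum() < 2:
        raise ValueError(f"divergence curve undefined over fit_range {fit_range}")
    ii, yy = ii[defined], yy[defined]
    slope, intercept = np.polyfit(ii, yy, 1)
    resid = yy - (slope * ii + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((yy - yy.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    curve = DivergenceCurve(steps=steps, y=y, pair_counts=counts)
    return LleResult(
        lambda1=float(slope),
        fit_range=(lo, hi),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        curve=curve,
        m=m,
        tau=tau,
        theiler=int(theiler),
    )


@dataclass
class FeatureConfig:
    """Knobs of the feature extraction stage."""

    m: int = DEFAULT_M
    tau: int = DEFAULT_TAU
    n_bins: int = DEFAULT_N_BINS
    theiler: int | None = None  # None -> per-part mean period
    max_step: int = DEFAULT_MAX_STEP
    fit_range: tuple[int, int] = DEFAULT_FIT_RANGE


def extract_features(
    parts: list[SegmentPart], config: FeatureConfig | None = None
) -> list[FeatureVector]:
    """Compute (LLE, entropy) for every part.

    Deterministic; raises with the part's identity attached if either
    estimator fails on it.
    """
    if not parts:
        raise ValueError("extract_features requires at least one part")
    cfg = config or FeatureConfig()
    out: list[FeatureVector] = []
    for idx, part in enumerate(parts):
        try:
            ent = shannon_entropy(part, n_bins=cfg.n_bins)
            lle = rosenstein_lle(
                part,
                m=cfg.m,
                tau=cfg.tau,
                theiler=cfg.theiler,
                max_step=cfg.max_step,
                fit_range=cfg.fit_range,
            )
        except Exception as exc:
            raise RuntimeError(f"feature extraction failed for part {part.part_id}") from exc
        out.append(
            FeatureVector(
                lle=lle.lambda1,
                entropy=ent.value,
                label=part.label,
                subject_id=part.subject_id,
                part_id=part.part_id,
                segment_index=part.segment_index,
                part_index=part.part_index,
            )
        )
        if (idx + 1) % 500 == 0:
            logger.info("extracted features for %d/%d parts", idx + 1, len(parts))
    return out
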