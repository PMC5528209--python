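"""Penalized-contrast segmentation of one-dimensional series (Lavielle).

Partitions the FPT series of a track (evaluated at the population radius
r_pop) into K contiguous, homogeneous movement bouts.  For each feasible K
the exact minimum-contrast segmentation is found by dynamic programming; the
number of segments K_opt is then chosen with the second-derivative rule on
the standardized contrast: the largest K whose discrete curvature exceeds a
threshold S (default 0.75).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fpt import FPTProfile, PopulationScale
from .telemetry import Track

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationConfig",
    "Segmentation",
    "segment_cost_matrix",
    "optimal_segmentation",
    "contrast_curve",
    "choose_kopt",
    "segment_path",
]

DEFAULT_S = 0.75


@dataclass(frozen=True)
class SegmentationConfig:
    """Tuning knobs for path segmentation.

    Lmin is the minimum number of fixes per segment (chosen so that
    Lmin x fix-interval is a fixed bout duration, e.g. 24 h).  Kmax caps the
    number of segments; None derives min(n // (2 Lmin), 40) from the series.
    ``contrast`` is "mean" (within-segment sum of squares about the segment
    mean) or "meanvar" (Gaussian contrast with per-segment mean and variance).
    ``log_series`` segments ln(FPT) instead of raw FPT.
    """

    lmin: int = 12
    kmax: int | None = None
    s_threshold: float = DEFAULT_S
    contrast: str = "mean"
    log_series: bool = False

    def __post_init__(self):
        if self.lmin < 2:
            raise ValueError("Lmin must be >= 2")
        if self.s_threshold <= 0:
            raise ValueError("S must be > 0")
        if self.contrast not in ("mean", "meanvar"):
            raise ValueError("contrast must be 'mean' or 'meanvar'")

    def resolve_kmax(self, n: int) -> int:
        if self.kmax is not None:
            return self.kmax
        return max(min(n // (2 * self.lmin), 40), 1)


@dataclass
class Segmentation:
    """Result of segmenting one series: breakpoints, contrast diagnostics, K_opt."""

    track_id: str
    series: np.ndarray
    breakpoints: list[int]  # segment start indices, breakpoints[0] == 0
    k_opt: int
    contrast: np.ndarray  # J(K), K = 1..Kmax
    standardized: np.ndarray  # J~(K)
    curvature: np.ndarray  # D(K); NaN at K = 1 and K = Kmax
    config: SegmentationConfig = field(default_factory=SegmentationConfig)

    @property
    def segments(self) -> list[tuple[int, int]]:
        """Half-open (start, stop) fix-index spans of each bout."""
        bounds = self.breakpoints + [self.series.size]
        return list(zip(bounds[:-1], bounds[1:]))

    def to_frame(self, track: Track | None = None) -> pd.DataFrame:
        rows = []
        for k, (lo, hi) in enumerate(self.segments):
            row = {
                "track_id": self.track_id,
                "segment": k,
                "start_fix": lo,
                "end_fix": hi - 1,
                "n_fixes": hi - lo,
                "mean_value": float(np.mean(self.series[lo:hi])),
            }
            if track is not None:
                row["start_time"] = track.timestamps[lo]
                row["end_time"] = track.timestamps[hi - 1]
            rows.append(row)
        return pd.DataFrame(rows)


def segment_cost_matrix(series: np.ndarray, contrast: str = "mean") -> np.ndarray:
    """cost[i, j] = contrast of the single segment series[i..j] (inclusive).

    For "mean": within-segment sum of squared deviations from the segment
    mean.  For "meanvar": n_seg * ln(sigma_hat^2) with the ML variance,
    floored at a tiny value for constant segments.  O(n^2) via cumulative
    sums.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x**2)])
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    length = j - i + 1
    with np.errstate(invalid="ignore", divide="ignore"):
        s1 = c1[j + 1] - c1[i]
        s2 = c2[j + 1] - c2[i]
        sse = s2 - s1**2 / np.maximum(length, 1)
    sse = np.maximum(sse, 0.0)  # guard tiny negative round-off
    if contrast == "mean":
        cost = sse
    else:
        var = np.maximum(sse / np.maximum(length, 1), 1e-300)
        cost = length * np.log(var)
    return np.where(j >= i, cost, np.inf)


def _dp_tables(cost: np.ndarray, kmax: int, lmin: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward DP: best[m, j] = min contrast of x[0..j] in m+1 segments.

    Each level is a min-plus product of the previous level with the cost
    matrix, restricted to segment length >= lmin; np.argmin's first-match
    rule breaks ties toward the earliest breakpoint.
    """
    n = cost.shape[0]
    best = np.full((kmax, n), np.inf)
    argcut = np.zeros((kmax, n), dtype=int)
    best[0] = cost[0]
    j_idx = np.arange(n)
    for m in range(1, kmax):
        starts = np.arange(m * lmin, n - lmin + 1)
        if starts.size == 0:
            break
        tot = best[m - 1, starts - 1][:, None] + cost[starts, :]
        tot = np.where(j_idx[None, :] >= (starts[:, None] + lmin - 1), tot, np.inf)
        a = np.argmin(tot, axis=0)
        best[m] = tot[a, j_idx]
        argcut[m] = starts[a]
    return best, argcut


def _backtrack(argcut: np.ndarray, k: int, n: int) -> list[int]:
    j = n - 1
    breaks = []
    for m in range(k - 1, 0, -1):
        j0 = int(argcut[m, j])
        breaks.append(j0)
        j = j0 - 1
    return [0] + breaks[::-1]


def optimal_segmentation(
    series: np.ndarray,
    k: int,
    lmin: int = 2,
    contrast: str = "mean",
    cost: np.ndarray | None = None,
) -> tuple[list[int], float]:
    """Exact minimum-contrast split of ``series`` into ``k`` segments of length >= lmin.

    Dynamic programming over (end position, number of segments); ties in the
    minimum break toward the earliest breakpoint.  Returns the segment start
    indices (first always 0) and the achieved contrast J(k).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if k * lmin > n:
        raise ValueError(f"infeasible: K*Lmin = {k * lmin} > n = {n}")
    if cost is None:
        cost = segment_cost_matrix(x, contrast)
    best, argcut = _dp_tables(cost, k, lmin)
    return _backtrack(argcut, k, n), float(best[k - 1, n - 1])


def contrast_curve(
    series: np.ndarray, kmax: int, lmin: int = 2, contrast: str = "mean"
) -> tuple[np.ndarray, list[list[int]]]:
    """J(K) and breakpoints for K = 1..kmax (one shared DP)."""
    x = np.asarray(series, dtype=float)
    n = x.size
    if kmax * lmin > n:
        raise ValueError(f"infeasible: Kmax*Lmin = {kmax * lmin} > n = {n}")
    cost = segment_cost_matrix(x, contrast)
    best, argcut = _dp_tables(cost, kmax, lmin)
    js = best[:, n - 1].copy()
    bps = [_backtrack(argcut, k, n) for k in range(1, kmax + 1)]
    return js, bps


def choose_kopt(
    j: np.ndarray, s_threshold: float = DEFAULT_S
) -> tuple[int, np.ndarray, np.ndarray]:
    """Second-derivative rule on the standardized contrast.

    Standardize J~(K) = (J(Kmax) - J(K)) / (J(Kmax) - J(1)) * (Kmax - 1) + 1,
    so J~ runs from Kmax (at K=1) down to 1.  The discrete curvature
    D(K) = J~(K-1) - 2 J~(K) + J~(K+1) measures how sharply the decrease
    stops at K; K_opt is the largest K with D(K) > S, or 1 if none qualifies
    (including the flat-contrast degenerate case).
    """
    j = np.asarray(j, dtype=float)
    kmax = j.size
    if kmax < 3:
        return 1, np.full(kmax, np.nan), np.full(kmax, np.nan)
    denom = j[kmax - 1] - j[0]
    if denom == 0:
        logger.warning("flat contrast curve (constant series?); K_opt = 1")
        return 1, np.full(kmax, np.nan), np.full(kmax, np.nan)
    std = (j[kmax - 1] - j) / denom * (kmax - 1) + 1
    curv = np.full(kmax, np.nan)
    curv[1 : kmax - 1] = std[:-2] - 2 * std[1:-1] + std[2:]
    qualifying = np.flatnonzero(np.nan_to_num(curv, nan=-np.inf) > s_threshold)
    k_opt = int(qualifying[-1]) + 1 if qualifying.size else 1
    return k_opt, std, curv


def segment_path(
    track: Track,
    profile: FPTProfile,
    scale: PopulationScale,
    cfg: SegmentationConfig | None = None,
) -> Segmentation:
    """Segment a track's FPT series at the population radius into movement bouts.

    Undefined FPT values at r_pop (track edges) are imputed from the nearest
    defined neighbor in time so fix indices stay aligned; series shorter than
    2*Lmin yield a single segment.
    """
    cfg = cfg or SegmentationConfig()
    rr = profile.radii.radii
    col = int(np.argmin(np.abs(rr - scale.r_pop)))
    series = profile.fpt[:, col].copy()
    undef = ~np.isfinite(series)
    if undef.all():
        raise ValueError(f"FPT undefined at every fix for r_pop = {scale.r_pop}")
    if undef.any():
        logger.info(
            "%s: imputing %d undefined FPT value(s) at r_pop from nearest neighbor",
            track.label,
            int(undef.sum()),
        )
        defined_idx = np.flatnonzero(~undef)
        nearest = defined_idx[
            np.argmin(np.abs(np.flatnonzero(undef)[:, None] - defined_idx[None, :]), axis=1)
        ]
        series[undef] = series[nearest]
    if cfg.log_series:
        series = np.log(series)

    n = series.size
    if n < 500:
        logger.warning(
            "%s: series has %d fixes (<500); the S threshold can be sensitive",
            track.label,
            n,
        )
    kmax = cfg.resolve_kmax(n)
    if n < 2 * cfg.lmin or kmax < 3:
        logger.warning("%s: series too short for segmentation; single segment", track.label)
        j1 = float(np.sum((series - series.mean()) ** 2))
        return Segmentation(
            track_id=track.label,
            series=series,
            breakpoints=[0],
            k_opt=1,
            contrast=np.array([j1]),
            standardized=np.array([np.nan]),
            curvature=np.array([np.nan]),
            config=cfg,
        )
    js, bps = contrast_curve(series, kmax, cfg.lmin, cfg.contrast)
    k_opt, std, curv = choose_kopt(js, cfg.s_threshold)
    return Segmentation(
        track_id=track.label,
        series=series,
        breakpoints=bps[k_opt - 1],
        k_opt=k_opt,
        contrast=js,
        standardized=std,
        curvature=curv,
        config=cfg,
    )
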