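"""Distribution comparison and multimodality testing for patch areas.

Patch areas are strongly right-skewed (approximately lognormal), so all
statistics operate on natural-log areas.  Two groups are compared with the
two-sample Kolmogorov-Smirnov test; each group is screened for multimodality
with Silverman's critical-bandwidth test: for k = 1..k_max, find the smallest
Gaussian-KDE bandwidth h_crit(k) at which the sample shows at most k modes,
then ask — via a smoothed bootstrap at exactly that bandwidth — how often a
sample that truly had <= k modes would need even more smoothing.  A small
Silverman p-value p(k) supports "more than k modes"; we report
m(k) = 1 - p(k) as multimodality support, declared at m >= 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AreaSample",
    "KSResult",
    "ModalityScan",
    "ks_compare",
    "count_modes",
    "critical_bandwidth",
    "silverman_test",
    "modality_scan",
]

MODE_GRID_SIZE = 512
DECISION_CUTOFF = 0.95


@dataclass
class AreaSample:
    """Patch areas (m^2) for one group, with their natural logs."""

    group: str
    areas: np.ndarray

    def __post_init__(self):
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.size == 0:
            raise ValueError("empty area sample")
        if np.any(self.areas <= 0) or not np.all(np.isfinite(self.areas)):
            raise ValueError("areas must be positive and finite")

    @property
    def n(self) -> int:
        return self.areas.size

    @property
    def log_areas(self) -> np.ndarray:
        return np.log(self.areas)

    @classmethod
    def from_patchset(cls, patchset, group: str | None = None) -> "AreaSample":
        return cls(group=group or patchset.species, areas=patchset.areas_m2)


@dataclass(frozen=True)
class KSResult:
    D: float
    p: float
    n1: int
    n2: int


@dataclass
class ModalityScan:
    """Per-k Silverman results over k = 1..k_max."""

    group: str
    k: np.ndarray
    h_crit: np.ndarray
    p: np.ndarray  # Silverman p-value for "at most k modes"
    m: np.ndarray  # multimodality support, 1 - p
    n_boot: int
    seed: int
    cutoff: float = DECISION_CUTOFF

    @property
    def best_k(self) -> int:
        """k with the strongest multimodality support."""
        return int(self.k[np.argmax(self.m)])

    @property
    def max_support(self) -> float:
        return float(np.max(self.m))

    @property
    def multimodal(self) -> bool:
        return bool(np.any(self.m >= self.cutoff))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k,
                "h_crit": self.h_crit,
                "p": self.p,
                "m": self.m,
                "decision": self.m >= self.cutoff,
            }
        )


def ks_compare(a: AreaSample, b: AreaSample) -> KSResult:
    """Two-sample KS test on log areas (asymptotic two-sided p)."""
    if a.n < 2 or b.n < 2:
        raise ValueError("KS comparison needs at least 2 observations per sample")
    res = stats.ks_2samp(a.log_areas, b.log_areas, method="asymp")
    return KSResult(D=float(res.statistic), p=float(res.pvalue), n1=a.n, n2=b.n)


def _kde_on_grid(x: np.ndarray, h: float) -> tuple[np.ndarray, np.ndarray]:
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, MODE_GRID_SIZE)
    dens = np.exp(-0.5 * ((grid[:, None] - x[None, :]) / h) ** 2).sum(axis=1)
    return grid, dens


def count_modes(x: np.ndarray, h: float) -> int:
    """Strict local maxima of the Gaussian KDE at bandwidth h on a 512-point grid.

    Plateaus (runs of equal density) count as a single mode.
    """
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    x = np.asarray(x, dtype=float)
    _, dens = _kde_on_grid(x, h)
    return _count_grid_modes(dens)


def _count_grid_modes(dens: np.ndarray) -> int:
    d = np.diff(dens)
    sign = np.sign(d)
    sign = sign[sign != 0]  # collapse plateaus
    if sign.size == 0:
        return 1
    n_down = int(np.sum((sign[:-1] > 0) & (sign[1:] < 0)))
    # a profile that starts falling or ends rising has a mode at the edge
    return n_down + (1 if sign[0] < 0 else 0) + (1 if sign[-1] > 0 else 0) or 1


def _batch_count_modes(samples: np.ndarray, h: float) -> np.ndarray:
    """count_modes for each row of ``samples`` (vectorized over rows)."""
    lo = samples.min(axis=1, keepdims=True) - 3 * h
    hi = samples.max(axis=1, keepdims=True) + 3 * h
    u = np.linspace(0.0, 1.0, MODE_GRID_SIZE)
    grids = lo + (hi - lo) * u[None, :]
    out = np.empty(samples.shape[0], dtype=int)
    chunk = max(1, int(4e6 // (samples.shape[1] * MODE_GRID_SIZE)) or 1)
    for s in range(0, samples.shape[0], chunk):
        e = min(s + chunk, samples.shape[0])
        diff = grids[s:e, :, None] - samples[s:e, None, :]
        dens = np.exp(-0.5 * (diff / h) ** 2).sum(axis=2)
        for i in range(e - s):
            out[s + i] = _count_grid_modes(dens[i])
    return out


def critical_bandwidth(x: np.ndarray, k: int, rtol: float = 1e-4) -> float:
    """Smallest bandwidth at which the KDE of ``x`` has at most k modes.

    The Gaussian-kernel mode count is nonincreasing in h, so the critical
    bandwidth is found by bisection to relative tolerance ``rtol``.
    """
    x = np.asarray(x, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    spread = x.max() - x.min()
    if spread == 0:
        raise ValueError("cannot bracket h_crit for a constant sample")
    hi = spread  # one kernel sd spanning the range is always unimodal
    while count_modes(x, hi) > k:  # pragma: no cover - spread suffices in practice
        hi *= 2
    lo = hi * 1e-6
    while count_modes(x, lo) <= k:
        lo /= 4
        if lo < spread * 1e-12:
            return float(lo)  # sample cannot show more than k modes at any h
    while (hi - lo) > rtol * hi:
        mid = 0.5 * (lo + hi)
        if count_modes(x, mid) <= k:
            hi = mid
        else:
            lo = mid
    return float(hi)


def silverman_test(
    x: np.ndarray,
    k: int = 1,
    n_boot: int = 999,
    seed: int | np.random.Generator = 0,
    h_crit: float | None = None,
) -> tuple[float, float, float]:
    """Silverman's smoothed-bootstrap test of "at most k modes".

    Bootstrap replicates are resampled from x, jittered with N(0, h_crit^2)
    noise and variance-rescaled by 1/sqrt(1 + h_crit^2/s^2) so their variance
    matches the sample's.  p = (1 + #{replicates needing > k modes at
    h_crit}) / (n_boot + 1); returns (p, m, h_crit) with m = 1 - p.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError("Silverman test needs n >= 5")
    if n_boot < 99:
        import warnings

        warnings.warn("n_boot < 99 gives unstable Silverman p-values", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if h_crit is None:
        h_crit = critical_bandwidth(x, k)
    n = x.size
    xbar = x.mean()
    s2 = x.var(ddof=1)
    scale = 1.0 / np.sqrt(1.0 + h_crit**2 / s2)
    idx = rng.integers(0, n, size=(n_boot, n))
    eps = rng.standard_normal((n_boot, n))
    y = xbar + (x[idx] - xbar + h_crit * eps) * scale
    exceed = _batch_count_modes(y, h_crit) > k
    p = (1.0 + exceed.sum()) / (n_boot + 1.0)
    return float(p), float(1.0 - p), float(h_crit)


def modality_scan(
    x: np.ndarray,
    k_max: int = 30,
    n_boot: int = 999,
    seed: int = 0,
    group: str = "",
    cutoff: float = DECISION_CUTOFF,
) -> ModalityScan:
    """Run Silverman's test for every k = 1..k_max on one sample."""
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    ks = np.arange(1, k_max + 1)
    h_crits, ps, ms = [], [], []
    for k in ks:
        p, m, h = silverman_test(x, int(k), n_boot=n_boot, seed=rng)
        h_crits.append(h)
        ps.append(p)
        ms.append(m)
    return ModalityScan(
        group=group,
        k=ks,
        h_crit=np.asarray(h_crits),
        p=np.asarray(ps),
        m=np.asarray(ms),
        n_boot=n_boot,
        seed=seed if np.isscalar(seed) else -1,
        cutoff=cutoff,
    )
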