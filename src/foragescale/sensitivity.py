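"""Sensitivity of the patch-area comparison to small distributional shifts.

Two empirical procedures answer "how small a difference could this framework
detect?": (1) shift a copy of the log-area sample by an increasing constant
and find the smallest shift at which the two-sample KS test rejects; (2) pool
the original with each shifted copy and find the smallest shift at which
Silverman's test declares the pooled sample bimodal.  Shifts are applied on
the natural-log scale by default, so a shift of delta corresponds to a
multiplicative change of exp(delta) in patch area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .modality import AreaSample, ks_compare, silverman_test

__all__ = ["SensitivityResult", "ks_shift_threshold", "pooled_bimodality_threshold"]


@dataclass
class SensitivityResult:
    """Detection thresholds over a grid of mean shifts (log-area units)."""

    group: str
    delta_grid: np.ndarray
    detail: pd.DataFrame  # per-delta statistics
    delta_detect: float | None  # smallest detected shift, None if not reached
    criterion: str  # "ks" or "bimodality"
    alpha: float | None = None
    cutoff: float | None = None
    n_boot: int | None = None
    seed: int | None = None

    @property
    def reached(self) -> bool:
        return self.delta_detect is not None


def _shift(sample: AreaSample, delta: float, log_scale: bool) -> AreaSample:
    if log_scale:
        return AreaSample(group=sample.group, areas=sample.areas * np.exp(delta))
    return AreaSample(group=sample.group, areas=sample.areas + delta)


def ks_shift_threshold(
    x: AreaSample,
    increment: float = 0.01,
    max_delta: float = 1.0,
    alpha: float = 0.05,
    log_scale: bool = True,
) -> SensitivityResult:
    """Smallest mean shift at which KS distinguishes shifted from original data.

    Deltas delta = increment, 2*increment, ... up to max_delta; detection is
    KS p < alpha comparing x against x shifted by +delta (log-area units by
    default).  Deterministic: no resampling is involved.
    """
    if x.n < 10:
        raise ValueError("sensitivity analysis needs n >= 10")
    deltas = np.arange(increment, max_delta + increment / 2, increment)
    rows, detect = [], None
    for delta in deltas:
        res = ks_compare(x, _shift(x, float(delta), log_scale))
        rows.append({"delta": float(delta), "D": res.D, "p": res.p})
        if detect is None and res.p < alpha:
            detect = float(delta)
            break
    return SensitivityResult(
        group=x.group,
        delta_grid=deltas,
        detail=pd.DataFrame(rows),
        delta_detect=detect,
        criterion="ks",
        alpha=alpha,
    )


def pooled_bimodality_threshold(
    x: AreaSample,
    increment: float = 0.01,
    max_delta: float = 1.0,
    n_boot: int = 999,
    seed: int = 0,
    cutoff: float = 0.95,
    log_scale: bool = True,
    coarse_factor: int = 5,
) -> SensitivityResult:
    """Smallest mean shift at which the pooled original+shifted sample is bimodal.

    For each delta the original sample is pooled with its shifted copy and
    Silverman's test run at k = 1; detection is multimodality support
    m = 1 - p >= cutoff.  Because each step costs a full bootstrap, the grid
    is first walked at ``coarse_factor`` x increment and then refined at the
    fine increment inside the bracketing interval.
    """
    if x.n < 10:
        raise ValueError("sensitivity analysis needs n >= 10")
    rng = np.random.default_rng(seed)
    logx = x.log_areas
    rows = []

    def support(delta: float) -> float:
        if log_scale:
            pooled = np.concatenate([logx, logx + delta])
        else:
            pooled = np.log(np.concatenate([x.areas, x.areas + delta]))
        p, m, _ = silverman_test(pooled, k=1, n_boot=n_boot, seed=rng)
        rows.append({"delta": float(delta), "p": p, "m": m})
        return m

    deltas = np.arange(increment, max_delta + increment / 2, increment)
    coarse = deltas[coarse_factor - 1 :: coarse_factor]
    if coarse.size == 0 or coarse[-1] != deltas[-1]:
        coarse = np.append(coarse, deltas[-1])
    detect = None
    prev = 0.0
    for delta in coarse:
        if support(float(delta)) >= cutoff:
            fine = deltas[(deltas > prev) & (deltas < delta)]
            detect = float(delta)
            for d in fine:
                if support(float(d)) >= cutoff:
                    detect = float(d)
                    break
            break
        prev = float(delta)
    detail = pd.DataFrame(rows).sort_values("delta").reset_index(drop=True)
    return SensitivityResult(
        group=x.group,
        delta_grid=deltas,
        detail=detail,
        delta_detect=detect,
        criterion="bimodality",
        cutoff=cutoff,
        n_boot=n_boot,
        seed=seed,
    )
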