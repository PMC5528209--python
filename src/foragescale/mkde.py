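"""Movement-based kernel density estimation (biased-random-bridge UDs).

Each movement bout (segment) yields a utilization distribution built by
smoothing along interpolated steps rather than around fixes alone: points are
placed at a fine time step along the straight line between consecutive fixes,
and each carries an isotropic Gaussian kernel whose variance follows the
bridge profile — minimal (hmin^2) at the fixes and largest at mid-step, where
the animal's true position is least constrained:

    h^2(p) = hmin^2 + 4 p (1 - p) D T,   p in (0, 1),

with D a diffusion coefficient (m^2/s) estimated from the bout's own steps
and T the step duration.  Steps longer than Tmax are treated as track
interruptions and skipped.  The 95% isopleth of the resulting UD is taken
cell-wise; its 8-connected components are the foraging patches, whose areas
are the framework's sampling units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import box, mapping
from shapely.ops import unary_union

__all__ = [
    "BRBParams",
    "UDGrid",
    "Patch",
    "PatchSet",
    "estimate_diffusion",
    "build_ud",
    "extract_patches",
]

#: 95% quantile of a chi-square with 2 df: a bivariate Gaussian's 95% isopleth
#: is the disk of squared radius CHI2_95 * sigma^2.
CHI2_95 = 5.991464547107979


@dataclass(frozen=True)
class BRBParams:
    """Biased-random-bridge smoothing parameters.

    hmin: minimum kernel sd (m), the positional smoothing at the fixes
    themselves — keep it a few times the GPS accuracy.  tmax: maximum step
    duration (s) still treated as continuous movement.  tau: interpolation
    time step (s) along each movement step.  cell_size: UD raster resolution
    (m).  diffusion: fixed D (m^2/s), or None to estimate per segment.
    grid_margin_sd: raster padding in units of the largest kernel sd.
    """

    hmin: float = 100.0
    tmax: float = 21_600.0
    tau: float = 720.0
    cell_size: float = 50.0
    diffusion: float | None = None
    grid_margin_sd: float = 5.0

    def __post_init__(self):
        if self.hmin <= 0 or self.tmax <= 0 or self.tau <= 0 or self.cell_size <= 0:
            raise ValueError("hmin, tmax, tau and cell_size must all be positive")

    @classmethod
    def for_fix_interval(cls, fix_interval_s: float, **kw) -> "BRBParams":
        """Defaults scaled to the nominal fix interval: Tmax = 3x, tau = 1/10th."""
        kw.setdefault("tmax", 3.0 * fix_interval_s)
        kw.setdefault("tau", fix_interval_s / 10.0)
        return cls(**kw)


@dataclass
class UDGrid:
    """Raster utilization distribution: probability mass per cell, summing to 1."""

    x0: float  # x of the west edge of column 0
    y0: float  # y of the south edge of row 0
    cell_size: float
    mass: np.ndarray  # (n_y, n_x), row 0 = southmost

    @property
    def shape(self) -> tuple[int, int]:
        return self.mass.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.mass.shape
        xs = self.x0 + self.cell_size * (np.arange(nx) + 0.5)
        ys = self.y0 + self.cell_size * (np.arange(ny) + 0.5)
        return xs, ys

    def to_ascii_raster(self) -> str:
        """ESRI ASCII raster (mass per cell); row order north-to-south."""
        ny, nx = self.mass.shape
        header = (
            f"ncols {nx}\nnrows {ny}\nxllcorner {self.x0:.3f}\n"
            f"yllcorner {self.y0:.3f}\ncellsize {self.cell_size:.3f}\nNODATA_value -9999\n"
        )
        body = "\n".join(
            " ".join(f"{v:.6e}" for v in row) for row in self.mass[::-1]
        )
        return header + body + "\n"


@dataclass
class Patch:
    """One connected component of an isopleth: a foraging patch."""

    polygon: object  # shapely geometry (union of selected cell squares)
    area_m2: float
    track_id: str = ""
    segment: int = -1

    @property
    def area_km2(self) -> float:
        return self.area_m2 / 1e6


@dataclass
class PatchSet:
    """Foraging patches pooled across segments/individuals of one group."""

    patches: list[Patch] = field(default_factory=list)
    species: str = ""
    isopleth: float = 0.95

    def __len__(self) -> int:
        return len(self.patches)

    def __iter__(self):
        return iter(self.patches)

    def extend(self, other: "PatchSet") -> None:
        self.patches.extend(other.patches)

    @property
    def areas_m2(self) -> np.ndarray:
        return np.asarray([p.area_m2 for p in self.patches], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "track_id": [p.track_id for p in self.patches],
                "segment": [p.segment for p in self.patches],
                "area_m2": [p.area_m2 for p in self.patches],
                "area_km2": [p.area_km2 for p in self.patches],
            }
        )

    def to_geojson(self) -> dict:
        feats = [
            {
                "type": "Feature",
                "geometry": mapping(p.polygon),
                "properties": {
                    "track_id": p.track_id,
                    "segment": p.segment,
                    "area_m2": p.area_m2,
                },
            }
            for p in self.patches
        ]
        return {"type": "FeatureCollection", "features": feats}


def estimate_diffusion(xy: np.ndarray, t: np.ndarray, tmax: float = np.inf) -> float:
    """Per-segment diffusion coefficient: median over steps of d^2 / (4 T).

    Only steps with duration <= tmax contribute.  The median is robust to the
    handful of long commuting steps that can sneak into a bout.
    """
    xy = np.asarray(xy, float)
    t = np.asarray(t, float)
    d2 = np.sum(np.diff(xy, axis=0) ** 2, axis=1)
    dt = np.diff(t)
    ok = dt <= tmax
    if not np.any(ok):
        raise ValueError("no steps with duration <= tmax")
    return float(np.median(d2[ok] / (4.0 * dt[ok])))


def build_ud(
    xy: np.ndarray,
    t: np.ndarray,
    params: BRBParams | None = None,
    track_id: str = "",
) -> UDGrid:
    """Biased-random-bridge UD from one segment's fixes.

    Each step of duration T <= Tmax is lined with interpolation points every
    tau seconds; the point at relative position p carries a Gaussian kernel
    of variance hmin^2 + 4 p (1-p) D T and a weight such that the step's
    total weight is proportional to T (time-weighted UD).  Kernels accumulate
    on a regular grid padded to ``grid_margin_sd`` kernel sds and the raster
    is normalized to total mass 1.
    """
    params = params or BRBParams()
    xy = np.asarray(xy, float)
    t = np.asarray(t, float)
    if xy.shape[0] < 2:
        raise ValueError("need at least 2 fixes to build a UD")
    dt = np.diff(t)
    usable = dt <= params.tmax
    if not np.any(usable):
        raise ValueError("every step exceeds Tmax; no continuous movement to smooth")
    d = params.diffusion
    if d is None:
        d = estimate_diffusion(xy, t, params.tmax)

    pts, sds, wts = [], [], []
    for j in np.flatnonzero(usable):
        T = dt[j]
        m = max(int(np.ceil(T / params.tau)), 1)
        # midpoints of m equal time slices: p = (k + 0.5)/m
        p = (np.arange(m) + 0.5) / m
        seg_pts = xy[j] + p[:, None] * (xy[j + 1] - xy[j])
        var = params.hmin**2 + 4.0 * p * (1.0 - p) * d * T
        pts.append(seg_pts)
        sds.append(np.sqrt(var))
        wts.append(np.full(m, T / m))
    pts = np.concatenate(pts)
    sds = np.concatenate(sds)
    wts = np.concatenate(wts)
    wts /= wts.sum()

    margin = params.grid_margin_sd * sds.max()
    cs = params.cell_size
    x0 = np.floor((pts[:, 0].min() - margin) / cs) * cs
    y0 = np.floor((pts[:, 1].min() - margin) / cs) * cs
    nx = int(np.ceil((pts[:, 0].max() + margin - x0) / cs)) + 1
    ny = int(np.ceil((pts[:, 1].max() + margin - y0) / cs)) + 1
    xs = x0 + cs * (np.arange(nx) + 0.5)
    ys = y0 + cs * (np.arange(ny) + 0.5)
    grid = np.zeros((ny, nx))

    # accumulate each kernel only on its local window (+- margin_sd sds)
    for (px, py), sd, w in zip(pts, sds, wts):
        half = params.grid_margin_sd * sd
        i0 = max(int((px - half - x0) / cs), 0)
        i1 = min(int((px + half - x0) / cs) + 1, nx)
        j0 = max(int((py - half - y0) / cs), 0)
        j1 = min(int((py + half - y0) / cs) + 1, ny)
        gx = np.exp(-0.5 * ((xs[i0:i1] - px) / sd) ** 2)
        gy = np.exp(-0.5 * ((ys[j0:j1] - py) / sd) ** 2)
        kern = np.outer(gy, gx)
        tot = kern.sum()
        if tot > 0:
            grid[j0:j1, i0:i1] += w * kern / tot
    grid /= grid.sum()
    return UDGrid(x0=x0, y0=y0, cell_size=cs, mass=grid)


_CONN8 = np.ones((3, 3), dtype=int)


def extract_patches(
    ud: UDGrid,
    isopleth: float = 0.95,
    track_id: str = "",
    segment: int = -1,
    species: str = "",
    build_polygons: bool = True,
) -> PatchSet:
    """Patches = 8-connected components of the isopleth cell set.

    The isopleth set is the smallest collection of highest-density cells whose
    cumulative mass reaches the isopleth fraction (ties broken by row-major
    cell index).  Patch area is cell count x cell area; the polygon is the
    union of the selected cell squares.
    """
    if not (0.0 < isopleth < 1.0):
        raise ValueError("isopleth must be in (0, 1)")
    flat = ud.mass.ravel()
    order = np.lexsort((np.arange(flat.size), -flat))
    csum = np.cumsum(flat[order])
    n_sel = int(np.searchsorted(csum, isopleth, side="left")) + 1
    selected = np.zeros(flat.size, dtype=bool)
    selected[order[:n_sel]] = True
    selected = selected.reshape(ud.mass.shape)

    labels, n_comp = ndimage.label(selected, structure=_CONN8)
    cell_area = ud.cell_size**2
    patches = []
    for comp in range(1, n_comp + 1):
        jj, ii = np.nonzero(labels == comp)
        poly = None
        if build_polygons:
            cells = [
                box(
                    ud.x0 + i * ud.cell_size,
                    ud.y0 + j * ud.cell_size,
                    ud.x0 + (i + 1) * ud.cell_size,
                    ud.y0 + (j + 1) * ud.cell_size,
                )
                for j, i in zip(jj, ii)
            ]
            poly = unary_union(cells)
        patches.append(
            Patch(
                polygon=poly,
                area_m2=float(jj.size * cell_area),
                track_id=track_id,
                segment=segment,
            )
        )
    return PatchSet(patches=patches, species=species, isopleth=isopleth)


def isopleth_mass(ud: UDGrid, isopleth: float = 0.95) -> float:
    """Total mass of the selected isopleth cells (for diagnostics/tests)."""
    flat = np.sort(ud.mass.ravel())[::-1]
    csum = np.cumsum(flat)
    n_sel = int(np.searchsorted(csum, isopleth, side="left")) + 1
    return float(csum[n_sel - 1])
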