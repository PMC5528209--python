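# foragescale

Quantifying the spatial scales at which tracked animals forage.

Movement ecologists often assume that animals of different body masses use
landscapes at different spatial scales. Testing that assumption needs a way
to measure, from GPS telemetry alone, the sizes of the patches an animal
actually forages in — and to compare the resulting patch-size distributions
between species. `foragescale` implements that framework end to end:

1. **First-passage time (FPT)** — at every fix, the time to cross a circle of
   radius *r* centered on that fix, for *r* on a grid (default 100–10,000 m
   in 80-m steps). The variance of log FPT peaks at the radius where
   movements are most clustered; averaging the curves over individuals and
   taking the peak gives a common population radius *r*<sub>pop</sub> per
   species.
2. **Penalized-contrast segmentation** (Lavielle) — the FPT series at
   *r*<sub>pop</sub> is split into homogeneous movement bouts by exact
   dynamic programming over segmentations with a minimum bout length
   *L*<sub>min</sub>; the number of bouts *K*<sub>opt</sub> is the largest
   *K* whose standardized-contrast second derivative exceeds *S* = 0.75.
3. **Movement-based kernel density estimation** (biased random bridges) —
   each bout's fixes produce a utilization distribution smoothed along
   interpolated steps with bridge-shaped kernel variance
   *h*²(*p*) = *h*²<sub>min</sub> + 4 *p*(1−*p*) *D* *T*. The 8-connected
   components of the 95% isopleth are the **foraging patches**; their areas
   are the sampling units.
4. **Statistics** — two-sample Kolmogorov–Smirnov comparison of log patch
   areas between species, and Silverman's smoothed-bootstrap
   critical-bandwidth test scanned over 1–30 modes for multimodality
   (declared at multimodality support *m* = 1 − *p* ≥ 0.95), plus a
   sensitivity analysis that finds the smallest mean log-area shift the KS
   and bimodality tests can detect.

A two-mode (area-restricted search / commuting) correlated-random-walk
simulator with known patch geometry provides ground truth for every stage,
and the published deployment-summary table for the two study species
(Egyptian Goose, 2-h fixes; Red-billed Teal, 4-h fixes) ships in
`foragescale.datasets`.

## Worked example

```python
import numpy as np
from foragescale import (
    ForagerConfig, ForagingScaleAnalysis, FrameworkConfig,
    RadiusGrid, SpeciesConfig, simulate_forager,
)

def make_group(name, seeds):
    tracks = []
    for s in seeds:
        t, _ = simulate_forager(ForagerConfig(patch_radius=500.0, seed=s))
        t.species = name
        tracks.append(t)
    return tracks

tracks = {"geese": make_group("geese", [1, 2, 3]),
          "teal": make_group("teal", [11, 12, 13])}
cfg = FrameworkConfig(
    species={g: SpeciesConfig(radius_grid=RadiusGrid(100, 5000, 80), lmin=12)
             for g in tracks},
    n_boot=499, seed=7,
)
results = ForagingScaleAnalysis(tracks, cfg).fit()
print(results.summary())
```

prints

```
Foraging-scale analysis
============================================================
species  n_individuals  r_pop_m  n_segments  n_patches  mean_log_area  sd_log_area
  geese              3    980.0          16         23      13.943644     1.543782
   teal              3    980.0          13         31      12.998152     2.451926

Two-sample KS on log patch areas (geese vs teal): D = 0.2146, p = 0.519 (n = 23, 31)
geese: max multimodality support m = 0.998 at k = 4 modes (multimodal at the 0.95 cut-off)
teal: max multimodality support m = 0.998 at k = 2 modes (multimodal at the 0.95 cut-off)
```

Both simulated groups forage in 500-m-radius patches, and the framework
recovers that: the variance-of-log-FPT peak lands at 980 m for both (the
radius–diameter band of a 500-m patch), and the KS test finds no difference
between their patch-area distributions (D = 0.21, p = 0.52) — the designed
null outcome. The high multimodality support reflects the strong
discreteness of small cell-quantized patch areas at these sample sizes (see
`docs/methods.md`).

`results.patch_table()`, `results.scale_table()`, `results.plot_density()`
and `results.save(outdir)` expose the underlying artifacts; the same
pipeline is scriptable via the `foragescale` CLI (`simulate`, `summarize`,
`fpt`, `segment`, `patches`, `compare`, `modality`, `sensitivity`, `run`).

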