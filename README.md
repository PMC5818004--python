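# isletmorph

Quantitative image analysis of pancreatic islet morphogenesis in
zebrafish larvae.

Secondary islets assemble in the larval pancreatic tail when
duct-associated endocrine progenitors differentiate, extend fine actin
protrusions (filopodia, < 2 µm diameter), and migrate into clusters.
`isletmorph` implements the measurements this process calls for, end to
end, on multi-channel fluorescence stacks:

- **Automated secondary-islet quantitation** — after a single user
  interaction (a polyline splitting the pancreatic head from the tail),
  the exocrine pancreas is segmented from the red channel (Gaussian
  smoothing σ = 0.5 µm, white-top-hat local background subtraction,
  thresholding, largest connected component on the tail side), green
  channel islet objects are extracted inside it (3D 26-connected
  components), objects below a minimum volume (default 100 µm³) are
  discarded, and a per-islet volume table plus QC montages are written.
  Batch mode processes whole directories.
- **Convex-hull clustering statistic** — cell coalescence is quantitated
  as the volume *V(t)* of the convex 3D polytope enclosing the tracked
  cell centres; *V(t)* decreases as cells come into closer proximity.
  Frame-to-frame tracking uses global minimum-cost (Hungarian) matching
  with a maximum-displacement gate.
- **Single-cell morphometry** — per-frame area *A*, perimeter *P*,
  circularity 4π·A/P² and solidity *A*/*A*<sub>hull</sub> of cell masks in
  physical units. Solidity is 1 for a round cell and decreases in
  proportion to protrusion formation; a morphological opening at the
  protrusion diameter defines the cell body for membrane-motility
  (expansion/retraction) analysis.
- **Filopodia kinetics** — backbone tracing of thin protrusions per
  frame (skeleton geodesics, with manual tip annotations taking
  precedence), instantaneous extension/retraction rates ΔL/Δt from true
  frame timestamps, maximal lengths, and cohort summaries (fraction of
  maxima below 9 µm, count above 15 µm).
- **Group statistics** — unpaired t-tests computable straight from
  printed mean ± s.d. summaries (pooled and Welch), Mann–Whitney U
  (exact for small samples), Kruskal–Wallis with Dunn's post-hoc, and
  one-way ANOVA with Dunnett's many-to-one comparisons.
- **Synthetic scenes** — a ground-truthed generator (ellipsoidal
  exocrine blob, spherical endocrine cells, Gaussian PSF, Poisson +
  Gaussian noise, attraction-plus-diffusion motion, piecewise-linear
  filopodium programs) so that every stage is validated against known
  truth without external data.

## Worked example

Segment a rendered two-channel stack and test a printed summary:

```python
import numpy as np
from isletmorph import (SceneSpec, render_scene, HeadTailROI,
                        delineate_pancreas, segment_islets,
                        GroupSummary, t_test_from_summary)

spec = SceneSpec(grid_shape=(32, 80, 80), voxel_size=(1.0, 0.5, 0.5),
                 pancreas_center=(16, 20, 20), pancreas_semiaxes=(12, 16, 16),
                 n_cells=2, seed=7)
centers = np.array([[16.0, 14.0, 20.0], [16.0, 28.0, 22.0]])
red, green, truth = render_scene(spec, centers=centers, radii=np.array([4.0, 2.5]))

roi = HeadTailROI(np.array([[0.0, 0.1], [100.0, 0.1]]), tail_side=1)
pancreas = delineate_pancreas(red, roi)
islets = segment_islets(green, pancreas.mask, min_volume=100.0)
print(len(islets), round(islets[0].volume, 1))

res = t_test_from_summary(GroupSummary("CTL", 16, 17.0, 4.0),
                          GroupSummary("LY", 14, 5.0, 2.0), variant="welch")
print(f"t = {res.statistic:.2f}, p = {res.p_value:.2e}")
```

prints

```
1 293.2
t = 10.58, p = 3.07e-10
```

The scene contains spheres of true volume ≈ 268 µm³ (r = 4 µm) and
≈ 65 µm³ (r = 2.5 µm); only the large one survives the 100 µm³ object
filter, and its recovered volume (293.2 µm³, measured through PSF blur,
shot noise and automatic thresholding) lands within ~10% of the analytic
value. The summary t-test shows a
beta-cell count of 17 ± 4 (n = 16) versus 5 ± 2 (n = 14) is different at
p < 0.0001.

The same pipeline is scriptable from the shell:

```bash
isletmorph segment --stack fish1.tif --roi fish1.roi.json --min-volume 100
isletmorph stats --data counts_summary.csv --design t-summary
```

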