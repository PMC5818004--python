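# Methods

This note documents the models and procedures `isletmorph` implements,
the parameters that matter, the numerical choices behind them, and what
the synthetic validation does and does not establish.

## Coordinate and unit conventions

Arrays are indexed `(z, y, x)` (2D: `(y, x)`); every physical quantity
is in micrometres and minutes; the centre of voxel `i` sits at
`(i + 0.5) · voxel_size`. All scale parameters (smoothing σ, background
radius, spot diameter, opening diameter) are specified in µm and
converted per axis, so anisotropic confocal stacks (z-step larger than
the xy pixel) are handled correctly: volumes are voxel counts times the
physical voxel volume, never voxel counts alone. If the voxel step
exceeds the object scale the pipeline warns and proceeds; it does not
try to correct for it.

## Automated islet quantitation

The pipeline mirrors the batch workflow used for secondary-islet
assays: one interactive input (a polyline ROI separating pancreatic
head from tail, stored as JSON so batch runs need no interaction), then
fully automatic processing.

1. *Pancreas delineation* (red/exocrine channel): Gaussian smoothing
   (σ = 0.5 µm default), white-top-hat local background subtraction
   (radius 10 µm default — a standard rolling-ball-scale choice;
   configurable), threshold, restrict to the tail side of the ROI, keep
   the largest 26-connected component. An image with no foreground
   yields an empty mask with a flag rather than an exception, so batch
   runs continue.
2. *Islet segmentation* (green/endocrine channel): the same smoothing
   and background subtraction, threshold inside the pancreas mask, 3D
   connected components (26-connectivity; stated because connectivity
   changes object counts), discard components below `min_volume`
   (default 100 µm³).
3. *Reporting*: one CSV row per islet (sample, group, label, volume,
   centroid, voxel count, mean intensity), a JSON run log listing every
   sample including those with zero objects, and per-sample pre/post
   montage PNGs for visual QC.

Thresholds default to Otsu's method computed on the relevant region
(tail side, or in-mask voxels), with a fixed-absolute-threshold
override for the "same settings applied uniformly to all images" mode.
The exact thresholding recipe of the original batch tool is not public;
Otsu-with-override is this package's declared substitute and is exposed
in the configuration so either behaviour is reproducible.

*Spot counting* (cell counts from nuclear labels) is
Laplacian-of-Gaussian blob detection at σ = d/(2√2) — the scale whose
LoG response peaks for a ball of the configured diameter d (default
5 µm) — with local maxima separated by at least d/2, restricted to a
mask, then filtered on centre intensity. This reproduces
"spot diameter" semantics without any proprietary internals.

## Convex-hull clustering statistic

Cell coalescence is summarized per frame as the volume of the convex
hull of the observed cell centres (`scipy.spatial.ConvexHull`).
Degenerate configurations — fewer than four cells, or affinely
dependent centres (rank checked by SVD at 1e-9 relative tolerance) —
report volume 0 with an explicit flag, and every frame also carries the
best-fit-plane 2D hull area and the maximum pairwise distance as
fallback columns, so low-n series remain informative rather than
silently zero.

Tracking is global minimum-cost bipartite matching per consecutive
frame pair (Hungarian algorithm on the Euclidean cost matrix) with
links longer than `max_displacement` (default 10 µm per frame)
forbidden; unmatched detections start new tracks. Frames missing from a
track are flagged and the statistic is computed on the cells actually
observed — no interpolation, to avoid inventing positions. Frame times
come from metadata and are not assumed uniform. Division-aware lineage
tracking is deliberately out of scope (the tracked endocrine cells are
post-mitotic).

Under the zero-noise attraction motion model each centre's offset from
the centroid shrinks by the factor `(1 − k·dt)` per Euler step, so the
hull volume contracts by exactly `(1 − k·dt)³` per frame — a closed
form the implementation is tested against at 1e-6 relative tolerance.

## Single-cell morphometry

Per frame and cell: area = pixel count × pixel area; perimeter = length
of the sub-pixel iso-contour polygon after Douglas-Peucker
simplification at 1.5 px tolerance (a raw marching-squares contour is a
staircase that overestimates smooth perimeters by ~5-7% and would bias
circularity low; the simplified polygon preserves genuine corners while
tracking smooth arcs to well under a percent at typical cell sizes);
circularity = 4πA/P² capped at 1; solidity = area / convex-hull area
(pixel-count convention via the convex hull image). Both ratios are
dimensionless and scale-invariant; solidity is 1 for convex shapes and
decreases in proportion to protrusion formation, which is what makes it
the workhorse readout for filopodia-forming cells.

The membrane-motility analysis separates fine protrusions from bulk
membrane movement: a morphological opening with a disk of the
protrusion diameter (default 2 µm, the upper bound of filopodium width)
defines the cell body; consecutive-frame bodies are compared to give
expansion area (gained), retraction area (lost), and a motility index
normalizing their sum by the mean body area. Raw areas and the
normalized index are both emitted because either normalization
convention is defensible.

Group tables pool all frames of all cells per treatment group — the
pooled-time-points design used for the group tests. Pooled frames of
one cell are not independent observations; the table keeps `cell_id`
so per-cell means are one `groupby` away, and this caveat is stated
rather than silently "fixed".

## Filopodia kinetics

A filopodium is traced per frame as the skeleton backbone of the
protrusion-only mask (the cell body, obtained by opening at the
protrusion diameter and dilated one pixel to clear rasterization
residue, is excluded). Length = (gap from the anchored base point to
the nearest skeleton pixel) + (longest Dijkstra geodesic along the
8-connected skeleton, measured on the Douglas-Peucker-simplified path
so the digital metric does not inflate curved backbones) + (the local
half-width at the far end, restoring the endpoint retraction inherent
to skeletonization). Branched skeletons follow the longest
base-to-endpoint path; branch counts are logged. Manual tip annotations
override automatic tracing frame by frame. On straight and
quarter-circle fixtures the traced length is accurate to ~0.2 µm at
0.1-0.2 µm pixels, and a curved backbone correctly measures its arc
length rather than the base-to-tip chord.

Instantaneous rates are consecutive-frame ΔL/Δt with the true
timestamps and no smoothing — at 12-20 s sampling this is a
near-derivative, and it is the smallest-commitment definition of
"instantaneous". Extension/retraction classification uses the sign of
ΔL with a ±0.1 µm dead-band per frame pair (configurable, off for
exact-recovery checks) to suppress segmentation jitter. Mean extension
is averaged over extension intervals only, mean retraction over the
magnitudes of retraction intervals. Cohort summaries report the
fraction of maximal lengths below 9 µm and the count above 15 µm, plus
the empirical CDF.

## Group statistics

- Unpaired two-sample t from summaries (n, mean, sd): closed-form
  pooled-variance and Welch variants, identical (to 1e-12) to the
  raw-data test when data match the summaries exactly. Both variants
  are always computable because published group comparisons rarely say
  which was used.
- Mann-Whitney U: exact null distribution for small untied samples,
  normal approximation with tie correction otherwise. One-tailed use
  requires the direction to be stated explicitly; a one-tailed p ≥ 0.5
  (effect opposite to the declared direction) is flagged.
- Kruskal-Wallis + Dunn: Dunn's z uses the rank variance with tie
  correction; multiplicity is Bonferroni over the tested pairs, the
  common reading of "Dunn's multiple comparison test".
- One-way ANOVA + Dunnett: Dunnett p-values from the multivariate-t
  reference distribution (seeded quadrature in `scipy.stats.dunnett`,
  reproducible for a fixed seed). All-identical groups make F undefined
  (zero within-group variance) and are flagged, not raised. Null
  simulations in the test suite confirm ~5% type-I error for the
  omnibus tests and familywise control for the post-hocs.

## Synthetic data: what it emulates and what it does not

The generator produces: (a) an ellipsoidal "exocrine pancreas" blob in
the red channel containing spherical "endocrine cells" in the green
channel, blurred by an anisotropic Gaussian PSF and corrupted by
Poisson shot noise plus additive Gaussian read noise (the standard
fluorescence model — the original imaging noise was never
characterized, so this is a generic stand-in); (b) centre trajectories
under attraction-plus-diffusion motion (Euler steps toward the group
centroid plus isotropic Gaussian noise); (c) 2D disk-bodied cells with
radial protrusions, star polygons with printed vertex lists for
hull-area oracles, and thin-filopodium mask series whose lengths follow
piecewise-linear programs; and (d) length-trace cohorts with known
per-filopodium extension/retraction speeds (drawn around cohort means
of 3.2 and 2.9 µm/min with 1.0 µm/min between-filopodium spread),
within-trace rate noise of 0.4 µm/min (≈ 0.1 µm of length jitter per
15 s frame, the scale the dead-band is designed to suppress), and
lognormal maximal lengths placing ~75% of maxima below 9 µm with a
small tail beyond 15 µm. Cohort ground truth records both the drawn
parameters and the realized per-phase rates (phase-final steps are
truncated at the length bounds, so realized rates are the exact truth
for recovery checks).

Intensity levels are free parameters: no published intensity statistics
exist for these channels, so amplitudes were fixed once at
signal-to-noise ratios where segmentation is comfortable but not
trivial.

What passing tests show: geometric correctness (hull volumes against
closed forms, Monte-Carlo and Delaunay oracles; sphere volumes within
the surface-shell voxelization bound, converging with resolution;
solidity against shoelace polygon oracles), statistical correctness
(exact enumeration, null calibration), pipeline determinism, and that
the qualitative phenotype direction — fewer/shorter protrusions read
out as higher solidity, higher circularity, lower area — is recovered
end to end. What they do not show: performance on real microscopy,
where debris, intensity inhomogeneity, touching islets, out-of-focus
light and registration errors are the dominant failure modes; none of
these are modelled. Absolute volumes from real stacks remain
settings-dependent (threshold choice shifts boundaries by a voxel
shell), which is why consistent settings across groups, not absolute
accuracy, is the design target — comparisons between groups are the
supported readout.

## Problem sizes used in validation

The shipped validation uses stacks up to 64³-80² ×32 voxels, 20-point
Monte-Carlo hull checks at 3×10⁵ samples each, 1000-replicate null
simulations for the rank tests and Dunnett, and cohorts of 41
filopodium traces — sizes chosen so the full suite and the acceptance
script each complete in seconds to a few minutes on one core while
keeping every statistical check adequately powered.
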