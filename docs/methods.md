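# Methods

## Detection model

Puncta are operationally defined as connected sets of pixels whose
intensity, in one analysis channel of an 8-bit image, is at or above a
user-chosen floor `t_min`.  "At or above" is inclusive (`>= t`), so a
sweep starting at 255 can seed saturated pixels.  The detector runs one
round per threshold from `t_start` (default 255) down to `t_min` in
decrements of `step` (default 1); the final round at exactly `t_min` is
always executed even when the step overshoots it.  Within a round:

1. *Candidates* are the unassigned in-region pixels with intensity at or
   above the current threshold.
2. *Expansion to a fixed point.*  Any candidate adjacent to an assigned
   pixel joins that pixel's punctum.  When a candidate touches members of
   two or more puncta it joins the punctum of the brightest adjacent
   member pixel, ties broken toward the lowest label.  Expansion is
   re-evaluated in simultaneous waves until nothing changes, so pixels
   assigned in one wave recruit their neighbours in the next.  The
   brightest-neighbour rule is a steepest-ascent heuristic: it places the
   boundary between touching puncta along the intensity ridge, which is
   what keeps adjacent puncta distinct.
3. *Formation.*  The remaining candidates are grouped into connected
   components; each component of at least `min_size` pixels (default 4)
   becomes a new punctum.  Smaller components are left unassigned and are
   ordinary candidates again in every later round — they are not objects
   and carry no state.

Puncta are never merged after formation: if two grown puncta come into
contact, the contested pixels are divided by the expansion rule and both
objects persist.  Adjacency defaults to 8-connectivity for both expansion
and formation (4-connectivity is available).  Labels are assigned in
row-major order of each new component's first pixel, and all tie-breaks
are fixed, so the full output (labels, pixel sets, statistics) is a
deterministic function of the inputs.

*Exact round skipping.*  A round whose threshold interval contains no
in-region pixel value cannot change the state: the candidate set is the
one the previous round already drove to a fixed point, and formation saw
the same components.  The implementation therefore skips such rounds.
This is an identity, not an approximation — with `step` 1 the result is
exactly the full 255→`t_min` schedule's.

Because expansion is exhaustive within each round, results are unchanged
under coarser `step` values whenever the coarser schedule still visits
the thresholds at which new components first reach `min_size` pixels;
with `step` 1 this holds by construction.

### Behaviour guarantees checked by the test suite

- With `t_start = t_min` the sweep degenerates to plain single-threshold
  connected-component detection (the classical baseline, implemented
  independently via `scipy.ndimage.label`): identical pixel-set
  partitions on a 100-image random suite.
- Every sweep punctum is a subset of exactly one single-threshold
  component at `t_min`, and the sweep never reports fewer puncta than the
  single threshold does.
- Integrated intensity is an exact integer sum; average intensity times
  area returns it exactly; no member pixel is below `t_min`; no punctum
  is smaller than `min_size`.
- Raising `t_min` never increases the total assigned pixel count.

## Marker filter

A punctum is attributed to the measured (transfected) neuron when it
overlaps the cell-fill/marker channel.  The filter keeps a punctum iff
its overlap fraction (pixels with marker intensity ≥ `marker_threshold`,
divided by punctum area) is positive and at least
`min_overlap_fraction`.  The default `min_overlap_fraction` of 0 means
any single overlapping pixel suffices — the weakest defensible reading of
"must overlap the marker" — and stricter fractions are configurable.

## Regions and geometry

Vertices are `(row, col)` floats in 0-based pixel coordinates; the pixel
at `(r, c)` has its center at exactly `(r, c)`.  A pixel belongs to a
polygon iff its center lies strictly inside (even-odd rule); centers
exactly on the boundary are excluded.  Rasterization is vectorized
through shapely and is tested against an exhaustive ray-crossing oracle.

Fixed-width dendrite bands buffer the centerline by `half_width` with
round joins and round end caps (shapely `buffer`, 16 segments per
quadrant).  `half_width_um` in ROI sidecars is physical and is converted
to pixels with the batch calibration.  Dendrite length is the centerline
arc length times `pixel_size`; densities always use this length, not the
band area.

Detection inside a region clips candidates at the mask boundary: a blob
straddling the boundary contributes only its in-mask pixels.  Fixtures
for exact-count tests therefore keep blobs interior to the band.

## Spine morphometry

Spines are landmark-based: base and tip points (length = Euclidean
distance × `pixel_size`), optional head and neck point pairs (widths).
Classification applies four rules in fixed order — filopodia, mushroom,
stubby, thin — so every measurement triple maps to exactly one class:

| rule | condition | default threshold |
|---|---|---|
| filopodia | head/neck ratio below cutoff AND long | ratio < 1.2, length ≥ 2.0 µm |
| mushroom | pronounced head | head/neck ≥ 1.5 |
| stubby | about as long as wide | length/head ≤ 1.0 |
| thin | otherwise | — |

No consensus quantitative criteria exist in the literature; these
defaults are this package's own, chosen to match the conventional verbal
descriptions of the four classes, and are deliberately configurable
(`SpineRules`).  They are echoed into every run's metadata so exported
results are self-describing.  Degenerate measurements are resolved
conservatively: a missing neck with a large head (≥ 0.6 µm by default)
still counts as mushroom; a long protrusion with no measured head counts
as filopodia; zero neck width gives an unbounded head/neck ratio
(mushroom).  Manual class labels always survive re-classification.

## Aggregation and export

The dendrite is the statistical unit.  Group statistics are unweighted
mean ± SD across the dendrites of a category (sample SD, ddof = 1; a
single-dendrite group reports SD 0).  The pooled ratio
Σcount/Σlength differs from the mean of per-dendrite densities when
lengths differ; the exported group value is the per-dendrite mean, and
the per-dendrite rows are always exported so either statistic can be
recomputed.  Two intensity summaries are exported per dendrite — the mean
over puncta of average intensity, and the mean of integrated intensity —
because "puncta intensity" is used for both in practice.

Densities are reported per µm and per 10 µm.  With the default
uncalibrated `pixel_size` of 1.0 the same columns are per pixel and per
10 pixels; a warning notes this.  TSV files use UTF-8, "." decimals and
Python's shortest-round-trip float repr, so re-parsing reproduces the
in-memory doubles exactly (verified in tests).  Generic-region intensity
measurements are recorded in `run_metadata.json`.

## Synthetic fixtures

The generator renders isotropic 2D Gaussian blobs on a flat background:
`value = clip(round(background + Σ A·exp(−d²/2σ²) + noise), 0, 255)`,
with optional bounded uniform integer noise in `[−k, k]` and an optional
filled marker polygon (rendered at 255 in a separate channel).  All
randomness flows through an explicit per-spec seed; there is no global
RNG state.

Whether two blobs merge at a threshold is governed by their *saddle*, the
minimum of the continuous noiseless field along the segment between the
peaks (sampled at 513 points).  `two_blob_merge_case` certifies its
expected counts before returning: the saddle must clear `t_min` by at
least one intensity unit (rounding margin), stay at least one unit below
the lower peak, and the rendered noiseless image must pass an independent
connected-component check (one ≥4-pixel component at `t_min`; two at
some higher threshold).  The discrete check matters because at small
separations a dim peak may never own four isolated pixels even though the
continuous saddle lies below it — such parameter combinations are
reported as infeasible rather than given wrong expectations.
Well-separated pairs (saddle below `t_min` with margin) are returned as
control cases expecting two puncta from both detectors.

`separated_fixture_spec` builds multi-blob images that are recoverable by
construction under noise: every pairwise saddle sits below `t_min` by
more than the noise amplitude plus one, and every blob's amplitude is
large enough that the four nearest neighbours of its peak clear `t_min`
under worst-case noise.  Default study conditions for the recovery suite:
5–12 blobs per 192×192 image, amplitudes in [120, 250] (floor + 50
margin), σ in [1.2, 2.2] px, uniform noise ±4, `t_min` 70 — amplitudes
and floor sit in the conventional working range for 8-bit confocal data
thresholded at ~70, and the noise bound keeps ground truth exact so
recovery failures indicate algorithm defects, not fixture ambiguity.

What the fixtures do *not* emulate: dendritic shaft autofluorescence,
anisotropic or overlapping puncta shapes beyond Gaussian sums, shot-noise
statistics, uneven illumination, or spine-shaped image content (spines
enter as landmark coordinates only).  Passing tests therefore demonstrate
the algorithmic contracts — splitting, counting, intensity bookkeeping,
geometry, reproducibility — not biological detection accuracy on real
tissue, which remains threshold- and staining-dependent.

## Problem sizes

The validation suites use 100 random 256×256 images (5–30 blobs) for the
equivalence/containment/intensity checks, a 600-combination parameter
grid (~290 feasible cases) for close-pair splitting, 100 noisy 192×192
images for recovery, 50 random convex polygons for the geometry oracle,
and 5-image batches for reproducibility; together they run in about two
minutes on one CPU, and the acceptance script repeats the same
computations from a command-line seed.

## Known limitations

- The sweep is O(rounds × image area) in the worst case; very large
  images with many distinct intensity levels pay for each level present.
- No automatic threshold selection; `t_min` is a scientific input, as in
  manual practice.
- Freehand polygons must be simple; self-intersecting outlines are
  rejected rather than repaired.
- GIF input is accepted through the generic reader but untested against
  palette quirks; TIFF or PNG are recommended.
- 16-bit sources are rescaled by container depth (65535 → 255), not by
  data range, to keep thresholds comparable across a batch; data
  acquired far below full scale will occupy few 8-bit levels.
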