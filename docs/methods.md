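# Methods

## The quantification model

A confocal acquisition of one scan site is an ordered sequence of `n`
equally sized grayscale planes (canonically `n = 10`). The pipeline treats
counting as a strictly 2-D problem per substack: the stack is partitioned
into contiguous plane intervals, each interval is collapsed to a single
projection image, each projection is segmented independently, and a
rule-based post-processing pass reconciles the per-substack mask lists into
one cell count. There is no volumetric segmentation and no tracking of
nuclei across non-adjacent substacks; a nucleus is assumed to appear in at
most a short run of consecutive substacks.

All intensities live on the 8-bit scale. 16-bit acquisitions are
down-scaled on load by integer division by 257 (0 → 0, 65535 → 255,
monotone and idempotent); the intensity thresholds below are *defined* on
the 8-bit scale and are never scaled up. Coordinates are row-major,
origin top-left, 0-based `(row, col)` everywhere.

## Projection and partitioning

Six per-pixel reductions are available: maximum, minimum, mean, median,
population standard deviation (divisor `n`), and sum. Mean, median and
standard deviation are rounded half-up to integers; the median of an even
plane count is the rounded average of the two middle values. Every result
is clipped to [0, 255]: in particular the sum projection **saturates**
rather than rescaling. This is deliberate — the downstream visibility (16)
and brightness (127) rules are 8-bit concepts, and rescaling would move
real signal below them. Users who project many high-intensity planes with
`sum` should expect saturation and are told so here.

Partitioning schemes: `complete` (one interval), `split5` (width-5
intervals) and `split2` (width-2 intervals). A plane count that is not a
multiple of the width produces a shorter final interval and a warning
rather than an error, since real scans occasionally drop planes.

## Segmentation backends

A backend is a pure function of `(image, params)` returning an integer
label map; identical inputs must give identical outputs. Labels are
canonically renumbered 1..k in raster order of each object's
topmost-leftmost pixel so mask lists are comparable across runs and
rotations.

**Reference backend.** Li minimum cross-entropy threshold → 8-connected
components → marker-based watershed splitting of fused components. Two
numerical choices matter:

* *Initial guess for Li.* The iteration is started from the intensity
  midrange, not the image mean: on sparse images (a few bright nuclei on a
  large dark background) the mean lies inside the noise floor and the
  iteration converges to a split of the background noise. Additionally, an
  image whose maximum is below 16 — the first intensity distinguishable
  from black — is treated as containing no segmentable signal and yields an
  empty label map; without this guard, a substack that happens to contain
  no nuclei gets its noise thresholded into hundreds of spurious objects.
* *Watershed markers.* Markers are the connected plateau regions of the
  regional maxima of the Euclidean distance transform; within one
  component, plateaus whose centroids lie closer than a minimum separation
  (default 5 px) are merged into one marker. A single elongated object
  (whose distance-transform ridge is one connected plateau) is therefore
  never shattered, while a dumbbell of two fused nuclei (two separate
  maxima) is split in two. Point-wise peak pickers were rejected because a
  flat ridge returns one peak per sampling position and fragments bars and
  strands. The construction is purely morphological, hence deterministic
  and equivariant under 90° rotation; the only residual asymmetry is the
  flood-order tie-break on the watershed dividing line, which can move the
  one-pixel boundary between two *split* fragments but never changes the
  number of objects. Object counts are therefore exactly invariant under
  90° rotation, and label maps are exactly equivariant whenever no split is
  involved.
* *Minimum object size.* Connected components smaller than 5 px are
  discarded before labeling, as in most practical segmenters; this also
  keeps the fixed-low-threshold mode (below) free of stray single-pixel
  noise components.

A numeric `threshold` backend parameter replaces Li with a fixed cut. The
benchmark presets containing dim structures use this (threshold 6) because
a threshold-based segmenter with an automatic global threshold cannot, by
construction, detect structures dimmer than the threshold — whereas the
invisibility rule exists precisely because learned segmenters over-detect.
The fixed low threshold emulates that over-detection deterministically.

**Conventional comparator.** The same thresholding, then binary watershed,
then particle analysis: keep objects with area ≥ 20 px² and Crofton-type
circularity `4πA/P²` (clipped at 1.0, where discrete perimeter estimates
overshoot) inside a configurable window, default [0, 1]. It deliberately
has no double-count handling, no elimination rules and no block
estimation — it is the baseline the rule-based pipeline is compared
against.

**Cellpose adapter.** A thin optional pass-through (cytoplasm-style model,
flow threshold 0.6, mask threshold 0.0 by default). It is never exercised
by the test suite, which must run without model downloads.

## Post-processing rules

Stages run in fixed order; a mask eliminated by an earlier stage is not
considered by later ones (precedence: double_counted > small > invisible >
big). All rule intensities are read from the substack projection the mask
was segmented on.

1. **Double-count elimination.** For each adjacent substack pair, in
   ascending order, overlapping mask pairs are examined in descending
   shared-area order. The overlap percent is
   `100·|A∩B| / min(|A|,|B|)` — the smaller-mask denominator makes a fully
   contained nucleus score 100 % and pairs naturally with eliminating the
   smaller member; intersection-over-union is available but non-default.
   Strictly above the threshold (default 60 %), the smaller mask is marked
   `double_counted` (area tie: the copy from the higher substack goes).
   A marked mask participates in no further comparisons, which stops
   eliminations cascading along runs of ≥3 substacks: a nucleus spanning
   three substacks keeps its first and third copies (2 counts). This
   conservative chain behavior is a documented consequence of the
   exclusion rule; spans of more than two substacks are rare at the
   canonical 2-plane substack width. Setting the threshold above 100
   disables the stage, since no overlap percent can strictly exceed 100.
2. **Small nuclei**: `area < small_nucleus_area_limit` (default 100 px),
   strictly — a 100 px mask is kept.
3. **Invisible nuclei**: strictly more than 50 % of mask pixels with
   intensity strictly below the visibility limit (default 16) — a pixel at
   16 is visible, a mask with exactly half its pixels dark is kept. The
   50 % fraction is part of the rule definition and not configurable.
4. **Cell blocks**: `area > big_nucleus_area_limit` AND strictly more than
   50 % of pixels strictly brighter than 127. The block's cell count is
   `area / average_nucleus_area`, rounded half-up, floored at 1. The
   average nucleus area default is 400 px; the big-nucleus limit default is
   800 px = 2 × the average area, chosen so a block must plausibly contain
   at least two average nuclei — it is a package choice and configurable.
   Rounding half-up was chosen among the unstated alternatives (floor,
   truncate) and is pinned by tests.

The sequence bookkeeping enforces three invariants: status counts sum to
the raw mask count; `removed = double_counted + small + invisible`;
`final = accepted + Σ block estimates`.

## Synthetic benchmark generator

The generator renders what the pipeline is designed for, reduced to its
analytically tractable core: bright filled disks (radius 11 px ≈ 380 px
projected area, near the 400 px average-nucleus calibration) on a dark
background, each spanning a contiguous plane interval, with seeded additive
Gaussian noise (sd 2 on the 8-bit scale — small relative to the
signal-background contrast) and byte-identical output per seed. Disks were
chosen over ellipses because their rasterized areas are known exactly from
the spec, which is what makes the ground truth computable without touching
pixels: expected raw counts come from interval overlap between each
nucleus's Z-span and the partition intervals, expected final counts from
applying the post-processing rules to the geometric areas and projected
peak intensities.

Presets (image 384×384, 10 planes): `clean` (20 separated nuclei),
`spanning` (15 nuclei, 5 crossing a substack boundary → raw 20, final 15),
`artifacts` (8 nuclei + 3 debris specks of ~45 px + 1 dim blob with peak 12),
`clusters` (8 nuclei + one fused bright blob of ~1130 px rendered as three
concentric cluster members → block estimate 1130/400 → 3), and `mixed`
(all stressors). Non-fused nuclei are placed by seeded rejection sampling
with a minimum footprint gap of 4 px; overlapping non-cluster nuclei are a
spec error, because separation is what keeps the ground truth exact.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: out-of-focus light and the microscope's point
spread function, intensity falloff with depth, photobleaching, irregular
nucleus shapes and chromatin texture, and densely packed nuclei whose
separation genuinely requires a learned segmenter. The synthetic benchmarks
verify the projection, bookkeeping and rule logic exactly; they do not
certify segmentation quality on real membranes.

The fused cluster is rendered as concentric members so the blob has a
single distance-transform maximum and is segmented as one mask,
exercising the block-estimation rule. Members placed side by side would be
split by the reference backend's watershed — correctly so, but that is the
separated-nuclei path, already covered by the other presets.

## Statistics

Mann–Whitney U uses midranks; `U = min(U1, U2)` is reported. With combined
sample size ≤ 16 and no ties, the two-sided p-value is exact by complete
enumeration of all rank assignments (fraction of assignments with
`min(U1,U2)` at most the observed value). Otherwise a normal approximation
with tie-corrected variance and 0.5 continuity correction applies. The
enumeration bound of 16 keeps the exact branch under ~13 000 assignments.

Kruskal–Wallis (tie-corrected H, χ² with k−1 df) requires ≥3 groups; two
groups are redirected to Mann–Whitney. Dunn's pairwise z statistics use the
pooled mid-ranks with tie correction; the multiplicity adjustment is
Bonferroni by default (none and Holm available) — the choice among
adjustments is genuinely open and deliberately configurable.

Boxplot summaries use linearly interpolated quartiles (the convention of
`numpy.percentile`) and Tukey whiskers at the most extreme point within
1.5 × IQR; "IQR" alone underdetermines the quartile rule, so it is pinned
here and in tests.

## Problem sizes

The test suite and the acceptance script run the full pipeline on 384×384
×10-plane stacks: 10 seeds per counting preset, 20 seeds for the rotation
and cluster-comparison checks, and 20–50 seeded draws for the enumeration
cross-checks of the statistics. These sizes give exact, deterministic
expectations for every check while keeping a complete run in the tens of
seconds on one core.

## Known limitations

* The reference backend is threshold-based: it cannot detect structures
  dimmer than its threshold, and with the default Li threshold the
  invisible-elimination rule is reachable only via the fixed-low-threshold
  mode or an over-detecting backend such as the Cellpose adapter.
* Nuclei spanning ≥3 substacks are over-counted by the chain rule (see
  above).
* The sum projection saturates at 255; quantitative intensity comparisons
  across projections should use mean or maximum.
* The conventional comparator's binary watershed shares the reference
  backend's marker construction rather than reproducing any particular
  ImageJ release bit-for-bit; its particle filter (area, circularity) is
  exact.
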