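# Methods

This note documents the statistical procedure `lrscan` implements, the
parameters that matter, the synthetic-data generator used to validate it,
and the numerical conventions and design choices a maintainer should know.

## Problem setting

The input is a per-cell measurement table from a segmented multiplex
fluorescence image: one row per cell with centroid (x, y) in pixels (origin
top-left, y downward), nuclear/cell area in px², and one mean-intensity
column per marker. The question is where in the tissue a target
ligand–receptor pair is *locally co-expressed* — ligand-positive and
receptor-positive cells co-occurring within the same small neighbourhood
(≤ ~100 cells), the spatial proxy for juxtacrine/paracrine signalling.
Same-cell colocalisation is deliberately not required: the two partners are
expected on different, adjacent cells.

## Pipeline

### QC

* **Z-aggregation.** When per-Z-slice intensity columns are present, the
  per-cell intensity is their arithmetic mean. All cells must share the
  slice count; ragged stacks are rejected.
* **Clipping.** Each marker is clipped to its upper `clip_percentile`
  (default 95) computed over all cells. This suppresses segmentation
  artefacts with artificially bright signal.
* **Area filter.** Cells with area strictly below the `area_percentile`
  (default 5) of all areas are removed — small detections are usually
  debris. Survivor order is preserved.
* **Gating.** A cell is positive for a marker iff its clipped intensity is
  strictly above the gate: a manual threshold, the q-quantile over all
  cells, or Otsu's two-class threshold on a 256-bin histogram. Gates for
  the target ligand and receptor must be configured explicitly. Positivity
  columns supplied with the input (e.g. cluster-derived phenotypes) are
  used as-is and gating is skipped; graph clustering itself is out of
  scope.

**Percentile convention.** The clip cap and the area cut use the
nearest-lower order statistic (numpy `method="lower"`), not linear
interpolation. The cap is then an observed value and a fixed point of the
operation: clipping a clipped table reproduces the same cap from the tied
values it created, so clipping is exactly idempotent. An interpolated cap
sits strictly between order statistics and drifts downward on
reapplication. Quantile gating keeps numpy's default interpolated quantile,
where no fixed-point property is needed. Note the interaction between
clipping and gating: a clip percentile at or below a marker's positive
fraction flattens *all* of its positives to the cap, after which no gate
above the cap can call anything positive. Clip above the expected positive
fraction (the benchmarks use 99.5 with ~3–5% positivity).

The area filter is *not* idempotent under recomputation, and cannot be: the
survivors' 5th percentile is strictly higher than the original cut whenever
areas are distinct, so a second pass removes more cells. It is a one-shot
ingest step.

### Adaptive window scan

An initial grid of windows with edge `init_rate` × image extent (default
0.125; the last row/column truncated at the border) is refined by a
worklist procedure: pop a window, count its member cells; fewer than
`min_cells` (default 2) → discard; between `min_cells` and
`cell_count_threshold` (default 100) → retain as a leaf with per-marker
positive counts; above the threshold → replace by a grid of children with
edges `subset_rate` × the parent's (default 0.5, i.e. quadrants; rates that
do not divide the parent evenly tile it with a truncated last row/column).

Two conventions make the scan total and well defined:

* **Half-open membership.** A cell belongs to `[x0,x1) × [y0,y1)` iff its
  centroid lies inside; cell extent is ignored. Sibling windows are
  disjoint and tile their parent, so each cell is counted in at most one
  leaf and `Σ leaf totals + discarded cells = all cells`.
* **Recursion floor.** A window still over the threshold whose edge is
  ≤ `min_window_edge` (default 16 px) is retained as a flagged *forced*
  leaf instead of being split forever — without the floor, more than
  `cell_count_threshold` cells sharing a centroid would never terminate.
  Retention at exactly the threshold is inclusive (≤).

Depth is bounded by log_{1/subset_rate}(init_edge/min_window_edge) + 1.

### Co-expression score

For a leaf window *w* with `n_ligand`, `n_receptor` positive cells out of
`n_total`:

    score(w) = (n_ligand + n_receptor) / n_total,   or 0 if either count is 0.

The score is symmetric in the pair, lives in [0, 2], and is 0 exactly when
a partner is absent. Double-positive cells contribute to both counts — the
two counts are independent tallies, and nothing in the procedure
deduplicates them.

### Significance

Each score-positive window *w* is ranked against a merged background
`B(w)` combining two nulls:

1. **Random-pair null (within the window).** The score of every
   non-interacting unordered marker pair of the panel — all n(n−1)/2 pairs
   minus the target pair and any pairs declared as known L-R interactions —
   evaluated on the *same* window. This asks whether the target pair is
   enriched beyond what arbitrary marker pairs show at this location. A
   panel needs ≥ 3 markers for this null to exist.
2. **Same-pair null (across the tissue).** The target pair's scores in all
   *other* score-positive windows. This asks whether this location is
   enriched beyond the rest of the tissue and suppresses windows where both
   markers appear only at background level.

With ties counted in favour of the observation
(`n_beaten = #{b ∈ B : score(w) ≥ b}`):

    percentile(w) = n_beaten / |B|
    p(w) = (|B| − n_beaten + 1) / (|B| + 1)

The p-value is the standard add-one empirical p for the one-sided test
"observation exceeds background"; it is a strictly decreasing transform of
the percentile, so rankings agree and −log10 p is largest exactly where the
percentile is highest (p ∈ [1/(|B|+1), 1], so −log10 p is finite).
Zero-score windows are not tested (p = 1, never significant) and do not
enter anyone's background. A positive window with an empty background is
flagged `untestable`. Windows are called significant at `p ≤ alpha`
(default 0.05).

Two consequences worth knowing:

* **Rank cap.** Because p is rank-based against a background dominated by
  the other windows' scores, at most ~alpha of tested windows can be
  significant, whatever the effect size. The method finds the most enriched
  minority of the tissue; it cannot declare half the tissue significant.
* **Tie direction.** Counting ties as beaten makes the p-value slightly
  anti-conservative where scores tie heavily (identical counts and
  totals). Under the null-calibration benchmark below the realised
  false-positive rate at α = 0.05 is ~0.05, within 3 binomial SEs.

No multiple-testing correction is applied by default; `bh_correction=True`
applies Benjamini–Hochberg across tested windows (an extension, off by
default). For 2-marker panels a fallback null is available (off by
default): ligand and receptor labels are shuffled tissue-wide and the
window's counts redrawn per shuffle — implemented as hypergeometric draws,
which is distributionally identical. A shuffle *within* one window would
leave the count-ratio score unchanged and carries no information, which is
why the tissue-wide shuffle is the implemented reading.

The min–max-normalised score `(s − min)/(max − min)` over windows (constant
input maps to 0) is exported alongside −log10 p; protein workflows often
plot the normalised score instead of the p-value, so both are first-class
map fields.

### Registration of imaging rounds

Stain–strip assays image marker subsets in separate rounds that must share
coordinates before pooling. `estimate_round_transform` runs
iterative-closest-point on the detected nuclear centroids: after
centre-of-mass pre-alignment, alternate nearest-neighbour correspondence
(moving → fixed, KD-tree) with a closed-form least-squares fit of the
requested family — centroid difference (translation), Kabsch (rigid),
Umeyama (similarity), normal equations (affine) — until the mean residual
improves by < 1e-6 px or `max_iter`. ICP is a local optimiser, so the
rotational families are multi-started from a grid of initial angles
(0, ±4°, ±8°, ±12°) and the best final residual wins; estimation is fully
deterministic (the `seed` argument exists only for signature symmetry with
simulation code). Collinear point sets cannot fix an affine map and raise
an estimation error.

Point-set ICP on centroids was chosen over intensity-based image
registration deliberately: the pipeline never touches pixels, centroids are
already available, and window-level counting only needs centroid-accurate
alignment (sub-pixel mean residual at the benchmark's 2%-of-spacing noise).

**Pooling convention.** Each marker must be imaged in exactly one round.
After alignment the rounds are concatenated; each marker's positive count
comes from the round that carries it, while `n_total` and the
split/discard decisions use only the *reference round's* cells (the round
whose nuclear stain defines "a cell"). This prevents double-counting nuclei
that were re-detected in both rounds. With this convention a marker's
positive count can in principle exceed the reference-round total (it is
counted over another round's detections), which is accepted: the score then
measures positives per reference cell.

## Synthetic tissues

`lrscan.simulate` generates tissues with known ground truth:

* **Positions** from a homogeneous Poisson process (count ~ Poisson(density
  × area), positions uniform). No cell-cell exclusion is modelled — the
  pipeline uses only centroid counts, for which the Poisson approximation
  is adequate; real nuclei have a hard core that slightly regularises
  counts.
* **Areas** lognormal(μ = 4.0, σ = 0.35) px² (~60 px² median).
* **Positivity** per marker: Bernoulli at `background_rate` outside
  hotspots; inside a hotspot the ligand and receptor use `hotspot_rate`
  instead. Hotspots are disjoint discs placed uniformly (fully inside the
  extent). An optional `double_positive_rate` forces joint positivity for
  a fraction of hotspot cells (default 0).
* **Intensities** from a two-component lognormal mixture selected by the
  true label: negatives LN(1.6, 0.5) (median ≈ 5 a.u.), positives
  LN(4.1, 0.5) (median ≈ 60 a.u.). The modes are separated enough that
  manual (valley ≈ 17 a.u., < 1% misclassification per component),
  quantile and Otsu gating are all exercisable.

Everything is reproducible bit-for-bit from the config seed.

What the generator does *not* emulate: spatial intensity gradients and
autofluorescence, segmentation errors (merged/split nuclei), cell-type
structure beyond the marker labels, irregular (non-disc) niche geometry,
and spatial correlation of positivity outside hotspots. Passing the
recovery benchmarks therefore shows the scan/score/test machinery is
correct and calibrated under the stated generative assumptions — not that
any particular biological dataset will behave this way.

### Study conditions

Two named configurations are the package's benchmark conditions:

* `null_calibration_config`: 2000 × 2000 px, 0.01 cells/px², five
  exchangeable markers at background rate 0.05, no hotspots. The default
  scan yields ~1000 leaves of ~40 cells, ~600–800 of them tested — enough
  to estimate the false-positive rate at α = 0.05 within ±0.03.
* `hotspot_recovery_config`: 4000 × 4000 px at 0.02 cells/px²
  (a ~5.6 × 5.6 mm section at ~1.4 µm/px and ~10,000 nuclei/mm²), three
  radius-150 px hotspots, ligand/receptor positivity 0.4 inside vs 0.03
  outside. The extent is deliberately large relative to the hotspots:
  by the rank cap above, recovering nearly all hotspot windows requires
  them to be a small minority of tested windows (~2.5% here), exactly as
  true signalling niches are in a whole section. Under these conditions
  windows containing ground-truth hotspot cells are recovered at ~0.90
  sensitivity with a ~0.03 false-positive rate elsewhere (20 seeds).

A *hotspot window* for these metrics is a leaf containing at least one
ground-truth hotspot-member cell. A window whose rectangle merely grazes a
disc without containing any of its cells has no elevated signal even in
principle; under the purely geometric intersection definition the same runs
measure ~0.86, the difference being exactly those empty-overlap slivers.
Both numbers are reported by `scripts/acceptance.py`.

Benchmark sizes (cells per section, seed counts, ICP run counts) were
chosen so the full suite completes in a few minutes on one CPU while
keeping the binomial error on every estimated rate well inside its
acceptance band.

## Numerical conventions and edge cases

* Empty tables pass through QC unchanged; an empty tissue scans to an
  empty window set (every initial window discarded).
* Constant intensity under Otsu gating: nothing is called positive (the
  threshold is the constant itself and gating is strictly-above).
* Markers absent from a pooled round carry NaN intensities; they are
  excluded from percentile/threshold computation and never called positive
  in that round. Infinite intensities are rejected.
* `normalize_minmax` maps constant input to all-zeros.
* Window ids are assigned in (y0, x0) order after the scan, making outputs
  independent of worklist traversal order; result CSVs are byte-identical
  across runs given the same config and seed.
* Float window bounds are generated by multiplication (`i × step`), not
  accumulation, so sibling bounds are bit-reproducible.

## Known limitations

* The significance machinery compares windows of different cell counts on
  one score scale; very small leaves have coarser score distributions and
  can crowd the top ranks. The default `min_cells = 2` keeps them in, as
  specified; raising it (or the BH option) tightens behaviour on sparse
  tissue.
* The rank cap means α bounds the *fraction* of windows that can be
  flagged; tissues where the true interacting region exceeds ~α of tested
  windows will be under-called.
* ICP handles the rigid/similarity misalignments typical of restitched
  rounds; it is not a deformable registration and will not correct local
  tissue distortion.
* Positivity gating is global per marker; spatially varying background
  (illumination gradients) should be corrected upstream.
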