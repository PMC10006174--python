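# Methods

## Problem setting

Imaging mass cytometry (IMC) rasterizes a tissue section at ~1 µm per
pixel, one intensity channel per metal-tagged antibody. Conventional
analysis first segments cells and then phenotypes the segments; pixplore
instead phenotypes *pixels* directly, which sidesteps segmentation errors
in dense tissue (lymphoid aggregates, epithelium) at the cost of working
with 10⁵–10⁶ observations per region of interest (ROI). The pipeline is:

1. **Preprocess** — per-channel maximum-signal clipping at a percentile,
   then the arcsinh variance-stabilizing transform; flatten to an
   N×M pixels-by-markers table.
2. **Hierarchy** — an HSNE-style multi-scale landmark hierarchy over the
   pixel table, so that a quarter-million pixels can be explored through a
   few hundred landmarks and drilled into selectively.
3. **Gating** — 2-D embedding of a scale, weighted mean-shift clustering
   of the embedding, expansion of landmark labels to all pixels through
   areas of influence, and naming of clusters against marker signatures.
4. **Render** — back-projection of up to 9 named classes onto the tissue
   raster with fixed unique colors, at the original resolution.
5. **Quantify** — double-positive pixel counting inside annotated regions
   (e.g. lymphoid follicles, LF, vs matched non-LF areas) and a one-tailed
   Mann–Whitney comparison of region groups.

## Preprocessing

* **Clipping.** The maximum-signal threshold is the q-th percentile
  (default q = 98) of all pixels of a channel within the ROI, computed
  with the linear-interpolation order-statistic convention
  (`numpy.percentile`, method `linear`); the channel is clipped as
  `min(x, t)`. Clipping at a *fixed* threshold is idempotent. Re-running
  the full operation re-estimates the threshold on the clipped channel;
  that re-estimate falls inside the interpolation gap just below the old
  threshold unless the rank position 0.98·(n−1) lands exactly on an order
  statistic, in which case the composite operation is exactly idempotent.
  Tests pin the exact case (n = 101) plus the interpolated value
  (1..100 → 98.02).
* **Transform.** `asinh(x / c)` with cofactor c = 5, the standard
  mass-cytometry stabilizer: linear for x ≪ c, logarithmic for x ≫ c,
  monotone, 0 ↦ 0. Clipping precedes the transform so the threshold is
  interpretable in raw count units.

## Landmark hierarchy

* **kNN graph.** Euclidean on transformed marker values; k = 30 by
  default. Exact brute force (stable tie-break by row index) up to 8192
  rows; sklearn nearest-neighbors at intermediate sizes; NN-descent
  (pynndescent, seeded) beyond 50 000 rows, which makes the
  2.5×10⁵-pixel ROI scale tractable on one CPU. Edge weights decay as
  exp(−d²/σᵢ²) with σᵢ the mean neighbor distance of node i.
* **Landmark selection.** 100 random walks of length 50 start from every
  node of the row-stochastic transition matrix; a node becomes a landmark
  when its total visit count exceeds 1.5× the expectation (walks ×
  length). Walks run in seeded numba kernels with an internal splitmix64
  generator — single-threaded and bit-reproducible.
* **Area of influence.** 100 absorbing walks per point (cap 500 steps)
  record which landmark each walk reaches first; a point that is itself a
  landmark absorbs at itself. Rows keep their 10 strongest absorption
  targets (singleton hits at this sampling depth are noise), then
  renormalize to sum exactly 1. Points whose walks never reach a landmark
  (possible in tiny disconnected components) fall back to a deterministic
  breadth-first search. Landmark weights are propagated as
  wₛ = Iᵀ wₛ₋₁, so the weight total equals the scale-0 pixel count at
  every scale — a conservation law the tests assert to 1e-3.
* **Next-scale similarities.** The transition matrix among landmarks is
  the weighted area-of-influence overlap Iᵀ diag(w) I with the diagonal
  removed, rows pruned to their 30 strongest entries and renormalized.
  Pruning bounds memory: without it the overlap at the 250 000-pixel scale
  holds >10⁸ nonzeros.
* **Scale count.** Default 3 (data scale + two landmark scales),
  mirroring an overview → tissue → immune-pixel drill sequence; the
  hierarchy truncates with a warning when a further scale would drop
  below 10 landmarks.

## Embedding

Each scale is laid out in 2-D by exact-gradient t-SNE. Similarities are
perplexity-calibrated Gaussian conditionals (perplexity 30) on
marker-feature distances among the scale's points — the stored kNN
distances at scale 0, a fresh exact kNN over the landmark features at
coarser scales — multiplied by the landmark weights so heavy landmarks
structure the layout. We evaluated the area-of-influence overlap itself as
the similarity (as in the HSNE literature) and found it poorly conditioned
on small fixtures: overlap rows connect landmarks only through shared
absorption mass, which is sparse and noisy at moderate sampling depth, and
layouts over-expanded (silhouette ≈ 0.3–0.45 on two planted classes
versus 0.78–0.96 with feature-space similarities). Optimization uses
early exaggeration 12 for 250 of 1000 iterations, momentum 0.5 → 0.8,
adaptive gains, learning rate max(n/12, 2), and a deterministic spectral
initialisation (top eigenvectors of the symmetrized similarity, seeded
ARPACK start vector). Identical seed and parameters reproduce coordinates
bit for bit. The exact gradient is O(n²); `embed_scale` refuses more than
12 000 points — embed a coarser scale or drill down instead.

## Gating

* **Clustering.** Weighted Gaussian mean-shift on the 2-D embedding:
  every point ascends the kernel density (bandwidth default 5% of the
  bounding-box diagonal, landmark weights as point masses); modes closer
  than half a bandwidth merge. Cluster ids follow lexicographic mode
  order, so the partition is invariant to row order.
* **Expansion.** A pixel takes the label of the landmark that holds its
  largest composed influence (ties → lowest landmark index); pixels
  without influence mass become background.
* **Naming.** Positivity thresholds are per-marker quantiles (default
  60th percentile) of transformed intensities over all analyzed pixels; a
  cluster is positive when its member-median *strictly* exceeds the
  threshold. The strict inequality matters for markers absent from most
  of the image: their threshold is 0 and medians of negative clusters are
  0, so nothing reads falsely positive. Signature matching is ordered
  first-match (mirroring hierarchical manual gating); clusters matching
  the same cell type merge; unmatched clusters stay "unassigned".
  "Dim" gates (e.g. CD45⁺/dim pixel selection before fine immune
  clustering) are provided as quantile-band marker gates (30th–60th), and
  the alternative embedding-selection route is drill-down on clustered
  landmarks.

## Quantification

A pixel is double-positive when both marker intensities are ≥ their
thresholds (boundary inclusive). Default thresholds are the per-channel
98th-percentile maximum-signal value scaled by 0.5; a channel whose 98th
percentile is 0 (no signal) yields no positive calls. Fractions
(count/area), not raw counts, are compared between region groups, because
control regions are drawn to similar but not identical surface areas; raw
counts are reported alongside. The group comparison is a one-tailed
Mann–Whitney U (mid-ranks): exact — the full permutation distribution over
all C(n₁+n₂, n₁) label arrangements — whenever n₁+n₂ ≤ 20 with no ties
(scipy's exact method; an independent enumeration oracle checks it in the
tests for all group sizes ≤ 8), otherwise the normal approximation with
tie and continuity corrections. A fully tied pooled sample returns p = 0.5
(U at its null mean). At the 7-vs-5 design, complete separation gives
exactly 1/792 ≈ 0.00126.

## Synthetic scenes

The generator plants rectangles and discs with group tags (LF / non-LF /
background), assigns classes per region by i.i.d. mixing fractions, stamps
per-class mean intensities and applies noise. It emulates the *structure*
of IMC data — count-like positive intensities, class-pure signal regions,
follicle-vs-control geometry — and deliberately omits channel spillover,
instrument drift, hot pixels and 3-D effects, so passing tests demonstrate
pipeline correctness on well-posed inputs, not robustness to acquisition
artifacts.

* Rasterization is pixel-center inclusion (a pixel belongs to a disc iff
  its integer center lies inside, boundary inclusive) — unambiguous and
  checkable against a brute-force point-in-disc oracle.
* Poisson noise uses the class mean as rate. Lognormal noise is
  mean-preserving: mean · exp(N(−σ²/2, σ²)), so the sample mean converges
  to the declared mean (the median sits a factor exp(−σ²/2) below). The
  mean-preserving form was chosen so that declared signatures are also the
  expected observed signal.
* Overlapping *exclusive* regions with different class mixtures are an
  error naming both regions; non-exclusive regions paint in list order
  (later wins), which lets follicle discs sit inside a lamina-propria bed.
* Seeds are explicit fields; identical (spec, seed) reproduces the image
  byte for byte.

Bundled scenes: a demo follicle scene (96×96, epithelium band, stromal
lamina propria with scattered immune cells, one LF and one control disc),
a full-ROI scene (500×500 = 2.5×10⁵ pixels over a 19-marker structural +
immune panel) used to exercise acquisition-ROI scale, and the 7-vs-5
follicle/control disc design for quantification. Control discs carry
sparse near-threshold CD161/CD69 signal so their double-positive fractions
are small but nonzero and untied — the exact Mann–Whitney path requires an
untied pooled sample.

## Problem sizes and defaults

| Stage | Parameter | Default | Why |
| --- | --- | --- | --- |
| preprocess | cofactor | 5 | standard IMC stabilizer scale |
| preprocess | percentile | 98 | maximum-signal threshold per ROI |
| hierarchy | k | 30 | dense enough for stable walks, sparse enough for memory |
| hierarchy | walks × length | 100 × 50 | visit-count concentration at ~1% Monte-Carlo error |
| hierarchy | landmark threshold | 1.5× expected visits | ~4–6× reduction per scale |
| hierarchy | influence walks / top | 100 / 10 | absorption frequencies; prune sampling noise |
| hierarchy | scales | 3 | overview → tissue → immune drill |
| embedding | perplexity / iters / EE | 30 / 1000 / 12 | t-SNE practice |
| gating | bandwidth | 5% of embedding diagonal | density modes ≈ visual gates |
| gating | positivity quantile | 0.60 (dim ≥ 0.30) | operational ⁺/dim definition |
| quantify | positivity fraction | 0.5 × 98th percentile | declared, not fitted |
| quantify | exact-test cutoff | n₁+n₂ ≤ 20 | enumeration instant at small designs |

The acceptance script and tests run the hierarchy at the full
2.5×10⁵-pixel ROI size (≈5–7 min, <2.5 GB on one CPU) and the recovery
chain on 60×60 four-class scenes over 5 seeds — sizes chosen so the whole
suite completes comfortably on a laptop-class machine.

## Known limitations

* Marker positivity by quantile thresholds assumes each signature marker
  is absent from a substantial share of analyzed pixels; a marker positive
  in ≫60% of pixels pushes the threshold into its positive population.
  Analyze a drilled subset (as the immune-marker step does) or adjust the
  quantile in that regime.
* The exact-gradient embedding caps at 12 000 points by design; larger
  scales must be drilled or coarsened first.
* Monte-Carlo influence at 100 walks quantizes probabilities to 1/100;
  the top-10 row pruning discards genuinely tiny cross-influences along
  with noise.
* No spillover compensation, hot-pixel removal or batch normalization —
  inputs are assumed exported from acquisition software already
  channel-calibrated.
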