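# Methods

## Image model and projection

A field of view is a z-stack `I(layer, row, col)` of non-negative
intensities in raw acquisition units; integer TIFF data are promoted to
float64 without rescaling so that the per-cell statistic V stays
comparable across fields imaged with identical settings. Layers are
combined per pixel before any analysis — sum projection by default, so V
computed on the projection equals the cell's stack-total intensity; max
projection is available (`segmentation.projection: max`) for users who
prefer peak response. Multi-channel TIFFs are rejected rather than
silently collapsed: the quantified signal is a single fluorophore.
Whether one optical section or the whole stack should contribute to V is
an acquisition-dependent choice; the sum-projection default treats every
acquired layer as signal.

## Second-order symmetry detector

Cell centers are localized with a rotational-symmetry detector operating
on local orientation. The gradient is taken as derivative-of-Gaussian
filters at scale `sigma_gradient` (default 2 px), combined into the
complex gradient g = gₓ + i·g_y, and squared: z = g². This double-angle
representation identifies orientations θ and θ+180°, so an orientation
field can be filtered linearly. The order-2 rotational basis

    b(u, v) = ((u + iv)/|u + iv|)² · w(u, v),   b(0, 0) = 0,

with w a Gaussian applicability window at scale `sigma_window` (default
2 px ≈ half the expected cell radius, kernel truncated at 3σ), is
correlated with z:

    S(x, y) = Σ_{u,v} conj(b(u, v)) · z(x + u, y + v).

For a radially symmetric blob the gradient is radial, z = |g|²·e^{i2φ},
and the correlation adds coherently exactly at the center; elsewhere the
contributions disperse in phase. In normalized mode |S| is divided by the
windowed orientation energy Σ w·|z| + ε (ε = 10⁻¹²), which bounds the
magnitude to [0, 1] and makes it invariant under global intensity
scaling; where the energy is below 10⁻⁹ of its maximum the ratio is a
0/0-style numerical shadow and is set to 0. Boundary handling is
reflective throughout, and the correlation is computed directly (not via
FFT), so the response is exactly the definition above.

A consequence worth knowing: normalized coherence measures *shape*, not
strength. An isolated weak ripple can score close to 1, so the raw peak
list always contains background artifacts. The pipeline's culling step is
the foreground mask — seeds outside it are dropped (with a warning) before
the watershed — and the relative magnitude threshold (`rel_threshold`,
default 0.3 of the global maximum) is deliberately permissive because
centers of touching cells dip to ~0.7 coherence through mutual
interference.

## Seeding and watershed

Seed candidates are local maxima of the magnitude above the relative
threshold, visited strongest-first (ties broken row-major) and kept
greedily subject to a pairwise minimum distance (`min_distance`, default
4 px ≈ the expected cell radius). The foreground is a histogram threshold
of the smoothed projection with holes filled and components below
`min_area` (default 20 px) removed. The default threshold is the triangle
method: on a background-dominated field of Gaussian-profile cells it
lands near the histogram foot, so the mask reaches the dim rim of each
cell whose tail belongs in V; Otsu is available but sits mid-slope on such
skewed histograms and clips roughly half of each cell's footprint area.
Because smoothing (Gaussian, `sigma_smooth` = 2 px, reflective boundary)
dilates every cell's support by about the smoothing scale, the mask is
eroded by round(`sigma_smooth`) pixels to return the ROI to the
unsmoothed footprint.

Segmentation is a marker-controlled watershed flooding the *negated
smoothed intensity projection* from one marker per seed, restricted to
the foreground mask with 4-connectivity, so boundaries between touching
cells follow the intensity valley between them. Flooding the negated
symmetry magnitude instead is exposed as `flood_on: symmetry`; the
intensity surface is the default because cell boundaries are intensity
structures, whereas the symmetry map is sharply peaked at centers and
nearly flat at boundaries. Regions below `min_area` are merged into
background and labels are relabeled contiguously; each final region is a
single 4-connected component confined to the mask.

## Quantification

V is the plain sum of projection intensities over the cell's labeled
region, computed with `math.fsum` (correctly rounded, order-independent);
on integer-valued images — which acquired 8/16-bit TIFFs are — V and the
partition identity Σ_k V_k + background = grand total are exact to the
last bit. No background is subtracted by default, matching the definition
of V as a raw regional sum. An optional `subtract_background` flag
removes (median of unlabeled pixels) × area from each V, clamped at 0:
with an additive offset present, ratios of raw sums shrink toward 1, so
the flag should be on whenever fold-changes are the quantity of interest
and the offset is non-negligible.

## Group statistics

Cells are grouped by class within each experiment (pooling across scenes
of the same class and experiment). Per class the median of V is taken
(even n: mean of the two central order statistics); each non-reference
class is compared to the reference by

* the signed fold-change: r = median_class/median_ref reported as +r if
  r ≥ 1, else −1/r, so |fold| ≥ 1 and the sign encodes direction; and
* a two-sided Wilcoxon rank-sum test of the equality of medians. For
  pooled samples of at most 20 tie-free observations the exact null
  distribution of the rank sum (counts of size-m subsets of {1..N} by
  sum, computed by dynamic programming) gives
  p = 2·min(P(W ≤ w), P(W ≥ w)) clamped to (0, 1]; otherwise midranks
  with tie-corrected variance and a 0.5 continuity correction feed a
  normal approximation. Forcing `exact` on tied data is an error — exact
  tie handling is out of scope.

Stars follow the fixed convention ** (p < 0.01), * (p < 0.05), NS; the
thresholds are deliberately not configurable. No multiple-testing
correction is applied across the class comparisons — each is starred on
its own p — and inference across experiments is descriptive only: the
per-experiment fold-changes are summarized as mean ± sample SD (n−1
denominator; a single experiment reports SD 0 with a warning). Mixing
signs across experiments can place the mean fold inside (−1, 1), which is
a property of the signed-reciprocal convention, not a bug. Pooling all
experiments into one test (`stats.pooling: pooled`) is available;
per-experiment testing is the default since replicate-level variation
should not be hidden inside a single p-value.

## Synthetic scenes and what they do (not) show

Each synthetic cell is an isotropic 2-D Gaussian of amplitude
A = amplitude_base × class_fold × L, where L is lognormal with mean 1 and
coefficient of variation `cell_cv`, and scale σ drawn uniformly from
`cell_radius_range`; the blob is truncated at 3σ. The rendered, truncated,
pixel-discretised sum of the cell's own blob is recorded as `true_V` —
the exact noiseless content of the image — and lies within 1.11%
(= e^{−9/2}, the exact 3σ truncation deficit) of the closed form 2πAσ².
Truth labels assign every pixel within 3σ of a center to the nearest such
center (ties to the lower cell id), giving disjoint 4-connected regions.
Signal is spread across layers by a uniform weight vector (no z-profile
is modeled); background is a constant per layer; noise — additive
Gaussian (clipped at 0, since a detector cannot report negative counts)
or Poisson with a gain — is applied after truth capture, so `true_V` is
exact. Touching pairs are placed at center distance 2.5 × mean σ: close
enough to merge under naive thresholding, far enough to present two
symmetry peaks. Placement is rejection sampling with 3σ-disc disjointness
(plus a 2 px guard) between non-paired cells; infeasible requests raise a
generation error rather than degrading silently. All draws come from one
`numpy.random.default_rng(seed)` in a fixed order, so scenes are
bit-reproducible.

Defaults emulate the imaging regime of the motivating study design:
256×256 fields, 3 layers, 8–9 cells per field (the acquired fields
contained 4–9 cells), σ 3–5 px, amplitude 100, background 5, read-noise
SD 2, cell_cv 0.2. The generator does not model optics (PSF, spectral
crosstalk, photobleaching), non-round or textured cells, or the selection
process by which representative cells were photographed. Passing the
synthetic benchmarks therefore demonstrates the correctness and
calibration of the *algorithms* under the stated cell model, not
performance on arbitrary real acquisitions.

## Benchmark sizes and measured behavior

The ground-truth benchmarks use noiseless well-separated scenes with
5–30 cells (frames 192–448 px so that rejection-sampling placement stays
feasible): recovered counts are exact, per-cell IoU against the 3σ truth
discs is ≥ 0.87, every touching pair splits, and matched-cell V errors
are below 1%. Fold recovery runs the full pipeline on 100 independently
seeded panels (reference + true folds {1.5, 2, 3}, 30 cells/class, fixed
σ = 4 so cell-size variation does not confound the amplitude effect,
cell_cv 0.2, Gaussian noise, background subtraction on). Two ceilings
bound what this can achieve: the ratio-of-sample-medians estimator at
n = 30 and cv = 0.2 satisfies |est/true − 1| < 10% with probability only
≈ 0.89 even with a perfect segmentation (order-statistic variance), and
amplitude-adaptive thresholding captures slightly more blob tail for
brighter classes (≈ +2–3% ratio bias — a property shared by any
threshold-based ROI quantification). The measured within-10% rate is
≈ 0.82–0.88 depending on seed. Null calibration (fold 1.0, 9 cells/class,
1000 replicates of the exact test at α = 0.05) rejects at ≈ 0.04,
matching the exact test's size of 0.0400 at these sample sizes.

## Degenerate inputs and tie-breaks

Single-valued images yield an empty foreground with a warning; an empty
seed set yields an all-background label map; an all-zero symmetry
magnitude yields no seeds. All tie-breaks (seed ordering, truth-label
assignment, relabeling) are deterministic row-major / lower-id. Label
maps read from disk are relabeled to a contiguous {0..K} preserving value
order; provenance (`computed` vs `provided`) is tracked so that runs fed
with precomputed masks skip segmentation.
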