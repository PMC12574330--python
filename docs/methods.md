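# Methods

## The test

Input is a nonnegative feature-by-spot matrix $X$ ($N \times M$, sparse)
and spot coordinates $S$ ($M \times D$, $D \in \{2,3\}$, arbitrary length
units).

**Density normalization.** Coordinates are multiplied by the isotropic
factor $(M / \prod_d \Delta s^{(d)})^{1/D}$, where $\Delta s^{(d)}$ is the
coordinate range along dimension $d$, so that the bounding box holds one
spot per unit volume and the average spot-to-spot spacing is slightly
below one unit. This is what lets fixed default radii work across
platforms whose raw units differ by orders of magnitude. Dimensions with
zero range (a single section stored with constant z) are excluded from
both the product and the exponent. Note the normalization is computed from
axis-aligned ranges: it is exactly invariant to translation and isotropic
scaling of the input, and to rotations that preserve the bounding-box
volume (e.g. quarter-turns); a generic rotation changes the box, hence the
effective radii, slightly.

**Patches.** For each spot $i$ and radius $R_k$ the patch is the set of
*other* spots at Euclidean distance strictly less than $R_k$ (ties at
exactly $R_k$ excluded; comparisons use squared distances so no square
root is taken). A spot with an empty patch gets itself as its patch — and
only then — so local means are always defined. Defaults: $R_1 = 1$,
$R_2 = 3$ normalized units. The exact backend (scipy cKDTree pair query)
reproduces brute-force all-pairs thresholding bit for bit. The optional
approximate backend uses the KD-tree's eps-relaxed ball query with exact
post-filtering: reported neighbors are always true neighbors, but points
in the thin shell $(R/(1+\varepsilon), R)$ may be missed where branches
were pruned. The knob `ann_accuracy` $\in (0,1]$ maps to
$\varepsilon = 1/\text{ann\_accuracy} - 1$; measured recall is typically
far above the geometric lower bound $(1/(1+\varepsilon))^D$ (≈ 0.999 at
`ann_accuracy=0.95` on 50,000 uniform 3-D spots). It is worthwhile only
above roughly 50,000 spots; results with `ann_accuracy=1` equal the exact
backend.

**Statistic.** Expression is scaled per feature by its maximum (max-abs
scaling), preserving sparsity and bounding values in $[0,1]$; all-zero
features pass through and end with p = 1. Local means
$\bar X^{(k)} = \tilde X B^{(k)\top}\mathrm{Diag}(1/\lVert b_i\rVert_1)$
are evaluated by sparse products in feature blocks (default 2048 rows), so
peak memory is O(block × M) and results are block-size independent. The
per-feature variance of local means uses the sample convention (divisor
$M-1$); the choice cancels in the ratio. The weight
$w_j = \sigma_j^2 / \max_n \sigma_n^2$ uses by default the variance of the
**raw** counts (`variance_source="raw"`); a `"scaled"` option computes it
on $\tilde X$ instead, since descriptions of the scheme are ambiguous on
this point. The acceptance checks and all benchmarks run under the
default. Degenerate cases are flagged, not fatal:
$\sigma^2_{j,1} = \sigma^2_{j,2} = 0$ ⇒ ratio undefined, p = 1;
$\sigma^2_{j,1} = 0 < \sigma^2_{j,2}$ ⇒ ratio $+\infty$, p = 0, excluded
from null fitting.

**Inference.** Under the assumption that most features are not spatially
variable, $\log r_j$ across features is approximately normal; the null is
fitted by the log-moment MLE (sample mean and sd of $\log r$ over all
finite positive ratios, untrimmed by default; a trim-fraction option
exists). One-sided p-values are the upper-tail mass
$1 - \Phi((\log r_j - \hat\mu)/\hat\sigma)$. The fit refuses fewer than
10 usable ratios, and panels under 1,000 features trigger a warning
recommending the permutation null, which recomputes $r$ on features
shuffled across spot positions (seeded, reproducible) and fits the same
lognormal. Significance defaults to raw p < 0.05; Benjamini–Hochberg
q-values are available but off by default. Stouffer's method
($z_i = \Phi^{-1}(1-p_i)$, combined $z = \sum z_i/\sqrt{k}$, unweighted)
combines per-sample p-values in multi-sample studies; exact 0/1 inputs are
clamped to the open interval rather than rejected.

## Simulated benchmarks

The generators emulate the benchmark designs standard in the SVG-detection
literature so that power and calibration can be measured without external data.

**3-D geometry.** Continuous-pattern data live on 10 z-sections (z =
1..10) of a 15×15 unit lattice (2,250 spots); discrete-pattern data on 10
sections of a 30×30 lattice spanning 0–30 (9,000 spots). Patterns are
unions of spheres: the three continuous patterns place sphere centers on a
random walk with fixed step length 2 (curved cell strand: walk
nondecreasing along two axes; tissue layer: one axis; irregular cell
aggregate: unconstrained), the discrete pattern (isolated cell nodules)
uses 16 centers on the $\{3,11,19,27\}^2$ lattice at z = 5.5 with
independent U(−2, 2) jitter per coordinate. Sphere radius grid:
1.5 / 2.0 / 2.5 (default 2.0). The number of walk spheres (default 8) and
the exact lattice placement within sections are free design choices; the defaults here keep the marked fraction near 10% of
spots.

**Expression.** The reference count distribution is
$\lfloor 1 + 10\,\mathrm{Beta}(1,5)\rfloor$ (support 1..10), the same law
used for the sparse throughput matrices; a negative-binomial reference
(mean 5, size 2) is available and is the default for the 2-D emulation.
Marked spots draw from the reference's *upper tail*; rather than fixing an
arbitrary quantile cut, the cut is calibrated analytically
so the tail's conditional mean equals FC × (base mean) exactly — on a
discrete support this requires mixing the two adjacent tail cuts. FC is
therefore the controlled parameter (3-D grid 2.0 / 2.5 / 3.0, default
2.5). The bounded beta-counts support caps attainable FC at ≈ 3.9, which
is why the 2-D grid (3 / 4 / 5) uses the negative-binomial reference.
Non-SVFs are spot permutations of randomly chosen SVF rows (identical
value multisets, no spatial alignment). Gaussian noise with sd =
σ × (mean per-feature sd), σ ∈ {0, 1, 2} (default 1), is added to every
entry, clipped at zero and rounded to integers. Dropout zeroes an exact
fraction (grid 0.1–0.3) of spot positions per feature. The
inter-plane-resolution variant multiplies z-coordinates by 10 *after*
marking, so truth and expression are unchanged. The 2-D benchmark is an
explicit synthetic stand-in for pattern studies built on mouse olfactory
bulb data: 260 uniform spots on a 10×10 field with a disc, band or
annulus marking 15–25% of spots; it preserves that design family's spot
count, feature counts (1,000 SVFs + 9,000 permuted nulls) and parameter
grids, not its exact spatial shapes. The fully null calibration dataset
permutes every feature (including the fold-change mixture rows used as
permutation sources), giving heterogeneous value distributions with no
spatial signal.

What the generators do **not** model: library-size variation between
spots, spatial autocorrelation of technical noise, segmentation errors,
multiplicative (dispersion-style) noise, or real tissue anatomy. Passing
the benchmarks therefore demonstrates correctness and calibration of the
statistic under controlled signal/noise/dropout, not end-to-end
performance on any particular platform.

**Power evaluation.** For an FDR level $f$, the p-threshold is the largest
one whose realized false-discovery proportion among calls is ≤ f
(thresholds must include whole p-value ties); power is the true-positive
rate at that threshold. AUROC scores $-\log p$ against truth. Benchmarks
default to 10 replicates with child seeds spawned from one master seed.

## Problem sizes and numerical choices

The standing validation suite runs the benchmarks at these scales, chosen
to exercise every code path at desk scale: dense-oracle agreement on 50
random instances (M ≤ 300, N ≤ 100, tolerance 1e-10 on ratios);
calibration on 10,000 features × 2,000 spots over 10 seeds (the lognormal
null is an approximation — the realized type-I error at α = 0.05 is
accepted in [0.01, 0.10]); curved-strand power at 100 SVFs + 900 nulls ×
2,250 spots over 10 seeds; approximate-backend fidelity at 50,000 spots ×
1,000 features. `scripts/acceptance.py` recomputes the same quantities
from scratch (5 power seeds) under a single user seed.

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` spawning, so every simulation, permutation and
benchmark is bit-reproducible. Ties in the radius comparison are excluded
by strict inequality on squared distances. Variances computed from sparse
moment sums clamp tiny negative rounding residue to zero. The lognormal
fit is deterministic; `sigma_log = 0` (all ratios identical) is reported
as an insufficient-variation error rather than producing degenerate
p-values.

## Known limitations

- The all-features null assumes SVFs are a minority; heavily structured
  panels (most features spatial) inflate the fitted null and cost power —
  use the permutation null.
- Exactly two granularities are supported; the radii are tunable but the
  test is not multi-scale beyond the pair.
- Euclidean distances only; no graph or geodesic patches, no periodic
  boundaries.
- The density normalization is bounding-box based and thus mildly
  sensitive to outlier spots and to generic rotations (see above).
- p-values are not adjusted for spatial correlation between features;
  BH-FDR treats features as exchangeable.
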