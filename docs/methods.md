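# Methods

This note documents the models behind each pipeline stage, the choices made
where the underlying procedure left room, and what the synthetic generators
do and do not emulate.

## Coordinate and unit conventions

Rasters are row-major with 0-based indices, pixel-center geometry, and y
increasing downward. Physical lengths are carried in nanometres through
`pixel_size_nm`; molecule-count maps default to 3 nm/px (the dSTORM density
rendering scale), two-channel border images to 30 nm/px (SIM-scale
sampling). Point-pattern coordinates are in nm. Angles of junction tangents
are axes, i.e. elements of [0, π).

## Puncta pipeline

The input is a molecule-count raster: each pixel holds the integer number of
localizations rendered into it. Binarization keeps pixels with at least
`min_count` molecules (default 1: any occupied pixel; no threshold is
defined for density renderings, so occupancy is the natural default).
Cluster identification closes the mask with a flat disk of radius 17 px —
the disk contains every pixel whose center is within the radius — labels the
closed mask with 8-connectivity, and multiplies the labels back onto the
original mask, so closing only decides which occupied pixels belong
together and never adds members. The closing is evaluated as if the mask
were embedded in an infinite empty plane (the array is padded before
dilate/erode), making the result independent of where the border sits in
the frame.

Clusters with ≥ 10 molecules (summed over the pre-binarization counts)
qualify as puncta; the remaining clusters contribute their pixels and
molecules to non-qualifying tallies, so pixel and molecule conservation
holds exactly — a property the tests assert on every synthetic map. Hull
area is the area of the convex hull of member pixel centers, in px²
(nm² via `pixel_size_nm²` in the exported table); density is molecules per
px² of hull. Hulls of < 3 or collinear pixels have zero area: such records
are flagged degenerate and excluded from density statistics rather than
padded, an explicit policy for a case the hull definition leaves open.
Mis-merged puncta are removed via an exclusion-list file; hull-outline
overlays are exported to support that review. No automated splitting is
attempted.

## Ripley's K/L and the group permutation test

For a pattern of n points in a rectangular window W,

    K̂(r) = |W| / (n(n−1)) · Σ_{i≠j} e_ij · 1(d_ij ≤ r),  L̂ = √(K̂/π),

using the unbiased intensity-square estimate λ̂² = n(n−1)/|W|². The
default edge correction is Ripley's isotropic weight: e_ij is the
reciprocal of the fraction of the circle of radius d_ij centered at point i
lying inside W, computed in closed form for rectangles by
inclusion–exclusion over crossed edges and corners (validated against an
arc-sampling oracle to ~1e−5 across the window diagonal). The translation
correction and an uncorrected variant are selectable.

Windows for puncta are the point bounding box plus a 200 nm buffer (half
per side), so L is evaluable well past typical punctum scales; `ripley_l`
truncates (with a warning) only beyond the window half-diagonal, where the
correction is no longer guaranteed finite for an arbitrary point. Actual
pair distances are bounded by the point cloud, which the buffered window
keeps strictly inside the finite-weight regime. The r grid is 201 even
radii on [0, r_max] and integrals use the trapezoid rule.

Groups of patterns are compared by a studentized permutation test. With
group-mean curves L̄_g(r) and within-group variances s_g²(r), the default
`tbar` statistic studentizes by the pooled within-group variance,

    T̄ = Σ_{g<h} ∫ (L̄_g − L̄_h)² / [(1/m_g + 1/m_h) s̄²(r)] dr,
    s̄²(r) = Σ_g (m_g−1) s_g²(r) / Σ_g (m_g−1),

and the `t` variant uses s_g²/m_g + s_h²/m_h instead. The integrand is set
to 0 where the variance vanishes (this occurs at r = 0, where every L is
0). Patterns with fewer than `min_points` (default 3) points are dropped
before testing. The p-value is (1 + #{T* ≥ T_obs}) / (n_perm + 1) over
random reassignments of patterns to groups; with 199 permutations the test
is exact, and its rejection rate at α = 0.05 measures 0.058 ± 0.009 over
600 null replicates. Pattern order is canonicalized (lexicographic in the
L curves) before permuting, so the p-value is bit-identical regardless of
the order groups are supplied in. Duplicate coordinates are disallowed in
patterns — one point per occupied pixel — mirroring the binarized input
convention, which also means molecule multiplicities do not inform the
clustering statistics and group differences are, if anything,
underestimated when the denser group also has more molecules per pixel.

## FRAP

The mobile fraction is M = (F_end − F_bleach)/(F_pre − F_bleach), with
F_bleach the first post-bleach frame, F_end the mean of the final three
timepoints, and F_pre the mean of the pre-bleach frames by default (a
single-frame option exists; the defining text does not specify which, and
the average is the lower-variance choice). No acquisition-photobleaching
correction is applied and no exponential fitting of rate constants is
performed — the readout is the normalized curve and M. Normalization is
invariant to affine intensity rescaling, which the tests assert. Values of
M outside [−0.1, 1.1] are flagged rather than clipped. Welch t-tests
(unequal variance, Welch–Satterthwaite df) compare groups; fold changes of
group means are reported half-up to one decimal alongside the exact ratio.

## Nematic polarity

Junctional planar polarity is 180°-periodic, so per cell we use the
intensity-weighted nematic vector Q = Σ I (cos 2θ, sin 2θ) / Σ I over the
cell's junction pixels; |Q| ∈ [0, 1] and the axis is ½·atan2(q2, q1). A
pixel shared by two cells contributes to both. Cells need ≥ 8 junction
pixels and nonzero total intensity. The tissue magnitude of average
polarity is Mp = |mean over cells of Q| — vector average first, magnitude
second, so opposing axes cancel — with the unweighted mean across cells;
averaging per-cell magnitudes instead would ignore axis alignment and is
deliberately not the default (the per-cell magnitudes are available for
that alternative). Mp ≤ mean |Q| by the triangle inequality, asserted on
all synthetic tissues. When tangent angles are not supplied, they are
estimated per junction pixel as the principal direction of the junction
pixels in a 5×5 neighborhood; isolated pixels are excluded.

## Border metrics

Band ROIs sample nearest pixels at unit arc-length steps along a polyline,
at signed perpendicular offsets spanning an odd `width_px` (default 5; the
ROI width used on the real data is unstated). Nearest-pixel assignment
keeps integer images integer-exact. Enrichment ratios are means of band or
mask samples: border over whole-cell-pair, or ROI-A over ROI-B for
junction/non-junction and contacting/free comparisons; ratios are invariant
to multiplicative intensity rescaling and respond to offsets only through
the additive term. Pearson colocalization is the plain sample correlation
over all band pixels with no intensity threshold. Along-border profiles are
per-arc-position band means; the two-channel phase call (correlated
≥ 0.5, anti-phase ≤ −0.2, else mixed) is a configurable reporting
convenience, not used by any quantitative result. The co-IP ratio is
(partner/bait) of the mutant over (partner/bait) of the wild type.
Background subtraction for confocal/SIM inputs is grayscale opening with a
flat disk (radius 100 and 50 px respectively on the real data), the
classic rolling-ball family; a flat element makes the operation exactly
idempotent on flat-background images.

## Synthetic data: what it emulates and what it does not

- `make_puncta_map` lays cluster centers sequentially along a border with
  truncated-normal spacing (default 150 ± 20 nm) — reproducing the evenly
  spaced wild-type phenotype better than a Poisson line process would —
  within a Gaussian perpendicular band (s.d. 25 nm), each center receiving
  a Poisson number of molecules (mean 60) spread isotropically
  (s.d. 20 nm), rasterized at 3 nm/px with counts accumulating per pixel.
  The mutant profile widens the band ×4 and scales molecules ×0.4; the
  `csr` profile scatters the same expected total uniformly. Localization
  precision, blinking, drift and the microscope PSF are *not* simulated:
  passing recovery tests shows the pipeline arithmetic is right, not that
  real dSTORM artifacts are handled.
- `make_frap_trace` draws the single-exponential recovery
  F(t) = F_bleach + M(F_pre − F_bleach)(1 − e^{−kt}) with additive Gaussian
  noise, sampled every 10 s with 3 pre-bleach frames and a 5 min recovery,
  default k = 0.02 s⁻¹ (no rate is reported for the real data; at this
  rate recovery is ~99.8% complete at the final frames, so the F_end
  readout is essentially unbiased). Diffusive or reaction-limited recovery
  shapes are not modeled.
- `make_polarized_tissue` tessellates a (jittered) hexagonal seed lattice
  into Voronoi cells and samples each shared edge at unit arc-length steps,
  so edges weight by length regardless of orientation — a rasterized band
  would over-weight axis-aligned edges and corrupt the nematic sum. Samples
  carry the exact edge tangent and intensity
  I = I0(1 + p cos 2(θ − θ0 − ε)), with per-edge axis jitter ε
  (s.d. `axis_noise_sd`) and additive intensity noise. For the unjittered
  lattice the three edge-orientation classes (120° apart) cancel exactly in
  the (cos 2θ, sin 2θ) sum, making the per-cell recovery |Q| = p/2 exact —
  the basis of the polarity recovery check. Default mesh jitter 0.15 of
  the cell spacing gives a qualitatively epithelium-like mesh. Real
  segmentation errors, curved junctions, and intensity variation along a
  single edge are not emulated.
- `make_border_channels` renders two channels along a straight border with
  a Gaussian perpendicular cross-section (s.d. 2 px = 60 nm, emulating
  ~100 nm optical resolution at 30 nm/px). `cross` mode offsets the
  channels by 40 nm perpendicular to the border — the scale of the
  intercellular cleft separating partners on opposing membranes, well
  below the emulated resolution, so the channels co-occur along the border
  (band Pearson ≈ 0.7 at moderate noise) — while `lateral` mode alternates
  complementary square-wave domains (default 300 nm) along the border,
  driving the correlation strongly negative. Curved borders and
  partial-phenotype mixtures are not generated.

All generators are deterministic for a fixed seed, and conservation
identities (molecules placed = molecules rasterized) hold exactly by
construction.

## Problem sizes and determinism

The validation suite runs entirely on synthetic data at sizes chosen to
exercise the statistics meaningfully while staying quick: 100 CSR patterns
of n = 500 for estimator calibration, 200 two-group comparisons
(20 patterns of n = 40 per group, 199 permutations) for test calibration,
250 FRAP traces, 100-cell tissues, and 100 seeds per border-channel mode.
Every stochastic test fixes its seeds; the acceptance script derives all
seeds from its single `--seed` argument.

## Known limitations

- The isotropic-correction closed form assumes rectangular windows; no
  polygonal-window support.
- The `tbar` pooled-variance statistic is one defensible reading of the
  studentized group test; the per-group-variance `t` variant is provided
  and selectable, and the two can disagree for strongly heteroscedastic
  groups.
- Density statistics silently exclude degenerate (collinear) puncta, which
  slightly biases summaries toward larger puncta on sparse borders.
- The quantitative results on real microscopy data depend on acquisition
  choices (rendering scale, ROI placement, curation) that the pipeline
  takes as inputs; synthetic recovery demonstrates correctness of the
  computation, not robustness to acquisition artifacts.
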