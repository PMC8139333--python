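# Methods

This note documents the models and procedures implemented in `fruitmorph`,
the parameters that matter, the numerical choices, and what the synthetic
data can and cannot show.

## Segmentation

Images are converted to grayscale with the Rec. 709 luminance weights and
blurred with a Gaussian whose sigma is derived from the requested window
size (window 5 by default; window 1 disables blurring). Two global
thresholds are offered: the mean of the blurred image (appropriate when the
dark background dominates the frame) and Otsu's criterion. Comparison is
strict (`>`); ties go to background. Erosion-then-dilation (opening) with a
square element removes speckle.

Connected components use 8-connectivity; components under 0.05 % of the
board area are dropped. The photographs contain a printed genotype card and
occasionally a rule or coin besides the fruits, and nothing intrinsic marks
which is which, so a rule is needed: an ROI is the **label card** iff its
extent (area / bounding-box area) is ≥ 0.85 and its mean HSV saturation is
≤ 0.15 — a bright, low-saturation rectangle — while ROIs larger than 25 %
of the board are distractors; everything else is a fruit. Card text is read
through a pluggable `LabelReader` hook whose default returns the file stem;
no OCR engine is bundled.

Tiles are square (default 1000 px) with the fruit's mask centroid within 2
px of the tile center and all non-fruit pixels exactly (0, 0, 0) — the
exact-black background is a contract the color and calyx stages rely on.
Fruits larger than the tile are downscaled preserving aspect and flagged.

The internal/external split is **batch-relative**: k-means (k = 2) on
standardized per-tile grayscale mean, SD and mean/SD ratio over fruit
pixels. Cut surfaces expose pale flesh, so the cluster with the higher mean
CIELAB L\* is labeled internal. Both sides must be present in a batch;
degenerate batches raise.

## Calyx removal

SLIC superpixels (CIELAB color + compactness-weighted spatial distance;
defaults n_segments = 60, compactness = 10, 10 iterations) partition the
fruit foreground. Tiles are fruit-centered, so the superpixel containing
the center pixel is flesh. A single superpixel under-covers a large fruit
at these segment counts, so the mask is grown across adjacent superpixels
whose mean CIELAB color is within 25 units of the central superpixel's mean
*and* closer to that mean than to the sepal reference green (76, 75, 20).
The output is always a subset of the fruit foreground. The growth threshold
(25) is permissive for shading gradients within flesh but refuses the
flesh/sepal contrast; it is exposed as a parameter.

## Linear descriptors

The boundary is traced by marching squares at level 0.5 on the zero-padded
mask, so a solid h×w pixel rectangle traces to an exactly h×w polygon;
perimeter is the polygon arc length. Circularity is `4πA / P²` with P the
*convex hull* perimeter of the traced contour (an option uses the raw
perimeter, giving the classical isoperimetric ratio). Solidity is area over
hull area, clipped at 1 because marching squares cuts convex corners by
half a pixel, which can push the raw ratio ~10⁻⁴ above 1. Widths are
horizontal foreground extents per pixel row measured from the top of the
bounding box (fruits are conventionally calyx-up); aspect is total height
over maximum width; the ellipse ratio comes from the second-central-moment
ellipse.

CIELAB statistics use the 8-bit offset encoding — `L·255/100`, `a+128`,
`b+128` — so channel means are commensurate with 0–255 conventions (a pure
mid-gray fruit has a = b = 128).

## Pseudolandmarks and GPA

Fifty landmarks are the intersections of equally spaced rays from the
polygon's *area* centroid (robust to uneven vertex spacing) with the
outline, computed by exact ray/segment algebra; where a ray crosses more
than once the farthest intersection is kept so protrusions survive. A
tolerance of 1e-9 on the segment parameter ensures a ray through a vertex
counts exactly once. Correspondence across fruits requires a common
orientation: `orient_contour` rotates the major principal axis vertical and
puts the flatter end (lower local radial variance — the calyx end) up; the
first ray points up.

GPA centers each configuration, scales to unit centroid size, and rotates
to the running mean by the SVD solution constrained to det +1 (no
reflection — all fruits are photographed the same way); the mean is
re-estimated and re-normalized until it moves by less than 1e-10. The
objective (summed squared distances to the mean) is recorded per iteration
and is non-increasing. Per-landmark SD is the root of the summed coordinate
variances of aligned positions; "variable regions" are landmarks with SD
strictly above the mean SD, with a 1e-9 absolute floor (aligned shapes have
unit size, so anything smaller is numerical noise).

The Procrustes ANOVA statistic is the classical F ratio on the flattened
aligned coordinates; the permutation p-value uses the add-one rule
`(1 + #{perm ≥ obs}) / (1 + n_perm)` (default 100 permutations), so p is
never 0 and lives on a grid.

## Elliptical Fourier descriptors

Kuhl–Giardina coefficients with **arc-length** parameterization of the
polygonal outline, computed by the exact piecewise-linear integrals; the dc
term is the trapezoid average of the coordinates over arc length. Four
harmonics (16 coefficients) are the default order. One consequence of arc
length worth stating: a non-circular ellipse is *not* a one-harmonic shape
under this parameterization (a 2:1 ellipse has a₃ ≈ 0.129 when a₁ ≈ 1.83);
the circle is the exact one-harmonic fixed point. The tests treat the
circle as the analytic limit and check the ellipse against an independent
quadrature oracle.

Normalization is the conventional first-ellipse procedure: shift the
parameter origin onto the first harmonic's semi-major axis, rotate that
axis onto x, and scale by its length (a₁ → 1, b₁, c₁ → 0). The residual
half-turn ambiguity of the major axis is broken deterministically by
choosing the candidate whose coefficient vector, rounded to 8 decimals, is
lexicographically larger — invariant to the input's rotation, scale and
starting vertex up to ~1e-8 noise. A circular first harmonic (axis
undefined) falls back to the identity rotation with a warning. The size
coefficient a₁ is retained in output but excluded from the cross-specimen
PCA.

## Shape discovery (VAE)

Inputs are binarized, calyx-free silhouettes resized to 64×64 — shape only,
so color cannot confound the clustering. Encoder: four 3×3 convolutions
with stride 2 and ReLU (channels 8, 16, 32, 32), flattened into two dense
heads for μ and log σ². Decoder: dense, reshape, four transposed
convolutions mirroring the encoder, final sigmoid. Loss: pixelwise binary
cross-entropy summed over pixels plus β times the KL divergence
`½(μ² + σ² − ln σ² − 1)` summed over the 8 latent dimensions, both averaged
over the batch; β = 1. Training uses Adam (lr 1e-3, batch 32); weights,
shuffling and the reparameterization draw all flow from one integer seed,
so a rerun is bitwise identical. The network core is a small numpy
framework (`fruitmorph.nn`) — im2col convolutions, transposed convolutions
via zero-dilation, max pooling, Adam — whose every layer is verified
against central-difference gradients in the tests.

The number of shapes is `argmax_k silhouette(k-means(μ), k)` for
k ∈ [2, 9] with 10 greedy-seeded restarts; ties break to smaller k;
clusters of one have silhouette 0. Decoding a k-means centroid yields the
cluster-typical silhouette. The silhouette-vs-k curve is exposed for
inspection (`plots.plot_silhouette_by_k`).

## Internal color

A convolutional denoising autoencoder (two conv + max-pool stages down, two
transposed-conv stages up, sigmoid output, MSE loss; Adam lr 1e-2, 40
epochs, additive Gaussian corruption σ = 15/255) smooths the cut-face
tiles. Fruit pixels (background is exactly black by the tile contract) are
clustered with k-means, k = 4; each cluster's mean is assigned to the
nearest reference color by Euclidean distance in raw RGB (CIELAB distance
is available but off by default, matching how the reference coordinates are
specified); clusters mapping to the same reference pool their shares, and
references with no cluster report 0. Percentages are reported both over all
four classes and flesh-only (green excluded, renormalized), since the green
class absorbs sepals.

## Genetics

A is built by the tabular method (`a_ii = 1 + ½a_sd`,
`a_ij = ½(a_{j,s} + a_{j,d})`), exact under inbreeding. D uses the
classical non-inbred approximation
`d_ij = ¼(a_ss' a_dd' + a_sd' a_ds')`, `d_ii = 1`; with related parents
this deviates from true identity-by-descent fraternity (gene-dropping shows
deviations up to ~0.1 on pedigrees with half-sib parents), which is a known
property of the formula, not an implementation artifact — the tests pin the
formula on designs where it is exact. Founders are assumed unrelated and
non-inbred except where records link them.

The model has a single residual term ε ~ N(0, Iσ²). The Gibbs sampler
works in the eigenbasis of each kernel, where the full conditional
precision of the transformed effects is diagonal: with A = U S Uᵀ and
a = Uγ, each γᵢ has precision `1/σ²_ε + 1/(sᵢ σ²ₐ)`, so a sweep costs a few
matrix-vector products. Eigenvalues below 1e-8 (relative) are truncated.
Variance priors are scaled-inverse-χ² with df = 5; the default scales put
half of var(y) on genetics (split equally between a and d) and half on the
residual, matching common practice for Bayesian RKHS regression. Defaults:
20 000 iterations, 5 000 burn-in, thinning 10. h² fractions are computed
from posterior-mean variances; per-sample fractions give credible
intervals. A split-chain potential-scale-reduction diagnostic on σ²ₐ is
reported in `summary()` and flags Rhat > 1.1.

On a simulated 24-cross × 20-offspring design (510 individuals) with
(σ²ₐ, σ²_d, σ²_ε) = (0.3, 0.3, 0.4), posterior means averaged over five
data replicates land within ±0.12 of the truth and h²ₐ + h²_d within ±0.15
of 0.6 — additive and dominance variance are partially confounded in a
single-generation full-sib design, so per-replicate estimates scatter more
than the averaged ones; the acceptance test asserts the averaged errors.

## Synthetic data: what it shows and what it does not

`fixtures` renders fruit silhouettes as radius-modulated ellipses (polar
ellipse radius times a low-order cosine perturbation, total amplitude =
`boundary_noise` ≤ 0.2) — star-shaped by construction, so radial
landmarking is always well-defined. Two families encode the study contrast:
globose (aspect 1.0) and elongated (aspect 2.0, SD 0.1), boundary noise
0.05 by default. Boards place non-overlapping fruits below a near-white
label card with glyph-like strokes on a near-black background (level 15);
fruits get a base color, a mild radial shading and σ = 4 pixel noise so
color statistics are non-degenerate. Phenotypes are drawn with covariance
`Aσ²ₐ + Dσ²_d + Iσ²_ε` through symmetric square roots of the kernels.

Passing tests on these fixtures demonstrate the correctness of the
geometry, the estimators and the pipeline plumbing under controlled
conditions. They do not demonstrate robustness to real-photo nuisances the
generator omits: shadows and uneven illumination, fruit-to-fruit contact,
specular highlights, textured or wet backgrounds, achenes, real calyx
geometry, camera distortion, or OCR of real label text. The discussion of
scope in the README applies: images must be taken on a homogeneous dark
surface under fixed camera settings.

## Problem sizes and seeds

The test and acceptance workloads are sized for a single CPU: VAE runs use
200 silhouettes at 64×64 for up to 30 epochs; the shape-count robustness
check uses 10 data seeds at 10 epochs; the ANOVA calibration uses 500 label
nulls over one 20-shape alignment; the variance-recovery check uses 5
replicates of the 510-individual design at the full 20 000-iteration chain;
gene-dropping oracles use 10⁶ allele drops. Every stochastic step takes an
explicit integer seed; the pipeline derives per-stage seeds from one global
seed by hashing, so stages are independently reproducible.
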