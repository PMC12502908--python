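# Methods

This note documents the models, numerical choices and limitations behind
`ssfembed`, in the spirit of a methods appendix: what each stage assumes, why
the defaults are what they are, and what the synthetic validations do and do
not establish.

## The signaling structure function

A cell's signaling state is summarized by H = c − n, the difference between
the normalized cytoplasmic and nuclear intensities. H is a metric function of
(c, n): |H(c₁, n₁) − H(c₂, n₂)| depends only on the difference
(c₁ − n₁) − (c₂ − n₂), so a fixed perturbation in intensity space moves the
readout by a fixed amount regardless of the base point. The conventional
cytonuclear ratio C/N (and the variant C/(C+N)) lack this property, which is
why distances computed from them are not comparable across conditions; both
baselines are implemented for comparison (`cn_ratio`, `cn_fraction`) and the
non-metricity is asserted by tests.

H is measured by a Laplacian-of-Gaussian filter rather than segmentation.
The d-dimensional kernel is the scale-normalized

K(x) = (Σᵢ (xᵢ/σᵢ)² − d) · Πᵢ G(xᵢ; σᵢ),

assembled separably as a sum over axes of one second-derivative factor
((x/σ)² − 1)G(x) times plain Gaussian factors on the other axes. Per-axis σ
handles anisotropic voxels; off-diagonal covariance (oriented ellipses) is
deliberately not supported.

**Radius-to-sigma mapping.** The filter's only parameter is the expected cell
radius r in μm. We use the zero-crossing relation σ = r / (√d · voxel size)
per axis, which is the radius at which the d-dimensional LoG response to an
ideal disk/sphere peaks; a linear mapping σ = r/d is available via
`sigma_rule="linear_d"` for comparison. Radii producing σ < 0.3 voxels on
any axis are rejected by name of the offending axis.

**Truncation and boundaries.** Kernels are truncated at ceil(4σ) voxels per
axis (< 1e-4 tail mass). At every voxel — boundary voxels whose footprint
protrudes included — the effective kernel is re-centered to sum to zero by
subtracting its in-image mean. The correction is computed separably (two
extra box passes), so a constant image gives an exactly zero response
everywhere and boundary artifacts are suppressed. Tests verify the separable
path against a dense convolution oracle to 1e-8 and scale invariance of the
matched-disk response to within 5% over radii 4–12 px.

**Calibration.** Raw responses are divided by the reference response: the
extremal LoG value for an ideal zero-intensity spheroid of the same radius on
a unit background, computed once and cached per (radius, voxel size,
dimensionality). This puts the response on the absolute [−1, 1] activation
scale — an ideal fully activated cell reads exactly 1 — which the absolute
phantom recoveries require. Calibration is on by default but optional, since
for relative analyses the pooled quantization normalizes scale anyway.

**Sign convention.** A dark nucleus on bright cytoplasm (activated KTR)
gives a positive response; a bright nucleus (e.g. an H2B marker) gives a
negative one. The multiscale sweep keeps, per voxel, the response of maximal
magnitude over the radius list (default 4.0–6.0 μm in 0.5 steps) with its
sign, and records the winning radius.

## Detection and linking

Detection is unsupervised. The nuclear channel is denoised by non-local
means (patch size 7, search distance 10, strength 1.15× the wavelet-estimated
noise σ — strong enough that the empirical SSF threshold below is meaningful
on noisy input). Foreground is where the calibrated H2B response is below
−0.01, the empirical threshold used unchanged across datasets. Touching
cells are split by a watershed on the *combined* response — the per-voxel
max-magnitude multiscale responses of all channels, summed — seeded at local
minima of that combined response.

Markers must be deeper than max(0.01, 0.1 × the frame's deepest minimum).
The relative floor exists because non-local-means residuals are spatially
correlated and carve shallow minima (depth ~0.02–0.03) that clear the tiny
absolute threshold, while true nuclei produce minima an order of magnitude
deeper (~0.6); a dim cell more than 10× shallower than the frame's deepest
nucleus would be missed, a tradeoff we accept and expose as
`marker_rel_depth`. Foreground containing no marker is discarded. Each
watershed region yields one detection at its |response|-weighted centroid.

Linking is greedy mutual-nearest-neighbor between consecutive frames under a
displacement gate — two detections link only if each is the other's nearest
neighbor and the displacement is within the gate. This is deliberately not a
multi-frame tracker (no lineaging, no division handling, no error
correction): the velocity readout only needs adjacent-frame displacements.
The per-centroid velocity value is the mean of the two adjacent step lengths
(single step at track endpoints) divided by the gate, clipped to [0, 1].

## Quantization

Compression backends need 8-bit input. All nonzero voxels of all volumes in
an experiment are pooled into a multiset V; 254 linearly spaced boundaries on
(μ(V) − σ(V), μ(V) + σ(V)) define 255 bins mapped to codes 1–255, saturating
below/above the range; code 0 is reserved for "no cell". Pooling across the
experiment keeps volumes byte-comparable. Degenerate pools (σ = 0) map to
the central code 128. For 3D+time movies, a sign-preserving
maximum-magnitude projection along z is applied *before* quantization, so
inhibition is not erased by weaker activation in the same column.

## Compression distances

NCD(x, y) = (Z(xy) − min(Z(x), Z(y))) / max(Z(x), Z(y)), with concatenation
along the time axis (temporal redundancy is the signal of interest). The
default backend compresses the raw voxel stream in fixed (t, y, x) order
with LZMA at preset 6; its large dictionary is what lets Z(xy) exploit
redundancy between the two halves, which windowed codecs (zlib) lose beyond
32 KB. An external FLIF binary is supported via subprocess and fails loudly
when absent — never a silent substitution, because NCD values are
backend-dependent and every distance matrix records its backend.

In the pairwise matrix, each unordered pair is compressed once in canonical
order (the standalone `ncd` averages both orders), the diagonal is forced to
zero, and byte-identical volumes are assigned distance zero by content hash:
real compressors report a small positive self-NCD (~0.08 for LZMA on these
volumes), but the information distance between identical objects is zero and
classical scaling needs a proper dissimilarity.

## Embedding

Classical multidimensional scaling: square the dissimilarities, double-center
(B = −½ J D² J), eigendecompose, scale eigenvectors by √eigenvalue. Exactly
Euclidean inputs are reproduced to numerical precision (tested at 1e-6);
NCD matrices are not exactly Euclidean, so negative eigenvalues appear —
they are dropped and their total magnitude reported (`dropped_mass_`), never
silently. Eigenvector signs are fixed by making each column's
largest-magnitude loading positive, so embeddings are reproducible.
Double-centering was chosen over eigendecomposing the raw dissimilarity
matrix because only the former has the distance-preservation property the
embedding is used for; the raw variant is kept behind `center=False` for
comparison. The embedding dimension defaults to the number of ground-truth
classes (capped at n − 1), per spectral-learning practice. The transformer
(`ClassicalScalingEmbedding`) follows scikit-learn conventions; there is no
out-of-sample extension.

## Cluster structure function

In compression form, the optimality deficiency of member yᵢ of cluster Y is
δ = Z(Y) + log₂|Y| − Z(yᵢ), with Z in bytes and the log in bits
(Kolmogorov convention; the base is configurable) — the mixed units follow
the defining formula as printed in the structure-function literature and are
documented rather than "fixed". Concatenating whole clusters of large
movies is intractable, so the working form evaluates the same idea in the
embedding: δ is the Euclidean distance of a point to its own cluster
centroid. Per-cluster deficiency means are averaged across the K clusters
(mean and std over the K per-cluster means); a per-element aggregation
(mean/std over all n points) is also reported because both summaries appear
in practice and they differ when cluster sizes are unequal. Paired
comparisons use the two-sided Wilcoxon signed-rank test; identical vectors
have no nonzero differences to rank and are reported as p = 1.

## Synthetic data

**KTR phantom.** A dark nucleus (radius 5 px, intensity 0) on a bright field
(intensity 1), cytoplasm annulus out to 20 px, 65×65 px — odd so the cell
sits on a voxel center, matching the voxel-centered calibration disk (an
even size alone biases recovery by ~1.5%). Activation a sets a
per-compartment flip rate p = (1 − a)/2: nuclear pixels flip white,
cytoplasmic pixels flip black, independently. Expected compartment
intensities are then ((1 + a)/2, (1 − a)/2) and the expected SSF is exactly
a; at a = 0.6 this is the 20%-white/20%-black ("40% shot noise") condition.
The filter is linear, so the mean recovered SSF over trials converges to the
response of the expected image, which the tests verify is within 0.03 of a
and linear in a (slope 1 ± 0.05).

**Velocity corpus.** Per image, 10 tracks with per-track constant speed
drawn from Normal(class mean, 0.5) truncated positive, class means
{1, 3, 5} px/frame, uniform random headings and start positions, reflecting
boundaries, 64 frames of 128×128 px (full scale: 100 images per class).
Field size, frame count, heading distribution and boundary behavior are not
dictated by the underlying experiment description; these defaults were
chosen once as a realistic imaging-field scale and are recorded in each
corpus's JSON spec. The velocity channel stores speed normalized by
(max class mean + 3σ) so values lie in (0, 1]; the control channel stores an
independent uniform integer in [1, 255] rescaled to (0, 1].

**Moving-nuclei movies.** Gaussian blobs (σ = radius/2, peak 1) with exact
ground-truth tracks; starts are rejection-sampled to keep nuclei ≥ 4 radii
apart so the ground-truth per-frame count is unambiguous. Optional additive
Gaussian noise.

What these generators do *not* emulate: point-spread blur, photobleaching,
uneven illumination, cell divisions and deaths, shape variation, or
out-of-focus light. Passing tests therefore establish the correctness of
the measurement and embedding machinery under controlled conditions, not
performance on real microscopy, where denoising quality and the empirical
threshold matter far more.

## Problem sizes and determinism

The shipped validation runs the velocity experiment at 20 images per class
(60 movies, 1 770 pair compressions per channel) and the phantom recovery at
100 trials per activation — sizes chosen so the whole suite completes on a
single CPU in minutes while leaving the statistics stable; the corpus scale
is a parameter throughout. All randomness flows through explicit
`numpy.random.Generator` seeds; same spec + seed gives bit-identical corpora
and, with a fixed backend, bit-identical embeddings.

## Known limitations

- Absolute NCD and CSF values are backend-dependent; with the LZMA stream
  backend the within-class/between-class NCD contrast on the velocity corpus
  is small (≈ 0.92 vs 0.95) and most eigenvalue mass is non-Euclidean, so
  CSF magnitudes are an order of magnitude smaller than with an image-aware
  codec, even though the orderings and class separability are stable. Only
  like-backend CSF values should ever be compared.
- `run_ssf` currently handles single-z movies end to end; for 3D+time data
  the per-stage functions (detection per 3D frame, `mip_z`, quantization)
  must be composed explicitly.
- The mutual-nearest-neighbor linker fragments tracks when cells pass within
  a gate of each other; fragmented tracks bias velocities near endpoints
  (single-step estimates).
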