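# Methods

## Model and procedure

The filter treats de-speckling as non-local weighted averaging with a
restricted, orientation-compensated candidate set.  The stages, in run
order:

1. **Gaussian guide blur.**  The noisy image ν is convolved with a
   normalised isotropic Gaussian mask `Gk_σ` on a (2m+1)×(2m+1) support
   (mirror boundaries).  The blurred image `Gb = Gk_σ ∗ ν` is a *guide*: it
   drives feature extraction and clustering only.  Restored intensities and
   patch distances are always read from the original noisy image — wiring
   the blurred image into the averaging itself would smooth twice, once by
   the kernel and once by the weights.  A toggle (`restore_from_guide`)
   exposes the alternative reading for comparison.

2. **Per-patch features.**  Every pixel owns a 15×15 patch (radius r = 7).
   Its descriptor is Hu's seven moment invariants of the *intensity-
   weighted* central moments, with the distribution normalised to unit
   total mass before the invariants are formed.  Two deliberate choices:
   - *Intensity weighting*: patches are gray-valued, and the block-matching
     centroid (below) is intensity-weighted; using the same weighting for
     the moments keeps the two consistent (binary shape moments would
     require a segmentation that does not exist here).
   - *Unit-mass normalisation* (η_pq = μ_pq/μ00): the classical
     η = μ/μ00^(1+(p+q)/2) exponent confers geometric-size invariance for
     binary shapes but is **not** invariant to intensity scaling of
     gray-weighted moments (each φ picks up a factor c^-(p+q)/2 under
     ν → c·ν).  Patch geometry is fixed here, so the property that matters
     is gain/brightness invariance, which unit-mass normalisation provides
     exactly.  φ7's sign (flips under mirroring, stable under rotation) is
     the mirror detector.
   Moments to third order are computed even though the descriptor is often
   described by its low-order terms, because φ3…φ7 require them.  The
   whole-image feature field is computed by correlating the guide with
   monomial kernels x^p·y^q and applying the binomial shift identities;
   this path is tested for equivalence against the per-patch double sum.

3. **Pre-classification.**  The per-pixel feature vectors are standardised
   per component (zero mean, unit variance; components with zero variance
   pass through as zeros) and partitioned by Lloyd's K-means with seeded
   k-means++ initialisation.  Standardisation is on by default because raw
   Hu components span many orders of magnitude and an unstandardised
   Euclidean objective is dominated by φ1; a flag restores raw-feature
   clustering.  Assignment ties break to the lowest cluster index; empty
   clusters are repaired by relocating the feature farthest from its
   center into the empty cluster (relocation, rather than reseed-and-
   reassign, keeps the objective non-increasing and terminates even when
   features are exact duplicates, e.g. on constant images).  The fit
   records the within-cluster sum of squares after every assignment so the
   monotonicity contract is checkable on every run.  The result is a
   look-up table (LUT): per cluster, the row-major list of member patch
   centers.  K defaults to 675 for a 225×225 image and scales with pixel
   count for other sizes (minimum 1); singleton clusters are legal — their
   pixel is restored as itself.

4. **Rotation- and mirror-compensated matching.**  For target i and
   candidate j in the same cluster:
   - mirroring is flagged when φ7(i)·φ7(j) < 0 (strict inequality: zero φ7
     never flags);
   - each patch's intensity centroid over the *circular* support (radius
     r inscribed in the square patch, so a rotated support never leaves
     the square) gives a direction; the frame `R = R_ci⁻¹ · R_m(cj)` is
     built from **unit-normalised** centroid directions — unnormalised
     centroids would make `R_u` a rotation-plus-scaling and corrupt the
     distance.  In the mirrored branch the candidate direction's x
     component is flipped before entering `R_u`, and the mapped point is
     flipped again after rotation.
   - the distance `dR(i,j)` sums squared intensity differences over the
     circular support, sampling the candidate patch at the rotated
     (fractional) coordinates by bilinear interpolation from the
     reflect-padded noisy image (margin ⌈r√2⌉+1, so any rotated offset
     stays in bounds).  `dR` is an unweighted sum; the Gaussian α-weighting
     of the similarity term belongs to the conventional-NLM baseline only.
   - patches whose centroid offset norm falls below ε_c = 1e-6 px are
     isotropic to first order: no rotation is estimable, and the distance
     falls back to the plain unrotated sum.  This is a fallback, not a
     skip — isotropic patches do not need rotation compensation.

5. **Reconstruction.**  `NLMp(ν)(i) = Σ_j wR(i,j) ν(j)` over the cluster
   members, `wR = exp(-dR/h²)/ZR(i)`, h = 12·σ_noise.  The self-candidate
   keeps dR = 0 (raw weight 1, the maximum): no self-weight cap is
   applied, since the cluster restriction already limits any one
   candidate's dominance.  Restoration is per-pixel; there is no patchwise
   aggregation step.  Output intensities are convex combinations of input
   intensities, so the output range never exceeds the input range; float
   intensities are only clipped/quantised at image write-out.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `patch_radius` | 7 | 15×15 patches; circular support radius for matching |
| `sigma_noise` σ | 20 | assumed noise SD on the 0–255 scale; drives the defaults below |
| `h` | 12·σ | weight bandwidth; larger → flatter weights, more smoothing |
| `kernel_sigma` | 0.5·σ | guide-blur SD |
| `kernel_radius` m | 4 | guide-blur mask radius (9×9) |
| `n_clusters` K | 675·(hw/225²) | candidate-set granularity; too large starves clusters of candidates |
| `standardize_features` | on | z-score Hu components before K-means |
| `rotation_enabled` | on | disable to get plain cluster-restricted NLM |
| `max_candidates` | off | deterministic per-cluster subsample bounding worst-case cost |
| `centroid_eps` | 1e-6 px | centroid norm below which no rotation is estimable |
| `seed` | 0 | all stochastic stages (k-means++ init, optional subsampling) |

The per-pixel matching loop is JIT-compiled (numba) with fast floating-
point reassociation enabled; results differ from the strict-order pure-
Python reference path (`weights_ribm`, `ribm.distance_dR`) only at the
~1e-13 relative level, which the equivalence tests cover.  Given identical
inputs, configuration and seed, repeated runs are bit-identical.

## Synthetic data

The phantom generator emulates what matters to this filter: piecewise-
smooth anatomy (elliptical hypo-/hyper-echoic lesions, default offsets
−55/+45 on background 120), a smooth stochastic texture (Gaussian field,
correlation length 3 px, SD 8) standing in for tissue echogenicity
variation, and two degradations — additive zero-mean Gaussian noise with
SD σ on the 0–255 scale (the model used by the replication experiments,
σ ∈ {10, 20, 50}), and a unit-mean log-normal multiplicative speckle model
with relative SD σ/255, reflecting speckle's multiplicative character.
The oriented-motif phantom stamps one anisotropic off-center blob at four
orientations (continuous spline resampling) to probe rotation
compensation directly.

What the phantoms do **not** emulate: the acoustic point-spread function,
fully developed Rayleigh speckle statistics, attenuation/TGC gradients,
shadowing and enhancement artifacts, or real anatomical texture.  Passing
tests therefore demonstrate the pipeline's contracts and its noise-
suppression behaviour under controlled degradations, not clinical-grade
performance on real B-mode frames.

## Numerical choices and degenerate inputs

- Borders: mirror reflection everywhere (padding, convolution, feature
  correlations), so border patches carry no dark bias; the edge pixel is
  not duplicated.
- All-zero (mass-free) patches map to the zero feature vector at the
  pipeline layer and cluster like any other vector; their centroid is a
  flagged degenerate state, so matching falls back to unrotated distances.
- K-means uses relative objective tolerance 1e-6 with a 100-iteration cap
  and stops at assignment fixed points.
- Bilinear sampling is exact at integer offsets; an exact-identity frame
  therefore reproduces the plain distance exactly.
- PSNR of identical images is the +inf sentinel, never an exception; the
  dynamic range defaults to the declared 0–255 scale with an option to use
  the reference's observed range.
- SSIM is the windowed form (11×11 Gaussian window, σ=1.5,
  C1=(0.01L)², C2=(0.03L)²); a global single-statistic variant is provided
  for comparison.

## Problem sizes

The self-contained experiments run at 128×128 (K = 218 by the pixel-count
scaling rule) for denoising efficacy, 24×24 for brute-force oracle
equivalence (the reference implementations are quadratic), and 16×16 for
convolution oracles.  These sizes were chosen so every oracle can be an
independent brute-force computation while the stochastic efficacy checks
still average over 20 noise realisations.

## Known limitations

- Centroid-based angle estimation needs a clearly anisotropic intensity
  distribution; on noise-dominated near-isotropic patches the estimated
  angle is noise-driven (the distance then behaves like a randomly rotated
  comparison, which is why the isotropic fallback exists but cannot trigger
  on noisy patches whose centroid norm exceeds ε_c).
- Cost is Σ_k |cluster_k|² distance evaluations; heavily skewed cluster
  size distributions (large homogeneous regions) dominate runtime.
  `max_candidates` bounds this deterministically at some cost in fidelity.
- The conventional-NLM baseline is quadratic in pixel count by design and
  guarded to small images.
- Only single-frame 2-D grayscale processing: no DICOM ingestion, cine
  loops, 3-D volumes, or Doppler overlays.
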