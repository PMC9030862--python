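# ribmnlm — rotation-invariant block-matching non-local means de-speckling

Speckle is the granular interference noise of coherent imaging: in B-mode
breast ultrasound it creates fine false structures, blurs true tissue
boundaries and degrades every downstream step (segmentation, feature
extraction, lesion classification).  `ribmnlm` implements a non-local-means
(NLM) de-speckling filter whose candidate search is both **pre-classified**
(K-means clustering of image patches on Hu's moment invariants, so
candidates may come from anywhere in the image, not just a spatial search
window) and **rotation/mirror-compensated** (candidate patches are rotated
into the target patch's orientation before their distance is measured), for
example to match the same tissue texture occurring at different
orientations.

## Method

For a noisy image `v`, classical NLM restores each pixel `i` as a weighted
average over candidate pixels `j`,

    NL(v)(i) = Σ_j w(i,j) v(j),   w(i,j) = exp(-||v(N_i) - v(N_j)||²_{2,α} / h²) / Z(i),

with `N_i` the patch around `i` and `h` the filtering bandwidth.  This
package's filter modifies both the candidate set and the distance:

1. **Guide blur.** The noisy image is convolved with a normalised Gaussian
   (σ_kernel = 0.5·σ_noise, radius m = 4) to form a guide image used only
   for feature extraction and clustering.
2. **Pre-classification.** Every pixel's 15×15 guide patch is summarised by
   Hu's seven rotation-invariant moments φ1…φ7 (intensity-weighted central
   moments normalised to unit mass, so brightness differences do not
   matter).  The feature vectors are standardised and partitioned by
   K-means (K = 675 for a 225×225 image, scaled with pixel count) into a
   look-up table of cluster members.
3. **Rotation-invariant block matching.** For a target patch `N_i` and a
   same-cluster candidate `N_j`, the sign of φ7 detects mirroring, and the
   intensity centroids of the two patches define the rotation frame
   `R = R_ci⁻¹ · R_m(cj)` aligning them.  The rotation-invariant distance

       dR(i,j) = Σ_q ( v_i(q) - In(v_j, m(R q)) )²

   sums squared differences over the circular patch support, sampling the
   candidate by bilinear interpolation `In` at the rotated coordinates.
4. **Reconstruction.** `NLMp(v)(i) = Σ_{j∈cluster(i)} wR(i,j) v(j)` with
   `wR(i,j) = exp(-dR(i,j)/h²) / ZR(i)` and `h = 12·σ_noise`, reading
   intensities from the original noisy image.

Quality is assessed with SSIM, PSNR, MSE and RMSE against the clean
reference.  A synthetic phantom generator (elliptical hypo-/hyper-echoic
lesions on textured background, additive Gaussian or multiplicative
log-normal speckle) makes the whole pipeline testable without external
data.

## Worked example

```python
import numpy as np
from ribmnlm import (DenoiseConfig, NoiseSpec, add_noise, default_phantom_spec,
                     despeckle_ribm_nlm, evaluate_pair, make_phantom)

clean = make_phantom(default_phantom_spec(128, 128, seed=0))
noisy = add_noise(clean, NoiseSpec(model="additive_gaussian", sigma=20.0, seed=1))
restored = despeckle_ribm_nlm(noisy, DenoiseConfig(sigma_noise=20.0, seed=1))

for name, img in [("noisy", noisy), ("restored", restored)]:
    rec = evaluate_pair(clean, img)
    print(f"{name:9s} SSIM={rec.ssim:.4f}  PSNR={rec.psnr:.2f} dB  "
          f"MSE={rec.mse:.1f}  RMSE={rec.rmse:.2f}")
```

prints

```
noisy     SSIM=0.2257  PSNR=22.15 dB  MSE=396.0  RMSE=19.90
restored  SSIM=0.8608  PSNR=31.59 dB  MSE=45.1  RMSE=6.72
```

i.e. at noise level σ = 20 the filter raises structural similarity from
0.23 to 0.86 and PSNR by ~9.4 dB on the default phantom: lesion boundaries
are preserved while the granular noise is averaged away within clusters of
structurally similar patches.

The same operations are available from the shell:

```
ribmnlm phantom --height 128 --width 128 --seed 0 --out clean.png
ribmnlm addnoise clean.png noisy.png --sigma 20 --seed 1
ribmnlm despeckle noisy.png restored.png --sigma 20 --seed 1
ribmnlm evaluate clean.png restored.png
ribmnlm experiment --phantom-size 128 --sigmas 10,20,50 --outdir results/
ribmnlm ksweep noisy.png --sigma 20 --k-values 25,50,100,200
```

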