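import math

import numpy as np
import pytest

from ribmnlm.image_core import pad_reflect, support_offsets
from ribmnlm.nlm_filter import (
    DenoiseConfig,
    NLMParams,
    compute_feature_store,
    despeckle_ribm_nlm,
    nlm_conventional,
    weights_ribm,
)
from ribmnlm.phantom_sim import NoiseSpec, add_noise, default_phantom_spec, make_phantom
from ribmnlm.preprocess import gaussian_blur, gaussian_kernel
from ribmnlm.quality_metrics import psnr


def brute_force_nlm(img, h, alpha, radius):
    """Triple-loop conventional NLM oracle (Gaussian-weighted patch distance)."""
    H, W = img.shape
    pad = pad_reflect(img, radius)
    n = 2 * radius + 1
    dy, dx = np.mgrid[-radius:radius + 1, -radius:radius + 1].astype(float)
    G = np.exp(-(dx**2 + dy**2) / (2 * alpha**2))
    G /= G.sum()
    out = np.zeros_like(img)
    for r in range(H):
        for c in range(W):
            Ni = pad[r:r + n, c:c + n]
            wsum = 0.0
            acc = 0.0
            for r2 in range(H):
                for c2 in range(W):
                    Nj = pad[r2:r2 + n, c2:c2 + n]
                    d = float((G * (Ni - Nj) ** 2).sum())
                    w = math.exp(-d / h**2)
                    wsum += w
                    acc += w * img[r2, c2]
            out[r, c] = acc / wsum
    return out


def brute_force_cluster_nlm(img, h, radius):
    """Unrotated, cluster-unrestricted filter oracle: every pixel a candidate,
    plain squared distance over the circular support, weights exp(-d/h²)."""
    H, W = img.shape
    margin = math.ceil(radius * math.sqrt(2.0)) + 1
    pad = pad_reflect(img, margin)
    dx, dy = support_offsets(radius)
    P = np.stack([
        pad[r + margin + dy, c + margin + dx]
        for r in range(H) for c in range(W)
    ])
    sq = np.einsum("ij,ij->i", P, P)
    D = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (P @ P.T), 0.0)
    np.fill_diagonal(D, 0.0)
    Wm = np.exp(-D / h**2)
    return ((Wm @ img.ravel()) / Wm.sum(axis=1)).reshape(H, W)


class TestConventionalNLM:
    def test_constant_image_fixed_point(self):
        img = np.full((10, 10), 42.0)
        out = nlm_conventional(img, NLMParams(h=100.0, radius=3))
        np.testing.assert_allclose(out, 42.0, rtol=1e-12)

    def test_flat_weight_limit_gives_global_mean(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, (8, 8))
        out = nlm_conventional(img, NLMParams(h=1e9, radius=2))
        np.testing.assert_allclose(out, img.mean(), atol=1e-6)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 255, (12, 12))
        params = NLMParams(h=240.0, radius=3)
        got = nlm_conventional(img, params)
        want = brute_force_nlm(img, params.h, params.resolved_alpha, params.radius)
        np.testing.assert_allclose(got, want, rtol=1e-9)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            NLMParams(h=0.0)
        with pytest.raises(ValueError):
            NLMParams(h=1.0, radius=0)


class TestWeightsRibm:
    @pytest.fixture()
    def small_setup(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 255, (20, 20))
        cfg = DenoiseConfig(sigma_noise=20.0, patch_radius=3, n_clusters=4, seed=0)
        guide = gaussian_blur(img, gaussian_kernel(10.0, 4))
        store = compute_feature_store(guide, 3)
        return img, cfg, store

    def test_singleton_candidate_weight_one(self, small_setup):
        img, cfg, store = small_setup
        ws = weights_ribm(img, (5, 5), [(5, 5)], cfg, store)
        np.testing.assert_array_equal(ws.normalized, [1.0])

    def test_two_candidate_closed_form(self, small_setup):
        img, cfg, store = small_setup
        cfg_plain = DenoiseConfig(sigma_noise=20.0, patch_radius=3,
                                  rotation_enabled=False)
        ws = weights_ribm(img, (5, 5), [(5, 5), (12, 9)], cfg_plain, store)
        margin = math.ceil(3 * math.sqrt(2)) + 1
        pad = pad_reflect(img, margin)
        dx, dy = support_offsets(3)
        d = float(((pad[5 + margin + dy, 5 + margin + dx]
                    - pad[12 + margin + dy, 9 + margin + dx]) ** 2).sum())
        h2 = (12.0 * 20.0) ** 2
        e = math.exp(-d / h2)
        np.testing.assert_allclose(ws.normalized, [1 / (1 + e), e / (1 + e)],
                                   rtol=1e-12)

    def test_weights_normalised_over_random_configurations(self, small_setup):
        img, cfg, store = small_setup
        rng = np.random.default_rng(3)
        for _ in range(50):
            m = int(rng.integers(1, 12))
            cands = [tuple(rng.integers(0, 20, 2)) for _ in range(m)]
            center = cands[int(rng.integers(0, m))]
            ws = weights_ribm(img, center, cands, cfg, store)
            assert abs(ws.normalized.sum() - 1.0) < 1e-9
            assert np.all(ws.normalized >= 0) and np.all(ws.normalized <= 1)

    def test_candidate_order_invariance(self, small_setup):
        img, cfg, store = small_setup
        cands = [(5, 5), (3, 12), (15, 2), (9, 9)]
        ws1 = weights_ribm(img, (5, 5), cands, cfg, store)
        ws2 = weights_ribm(img, (5, 5), cands[::-1], cfg, store)
        np.testing.assert_allclose(ws1.normalized, ws2.normalized[::-1],
                                   rtol=1e-12)
        v1 = ws1.normalized @ [img[c] for c in cands]
        v2 = ws2.normalized @ [img[c] for c in cands[::-1]]
        assert abs(v1 - v2) < 1e-12 * max(1.0, abs(v1))

    def test_empty_candidate_list_rejected(self, small_setup):
        img, cfg, store = small_setup
        with pytest.raises(ValueError):
            weights_ribm(img, (5, 5), [], cfg, store)


class TestDespeckle:
    def test_constant_image_unchanged(self):
        img = np.full((24, 24), 77.0)
        out = despeckle_ribm_nlm(img, DenoiseConfig(sigma_noise=20.0, n_clusters=4))
        np.testing.assert_allclose(out, 77.0, rtol=1e-12)

    def test_k1_unrotated_matches_brute_force(self):
        rng = np.random.default_rng(4)
        img = rng.uniform(0, 255, (24, 24))
        cfg = DenoiseConfig(sigma_noise=20.0, n_clusters=1,
                            rotation_enabled=False, seed=0)
        got = despeckle_ribm_nlm(img, cfg)
        want = brute_force_cluster_nlm(img, 12.0 * 20.0, 7)
        np.testing.assert_allclose(got, want, rtol=1e-9)

    def test_output_within_input_range(self, phantom48):
        _, noisy = phantom48
        out = despeckle_ribm_nlm(noisy, DenoiseConfig(sigma_noise=20.0, seed=1))
        assert out.min() >= noisy.min() - 1e-9
        assert out.max() <= noisy.max() + 1e-9

    def test_seed_determinism_bit_identical(self, phantom48):
        _, noisy = phantom48
        cfg = DenoiseConfig(sigma_noise=20.0, seed=5)
        a = despeckle_ribm_nlm(noisy, cfg)
        b = despeckle_ribm_nlm(noisy, cfg)
        np.testing.assert_array_equal(a, b)

    def test_kernel_agrees_with_python_weight_path(self):
        rng = np.random.default_rng(6)
        img = rng.uniform(0, 255, (20, 20))
        cfg = DenoiseConfig(sigma_noise=20.0, patch_radius=3, n_clusters=5,
                            kernel_radius=2, seed=2)
        out, details = despeckle_ribm_nlm(img, cfg, return_details=True)
        table = details["cluster_table"]
        store = details["store"]
        rcfg = details["config"]
        for center in [(0, 0), (7, 13), (19, 19), (10, 4)]:
            k = table.labels[center]
            cands = table.members[k]
            ws = weights_ribm(img, center, cands, rcfg, store)
            val = float(ws.normalized @ img[cands[:, 0], cands[:, 1]])
            np.testing.assert_allclose(out[center], val, rtol=1e-9)

    def test_denoising_improves_psnr(self, phantom48):
        clean, noisy = phantom48
        out = despeckle_ribm_nlm(noisy, DenoiseConfig(sigma_noise=20.0, seed=3))
        assert psnr(clean, out) > psnr(clean, noisy)

    def test_max_candidates_caps_cluster_size(self):
        rng = np.random.default_rng(8)
        img = rng.uniform(0, 255, (16, 16))
        cfg = DenoiseConfig(sigma_noise=20.0, n_clusters=2, max_candidates=10,
                            rotation_enabled=False, seed=1)
        out = despeckle_ribm_nlm(img, cfg)
        assert out.shape == img.shape
        assert np.all(np.isfinite(out))

    def test_stage_errors_are_labelled(self):
        img = np.full((6, 6), 10.0)
        # kernel radius 4 -> 9x9 mask larger than the image: preprocess fails
        with pytest.raises(ValueError, match="preprocess stage"):
            despeckle_ribm_nlm(img, DenoiseConfig(sigma_noise=20.0))

    def test_restore_from_guide_toggle_changes_source(self, phantom48):
        _, noisy = phantom48
        a = despeckle_ribm_nlm(noisy, DenoiseConfig(sigma_noise=20.0, seed=2))
        b = despeckle_ribm_nlm(noisy, DenoiseConfig(sigma_noise=20.0, seed=2,
                                                    restore_from_guide=True))
        assert not np.array_equal(a, b)


class TestRotationBenefit:
    def test_motif_distances_lower_with_rotation(self):
        from ribmnlm import ribm
        from ribmnlm.moment_features import hu_field
        from ribmnlm.phantom_sim import make_motif_phantom

        img, centers, _ = make_motif_phantom()
        noisy = add_noise(img, NoiseSpec(sigma=5.0, seed=0))
        guide = gaussian_blur(noisy, gaussian_kernel(2.5, 4))
        r = 7
        margin = math.ceil(r * math.sqrt(2)) + 1
        pad = pad_reflect(noisy, margin)
        hu = hu_field(guide, r)
        ux, uy, valid = ribm.centroid_field(guide, r)
        plain = ribm.RotationFrame(R=np.eye(2), mirrored=False, valid=False)
        d_rot, d_plain = [], []
        for a in range(len(centers)):
            for b in range(len(centers)):
                if a == b:
                    continue
                ca, cb = centers[a], centers[b]
                ci = ribm.Centroid(vec=(ux[ca], uy[ca]), norm=1.0,
                                   unit=(ux[ca], uy[ca]))
                cj = ribm.Centroid(vec=(ux[cb], uy[cb]), norm=1.0,
                                   unit=(ux[cb], uy[cb]))
                mir = bool(hu[ca][6] * hu[cb][6] < 0)
                f = ribm.rotation_frame(ci, cj, mir)
                pa = (ca[0] + margin, ca[1] + margin)
                pb = (cb[0] + margin, cb[1] + margin)
                d_rot.append(ribm.distance_dR(pad, pa, pb, f, r))
                d_plain.append(ribm.distance_dR(pad, pa, pb, plain, r))
        assert np.mean(d_rot) < np.mean(d_plain)
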