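import numpy as np
import pytest
from scipy import ndimage as ndi

from hepavess.ced import (
    CEDParams,
    ced_diffusion_tensor,
    ced_filter,
    ced_step,
    coherence_ratio,
    enhance,
    structure_tensor,
)
from hepavess.io_volumes import BinaryMask3D, Volume3D
from hepavess.phantom import PhantomSpec, make_phantom, make_shape_probe
from hepavess.tensorfield import TensorField3D


def _st_from_mu(mu: np.ndarray):
    """Structure-tensor field with prescribed eigenvalues and identity axes."""
    from hepavess.ced import StructureTensorField

    shape = mu.shape[:-1]
    vec = np.broadcast_to(np.eye(3), shape + (3, 3)).copy()
    j = np.einsum("...ik,...k,...jk->...ij", vec, mu, vec)
    return StructureTensorField(j.astype(np.float32), mu, vec, 1.0, 2.0)


class TestStructureTensor:
    def test_constant_volume_gives_zero_tensor(self):
        st = structure_tensor(Volume3D(np.full((20, 20, 20), 3.0, np.float32)))
        assert np.abs(st.tensor).max() < 1e-8
        assert np.abs(st.mu).max() < 1e-8

    def test_linear_ramp_has_single_gradient_eigenvalue(self):
        x = np.arange(32, dtype=np.float32)
        vol = Volume3D(np.broadcast_to(x[:, None, None], (32, 32, 32)).copy())
        st = structure_tensor(vol, sigma=1.0, rho=2.0)
        core = tuple(slice(10, 22) for _ in range(3))
        np.testing.assert_allclose(st.mu[core][..., 0], 1.0, rtol=1e-3)
        assert np.abs(st.mu[core][..., 1:]).max() < 1e-4

    def test_v3_aligns_with_tube_axis(self):
        vol, mask = make_shape_probe("tube", size=48, radius=5.0)
        st = structure_tensor(vol, sigma=1.0, rho=2.0)
        # tube runs along the third axis; V3 (smallest eigenvalue) should too
        center = np.nonzero(mask.data[24, 24, :])[0]
        v3 = st.vectors[24, 24, center[10:-10], :, 2]
        assert np.abs(v3[:, 2]).min() > 0.99

    def test_positive_semidefinite(self, rng):
        vol = Volume3D(rng.normal(size=(24, 24, 24)).astype(np.float32))
        st = structure_tensor(vol)
        assert st.mu[..., 2].min() >= -1e-8
        assert np.all(np.diff(st.mu, axis=-1) <= 1e-6)  # descending


class TestCoherenceRatio:
    def test_isotropic_region_is_near_one(self):
        st = _st_from_mu(np.full((4, 4, 4, 3), 2.0))
        np.testing.assert_allclose(coherence_ratio(st), 1.0, rtol=1e-6)

    def test_zero_tensor_gives_zero(self):
        st = _st_from_mu(np.zeros((4, 4, 4, 3)))
        assert np.abs(coherence_ratio(st)).max() == 0.0

    def test_tube_centerline_ratio_is_large(self):
        vol, mask = make_shape_probe("tube", size=48, radius=5.0)
        st = structure_tensor(vol, sigma=1.0, rho=2.0)
        k = coherence_ratio(st)
        center = np.nonzero(mask.data[24, 24, :])[0]
        assert k[24, 24, center[10:-10]].min() > 10.0


class TestDiffusionTensor:
    def test_zero_coherence_gives_baseline_diffusivity(self):
        p = CEDParams()
        d = ced_diffusion_tensor(_st_from_mu(np.zeros((3, 3, 3, 3))), p).tensor
        expected = np.broadcast_to(p.alpha_reg * np.eye(3), d.shape)
        np.testing.assert_allclose(d, expected, atol=1e-8)

    def test_unit_coherence_example(self):
        # mu = (2, 1, 1): k = 1, lam3 = 0.001 + 0.999 * e^-1
        p = CEDParams(alpha_reg=0.001, C=1.0, eps_ratio=0.0)
        mu = np.broadcast_to(np.array([2.0, 1.0, 1.0]), (2, 2, 2, 3)).copy()
        d = ced_diffusion_tensor(_st_from_mu(mu), p).tensor
        lam3 = 0.001 + 0.999 * np.exp(-1.0)
        assert d[0, 0, 0, 2, 2] == pytest.approx(lam3, rel=1e-6)
        assert d[0, 0, 0, 0, 0] == pytest.approx(p.alpha_reg, rel=1e-5)

    def test_high_coherence_saturates_to_one(self):
        p = CEDParams()
        mu = np.broadcast_to(np.array([5.0, 5.0, 1e-9]), (2, 2, 2, 3)).copy()
        d = ced_diffusion_tensor(_st_from_mu(mu), p).tensor
        assert d[0, 0, 0, 2, 2] == pytest.approx(1.0, abs=1e-6)

    def test_spd_everywhere_on_random_volume(self, rng):
        vol = Volume3D(rng.normal(size=(16, 16, 16)).astype(np.float32))
        p = CEDParams()
        d = ced_diffusion_tensor(structure_tensor(vol), p)
        w = np.linalg.eigvalsh(d.tensor.astype(np.float64))
        assert w.min() >= p.alpha_reg - 1e-6
        assert w.max() <= 1.0 + 1e-6


class TestCedStep:
    def test_constant_volume_is_fixed_point(self):
        vol = Volume3D(np.full((16, 16, 16), 4.0, np.float32))
        d = ced_diffusion_tensor(structure_tensor(vol), CEDParams())
        out = ced_step(vol, d, tau=0.1)
        np.testing.assert_allclose(out.data, vol.data, atol=1e-6)

    def test_global_mean_is_conserved(self, rng):
        vol = Volume3D(rng.normal(100, 20, size=(24, 24, 24)).astype(np.float32))
        d = ced_diffusion_tensor(structure_tensor(vol), CEDParams())
        out = ced_step(vol, d, tau=0.1)
        rel = abs(out.data.mean() - vol.data.mean()) / abs(vol.data.mean())
        assert rel < 1e-5

    def test_isotropic_limit_matches_gaussian_smoothing(self, rng):
        # D = I turns the step into the heat equation; after time t the
        # solution is a Gaussian blur with sigma = sqrt(2 t)
        u0 = ndi.gaussian_filter(rng.normal(size=(32, 32, 32)), 2.0).astype(np.float32)
        vol = Volume3D(u0)
        eye = TensorField3D(np.broadcast_to(np.eye(3, dtype=np.float32),
                                            u0.shape + (3, 3)).copy())
        tau, steps = 0.1, 10  # t = 1.0
        out = vol
        for _ in range(steps):
            out = ced_step(out, eye, tau)
        ref = ndi.gaussian_filter(u0.astype(np.float64), np.sqrt(2.0 * tau * steps),
                                  mode="reflect")
        core = tuple(slice(4, -4) for _ in range(3))
        rms = np.sqrt(np.mean((out.data[core] - ref[core]) ** 2))
        assert rms / (u0.max() - u0.min()) < 0.01

    def test_unstable_tau_rejected(self, rng):
        vol = Volume3D(rng.normal(size=(8, 8, 8)).astype(np.float32))
        d = ced_diffusion_tensor(structure_tensor(vol), CEDParams())
        with pytest.raises(ValueError, match="tau"):
            ced_step(vol, d, tau=0.5)

    def test_step_does_not_amplify_max_norm(self, rng):
        vol = Volume3D(rng.normal(size=(20, 20, 20)).astype(np.float32))
        d = ced_diffusion_tensor(structure_tensor(vol), CEDParams())
        out = ced_step(vol, d, tau=0.1)
        assert np.abs(out.data).max() <= np.abs(vol.data).max() * (1 + 1e-6)


class TestCedFilter:
    def test_zero_iterations_is_identity(self, rng):
        vol = Volume3D(rng.normal(size=(12, 12, 12)).astype(np.float32))
        out = ced_filter(vol, CEDParams(n_iter=0))
        np.testing.assert_array_equal(out.data, vol.data)

    def test_noisy_tube_smoothed_but_edges_kept(self):
        vol, mask = make_shape_probe("tube", size=48, radius=5.0,
                                     contrast=60.0, noise_sigma=10.0, seed=4)
        out = ced_filter(vol, CEDParams(n_iter=10))
        tube = mask.data.astype(bool)
        bg = ~tube
        assert out.data[tube].std() < vol.data[tube].std()
        contrast_in = vol.data[tube].mean() - vol.data[bg].mean()
        contrast_out = out.data[tube].mean() - out.data[bg].mean()
        assert contrast_out > 0.8 * contrast_in

    def test_output_range_overshoot_bounded(self, rng):
        vol = Volume3D(rng.normal(100, 15, size=(24, 24, 24)).astype(np.float32))
        out = ced_filter(vol, CEDParams(n_iter=10))
        span = vol.data.max() - vol.data.min()
        assert out.data.max() <= vol.data.max() + 0.01 * span
        assert out.data.min() >= vol.data.min() - 0.01 * span

    def test_params_validation(self):
        with pytest.raises(ValueError):
            CEDParams(tau=0.2)
        with pytest.raises(ValueError):
            CEDParams(alpha_reg=1.5)


class TestEnhance:
    def test_deterministic(self):
        vol, liver, _ = make_phantom(PhantomSpec(shape=(48, 48, 48), tree_depth=2,
                                                 root_radius=3.5, seed=2))
        a, _ = enhance(vol, liver)
        b, _ = enhance(vol, liver)
        np.testing.assert_array_equal(a.data, b.data)

    def test_background_only_phantom_maps_to_zero(self, rng):
        data = np.full((40, 40, 40), 100.0, dtype=np.float32)
        liver = np.zeros((40, 40, 40), dtype=np.uint8)
        liver[8:32, 8:32, 8:32] = 1
        out, _ = enhance(Volume3D(data), BinaryMask3D(liver))
        assert np.abs(out.data).max() < 1e-3

    def test_enhancement_raises_contrast_to_noise(self, phantom_triplet):
        from hepavess.io_volumes import crop

        vol, liver, vessels = phantom_triplet
        enhanced, box = enhance(vol, liver)
        raw = crop(vol, box)
        ves = crop(vessels, box).data.astype(bool)
        liv = crop(liver, box).data.astype(bool)
        bg = liv & ~ves

        def cnr(a):
            return (a[ves].mean() - a[bg].mean()) / a[bg].std()

        assert cnr(enhanced.data) > cnr(raw.data)

    def test_skip_flags_reproduce_raw_crop(self, small_phantom):
        from hepavess.io_volumes import crop

        vol, liver, _ = small_phantom
        out, box = enhance(vol, liver, skip_vesselness=True, skip_ced=True)
        np.testing.assert_array_equal(out.data, crop(vol, box).data)
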