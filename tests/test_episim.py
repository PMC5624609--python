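import numpy as np
import pytest
import scipy.ndimage as ndi

import susim as s
from susim.episim import (
    DisplacementField,
    acquire_kspace,
    distort_volume,
    image_noise_sigma,
    unwarp_volume,
)
from susim.fieldsim import RigidTransform


class TestFieldToDisplacement:
    def test_zero_field(self, protocol):
        fm = s.FieldMap(np.zeros((8, 8, 4)), (3.0, 3.0, 3.0))
        d = s.field_to_displacement(fm, protocol)
        assert np.all(d.shift == 0)
        assert np.allclose(d.jacobian, 1.0)

    def test_printed_protocol_conversion(self):
        # 30 Hz at 9.5 Hz/pixel and 2 mm voxels -> 3.16 voxels = 6.3 mm
        fm = s.FieldMap(np.full((4, 4, 4), 30.0), (2.0, 2.0, 2.0))
        prot = s.Protocol(matrix=(4, 4), n_slices=4, voxel_size=(2.0, 2.0, 2.0),
                          bandwidth_per_pixel=9.5, pe_axis="PA")
        d = s.field_to_displacement(fm, prot)
        assert np.abs(d.shift).max() == pytest.approx(30.0 / 9.5)
        assert np.abs(d.to_mm()).max() == pytest.approx(6.3158, abs=1e-3)

    def test_reversed_polarity_negates_shift(self, prepared_field, protocol):
        d_ap = s.field_to_displacement(prepared_field, protocol)
        d_pa = s.field_to_displacement(prepared_field, protocol.with_pe_axis("PA"))
        assert np.array_equal(d_ap.shift, -d_pa.shift)


class TestDistortVolume:
    def test_zero_displacement_is_identity(self, b0_image, phantom):
        d = DisplacementField(np.zeros(phantom.grid_shape), 1, phantom.voxel_size)
        out = distort_volume(b0_image, d)
        assert np.allclose(out, b0_image, atol=1e-12)

    def test_collapse_oracle_1d(self):
        # two bright voxels collapsed onto one cell: all signal piles up
        col = np.array([0.0, 10.0, 10.0, 0.0]).reshape(4, 1, 1)
        shift = np.array([0.0, 0.0, -1.0, -1.0]).reshape(4, 1, 1)
        out = distort_volume(col, DisplacementField(shift, 0))
        assert np.allclose(out.ravel(), [0.0, 20.0, 0.0, 0.0])
        assert out.sum() == pytest.approx(col.sum())

    def test_signal_conservation(self, b0_image, bump_field, protocol):
        d = s.field_to_displacement(bump_field, protocol)
        out = distort_volume(b0_image, d)
        assert abs(out.sum() - b0_image.sum()) <= 1e-6 * b0_image.sum()

    def test_compression_expansion_pairing(self, b0_image, bump_field, protocol):
        # blip-up and blip-down distortions have reciprocal-ordered Jacobians:
        # where one compresses, the other stretches
        d_up = s.field_to_displacement(bump_field, protocol)
        d_dn = s.field_to_displacement(bump_field, protocol.with_pe_axis("PA"))
        j_up, j_dn = d_up.jacobian, d_dn.jacobian
        sel = np.abs(j_up - 1) > 0.05
        assert np.all(np.sign(j_up[sel] - 1) == -np.sign(j_dn[sel] - 1))

    def test_shape_mismatch_rejected(self):
        d = DisplacementField(np.zeros((4, 4, 4)), 1)
        with pytest.raises(ValueError, match="shape"):
            distort_volume(np.zeros((5, 4, 4)), d)


class TestUnwarpVolume:
    def test_zero_displacement_is_identity(self, b0_image, phantom):
        d = DisplacementField(np.zeros(phantom.grid_shape), 1, phantom.voxel_size)
        assert np.allclose(unwarp_volume(b0_image, d), b0_image)

    def test_roundtrip_in_smooth_stretch_region(
        self, phantom, b0_image, bump_field, protocol
    ):
        d = s.field_to_displacement(bump_field, protocol)
        distorted = distort_volume(b0_image, d)
        recovered = unwarp_volume(distorted, d, jacobian_modulate=True)
        sel = phantom.brain_mask() & (d.jacobian >= 1.0)  # stretch only
        sel = ndi.binary_erosion(sel, iterations=1)
        rel = np.sqrt(np.mean((recovered[sel] - b0_image[sel]) ** 2))
        rel /= np.sqrt(np.mean(b0_image[sel] ** 2))
        assert rel < 0.02

    def test_residual_concentrates_at_pileup(
        self, phantom, b0_image, prepared_field, protocol
    ):
        # compressed regions lose information: round-trip error there exceeds
        # the error in well-behaved regions
        d = s.field_to_displacement(prepared_field, protocol)
        distorted = distort_volume(b0_image, d)
        recovered = unwarp_volume(distorted, d, jacobian_modulate=True)
        err = np.abs(recovered - b0_image)
        mask = phantom.brain_mask()
        pileup = mask & (d.jacobian < 0.5)
        ok = mask & (d.jacobian > 0.9) & (d.jacobian < 1.1)
        assert err[pileup].mean() > 3 * err[ok].mean()

    def test_noninvertible_field_rejected_without_clamp(self, phantom):
        shift = np.zeros(phantom.grid_shape)
        shift[:, 20, :] = 0.0
        shift[:, 21, :] = -2.0  # jacobian <= 0 between rows
        d = DisplacementField(shift, 1, phantom.voxel_size)
        with pytest.raises(ValueError, match="jacobian"):
            unwarp_volume(np.ones(phantom.grid_shape), d, jacobian_clamp=None)


class TestKspaceAcquisition:
    def test_noise_free_no_apodization_identity(self, b0_image, protocol):
        prot = s.desk_protocol()
        prot.apodize = False
        out = acquire_kspace(b0_image, prot, 0.0)
        assert np.allclose(out, b0_image, atol=1e-10)

    def test_hamming_reduces_gibbs_ringing(self):
        # sharp-edged disc acquired at half its native resolution: the
        # band limiting produces Gibbs overshoot outside the disc, and the
        # Hamming window strictly reduces it
        x, y = np.meshgrid(np.arange(128), np.arange(128), indexing="ij")
        disc = (((x - 64) ** 2 + (y - 64) ** 2) < 24**2).astype(float)
        vol = np.repeat(disc[:, :, None], 2, axis=2)
        prot_on = s.desk_protocol()
        prot_off = s.desk_protocol()
        prot_off.apodize = False
        ring_on = acquire_kspace(vol, prot_on, 0.0, output_shape=(64, 64))
        ring_off = acquire_kspace(vol, prot_off, 0.0, output_shape=(64, 64))
        outside = (((x[::2, ::2] - 64) ** 2 + (y[::2, ::2] - 64) ** 2) > 32**2)
        outside = np.repeat(outside[:, :, None], 2, axis=2)
        assert ring_off[outside].max() > 0.02  # ringing is present
        assert ring_on[outside].max() < ring_off[outside].max()

    def test_rayleigh_background_statistics(self, protocol):
        rng = np.random.default_rng(0)
        zero = np.zeros((64, 64, 8))
        sigma_k = 50.0
        noisy = acquire_kspace(zero, protocol, sigma_k, rng)
        sigma_img = image_noise_sigma(sigma_k, (64, 64))
        expected_mean = sigma_img * np.sqrt(np.pi / 2)
        assert noisy.mean() == pytest.approx(expected_mean, rel=0.02)


class TestNoiseCalibration:
    def test_linearity(self, phantom, protocol):
        s40 = s.calibrate_noise_sigma(phantom, protocol, 40.0)
        s80 = s.calibrate_noise_sigma(phantom, protocol, 80.0)
        assert s40 == pytest.approx(2.0 * s80)

    def test_infinite_snr_gives_zero(self, phantom, protocol):
        assert s.calibrate_noise_sigma(phantom, protocol, np.inf) == 0.0

    def test_roundtrip_within_5pct(self, phantom, protocol, b0_image):
        sigma = s.calibrate_noise_sigma(phantom, protocol, 40.0)
        brain = phantom.brain_mask()
        bg = ndi.binary_erosion(phantom.labels == 0, iterations=3)
        snrs = [
            s.measure_snr(
                acquire_kspace(b0_image, protocol, sigma, np.random.default_rng(r)),
                brain, bg,
            )
            for r in range(5)
        ]
        assert np.mean(snrs) == pytest.approx(40.0, rel=0.05)

    def test_invalid_target_rejected(self, phantom, protocol):
        with pytest.raises(ValueError):
            s.calibrate_noise_sigma(phantom, protocol, 0.0)


class TestSimulateDataset:
    def test_full_scale_protocol_dual_pe_gives_72_volumes(self):
        prot = s.full_scale_protocol()
        assert prot.n_volumes == 36
        ph = s.make_head_phantom(prot.grid_shape, prot.voxel_size, seed=1)
        ds = s.simulate_dataset(
            ph, prot, field_mode="none", dual_pe=True, seed=0,
            signal_model="tensor",
        )
        assert ds.n_volumes == 72

    def test_clean_dataset_equals_forward_signals(self, phantom):
        prot = s.desk_protocol()
        prot.apodize = False
        ds = s.simulate_dataset(
            phantom, prot, field_mode="none", seed=0, signal_model="tensor"
        )
        b0 = s.synthesize_dwi_signal(phantom, 0.0, (1, 0, 0), te=prot.te)
        assert np.allclose(ds.volumes[..., 0], b0, atol=1e-10)
        dwi = s.synthesize_dwi_signal(phantom, 1000.0, prot.bvecs[2], te=prot.te)
        assert np.allclose(ds.volumes[..., 2], dwi, atol=1e-10)

    def test_deterministic_under_seed(self, phantom):
        prot = s.desk_protocol(snr_target=40.0)
        a = s.simulate_dataset(phantom, prot, field_mode="static", seed=7)
        b = s.simulate_dataset(phantom, prot, field_mode="static", seed=7)
        assert np.array_equal(a.volumes, b.volumes)

    def test_motion_length_mismatch_rejected(self, phantom, protocol):
        motion = s.generate_motion_trace(3, 1.0, 0)
        with pytest.raises(ValueError, match="length"):
            s.simulate_dataset(phantom, protocol, motion=motion)

    def test_grid_mismatch_rejected(self, protocol):
        ph = s.make_head_phantom((32, 32, 32), 3.0, seed=0)
        with pytest.raises(ValueError, match="grid"):
            s.simulate_dataset(ph, protocol)


class TestGroundTruthDisplacement:
    def test_identity_transform_reduces_to_field_conversion(
        self, prepared_field, protocol
    ):
        gt = s.ground_truth_displacement(prepared_field, RigidTransform(), protocol)
        ref = s.field_to_displacement(prepared_field, protocol)
        assert np.array_equal(gt.shift, ref.shift)

    def test_pure_motion_zero_field_gives_rigid_pe_component(self, protocol):
        zero = s.FieldMap(np.zeros((64, 64, 32)), (3.0, 3.0, 3.0))
        tr = RigidTransform((0, 0, 0), (0.0, 6.0, 0.0))  # 2 voxels along +y (PE)
        gt = s.ground_truth_displacement(zero, tr, protocol)
        assert np.allclose(gt.shift, 2.0, atol=1e-9)


class TestAuxiliaryScans:
    def test_gre_zero_field_zero_phase(self, phantom):
        zero = s.FieldMap(np.zeros(phantom.grid_shape), phantom.voxel_size)
        gre = s.simulate_gre_pair(phantom, zero, noise_sigma=0.0)
        assert np.allclose(gre.phase1, 0.0) and np.allclose(gre.phase2, 0.0)

    def test_gre_phase_difference_closed_form(self, phantom):
        # 100 Hz with printed TEs 4.92 / 7.38 ms: 2*pi*100*0.00246 = 1.546 rad
        fm = s.FieldMap(np.full(phantom.grid_shape, 100.0), phantom.voxel_size)
        gre = s.simulate_gre_pair(phantom, fm, noise_sigma=0.0)
        head = phantom.brain_mask()
        dphi = np.angle(np.exp(1j * (gre.phase2 - gre.phase1)))
        assert dphi[head].mean() == pytest.approx(1.5456, abs=1e-3)

    def test_gre_phase_wrapped_convention(self, phantom):
        fm = s.FieldMap(np.full(phantom.grid_shape, 300.0), phantom.voxel_size)
        gre = s.simulate_gre_pair(phantom, fm, noise_sigma=0.0)
        for p in (gre.phase1, gre.phase2):
            assert p.max() <= np.pi and p.min() > -np.pi

    def test_gre_echo_order_enforced(self, phantom):
        zero = s.FieldMap(np.zeros(phantom.grid_shape), phantom.voxel_size)
        with pytest.raises(ValueError, match="te2"):
            s.simulate_gre_pair(phantom, zero, te1=7.38, te2=4.92)

    def test_structural_pd_limit(self, phantom):
        img = s.simulate_structural(phantom, te=0.0, tr=1e9)
        assert np.allclose(img, phantom.param_map("pd"))

    def test_structural_csf_brighter_than_tissue(self, phantom):
        img = s.simulate_structural(phantom)  # TE 110, TR 2200
        csf = img[phantom.labels == 2].mean()
        tissue = img[phantom.labels == 1].mean()
        assert csf > 2 * tissue
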