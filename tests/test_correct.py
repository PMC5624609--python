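import numpy as np
import pytest
import scipy.ndimage as ndi

import susim as s
from susim.episim import distort_volume
from susim.fieldsim import RigidTransform


@pytest.fixture(scope="module")
def distorted_pair(phantom, b0_image, prepared_field, protocol):
    """Noise-free blip-up/blip-down b=0 pair under the phantom field."""
    d_up = s.field_to_displacement(prepared_field, protocol)
    d_dn = s.field_to_displacement(prepared_field, protocol.with_pe_axis("PA"))
    return distort_volume(b0_image, d_up), distort_volume(b0_image, d_dn)


class TestFieldmapEstimation:
    def test_zero_phase_gives_zero_field(self, phantom):
        zero = s.FieldMap(np.zeros(phantom.grid_shape), phantom.voxel_size)
        gre = s.simulate_gre_pair(phantom, zero, noise_sigma=0.0)
        est = s.estimate_fieldmap_gre(gre, mask=phantom.head_mask(),
                                      voxel_size=phantom.voxel_size)
        assert np.allclose(est.values, 0.0, atol=1e-9)

    def test_uniform_field_recovered_exactly(self, phantom):
        fm = s.FieldMap(np.full(phantom.grid_shape, 100.0), phantom.voxel_size)
        gre = s.simulate_gre_pair(phantom, fm, noise_sigma=0.0)
        est = s.estimate_fieldmap_gre(gre, mask=phantom.head_mask(),
                                      voxel_size=phantom.voxel_size)
        assert np.allclose(est.values, 100.0, atol=1e-9)

    def test_wrapped_ramp_recovered_after_unwrapping(self, phantom):
        # ramp crossing the +-pi phase wrap but within the 1/(2 dTE)
        # unambiguous range: spatial unwrapping restores it exactly
        ramp = np.linspace(0.0, 300.0, 64)[None, :, None] * np.ones(
            phantom.grid_shape
        )
        gre = s.simulate_gre_pair(phantom, s.FieldMap(ramp, phantom.voxel_size),
                                  noise_sigma=0.0)
        est = s.estimate_fieldmap_gre(gre, mask=phantom.head_mask(),
                                      voxel_size=phantom.voxel_size)
        inside = s.erode_mask(phantom.head_mask(), 2)
        assert np.abs(est.values - ramp)[inside].max() < 1e-6
        # without unwrapping the same data jumps by 1/dTE = 406.5 Hz
        dte = (gre.te2 - gre.te1) * 1e-3
        naive = np.angle(np.exp(1j * (gre.phase2 - gre.phase1))) / (2 * np.pi * dte)
        assert np.abs(naive - ramp)[inside].max() == pytest.approx(1.0 / dte, rel=0.05)

    def test_empty_mask_rejected(self, phantom):
        zero = s.FieldMap(np.zeros(phantom.grid_shape), phantom.voxel_size)
        gre = s.simulate_gre_pair(phantom, zero, noise_sigma=0.0)
        with pytest.raises(ValueError, match="empty"):
            s.estimate_fieldmap_gre(gre, mask=np.zeros(phantom.grid_shape, bool))


class TestFmbCorrect:
    def test_true_field_gives_small_displacement_error(
        self, phantom, prepared_field, protocol, b0_image
    ):
        d_true = s.field_to_displacement(prepared_field, protocol)
        ds = _single_volume_dataset(b0_image, d_true, protocol)
        res = s.fmb_correct(ds, prepared_field, smoothing_sigma=0.0)
        err = np.abs(res.displacement.shift - d_true.shift)
        assert err[phantom.brain_mask()].mean() < 1e-9
        # residual intensity error concentrates at pile-up
        diff = np.abs(res.corrected.volumes[..., 0] - b0_image)
        mask = phantom.brain_mask()
        pile = mask & (d_true.jacobian < 0.5)
        ok = mask & (np.abs(d_true.jacobian - 1) < 0.1)
        assert diff[pile].mean() > 3 * diff[ok].mean()

    def test_zero_field_is_identity(self, phantom, b0_image, protocol):
        zero = s.FieldMap(np.zeros(phantom.grid_shape), phantom.voxel_size)
        d0 = s.field_to_displacement(zero, protocol)
        ds = _single_volume_dataset(b0_image, d0, protocol)
        res = s.fmb_correct(ds, zero, smoothing_sigma=0.0)
        assert np.allclose(res.corrected.volumes[..., 0], b0_image)


def _single_volume_dataset(volume, disp, protocol):
    distorted = distort_volume(volume, disp)
    return s.DWIDataset(
        volumes=distorted[..., None],
        bvals=np.zeros(1),
        bvecs=np.array([[1.0, 0.0, 0.0]]),
        pe_axes=[protocol.pe_axis],
        protocol=protocol,
    )


class TestMpbEstimation:
    def test_identical_images_give_zero_field(self, b0_image, protocol):
        est, _ = s.mpb_estimate_field(b0_image, b0_image, protocol)
        assert np.allclose(est.values, 0.0, atol=1e-9)

    def test_smooth_field_recovered(self, phantom, b0_image, bump_field, protocol):
        # noise-free known smooth field: displacement recovered to < 0.1 voxel
        # away from pile-up
        d_up = s.field_to_displacement(bump_field, protocol)
        d_dn = s.field_to_displacement(bump_field, protocol.with_pe_axis("PA"))
        up = distort_volume(b0_image, d_up)
        dn = distort_volume(b0_image, d_dn)
        est, diag = s.mpb_estimate_field(up, dn, protocol)
        err = np.abs(est.values - bump_field.values) / protocol.bw_per_pixel
        good = phantom.brain_mask() & (d_up.jacobian > 0.5) & (d_up.jacobian < 2.0)
        assert err[good].mean() < 0.1

    def test_antisymmetric_under_pair_swap(self, distorted_pair, protocol):
        up, dn = distorted_pair
        a, _ = s.mpb_estimate_field(up, dn, protocol)
        b, _ = s.mpb_estimate_field(dn, up, protocol)
        assert np.allclose(a.values, -b.values, atol=1e-9)


class TestMpbCorrect:
    def test_pair_average_of_identical_volumes(self, phantom, b0_image, protocol):
        zero = s.FieldMap(np.zeros(phantom.grid_shape), phantom.voxel_size)
        ds = s.DWIDataset(
            volumes=np.stack([b0_image, b0_image], axis=-1),
            bvals=np.zeros(2),
            bvecs=np.array([[1.0, 0, 0], [1.0, 0, 0]]),
            pe_axes=["AP", "PA"],
            protocol=protocol,
        )
        res = s.mpb_correct(ds, zero, combine="pair_average")
        assert res.corrected.n_volumes == 1
        assert np.allclose(res.corrected.volumes[..., 0], b0_image)

    def test_mismatched_pair_metadata_rejected(self, phantom, b0_image, protocol):
        zero = s.FieldMap(np.zeros(phantom.grid_shape), phantom.voxel_size)
        ds = s.DWIDataset(
            volumes=np.stack([b0_image, b0_image], axis=-1),
            bvals=np.array([0.0, 1000.0]),
            bvecs=np.array([[1.0, 0, 0], [0, 1.0, 0]]),
            pe_axes=["AP", "PA"],
            protocol=protocol,
        )
        with pytest.raises(ValueError, match="mismatch"):
            s.mpb_correct(ds, zero, combine="pair_average")

    def test_pileup_recovery_of_full_variant(
        self, phantom, b0_image, prepared_field, protocol, distorted_pair
    ):
        # MPB/F resamples the compressed region from its expanded counterpart:
        # its intensity error in pile-up voxels is below plain MPB's
        up, dn = distorted_pair
        ds = s.DWIDataset(
            volumes=np.stack([up, dn], axis=-1),
            bvals=np.zeros(2),
            bvecs=np.array([[1.0, 0, 0], [1.0, 0, 0]]),
            pe_axes=["AP", "PA"],
            protocol=protocol,
        )
        est, _ = s.mpb_estimate_field(up, dn, protocol)
        single = s.mpb_correct(ds.subset([0]), est, combine="none")
        full = s.mpb_correct(ds, est, combine="pair_average")
        d_true = s.field_to_displacement(prepared_field, protocol)
        pile = phantom.brain_mask() & (d_true.jacobian < 0.5)
        err_single = np.abs(single.corrected.volumes[..., 0] - b0_image)[pile].mean()
        err_full = np.abs(full.corrected.volumes[..., 0] - b0_image)[pile].mean()
        assert err_full < err_single


class TestRbCorrect:
    def test_undistorted_input_near_identity(self, phantom, protocol):
        ds = s.simulate_dataset(
            phantom, protocol, field_mode="none", seed=0, signal_model="tensor"
        )
        res = s.rb_correct(ds, s.simulate_structural(phantom))
        assert np.abs(res.displacement.shift)[phantom.brain_mask()].mean() < 0.1

    def test_infinite_bending_weight_freezes_displacement(
        self, phantom, protocol, b0_image, prepared_field
    ):
        d = s.field_to_displacement(prepared_field, protocol)
        ds = _single_volume_dataset(b0_image, d, protocol)
        res = s.rb_correct(ds, s.simulate_structural(phantom), bending_weight=1e9)
        assert np.abs(res.displacement.shift).max() < 1e-3

    def test_constant_images_rejected(self, phantom, protocol):
        ds = s.DWIDataset(
            volumes=np.ones(phantom.grid_shape + (1,)),
            bvals=np.zeros(1),
            bvecs=np.array([[1.0, 0, 0]]),
            pe_axes=["AP"],
            protocol=protocol,
        )
        with pytest.raises(ValueError, match="degenerate|constant"):
            s.rb_correct(ds, np.ones(phantom.grid_shape))


class TestRigidRegister:
    def test_identity(self, b0_image, phantom):
        tr = s.rigid_register(b0_image, b0_image, phantom.voxel_size)
        assert max(abs(r) for r in tr.rotations) < 0.05
        assert max(abs(t) for t in tr.translations) < 0.15

    def test_known_rotation_recovered(self, b0_image, phantom):
        truth = RigidTransform((0.0, 3.0, 0.0))
        moved = s.resample_rigid(b0_image, truth, phantom.voxel_size)
        rec = s.rigid_register(moved, b0_image, phantom.voxel_size)
        assert rec.rotations[1] == pytest.approx(3.0, abs=0.2)
        comp = rec.compose(truth.inverse())
        assert max(abs(r) for r in comp.rotations) < 0.2


class TestMasks:
    def test_brain_mask_covers_brain(self, phantom, b0_image):
        mask = s.brain_mask_from_image(b0_image)
        brain = phantom.brain_mask()
        assert (mask & brain).sum() > 0.95 * brain.sum()

    def test_erosion_shrinks_mask(self, phantom):
        m = phantom.head_mask()
        e = s.erode_mask(m, 1)
        assert e.sum() < m.sum()
        assert np.all(m[e])
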