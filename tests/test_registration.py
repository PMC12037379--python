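import numpy as np
import pytest

from siscom.registration import (
    RegistrationConfig,
    RigidTransform,
    joint_histogram,
    mutual_information,
    register_rigid,
    resample,
)
from siscom.siscom_core import compute_brain_mask
from siscom.synthetic_data import PhantomSpec, make_phantom_pair
from siscom.volume_io import PerfusionVolume

from .oracles import histogram_entropy


def _small_phantom(seed=0, **kw):
    spec = PhantomSpec(seed=seed, **kw)
    return make_phantom_pair(spec)


class TestRigidTransform:
    def test_inverse_composition_is_identity(self):
        T = RigidTransform(
            translation=[3.0, -2.0, 1.5],
            rotation=np.radians([4.0, -3.0, 6.0]),
            center=[10.0, -5.0, 2.0],
        )
        probes = np.random.default_rng(1).uniform(-90, 90, (50, 3))
        back = T.inverse().apply(T.apply(probes))
        assert np.abs(back - probes).max() < 1e-9

    def test_rotation_block_is_proper(self):
        T = RigidTransform(rotation=np.radians([10, 20, -30]))
        R = T.matrix[:3, :3]
        assert abs(np.linalg.det(R) - 1.0) < 1e-9
        assert np.abs(R @ R.T - np.eye(3)).max() < 1e-9

    def test_matrix_apply_agree(self):
        T = RigidTransform(
            translation=[1, 2, 3], rotation=np.radians([5, -4, 2]), center=[7, 8, 9]
        )
        pts = np.random.default_rng(2).uniform(-50, 50, (20, 3))
        hom = np.c_[pts, np.ones(len(pts))] @ T.matrix.T
        assert np.abs(hom[:, :3] - T.apply(pts)).max() < 1e-9

    def test_json_round_trip(self):
        T = RigidTransform(translation=[1, 2, 3], rotation=np.radians([5, -4, 2]))
        back = RigidTransform.from_dict(T.to_dict())
        assert np.allclose(back.translation, T.translation)
        assert np.allclose(back.rotation, T.rotation)


class TestMutualInformation:
    def test_self_mi_equals_entropy(self):
        ictal, _, truth = _small_phantom(seed=5)
        mask = truth.brain_mask
        hist = joint_histogram(ictal, ictal, RigidTransform.identity(), bins=32, mask=mask)
        mi = hist.mutual_information()
        edges = hist.bin_edges_fixed
        vals = np.clip(ictal.data[mask.data], edges[0], edges[-1])
        h = histogram_entropy(vals, edges)
        assert mi == pytest.approx(h, rel=1e-6)

    def test_independent_noise_has_near_zero_mi(self):
        rng = np.random.default_rng(42)
        a = PerfusionVolume(data=rng.uniform(0, 1, (24, 24, 24)), spacing=(3, 3, 3))
        b = PerfusionVolume(data=rng.uniform(0, 1, (24, 24, 24)), spacing=(3, 3, 3))
        mi = mutual_information(a, b, bins=32)
        assert 0 <= mi <= 0.05

    def test_invariant_to_intensity_relabeling(self):
        rng = np.random.default_rng(3)
        two_level = rng.choice([10.0, 200.0], size=(20, 20, 20))
        a = PerfusionVolume(data=two_level, spacing=(3, 3, 3))
        inverted = PerfusionVolume(data=210.0 - two_level, spacing=(3, 3, 3))
        mi = mutual_information(a, inverted, bins=16)
        h = joint_histogram(a, a, RigidTransform.identity(), bins=16).entropy_fixed()
        assert mi == pytest.approx(h, rel=1e-6)

    def test_rejects_bad_bins(self):
        a = PerfusionVolume(data=np.random.default_rng(0).random((12, 12, 12)),
                            spacing=(3, 3, 3))
        with pytest.raises(ValueError, match="bins"):
            mutual_information(a, a, bins=1)


class TestResample:
    def test_identity_is_noop(self):
        ictal, _, _ = _small_phantom(seed=6)
        out = resample(ictal, RigidTransform.identity(), ictal)
        assert np.abs(out.data - ictal.data).max() < 1e-6

    def test_integer_shift_preserves_constant(self):
        vol = PerfusionVolume(data=np.full((16, 16, 16), 7.0), spacing=(2, 2, 2))
        T = RigidTransform(translation=[4.0, -2.0, 2.0])  # integer voxels
        out = resample(vol, T, vol)
        interior = out.data[4:12, 4:12, 4:12]
        assert np.abs(interior - 7.0).max() < 1e-12

    def test_half_voxel_shift_on_ramp_matches_analytic(self):
        shape = (16, 16, 16)
        ramp = np.broadcast_to(
            np.arange(shape[0], dtype=float)[:, None, None], shape
        ).copy()
        vol = PerfusionVolume(data=ramp, spacing=(2, 2, 2))
        T = RigidTransform(translation=[1.0, 0, 0])  # +0.5 voxel along x
        out = resample(vol, T, vol)
        expected = ramp + 0.5
        interior = (slice(1, 14), slice(None), slice(None))
        assert np.abs(out.data[interior] - expected[interior]).max() < 1e-6


class TestRegisterRigid:
    def test_self_registration_is_identity(self):
        ictal, _, _ = _small_phantom(seed=7, noise_sd_pct=0.0)
        res = register_rigid(ictal, ictal)
        assert np.abs(res.transform.translation).max() < 0.1
        assert np.abs(np.degrees(res.transform.rotation)).max() < 0.1
        assert res.final_mi >= res.mi_at_identity

    def test_pure_translation_recovery_noiseless(self):
        T = RigidTransform(translation=[3.0, -2.0, 1.0])
        ictal, interictal, _ = _small_phantom(seed=8, misalignment=T, noise_sd_pct=0.0)
        res = register_rigid(ictal, interictal)
        assert np.abs(res.transform.translation - T.translation).max() < 0.5
        assert np.abs(np.degrees(res.transform.rotation)).max() < 0.5

    def test_rotation_recovery_with_noise(self):
        T = RigidTransform(rotation=np.radians([0.0, 0.0, 5.0]))
        ictal, interictal, _ = _small_phantom(seed=9, misalignment=T, noise_sd_pct=5.0)
        res = register_rigid(ictal, interictal)
        assert abs(np.degrees(res.transform.rotation[2]) - 5.0) < 1.0

    def test_forward_and_reverse_transforms_are_mutual_inverses(self):
        T = RigidTransform(translation=[4, -3, 2], rotation=np.radians([2, -1, 3]))
        ictal, interictal, _ = _small_phantom(seed=10, misalignment=T, noise_sd_pct=3.0)
        fwd = register_rigid(ictal, interictal).transform
        rev = register_rigid(interictal, ictal).transform
        comp = fwd.compose(rev)  # should be ~identity as a world map
        probes = np.random.default_rng(0).uniform(-80, 80, (30, 3))
        assert np.abs(comp.apply(probes) - probes).max() < 2.0  # mm, incl. lever arm
        assert np.abs(np.degrees(fwd.rotation) + np.degrees(rev.rotation)).max() < 1.0

    def test_recovery_rate_over_phantom_batch(self, registration_recovery):
        """>= 90% of seeded misalignments recovered within 1 mm / 1 deg."""
        ok = sum(terr <= 1.0 and rerr <= 1.0 for terr, rerr in registration_recovery)
        assert ok >= 0.9 * len(registration_recovery)


class TestAgainstSimpleITK:
    def test_translation_agrees_with_itk_oracle(self):
        sitk = pytest.importorskip("SimpleITK")
        T = RigidTransform(translation=[5.0, -3.0, 2.0])
        ictal, interictal, _ = _small_phantom(seed=12, misalignment=T, noise_sd_pct=2.0)
        ours = register_rigid(ictal, interictal).transform

        def to_itk(vol):
            # identity direction + our origin/spacing: ITK's index->world
            # map then coincides with our affine, so transform parameters
            # are directly comparable
            img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.T))
            img.SetSpacing(tuple(float(s) for s in vol.spacing))
            img.SetOrigin(tuple(float(o) for o in vol.affine[:3, 3]))
            return img

        fixed, moving = to_itk(ictal), to_itk(interictal)
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMattesMutualInformation(32)
        reg.SetMetricSamplingStrategy(reg.NONE)
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsPowell(
            numberOfIterations=30, maximumLineIterations=25,
            stepLength=2.0, stepTolerance=1e-4, valueTolerance=1e-8,
        )
        reg.SetShrinkFactorsPerLevel([2, 1])
        reg.SetSmoothingSigmasPerLevel([1.0, 0.5])
        reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
        reg.SetInitialTransform(
            sitk.CenteredTransformInitializer(
                fixed, moving, sitk.Euler3DTransform(),
                sitk.CenteredTransformInitializerFilter.MOMENTS,
            ),
            inPlace=False,
        )
        out = reg.Execute(fixed, moving)
        itk_t = np.array(out.GetParameters()[3:])
        assert np.abs(itk_t - ours.translation).max() < 1.0
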