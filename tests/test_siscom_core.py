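import numpy as np
import pytest
from scipy.stats import norm

from siscom.pipeline import SiscomConfig, run_siscom
from siscom.siscom_core import (
    DegenerateInputError,
    ZMap,
    compute_brain_mask,
    normalize_global,
    subtract,
    threshold_map,
    zscore_map,
)
from siscom.synthetic_data import PhantomSpec, make_phantom_pair
from siscom.volume_io import BrainMask, PerfusionVolume


def _vol(data, spacing=(3, 3, 3)):
    return PerfusionVolume(data=np.asarray(data, dtype=float), spacing=spacing)


def _mask_like(vol, sel=None):
    data = np.ones(vol.shape, bool) if sel is None else sel
    return BrainMask(data=data, spacing=vol.spacing, affine=vol.affine)


class TestBrainMask:
    def test_recovers_phantom_ellipsoid(self):
        # sharp-edged phantom: with smoothing the mask grows by ~half a
        # kernel width, so ground-truth Dice is only meaningful unsmoothed
        spec = PhantomSpec(seed=1, noise_sd_pct=0.0, smooth_fwhm_mm=0.0)
        ictal, _, truth = make_phantom_pair(spec)
        mask = compute_brain_mask(ictal)
        inter = (mask.data & truth.brain_mask.data).sum()
        dice = 2 * inter / (mask.n_voxels + truth.brain_mask.n_voxels)
        assert dice >= 0.98

    def test_constant_volume_rejected(self):
        with pytest.raises(DegenerateInputError):
            compute_brain_mask(_vol(np.zeros((8, 8, 8))))

    def test_disconnected_artifact_excluded(self):
        data = np.zeros((24, 24, 24))
        data[6:18, 6:18, 6:18] = 100.0  # "brain"
        data[1, 1, 1] = data[1, 1, 2] = 5000.0  # bright 2-voxel artifact
        mask = compute_brain_mask(_vol(data))
        assert not mask.data[1, 1, 1] and not mask.data[1, 1, 2]
        assert mask.data[12, 12, 12]


class TestNormalizeGlobal:
    def test_constant_maps_to_100(self):
        vol = _vol(np.full((6, 6, 6), 7.0))
        out = normalize_global(vol, _mask_like(vol))
        assert np.abs(out.data - 100.0).max() < 1e-9

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        vol = _vol(rng.uniform(10, 200, (8, 8, 8)))
        mask = _mask_like(vol)
        a = normalize_global(vol, mask)
        b = normalize_global(vol.with_data(vol.data * 3.7), mask)
        np.testing.assert_allclose(a.data, b.data, rtol=1e-12)

    def test_mean_100_fixed_point(self):
        data = np.zeros((4, 4, 4))
        data[0, 0, 0], data[0, 0, 1] = 50.0, 150.0
        sel = np.zeros((4, 4, 4), bool)
        sel[0, 0, 0] = sel[0, 0, 1] = True
        vol = _vol(data)
        out = normalize_global(vol, _mask_like(vol, sel))
        assert out.data[0, 0, 0] == pytest.approx(50.0)
        assert out.data[0, 0, 1] == pytest.approx(150.0)

    def test_nonpositive_mean_rejected(self):
        vol = _vol(np.full((4, 4, 4), -1.0))
        with pytest.raises(DegenerateInputError):
            normalize_global(vol, _mask_like(vol))


class TestSubtract:
    def test_self_subtraction_is_zero(self):
        vol = _vol(np.random.default_rng(1).random((6, 6, 6)))
        out = subtract(vol, vol, _mask_like(vol))
        assert np.abs(out.data).max() == 0.0

    def test_focal_difference_exact(self):
        base = _vol(np.full((8, 8, 8), 100.0))
        bump = base.data.copy()
        bump[2:4, 2:4, 2:4] += 5.0
        d = subtract(_vol(bump), base, _mask_like(base))
        assert np.all(d.data[2:4, 2:4, 2:4] == 5.0)
        assert np.count_nonzero(d.data) == 8

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        a, b = _vol(rng.random((6, 6, 6))), _vol(rng.random((6, 6, 6)))
        m = _mask_like(a)
        np.testing.assert_allclose(
            subtract(a, b, m).data, -subtract(b, a, m).data, atol=1e-15
        )

    def test_grid_mismatch_rejected(self):
        a = _vol(np.zeros((6, 6, 6)))
        b = _vol(np.zeros((6, 6, 7)))
        with pytest.raises(ValueError, match="grid mismatch"):
            subtract(a, b, _mask_like(a))


class TestZScore:
    def test_three_point_example(self):
        data = np.zeros((4, 4, 4))
        sel = np.zeros((4, 4, 4), bool)
        for k, v in enumerate([1.0, 2.0, 3.0]):
            data[0, 0, k] = v
            sel[0, 0, k] = True
        vol = _vol(data)
        z = zscore_map(vol, _mask_like(vol, sel))
        np.testing.assert_allclose(z.data[0, 0, :3], [-1.0, 0.0, 1.0], atol=1e-12)
        assert z.mu_d == pytest.approx(2.0) and z.sigma_d == pytest.approx(1.0)

    def test_in_mask_mean_zero_sd_one(self, aligned_result):
        z = aligned_result.zmap
        vals = z.data[z.mask.data]
        assert abs(vals.mean()) < 1e-9
        assert abs(vals.std(ddof=1) - 1.0) < 1e-9

    def test_constant_difference_rejected(self):
        vol = _vol(np.full((4, 4, 4), 3.0))
        with pytest.raises(DegenerateInputError):
            zscore_map(vol, _mask_like(vol))

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        vol = _vol(rng.normal(size=(8, 8, 8)))
        mask = _mask_like(vol)
        z1 = zscore_map(vol, mask)
        z2 = zscore_map(vol.with_data(2.5 * vol.data + 17.0), mask)
        np.testing.assert_allclose(z1.data, z2.data, atol=1e-9)


class TestThreshold:
    def _zmap(self, values):
        data = np.zeros((4, 4, 4))
        sel = np.zeros((4, 4, 4), bool)
        for k, v in enumerate(values):
            data[0, 0, k] = v
            sel[0, 0, k] = True
        mask = BrainMask(data=sel, spacing=(1, 1, 1), affine=np.eye(4))
        return ZMap(data=data, mask=mask, mu_d=0.0, sigma_d=1.0)

    def test_two_sided_example(self):
        sig = threshold_map(self._zmap([2.5, 1.9, -3.0]), 2.0, "two-sided")
        assert list(sig.data[0, 0, :3]) == [1, 0, -1]

    def test_positive_only_example(self):
        sig = threshold_map(self._zmap([2.5, 1.9, -3.0]), 2.0, "positive-only")
        assert list(sig.data[0, 0, :3]) == [1, 0, 0]

    def test_strict_inequality_at_threshold(self):
        sig = threshold_map(self._zmap([2.0, -2.0]), 2.0, "two-sided")
        assert sig.n_significant == 0

    def test_counts_monotone_in_threshold(self):
        rng = np.random.default_rng(8)
        data = rng.normal(size=(12, 12, 12))
        mask = BrainMask(data=np.ones(data.shape, bool), spacing=(1, 1, 1), affine=np.eye(4))
        z = ZMap(data=data, mask=mask, mu_d=0.0, sigma_d=1.0)
        counts = [
            threshold_map(z, t, "two-sided").n_significant
            for t in (1.0, 1.5, 2.0, 2.5, 3.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_gaussian_exceedance_fraction(self):
        # two-sided exceedance of N(0,1) at t=2 is 2*(1-Phi(2)) = 4.55%
        rng = np.random.default_rng(99)
        data = rng.standard_normal((50, 50, 40))
        mask = BrainMask(data=np.ones(data.shape, bool), spacing=(1, 1, 1), affine=np.eye(4))
        z = ZMap(data=data, mask=mask, mu_d=0.0, sigma_d=1.0)
        frac = threshold_map(z, 2.0, "two-sided").n_significant / data.size
        expected = 2 * (1 - norm.cdf(2.0))
        assert frac == pytest.approx(expected, abs=0.005)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_map(self._zmap([1.0]), 0.0)


def test_end_to_end_scale_invariance():
    """Multiplying either raw input by c > 0 leaves the z map unchanged."""
    spec = PhantomSpec(seed=21, noise_sd_pct=3.0)
    ictal, interictal, _ = make_phantom_pair(spec)
    cfg = SiscomConfig(register=False)
    base = run_siscom(ictal, interictal, config=cfg)
    scaled = run_siscom(
        ictal.with_data(ictal.data * 5.3), interictal, config=cfg
    )
    np.testing.assert_allclose(scaled.zmap.data, base.zmap.data, atol=1e-9)
    assert scaled.significance.n_significant == base.significance.n_significant
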