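import numpy as np
import pytest

from emplace.density import (
    DensityMap,
    UndefinedCorrelationError,
    apply_symmetry,
    difference_map,
    fsc,
    lowpass_filter,
    mirror_map,
    mass_based_contour,
    ncc_translation_scan,
    normalized_cross_correlation,
    read_density,
    resolution_at,
    simulate_density,
    volume_coverage,
    write_density,
)
from emplace.structures import coarse_grain

from conftest import make_model


def _pearson(a, b):
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


class TestMapIO:
    def test_zero_map_roundtrip(self, tmp_path):
        m = DensityMap(values=np.zeros((8, 8, 8), dtype=np.float32), voxel=2.0)
        write_density(m, tmp_path / "z.mrc")
        back = read_density(tmp_path / "z.mrc")
        assert back.voxel == pytest.approx(2.0)
        np.testing.assert_array_equal(back.values, 0.0)

    def test_origin_places_first_voxel(self, tmp_path):
        m = DensityMap(values=np.zeros((4, 4, 4), dtype=np.float32), voxel=1.5,
                       origin=(10.0, 10.0, 10.0))
        write_density(m, tmp_path / "o.mrc")
        back = read_density(tmp_path / "o.mrc")
        np.testing.assert_allclose(back.index_to_physical((0, 0, 0)),
                                   (10.0, 10.0, 10.0))

    def test_random_map_roundtrip_bit_exact(self, tmp_path):
        vals = np.random.default_rng(1).random((16, 16, 16)).astype(np.float32)
        m = DensityMap(values=vals, voxel=4.0, origin=(-3.0, 2.0, 7.5))
        write_density(m, tmp_path / "r.mrc")
        back = read_density(tmp_path / "r.mrc")
        assert np.abs(back.values - vals).max() == 0.0
        np.testing.assert_array_equal(back.origin, m.origin)


class TestSimulateDensity:
    def test_maximum_at_atom_voxel(self):
        m = simulate_density(make_model([[5.0, 5.0, 5.0]]), resolution=8.0,
                             voxel=2.0, padding=12.0)
        peak = np.unravel_index(np.argmax(m.values), m.shape)
        np.testing.assert_allclose(m.index_to_physical(peak), [5, 5, 5],
                                   atol=m.voxel)

    def test_mass_linearity(self, small_truth):
        model = small_truth.model
        m1 = simulate_density(model, 20.0, 4.0)
        w = np.full(model.ca_model().n_atoms, 220.0)
        m2 = simulate_density(model, 20.0, 4.0, weights=w)
        np.testing.assert_allclose(m2.values, 2.0 * m1.values, rtol=1e-12)

    def test_integral_equals_total_weight(self, small_truth):
        m = simulate_density(small_truth.model, 18.0, 3.0)
        total = m.values.sum() * m.voxel**3
        expected = small_truth.model.ca_model().n_atoms * 110.0
        assert total == pytest.approx(expected, rel=0.01)

    def test_empty_model_raises(self):
        from emplace.structures import BeadModel
        empty = BeadModel(centers=np.zeros((0, 3)), radii=np.zeros(0),
                          parent=[], spans=[])
        with pytest.raises(ValueError):
            simulate_density(empty, 10.0, 2.0)


class TestNCC:
    def test_self_correlation_is_one(self, random_map):
        assert normalized_cross_correlation(random_map, random_map,
                                            mask=None) == pytest.approx(1.0)

    def test_affine_invariance(self, random_map):
        other = random_map.copy(values=3.5 * random_map.values + 1.2)
        assert normalized_cross_correlation(random_map, other,
                                            mask=None) == pytest.approx(1.0)

    def test_tiny_grid_hand_computed(self):
        a = DensityMap(values=np.arange(8, dtype=float).reshape(2, 2, 2), voxel=1)
        b = a.copy(values=a.values[::-1, ::-1, ::-1].copy())
        assert normalized_cross_correlation(a, b, mask=None) == pytest.approx(-1.0)

    def test_constant_map_is_undefined(self):
        m = DensityMap(values=np.ones((4, 4, 4)), voxel=1.0)
        with pytest.raises(UndefinedCorrelationError):
            normalized_cross_correlation(m, m, mask=None)

    def test_translation_scan_matches_direct_oracle(self):
        rng = np.random.default_rng(4)
        a = DensityMap(values=rng.normal(size=(6, 5, 4)), voxel=1.0)
        b = DensityMap(values=rng.normal(size=(6, 5, 4)), voxel=1.0)
        scan = ncc_translation_scan(a, b)
        for shift in [(0, 0, 0), (1, 0, 0), (2, 3, 1), (5, 4, 3)]:
            direct = _pearson(a.values, np.roll(b.values, shift, axis=(0, 1, 2)))
            assert scan[shift] == pytest.approx(direct, abs=1e-6)


class TestLowpass:
    def test_constant_map_unchanged(self):
        m = DensityMap(values=np.full((8, 8, 8), 2.5), voxel=2.0)
        out = lowpass_filter(m, 12.0)
        np.testing.assert_allclose(out.values, 2.5, atol=1e-12)

    def test_gaussian_composition(self, random_map):
        once_twice = lowpass_filter(lowpass_filter(random_map, 9.0), 9.0)
        combined = lowpass_filter(random_map, 9.0 * np.sqrt(2.0))
        np.testing.assert_allclose(once_twice.values, combined.values, atol=1e-10)

    def test_variance_shrinks(self, random_map):
        out = lowpass_filter(random_map, 12.0)
        assert out.values.std() < random_map.values.std()

    def test_mean_preserved(self, random_map):
        out = lowpass_filter(random_map, 10.0)
        assert out.values.mean() == pytest.approx(random_map.values.mean())


class TestMirrorAndSymmetry:
    def test_mirror_is_involution(self, random_map):
        twice = mirror_map(mirror_map(random_map))
        np.testing.assert_array_equal(twice.values, random_map.values)

    @staticmethod
    def _centered_grid(n=21, voxel=2.0):
        half = (n - 1) / 2 * voxel
        return DensityMap(values=np.zeros((n, n, n)), voxel=voxel,
                          origin=(-half, -half, -half))

    def test_mirror_symmetric_model_correlates_with_mirror(self):
        # model symmetric about the grid's central yz-plane
        pts = np.array([[8, 0, 0], [-8, 0, 0], [3, 6, 2], [-3, 6, 2]], float)
        m = simulate_density(make_model(pts), 10.0, 2.0,
                             grid_like=self._centered_grid())
        r = normalized_cross_correlation(m, mirror_map(m), mask=None)
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_chiral_model_correlates_worse(self):
        pts = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [3, 3, 10]], float)
        m = simulate_density(make_model(pts), 10.0, 2.0,
                             grid_like=self._centered_grid())
        r = normalized_cross_correlation(m, mirror_map(m), mask=None)
        assert r < 0.95

    def test_c2_on_symmetric_map_is_identity(self):
        base = np.random.default_rng(2).random((9, 9, 9))
        vals = 0.5 * (base + base[::-1, ::-1, :])  # exactly C2(z)-symmetric
        m = DensityMap(values=vals, voxel=2.0)
        out = apply_symmetry(m, 2)
        np.testing.assert_allclose(out.values, vals, atol=1e-12)

    def test_c2_is_idempotent(self, random_map):
        once = apply_symmetry(random_map, 2)
        twice = apply_symmetry(once, 2)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_mean_preserved_exactly(self, random_map):
        out = apply_symmetry(random_map, 2)
        assert out.values.mean() == pytest.approx(random_map.values.mean(),
                                                  abs=1e-12)

    def test_order_one_rejected(self, random_map):
        with pytest.raises(ValueError):
            apply_symmetry(random_map, 1)


class TestDifferenceMap:
    def test_self_difference_is_zero(self, small_map):
        d = difference_map(small_map, small_map)
        np.testing.assert_allclose(d.values, 0.0, atol=1e-10)

    def test_antisymmetry(self, small_truth, small_map):
        other = small_map.copy(values=small_map.values * 2.0 + 0.1)
        other.values[3:6, 3:6, 3:6] += 1.0
        ab = difference_map(small_map, other)
        ba = difference_map(other, small_map)
        np.testing.assert_allclose(ab.values, -ba.values, atol=1e-10)

    def test_blob_localizes(self):
        rng = np.random.default_rng(3)
        base = rng.random((24, 24, 24)) * 0.05
        a = base.copy()
        a[14:18, 14:18, 14:18] += 2.0  # localized extra density
        ma = DensityMap(values=a, voxel=4.0)
        mb = DensityMap(values=base, voxel=4.0)
        d = difference_map(ma, mb, common_resolution=20.0)
        peak = np.unravel_index(np.argmax(d.values), d.shape)
        assert all(10 <= p <= 21 for p in peak)


class TestFsc:
    def test_identity_gives_unity(self, random_map):
        curve = fsc(random_map, random_map)
        np.testing.assert_allclose(curve.correlation, 1.0, atol=1e-9)

    def test_negated_gives_minus_one(self, random_map):
        neg = random_map.copy(values=-random_map.values)
        curve = fsc(random_map, neg)
        np.testing.assert_allclose(curve.correlation, -1.0, atol=1e-9)

    def test_independent_noise_fsc_near_zero(self):
        rng = np.random.default_rng(9)
        a = DensityMap(values=rng.normal(size=(20, 20, 20)), voxel=2.0)
        b = DensityMap(values=rng.normal(size=(20, 20, 20)), voxel=2.0)
        curve = fsc(a, b)
        bound = 3.0 / np.sqrt(np.maximum(curve.n_voxels, 1))
        assert np.mean(np.abs(curve.correlation) <= bound) > 0.9

    def test_matches_direct_dft_oracle(self):
        rng = np.random.default_rng(5)
        a = DensityMap(values=rng.normal(size=(8, 8, 8)), voxel=2.0)
        b = DensityMap(values=rng.normal(size=(8, 8, 8)) + 0.5 * a.values,
                       voxel=2.0)
        curve = fsc(a, b)
        # direct-summation oracle over explicit DFT coefficients
        n = 8
        fa = np.zeros((n, n, n), complex)
        fb = np.zeros((n, n, n), complex)
        grid = np.arange(n)
        for h in range(n):
            for k in range(n):
                for l in range(n):
                    phase = np.exp(-2j * np.pi * (h * grid[:, None, None]
                                                  + k * grid[None, :, None]
                                                  + l * grid[None, None, :]) / n)
                    fa[h, k, l] = (a.values * phase).sum()
                    fb[h, k, l] = (b.values * phase).sum()
        freqs = np.fft.fftfreq(n, d=2.0)
        fmag = np.sqrt(freqs[:, None, None]**2 + freqs[None, :, None]**2
                       + freqs[None, None, :]**2)
        df = 1.0 / (n * 2.0)
        shell = np.round(fmag / df).astype(int)
        for si, f in enumerate(curve.frequency):
            s = int(round(f / df))
            sel = shell == s
            num = (fa[sel] * np.conj(fb[sel])).sum().real
            den = np.sqrt((np.abs(fa[sel])**2).sum() * (np.abs(fb[sel])**2).sum())
            assert curve.correlation[si] == pytest.approx(num / den, abs=1e-6)

    def test_resolution_at_interpolates(self):
        from emplace.density import FscCurve
        curve = FscCurve(frequency=[0.01, 0.02, 0.03],
                         correlation=[1.0, 0.5, 0.0], n_voxels=[10, 20, 30])
        est = resolution_at(curve, 0.143)
        assert est.crossed
        # linear interpolation between 0.02 and 0.03
        fx = 0.02 + (0.5 - 0.143) / 0.5 * 0.01
        assert est.resolution == pytest.approx(1.0 / fx)

    def test_never_crossing_flags(self):
        from emplace.density import FscCurve
        curve = FscCurve(frequency=[0.01, 0.02], correlation=[0.9, 0.8],
                         n_voxels=[5, 9])
        est = resolution_at(curve, 0.143)
        assert not est.crossed

    def test_text_roundtrip(self, tmp_path, random_map):
        curve = fsc(random_map, random_map)
        curve.to_text(tmp_path / "fsc.tsv")
        from emplace.density import FscCurve
        back = FscCurve.from_text(tmp_path / "fsc.tsv")
        np.testing.assert_allclose(back.frequency, curve.frequency)
        np.testing.assert_allclose(back.correlation, curve.correlation)


class TestVolumeCoverage:
    def test_self_model_covers_fully(self, small_truth, small_map):
        beads = coarse_grain(small_truth.model)
        cov = volume_coverage(small_map, beads, envelope_pad=25.0)
        assert cov == pytest.approx(1.0)

    def test_empty_model_covers_nothing(self, small_map):
        from emplace.structures import BeadModel
        empty = BeadModel(centers=np.zeros((0, 3)), radii=np.zeros(0),
                          parent=[], spans=[])
        assert volume_coverage(small_map, empty,
                               contour=float(small_map.values.mean())) == 0.0

    def test_half_covered_two_blob_map(self):
        blob1 = make_model(np.zeros((40, 3)))
        blob2 = make_model(np.zeros((40, 3)) + [60.0, 0, 0])
        both = make_model(np.concatenate([np.zeros((40, 3)),
                                          np.zeros((40, 3)) + [60.0, 0, 0]]))
        m = simulate_density(both, 16.0, 4.0, padding=24.0)
        beads = coarse_grain(blob1)
        cov = volume_coverage(m, beads, mass_da=40 * 110.0, envelope_pad=10.0)
        assert cov == pytest.approx(0.5, abs=0.05)

    def test_contour_above_max_raises(self, small_map):
        beads_src = make_model(np.zeros((10, 3)))
        with pytest.raises(ValueError):
            volume_coverage(small_map, coarse_grain(beads_src),
                            contour=float(small_map.values.max()) + 1.0)
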