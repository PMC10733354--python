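import numpy as np
import pytest

from btseg import wavelet as W


def pywt_reference_dwt2(x, name):
    """PyWavelets as an independent oracle, mapped onto this package's
    conventions (convolution with even-index downsampling).

    PyWavelets periodization correlates with the reversed filter at a
    half-support delay; reversing the input with offset s and remapping the
    output index i -> (t - i) mod n/2 makes the two conventions coincide.
    """
    import pywt

    L = len(pywt.Wavelet(name).dec_lo)
    s = 0 if L == 2 else 1
    t = (s - 1 + L // 2) // 2
    n0, n1 = x.shape
    rev = x[(s - np.arange(n0)) % n0][:, (s - np.arange(n1)) % n1]
    cA, (cH, cV, cD) = pywt.dwt2(rev, name, mode="periodization")
    m0, m1 = cA.shape

    def remap(c):
        return c[(t - np.arange(m0)) % m0][:, (t - np.arange(m1)) % m1]

    # pywt's cH is high-pass along axis 0 in this orientation
    return remap(cA), remap(cH), remap(cV), remap(cD)


class TestFilterPairs:
    @pytest.mark.parametrize("name", ["haar", "db2", "db4"])
    def test_orthonormal_filter_identities(self, name):
        fp = W.get_wavelet(name)
        assert np.sum(fp.h**2) == pytest.approx(1.0, abs=1e-10)
        assert np.sum(fp.g) == pytest.approx(0.0, abs=1e-10)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            W.get_wavelet("sym5")


class TestAdmissibility:
    def test_haar_mother_passes(self):
        t = np.linspace(0, 1, 1000, endpoint=False)
        psi = np.where(t < 0.5, 1.0, -1.0)
        res = W.check_admissibility(psi, dt=1e-3)
        assert res.passed
        assert res.energy == pytest.approx(1.0, rel=1e-6)
        assert abs(res.integral) < 1e-9

    def test_constant_function_fails_zero_mean(self):
        res = W.check_admissibility(np.ones(100), dt=0.01)
        assert not res.passed and not res.zero_mean

    def test_gaussian_bump_fails(self):
        t = np.linspace(-5, 5, 500)
        res = W.check_admissibility(np.exp(-t**2), dt=t[1] - t[0])
        assert not res.passed

    def test_nonuniform_grid_rejected(self):
        with pytest.raises(ValueError):
            W.check_admissibility(np.ones(4), dt=0.1, t=np.array([0, 0.1, 0.3, 0.4]))


class TestDWT:
    def test_constant_image_haar(self):
        bands = W.dwt2(np.full((2, 2), 3.0))
        assert bands.a[0, 0] == pytest.approx(6.0)
        for b in (bands.h, bands.v, bands.d):
            assert np.allclose(b, 0.0)

    @pytest.mark.parametrize("name", ["haar", "db2", "db4"])
    def test_energy_conservation(self, name, rng):
        x = rng.normal(size=(16, 16))
        bands = W.dwt2(x, W.get_wavelet(name))
        e = sum(float((b**2).sum()) for b in bands.bands().values())
        assert e == pytest.approx(float((x**2).sum()), rel=1e-9)

    @pytest.mark.parametrize("name", ["haar", "db2", "db4"])
    def test_matches_external_reference(self, name, rng):
        pytest.importorskip("pywt")
        x = rng.normal(size=(8, 8))
        bands = W.dwt2(x, W.get_wavelet(name))
        cA, cH, cV, cD = pywt_reference_dwt2(x, name)
        assert np.allclose(bands.a, cA, atol=1e-9)
        assert np.allclose(bands.h, cH, atol=1e-9)
        assert np.allclose(bands.v, cV, atol=1e-9)
        assert np.allclose(bands.d, cD, atol=1e-9)

    def test_critical_sampling_coefficient_count(self, rng):
        x = rng.normal(size=(10, 10))
        bands = W.dwt2(x)
        assert sum(b.size for b in bands.bands().values()) == x.size

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            W.dwt2(np.ones((1, 5)))


class TestIDWT:
    @pytest.mark.parametrize("name", ["haar", "db2"])
    def test_perfect_reconstruction(self, name, rng):
        x = rng.normal(size=(16, 16))
        fp = W.get_wavelet(name)
        assert np.abs(W.idwt2(W.dwt2(x, fp), fp) - x).max() < 1e-9

    def test_zero_bands_give_zero_raster(self):
        z = np.zeros((4, 4))
        bands = W.SubbandSet(a=z, h=z, v=z, d=z)
        assert np.allclose(W.idwt2(bands), 0.0)

    def test_approximation_only_reconstructs_constant(self):
        x = np.full((8, 8), 5.0)
        bands = W.dwt2(x)
        zeroed = W.SubbandSet(a=bands.a, h=np.zeros_like(bands.h),
                              v=np.zeros_like(bands.v), d=np.zeros_like(bands.d))
        assert np.allclose(W.idwt2(zeroed), x, atol=1e-9)

    def test_mismatched_band_shapes_rejected(self):
        with pytest.raises(ValueError):
            W.idwt2(W.SubbandSet(a=np.zeros((2, 2)), h=np.zeros((3, 2)),
                                 v=np.zeros((2, 2)), d=np.zeros((2, 2))))


class TestMultilevel:
    def test_level_one_equals_dwt2(self, rng):
        x = rng.normal(size=(8, 8))
        single = W.dwt2(x)
        multi = W.multilevel_dwt(x, level=1)
        assert len(multi) == 1
        assert np.allclose(multi[0].a, single.a)

    def test_dyadic_halving_depth(self, rng):
        x = rng.normal(size=(8, 8))
        bands = W.multilevel_dwt(x, level=3)
        assert bands[-1].a.shape == (1, 1)

    def test_telescoping_energy_conservation(self, rng):
        x = rng.normal(size=(16, 16))
        bands = W.multilevel_dwt(x, level=3)
        e = float((bands[-1].a**2).sum())
        e += sum(float((b.h**2).sum() + (b.v**2).sum() + (b.d**2).sum())
                 for b in bands)
        assert e == pytest.approx(float((x**2).sum()), rel=1e-9)


class TestDWFT:
    def test_subband_shapes_equal_input_shape(self, rng):
        x = rng.normal(size=(16, 16))
        for bands in W.dwft2(x, level=3):
            for b in bands.bands().values():
                assert b.shape == x.shape

    def test_shift_equivariance(self, rng):
        x = rng.normal(size=(16, 16))
        shifted = np.roll(x, (1, 0), axis=(0, 1))
        for b0, b1 in zip(W.dwft2(x, level=2), W.dwft2(shifted, level=2)):
            for k in "ahvd":
                assert np.allclose(np.roll(getattr(b0, k), (1, 0), axis=(0, 1)),
                                   getattr(b1, k), atol=1e-12)

    def test_decimating_level1_recovers_dwt(self, rng):
        x = rng.normal(size=(16, 16))
        frame = W.dwft2(x, level=1)[0]
        dec = W.dwt2(x)
        for k in "ahvd":
            assert np.allclose(getattr(frame, k)[::2, ::2], getattr(dec, k),
                               atol=1e-12)

    def test_excessive_level_rejected(self):
        with pytest.raises(ValueError):
            W.dwft2(np.ones((4, 4)), W.get_wavelet("db4"), level=3)


class TestEnergyFeatures:
    def test_zero_image_all_zero_energies(self):
        feats = W.subband_energy_features(W.multilevel_dwt(np.zeros((8, 8)) + 0.0,
                                                           level=2))
        assert all(v == 0.0 for v in feats.values())

    def test_constant_image_only_approximation_energy(self):
        feats = W.subband_energy_features(W.multilevel_dwt(np.full((8, 8), 9.0),
                                                           level=2))
        for name, v in feats.items():
            if "A" in name:
                assert v > 0
            else:
                assert v == pytest.approx(0.0, abs=1e-18)

    def test_feature_count_and_order(self, rng):
        feats = W.subband_energy_features(W.multilevel_dwt(rng.normal(size=(16, 16)),
                                                           level=3))
        assert len(feats) == 3 * 3 + 1
        assert list(feats)[0] == "wav_energy_A3"

    def test_frame_energies_shift_invariant(self, rng):
        x = rng.normal(size=(16, 16))
        f0 = W.subband_energy_features(W.dwft2(x, level=2))
        f1 = W.subband_energy_features(W.dwft2(np.roll(x, (3, 5), axis=(0, 1)),
                                               level=2))
        for k in f0:
            assert f0[k] == pytest.approx(f1[k], abs=1e-9)
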