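"""Texture engine: filters, resampling, quantization, features, invariants."""

import numpy as np
import pytest

from rtlipred.containers import ScanVolume, parse_feature_name
from rtlipred.texture import (
    COARSENESS_CAP,
    DIRECTIONS_13,
    QuantizedROI,
    RadiomicsExtractor,
    TextureParameterGrid,
    TextureParams,
    extract_all,
    glcm_features,
    glcm_matrix,
    glrlm_features,
    glrlm_matrix,
    glszm_features,
    glszm_matrix,
    global_features,
    ngtdm_features,
    ngtdm_table,
    nontexture_features,
    quantize,
    resample_isotropic,
    wavelet_bandpass_filter,
)



def _iso_vol(data, spacing=1.0):
    return ScanVolume(np.asarray(data, float), (spacing, spacing, spacing))


class TestResample:
    def test_identity_at_native_isotropic_spacing(self):
        rng = np.random.default_rng(0)
        v = _iso_vol(rng.normal(size=(10, 10, 10)))
        out = resample_isotropic(v, 1.0)
        np.testing.assert_allclose(out.data, v.data, atol=1e-12)

    def test_doubling_scale_halves_axes(self):
        v = _iso_vol(np.zeros((20, 16, 12)))
        out = resample_isotropic(v, 2.0)
        assert out.data.shape == (10, 8, 6)

    def test_sphere_volume_preserved(self):
        """10 mm sphere mask resampled 1 -> 2 mm keeps physical volume to 5%."""
        g = np.mgrid[:24, :24, :24]
        r2 = sum((a - 11.5) ** 2 for a in g)
        mask = r2 <= 10.0**2
        from rtlipred.texture import resample_mask

        out = resample_mask(mask, (1, 1, 1), 2.0)
        vol_in = mask.sum() * 1.0
        vol_out = out.sum() * 8.0
        assert abs(vol_out - vol_in) / vol_in < 0.05


class TestWaveletBandpass:
    def test_ratio_one_is_identity(self):
        rng = np.random.default_rng(1)
        v = _iso_vol(rng.normal(size=(16, 16, 16)))
        out = wavelet_bandpass_filter(v, 1.0)
        np.testing.assert_allclose(out.data, v.data, atol=1e-6)

    def test_linearity(self):
        rng = np.random.default_rng(2)
        v = _iso_vol(rng.normal(size=(12, 12, 12)))
        f1 = wavelet_bandpass_filter(v, 2.0).data
        f3 = wavelet_bandpass_filter(_iso_vol(3.0 * v.data), 2.0).data
        np.testing.assert_allclose(f3, 3.0 * f1, rtol=1e-9, atol=1e-9)

    def test_bandpass_boost_raises_checker_energy_share(self):
        """R = 2 amplifies a high-frequency checker pattern relative to a
        smooth background, compared to R = 1."""
        g = np.mgrid[:16, :16, :16]
        smooth = np.sin(g[0] / 8.0) + np.cos(g[1] / 8.0)
        checker = 0.3 * ((g.sum(axis=0) % 2) * 2.0 - 1.0)
        v = _iso_vol(smooth + checker)

        def checker_share(r):
            out = wavelet_bandpass_filter(v, r, basis="db2").data
            hp = out - smooth
            return (hp**2).sum() / (out**2).sum()

        assert checker_share(2.0) > checker_share(1.0)

    def test_invalid_basis(self):
        with pytest.raises(ValueError, match="basis"):
            wavelet_bandpass_filter(_iso_vol(np.zeros((8, 8, 8))), 1.0, basis="nosuchwav")


class TestQuantize:
    def test_equalprob_uniform_occupancy(self):
        data = np.arange(1, 101, dtype=float).reshape(4, 5, 5)
        q = quantize(data, np.ones(data.shape, bool), "equalprob", 4)
        assert list(np.bincount(q.values)[1:]) == [25, 25, 25, 25]

    def test_uniform_threshold_at_half(self):
        data = np.linspace(0, 1, 64).reshape(4, 4, 4)
        q = quantize(data, np.ones(data.shape, bool), "uniform", 2)
        np.testing.assert_array_equal(q.values == 2, data.ravel() >= 0.5)

    def test_constant_roi_degenerate(self):
        q = quantize(np.ones((4, 4, 4)), np.ones((4, 4, 4), bool), "uniform", 8)
        assert q.degenerate and set(q.values) == {1}

    def test_levels_in_range(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(6, 6, 6))
        mask = rng.random((6, 6, 6)) > 0.3
        for quant in ("uniform", "equalprob"):
            q = quantize(data, mask, quant, 5)
            assert q.values.min() >= 1 and q.values.max() <= 5
            assert q.n_voxels == mask.sum()


def _const_roi(n=4, level=1, ng=4):
    levels = np.full((n, n, n), level, dtype=np.int32)
    return QuantizedROI(levels=levels, mask=np.ones((n, n, n), bool), n_levels=ng)


class TestGlobalFeatures:
    def test_constant_policy(self):
        f = global_features(_const_roi())
        assert f == {"variance": 0.0, "skewness": 0.0, "kurtosis": 0.0}

    def test_symmetric_two_point_zero_skewness(self):
        levels = np.array([1, 1, 3, 3], dtype=np.int32).reshape(4, 1, 1)
        q = QuantizedROI(levels=levels, mask=np.ones((4, 1, 1), bool), n_levels=3)
        assert global_features(q)["skewness"] == pytest.approx(0.0)

    def test_textbook_moments(self):
        x = np.array([1, 2, 2, 3, 7], dtype=float)
        levels = x.astype(np.int32).reshape(5, 1, 1)
        q = QuantizedROI(levels=levels, mask=np.ones((5, 1, 1), bool), n_levels=7)
        f = global_features(q)
        c = x - x.mean()
        m2, m3, m4 = (np.mean(c**p) for p in (2, 3, 4))
        assert f["variance"] == pytest.approx(x.var(ddof=1))
        assert f["skewness"] == pytest.approx(m3 / m2**1.5)
        assert f["kurtosis"] == pytest.approx(m4 / m2**2 - 3)


class TestMatrixDegeneracies:
    def test_constant_roi(self):
        q = _const_roi(4)
        g = glcm_features(q)
        assert g["energy"] == 1.0 and g["contrast"] == 0.0
        r = glrlm_matrix(q)
        # all runs carry the single level and jointly cover every voxel once per direction
        assert r[1:, :].sum() == 0
        assert (r * np.arange(1, r.shape[1] + 1)).sum() == 13 * 64
        # full-length runs: 3 axis dirs x 16 lines + 6 face-diagonal dirs x 4 + 4 body diagonals
        assert r[0, 3] == 48 + 24 + 4
        z = glszm_matrix(q)
        assert z.sum() == 1.0  # exactly one zone
        n = ngtdm_features(q)
        assert n["coarseness"] == COARSENESS_CAP

    def test_single_voxel_roi(self):
        levels = np.zeros((3, 3, 3), dtype=np.int32)
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        levels[1, 1, 1] = 2
        q = QuantizedROI(levels=levels, mask=mask, n_levels=4)
        g = glcm_features(q)
        assert g["energy"] == 1.0 and g["contrast"] == 0.0
        assert glrlm_features(q)["rlv"] == 0.0
        assert glszm_features(q)["zsv"] == 0.0

    def test_checkerboard_contrast_maximal(self):
        g = np.indices((6, 6, 6)).sum(axis=0)
        levels = (g % 2 + 1).astype(np.int32)
        q = QuantizedROI(levels=levels, mask=np.ones((6, 6, 6), bool), n_levels=2)
        P = glcm_matrix(q)
        # axis-aligned neighbours always differ, so off-diagonal mass dominates
        assert P[0, 1] + P[1, 0] > P[0, 0] + P[1, 1]


class TestMatrixInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_mass_and_count_conservation(self, seed):
        from conftest import random_quantized_roi

        q = random_quantized_roi(np.random.default_rng(seed))
        assert glcm_matrix(q).sum() == pytest.approx(1.0)
        R = glrlm_matrix(q)
        lengths = np.arange(1, R.shape[1] + 1)
        assert (R * lengths).sum() == pytest.approx(len(DIRECTIONS_13) * q.n_voxels)
        S = glszm_matrix(q)
        sizes = np.arange(1, S.shape[1] + 1)
        assert (S * sizes).sum() == pytest.approx(q.n_voxels)
        p, s, n = ngtdm_table(q)
        if n > 0:
            assert p.sum() == pytest.approx(1.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(7)
        core = rng.integers(1, 5, size=(5, 5, 5)).astype(np.int32)
        feats = []
        for offset in ((0, 0, 0), (3, 2, 1)):
            levels = np.zeros((12, 12, 12), dtype=np.int32)
            mask = np.zeros((12, 12, 12), bool)
            sl = tuple(slice(o, o + 5) for o in offset)
            levels[sl] = core
            mask[sl] = True
            q = QuantizedROI(levels=levels, mask=mask, n_levels=4)
            f = {}
            for fn in (glcm_features, glrlm_features, glszm_features, ngtdm_features):
                f.update({f"{fn.__name__}.{k}": v for k, v in fn(q).items()})
            feats.append(f)
        for k in feats[0]:
            assert feats[0][k] == pytest.approx(feats[1][k], rel=1e-12), k


class TestNontexture:
    def test_cube(self):
        mask = np.zeros((14, 14, 14), bool)
        mask[2:12, 2:12, 2:12] = True
        f = nontexture_features(mask, (1, 1, 1))
        assert f["volume"] == pytest.approx(1000.0)
        assert f["solidity"] == pytest.approx(1.0, abs=1e-9)

    def test_rod_size(self):
        mask = np.zeros((3, 3, 22), bool)
        mask[1, 1, 1:21] = True
        f = nontexture_features(mask, (1, 1, 1))
        assert f["size"] == pytest.approx(19.0, abs=0.1)

    def test_sphere_vs_ellipsoid_eccentricity(self):
        g = np.mgrid[:25, :25, :25].astype(float)
        r2 = sum((a - 12.0) ** 2 for a in g)
        sphere = r2 <= 9.0**2
        fs = nontexture_features(sphere, (1, 1, 1))
        assert fs["eccentricity"] == pytest.approx(0.0, abs=0.05)

        g = np.mgrid[:61, :25, :25].astype(float)
        ell = ((g[0] - 30) / 27.0) ** 2 + ((g[1] - 12) / 9.0) ** 2 + ((g[2] - 12) / 9.0) ** 2 <= 1
        fe = nontexture_features(ell, (1, 1, 1))
        # 3:1 axis ratio: ecc = sqrt(1 - (1/3)^2)
        assert fe["eccentricity"] == pytest.approx(np.sqrt(1 - 1 / 9), abs=0.02)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            nontexture_features(np.zeros((4, 4, 4), bool), (1, 1, 1))


class TestExtractAll:
    def test_minimal_grid_counts(self, small_subject):
        grid = TextureParameterGrid(ratios=(1.0,), scales=(3.0,), quantizers=("uniform",), gray_levels=(8,))
        fv = extract_all(
            {"T2w": small_subject.scans[1]["T2w"]}, small_subject.rois, grid=grid, tissues=("mtl",)
        )
        fams = [parse_feature_name(c)["family"] for c in fv.index]
        assert len(fv) == 47
        assert fams.count("nontexture") == 4
        assert fv.notna().all()

    def test_grid_cardinality_formula(self):
        grid = TextureParameterGrid(ratios=(1.0, 2.0), scales=(2.0,), quantizers=("uniform", "equalprob"), gray_levels=(8, 16, 32))
        assert len(grid) == 2 * 1 * 2 * 3
        assert grid.n_texture_features == 43 * len(grid)

    def test_enumeration_order_irrelevant(self, small_subject):
        base = TextureParameterGrid(ratios=(1.0, 2.0), scales=(3.0,), quantizers=("uniform",), gray_levels=(8, 16))
        shuffled = TextureParameterGrid(ratios=(2.0, 1.0), scales=(3.0,), quantizers=("uniform",), gray_levels=(16, 8))
        scans = {"T2w": small_subject.scans[2]["T2w"]}
        a = extract_all(scans, small_subject.rois, grid=base, tissues=("mtl",))
        b = extract_all(scans, small_subject.rois, grid=shuffled, tissues=("mtl",))
        assert sorted(a.index) == sorted(b.index)
        np.testing.assert_allclose(a.sort_index().values, b.sort_index().values, rtol=1e-12)

    def test_extractor_rows_and_params_validation(self, small_subject):
        grid = TextureParameterGrid(ratios=(1.0,), scales=(3.0,), quantizers=("uniform",), gray_levels=(8,))
        ext = RadiomicsExtractor(grid=grid, tissues=("mtl",), sequences=("T2w",), time_indices=(1, 2))
        table = ext.transform([small_subject])
        assert table.shape == (2, 47)
        assert table.index.names == ["subject_id", "time_index"]
        with pytest.raises(ValueError):
            TextureParams(ratio=-1, scale=1.0, quantizer="uniform", n_levels=8)
        with pytest.raises(ValueError):
            TextureParams(ratio=1, scale=1.0, quantizer="median", n_levels=8)
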