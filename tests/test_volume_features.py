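"""Texture/shape/first-order features against dense brute-force loop oracles
on tiny volumes, plus closed-form phantom checks."""

import numpy as np
import pytest

from tests.conftest import toy_roi
from vmatqa.dicomrt import CTVolume, DoseVolume, StructureMask
from vmatqa.volume_features import (
    DIRECTIONS,
    EmptyROIError,
    first_order_features,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    higher_order_features,
    ngtdm_features,
    preprocess_ptv,
    shape_features,
    extract_volume_features,
    _glcm_matrix,
    _glrlm_matrix,
)

rng = np.random.default_rng(12345)


# --------------------------------------------------------------------------
# brute-force oracles (independent dense loops)
# --------------------------------------------------------------------------

def brute_glcm(levels, mask, Ng, offset):
    mat = np.zeros((Ng, Ng))
    nz, ny, nx = levels.shape
    dz, dy, dx = offset
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                z2, y2, x2 = z + dz, y + dy, x + dx
                if not (0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx):
                    continue
                if mask[z, y, x] and mask[z2, y2, x2]:
                    mat[levels[z, y, x] - 1, levels[z2, y2, x2] - 1] += 1
    return mat + mat.T


def brute_runs(levels, mask, Ng, offset):
    """All runs of equal gray level along one direction, by walking rays."""
    lv = np.where(mask, levels, 0)
    nz, ny, nx = lv.shape
    dz, dy, dx = offset
    runs = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                pz, py, px = z - dz, y - dy, x - dx
                if 0 <= pz < nz and 0 <= py < ny and 0 <= px < nx:
                    continue  # not a ray start
                cz, cy, cx = z, y, x
                cur, n = 0, 0
                while 0 <= cz < nz and 0 <= cy < ny and 0 <= cx < nx:
                    v = lv[cz, cy, cx]
                    if v == cur and v != 0:
                        n += 1
                    else:
                        if cur != 0:
                            runs.append((cur, n))
                        cur, n = v, (1 if v != 0 else 0)
                    cz, cy, cx = cz + dz, cy + dy, cx + dx
                if cur != 0:
                    runs.append((cur, n))
    mat = np.zeros((Ng, max((n for _, n in runs), default=1)))
    for g, n in runs:
        mat[g - 1, n - 1] += 1
    return mat


def brute_first_order(x, levels, Ng, voxel_vol=1.0):
    """Direct per-formula recomputation of all 18 first-order features."""
    x = np.asarray(x, float).ravel()
    n = len(x)
    p = np.array([(levels == g).sum() for g in range(1, Ng + 1)]) / n
    pnz = p[p > 0]
    mean = x.sum() / n
    std = np.sqrt(((x - mean) ** 2).sum() / n)
    p10, p90 = np.percentile(x, [10, 90])
    robust = x[(x >= p10) & (x <= p90)]
    out = {
        "fo_energy": (x**2).sum(),
        "fo_total_energy": voxel_vol * (x**2).sum(),
        "fo_entropy": -(pnz * np.log2(pnz)).sum(),
        "fo_minimum": x.min(),
        "fo_percentile10": p10,
        "fo_percentile90": p90,
        "fo_maximum": x.max(),
        "fo_mean": mean,
        "fo_median": np.median(x),
        "fo_interquartile_range": np.percentile(x, 75) - np.percentile(x, 25),
        "fo_range": x.max() - x.min(),
        "fo_mean_absolute_deviation": np.abs(x - mean).sum() / n,
        "fo_robust_mean_absolute_deviation":
            np.abs(robust - robust.mean()).mean(),
        "fo_root_mean_squared": np.sqrt((x**2).sum() / n),
        "fo_standard_deviation": std,
        "fo_skewness": (((x - mean) / std) ** 3).mean() if std else 0.0,
        "fo_kurtosis": (((x - mean) / std) ** 4).mean() if std else 0.0,
        "fo_uniformity": (p**2).sum(),
    }
    return out


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

class TestPreprocess:
    @staticmethod
    def make_vol(values, mask=None):
        values = np.asarray(values, float)
        ct = CTVolume(voxels=values, spacing=(1, 1, 1), origin=(0, 0, 0))
        m = np.ones(values.shape, bool) if mask is None else mask
        return ct, StructureMask("PTV", m)

    def test_constant_region_single_level(self):
        ct, m = self.make_vol(np.zeros((4, 4, 4)))
        roi = preprocess_ptv(ct, m, "radiomic")
        assert roi.Ng == 1
        assert np.all(roi.levels[roi.mask] == 1)

    def test_level_count_by_enumeration(self):
        vals = np.linspace(-100, 100, 64).reshape(4, 4, 4)
        ct, m = self.make_vol(vals)
        roi = preprocess_ptv(ct, m, "radiomic")
        # floor((100 - (-100)) / 25) + 1 = 9
        assert roi.Ng == 9

    def test_cavity_voxels_removed_for_radiomic(self):
        vals = np.full((4, 4, 4), 40.0)
        vals[2, 2, 2] = -500.0
        ct, m = self.make_vol(vals)
        roi = preprocess_ptv(ct, m, "radiomic")
        assert roi.mask.sum() == 63
        # dosimetric keeps the anatomical mask
        dose = DoseVolume(voxels=np.abs(vals), spacing=(1, 1, 1), origin=(0, 0, 0))
        roi_d = preprocess_ptv(dose, StructureMask("PTV", m.mask), "dosimetric")
        assert roi_d.mask.sum() == 64

    def test_all_below_threshold_is_error(self):
        ct, m = self.make_vol(np.full((3, 3, 3), -800.0))
        with pytest.raises(EmptyROIError):
            preprocess_ptv(ct, m, "radiomic")


# --------------------------------------------------------------------------
# families vs oracles
# --------------------------------------------------------------------------

class TestGLCM:
    def test_random_volume_matches_bruteforce(self):
        vals = rng.integers(0, 8, size=(6, 6, 6)).astype(float)
        roi = toy_roi(vals)
        for off in DIRECTIONS[::4]:
            impl = _glcm_matrix(roi.levels, roi.mask, roi.Ng, off)
            ref = brute_glcm(roi.levels, roi.mask, roi.Ng, off)
            np.testing.assert_array_equal(impl, ref)

    def test_features_match_dense_recomputation(self):
        """Every GLCM feature equals an independent dense recomputation."""
        vals = rng.integers(0, 5, size=(5, 5, 5)).astype(float)
        roi = toy_roi(vals)
        feats = glcm_features(roi)
        # independent recomputation of a subset with straightforward loops
        per_dir = []
        for off in DIRECTIONS:
            P = brute_glcm(roi.levels, roi.mask, roi.Ng, off)
            p = P / P.sum()
            Ng = roi.Ng
            contrast = sum(
                (i - j) ** 2 * p[i - 1, j - 1]
                for i in range(1, Ng + 1) for j in range(1, Ng + 1))
            energy = (p**2).sum()
            ent = -(p[p > 0] * np.log2(p[p > 0])).sum()
            maxp = p.max()
            idm = sum(
                p[i - 1, j - 1] / (1 + (i - j) ** 2)
                for i in range(1, Ng + 1) for j in range(1, Ng + 1))
            per_dir.append((contrast, energy, ent, maxp, idm))
        ref = np.mean(per_dir, axis=0)
        assert feats["glcm_contrast"] == pytest.approx(ref[0], abs=1e-10)
        assert feats["glcm_joint_energy"] == pytest.approx(ref[1], abs=1e-10)
        assert feats["glcm_joint_entropy"] == pytest.approx(ref[2], abs=1e-10)
        assert feats["glcm_maximum_probability"] == pytest.approx(ref[3], abs=1e-10)
        assert feats["glcm_idm"] == pytest.approx(ref[4], abs=1e-10)

    def test_constant_volume_degenerate(self):
        roi = toy_roi(np.zeros((4, 4, 4)))
        feats = glcm_features(roi)
        assert feats["glcm_joint_energy"] == pytest.approx(1.0)
        assert feats["glcm_contrast"] == pytest.approx(0.0)
        assert feats["glcm_correlation"] == 0.0  # convention at zero variance

    def test_checkerboard_axis_offsets(self):
        """2-level 3-D checkerboard: along any axis offset every pair is a
        transition, so contrast = 1 and joint energy = 1/2."""
        z, y, x = np.indices((4, 4, 4))
        vals = ((x + y + z) % 2).astype(float)
        roi = toy_roi(vals)
        for off in [(0, 0, 1), (0, 1, 0), (1, 0, 0)]:
            P = _glcm_matrix(roi.levels, roi.mask, roi.Ng, off)
            p = P / P.sum()
            assert ((1 - 0) ** 2 * p[0, 1] + p[1, 0]) == pytest.approx(1.0)
            assert (p**2).sum() == pytest.approx(0.5)


class TestFirstOrder:
    def test_hand_written_array_all_18(self):
        vals = rng.uniform(-50, 80, size=(3, 3, 3))
        roi = toy_roi(vals, bin_width=25.0)
        feats = first_order_features(roi)
        ref = brute_first_order(vals, roi.levels, roi.Ng)
        assert set(feats) == set(ref)
        for k in ref:
            assert feats[k] == pytest.approx(ref[k], rel=1e-10), k

    def test_constant_region(self):
        roi = toy_roi(np.full((3, 3, 3), 7.0))
        feats = first_order_features(roi)
        assert feats["fo_entropy"] == 0.0
        assert feats["fo_uniformity"] == 1.0
        assert feats["fo_standard_deviation"] == 0.0

    def test_two_level_half_half(self):
        vals = np.zeros((2, 2, 2))
        vals[0] = 100.0
        roi = toy_roi(vals, bin_width=25.0)
        feats = first_order_features(roi)
        assert feats["fo_entropy"] == pytest.approx(1.0)
        assert feats["fo_uniformity"] == pytest.approx(0.5)


class TestRunLengthAndZones:
    def test_glrlm_matrix_matches_ray_walk(self):
        vals = rng.integers(0, 4, size=(5, 5, 5)).astype(float)
        roi = toy_roi(vals)
        for off in DIRECTIONS[::3]:
            impl = _glrlm_matrix(roi.levels, roi.mask, roi.Ng, off)
            ref = brute_runs(roi.levels, roi.mask, roi.Ng, off)
            np.testing.assert_array_equal(impl[:, :ref.shape[1]], ref)
            assert impl[:, ref.shape[1]:].sum() == 0

    def test_stripes_run_distribution(self):
        """Width-2 stripes along x: runs along (0,0,1) are all length 2."""
        z, y, x = np.indices((4, 4, 4))
        vals = ((x // 2) % 2).astype(float)
        roi = toy_roi(vals)
        P = _glrlm_matrix(roi.levels, roi.mask, roi.Ng, (0, 0, 1))
        assert P[:, 1].sum() == 32  # 2 levels x 16 rays each... all runs len 2
        assert P.sum() == 32 and P[:, 0].sum() == 0

    def test_glszm_constant_volume_single_zone(self):
        roi = toy_roi(np.zeros((4, 4, 4)))
        feats = glszm_features(roi)
        assert feats["glszm_size_zone_nonuniformity"] == pytest.approx(1.0)
        assert feats["glszm_zone_percentage"] == pytest.approx(1.0 / 64.0)

    def test_glszm_two_disjoint_zones(self):
        vals = np.zeros((3, 3, 3))
        vals[0, 0, 0] = 5.0
        vals[2, 2, 2] = 5.0  # not 26-connected to the first
        roi = toy_roi(vals, bin_width=1.0)
        feats = glszm_features(roi)
        # zones: one background zone (25 voxels) + two single-voxel zones
        assert feats["glszm_zone_percentage"] == pytest.approx(3.0 / 27.0)

    def test_gldm_alpha0_dependence_counts(self):
        """Dependence of a constant volume: interior voxel has 26 dependent
        neighbours -> dependence size 27."""
        roi = toy_roi(np.zeros((5, 5, 5)))
        feats = gldm_features(roi)
        assert feats["gldm_large_dependence_emphasis"] <= 27.0**2
        # hand check small dependence on a 2x2x2 volume: everyone has 7
        roi2 = toy_roi(np.zeros((2, 2, 2)))
        f2 = gldm_features(roi2)
        assert f2["gldm_large_dependence_emphasis"] == pytest.approx(64.0)
        assert f2["gldm_small_dependence_emphasis"] == pytest.approx(1.0 / 64.0)

    def test_ngtdm_constant_volume_capped_coarseness(self):
        roi = toy_roi(np.zeros((4, 4, 4)))
        feats = ngtdm_features(roi)
        assert feats["ngtdm_coarseness"] == 1e6  # divergent -> capped sentinel
        assert feats["ngtdm_contrast"] == 0.0

    def test_family_sizes(self):
        roi = toy_roi(rng.integers(0, 6, size=(5, 5, 5)).astype(float))
        out = higher_order_features(roi)
        assert sum(k.startswith("glrlm_") for k in out) == 16
        assert sum(k.startswith("glszm_") for k in out) == 16
        assert sum(k.startswith("gldm_") for k in out) == 14
        assert sum(k.startswith("ngtdm_") for k in out) == 5


class TestShape:
    def test_digital_ball_sphericity(self):
        z, y, x = np.indices((25, 25, 25))
        r = 10.0
        mask = (x - 12) ** 2 + (y - 12) ** 2 + (z - 12) ** 2 <= r**2
        feats = shape_features(mask, (1.0, 1.0, 1.0))
        assert feats["shape_sphericity"] == pytest.approx(1.0, rel=0.03)
        assert feats["shape_mesh_volume"] == pytest.approx(
            4 / 3 * np.pi * r**3, rel=0.05)

    def test_cube_closed_form(self):
        # the pre-mesh smoothing erodes sharp corners, so the cube carries a
        # wider digitization tolerance than the ball
        mask = np.zeros((14, 14, 14), bool)
        mask[2:12, 2:12, 2:12] = True
        feats = shape_features(mask, (1.0, 1.0, 1.0))
        assert feats["shape_mesh_volume"] == pytest.approx(1000.0, rel=0.08)
        assert feats["shape_surface_area"] == pytest.approx(600.0, rel=0.15)

    def test_ellipsoid_elongation(self):
        """Axis-aligned ellipsoid with diameters 40/20/20 -> elongation 0.5."""
        z, y, x = np.indices((30, 30, 50))
        mask = (((x - 25) / 20.0) ** 2 + ((y - 15) / 10.0) ** 2
                + ((z - 15) / 10.0) ** 2) <= 1.0
        feats = shape_features(mask, (1.0, 1.0, 1.0))
        assert feats["shape_elongation"] == pytest.approx(0.5, rel=0.05)
        assert feats["shape_flatness"] == pytest.approx(0.5, rel=0.05)
        assert feats["shape_max_3d_diameter"] == pytest.approx(40.0, rel=0.08)

    def test_single_voxel_degenerate(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        feats = shape_features(mask, (1.0, 1.0, 1.0))
        assert feats["shape_major_axis_length"] == 0.0
        assert np.isfinite(list(feats.values())).all()


class TestExtractVolumeFeatures:
    def test_lengths_and_determinism(self, phantom):
        from vmatqa.dicomrt import (
            rasterize_structure, read_ct_series, read_rtdose,
            resample_dose_to_ct)

        ct = read_ct_series(phantom["ct_dir"])
        dose = resample_dose_to_ct(read_rtdose(phantom["rtdose"]), ct)
        mask = rasterize_structure(phantom["rtstruct"], ct, "PTV")
        r1, d1 = extract_volume_features(ct, dose, mask)
        r2, d2 = extract_volume_features(ct, dose, mask)
        assert len(r1) == 107 and len(d1) == 93
        assert r1 == r2 and d1 == d2
        assert np.isfinite(list(r1.values())).all()
        assert np.isfinite(list(d1.values())).all()

    def test_modality_symmetry_on_identical_arrays(self):
        """Non-shape features agree when CT and dose carry identical values
        (same bin width, no cavity filter triggered)."""
        vals = rng.uniform(10, 400, size=(8, 8, 8))
        ct = CTVolume(voxels=vals, spacing=(1, 1, 1), origin=(0, 0, 0))
        dose = DoseVolume(voxels=vals, spacing=(1, 1, 1), origin=(0, 0, 0))
        m = np.zeros(vals.shape, bool)
        m[2:6, 2:6, 2:6] = True
        mask = StructureMask("PTV", m)
        r, d = extract_volume_features(ct, dose, mask)
        for k, v in d.items():
            assert r[k] == pytest.approx(v, rel=1e-12), k

    def test_pad_to_123(self, phantom):
        from vmatqa.dicomrt import (
            rasterize_structure, read_ct_series, read_rtdose,
            resample_dose_to_ct)

        ct = read_ct_series(phantom["ct_dir"])
        dose = resample_dose_to_ct(read_rtdose(phantom["rtdose"]), ct)
        mask = rasterize_structure(phantom["rtstruct"], ct, "PTV")
        r, d = extract_volume_features(ct, dose, mask, pad_to_123=True)
        assert len(r) == 123 and len(d) == 123

    def test_cavity_reduces_radiomic_mask(self, phantom_cavity):
        from vmatqa.dicomrt import rasterize_structure, read_ct_series

        ct = read_ct_series(phantom_cavity["ct_dir"])
        mask = rasterize_structure(phantom_cavity["rtstruct"], ct, "PTV")
        roi = preprocess_ptv(ct, mask, "radiomic")
        cfg = phantom_cavity["config"]
        cavity_vox = (4 / 3 * np.pi * cfg.cavity_radius_mm**3
                      / np.prod(cfg.spacing))
        removed = mask.mask.sum() - roi.mask.sum()
        assert removed == pytest.approx(cavity_vox, rel=0.25)


class TestInvariantProperties:
    def test_matrices_normalize_and_symmetrize(self):
        vals = rng.integers(0, 6, size=(5, 5, 5)).astype(float)
        roi = toy_roi(vals)
        for off in DIRECTIONS[::5]:
            P = _glcm_matrix(roi.levels, roi.mask, roi.Ng, off)
            np.testing.assert_array_equal(P, P.T)

    def test_bin_width_shift_invariance(self):
        """Shifting intensities by an exact bin-width multiple leaves every
        discretized feature unchanged."""
        vals = rng.uniform(0, 200, size=(5, 5, 5))
        r1 = toy_roi(vals, bin_width=25.0)
        r2 = toy_roi(vals + 75.0, bin_width=25.0)
        f1, f2 = glcm_features(r1), glcm_features(r2)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], abs=1e-9), k

    def test_rotation_invariance_of_direction_averaged_features(self):
        vals = rng.integers(0, 5, size=(6, 6, 6)).astype(float)
        rot = np.rot90(vals, k=1, axes=(1, 2))
        f1 = glcm_features(toy_roi(vals))
        f2 = glcm_features(toy_roi(rot))
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], abs=1e-9), k
        g1 = glrlm_features(toy_roi(vals))
        g2 = glrlm_features(toy_roi(rot))
        for k in g1:
            assert g1[k] == pytest.approx(g2[k], abs=1e-9), k
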