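"""Radiomic (CT) and dosimetric (dose) texture features inside the PTV.

Implements the standard 3-D feature families on unfiltered images: shape (14,
CT only), first-order statistics (18), GLCM (24), GLDM (14), GLRLM (16),
GLSZM (16) and NGTDM (5).  Radiomic vectors have 107 entries, dosimetric 93
(no shape family).

Preprocessing follows fixed-bin-width discretization (25 HU for CT, 25 cGy
for dose), a tight bounding box around the PTV with a 10-voxel buffer, and —
for CT only — exclusion of cavity voxels below -200 HU from the mask.
Texture matrices are accumulated over the 13 unique distance-1 direction
offsets, symmetrized where applicable, and features are averaged over
directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage import measure

from .dicomrt import CTVolume, DoseVolume, StructureMask

HU_CAVITY_THRESHOLD = -200.0
BIN_WIDTH_HU = 25.0
BIN_WIDTH_CGY = 25.0
BBOX_BUFFER = 10
NGTDM_COARSENESS_CAP = 1e6
MESH_SMOOTHING_SIGMA = 0.8  # voxels; see shape_features

#: 13 unique 3-D direction offsets at distance 1 (half of the 26-neighborhood)
DIRECTIONS = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]
assert len(DIRECTIONS) == 13

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


class EmptyROIError(ValueError):
    pass


@dataclass
class DiscretizedROI:
    """Cropped, discretized ROI: gray levels 1..Ng inside the mask, 0 outside."""

    levels: np.ndarray       # int array, 0 = background sentinel
    raw: np.ndarray          # cropped raw intensities (same shape)
    mask: np.ndarray         # bool, same shape
    bin_width: float
    Ng: int
    spacing: tuple[float, float, float]  # (x, y, z) mm


def preprocess_ptv(
    volume: CTVolume | DoseVolume,
    mask: StructureMask,
    modality: str,
) -> DiscretizedROI:
    """Crop to the PTV bounding box (+10-voxel buffer) and discretize.

    For ``modality='radiomic'`` voxels below -200 HU (air cavities) are
    removed from the mask before discretization.
    """
    if modality not in ("radiomic", "dosimetric"):
        raise ValueError(f"unknown modality {modality!r}")
    m = mask.mask.copy()
    vox = volume.voxels
    if m.shape != vox.shape:
        raise ValueError("mask and volume shapes differ")
    if modality == "radiomic":
        m &= vox >= HU_CAVITY_THRESHOLD
        if not m.any():
            raise EmptyROIError("PTV entirely below the -200 HU cavity threshold")
    bw = BIN_WIDTH_HU if modality == "radiomic" else BIN_WIDTH_CGY

    idx = np.nonzero(m)
    lo = [max(int(i.min()) - BBOX_BUFFER, 0) for i in idx]
    hi = [min(int(i.max()) + BBOX_BUFFER + 1, s) for i, s in zip(idx, m.shape)]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    raw = vox[sl].astype(float)
    mc = m[sl]

    inside = raw[mc]
    levels = np.zeros(raw.shape, dtype=np.int64)
    levels[mc] = np.floor((raw[mc] - inside.min()) / bw).astype(np.int64) + 1
    return DiscretizedROI(
        levels=levels, raw=raw, mask=mc, bin_width=bw,
        Ng=int(levels.max()), spacing=tuple(volume.spacing),
    )


# --------------------------------------------------------------------------
# shape (14)
# --------------------------------------------------------------------------

def shape_features(mask: StructureMask | np.ndarray,
                   spacing: tuple[float, float, float]) -> dict[str, float]:
    """14 mesh- and PCA-based 3-D shape descriptors of the ROI."""
    m = mask.mask if isinstance(mask, StructureMask) else np.asarray(mask, bool)
    sx, sy, sz = spacing
    # mesh the Gaussian-smoothed occupancy field: a binary marching-cubes
    # surface overestimates curved areas by ~10% (staircase bevels), and PTVs
    # are predominantly round; sigma in voxel units, iso-level 0.5
    field = ndimage.gaussian_filter(np.pad(m.astype(float), 2), MESH_SMOOTHING_SIGMA)
    if field.max() <= 0.5:  # tiny masks: fall back to the raw occupancy
        field = np.pad(m.astype(float), 2)
    verts, faces, _, _ = measure.marching_cubes(
        field, level=0.5, spacing=(sz, sy, sx)
    )
    area = float(measure.mesh_surface_area(verts, faces))
    # mesh volume via divergence theorem
    tri = verts[faces]
    vol = float(abs(np.einsum("ij,ij->i", tri[:, 0],
                              np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)
    if vol <= 0:
        vol = float(m.sum()) * sx * sy * sz

    sphericity = np.pi ** (1 / 3) * (6.0 * vol) ** (2 / 3) / area
    r_equiv = (3.0 * vol / (4.0 * np.pi)) ** (1 / 3)
    disproportion = area / (4.0 * np.pi * r_equiv**2)

    zz, yy, xx = np.nonzero(m)
    pts = np.column_stack([xx * sx, yy * sy, zz * sz]).astype(float)
    single = len(pts) < 4
    if single:
        major = minor = least = elong = flat = 0.0
        max3d = max_ax = max_co = max_sa = 0.0
    else:
        cov = np.cov(pts.T)
        lam = np.sort(np.linalg.eigvalsh(cov))[::-1]
        lam = np.clip(lam, 0.0, None)
        major, minor, least = (4.0 * np.sqrt(lam)).tolist()
        elong = float(np.sqrt(lam[1] / lam[0])) if lam[0] > 0 else 0.0
        flat = float(np.sqrt(lam[2] / lam[0])) if lam[0] > 0 else 0.0

        surf = m & ~ndimage.binary_erosion(m)
        zz, yy, xx = np.nonzero(surf)
        sp = np.column_stack([xx * sx, yy * sy, zz * sz]).astype(float)
        try:
            hull = sp[ConvexHull(sp).vertices]
        except Exception:  # degenerate (flat) point sets
            hull = sp
        d = hull[:, None, :] - hull[None, :, :]
        max3d = float(np.sqrt((d**2).sum(-1)).max())

        def max2d(points, plane_axis, keep):
            best = 0.0
            for v in np.unique(points[:, plane_axis]):
                q = points[points[:, plane_axis] == v][:, keep]
                if len(q) > 1:
                    dd = q[:, None, :] - q[None, :, :]
                    best = max(best, float(np.sqrt((dd**2).sum(-1)).max()))
            return best

        # columns of sp are (x, y, z)
        max_ax = max2d(sp, 2, [0, 1])  # axial: per z, in (x, y)
        max_co = max2d(sp, 1, [0, 2])  # coronal: per y, in (x, z)
        max_sa = max2d(sp, 0, [1, 2])  # sagittal: per x, in (y, z)

    return {
        "shape_mesh_volume": vol,
        "shape_surface_area": area,
        "shape_surface_volume_ratio": area / vol,
        "shape_sphericity": float(sphericity),
        "shape_spherical_disproportion": float(disproportion),
        "shape_max_3d_diameter": max3d,
        "shape_max_2d_diameter_axial": max_ax,
        "shape_max_2d_diameter_coronal": max_co,
        "shape_max_2d_diameter_sagittal": max_sa,
        "shape_major_axis_length": major,
        "shape_minor_axis_length": minor,
        "shape_least_axis_length": least,
        "shape_elongation": elong,
        "shape_flatness": flat,
    }


# --------------------------------------------------------------------------
# first order (18)
# --------------------------------------------------------------------------

def first_order_features(roi: DiscretizedROI) -> dict[str, float]:
    """18 first-order statistics; entropy/uniformity on the discretized
    histogram, the rest on raw intensities."""
    x = roi.raw[roi.mask].astype(float)
    n = x.size
    voxel_vol = float(np.prod(roi.spacing))
    levels = roi.levels[roi.mask]
    p = np.bincount(levels, minlength=roi.Ng + 1)[1:] / n
    p_nz = p[p > 0]

    mean = float(x.mean())
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    std = float(x.std())  # population
    centered = x - mean
    skew = float((centered**3).mean() / std**3) if std > 0 else 0.0
    kurt = float((centered**4).mean() / std**4) if std > 0 else 0.0

    return {
        "fo_energy": float((x**2).sum()),
        "fo_total_energy": voxel_vol * float((x**2).sum()),
        "fo_entropy": float(-(p_nz * np.log2(p_nz)).sum()),
        "fo_minimum": float(x.min()),
        "fo_percentile10": float(p10),
        "fo_percentile90": float(p90),
        "fo_maximum": float(x.max()),
        "fo_mean": mean,
        "fo_median": float(p50),
        "fo_interquartile_range": float(p75 - p25),
        "fo_range": float(x.max() - x.min()),
        "fo_mean_absolute_deviation": float(np.abs(centered).mean()),
        "fo_robust_mean_absolute_deviation":
            float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0,
        "fo_root_mean_squared": float(np.sqrt((x**2).mean())),
        "fo_standard_deviation": std,
        "fo_skewness": skew,
        "fo_kurtosis": kurt,
        "fo_uniformity": float((p**2).sum()),
    }


# --------------------------------------------------------------------------
# GLCM (24)
# --------------------------------------------------------------------------

def _glcm_matrix(levels: np.ndarray, mask: np.ndarray, Ng: int,
                 offset: tuple[int, int, int]) -> np.ndarray:
    """Symmetric co-occurrence count matrix for one offset."""
    shp = levels.shape
    sl_a, sl_b = [], []
    for d, s in zip(offset, shp):
        if d >= 0:
            sl_a.append(slice(0, s - d))
            sl_b.append(slice(d, s))
        else:
            sl_a.append(slice(-d, s))
            sl_b.append(slice(0, s + d))
    a = levels[tuple(sl_a)]
    b = levels[tuple(sl_b)]
    valid = mask[tuple(sl_a)] & mask[tuple(sl_b)]
    i, j = a[valid] - 1, b[valid] - 1
    mat = np.zeros((Ng, Ng))
    np.add.at(mat, (i, j), 1.0)
    return mat + mat.T


def _glcm_features_single(P: np.ndarray) -> dict[str, float]:
    Ng = P.shape[0]
    total = P.sum()
    if total == 0:
        return {k: 0.0 for k in GLCM_NAMES}
    p = P / total
    i = np.arange(1, Ng + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = p.sum(1)
    py = p.sum(0)
    ux = float((i * px).sum())
    uy = float((i * py).sum())
    sx = float(np.sqrt(((i - ux) ** 2 * px).sum()))
    sy = float(np.sqrt(((i - uy) ** 2 * py).sum()))

    k_sum = np.arange(2, 2 * Ng + 1)
    p_sum = np.zeros(len(k_sum))
    np.add.at(p_sum, (I + J).ravel() - 2, p.ravel())
    k_diff = np.arange(0, Ng)
    p_diff = np.zeros(Ng)
    np.add.at(p_diff, np.abs(I - J).ravel(), p.ravel())

    eps = np.finfo(float).tiny
    HX = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    HY = float(-(py[py > 0] * np.log2(py[py > 0])).sum())
    HXY = float(-(p[p > 0] * np.log2(p[p > 0])).sum())
    pxy = np.outer(px, py)
    HXY1 = float(-(p * np.log2(pxy + eps)).sum())
    HXY2 = float(-(pxy[pxy > 0] * np.log2(pxy[pxy > 0])).sum())

    da = float((k_diff * p_diff).sum())
    contrast = float(((I - J) ** 2 * p).sum())
    corr = 0.0
    if sx > 0 and sy > 0:
        corr = float(((I * J * p).sum() - ux * uy) / (sx * sy))

    imc1 = 0.0
    if max(HX, HY) > 0:
        imc1 = (HXY - HXY1) / max(HX, HY)
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (HXY2 - HXY)))))

    # MCC: second largest eigenvalue of Q
    mcc = 1.0
    if Ng > 1 and px.min() > 0 and py.min() > 0:
        Q = (p / px[:, None]) @ (p / py[:, None]).T
        ev = np.sort(np.abs(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(0.0, ev[-2]))) if len(ev) > 1 else 1.0

    off_diag = np.abs(I - J) > 0
    inv_var = float((p[off_diag] / (I - J)[off_diag] ** 2).sum())

    return {
        "glcm_autocorrelation": float((I * J * p).sum()),
        "glcm_joint_average": ux,
        "glcm_cluster_prominence": float(((I + J - ux - uy) ** 4 * p).sum()),
        "glcm_cluster_shade": float(((I + J - ux - uy) ** 3 * p).sum()),
        "glcm_cluster_tendency": float(((I + J - ux - uy) ** 2 * p).sum()),
        "glcm_contrast": contrast,
        "glcm_correlation": corr,
        "glcm_difference_average": da,
        "glcm_difference_entropy":
            float(-(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0])).sum()),
        "glcm_difference_variance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "glcm_joint_energy": float((p**2).sum()),
        "glcm_joint_entropy": HXY,
        "glcm_imc1": imc1,
        "glcm_imc2": imc2,
        "glcm_idm": float((p / (1.0 + (I - J) ** 2)).sum()),
        "glcm_idmn": float((p / (1.0 + ((I - J) / Ng) ** 2)).sum()),
        "glcm_id": float((p / (1.0 + np.abs(I - J))).sum()),
        "glcm_idn": float((p / (1.0 + np.abs(I - J) / Ng)).sum()),
        "glcm_inverse_variance": inv_var,
        "glcm_maximum_probability": float(p.max()),
        "glcm_sum_average": float((k_sum * p_sum).sum()),
        "glcm_sum_entropy":
            float(-(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0])).sum()),
        "glcm_sum_squares": float(((I - ux) ** 2 * p).sum()),
        "glcm_mcc": mcc,
    }


GLCM_NAMES = list(_glcm_features_single(np.ones((2, 2))).keys())


def glcm_features(roi: DiscretizedROI) -> dict[str, float]:
    """24 GLCM features averaged over the 13 directions."""
    per_dir = [
        _glcm_features_single(_glcm_matrix(roi.levels, roi.mask, roi.Ng, off))
        for off in DIRECTIONS
    ]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLCM_NAMES}


# --------------------------------------------------------------------------
# GLRLM (16)
# --------------------------------------------------------------------------

def _glrlm_matrix(levels: np.ndarray, mask: np.ndarray, Ng: int,
                  offset: tuple[int, int, int]) -> np.ndarray:
    """Run-length count matrix for one direction (runs of equal gray level)."""
    lv = np.where(mask, levels, 0)
    shp = lv.shape
    max_run = int(np.ceil(np.sqrt(sum(s**2 for s in shp)))) + 1
    P = np.zeros((Ng, max_run))

    dz, dy, dx = offset
    # starting voxels: those with no valid predecessor along the offset
    starts = []
    for z in range(shp[0]):
        for y in range(shp[1]):
            for x in range(shp[2]):
                pz, py_, px_ = z - dz, y - dy, x - dx
                if not (0 <= pz < shp[0] and 0 <= py_ < shp[1] and 0 <= px_ < shp[2]):
                    starts.append((z, y, x))
    for z0, y0, x0 in starts:
        z, y, x = z0, y0, x0
        cur, run = 0, 0
        while 0 <= z < shp[0] and 0 <= y < shp[1] and 0 <= x < shp[2]:
            v = lv[z, y, x]
            if v == cur and v != 0:
                run += 1
            else:
                if cur != 0:
                    P[cur - 1, run - 1] += 1
                cur, run = v, (1 if v != 0 else 0)
            z, y, x = z + dz, y + dy, x + dx
        if cur != 0:
            P[cur - 1, run - 1] += 1
    return P


def _rl_features(P: np.ndarray, Np: int, prefix: str, names: dict[str, str]) -> dict[str, float]:
    """Shared run-length / size-zone feature formulas on a (Ng x Ns) matrix."""
    Nz = P.sum()
    if Nz == 0:
        return {prefix + v: 0.0 for v in names.values()}
    Ng, Ns = P.shape
    i = np.arange(1, Ng + 1)[:, None]
    j = np.arange(1, Ns + 1)[None, :]
    p = P / Nz
    ri = P.sum(1)   # per gray level
    rj = P.sum(0)   # per run length / zone size
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    p_nz = p[p > 0]
    out = {
        "sre": float((P / j**2).sum() / Nz),
        "lre": float((P * j**2).sum() / Nz),
        "gln": float((ri**2).sum() / Nz),
        "glnn": float((ri**2).sum() / Nz**2),
        "rln": float((rj**2).sum() / Nz),
        "rlnn": float((rj**2).sum() / Nz**2),
        "rp": float(Nz / Np),
        "glv": float(((i - mu_i) ** 2 * p).sum()),
        "rv": float(((j - mu_j) ** 2 * p).sum()),
        "re": float(-(p_nz * np.log2(p_nz)).sum()),
        "lgle": float((P / i**2).sum() / Nz),
        "hgle": float((P * i**2).sum() / Nz),
        "srlgle": float((P / (i**2 * j**2)).sum() / Nz),
        "srhgle": float((P * i**2 / j**2).sum() / Nz),
        "lrlgle": float((P * j**2 / i**2).sum() / Nz),
        "lrhgle": float((P * i**2 * j**2).sum() / Nz),
    }
    return {prefix + names[k]: out[k] for k in names}


_GLRLM_NAMES = {
    "sre": "short_run_emphasis", "lre": "long_run_emphasis",
    "gln": "gray_level_nonuniformity", "glnn": "gray_level_nonuniformity_normalized",
    "rln": "run_length_nonuniformity", "rlnn": "run_length_nonuniformity_normalized",
    "rp": "run_percentage", "glv": "gray_level_variance", "rv": "run_variance",
    "re": "run_entropy", "lgle": "low_gray_level_run_emphasis",
    "hgle": "high_gray_level_run_emphasis",
    "srlgle": "short_run_low_gray_level_emphasis",
    "srhgle": "short_run_high_gray_level_emphasis",
    "lrlgle": "long_run_low_gray_level_emphasis",
    "lrhgle": "long_run_high_gray_level_emphasis",
}

_GLSZM_NAMES = {
    "sre": "small_area_emphasis", "lre": "large_area_emphasis",
    "gln": "gray_level_nonuniformity", "glnn": "gray_level_nonuniformity_normalized",
    "rln": "size_zone_nonuniformity", "rlnn": "size_zone_nonuniformity_normalized",
    "rp": "zone_percentage", "glv": "gray_level_variance", "rv": "zone_variance",
    "re": "zone_entropy", "lgle": "low_gray_level_zone_emphasis",
    "hgle": "high_gray_level_zone_emphasis",
    "srlgle": "small_area_low_gray_level_emphasis",
    "srhgle": "small_area_high_gray_level_emphasis",
    "lrlgle": "large_area_low_gray_level_emphasis",
    "lrhgle": "large_area_high_gray_level_emphasis",
}


def glrlm_features(roi: DiscretizedROI) -> dict[str, float]:
    """16 run-length features averaged over the 13 directions."""
    Np = int(roi.mask.sum())
    per_dir = [
        _rl_features(_glrlm_matrix(roi.levels, roi.mask, roi.Ng, off),
                     Np, "glrlm_", _GLRLM_NAMES)
        for off in DIRECTIONS
    ]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


def glszm_features(roi: DiscretizedROI) -> dict[str, float]:
    """16 size-zone features (zones by 26-connectivity)."""
    Np = int(roi.mask.sum())
    zones: list[tuple[int, int]] = []
    for g in range(1, roi.Ng + 1):
        lab, nlab = ndimage.label(roi.levels == g, structure=_STRUCT26)
        if nlab:
            sizes = np.bincount(lab.ravel())[1:]
            zones.extend((g, int(s)) for s in sizes)
    if not zones:
        return {("glszm_" + v): 0.0 for v in _GLSZM_NAMES.values()}
    max_s = max(s for _, s in zones)
    P = np.zeros((roi.Ng, max_s))
    for g, s in zones:
        P[g - 1, s - 1] += 1
    return _rl_features(P, Np, "glszm_", _GLSZM_NAMES)


# --------------------------------------------------------------------------
# GLDM (14)
# --------------------------------------------------------------------------

def _neighbor_stacks(levels: np.ndarray, mask: np.ndarray):
    """For each voxel, iterate (neighbor_level, neighbor_valid) per 26-offset."""
    offs = [
        (dz, dy, dx)
        for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for off in offs:
        shifted = np.zeros_like(levels)
        valid = np.zeros_like(mask)
        src, dst = [], []
        for d, s in zip(off, levels.shape):
            if d >= 0:
                src.append(slice(0, s - d))
                dst.append(slice(d, s))
            else:
                src.append(slice(-d, s))
                dst.append(slice(0, s + d))
        shifted[tuple(dst)] = levels[tuple(src)]
        valid[tuple(dst)] = mask[tuple(src)]
        yield shifted, valid


def gldm_features(roi: DiscretizedROI, alpha: int = 0) -> dict[str, float]:
    """14 gray-level dependence features (26-neighborhood, |diff| <= alpha)."""
    dep = np.zeros(roi.levels.shape, dtype=np.int64)
    for nb, valid in _neighbor_stacks(roi.levels, roi.mask):
        dep += (valid & (np.abs(nb - roi.levels) <= alpha)).astype(np.int64)
    d = dep[roi.mask] + 1  # dependence size includes the center voxel
    g = roi.levels[roi.mask]
    Nd = int(d.max())
    P = np.zeros((roi.Ng, Nd))
    np.add.at(P, (g - 1, d - 1), 1.0)

    Nz = P.sum()
    i = np.arange(1, roi.Ng + 1)[:, None]
    j = np.arange(1, Nd + 1)[None, :]
    p = P / Nz
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    p_nz = p[p > 0]
    return {
        "gldm_small_dependence_emphasis": float((P / j**2).sum() / Nz),
        "gldm_large_dependence_emphasis": float((P * j**2).sum() / Nz),
        "gldm_gray_level_nonuniformity": float((P.sum(1) ** 2).sum() / Nz),
        "gldm_dependence_nonuniformity": float((P.sum(0) ** 2).sum() / Nz),
        "gldm_dependence_nonuniformity_normalized":
            float((P.sum(0) ** 2).sum() / Nz**2),
        "gldm_gray_level_variance": float(((i - mu_i) ** 2 * p).sum()),
        "gldm_dependence_variance": float(((j - mu_j) ** 2 * p).sum()),
        "gldm_dependence_entropy": float(-(p_nz * np.log2(p_nz)).sum()),
        "gldm_low_gray_level_emphasis": float((P / i**2).sum() / Nz),
        "gldm_high_gray_level_emphasis": float((P * i**2).sum() / Nz),
        "gldm_small_dependence_low_gray_level_emphasis":
            float((P / (i**2 * j**2)).sum() / Nz),
        "gldm_small_dependence_high_gray_level_emphasis":
            float((P * i**2 / j**2).sum() / Nz),
        "gldm_large_dependence_low_gray_level_emphasis":
            float((P * j**2 / i**2).sum() / Nz),
        "gldm_large_dependence_high_gray_level_emphasis":
            float((P * i**2 * j**2).sum() / Nz),
    }


# --------------------------------------------------------------------------
# NGTDM (5)
# --------------------------------------------------------------------------

def ngtdm_features(roi: DiscretizedROI) -> dict[str, float]:
    """5 neighborhood gray-tone difference features (26-neighborhood means)."""
    nb_sum = np.zeros(roi.levels.shape, dtype=float)
    nb_cnt = np.zeros(roi.levels.shape, dtype=float)
    for nb, valid in _neighbor_stacks(roi.levels, roi.mask):
        nb_sum += np.where(valid, nb, 0.0)
        nb_cnt += valid
    has_nb = roi.mask & (nb_cnt > 0)
    gi = roi.levels[has_nb].astype(float)
    mean_nb = nb_sum[has_nb] / nb_cnt[has_nb]
    diff = np.abs(gi - mean_nb)

    Ng = roi.Ng
    n = np.zeros(Ng)
    s = np.zeros(Ng)
    np.add.at(n, gi.astype(int) - 1, 1.0)
    np.add.at(s, gi.astype(int) - 1, diff)
    Nvp = n.sum()
    p = n / Nvp
    present = p > 0
    Ngp = int(present.sum())
    lv = np.arange(1, Ng + 1, dtype=float)

    ps_sum = float((p * s).sum())
    coarseness = 1.0 / ps_sum if ps_sum > 0 else NGTDM_COARSENESS_CAP
    coarseness = min(coarseness, NGTDM_COARSENESS_CAP)

    contrast = 0.0
    if Ngp > 1:
        pi, pj = np.meshgrid(p, p, indexing="ij")
        li, lj = np.meshgrid(lv, lv, indexing="ij")
        contrast = float(
            (pi * pj * (li - lj) ** 2).sum() / (Ngp * (Ngp - 1)) * (s.sum() / Nvp)
        )

    busy_den = 0.0
    complexity = 0.0
    strength_num = 0.0
    pi, pj = np.meshgrid(p, p, indexing="ij")
    li, lj = np.meshgrid(lv, lv, indexing="ij")
    both = (pi > 0) & (pj > 0)
    busy_den = float(np.abs(li * pi - lj * pj)[both].sum())
    si, sj = np.meshgrid(s, s, indexing="ij")
    with np.errstate(divide="ignore", invalid="ignore"):
        comp = np.abs(li - lj) / (pi + pj) * (pi * si + pj * sj)
    complexity = float(np.where(both, comp, 0.0).sum() / Nvp)
    strength_num = float(((pi + pj) * (li - lj) ** 2)[both].sum())
    busyness = ps_sum / busy_den if busy_den > 0 else 0.0
    strength = strength_num / s.sum() if s.sum() > 0 else 0.0

    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------

def higher_order_features(roi: DiscretizedROI) -> dict[str, float]:
    """GLRLM (16) + GLSZM (16) + GLDM (14) + NGTDM (5)."""
    out: dict[str, float] = {}
    out.update(glrlm_features(roi))
    out.update(glszm_features(roi))
    out.update(gldm_features(roi))
    out.update(ngtdm_features(roi))
    return out


def extract_volume_features(
    ct: CTVolume,
    dose: DoseVolume,
    mask: StructureMask,
    pad_to_123: bool = False,
) -> tuple[dict[str, float], dict[str, float]]:
    """Radiomic (107) and dosimetric (93) feature vectors for one PTV.

    ``pad_to_123`` appends zero-valued placeholder features so each vector
    has 123 entries (shape compatibility with externally stated matrix
    sizes); off by default.
    """
    roi_r = preprocess_ptv(ct, mask, "radiomic")
    radiomic: dict[str, float] = {}
    radiomic.update(shape_features(StructureMask(mask.name, roi_r.mask), roi_r.spacing))
    radiomic.update(first_order_features(roi_r))
    radiomic.update(glcm_features(roi_r))
    radiomic.update(higher_order_features(roi_r))

    roi_d = preprocess_ptv(dose, mask, "dosimetric")
    dosimetric: dict[str, float] = {}
    dosimetric.update(first_order_features(roi_d))
    dosimetric.update(glcm_features(roi_d))
    dosimetric.update(higher_order_features(roi_d))

    if pad_to_123:
        for vec in (radiomic, dosimetric):
            k = 0
            while len(vec) < 123:
                vec[f"pad_{k:02d}"] = 0.0
                k += 1
    assert len(radiomic) in (107, 123) and len(dosimetric) in (93, 123)
    return radiomic, dosimetric


RADIOMIC_LENGTH = 107
DOSIMETRIC_LENGTH = 93


def feature_dictionary() -> list[dict]:
    """Name / family / modality records for every emitted feature."""
    families = {
        "shape_": "shape", "fo_": "first_order", "glcm_": "glcm",
        "glrlm_": "glrlm", "glszm_": "glszm", "gldm_": "gldm",
        "ngtdm_": "ngtdm",
    }
    sample = DiscretizedROI(
        levels=np.ones((2, 2, 2), dtype=np.int64),
        raw=np.zeros((2, 2, 2)), mask=np.ones((2, 2, 2), bool),
        bin_width=25.0, Ng=1, spacing=(1.0, 1.0, 1.0),
    )
    names = list(shape_features(np.ones((3, 3, 3), bool), (1.0, 1.0, 1.0)))
    names += list(first_order_features(sample))
    names += GLCM_NAMES
    names += list(higher_order_features(sample))
    out = []
    for name in names:
        family = next(v for k, v in families.items() if name.startswith(k))
        modality = "radiomic" if family == "shape" else "radiomic+dosimetric"
        out.append({"name": name, "family": family, "modality": modality})
    assert len(out) == RADIOMIC_LENGTH
    return out
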