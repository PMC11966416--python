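"""Reading and gridding of DICOM-RT inputs: CT series, RTPLAN, RTDOSE, RTSTRUCT.

Internal conventions: arrays are ordered (z, y, x) with 0-based indices and
voxel-center coordinates; DICOM patient coordinates (x, y, z in mm) appear only
at the I/O boundary.  Dose is carried in cGy throughout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pydicom
from matplotlib.path import Path as MplPath
from scipy import ndimage


class DicomParseError(ValueError):
    """Structured parse failure naming the offending object."""


class UnsupportedGeometryError(DicomParseError):
    """Geometry outside the supported model (e.g. non-60-pair MLC)."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class CTVolume:
    """CT image on a regular grid; ``voxels[z, y, x]`` in Hounsfield units."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]  # (x, y, z) mm
    origin: tuple[float, float, float]   # patient coords of voxel (0,0,0) center
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("CTVolume.voxels must be 3-D (z, y, x)")
        if not all(s > 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class DoseVolume:
    """Absorbed dose in cGy on a regular grid, same layout as :class:`CTVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    grid_resolution_mm: float = 2.5

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("DoseVolume.voxels must be 3-D (z, y, x)")
        if np.any(self.voxels < 0):
            raise ValueError("dose must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class StructureMask:
    """Boolean ROI mask congruent with its paired CT grid."""

    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"structure {self.name!r} has no voxels")


@dataclass
class ControlPoint:
    left_bank: np.ndarray    # 60 leaf tips, mm at isocenter plane
    right_bank: np.ndarray
    jaws: tuple[float, float, float, float]  # X1, X2, Y1, Y2 mm
    cumulative_weight: float
    gantry_angle: float = 0.0

    def __post_init__(self) -> None:
        self.left_bank = np.asarray(self.left_bank, dtype=float)
        self.right_bank = np.asarray(self.right_bank, dtype=float)
        if self.left_bank.shape != (60,) or self.right_bank.shape != (60,):
            raise UnsupportedGeometryError("expected 60 leaf pairs per bank")
        x1, x2, y1, y2 = self.jaws
        if x1 > x2 or y1 > y2:
            raise ValueError("jaws must satisfy X1<=X2, Y1<=Y2")


@dataclass
class Beam:
    energy_label: str           # "6MV" | "6MV-FFF"
    machine_id: str
    mlc_model: str
    control_points: list[ControlPoint]
    total_mu: float

    @property
    def n_control_points(self) -> int:
        return len(self.control_points)


@dataclass
class PlanGeometry:
    beams: list[Beam]
    plan_label: str = ""


# Millennium 120: 10 outer 10-mm pairs, 40 central 5-mm pairs, 10 outer 10-mm
# pairs; spans y in [-200, 200] mm at isocenter.
MILLENNIUM120_WIDTHS = np.concatenate(
    [np.full(10, 10.0), np.full(40, 5.0), np.full(10, 10.0)]
)
MILLENNIUM120_BOUNDARIES = np.concatenate([[-200.0], -200.0 + np.cumsum(MILLENNIUM120_WIDTHS)])


# --------------------------------------------------------------------------
# readers
# --------------------------------------------------------------------------

def read_rtplan(path: str | os.PathLike) -> PlanGeometry:
    """Parse an RTPLAN file into per-beam control-point geometry.

    Cumulative meterset weights are normalised to [0, 1]; leaf positions are
    kept in mm at the isocenter plane (RTPLAN native convention).
    """
    ds = pydicom.dcmread(path, force=True)
    if not hasattr(ds, "BeamSequence") or len(ds.BeamSequence) == 0:
        raise DicomParseError(f"{path}: RTPLAN has no BeamSequence")

    beam_mu: dict[int, float] = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            if hasattr(rb, "BeamMeterset"):
                beam_mu[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)

    beams: list[Beam] = []
    for b in ds.BeamSequence:
        name = str(getattr(b, "BeamName", getattr(b, "BeamNumber", "?")))
        n_pairs = None
        for bld in getattr(b, "BeamLimitingDeviceSequence", []):
            if bld.RTBeamLimitingDeviceType in ("MLCX", "MLCY"):
                n_pairs = int(bld.NumberOfLeafJawPairs)
        if n_pairs is None:
            raise DicomParseError(f"beam {name!r}: no MLC in BeamLimitingDeviceSequence")
        if n_pairs != 60:
            raise UnsupportedGeometryError(
                f"beam {name!r}: {n_pairs}-pair MLC unsupported (expected 60)"
            )

        cps_raw = getattr(b, "ControlPointSequence", None)
        if not cps_raw:
            raise DicomParseError(f"beam {name!r}: no ControlPointSequence")

        final_w = float(getattr(b, "FinalCumulativeMetersetWeight", 1.0)) or 1.0
        jaws = (-200.0, 200.0, -200.0, 200.0)
        mlc = None
        energy = "6MV"
        cps: list[ControlPoint] = []
        gantry = 0.0
        for cp in cps_raw:
            if hasattr(cp, "NominalBeamEnergy"):
                e = float(cp.NominalBeamEnergy)
                fff = "FFF" in str(getattr(b, "FluenceModeID", "")).upper()
                energy = f"{e:.0f}MV" + ("-FFF" if fff else "")
            if hasattr(cp, "GantryAngle"):
                gantry = float(cp.GantryAngle)
            for bld in getattr(cp, "BeamLimitingDevicePositionSequence", []):
                kind = bld.RTBeamLimitingDeviceType
                pos = [float(v) for v in bld.LeafJawPositions]
                if kind in ("X", "ASYMX"):
                    jaws = (pos[0], pos[1], jaws[2], jaws[3])
                elif kind in ("Y", "ASYMY"):
                    jaws = (jaws[0], jaws[1], pos[0], pos[1])
                elif kind in ("MLCX", "MLCY"):
                    mlc = np.asarray(pos, dtype=float)
            if mlc is None:
                raise DicomParseError(f"beam {name!r}: control point without MLC positions")
            cps.append(
                ControlPoint(
                    left_bank=mlc[:60],
                    right_bank=mlc[60:],
                    jaws=jaws,
                    cumulative_weight=float(cp.CumulativeMetersetWeight) / final_w,
                    gantry_angle=gantry,
                )
            )
        weights = [c.cumulative_weight for c in cps]
        if any(b2 < a - 1e-9 for a, b2 in zip(weights, weights[1:])):
            raise DicomParseError(f"beam {name!r}: cumulative weights decrease")
        beams.append(
            Beam(
                energy_label=energy,
                machine_id=str(getattr(b, "TreatmentMachineName", "unknown")),
                mlc_model="Millennium120",
                control_points=cps,
                total_mu=beam_mu.get(int(getattr(b, "BeamNumber", 0)), 0.0),
            )
        )
    return PlanGeometry(beams=beams, plan_label=str(getattr(ds, "RTPlanLabel", "")))


def read_ct_series(directory: str | os.PathLike) -> CTVolume:
    """Read a directory of single-frame CT slices into one HU volume.

    Slices are sorted by their projected position along the slice normal and
    the rescale slope/intercept is applied.
    """
    files = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if f.lower().endswith(".dcm")
    )
    if not files:
        raise DicomParseError(f"{directory}: no .dcm files")
    slices = [pydicom.dcmread(f) for f in files]
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))

    zs = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    if len(zs) > 1:
        dz = np.diff(zs)
        if np.ptp(dz) > 1e-3:
            gaps = np.where(np.abs(dz - np.median(dz)) > 1e-3)[0]
            raise DicomParseError(
                f"inconsistent slice spacing; gaps after slice indices {gaps.tolist()}"
            )
        dz0 = float(np.median(dz))
    else:
        dz0 = float(getattr(slices[0], "SliceThickness", 1.0))

    first = slices[0]
    row_sp, col_sp = (float(v) for v in first.PixelSpacing)
    vol = np.stack(
        [
            s.pixel_array * float(getattr(s, "RescaleSlope", 1.0))
            + float(getattr(s, "RescaleIntercept", 0.0))
            for s in slices
        ]
    ).astype(float)
    origin = tuple(float(v) for v in first.ImagePositionPatient)
    return CTVolume(voxels=vol, spacing=(col_sp, row_sp, dz0), origin=origin)


def read_rtdose(path: str | os.PathLike) -> DoseVolume:
    """Read an RTDOSE grid; Gy values are converted to cGy."""
    ds = pydicom.dcmread(path)
    if not hasattr(ds, "DoseGridScaling"):
        raise DicomParseError(f"{path}: RTDOSE missing DoseGridScaling")
    scaling = float(ds.DoseGridScaling)
    arr = ds.pixel_array.astype(float) * scaling
    units = str(getattr(ds, "DoseUnits", "GY")).upper()
    if units == "GY":
        arr = arr * 100.0  # -> cGy
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
    offsets = np.array([float(v) for v in ds.GridFrameOffsetVector])
    dz = float(offsets[1] - offsets[0]) if len(offsets) > 1 else 1.0
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    return DoseVolume(
        voxels=arr, spacing=(col_sp, row_sp, dz), origin=origin,
        grid_resolution_mm=col_sp,
    )


# --------------------------------------------------------------------------
# structure rasterization
# --------------------------------------------------------------------------

def rasterize_structure(
    rtstruct_path: str | os.PathLike, target: CTVolume, roi_name: str
) -> StructureMask:
    """Rasterize a named planar-contour ROI onto the CT grid.

    A voxel belongs to the ROI iff its center lies inside the contour polygon;
    nested contours on one slice combine by the even-odd rule (XOR), so holes
    are carved out.
    """
    ds = pydicom.dcmread(rtstruct_path)
    names = {}
    for roi in getattr(ds, "StructureSetROISequence", []):
        names[int(roi.ROINumber)] = str(roi.ROIName)
    wanted = None
    for num, nm in names.items():
        if nm == roi_name:
            wanted = num
    if wanted is None:
        raise DicomParseError(
            f"ROI {roi_name!r} not found; available: {sorted(names.values())}"
        )

    ox, oy, oz = target.origin
    sx, sy, sz = target.spacing  # (x, y, z)
    nz, ny, nx = target.shape
    # voxel-center coordinate vectors in patient space
    xs = ox + np.arange(nx) * sx
    ys = oy + np.arange(ny) * sy
    gx, gy = np.meshgrid(xs, ys)  # shape (ny, nx)
    pts = np.column_stack([gx.ravel(), gy.ravel()])

    mask = np.zeros(target.shape, dtype=bool)
    any_contour = False
    for rc in getattr(ds, "ROIContourSequence", []):
        if int(rc.ReferencedROINumber) != wanted:
            continue
        for c in getattr(rc, "ContourSequence", []):
            data = np.asarray([float(v) for v in c.ContourData]).reshape(-1, 3)
            any_contour = True
            zc = data[0, 2]
            k = int(round((zc - oz) / sz))
            if k < 0 or k >= nz:
                continue
            # repeat the first vertex: Path(closed=True) consumes the last
            # point as its CLOSEPOLY code
            poly = MplPath(np.vstack([data[:, :2], data[:1, :2]]), closed=True)
            inside = poly.contains_points(pts).reshape(ny, nx)
            mask[k] ^= inside  # even-odd rule across nested contours
    if not any_contour:
        raise DicomParseError(f"ROI {roi_name!r} has no contour data")
    if not mask.any():
        raise DicomParseError(f"ROI {roi_name!r} rasterizes to an empty mask")
    return StructureMask(name=roi_name, mask=mask)


def resample_dose_to_ct(dose: DoseVolume, ct: CTVolume) -> DoseVolume:
    """Trilinearly resample a dose grid onto the CT grid (axis-aligned grids).

    Voxels outside the dose extent get 0.  Raises if the physical extents are
    disjoint.
    """
    same = (
        dose.shape == ct.shape
        and np.allclose(dose.spacing, ct.spacing)
        and np.allclose(dose.origin, ct.origin)
    )
    if same:
        return DoseVolume(
            voxels=dose.voxels.copy(),
            spacing=ct.spacing,
            origin=ct.origin,
            grid_resolution_mm=dose.grid_resolution_mm,
        )

    def extent(vol):
        o = np.asarray(vol.origin)  # (x, y, z)
        sp = np.asarray(vol.spacing)
        n = np.asarray(vol.shape)[::-1]  # (nx, ny, nz) from (nz, ny, nx)
        return o, o + sp * (n - 1)

    (dlo, dhi), (clo, chi) = extent(dose), extent(ct)
    if np.any(dhi < clo) or np.any(dlo > chi):
        raise ValueError("dose and CT extents are disjoint")

    nz, ny, nx = ct.shape
    ox, oy, oz = ct.origin
    sx, sy, sz = ct.spacing
    dox, doy, doz = dose.origin
    dsx, dsy, dsz = dose.spacing
    # fractional dose-grid indices of CT voxel centers, per axis
    iz = (oz + np.arange(nz) * sz - doz) / dsz
    iy = (oy + np.arange(ny) * sy - doy) / dsy
    ix = (ox + np.arange(nx) * sx - dox) / dsx
    Z, Y, X = np.meshgrid(iz, iy, ix, indexing="ij")
    out = ndimage.map_coordinates(
        dose.voxels, [Z, Y, X], order=1, mode="constant", cval=0.0
    )
    out = np.clip(out, 0.0, None)
    return DoseVolume(
        voxels=out, spacing=ct.spacing, origin=ct.origin,
        grid_resolution_mm=dose.grid_resolution_mm,
    )
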