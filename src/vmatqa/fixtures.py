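"""Tiny synthetic DICOM-RT fixtures (test doubles for clinical inputs).

Writes minimal but standards-shaped RTPLAN / CT series / RTDOSE / RTSTRUCT
files: a 1-2 arc VMAT plan with 60-pair MLC and sinusoidally modulated leaf
trajectories, an ellipsoidal soft-tissue PTV phantom (optional air cavity),
and a Gaussian dose blob centered on the PTV.  All geometry is known in
closed form, so extractor outputs can be checked against construction.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .dicomrt import MILLENNIUM120_BOUNDARIES


def _base_dataset(path, sop_class_uid: str, modality: str) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class_uid
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = sop_class_uid
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = modality
    ds.PatientName = "QA^Phantom"
    ds.PatientID = "QA0001"
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    return ds


@dataclass
class RTPlanFixtureConfig:
    n_beams: int = 1
    n_control_points: int = 10
    field_size_mm: float = 100.0     # baseline rectangle (square) side
    modulation_amplitude_mm: float = 0.0  # per-pair sinusoidal leaf modulation
    total_mu: float = 400.0
    energy: str = "6MV"
    machine_id: str = "TB1"
    gantry_arc: float = 180.0
    seed: int = 0


def leaf_trajectories(cfg: RTPlanFixtureConfig) -> tuple[np.ndarray, np.ndarray]:
    """(n_cp, 60) left/right bank trajectories: a baseline rectangle with
    per-pair sinusoidal modulation (amplitude 0 -> static field)."""
    n_cp = cfg.n_control_points
    half = cfg.field_size_mm / 2.0
    centers = 0.5 * (MILLENNIUM120_BOUNDARIES[:-1] + MILLENNIUM120_BOUNDARIES[1:])
    open_pairs = np.abs(centers) <= half
    left = np.full((n_cp, 60), 0.0)
    right = np.full((n_cp, 60), 0.0)
    left[:, open_pairs] = -half
    right[:, open_pairs] = half
    if cfg.modulation_amplitude_mm > 0:
        t = np.linspace(0, 2 * np.pi, n_cp)[:, None]
        phase = np.linspace(0, np.pi, 60)[None, :]
        wig = cfg.modulation_amplitude_mm * np.sin(t + phase)
        left[:, open_pairs] = (-half + np.abs(wig) )[:, open_pairs]
        right[:, open_pairs] = (half - np.abs(
            cfg.modulation_amplitude_mm * np.sin(t + phase + np.pi / 3)))[:, open_pairs]
        right = np.maximum(right, left)  # never cross
    return left, right


def make_rtplan_fixture(path, cfg: RTPlanFixtureConfig | None = None) -> str:
    """Write a synthetic RTPLAN; returns the path."""
    cfg = cfg or RTPlanFixtureConfig()
    ds = _base_dataset(path, "1.2.840.10008.5.1.4.1.1.481.5", "RTPLAN")
    ds.RTPlanLabel = "SYNTH-VMAT"

    half = cfg.field_size_mm / 2.0
    ds.FractionGroupSequence = []
    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.ReferencedBeamSequence = []
    ds.BeamSequence = []
    for b in range(cfg.n_beams):
        beam = Dataset()
        beam.BeamNumber = b + 1
        beam.BeamName = f"Arc{b + 1}"
        beam.TreatmentMachineName = cfg.machine_id
        if cfg.energy.endswith("FFF"):
            beam.FluenceModeID = "FFF"
        bld = Dataset()
        bld.RTBeamLimitingDeviceType = "MLCX"
        bld.NumberOfLeafJawPairs = 60
        bld.LeafPositionBoundaries = [f"{v:.1f}" for v in MILLENNIUM120_BOUNDARIES]
        beam.BeamLimitingDeviceSequence = [bld]
        beam.FinalCumulativeMetersetWeight = 1.0
        beam.NumberOfControlPoints = cfg.n_control_points

        left, right = leaf_trajectories(cfg)
        cps = []
        for k in range(cfg.n_control_points):
            cp = Dataset()
            cp.ControlPointIndex = k
            cp.CumulativeMetersetWeight = k / (cfg.n_control_points - 1)
            cp.GantryAngle = (180.0 - cfg.gantry_arc / 2.0
                              + cfg.gantry_arc * k / (cfg.n_control_points - 1)) % 360
            if k == 0:
                cp.NominalBeamEnergy = float(cfg.energy.split("MV")[0])
            seq = []
            for kind, pos in (
                ("ASYMX", [-half - 5.0, half + 5.0]),
                ("ASYMY", [-half - 5.0, half + 5.0]),
                ("MLCX", list(left[k]) + list(right[k])),
            ):
                d = Dataset()
                d.RTBeamLimitingDeviceType = kind
                d.LeafJawPositions = [f"{v:.2f}" for v in pos]
                seq.append(d)
            cp.BeamLimitingDevicePositionSequence = seq
            cps.append(cp)
        beam.ControlPointSequence = cps
        ds.BeamSequence.append(beam)

        rb = Dataset()
        rb.ReferencedBeamNumber = b + 1
        rb.BeamMeterset = cfg.total_mu
        fg.ReferencedBeamSequence.append(rb)
    ds.FractionGroupSequence.append(fg)
    ds.save_as(str(path), enforce_file_format=True)
    return str(path)


@dataclass
class ImageFixtureConfig:
    shape: tuple[int, int, int] = (20, 48, 48)   # (nz, ny, nx)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)  # (x, y, z) mm
    ptv_axes_mm: tuple[float, float, float] = (30.0, 20.0, 20.0)  # semi-axes x,y,z
    ptv_hu: float = 40.0
    background_hu: float = -20.0
    cavity: bool = False
    cavity_radius_mm: float = 6.0
    cavity_hu: float = -500.0
    dose_peak_cgy: float = 6000.0
    dose_sigma_mm: float = 25.0
    roi_name: str = "PTV"
    seed: int = 0


def _grids(cfg: ImageFixtureConfig):
    nz, ny, nx = cfg.shape
    sx, sy, sz = cfg.spacing
    x = (np.arange(nx) - (nx - 1) / 2) * sx
    y = (np.arange(ny) - (ny - 1) / 2) * sy
    z = (np.arange(nz) - (nz - 1) / 2) * sz
    return np.meshgrid(z, y, x, indexing="ij"), (x, y, z)


def phantom_arrays(cfg: ImageFixtureConfig):
    """(ct_hu, dose_cgy, ptv_mask) ground-truth arrays of the phantom."""
    (Z, Y, X), _ = _grids(cfg)
    ax, ay, az = cfg.ptv_axes_mm
    inside = (X / ax) ** 2 + (Y / ay) ** 2 + (Z / az) ** 2 <= 1.0
    ct = np.full(cfg.shape, cfg.background_hu)
    ct[inside] = cfg.ptv_hu
    if cfg.cavity:
        cav = X**2 + Y**2 + Z**2 <= cfg.cavity_radius_mm**2
        ct[cav & inside] = cfg.cavity_hu
    r2 = X**2 + Y**2 + Z**2
    dose = cfg.dose_peak_cgy * np.exp(-r2 / (2 * cfg.dose_sigma_mm**2))
    return ct, dose, inside


def make_image_fixtures(directory, cfg: ImageFixtureConfig | None = None) -> dict:
    """Write a CT series, RTDOSE and RTSTRUCT for the ellipsoid phantom.

    Returns paths plus the ground-truth arrays used to build the files.
    """
    cfg = cfg or ImageFixtureConfig()
    os.makedirs(directory, exist_ok=True)
    ct, dose, mask = phantom_arrays(cfg)
    nz, ny, nx = cfg.shape
    sx, sy, sz = cfg.spacing
    origin = (-(nx - 1) / 2 * sx, -(ny - 1) / 2 * sy, -(nz - 1) / 2 * sz)

    # ---- CT slices
    ct_dir = os.path.join(directory, "ct")
    os.makedirs(ct_dir, exist_ok=True)
    frame_uid = generate_uid()
    series_uid = generate_uid()
    for k in range(nz):
        ds = _base_dataset(os.path.join(ct_dir, f"ct_{k:03d}.dcm"),
                           "1.2.840.10008.5.1.4.1.1.2", "CT")
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.Rows, ds.Columns = ny, nx
        ds.PixelSpacing = [f"{sy:.3f}", f"{sx:.3f}"]
        ds.SliceThickness = sz
        ds.ImagePositionPatient = [origin[0], origin[1], origin[2] + k * sz]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        stored = np.round(ct[k] + 1024.0).astype(np.uint16)
        ds.PixelData = stored.tobytes()
        ds.save_as(os.path.join(ct_dir, f"ct_{k:03d}.dcm"),
                   enforce_file_format=True)

    # ---- RTDOSE (16-bit scaled)
    dose_path = os.path.join(directory, "rtdose.dcm")
    ds = _base_dataset(dose_path, "1.2.840.10008.5.1.4.1.1.481.2", "RTDOSE")
    ds.FrameOfReferenceUID = frame_uid
    ds.Rows, ds.Columns = ny, nx
    ds.NumberOfFrames = nz
    ds.PixelSpacing = [f"{sy:.3f}", f"{sx:.3f}"]
    ds.ImagePositionPatient = list(origin)
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.GridFrameOffsetVector = [k * sz for k in range(nz)]
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    dose_gy = dose / 100.0
    scaling = dose_gy.max() / 60000.0 if dose_gy.max() > 0 else 1.0
    ds.DoseGridScaling = scaling
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    stored = np.round(dose_gy / scaling).astype(np.uint16)
    ds.PixelData = stored.tobytes()
    ds.save_as(dose_path, enforce_file_format=True)

    # ---- RTSTRUCT: per-slice circle contours of the ellipsoid
    struct_path = os.path.join(directory, "rtstruct.dcm")
    ds = _base_dataset(struct_path, "1.2.840.10008.5.1.4.1.1.481.3", "RTSTRUCT")
    ds.StructureSetLabel = "SYNTH"
    roi = Dataset()
    roi.ROINumber = 1
    roi.ROIName = cfg.roi_name
    roi.ReferencedFrameOfReferenceUID = frame_uid
    ds.StructureSetROISequence = [roi]
    rc = Dataset()
    rc.ReferencedROINumber = 1
    rc.ContourSequence = []
    ax, ay, az = cfg.ptv_axes_mm
    _, (xg, yg, zg) = _grids(cfg)
    for k, z in enumerate(zg):
        f = 1.0 - (z / az) ** 2
        if f <= 0:
            continue
        rx, ry = ax * np.sqrt(f), ay * np.sqrt(f)
        theta = np.linspace(0, 2 * np.pi, 73)[:-1]
        pts = np.column_stack([rx * np.cos(theta), ry * np.sin(theta),
                               np.full_like(theta, z)])
        c = Dataset()
        c.ContourGeometricType = "CLOSED_PLANAR"
        c.NumberOfContourPoints = len(pts)
        c.ContourData = [f"{v:.4f}" for v in pts.ravel()]
        rc.ContourSequence.append(c)
    ds.ROIContourSequence = [rc]
    ds.save_as(struct_path, enforce_file_format=True)

    return {
        "ct_dir": ct_dir, "rtdose": dose_path, "rtstruct": struct_path,
        "ct_array": ct, "dose_array": dose, "mask_array": mask,
        "config": cfg,
    }
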