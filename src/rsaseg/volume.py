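"""Voxel-volume container and I/O: DICOM series and a raw fixture format.

A CBCT scan of an isolated tooth is held as an 8-bit grayscale voxel grid
with physical spacing. Axial slices are the first array axis, so the
per-slice edge rule elsewhere in the package operates within ``volume.intensities[z]``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from .errors import CorruptFixtureError, InputError, UnsupportedFormatError

log = logging.getLogger(__name__)

#: In-plane pixel pitch and axial slice pitch assumed when DICOM metadata is
#: silent: the 0.3 mm isotropic voxel geometry of the target acquisition.
DEFAULT_SPACING_MM = 0.3

_FIXTURE_MAGIC = b"RSAVOL1\n"


@dataclass(frozen=True)
class VoxelVolume:
    """8-bit grayscale voxel grid with physical spacing.

    Parameters
    ----------
    intensities
        ``uint8`` array indexed ``(z, y, x)``: axial slice, row, column.
    pixel_size_mm
        In-plane pixel pitch (isotropic), millimetres.
    slice_spacing_mm
        Distance between consecutive axial slices, millimetres.
    """

    intensities: np.ndarray
    pixel_size_mm: float = DEFAULT_SPACING_MM
    slice_spacing_mm: float = DEFAULT_SPACING_MM

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3:
            raise InputError(f"volume must be 3-D (z, y, x); got shape {arr.shape}")
        if arr.shape[0] < 1 or arr.shape[1] < 3 or arr.shape[2] < 3:
            raise InputError(f"volume needs >=1 slice of >=3x3 pixels; got {arr.shape}")
        if arr.dtype != np.uint8:
            if arr.min() < 0 or arr.max() > 255:
                raise InputError("intensities must lie in [0, 255] (8-bit grayscale)")
            arr = arr.astype(np.uint8)
        if not (self.pixel_size_mm > 0 and self.slice_spacing_mm > 0):
            raise InputError("pixel_size_mm and slice_spacing_mm must be positive")
        object.__setattr__(self, "intensities", arr)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[0]

    def __eq__(self, other) -> bool:
        if not isinstance(other, VoxelVolume):
            return NotImplemented
        return (
            self.intensities.shape == other.intensities.shape
            and bool(np.array_equal(self.intensities, other.intensities))
            and self.pixel_size_mm == other.pixel_size_mm
            and self.slice_spacing_mm == other.slice_spacing_mm
        )


def rescale_to_uint8(pixels: np.ndarray) -> np.ndarray:
    """Min-max map an arbitrary-depth grayscale array onto 0-255.

    Round-half-up after the linear map; a constant image maps to 0.
    """
    arr = np.asarray(pixels, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    scaled = (arr - lo) * (255.0 / (hi - lo))
    return np.floor(scaled + 0.5).clip(0, 255).astype(np.uint8)


def _slice_sort_key(ds) -> float:
    # Spatial position along the scan axis; filename order is unreliable.
    if "ImagePositionPatient" in ds and ds.ImagePositionPatient is not None:
        return float(ds.ImagePositionPatient[2])
    if "SliceLocation" in ds:
        return float(ds.SliceLocation)
    return float(ds.get("InstanceNumber", 0))


def read_dicom_series(directory: str | Path) -> VoxelVolume:
    """Read one single-frame grayscale DICOM series into a :class:`VoxelVolume`.

    Slices are ordered by spatial position along the scan axis, not by
    filename. Volumes stored at more than 8 bits are min-max rescaled to
    0-255. Missing spacing metadata falls back to 0.3 mm with a warning.

    Raises
    ------
    InputError
        Empty directory, or files from more than one series.
    UnsupportedFormatError
        Non-grayscale (colour) pixel data.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(p)
        except Exception:
            continue  # non-DICOM clutter is ignored
        if "PixelData" in ds:
            datasets.append(ds)
    if not datasets:
        raise InputError(f"no DICOM image files found in {directory}")

    uids = {ds.get("SeriesInstanceUID", "") for ds in datasets}
    if len(uids) > 1:
        raise InputError(f"directory mixes {len(uids)} DICOM series; expected one")
    for ds in datasets:
        photometric = str(ds.get("PhotometricInterpretation", "MONOCHROME2"))
        if not photometric.startswith("MONOCHROME") or int(ds.get("SamplesPerPixel", 1)) != 1:
            raise UnsupportedFormatError(f"non-grayscale DICOM ({photometric})")

    datasets.sort(key=_slice_sort_key)
    stack = np.stack([ds.pixel_array for ds in datasets])
    if stack.dtype != np.uint8 or stack.max(initial=0) > 255:
        stack = rescale_to_uint8(stack)

    first = datasets[0]
    if "PixelSpacing" in first:
        pixel_size = float(first.PixelSpacing[0])
    else:
        warnings.warn("PixelSpacing absent; assuming 0.3 mm", stacklevel=2)
        pixel_size = DEFAULT_SPACING_MM

    if len(datasets) >= 2:
        positions = [_slice_sort_key(ds) for ds in datasets]
        spacing = float(np.median(np.diff(positions)))
        slice_spacing = abs(spacing) if spacing != 0 else DEFAULT_SPACING_MM
    elif "SliceThickness" in first:
        slice_spacing = float(first.SliceThickness)
    else:
        warnings.warn("slice spacing metadata absent; assuming 0.3 mm", stacklevel=2)
        slice_spacing = DEFAULT_SPACING_MM

    return VoxelVolume(stack, pixel_size_mm=pixel_size, slice_spacing_mm=slice_spacing)


def write_dicom_series(volume: VoxelVolume, directory: str | Path, shuffle_names: bool = False) -> list[Path]:
    """Write a volume as one single-frame secondary-capture DICOM per slice.

    Intended for phantoms and round-trip tests, not for clinical export.
    With ``shuffle_names`` the file names are deliberately out of slice
    order while the spatial metadata stays correct.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    n = volume.n_slices
    name_order = list(range(n))
    if shuffle_names:
        name_order = name_order[::-1]
    paths = []
    for z in range(n):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "OT"
        ds.PatientName = "PHANTOM"
        ds.PatientID = "PHANTOM"
        ds.InstanceNumber = z + 1
        ds.ImagePositionPatient = [0.0, 0.0, z * volume.slice_spacing_mm]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.SliceThickness = volume.slice_spacing_mm
        ds.PixelSpacing = [volume.pixel_size_mm, volume.pixel_size_mm]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.Rows, ds.Columns = volume.intensities.shape[1:]
        ds.BitsAllocated = 8
        ds.BitsStored = 8
        ds.HighBit = 7
        ds.PixelRepresentation = 0
        ds.PixelData = volume.intensities[z].tobytes()
        path = directory / f"slice_{name_order[z]:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def write_fixture(volume: VoxelVolume, path: str | Path) -> Path:
    """Write the raw-volume fixture format.

    Byte layout: magic ``RSAVOL1\\n``, one ASCII header line
    ``"<nz> <ny> <nx> <pixel_size_mm> <slice_spacing_mm>\\n"``, then
    ``nz*ny*nx`` raw uint8 voxels in C order (z fastest-varying last).
    """
    path = Path(path)
    nz, ny, nx = volume.shape
    header = f"{nz} {ny} {nx} {volume.pixel_size_mm!r} {volume.slice_spacing_mm!r}\n"
    with open(path, "wb") as fh:
        fh.write(_FIXTURE_MAGIC)
        fh.write(header.encode("ascii"))
        fh.write(volume.intensities.tobytes())
    return path


def read_fixture(path: str | Path) -> VoxelVolume:
    """Read the raw-volume fixture format written by :func:`write_fixture`.

    ``read_fixture(write_fixture(v)) == v`` bit-exactly.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(len(_FIXTURE_MAGIC))
        if magic != _FIXTURE_MAGIC:
            raise CorruptFixtureError(f"{path}: bad magic {magic!r}")
        header = fh.readline().decode("ascii", errors="replace").split()
        if len(header) != 5:
            raise CorruptFixtureError(f"{path}: malformed header {header}")
        try:
            nz, ny, nx = (int(tok) for tok in header[:3])
            pixel_size, slice_spacing = float(header[3]), float(header[4])
        except ValueError as exc:
            raise CorruptFixtureError(f"{path}: malformed header {header}") from exc
        payload = fh.read()
    expected = nz * ny * nx
    if len(payload) != expected:
        raise CorruptFixtureError(
            f"{path}: payload is {len(payload)} bytes, header promises {expected}"
        )
    arr = np.frombuffer(payload, dtype=np.uint8).reshape(nz, ny, nx).copy()
    return VoxelVolume(arr, pixel_size_mm=pixel_size, slice_spacing_mm=slice_spacing)
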