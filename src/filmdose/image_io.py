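"""Scanner TIFF and DICOM RT Dose input/output, plus dose-grid resampling.

Geometry convention used throughout the package: 0-based (row, col) pixel
indices; the physical position of pixel (i, j) center is
``origin_mm + (i, j) * pixel_spacing_mm`` with the row axis increasing
downward (flatbed-scanner convention).  All physical lengths are in mm,
all doses in Gy.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pydicom
import tifffile
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from scipy import ndimage

__all__ = [
    "ScannedFilm",
    "DoseMap",
    "read_tiff_film",
    "write_tiff_film",
    "read_rtdose",
    "write_rtdose",
    "resample_to_grid",
]

RTDOSE_SOP_CLASS_UID = "1.2.840.10008.5.1.4.1.1.481.2"


@dataclasses.dataclass
class ScannedFilm:
    """A digitized film: raw integer scanner counts with physical spacing.

    Attributes
    ----------
    pixels : ndarray, shape (rows, cols, 3)
        Unsigned-integer pixel values (PV), channels ordered R, G, B.
    bit_depth : int
        Bits per channel (8 or 16 for flatbed scanners).
    pixel_spacing_mm : (float, float)
        Physical size of one pixel along (row, col), mm.
    orientation_applied : list of str
        Names of the pre-processing transforms already applied
        (e.g. ``["flip_vertical", "rotate_180"]``).
    """

    pixels: np.ndarray
    bit_depth: int
    pixel_spacing_mm: tuple[float, float]
    orientation_applied: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"film must be a (rows, cols, 3) RGB array, got shape {self.pixels.shape}"
            )
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValueError("film pixels must be integer counts")
        sp = tuple(float(s) for s in self.pixel_spacing_mm)
        if len(sp) != 2 or any(s <= 0 for s in sp):
            raise ValueError(f"pixel_spacing_mm must be two positive values, got {sp}")
        self.pixel_spacing_mm = sp
        if self.pixels.min() < 0 or self.pixels.max() > self.max_value:
            raise ValueError(
                f"pixel values outside [0, {self.max_value}] for bit depth {self.bit_depth}"
            )

    @property
    def max_value(self) -> int:
        """Largest representable count, ``2**bit_depth - 1``."""
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def channel(self, which: int | str) -> np.ndarray:
        """Return one channel as a 2-D array; ``which`` is 0/1/2 or 'R'/'G'/'B'."""
        if isinstance(which, str):
            which = "RGB".index(which.upper())
        return self.pixels[:, :, which]


@dataclasses.dataclass
class DoseMap:
    """A 2-D absorbed-dose grid in Gy with physical pixel spacing."""

    dose_gy: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.dose_gy = np.asarray(self.dose_gy, dtype=float)
        if self.dose_gy.ndim != 2 or self.dose_gy.size == 0:
            raise ValueError("dose grid must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.dose_gy)):
            raise ValueError("dose grid contains non-finite values")
        if self.dose_gy.min() < 0:
            raise ValueError("dose grid contains negative dose")
        sp = tuple(float(s) for s in self.pixel_spacing_mm)
        if len(sp) != 2 or any(s <= 0 for s in sp):
            raise ValueError(f"pixel_spacing_mm must be two positive values, got {sp}")
        self.pixel_spacing_mm = sp
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dose_gy.shape

    @property
    def extent_mm(self) -> tuple[float, float]:
        """Physical (height, width) covered by the grid, mm."""
        return (
            self.shape[0] * self.pixel_spacing_mm[0],
            self.shape[1] * self.pixel_spacing_mm[1],
        )


def _resolution_to_dpi(tag_value, unit: int) -> float | None:
    """Convert a TIFF resolution tag (rational or float) + unit to dots/inch."""
    if tag_value is None:
        return None
    if isinstance(tag_value, tuple):
        num, den = tag_value
        if den == 0:
            return None
        value = num / den
    else:
        value = float(tag_value)
    if value <= 1:
        return None  # 0/1 dot-per-unit is a writer default, not a real scan dpi
    if unit == 1:
        return None  # RESUNIT.NONE: aspect ratio only, no physical scale
    if unit == 3:  # resolution per centimeter
        value *= 2.54
    return value


def read_tiff_film(path: str | Path, dpi: float | None = None) -> ScannedFilm:
    """Read an uncompressed RGB scanner TIFF into a :class:`ScannedFilm`.

    Pixel spacing is taken from the TIFF resolution tags
    (``pixel_spacing_mm = 25.4 / dpi``); if the tags are absent the caller
    must supply ``dpi`` explicitly — guessing a default would silently
    corrupt every distance-to-agreement computation downstream.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"TIFF file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        tags = page.tags
        unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else 2
        unit = int(getattr(unit, "value", unit))
        xres = tags["XResolution"].value if "XResolution" in tags else None
        yres = tags["YResolution"].value if "YResolution" in tags else None
    if arr.ndim == 3 and arr.shape[2] > 3:
        arr = arr[:, :, :3]  # drop alpha
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path.name}: not a 3-channel image (shape {arr.shape})")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise ValueError(f"{path.name}: unsupported pixel type {arr.dtype}")
    dpi_row = _resolution_to_dpi(yres, unit)
    dpi_col = _resolution_to_dpi(xres, unit)
    if dpi_row is None or dpi_col is None:
        if dpi is None:
            raise ValueError(
                f"{path.name}: missing XResolution/YResolution tags and no dpi override given"
            )
        dpi_row = dpi_col = float(dpi)
    spacing = (25.4 / dpi_row, 25.4 / dpi_col)
    return ScannedFilm(pixels=arr, bit_depth=depth, pixel_spacing_mm=spacing)


def write_tiff_film(film: ScannedFilm, path: str | Path) -> None:
    """Write a film as an uncompressed RGB TIFF with resolution tags."""
    dpi_row = 25.4 / film.pixel_spacing_mm[0]
    dpi_col = 25.4 / film.pixel_spacing_mm[1]
    tifffile.imwrite(
        str(path),
        film.pixels,
        photometric="rgb",
        resolution=(dpi_col, dpi_row),
        resolutionunit="INCH",
        compression=None,
    )


def read_rtdose(path: str | Path) -> DoseMap:
    """Read a single-frame DICOM RT Dose file into a :class:`DoseMap`.

    Dose is reconstructed as ``stored integers × DoseGridScaling``.  A file
    missing the scaling or spacing tags is rejected with an error naming the
    tag; multi-frame (3-D) dose grids are rejected — this package handles
    planar dose maps only.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"DICOM file not found: {path}")
    ds = pydicom.dcmread(str(path))
    n_frames = int(getattr(ds, "NumberOfFrames", 1))
    if n_frames > 1:
        raise ValueError(f"{path.name}: multi-frame RT Dose not supported (2-D maps only)")
    if "DoseGridScaling" not in ds:
        raise ValueError(f"{path.name}: missing required tag DoseGridScaling")
    if "PixelSpacing" not in ds:
        raise ValueError(f"{path.name}: missing required tag PixelSpacing")
    scaling = float(ds.DoseGridScaling)
    spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    dose = ds.pixel_array.astype(float) * scaling
    if dose.ndim == 3 and dose.shape[0] == 1:
        dose = dose[0]
    origin = (0.0, 0.0)
    if "ImagePositionPatient" in ds:
        ipp = ds.ImagePositionPatient
        origin = (float(ipp[1]), float(ipp[0]))  # (row, col) <- (y, x)
    return DoseMap(dose_gy=dose, pixel_spacing_mm=spacing, origin_mm=origin)


def write_rtdose(dose_map: DoseMap, path: str | Path) -> None:
    """Write a :class:`DoseMap` as a single-frame DICOM RT Dose file.

    Doses are stored as 16-bit unsigned integers with
    ``DoseGridScaling = max_dose / 65535`` (``1e-4`` Gy for an all-zero
    map), so the maximum dose uses the full integer range and the
    per-pixel round-trip error is bounded by half the scaling.
    """
    dose = dose_map.dose_gy  # DoseMap invariants already reject NaN/negative
    max_dose = float(dose.max())
    scaling = max_dose / 65535.0 if max_dose > 0 else 1e-4
    stored = np.round(dose / scaling).astype(np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTDOSE_SOP_CLASS_UID
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = RTDOSE_SOP_CLASS_UID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = dose.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.DoseGridScaling = scaling
    ds.PixelSpacing = [dose_map.pixel_spacing_mm[0], dose_map.pixel_spacing_mm[1]]
    ds.ImagePositionPatient = [dose_map.origin_mm[1], dose_map.origin_mm[0], 0.0]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelData = stored.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def resample_to_grid(dose_map: DoseMap, target_spacing_mm: tuple[float, float]) -> DoseMap:
    """Bilinearly resample a dose map onto a grid with the given spacing.

    The physical extent is preserved to within one target pixel and the
    position of the (0, 0) pixel center is kept fixed.  Values beyond the
    source pixel centers are clamped to the edge value; output dose is
    clipped at zero to absorb interpolation undershoot.
    """
    ts = tuple(float(s) for s in target_spacing_mm)
    if len(ts) != 2 or any(s <= 0 for s in ts):
        raise ValueError(f"target spacing must be two positive values, got {target_spacing_mm}")
    sp = dose_map.pixel_spacing_mm
    if ts == sp:
        return DoseMap(dose_map.dose_gy.copy(), sp, dose_map.origin_mm)
    rows, cols = dose_map.shape
    n_rows = max(1, int(round(rows * sp[0] / ts[0])))
    n_cols = max(1, int(round(cols * sp[1] / ts[1])))
    # target pixel centers in source pixel coordinates
    ri = np.arange(n_rows) * ts[0] / sp[0]
    ci = np.arange(n_cols) * ts[1] / sp[1]
    grid = np.meshgrid(ri, ci, indexing="ij")
    out = ndimage.map_coordinates(dose_map.dose_gy, grid, order=1, mode="nearest")
    return DoseMap(np.clip(out, 0.0, None), ts, dose_map.origin_mm)
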