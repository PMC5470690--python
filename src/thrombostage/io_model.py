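"""Core record types and file readers/writers shared by all pipeline stages.

Conventions: pixel coordinates are 0-based, row-major, origin top-left.
Images are 8-bit RGB rasters; ROI masks are same-shape boolean rasters read
from single-channel PNGs (nonzero = inside). Measurement tables are
comma-separated UTF-8 with a header row. Reports are JSON; fraction values
are serialized as percentages rounded to 2 decimals.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .errors import (
    DimensionError,
    EmptyRoiError,
    FormatError,
    IOFailure,
    ParseError,
    SchemaError,
    ValidationError,
)

DAY_MIN = 1
DAY_MAX = 14
EMEAN_SCALE_KPA = (0.0, 80.0)  # device color-scale range


class Part(str, Enum):
    """The three trisected thrombus parts, measured independently."""

    HEAD = "head"
    BODY = "body"
    TAIL = "tail"


@dataclass(frozen=True, eq=False)
class SectionImage:
    """An 8-bit RGB histology raster.

    ``resolution_um_per_px`` is metadata only and never enters computation
    (the source scanner's pixel size is unknown).
    """

    pixels: np.ndarray
    resolution_um_per_px: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(f"expected H x W x 3 RGB array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError("image must have at least one pixel")
        if px.dtype != np.uint8:
            raise FormatError(f"expected 8-bit channels, got dtype {px.dtype}")
        if self.resolution_um_per_px is not None and self.resolution_um_per_px <= 0:
            raise ValidationError("resolution_um_per_px must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass(frozen=True, eq=False)
class RoiMask:
    """Boolean raster marking the thrombus cross-section (True = inside)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise DimensionError(f"mask must be 2-D, got shape {m.shape}")
        if m.dtype != bool:
            m = m.astype(bool)
        object.__setattr__(self, "mask", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def n_inside(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class ElasticityRecord:
    """One Q-Box elasticity measurement (Emean and its SD are recorded;
    Emin/Emax, if present in a file, are parsed and discarded)."""

    animal_id: str
    day: int
    part: Part
    replicate: int
    emean_kpa: float
    sd_kpa: float

    def __post_init__(self) -> None:
        if not (DAY_MIN <= self.day <= DAY_MAX):
            raise ValidationError(
                f"day {self.day} outside study window [{DAY_MIN}, {DAY_MAX}]"
            )
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")
        lo, hi = EMEAN_SCALE_KPA
        if not (lo <= self.emean_kpa <= hi):
            raise ValidationError(
                f"emean_kpa {self.emean_kpa} outside device scale [{lo}, {hi}]"
            )
        if self.sd_kpa < 0:
            raise ValidationError("sd_kpa must be non-negative")


@dataclass(frozen=True, eq=False)
class ThrombusSection:
    """A section image paired with its ROI mask and provenance keys."""

    animal_id: str
    day: int
    part: Part
    image: SectionImage
    mask: RoiMask

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise DimensionError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}"
            )


@dataclass(frozen=True)
class CompositionRecord:
    """Per-section composition result keyed like an elasticity record.

    ``fractions`` is any object exposing ``rr``/``rp``/``rb`` attributes.
    """

    animal_id: str
    day: int
    part: Part
    fractions: Any


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_CSV_REQUIRED = ("animal_id", "day", "part", "replicate", "emean_kpa", "sd_kpa")


def read_section_image(path: str | Path) -> SectionImage:
    """Read an 8-bit RGB TIFF or PNG section image.

    RGBA alpha is dropped; fully transparent pixels are whited out so the
    classifier treats them as background. Non-RGB modes (grayscale, 16-bit,
    palette) raise :class:`FormatError` naming the offending property.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        # tifffile preserves bit depth (PIL would silently downconvert)
        import tifffile

        try:
            arr = tifffile.imread(path)
        except FileNotFoundError as exc:
            raise IOFailure(f"cannot read image {path}: {exc}") from exc
        except (ValueError, tifffile.TiffFileError) as exc:
            raise IOFailure(f"cannot read image {path}: {exc}") from exc
        if arr.dtype != np.uint8:
            raise FormatError(
                f"{path.name}: bit depth {arr.dtype} not supported; expected uint8"
            )
        if arr.ndim != 3 or arr.shape[2] not in (3, 4):
            raise FormatError(
                f"{path.name}: expected RGB(A) TIFF, got shape {arr.shape}"
            )
        if arr.shape[2] == 4:
            alpha = arr[:, :, 3]
            rgb = arr[:, :, :3].copy()
            rgb[alpha == 0] = 255
        else:
            rgb = arr
        return SectionImage(pixels=rgb, source_id=path.name)

    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            if mode == "RGBA":
                arr = np.asarray(im, dtype=np.uint8)
                alpha = arr[:, :, 3]
                rgb = arr[:, :, :3].copy()
                rgb[alpha == 0] = 255
            elif mode == "RGB":
                rgb = np.asarray(im, dtype=np.uint8)
            else:
                raise FormatError(
                    f"{path.name}: unsupported image mode {mode!r}; "
                    "expected 8-bit RGB (or RGBA)"
                )
    except FileNotFoundError as exc:
        raise IOFailure(f"cannot read image {path}: {exc}") from exc
    except UnidentifiedImageError as exc:
        raise IOFailure(f"cannot read image {path}: not a recognized image") from exc
    return SectionImage(pixels=rgb, source_id=path.name)


def read_roi_mask(path: str | Path, shape: tuple[int, int]) -> RoiMask:
    """Read a single-channel PNG mask; nonzero pixels are inside the ROI."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode not in ("1", "L"):
                raise FormatError(
                    f"{path.name}: mask must be single-channel, got mode {im.mode!r}"
                )
            arr = np.asarray(im)
    except FileNotFoundError as exc:
        raise IOFailure(f"cannot read mask {path}: {exc}") from exc
    except UnidentifiedImageError as exc:
        raise IOFailure(f"cannot read mask {path}: not a recognized image") from exc
    if arr.shape != tuple(shape):
        raise DimensionError(
            f"{path.name}: mask shape {arr.shape} does not match image shape {tuple(shape)}"
        )
    mask = arr != 0
    if not mask.any():
        raise EmptyRoiError(f"{path.name}: mask selects no pixels")
    return RoiMask(mask=mask)


def write_section_image(image: SectionImage, path: str | Path) -> None:
    """Write a section image as PNG or TIFF according to the suffix."""
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            tifffile.imwrite(path, image.pixels, photometric="rgb")
        else:
            Image.fromarray(image.pixels, mode="RGB").save(path)
    except OSError as exc:
        raise IOFailure(f"cannot write image {path}: {exc}") from exc


def write_roi_mask(mask: RoiMask, path: str | Path) -> None:
    path = Path(path)
    try:
        Image.fromarray(mask.mask.astype(np.uint8) * 255, mode="L").save(path)
    except OSError as exc:
        raise IOFailure(f"cannot write mask {path}: {exc}") from exc


def read_elasticity_csv(path: str | Path) -> list[ElasticityRecord]:
    """Parse a measurement CSV into :class:`ElasticityRecord` rows.

    Required columns: animal_id, day, part, replicate, emean_kpa, sd_kpa.
    Extra columns (e.g. emin_kpa/emax_kpa) are ignored. Part names are
    normalized to lower case. Parse errors carry the 1-based file row number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except FileNotFoundError as exc:
        raise IOFailure(f"cannot read CSV {path}: {exc}") from exc
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path.name}: malformed CSV: {exc}") from exc

    missing = [c for c in _CSV_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {', '.join(missing)}")

    records: list[ElasticityRecord] = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # header is row 1
        try:
            day = int(row["day"])
            replicate = int(row["replicate"])
            emean = float(row["emean_kpa"])
            sd = float(row["sd_kpa"])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path.name} row {rownum}: {exc}") from exc
        part_raw = str(row["part"]).strip().lower()
        try:
            part = Part(part_raw)
        except ValueError as exc:
            raise SchemaError(
                f"{path.name} row {rownum}: unknown part {part_raw!r}"
            ) from exc
        try:
            rec = ElasticityRecord(
                animal_id=str(row["animal_id"]).strip(),
                day=day,
                part=part,
                replicate=replicate,
                emean_kpa=emean,
                sd_kpa=sd,
            )
        except ValidationError as exc:
            raise ValidationError(f"{path.name} row {rownum}: {exc}") from exc
        records.append(rec)
    return records


def write_elasticity_csv(records: Iterable[ElasticityRecord], path: str | Path) -> None:
    rows = [
        {
            "animal_id": r.animal_id,
            "day": r.day,
            "part": r.part.value,
            "replicate": r.replicate,
            "emean_kpa": r.emean_kpa,
            "sd_kpa": r.sd_kpa,
        }
        for r in records
    ]
    try:
        pd.DataFrame(rows).to_csv(path, index=False)
    except OSError as exc:
        raise IOFailure(f"cannot write CSV {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# report serialization
# ---------------------------------------------------------------------------


def report_to_dict(report: Any) -> dict:
    """Convert a result record to a plain JSON-ready dict with stable keys."""
    if isinstance(report, dict):
        return report
    to_dict = getattr(report, "to_report_dict", None)
    if to_dict is None:
        raise ValidationError(
            f"object of type {type(report).__name__} is not a serializable report"
        )
    return to_dict()


def write_report(report: Any, path: str | Path) -> None:
    """Serialize a result record to JSON (UTF-8, stable key order)."""
    doc = report_to_dict(report)
    try:
        Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
    except OSError as exc:
        raise IOFailure(f"cannot write report {path}: {exc}") from exc


def read_report(path: str | Path) -> dict:
    try:
        return json.loads(Path(path).read_text(encoding="utf-8"))
    except FileNotFoundError as exc:
        raise IOFailure(f"cannot read report {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON: {exc}") from exc


def round2(x: float) -> float:
    """Reporting precision for percents and kPa (2 decimals)."""
    if not math.isfinite(x):
        raise ValidationError(f"non-finite value {x!r} in report")
    return round(x, 2)
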