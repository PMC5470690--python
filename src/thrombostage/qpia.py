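"""Pixel classification of HE-stained sections and composition fractions.

Every in-ROI pixel is either *background* (bright and nearly achromatic:
lumen, slide, tears) or assigned to the nearest of three reference hues --
red (RBC / platelet trabecula), pink (fibrin), blue (nucleus / calcium
deposition) -- by Euclidean distance in RGB. Composition is summarized as
the triple (Rr, Rp, Rb) over in-ROI tissue pixels:

* a red pixel contributes a *mass* ``w(f_red)`` where ``f_red = R/(R+G+B)``
  and ``w`` is a thresholded power law (nonlinear intensity weighting),
* pink and blue pixels contribute mass 1,
* ``Rr = red mass / total mass``, ``Rp = pink mass / total mass`` and
  ``Rb = 1 - Rr - Rp`` (blue is the remainder by definition).

Background and out-of-ROI pixels contribute nothing to either numerator or
denominator: the fractions describe tissue composition, not lumen area.

The weighting exponent ``gamma = 0`` switches weighting off (every tissue
pixel counts 1), which is useful for sensitivity checks and for recovering
planted label-area fractions from synthetic sections.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    CardinalityError,
    DegenerateSectionError,
    EmptyRoiError,
    IncompleteError,
    InvariantError,
    ValidationError,
)
from .io_model import SectionImage, ThrombusSection, round2

# label codes, fixed order (also the nearest-color tie-break order)
RED, PINK, BLUE, BACKGROUND, OUTSIDE_ROI = 0, 1, 2, 3, 4
LABEL_NAMES = {
    RED: "red",
    PINK: "pink",
    BLUE: "blue",
    BACKGROUND: "background",
    OUTSIDE_ROI: "outside_roi",
}

SUM_TOL = 1e-9


@dataclass(frozen=True)
class Palette:
    """Reference hues and background gating thresholds.

    A pixel is background when brightness (max channel) exceeds ``b0`` AND
    saturation ((max-min)/max, 0 when max=0) is below ``s0``.
    """

    red: tuple[int, int, int] = (150, 30, 40)
    pink: tuple[int, int, int] = (230, 160, 180)
    blue: tuple[int, int, int] = (70, 60, 140)
    b0: float = 230.0
    s0: float = 0.12

    def __post_init__(self) -> None:
        refs = (self.red, self.pink, self.blue)
        for c in refs:
            if len(c) != 3 or any(not (0 <= v <= 255) for v in c):
                raise ValidationError(f"palette color {c} outside 8-bit RGB range")
        if len({tuple(c) for c in refs}) != 3:
            raise ValidationError("palette reference colors must be pairwise distinct")
        if not (0 <= self.b0 <= 255):
            raise ValidationError(f"b0 {self.b0} outside [0, 255]")
        if not (0 <= self.s0 <= 1):
            raise ValidationError(f"s0 {self.s0} outside [0, 1]")

    def reference_array(self) -> np.ndarray:
        """(3, 3) float array in class order red < pink < blue."""
        return np.array([self.red, self.pink, self.blue], dtype=float)

    def to_report_dict(self) -> dict:
        return {
            "red": list(self.red),
            "pink": list(self.pink),
            "blue": list(self.blue),
            "b0": self.b0,
            "s0": self.s0,
        }


@dataclass(frozen=True)
class WeightingParams:
    """Thresholded power-law weighting of the red fractional intensity.

    ``w(f) = (max(0, (f - f0) / (1 - f0))) ** gamma`` so that ``w(f0) = 0``
    and ``w(1) = 1``. ``gamma = 0`` disables weighting (w = 1 everywhere).
    """

    f0: float = 1.0 / 3.0  # achromatic red fraction
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if not (0 <= self.f0 < 1):
            raise ValidationError(f"f0 must be in [0, 1), got {self.f0}")
        if self.gamma < 0:
            raise ValidationError(f"gamma must be >= 0, got {self.gamma}")

    def to_report_dict(self) -> dict:
        return {"f0": self.f0, "gamma": self.gamma}


@dataclass(frozen=True, eq=False)
class PixelClassMap:
    """H x W label grid over {red, pink, blue, background, outside_roi}."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValidationError(f"label map must be 2-D, got shape {lab.shape}")
        object.__setattr__(self, "labels", lab.astype(np.uint8))

    def counts(self) -> dict[str, int]:
        binc = np.bincount(self.labels.ravel(), minlength=5)
        return {LABEL_NAMES[k]: int(binc[k]) for k in range(5)}


@dataclass(frozen=True)
class CompositionFractions:
    """Relative (Rr, Rp, Rb) content of one section; sums to 1.

    Rb is defined as the remainder ``1 - Rr - Rp`` and bundles nuclei with
    calcium deposition (the two are not separable by hue).
    """

    rr: float
    rp: float
    rb: float

    def __post_init__(self) -> None:
        for name, v in (("Rr", self.rr), ("Rp", self.rp), ("Rb", self.rb)):
            if not np.isfinite(v) or v < -SUM_TOL or v > 1 + SUM_TOL:
                raise InvariantError(f"{name} = {v} outside [0, 1]")
        if abs((self.rr + self.rp + self.rb) - 1.0) > SUM_TOL:
            raise InvariantError(
                f"fractions sum to {self.rr + self.rp + self.rb}, expected 1"
            )

    @classmethod
    def from_red_pink(cls, rr: float, rp: float) -> "CompositionFractions":
        """Remainder rule: Rb = 1 - Rr - Rp."""
        return cls(rr=rr, rp=rp, rb=1.0 - (rr + rp))

    @classmethod
    def from_percents(cls, rr_pct: float, rp_pct: float) -> "CompositionFractions":
        return cls.from_red_pink(rr_pct / 100.0, rp_pct / 100.0)

    def to_report_dict(self) -> dict:
        return {
            "Rr": round2(self.rr * 100.0),
            "Rp": round2(self.rp * 100.0),
            "Rb": round2(self.rb * 100.0),
        }


def classify_pixels(section: ThrombusSection, palette: Palette | None = None) -> PixelClassMap:
    """Label every pixel of a section.

    In-ROI pixels are gated to background first (brightness > b0 and
    saturation < s0), otherwise assigned the nearest palette reference color
    in RGB; ties break in the fixed order red < pink < blue. Pixels outside
    the ROI get the ``outside_roi`` label and never influence anything.
    """
    palette = palette or Palette()
    mask = section.mask.mask
    if not mask.any():
        raise EmptyRoiError("section mask selects no pixels")

    rgb = section.image.pixels.astype(float)
    mx = rgb.max(axis=2)
    mn = rgb.min(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(mx > 0, (mx - mn) / np.where(mx > 0, mx, 1.0), 0.0)
    is_bg = (mx > palette.b0) & (sat < palette.s0)

    refs = palette.reference_array()  # (3, 3)
    d2 = ((rgb[:, :, None, :] - refs[None, None, :, :]) ** 2).sum(axis=3)
    nearest = d2.argmin(axis=2).astype(np.uint8)  # argmin keeps first on ties

    labels = np.where(is_bg, np.uint8(BACKGROUND), nearest)
    labels = np.where(mask, labels, np.uint8(OUTSIDE_ROI))
    return PixelClassMap(labels=labels)


def red_weight(f_red, params: WeightingParams | None = None):
    """Nonlinear weight of the red fractional intensity; scalar or array.

    Total on [0, 1]: monotone non-decreasing, w(f0) = 0, w(1) = 1.
    gamma = 0 returns 1 everywhere (weighting off).
    """
    params = params or WeightingParams()
    f = np.asarray(f_red, dtype=float)
    if params.gamma == 0:
        w = np.ones_like(f)
    else:
        x = np.clip((f - params.f0) / (1.0 - params.f0), 0.0, None)
        w = x**params.gamma
    return float(w) if np.isscalar(f_red) else w


def compute_fractions(
    labels: PixelClassMap,
    image: SectionImage,
    params: WeightingParams | None = None,
) -> CompositionFractions:
    """Reduce a label map to (Rr, Rp, Rb) over in-ROI tissue pixels."""
    params = params or WeightingParams()
    lab = labels.labels
    if lab.shape != image.shape:
        raise ValidationError(
            f"label map shape {lab.shape} != image shape {image.shape}"
        )

    red_sel = lab == RED
    n_pink = int((lab == PINK).sum())
    n_blue = int((lab == BLUE).sum())

    if red_sel.any():
        rgb = image.pixels.astype(float)
        chan_sum = rgb.sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_red = np.where(chan_sum > 0, rgb[:, :, 0] / np.where(chan_sum > 0, chan_sum, 1.0), 0.0)
        red_mass = float(red_weight(f_red[red_sel], params).sum())
    else:
        red_mass = 0.0

    total = red_mass + n_pink + n_blue
    if total <= 0:
        raise DegenerateSectionError(
            "all in-ROI pixels are background (or red mass is zero): no tissue"
        )
    rr = red_mass / total
    rp = n_pink / total
    return CompositionFractions.from_red_pink(rr, rp)


def quantify_section(
    section: ThrombusSection,
    palette: Palette | None = None,
    params: WeightingParams | None = None,
) -> tuple[CompositionFractions, PixelClassMap]:
    """classify_pixels + compute_fractions in one call."""
    labels = classify_pixels(section, palette)
    return compute_fractions(labels, section.image, params), labels


# ---------------------------------------------------------------------------
# aggregation rules
# ---------------------------------------------------------------------------


def triplicate_mean(values: Sequence[float], strict: bool = True) -> float:
    """Mean of the three replicate Emean values for one measurement point.

    In strict mode any count other than 3 raises; in lenient mode the mean
    of whatever replicates are present is returned (callers log the fallback).
    """
    vals = [float(v) for v in values]
    if len(vals) == 0:
        raise CardinalityError("no replicate values")
    if strict and len(vals) != 3:
        raise CardinalityError(f"expected 3 replicates, got {len(vals)}")
    return statistics.fmean(vals)


def aggregate_whole_elasticity(head: float, body: float, tail: float) -> float:
    """Whole-thrombus Young's modulus: mean of the three parts, 2 decimals."""
    for name, v in (("head", head), ("body", body), ("tail", tail)):
        if v is None or not np.isfinite(v):
            raise IncompleteError(f"missing or non-finite YM value for part {name!r}")
    return round2((head + body + tail) / 3.0)


def aggregate_whole_composition(
    head: CompositionFractions,
    body: CompositionFractions,
    tail: CompositionFractions,
) -> CompositionFractions:
    """Whole-thrombus composition: componentwise mean of the three parts."""
    parts = (head, body, tail)
    for p in parts:
        if abs((p.rr + p.rp + p.rb) - 1.0) > SUM_TOL:
            raise InvariantError(f"input fractions sum to {p.rr + p.rp + p.rb}")
    rr = sum(p.rr for p in parts) / 3.0
    rp = sum(p.rp for p in parts) / 3.0
    return CompositionFractions.from_red_pink(rr, rp)
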