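"""Seeded generators for histology-like sections and staged day-series.

The study's raw images and measurement tables are not deposited, so every
pipeline stage is exercised against synthetic fixtures with planted ground
truth instead:

* sections: a smoothed random field is rank-thresholded inside an
  elliptical ROI so the planted red/pink/blue label areas hit the target
  fractions (remainder = white background), then colored from the default
  palette with optional per-channel Gaussian noise;
* elasticity series: continuous three-segment piecewise-linear rise with a
  slow/fast/medium slope ordering around planted changepoint days, plus
  optionally day-inflating Gaussian noise;
* composition series: Rr declines piecewise-linearly from ~0.95, reverses
  upward at a planted recanalization day, and Rp/Rb absorb the complement
  in a fixed 4:1 split; all three renormalized onto the simplex.

Default endpoints come from the per-part whole-study ranges (head
2.01->13.29, body 3.27->15.91, tail 1.79->10.51, whole 2.36->13.24 kPa);
default changepoints are (4, 6) head, (4, 7) body, (3, 6) tail; default
reversal days are 9 head, 10 tail, 11 body. Day-by-day composition values
between the anchored days are linear interpolations, flagged as such in
the cohort manifest.

Every generator draws from a single ``numpy.random.default_rng(seed)``
stream; identical spec + seed reproduces artifacts bit for bit. Cohorts
derive per-animal seeds as ``seed + animal_index``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import IOFailure, SpecError
from .io_model import (
    ElasticityRecord,
    Part,
    RoiMask,
    SectionImage,
    write_elasticity_csv,
    write_roi_mask,
    write_section_image,
)
from .qpia import (
    BACKGROUND,
    BLUE,
    OUTSIDE_ROI,
    PINK,
    RED,
    CompositionFractions,
    Palette,
    PixelClassMap,
)
from .staging import DailySeries

STUDY_DAYS = tuple(range(1, 15))

# per-part series endpoints (kPa) over the 14-day window
DEFAULT_ENDPOINTS = {
    "head": (2.01, 13.29),
    "body": (3.27, 15.91),
    "tail": (1.79, 10.51),
    "whole": (2.36, 13.24),
}
DEFAULT_CHANGEPOINTS = {
    "head": (4, 6),
    "body": (4, 7),
    "tail": (3, 6),
    "whole": (4, 7),
}
DEFAULT_REVERSAL_DAYS = {"head": 9, "tail": 10, "body": 11}

# slope ordering low / high / medium across the three segments; the
# high/low contrast is strong enough that the planted changepoints survive
# noise at 5% of the total rise (see the staging recovery properties)
_SLOPE_WEIGHTS = (0.15, 3.5, 0.8)

# composition decline slopes (per day) and post-reversal recovery slope
_RR_START = 0.965
_RR_SLOPES = (-0.005, -0.055, -0.085)
_RR_RECOVERY = 0.03
_PINK_SHARE = 0.8  # Rp : Rb split of the non-red complement


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Parameters for one generated section image."""

    height: int = 128
    width: int = 128
    target_fractions: tuple[float, float, float] = (0.6, 0.3, 0.1)
    blob_scale: float = 6.0
    color_noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise SpecError("image dimensions must be positive")
        fr = self.target_fractions
        if len(fr) != 3 or any(f < 0 or f > 1 for f in fr):
            raise SpecError(f"target fractions {fr} must each lie in [0, 1]")
        if sum(fr) > 1 + 1e-12:
            raise SpecError(f"target fractions {fr} sum to {sum(fr)} > 1")
        if sum(fr) <= 0:
            raise SpecError("target fractions must not all be zero")
        if self.blob_scale <= 0:
            raise SpecError("blob_scale must be positive")
        if self.color_noise_sd < 0:
            raise SpecError("color_noise_sd must be non-negative")


@dataclass(frozen=True)
class SyntheticSeriesSpec:
    """Parameters for one generated day-series (elasticity or composition).

    ``start_value``/``end_value`` and ``changepoints`` default per part;
    ``reversal_day`` applies to composition series only (None disables the
    planted recanalization upturn).
    """

    part: str = "head"
    start_value: float | None = None
    end_value: float | None = None
    changepoints: tuple[int, int] | None = None
    noise_sd0: float = 0.0
    noise_growth: float = 0.0
    reversal_day: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.part not in DEFAULT_ENDPOINTS:
            raise SpecError(f"unknown part {self.part!r}")
        if self.noise_sd0 < 0 or self.noise_growth < 0:
            raise SpecError("noise parameters must be non-negative")
        cps = self.resolved_changepoints()
        d1, d2 = cps
        if not (STUDY_DAYS[0] < d1 < d2 < STUDY_DAYS[-1]):
            raise SpecError(f"changepoints {cps} must be interior to the study window")

    def resolved_changepoints(self) -> tuple[int, int]:
        if self.changepoints is not None:
            return tuple(int(d) for d in self.changepoints)  # type: ignore[return-value]
        return DEFAULT_CHANGEPOINTS[self.part]

    def resolved_endpoints(self) -> tuple[float, float]:
        lo, hi = DEFAULT_ENDPOINTS[self.part]
        start = lo if self.start_value is None else float(self.start_value)
        end = hi if self.end_value is None else float(self.end_value)
        return start, end

    def resolved_reversal_day(self) -> int | None:
        if self.reversal_day is not None:
            return int(self.reversal_day)
        return DEFAULT_REVERSAL_DAYS.get(self.part)


# ---------------------------------------------------------------------------
# section images
# ---------------------------------------------------------------------------


def generate_section_image(
    spec: SyntheticImageSpec, palette: Palette | None = None
) -> tuple[SectionImage, RoiMask, PixelClassMap, CompositionFractions]:
    """Generate one section with planted labels and exact achieved fractions.

    Returns (image, mask, ground-truth label map, planted tissue fractions).
    Planted fractions are label-area fractions over tissue (non-background)
    pixels, i.e. what unweighted counting recovers from a noise-free image.
    """
    palette = palette or Palette()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = 0.45 * h, 0.45 * w
    mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0

    field = gaussian_filter(rng.normal(size=(h, w)), sigma=spec.blob_scale)

    labels = np.full((h, w), OUTSIDE_ROI, dtype=np.uint8)
    inside = np.flatnonzero(mask.ravel())
    n = inside.size
    order = inside[np.argsort(field.ravel()[inside], kind="stable")]

    fr, fp, fb = spec.target_fractions
    n_red = int(round(fr * n))
    n_pink = int(round(fp * n))
    n_blue = int(round(fb * n))
    while n_red + n_pink + n_blue > n:  # rounding overshoot
        n_blue = max(0, n_blue - 1) if n_blue else n_blue
        if n_red + n_pink + n_blue > n:
            n_pink = max(0, n_pink - 1)

    flat = labels.ravel()
    flat[order[:n_red]] = RED
    flat[order[n_red : n_red + n_pink]] = PINK
    flat[order[n_red + n_pink : n_red + n_pink + n_blue]] = BLUE
    flat[order[n_red + n_pink + n_blue :]] = BACKGROUND
    labels = flat.reshape(h, w)

    colors = np.full((h, w, 3), 255.0)
    refs = palette.reference_array()
    for code, ref in zip((RED, PINK, BLUE), refs):
        colors[labels == code] = ref
    if spec.color_noise_sd > 0:
        colors = colors + rng.normal(0.0, spec.color_noise_sd, size=colors.shape)
    pixels = np.clip(np.rint(colors), 0, 255).astype(np.uint8)

    n_tissue = n_red + n_pink + n_blue
    planted = CompositionFractions.from_red_pink(n_red / n_tissue, n_pink / n_tissue)
    return (
        SectionImage(pixels=pixels, source_id=f"synthetic-seed{spec.seed}"),
        RoiMask(mask=mask),
        PixelClassMap(labels=labels),
        planted,
    )


# ---------------------------------------------------------------------------
# day-series
# ---------------------------------------------------------------------------


def _piecewise_mean(
    days: np.ndarray, start: float, end: float, cps: tuple[int, int]
) -> np.ndarray:
    """Continuous 3-segment line through (day1, start) .. (day_n, end) with
    slope ratios _SLOPE_WEIGHTS (low, high, medium)."""
    d0, dn = days[0], days[-1]
    c1, c2 = cps
    L = np.array([c1 - d0, c2 - c1, dn - c2], dtype=float)
    wgt = np.array(_SLOPE_WEIGHTS)
    slopes = (end - start) * wgt / float(wgt @ L)
    knots_t = np.array([d0, c1, c2, dn], dtype=float)
    knots_v = start + np.concatenate([[0.0], np.cumsum(slopes * L)])
    return np.interp(days.astype(float), knots_t, knots_v)


def generate_elasticity_series(spec: SyntheticSeriesSpec) -> DailySeries:
    """Planted piecewise-linear Young's-modulus series over days 1-14.

    Noise SD on day d is ``noise_sd0 * (1 + noise_growth * (d - 1))``;
    values are clipped at 0 (the device never reports negative stiffness).
    """
    start, end = spec.resolved_endpoints()
    if end < start:
        raise SpecError(
            f"end_value {end} < start_value {start}: only the stiffening regime "
            "is emulated"
        )
    rng = np.random.default_rng(spec.seed)
    days = np.array(STUDY_DAYS)
    mean = _piecewise_mean(days, start, end, spec.resolved_changepoints())
    if spec.noise_sd0 > 0:
        sd = spec.noise_sd0 * (1.0 + spec.noise_growth * (days - 1))
        mean = mean + rng.normal(0.0, 1.0, size=days.size) * sd
    values = np.clip(mean, 0.0, None)
    return DailySeries(
        part=spec.part,
        quantity="ym_kpa",
        days=tuple(int(d) for d in days),
        values=tuple(float(v) for v in values),
    )


def _composition_means(spec: SyntheticSeriesSpec) -> np.ndarray:
    days = np.array(STUDY_DAYS, dtype=float)
    c1, c2 = spec.resolved_changepoints()
    reversal = spec.resolved_reversal_day()
    if reversal is not None and reversal <= c2:
        raise SpecError(
            f"reversal_day {reversal} must come after the second changepoint {c2}"
        )
    s1, s2, s3 = _RR_SLOPES
    trough_day = days[-1] if reversal is None else reversal - 1
    knots_t = [days[0], c1, c2, trough_day]
    knots_v = [
        _RR_START,
        _RR_START + s1 * (c1 - days[0]),
    ]
    knots_v.append(knots_v[-1] + s2 * (c2 - c1))
    knots_v.append(knots_v[-1] + s3 * (trough_day - c2))
    if reversal is not None and trough_day < days[-1]:
        knots_t.append(days[-1])
        knots_v.append(knots_v[-1] + _RR_RECOVERY * (days[-1] - trough_day))
    rr = np.clip(np.interp(days, knots_t, knots_v), 0.0, 1.0)
    return rr


def generate_composition_series(
    spec: SyntheticSeriesSpec,
) -> tuple[DailySeries, DailySeries, DailySeries]:
    """Planted (Rr, Rp, Rb) series; each day lies exactly on the simplex."""
    rng = np.random.default_rng(spec.seed)
    days = np.array(STUDY_DAYS)
    rr = _composition_means(spec)
    rp = _PINK_SHARE * (1.0 - rr)
    rb = (1.0 - _PINK_SHARE) * (1.0 - rr)
    triple = np.stack([rr, rp, rb], axis=0)
    if spec.noise_sd0 > 0:
        sd = spec.noise_sd0 * (1.0 + spec.noise_growth * (days - 1))
        triple = triple + rng.normal(0.0, 1.0, size=triple.shape) * sd
        triple = np.clip(triple, 0.0, 1.0)
    triple = triple / triple.sum(axis=0, keepdims=True)
    triple[2] = 1.0 - (triple[0] + triple[1])  # exact remainder per day

    out = []
    for q, vals in zip(("rr", "rp", "rb"), triple):
        out.append(
            DailySeries(
                part=spec.part,
                quantity=q,
                days=tuple(int(d) for d in days),
                values=tuple(float(v) for v in vals),
            )
        )
    return tuple(out)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def generate_cohort(
    out_dir: str | Path,
    n_animals: int = 3,
    seed: int = 0,
    noise_sd0: float = 0.0,
    noise_growth: float = 0.0,
    composition_noise_sd: float = 0.0,
    replicate_sd: float = 0.0,
    endpoint_jitter: float = 0.0,
    image_days: tuple[int, ...] = (2, 5, 11),
    image_size: int = 96,
    image_noise_sd: float = 0.0,
) -> dict:
    """Emit a full synthetic cohort: measurement CSV, section images + masks,
    and a manifest JSON recording every planted truth.

    Per animal ``a`` (1-based) all randomness derives from
    ``default_rng(seed + a)``. Three replicate Emean rows are written per
    animal/day/part. Section images are generated for ``image_days`` with
    target fractions read off the planted composition series (scaled by a
    0.9 tissue fill so a white lumen remains). Returns the manifest dict.
    """
    if n_animals < 1:
        raise SpecError("n_animals must be >= 1")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOFailure(f"cannot create output directory {out_dir}: {exc}") from exc

    records: list[ElasticityRecord] = []
    manifest: dict = {
        "seed": seed,
        "n_animals": n_animals,
        "noise": {
            "noise_sd0": noise_sd0,
            "noise_growth": noise_growth,
            "composition_noise_sd": composition_noise_sd,
            "replicate_sd": replicate_sd,
            "endpoint_jitter": endpoint_jitter,
            "image_noise_sd": image_noise_sd,
        },
        "composition_day_values_note": (
            "daily composition values between anchored days are linear "
            "interpolations of the planted piecewise model"
        ),
        "animals": {},
    }

    for a in range(1, n_animals + 1):
        animal_id = f"animal{a:02d}"
        animal_seed = seed + a
        rng = np.random.default_rng(animal_seed)
        animal_entry: dict = {"seed": animal_seed, "parts": {}}

        for part in Part:
            lo, hi = DEFAULT_ENDPOINTS[part.value]
            start = lo * (1.0 + endpoint_jitter * rng.standard_normal())
            end = hi * (1.0 + endpoint_jitter * rng.standard_normal())
            start = float(max(start, 0.1))
            end = float(max(end, start + 1.0))
            cps = DEFAULT_CHANGEPOINTS[part.value]
            reversal = DEFAULT_REVERSAL_DAYS[part.value]

            e_spec = SyntheticSeriesSpec(
                part=part.value,
                start_value=start,
                end_value=end,
                changepoints=cps,
                noise_sd0=noise_sd0,
                noise_growth=noise_growth,
                seed=int(rng.integers(2**31)),
            )
            ym = generate_elasticity_series(e_spec)

            c_spec = SyntheticSeriesSpec(
                part=part.value,
                changepoints=cps,
                noise_sd0=composition_noise_sd,
                reversal_day=reversal,
                seed=int(rng.integers(2**31)),
            )
            rr_s, rp_s, rb_s = generate_composition_series(c_spec)

            for day, value in zip(ym.days, ym.values):
                for rep in (1, 2, 3):
                    emean = value + (
                        replicate_sd * rng.standard_normal() if replicate_sd > 0 else 0.0
                    )
                    emean = float(np.clip(emean, 0.0, 80.0))
                    records.append(
                        ElasticityRecord(
                            animal_id=animal_id,
                            day=int(day),
                            part=part,
                            replicate=rep,
                            emean_kpa=round(emean, 4),
                            sd_kpa=round(0.1 * emean, 4),
                        )
                    )

            images_entry = {}
            for day in image_days:
                i = rr_s.days.index(day)
                target = (
                    0.9 * rr_s.values[i],
                    0.9 * rp_s.values[i],
                    0.9 * rb_s.values[i],
                )
                img_spec = SyntheticImageSpec(
                    height=image_size,
                    width=image_size,
                    target_fractions=target,
                    color_noise_sd=image_noise_sd,
                    seed=int(rng.integers(2**31)),
                )
                image, mask, _, planted = generate_section_image(img_spec)
                stem = f"{animal_id}_day{day:02d}_{part.value}"
                write_section_image(image, out_dir / f"{stem}.png")
                write_roi_mask(mask, out_dir / f"{stem}_mask.png")
                images_entry[str(day)] = {
                    "image": f"{stem}.png",
                    "mask": f"{stem}_mask.png",
                    "target_fractions": [float(t) for t in target],
                    "planted_tissue_fractions": {
                        "rr": planted.rr,
                        "rp": planted.rp,
                        "rb": planted.rb,
                    },
                    "image_seed": img_spec.seed,
                }

            animal_entry["parts"][part.value] = {
                "endpoints_kpa": [start, end],
                "changepoints": list(cps),
                "reversal_day": reversal,
                "ym_series": {str(d): v for d, v in zip(ym.days, ym.values)},
                "composition_series": {
                    str(d): [rr_s.values[i], rp_s.values[i], rb_s.values[i]]
                    for i, d in enumerate(rr_s.days)
                },
                "images": images_entry,
            }
        manifest["animals"][animal_id] = animal_entry

    write_elasticity_csv(records, out_dir / "measurements.csv")
    manifest["measurements_csv"] = "measurements.csv"
    try:
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
        )
    except OSError as exc:
        raise IOFailure(f"cannot write manifest: {exc}") from exc
    return manifest
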