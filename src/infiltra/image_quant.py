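"""Automated digital image analysis: ROI restriction, per-image white
balance, uniform three-class HSV color thresholds, cumulative area
measurement, and area ratios.

Conventions
-----------
Pixel coordinates are 0-based with origin at the top-left; pixel (row, col)
covers the half-open square [col, col+1) x [row, row+1) and is represented by
its center (col + 0.5, row + 0.5). A pixel belongs to an ROI iff its center
lies strictly inside the polygon.

Classification runs in HSV after white balance. Hue windows are given in
degrees [0, 360) and may wrap through 0. A pixel is assigned to at most one
class; on overlapping windows the priority is purple > red > green (a
CD3+CD8+ pixel is also CD3+, but is counted once).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from shapely.geometry import Polygon
from skimage.color import rgb2hsv

from infiltra.errors import (
    ConfigurationError,
    InputError,
    InsufficientContrastError,
    ROIError,
    UndefinedRatioError,
)

#: Mask classes in classification priority order.
PRIORITY = ("purple", "red", "green")

#: Euclidean RGB distance (0-1 scale) below which two references are
#: considered indistinguishable: 10 gray levels out of 255.
CONTRAST_TOLERANCE = 10.0 / 255.0


# ---------------------------------------------------------------------------
# ROI


@dataclass(frozen=True)
class ROIPolygon:
    """Simple polygon in pixel coordinates."""

    vertices: tuple
    closed: bool = True

    def __post_init__(self):
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 3:
            raise ROIError("polygon needs at least 3 vertices")
        poly = Polygon(verts)
        if not poly.is_simple:
            raise ROIError("polygon is self-intersecting")
        if poly.area == 0:
            raise ROIError("polygon has zero area")

    @classmethod
    def rectangle(cls, width: int, height: int) -> "ROIPolygon":
        """Full-image rectangle ROI."""
        return cls(((0, 0), (width, 0), (width, height), (0, height)))

    def as_shapely(self) -> Polygon:
        return Polygon(self.vertices)


def roi_mask(roi: ROIPolygon, shape) -> np.ndarray:
    """Boolean mask of pixels whose centers lie inside the polygon."""
    h, w = shape[:2]
    poly = roi.as_shapely()
    minx, miny, maxx, maxy = poly.bounds
    if minx < -1e-9 or miny < -1e-9 or maxx > w + 1e-9 or maxy > h + 1e-9:
        raise ROIError("ROI extends outside image bounds")
    yy, xx = np.mgrid[0:h, 0:w]
    mask = shapely.contains_xy(poly, xx.ravel() + 0.5, yy.ravel() + 0.5)
    return mask.reshape(h, w)


def apply_roi(image: np.ndarray, roi: ROIPolygon):
    """Zero out pixels outside the ROI.

    Returns (masked image, boolean mask, roi area in pixels).
    """
    mask = roi_mask(roi, image.shape)
    area = int(mask.sum())
    if area == 0:
        raise ROIError("ROI covers no pixel centers")
    out = image.copy()
    out[~mask] = 0
    return out, mask, area


# ---------------------------------------------------------------------------
# White balance


@dataclass(frozen=True)
class WhiteBalanceCalibration:
    """Per-channel affine map ``out = gain * in + offset`` computed from
    user-designated background / foreground / autofluorescence pixel sets."""

    gain: tuple
    offset: tuple
    background_ref: tuple
    foreground_ref: dict
    autofluorescence_ref: tuple | None = None

    def apply(self, image: np.ndarray) -> np.ndarray:
        img = _as_float(image)
        out = img * np.asarray(self.gain) + np.asarray(self.offset)
        return np.clip(out, 0.0, 1.0)


def _as_float(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.dtype == np.uint8:
        return img.astype(np.float64) / 255.0
    return img.astype(np.float64)


def _mean_at(img: np.ndarray, px) -> np.ndarray:
    rows, cols = np.asarray(px, dtype=int).T
    return img[rows, cols].mean(axis=0)


def calibrate_white_balance(
    image: np.ndarray,
    background_px,
    foreground_px: dict,
    autofluorescence_px=None,
    reference: float | None = None,
):
    """Compute a per-channel affine white balance from designated pixel sets.

    Pixel sets are sequences of (row, col) pairs. The map subtracts the mean
    background per channel; when ``reference`` is given, each channel is
    additionally scaled so the brightest class-foreground mean of that channel
    lands at ``reference``. With ``reference=None`` the foreground levels are
    preserved (gain 1), so an already-balanced image maps to itself and a
    uniformly offset image is restored exactly.
    """
    if len(background_px) == 0 or not foreground_px:
        raise InputError("background and foreground pixel sets must be non-empty")
    img = _as_float(image)
    bg = _mean_at(img, background_px)
    fg = {}
    for cls, px in foreground_px.items():
        if len(px) == 0:
            raise InputError(f"empty foreground set for class {cls!r}")
        ref = _mean_at(img, px)
        if float(np.linalg.norm(ref - bg)) < CONTRAST_TOLERANCE:
            raise InsufficientContrastError(
                f"background and {cls} foreground references closer than tolerance"
            )
        fg[cls] = tuple(ref)
    af = None
    if autofluorescence_px is not None and len(autofluorescence_px) > 0:
        af_raw = _mean_at(img, autofluorescence_px)
        af = tuple(np.clip(af_raw - bg, 0.0, 1.0))

    if reference is None:
        gain = np.ones(3)
    else:
        fg_max = np.max(np.asarray(list(fg.values())), axis=0)
        span = fg_max - bg
        gain = np.where(np.abs(span) > 1e-9, reference / np.where(span == 0, 1, span), 1.0)
    offset = -gain * bg
    return WhiteBalanceCalibration(
        gain=tuple(gain),
        offset=tuple(offset),
        background_ref=tuple(bg),
        foreground_ref=fg,
        autofluorescence_ref=af,
    )


# ---------------------------------------------------------------------------
# Thresholds and classification


@dataclass(frozen=True)
class ClassWindow:
    hue_lo: float  # degrees, window may wrap through 0
    hue_hi: float
    min_saturation: float = 0.3
    min_value: float = 0.15


def _window_degrees(w: ClassWindow) -> set:
    lo, hi = w.hue_lo % 360, w.hue_hi % 360
    if lo <= hi:
        return set(range(int(lo), int(hi) + 1))
    return set(range(int(lo), 360)) | set(range(0, int(hi) + 1))


@dataclass(frozen=True)
class ColorThresholds:
    """Uniform per-class HSV thresholds applied identically to every image of
    a batch."""

    green: ClassWindow = field(default_factory=lambda: ClassWindow(80, 160))
    red: ClassWindow = field(default_factory=lambda: ClassWindow(335, 25))
    purple: ClassWindow = field(default_factory=lambda: ClassWindow(250, 310, 0.2))

    def __post_init__(self):
        wins = {c: _window_degrees(getattr(self, c)) for c in PRIORITY}
        names = list(wins)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if wins[a] & wins[b]:
                    raise ConfigurationError(f"hue windows of {a} and {b} overlap")


def _in_window(hue_deg: np.ndarray, w: ClassWindow) -> np.ndarray:
    lo, hi = w.hue_lo % 360, w.hue_hi % 360
    if lo <= hi:
        return (hue_deg >= lo) & (hue_deg <= hi)
    return (hue_deg >= lo) | (hue_deg <= hi)


def classify_pixels(
    image: np.ndarray,
    thresholds: ColorThresholds,
    roi: np.ndarray | None = None,
    autofluorescence_ref=None,
    autofluorescence_tolerance: float = 0.15,
) -> dict:
    """Threshold a (calibrated) RGB image into three disjoint class masks.

    Pixels outside ``roi``, and pixels within the RGB exclusion radius of the
    autofluorescence reference, are voided before classification.
    """
    img = _as_float(image)
    hsv = rgb2hsv(img)
    hue = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    val = hsv[..., 2]

    eligible = np.ones(img.shape[:2], dtype=bool)
    if roi is not None:
        eligible &= roi
    if autofluorescence_ref is not None:
        dist = np.linalg.norm(img - np.asarray(autofluorescence_ref), axis=-1)
        eligible &= dist >= autofluorescence_tolerance

    masks = {}
    taken = np.zeros(img.shape[:2], dtype=bool)
    for cls in PRIORITY:
        w: ClassWindow = getattr(thresholds, cls)
        m = (
            eligible
            & ~taken
            & _in_window(hue, w)
            & (sat >= w.min_saturation)
            & (val >= w.min_value)
        )
        masks[cls] = m
        taken |= m
    return masks


# ---------------------------------------------------------------------------
# Areas and ratios


@dataclass
class AreaQuantResult:
    """Cumulative per-class areas and area ratios for one image (or one
    patient after accumulation)."""

    image_id: str
    green_area: int
    red_area: int
    purple_area: int
    roi_area: int
    cd3_to_cd1a_ratio: float | None = None
    cd8_to_cd1a_ratio: float | None = None


def measure_cumulative_areas(masks: dict, image_id: str = "", roi_area: int | None = None) -> AreaQuantResult:
    """Count set pixels per class mask."""
    shapes = {m.shape for m in masks.values()}
    if len(shapes) != 1:
        raise InputError("class masks differ in shape")
    roi_area = int(roi_area) if roi_area is not None else int(next(iter(shapes))[0] * next(iter(shapes))[1])
    return AreaQuantResult(
        image_id=image_id,
        green_area=int(masks["green"].sum()),
        red_area=int(masks["red"].sum()),
        purple_area=int(masks["purple"].sum()),
        roi_area=roi_area,
    )


def accumulate_areas(results, image_id: str = "patient") -> AreaQuantResult:
    """Sum areas over the multiple images of one patient."""
    results = list(results)
    if not results:
        raise InputError("no results to accumulate")
    return AreaQuantResult(
        image_id=image_id,
        green_area=sum(r.green_area for r in results),
        red_area=sum(r.red_area for r in results),
        purple_area=sum(r.purple_area for r in results),
        roi_area=sum(r.roi_area for r in results),
    )


def compute_area_ratios(result: AreaQuantResult) -> AreaQuantResult:
    """Fill in (red+purple)/green and purple/green area ratios.

    A zero green area is an explicit flag condition, never a silent 0.
    """
    if result.green_area == 0:
        raise UndefinedRatioError(
            f"image {result.image_id!r}: green (CD1a) area is 0; ratios undefined"
        )
    return replace(
        result,
        cd3_to_cd1a_ratio=(result.red_area + result.purple_area) / result.green_area,
        cd8_to_cd1a_ratio=result.purple_area / result.green_area,
    )


def quantify_image(
    image: np.ndarray,
    roi: ROIPolygon | None = None,
    thresholds: ColorThresholds | None = None,
    calibration: WhiteBalanceCalibration | None = None,
    image_id: str = "",
) -> AreaQuantResult:
    """ROI -> white balance -> classify -> areas -> ratios, for one image."""
    thresholds = thresholds or ColorThresholds()
    mask = None
    roi_area = image.shape[0] * image.shape[1]
    if roi is not None:
        image, mask, roi_area = apply_roi(image, roi)
    af_ref = None
    if calibration is not None:
        image = calibration.apply(image)
        af_ref = calibration.autofluorescence_ref
    masks = classify_pixels(image, thresholds, roi=mask, autofluorescence_ref=af_ref)
    result = measure_cumulative_areas(masks, image_id=image_id, roi_area=roi_area)
    return compute_area_ratios(result)
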