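"""Synthetic fluorescence lesion images with exact pixel-level ground truth.

Cells are rendered as non-overlapping opaque disks so that the true pixel
area of each class is exactly the number of rendered pixels, which makes the
downstream area-quantification oracle exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from infiltra.errors import ConfigurationError, PlacementError

#: Stain classes rendered in distinct display colors.
CLASSES = ("CD1a", "CD3CD8neg", "CD3CD8pos")

DEFAULT_COLORS = {
    "CD1a": (0, 255, 0),        # green
    "CD3CD8neg": (255, 0, 0),   # red
    "CD3CD8pos": (160, 32, 240),  # purple
}

#: Amber-ish autofluorescence color, outside every class hue window.
AUTOFLUORESCENCE_COLOR = (255, 200, 100)

#: Minimum gap (pixels) between disk rims so connected components never merge.
_MIN_GAP = 2.0

_MAX_RETRIES = 1000


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Parameters of one synthetic lesion image."""

    width: int = 512
    height: int = 512
    n_cd1a: int = 40
    n_cd3cd8neg: int = 10
    n_cd3cd8pos: int = 5
    cell_radius_range: tuple[float, float] = (4.0, 7.0)
    channel_colors: dict = field(default_factory=lambda: dict(DEFAULT_COLORS))
    background_level: float = 0.03
    autofluorescence_blob_count: int = 0
    bleach_factor: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        counts = (self.n_cd1a, self.n_cd3cd8neg, self.n_cd3cd8pos)
        if any(c < 0 for c in counts):
            raise ConfigurationError("cell counts must be non-negative")
        if not 0.0 < self.bleach_factor <= 1.0:
            raise ConfigurationError("bleach_factor must lie in (0, 1]")
        if not 0.0 <= self.background_level <= 1.0:
            raise ConfigurationError("background_level must lie in [0, 1]")
        rmin, rmax = self.cell_radius_range
        if rmin <= 0 or rmax < rmin:
            raise ConfigurationError("invalid cell_radius_range")
        colors = [tuple(self.channel_colors[c]) for c in CLASSES]
        if len(set(colors)) != len(colors):
            raise ConfigurationError("channel colors must be distinct")

    @property
    def counts(self) -> dict:
        return {
            "CD1a": self.n_cd1a,
            "CD3CD8neg": self.n_cd3cd8neg,
            "CD3CD8pos": self.n_cd3cd8pos,
        }


@dataclass(frozen=True)
class CellRecord:
    x: float
    y: float
    radius: float
    cls: str


@dataclass
class GroundTruthCellMap:
    """Simulated cell positions/classes behind one synthetic image."""

    cells: list[CellRecord]
    true_counts: dict
    true_pixel_area: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.x, c.y, c.radius, c.cls) for c in self.cells],
            columns=["x", "y", "radius", "class"],
        )

    def summary(self) -> dict:
        return {
            "true_counts": dict(self.true_counts),
            "true_pixel_area": {k: int(v) for k, v in self.true_pixel_area.items()},
        }


def _disk_pixels(cx: float, cy: float, r: float, shape) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of pixels whose integer grid point lies inside the disk."""
    h, w = shape
    y0 = max(0, int(math.floor(cy - r)))
    y1 = min(h - 1, int(math.ceil(cy + r)))
    x0 = max(0, int(math.floor(cx - r)))
    x1 = min(w - 1, int(math.ceil(cx + r)))
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    return yy[inside], xx[inside]


def generate_lesion_image(spec: SyntheticImageSpec):
    """Render a synthetic lesion image.

    Returns
    -------
    image : uint8 RGB array of shape (height, width, 3)
    truth : GroundTruthCellMap listing every drawn cell with exact pixel areas

    Raises
    ------
    PlacementError
        If a cell of some class cannot be placed without overlap within the
        retry budget (1000 retries per cell).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    img = np.full((h, w, 3), spec.background_level, dtype=np.float64)

    rmin, rmax = spec.cell_radius_range
    af = np.asarray(AUTOFLUORESCENCE_COLOR, dtype=np.float64) / 255.0
    for _ in range(spec.autofluorescence_blob_count):
        br = rng.uniform(rmax, 2.5 * rmax)
        bx = rng.uniform(br + 1, w - br - 2)
        by = rng.uniform(br + 1, h - br - 2)
        yy, xx = _disk_pixels(bx, by, br, (h, w))
        img[yy, xx] = af * spec.bleach_factor

    placed_x: list[float] = []
    placed_y: list[float] = []
    placed_r: list[float] = []
    cells: list[CellRecord] = []
    area = dict.fromkeys(CLASSES, 0)

    for cls in CLASSES:
        color = np.asarray(spec.channel_colors[cls], dtype=np.float64) / 255.0
        color = color * spec.bleach_factor
        for _ in range(spec.counts[cls]):
            for _attempt in range(_MAX_RETRIES):
                r = rng.uniform(rmin, rmax)
                if 2 * r + 4 >= min(w, h):
                    continue
                cx = rng.uniform(r + 1, w - r - 2)
                cy = rng.uniform(r + 1, h - r - 2)
                if placed_x:
                    dx = np.asarray(placed_x) - cx
                    dy = np.asarray(placed_y) - cy
                    lim = np.asarray(placed_r) + r + _MIN_GAP
                    if np.any(dx * dx + dy * dy <= lim * lim):
                        continue
                break
            else:
                raise PlacementError(
                    f"could not place {cls} cell without overlap "
                    f"after {_MAX_RETRIES} retries"
                )
            placed_x.append(cx)
            placed_y.append(cy)
            placed_r.append(r)
            yy, xx = _disk_pixels(cx, cy, r, (h, w))
            img[yy, xx] = color
            area[cls] += int(yy.size)
            cells.append(CellRecord(x=cx, y=cy, radius=r, cls=cls))

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)

    img = np.clip(img, 0.0, 1.0)
    image = np.round(img * 255.0).astype(np.uint8)
    truth = GroundTruthCellMap(
        cells=cells,
        true_counts={c: sum(1 for rec in cells if rec.cls == c) for c in CLASSES},
        true_pixel_area=area,
    )
    return image, truth


def simulate_counters(
    truth,
    counter_cv: float,
    n_counters: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulate independent human counters with multiplicative lognormal noise.

    Each count is ``round(truth * F)`` with ``F`` lognormal of mean exactly 1
    and coefficient of variation ``counter_cv`` (so counter means are
    unbiased), floored at 0.

    Parameters
    ----------
    truth : GroundTruthCellMap or mapping class -> true count
    """
    if n_counters < 1:
        raise ConfigurationError("n_counters must be >= 1")
    if counter_cv < 0:
        raise ConfigurationError("counter_cv must be >= 0")
    counts = truth.true_counts if isinstance(truth, GroundTruthCellMap) else dict(truth)
    rng = np.random.default_rng(seed)
    rows = []
    if counter_cv > 0:
        sigma = math.sqrt(math.log1p(counter_cv**2))
        mu = -0.5 * sigma**2
    for i in range(n_counters):
        row = {"counter_id": f"C{i + 1}"}
        for cls in CLASSES:
            t = counts.get(cls, 0)
            if counter_cv == 0:
                row[cls] = int(t)
            else:
                f = rng.lognormal(mean=mu, sigma=sigma)
                row[cls] = max(0, int(math.floor(t * f + 0.5)))
        rows.append(row)
    return pd.DataFrame(rows)
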