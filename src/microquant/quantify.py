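"""Point-intensity measurement and positivity classification.

The measurement protocol mirrors manual counting in an image viewer: a
rater samples five (or more) background points per channel, marks each
Iba1-positive cell body at one coordinate, and the analysis reads the
single-pixel grey value (the *point intensity*, PI, 0-255) of every channel
at that coordinate.  A cell is Iba1-positive if its Iba1 PI is at least 20
grey values above the channel background; HLA-DR/MOI positivity uses a
per-marker threshold in the 20-40 range.  Because a single pixel may not
represent the whole cell body, a validation protocol re-samples 10 random
pixels per soma and correlates their mean with the original PI.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Point, Polygon

from .io import MultiChannelImage

logger = logging.getLogger(__name__)

IBA1_THRESHOLD = 20.0
MARKER_THRESHOLD_RANGE = (20.0, 40.0)


@dataclasses.dataclass
class BackgroundEstimate:
    """Mean grey value of >= 5 sampled background pixels in one channel."""

    channel: str
    sample_points: list[tuple[int, int]]
    value: float

    def __post_init__(self) -> None:
        if len(self.sample_points) < 5:
            raise ValueError("a background estimate needs at least 5 points")
        if not 0.0 <= self.value <= 255.0:
            raise ValueError("background grey value must lie in [0, 255]")


def _check_bounds(image: MultiChannelImage, row: int, col: int) -> None:
    h, w = image.shape
    if not (0 <= row < h and 0 <= col < w):
        raise IndexError(f"point (row={row}, col={col}) outside {h}x{w} image")


def measure_point_intensity(
    image: MultiChannelImage, channel: str, row: int, col: int
) -> int:
    """Grey value of the single pixel at (row, col); no interpolation."""
    _check_bounds(image, row, col)
    return int(image.require(channel)[row, col])


def estimate_background(
    image: MultiChannelImage, channel: str, points
) -> BackgroundEstimate:
    """Arithmetic mean of the grey values at >= 5 sampled points."""
    points = [(int(r), int(c)) for r, c in points]
    if len(points) < 5:
        raise ValueError(
            f"background estimation needs at least 5 points, got {len(points)}"
        )
    for r, c in points:
        _check_bounds(image, r, c)
    values = [measure_point_intensity(image, channel, r, c) for r, c in points]
    return BackgroundEstimate(
        channel=channel, sample_points=points, value=float(np.mean(values))
    )


def _bg_value(bg) -> float:
    return bg.value if isinstance(bg, BackgroundEstimate) else float(bg)


def classify_iba1(pi: float, bg, threshold: float = IBA1_THRESHOLD) -> bool:
    """Iba1-positive iff PI >= background + threshold (inclusive)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return pi >= _bg_value(bg) + threshold


def classify_marker(pi: float, bg, threshold: float = 20.0) -> bool:
    """HLA-DR/MOI immunoreactive iff PI >= background + threshold.

    Thresholds outside the documented 20-40 grey-value range are allowed
    but logged as a warning.
    """
    lo, hi = MARKER_THRESHOLD_RANGE
    if not lo <= threshold <= hi:
        warnings.warn(
            f"marker threshold {threshold} outside the documented "
            f"[{lo:g}, {hi:g}] grey-value range",
            stacklevel=2,
        )
    return pi >= _bg_value(bg) + threshold


def measure_cells(
    image: MultiChannelImage,
    cells: pd.DataFrame,
    backgrounds: dict[str, BackgroundEstimate],
    iba1_threshold: float = IBA1_THRESHOLD,
    marker_thresholds: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Measure PIs at every cell coordinate and call positivity.

    Returns a copy of ``cells`` augmented with ``pi_<channel>`` columns and
    ``iba1_positive`` / ``hla_dr_positive`` / ``moi_positive`` booleans.
    """
    marker_thresholds = dict(marker_thresholds or {"hla_dr": 20.0, "moi": 20.0})
    out = cells.copy()
    for ch in ("iba1", "hla_dr", "moi"):
        out[f"pi_{ch}"] = [
            measure_point_intensity(image, ch, r, c)
            for r, c in zip(out["row"], out["col"])
        ]
    out["iba1_positive"] = [
        classify_iba1(pi, backgrounds["iba1"], iba1_threshold)
        for pi in out["pi_iba1"]
    ]
    for marker, thr in marker_thresholds.items():
        out[f"{marker}_positive"] = [
            classify_marker(pi, backgrounds[marker], thr)
            for pi in out[f"pi_{marker}"]
        ]
    return out


def sample_cell_intensities(
    image: MultiChannelImage,
    channel: str,
    row: int,
    col: int,
    n: int = 10,
    soma_radius_px: float = 4.0,
    rng: np.random.Generator | int | None = 0,
) -> np.ndarray:
    """Grey values at ``n`` distinct pixels sampled uniformly within the
    soma disk centered on (row, col); seed-deterministic.

    Pixels outside the image are excluded; fewer than ``n`` in-bounds
    pixels is an error.
    """
    if soma_radius_px <= 0:
        raise ValueError("soma_radius_px must be positive")
    _check_bounds(image, row, col)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    h, w = image.shape
    rad = int(np.ceil(soma_radius_px))
    rr, cc = np.mgrid[row - rad : row + rad + 1, col - rad : col + rad + 1]
    inside = (rr - row) ** 2 + (cc - col) ** 2 <= soma_radius_px**2
    inbounds = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    rr, cc = rr[inside & inbounds], cc[inside & inbounds]
    if len(rr) < n:
        raise ValueError(
            f"only {len(rr)} in-bounds pixels within radius {soma_radius_px} "
            f"of (row={row}, col={col}); cannot sample {n}"
        )
    pick = rng.choice(len(rr), size=n, replace=False)
    return image.require(channel)[rr[pick], cc[pick]].astype(float)


def interpret_correlation(r: float) -> str:
    """Strength band on |r|: weak [0, 0.3], moderate (0.3, 0.8), strong
    [0.8, 1].  Overlapping printed boundaries are assigned to the lower
    band; NaN maps to 'undefined'."""
    if np.isnan(r):
        return "undefined"
    a = abs(r)
    if a > 1.0:
        raise ValueError(f"|r|={a} > 1")
    if a <= 0.3:
        return "weak"
    if a < 0.8:
        return "moderate"
    return "strong"


def validate_point_intensity(
    cells: pd.DataFrame,
    image: MultiChannelImage | dict[str, MultiChannelImage],
    markers=("hla_dr", "moi"),
    n: int = 10,
    soma_radius_px: float = 4.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Correlate each cell's single-pixel PI against the mean of ``n``
    pixels re-sampled within its soma.

    ``image`` may be one image or a mapping ``case_id -> image`` for a
    multi-case cohort.  Returns one row per marker: Pearson r, two-sided
    p, strength band and an ``undefined`` flag set when either variable
    has zero variance.
    """
    if len(cells) < 3:
        raise ValueError("validation needs at least 3 cells")
    images = image if isinstance(image, dict) else None
    rows = []
    for marker in markers:
        rng = np.random.default_rng([seed, hashlib_stable(marker)])
        single, mean10 = [], []
        for _, cell in cells.iterrows():
            img = images[cell["case_id"]] if images else image
            single.append(float(cell[f"pi_{marker}"]))
            mean10.append(
                float(
                    sample_cell_intensities(
                        img, marker, int(cell["row"]), int(cell["col"]),
                        n=n, soma_radius_px=soma_radius_px, rng=rng,
                    ).mean()
                )
            )
        single_a, mean_a = np.asarray(single), np.asarray(mean10)
        undefined = single_a.std() == 0.0 or mean_a.std() == 0.0
        if undefined:
            r, p = float("nan"), float("nan")
        else:
            r, p = stats.pearsonr(single_a, mean_a)
        rows.append(
            {
                "marker": marker,
                "n_cells": len(cells),
                "n_points": n,
                "r": float(r),
                "p": float(p),
                "band": interpret_correlation(r),
                "undefined": bool(undefined),
            }
        )
    return pd.DataFrame(rows)


def hashlib_stable(text: str) -> int:
    """Process-stable small integer from a string (for seed derivation)."""
    import hashlib

    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:4], "big") % 2**31


@dataclasses.dataclass
class RoiPolygon:
    """Simple polygon region of interest in pixel coordinates.

    Containment is half-open: a cell exactly on the boundary counts as
    inside on the top/left edges and outside on the bottom/right edges,
    so tiled ROIs never double-count.
    """

    vertices: np.ndarray  # (N, 2) array of (row, col)
    region: str = "GM"
    um_per_px: float = 1.0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise ValueError("a polygon needs an (N>=3, 2) vertex array")
        self._poly = Polygon([(c, r) for r, c in self.vertices])
        if not self._poly.is_valid:
            raise ValueError("polygon is self-intersecting or degenerate")
        if self._poly.area <= 0:
            raise ValueError("polygon area must be > 0")

    @property
    def area_mm2(self) -> float:
        return self._poly.area * (self.um_per_px / 1000.0) ** 2

    def contains(self, row: float, col: float) -> bool:
        # +eps down-right shift makes top/left boundaries inclusive and
        # bottom/right exclusive under strict containment
        eps = 1e-7
        return self._poly.contains(Point(col + eps, row + eps))


def cell_density(cells: pd.DataFrame, roi: RoiPolygon) -> float:
    """Iba1-positive cells inside the ROI per mm^2."""
    if roi.area_mm2 <= 0:
        raise ValueError("ROI area must be positive")
    pos = (
        cells[cells["iba1_positive"].astype(bool)]
        if "iba1_positive" in cells
        else cells
    )
    n_inside = sum(roi.contains(r, c) for r, c in zip(pos["row"], pos["col"]))
    return n_inside / roi.area_mm2
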