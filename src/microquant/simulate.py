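"""Synthetic multiplex-image generator with planted ground truth.

Emulates manually counted myeloid cells in immunofluorescence sections:
each simulated cell has a morphology class, a grey-/white-matter label, a
planted Iba1 positivity, and a jointly planted HLA-DR / marker-of-interest
(MOI) high/low state whose dependence is controlled by a log odds ratio.
Rendering produces one 8-bit channel per marker (flat background + cell
shape templates + Gaussian pixel noise, clipped to 0-255) plus a nuclear
channel with one blob per cell, so that every downstream measurement can be
checked against known truth.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from .io import (
    MultiChannelImage,
    write_background_points,
    write_cells,
    write_image,
)

MARKERS = ("iba1", "hla_dr", "moi")
CHANNELS = ("hoechst",) + MARKERS
MORPHOLOGIES = ("ramified", "hypertrophic", "dystrophic", "rod", "amoeboid")


def _as_channel_map(value, keys) -> dict:
    if isinstance(value, dict):
        return dict(value)
    return {k: value for k in keys}


@dataclasses.dataclass
class SimulationConfig:
    """Everything the generator needs, with defaults sized like one
    counting field (~1 mm^2 of cortex at 1 um/px).

    ``p_positive`` gives the marginal probability of the Iba1-positive
    state and of the HLA-DR/MOI *high* states; ``dependence_log_odds``
    couples the HLA-DR and MOI high states (0 = independence).  Intensity
    parameters are grey-value amplitudes *above* the per-channel flat
    background; 8-bit saturation happens at render time.
    """

    image_height_px: int = 1024
    image_width_px: int = 1024
    um_per_px: float = 1.0
    n_cells: int = 150
    case_id: str = "SIM01"
    region_label: str = "GM"
    background_grey: dict | float = dataclasses.field(
        default_factory=lambda: {"hoechst": 10, "iba1": 20, "hla_dr": 20, "moi": 20}
    )
    noise_sd: dict | float = dataclasses.field(
        default_factory=lambda: {ch: 4.0 for ch in CHANNELS}
    )
    p_positive: dict = dataclasses.field(
        default_factory=lambda: {"iba1": 0.95, "hla_dr": 0.5, "moi": 0.4}
    )
    dependence_log_odds: float = 1.0
    intensity_neg_mean: dict | float = dataclasses.field(
        default_factory=lambda: {m: 8.0 for m in MARKERS}
    )
    intensity_pos_mean: dict | float = dataclasses.field(
        default_factory=lambda: {m: 120.0 for m in MARKERS}
    )
    intensity_sd: dict | float = dataclasses.field(
        default_factory=lambda: {m: 15.0 for m in MARKERS}
    )
    morphology_probs: dict = dataclasses.field(
        default_factory=lambda: {
            "ramified": 0.55,
            "hypertrophic": 0.25,
            "dystrophic": 0.08,
            "rod": 0.07,
            "amoeboid": 0.05,
        }
    )
    min_distance_px: float = 12.0
    soma_radius_px: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.background_grey = _as_channel_map(self.background_grey, CHANNELS)
        self.noise_sd = _as_channel_map(self.noise_sd, CHANNELS)
        self.intensity_neg_mean = _as_channel_map(self.intensity_neg_mean, MARKERS)
        self.intensity_pos_mean = _as_channel_map(self.intensity_pos_mean, MARKERS)
        self.intensity_sd = _as_channel_map(self.intensity_sd, MARKERS)
        self.validate()

    def validate(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.region_label not in ("GM", "WM"):
            raise ValueError("region_label must be 'GM' or 'WM'")
        for m, p in self.p_positive.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_positive[{m!r}]={p} outside [0, 1]")
        if set(self.morphology_probs) != set(MORPHOLOGIES):
            raise ValueError(f"morphology_probs must cover {MORPHOLOGIES}")
        total = sum(self.morphology_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"morphology_probs sum to {total}, not 1")
        if any(p < 0 for p in self.morphology_probs.values()):
            raise ValueError("morphology probabilities must be >= 0")
        if self.min_distance_px <= 0 or self.soma_radius_px <= 0:
            raise ValueError("distances must be positive")


def joint_highlow_probs(
    p_a: float, p_b: float, log_odds: float
) -> tuple[float, float, float, float]:
    """Cell probabilities (p_hh, p_hl, p_lh, p_ll) of the unique 2x2 table
    with marginals ``p_a``, ``p_b`` and odds ratio ``exp(log_odds)``.

    Solved by one-dimensional root finding on the high/high probability;
    degenerate marginals (0 or 1) force the corresponding margin.
    """
    if not (0.0 <= p_a <= 1.0 and 0.0 <= p_b <= 1.0):
        raise ValueError("marginal probabilities must lie in [0, 1]")
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        p_hh = p_a * p_b
    elif log_odds == 0.0:
        p_hh = p_a * p_b
    else:
        lo = max(0.0, p_a + p_b - 1.0)
        hi = min(p_a, p_b)

        def f(p11: float) -> float:
            # log OR of the implied table minus the target; strictly
            # increasing in p11 on (lo, hi)
            p10 = p_a - p11
            p01 = p_b - p11
            p00 = 1.0 - p_a - p_b + p11
            return math.log(p11) + math.log(p00) - math.log(p10) - math.log(p01) - log_odds

        eps = 1e-12
        p_hh = brentq(f, lo + eps * (hi - lo) + eps, hi - eps * (hi - lo) - eps, xtol=1e-14)
    p_hl = p_a - p_hh
    p_lh = p_b - p_hh
    p_ll = 1.0 - p_a - p_b + p_hh
    return (p_hh, max(p_hl, 0.0), max(p_lh, 0.0), max(p_ll, 0.0))


def draw_joint_states(
    n: int,
    p_a: float,
    p_b: float,
    log_odds: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` coupled (A-high, B-high) boolean pairs."""
    probs = joint_highlow_probs(p_a, p_b, log_odds)
    cat = rng.choice(4, size=n, p=probs)
    a_high = np.isin(cat, (0, 1))
    b_high = np.isin(cat, (0, 2))
    return a_high, b_high


def _place_centers(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform centers with a hard minimum pairwise distance (grid hashing)."""
    h, w = config.image_height_px, config.image_width_px
    margin = config.soma_radius_px
    n, d = config.n_cells, config.min_distance_px
    usable = (h - 2 * margin) * (w - 2 * margin)
    # disks of radius d/2 around each center are disjoint; refuse clearly
    # impossible requests before sampling
    if n * math.pi * (d / 2.0) ** 2 > usable:
        raise ValueError(
            f"cannot place {n} cells at min distance {d} px in a "
            f"{h}x{w} px image: density limit is "
            f"{int(usable / (math.pi * (d / 2.0) ** 2))} cells"
        )
    cell = d  # hash-grid pitch; neighbours within d are in the 3x3 block
    grid: dict[tuple[int, int], list[int]] = {}
    centers = np.empty((n, 2))
    placed = 0
    attempts = 0
    max_attempts = 200 * max(n, 1)
    while placed < n:
        if attempts >= max_attempts:
            raise ValueError(
                f"placed only {placed}/{n} cells after {max_attempts} draws; "
                f"min distance {d} px is too dense for a {h}x{w} px image"
            )
        attempts += 1
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        key = (int(r // cell), int(c // cell))
        ok = True
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                for idx in grid.get((key[0] + dr, key[1] + dc), ()):
                    if np.hypot(*(centers[idx] - (r, c))) < d:
                        ok = False
                        break
        if ok:
            centers[placed] = (r, c)
            grid.setdefault(key, []).append(placed)
            placed += 1
    return np.floor(centers).astype(int)


def generate_cells(config: SimulationConfig) -> pd.DataFrame:
    """Generate the ground-truth cell table for one simulated image.

    Returns a DataFrame with one row per cell: coordinates, morphology
    class, region, planted Iba1 positivity and HLA-DR/MOI high/low states,
    and the latent (pre-clipping) intensity amplitudes above background.
    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_cells
    centers = _place_centers(config, rng) if n else np.empty((0, 2), dtype=int)
    morph = rng.choice(
        MORPHOLOGIES, size=n, p=[config.morphology_probs[m] for m in MORPHOLOGIES]
    )
    iba1_pos = rng.random(n) < config.p_positive["iba1"]
    hla_high, moi_high = draw_joint_states(
        n,
        config.p_positive["hla_dr"],
        config.p_positive["moi"],
        config.dependence_log_odds,
        rng,
    )

    def latent(marker: str, high: np.ndarray) -> np.ndarray:
        mean = np.where(
            high, config.intensity_pos_mean[marker], config.intensity_neg_mean[marker]
        )
        return np.clip(rng.normal(mean, config.intensity_sd[marker]), 0.0, None)

    table = pd.DataFrame(
        {
            "cell_id": [
                f"{config.case_id}-{config.region_label}-{i:05d}" for i in range(n)
            ],
            "case_id": config.case_id,
            "region": config.region_label,
            "row": centers[:, 0],
            "col": centers[:, 1],
            "morphology": morph,
            "iba1_state": np.where(iba1_pos, "pos", "neg"),
            "hla_state": np.where(hla_high, "high", "low"),
            "moi_state": np.where(moi_high, "high", "low"),
            "latent_hla": latent("hla_dr", hla_high),
            "latent_moi": latent("moi", moi_high),
            "latent_iba1": latent("iba1", iba1_pos),
        }
    )
    return table


# ---------------------------------------------------------------------------
# rendering

def _random_walk(rng, r0, c0, length, persistence=0.8):
    """8-neighbourhood random walk used for microglial processes."""
    steps = np.array(
        [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    )
    d = rng.integers(8)
    pts = [(r0, c0)]
    r, c = r0, c0
    for _ in range(length):
        if rng.random() > persistence:
            d = (d + rng.choice((-1, 1))) % 8
        r, c = r + steps[d][0], c + steps[d][1]
        pts.append((r, c))
    return pts


def _stamp(canvas, rr, cc, value):
    h, w = canvas.shape
    keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    rr, cc = rr[keep], cc[keep]
    np.maximum.at(canvas, (rr, cc), value)


def _render_cell(canvas, r, c, morphology, amplitude, soma_radius, rng):
    """Stamp one cell's shape template, scaled so the center pixel equals
    ``amplitude`` exactly (processes are dimmer than the soma)."""
    sr = soma_radius
    if morphology == "ramified":
        rr, cc = draw_disk((r, c), sr * 0.8, shape=canvas.shape)
        _stamp(canvas, rr, cc, amplitude)
        for _ in range(rng.integers(4, 7)):
            for pr, pc in _random_walk(rng, r, c, int(sr * 4)):
                _stamp(canvas, np.array([pr]), np.array([pc]), amplitude * 0.7)
    elif morphology == "hypertrophic":
        rr, cc = draw_disk((r, c), sr * 1.4, shape=canvas.shape)
        _stamp(canvas, rr, cc, amplitude)
        for sign in (-1, 1):  # thick bipolar processes
            pts = _random_walk(rng, r, c + sign * int(sr), int(sr * 3))
            for pr, pc in pts:
                rr, cc = draw_disk((pr, pc), 1.8, shape=canvas.shape)
                _stamp(canvas, rr, cc, amplitude * 0.8)
    elif morphology == "dystrophic":
        rr, cc = draw_disk((r, c), sr * 0.7, shape=canvas.shape)
        _stamp(canvas, rr, cc, amplitude)
        for _ in range(rng.integers(3, 6)):  # fragmented, beaded processes
            pts = _random_walk(rng, r, c, int(sr * 3))
            for i, (pr, pc) in enumerate(pts):
                if i % 3 != 2:  # membrane fragmentation: gaps along the walk
                    _stamp(canvas, np.array([pr]), np.array([pc]), amplitude * 0.6)
    elif morphology == "rod":
        # elongated soma parallel to the cortical (row) axis
        rr, cc = draw_ellipse(r, c, sr * 2.2, sr * 0.8, shape=canvas.shape)
        _stamp(canvas, rr, cc, amplitude)
        for sign in (-1, 1):
            rr, cc = draw_line(
                r + sign * int(sr * 2), c, r + sign * int(sr * 4), c
            )
            _stamp(canvas, rr, cc, amplitude * 0.7)
    else:  # amoeboid: perinuclear ring, no processes
        rr, cc = draw_disk((r, c), sr * 1.2, shape=canvas.shape)
        _stamp(canvas, rr, cc, amplitude)


def render_image(truth: pd.DataFrame, config: SimulationConfig) -> MultiChannelImage:
    """Render the ground truth into a 4-channel 8-bit image.

    Per channel: flat background + per-cell morphology templates (the pixel
    at each cell center carries exactly the cell's latent amplitude above
    background) + independent Gaussian noise, clipped to [0, 255].
    """
    rng = np.random.default_rng([config.seed, 1])
    h, w = config.image_height_px, config.image_width_px
    amplitude_col = {"iba1": "latent_iba1", "hla_dr": "latent_hla", "moi": "latent_moi"}
    channels: dict[str, np.ndarray] = {}
    shape_seeds = (
        rng.integers(0, 2**31, size=len(truth)) if len(truth) else np.empty(0, int)
    )
    for ch in CHANNELS:
        canvas = np.zeros((h, w))
        if ch == "hoechst":
            for _, cell in truth.iterrows():
                rr, cc = draw_disk(
                    (cell.row, cell.col), config.soma_radius_px * 0.6, shape=(h, w)
                )
                _stamp(canvas, rr, cc, 160.0)
        else:
            for (_, cell), s in zip(truth.iterrows(), shape_seeds):
                # one shape stream per cell, shared across marker channels
                # so morphology is identical in every channel
                _render_cell(
                    canvas,
                    int(cell.row),
                    int(cell.col),
                    cell.morphology,
                    float(cell[amplitude_col[ch]]),
                    config.soma_radius_px,
                    np.random.default_rng(int(s)),
                )
        noise = (
            rng.normal(0.0, config.noise_sd[ch], size=(h, w))
            if config.noise_sd[ch] > 0
            else 0.0
        )
        grey = np.clip(config.background_grey[ch] + canvas + noise, 0, 255)
        channels[ch] = np.round(grey).astype(np.uint8)
    return MultiChannelImage(channels=channels, um_per_px=config.um_per_px)


def make_background_points(
    truth: pd.DataFrame,
    config: SimulationConfig,
    n_per_channel: int = 5,
) -> pd.DataFrame:
    """Pick background sample points clear of every rendered cell (beyond
    the longest process reach), one set per channel, as a manual rater
    would."""
    rng = np.random.default_rng([config.seed, 2])
    h, w = config.image_height_px, config.image_width_px
    clearance = 4.5 * config.soma_radius_px
    centers = truth[["row", "col"]].to_numpy(dtype=float)
    rows = []
    for ch in CHANNELS:
        found = 0
        attempts = 0
        while found < n_per_channel:
            attempts += 1
            if attempts > 10000:
                raise ValueError("could not find background points clear of cells")
            r, c = rng.integers(0, h), rng.integers(0, w)
            if len(centers) == 0 or np.min(
                np.hypot(centers[:, 0] - r, centers[:, 1] - c)
            ) >= clearance:
                rows.append({"channel": ch, "row": int(r), "col": int(c)})
                found += 1
    return pd.DataFrame(rows, columns=["channel", "row", "col"])


def write_fixture(
    truth: pd.DataFrame,
    image: MultiChannelImage,
    directory: str | Path,
    config: SimulationConfig,
    case_meta: dict | None = None,
) -> dict[str, Path]:
    """Write one simulated case to disk: TIFF + sidecar, cells CSV,
    background-points CSV and a one-row case metadata CSV.

    Returns the paths keyed by artifact name.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": directory / "image.tif",
        "cells": directory / "cells.csv",
        "background": directory / "background.csv",
        "cases": directory / "cases.csv",
    }
    write_image(image, paths["image"])
    write_cells(truth, paths["cells"])
    write_background_points(make_background_points(truth, config), paths["background"])
    meta = {
        "case_id": config.case_id,
        "age_years": 78,
        "sex": "F",
        "pmd_hours": 19.0,
        "fixation": "synthetic",
    }
    if case_meta:
        meta.update(case_meta)
    pd.DataFrame([meta]).to_csv(paths["cases"], index=False)
    return paths
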