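"""Readers and writers for the pipeline's on-disk artifacts.

All tabular artifacts are plain CSV (comma-separated, UTF-8, header
required).  Images are multi-page 8-bit grayscale TIFFs with a YAML sidecar
declaring the channel order and the physical pixel size.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

#: Channel names every multiplex image must carry.
REQUIRED_CHANNELS = ("hoechst", "iba1", "hla_dr", "moi")

#: Columns every cell table must carry, in canonical order.
CELL_COLUMNS = (
    "cell_id",
    "case_id",
    "region",
    "row",
    "col",
    "morphology",
    "iba1_state",
    "hla_state",
    "moi_state",
    "latent_hla",
    "latent_moi",
)

BACKGROUND_COLUMNS = ("channel", "row", "col")


@dataclasses.dataclass
class MultiChannelImage:
    """Named-channel 8-bit raster with a physical pixel size.

    Parameters
    ----------
    channels
        Mapping from channel name (``hoechst``, ``iba1``, ``hla_dr``,
        ``moi``) to a 2-D ``uint8`` array.  All channels must share one
        shape.
    um_per_px
        Micrometres per pixel (isotropic).
    """

    channels: dict[str, np.ndarray]
    um_per_px: float = 1.0

    def __post_init__(self) -> None:
        shapes = {ch: arr.shape for ch, arr in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for ch, arr in self.channels.items():
            if arr.ndim != 2:
                raise ValueError(f"channel {ch!r} is not 2-D")
            if arr.dtype != np.uint8:
                raise ValueError(
                    f"channel {ch!r} has dtype {arr.dtype}; grey values must "
                    "be 8-bit (0-255) — convert the image to uint8 first"
                )
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def require(self, channel: str) -> np.ndarray:
        if channel not in self.channels:
            raise KeyError(
                f"image has no {channel!r} channel (present: "
                f"{sorted(self.channels)})"
            )
        return self.channels[channel]


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".yaml")


def write_image(image: MultiChannelImage, path: str | Path) -> Path:
    """Write a multi-page grayscale TIFF plus its YAML channel map.

    Returns the sidecar path.
    """
    path = Path(path)
    order = list(image.channels)
    stack = np.stack([image.channels[ch] for ch in order])
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = _sidecar_path(path)
    with open(sidecar, "w") as fh:
        yaml.safe_dump({"channels": order, "um_per_px": float(image.um_per_px)}, fh)
    return sidecar


def read_image(path: str | Path) -> MultiChannelImage:
    """Read a multi-page TIFF using its YAML sidecar for channel names.

    Raises on non-8-bit data or a missing required channel.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"channel-map sidecar not found: {sidecar}")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.dtype != np.uint8:
        raise ValueError(
            f"{path} holds {stack.dtype} data; point intensities are defined "
            "on 8-bit grey values — convert to uint8 before analysis"
        )
    names = list(meta["channels"])
    if len(names) != stack.shape[0]:
        raise ValueError(
            f"sidecar lists {len(names)} channels but TIFF has "
            f"{stack.shape[0]} pages"
        )
    channels = dict(zip(names, stack))
    for ch in REQUIRED_CHANNELS:
        if ch not in channels:
            raise ValueError(f"image {path} is missing the {ch!r} channel")
    return MultiChannelImage(channels=channels, um_per_px=float(meta["um_per_px"]))


def write_cells(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cell table; canonical columns first, extras preserved after."""
    missing = [c for c in CELL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cell table is missing required columns: {missing}")
    extras = [c for c in table.columns if c not in CELL_COLUMNS]
    table[list(CELL_COLUMNS) + extras].to_csv(path, index=False)


def read_cells(path: str | Path) -> pd.DataFrame:
    """Read a cell table; region labels are normalised to upper case."""
    table = pd.read_csv(path)
    missing = [c for c in CELL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path} is missing required columns: {missing}")
    table["region"] = table["region"].astype(str).str.upper()
    return table


def write_background_points(points: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in BACKGROUND_COLUMNS if c not in points.columns]
    if missing:
        raise ValueError(f"background table is missing columns: {missing}")
    points[list(BACKGROUND_COLUMNS)].to_csv(path, index=False)


def read_background_points(path: str | Path) -> pd.DataFrame:
    points = pd.read_csv(path)
    missing = [c for c in BACKGROUND_COLUMNS if c not in points.columns]
    if missing:
        raise ValueError(f"{path} is missing columns: {missing}")
    return points


def read_cases(path: str | Path) -> pd.DataFrame:
    """Read a case metadata table (case_id, age_years, sex, pmd_hours, ...)."""
    cases = pd.read_csv(path)
    for col in ("case_id", "age_years", "pmd_hours"):
        if col not in cases.columns:
            raise ValueError(f"{path} is missing column {col!r}")
    return cases
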