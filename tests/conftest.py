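import numpy as np
import pandas as pd
import pytest

from microquant import quantify, simulate
from microquant.io import MultiChannelImage


def flat_image(value: int = 0, size: int = 64, um_per_px: float = 1.0,
               overrides: dict | None = None) -> MultiChannelImage:
    """Uniform image; per-channel full-array overrides for targeted tests."""
    channels = {
        ch: np.full((size, size), value, dtype=np.uint8)
        for ch in simulate.CHANNELS
    }
    if overrides:
        channels.update({k: v.astype(np.uint8) for k, v in overrides.items()})
    return MultiChannelImage(channels=channels, um_per_px=um_per_px)


def estimate_all_backgrounds(image, points: pd.DataFrame) -> dict:
    return {
        ch: quantify.estimate_background(image, ch, grp[["row", "col"]].to_numpy())
        for ch, grp in points.groupby("channel")
    }


@pytest.fixture(scope="session")
def sparse_cfg():
    """Noise-free, well-separated cells: planted states must be exactly
    recoverable (no pixel noise, no intensity spread, no cell overlap)."""
    return simulate.SimulationConfig(
        n_cells=300,
        image_height_px=1024,
        image_width_px=1024,
        min_distance_px=42.0,
        noise_sd=0.0,
        intensity_sd=0.0,
        intensity_neg_mean=8.0,
        intensity_pos_mean=120.0,
        p_positive={"iba1": 0.9, "hla_dr": 0.5, "moi": 0.4},
        dependence_log_odds=1.0,
        seed=101,
    )


@pytest.fixture(scope="session")
def sparse_truth(sparse_cfg):
    return simulate.generate_cells(sparse_cfg)


@pytest.fixture(scope="session")
def sparse_image(sparse_truth, sparse_cfg):
    return simulate.render_image(sparse_truth, sparse_cfg)


@pytest.fixture(scope="session")
def sparse_backgrounds(sparse_image, sparse_truth, sparse_cfg):
    points = simulate.make_background_points(sparse_truth, sparse_cfg)
    return estimate_all_backgrounds(sparse_image, points)


@pytest.fixture(scope="session")
def sparse_measured(sparse_image, sparse_truth, sparse_backgrounds):
    return quantify.measure_cells(sparse_image, sparse_truth, sparse_backgrounds)


@pytest.fixture(scope="session")
def noisy_cfg():
    return simulate.SimulationConfig(
        n_cells=100,
        image_height_px=512,
        image_width_px=512,
        noise_sd=4.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def noisy_truth(noisy_cfg):
    return simulate.generate_cells(noisy_cfg)


@pytest.fixture(scope="session")
def noisy_image(noisy_truth, noisy_cfg):
    return simulate.render_image(noisy_truth, noisy_cfg)


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """Three simulated donors with GM and WM fixtures each, on disk."""
    root = tmp_path_factory.mktemp("cohort")
    entries = []
    for i, case in enumerate(("C1", "C2", "C3")):
        for j, region in enumerate(("GM", "WM")):
            cfg = simulate.SimulationConfig(
                n_cells=60,
                image_height_px=512,
                image_width_px=512,
                case_id=case,
                region_label=region,
                dependence_log_odds=1.5,
                seed=100 + 10 * i + j,
            )
            truth = simulate.generate_cells(cfg)
            image = simulate.render_image(truth, cfg)
            paths = simulate.write_fixture(truth, image, root / f"{case}_{region}", cfg)
            entries.append(
                {
                    "case_id": case,
                    "region": region,
                    "tiff": str(paths["image"]),
                    "cells": str(paths["cells"]),
                    "background": str(paths["background"]),
                }
            )
    return {"root": root, "entries": entries}
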