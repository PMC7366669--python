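"""Per-case marker abundance statistics.

Marker abundance is expressed as the percentage of Iba1-positive cells
immunoreactive for the marker, per case and region; grey and white matter
are compared with paired t-tests, and the percentages are rank-correlated
with donor age and post-mortem delay.  A published 11-donor normal cohort
(ages 57-98, both fixation types) ships with the package as
``load_reference_cases()`` for worked examples and checks.
"""

from __future__ import annotations

import importlib.resources
import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def load_reference_cases() -> pd.DataFrame:
    """The bundled 11-case normal cohort (case_id, fixation, hemisphere,
    age_years, sex, pmd_hours)."""
    ref = importlib.resources.files("microquant.data") / "reference_cases.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def summarize_cases(cases: pd.DataFrame) -> pd.DataFrame:
    """Mean, sample SD (n-1 denominator), min and max of donor age and
    post-mortem delay."""
    if len(cases) < 2:
        raise ValueError("need at least 2 cases to summarise")
    rows = []
    for col in ("age_years", "pmd_hours"):
        v = cases[col].astype(float)
        rows.append(
            {
                "variable": col,
                "n": len(v),
                "mean": v.mean(),
                "sd": v.std(ddof=1),
                "min": v.min(),
                "max": v.max(),
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def positive_fraction(cells: pd.DataFrame, marker: str) -> pd.DataFrame:
    """Percentage of Iba1-positive cells immunoreactive for ``marker``,
    per case and region.

    Returns columns ``n_iba1``, ``n_marker_pos``, ``percent`` and an
    ``undefined`` flag (True where a stratum has no Iba1-positive cells,
    in which case ``percent`` is NaN).
    """
    col = f"{marker}_positive"
    if col not in cells.columns or "iba1_positive" not in cells.columns:
        raise ValueError(f"cells must carry iba1_positive and {col} calls")
    rows = []
    for (case_id, region), grp in cells.groupby(["case_id", "region"], sort=True):
        iba1 = grp[grp["iba1_positive"]]
        n_iba1 = len(iba1)
        n_pos = int(iba1[col].sum())
        rows.append(
            {
                "case_id": case_id,
                "region": region,
                "marker": marker,
                "n_iba1": n_iba1,
                "n_marker_pos": n_pos,
                "percent": 100.0 * n_pos / n_iba1 if n_iba1 else float("nan"),
                "undefined": n_iba1 == 0,
            }
        )
    return pd.DataFrame(rows)


def compare_gm_wm(fractions: pd.DataFrame) -> dict:
    """Two-sided paired t-test of GM vs WM percentages across cases.

    Cases missing either region are dropped pairwise (logged).  A
    zero-variance difference vector is flagged ``degenerate`` with NaN
    statistics, except the all-zero case where t=0, p=1 exactly.
    """
    wide = fractions.pivot_table(
        index="case_id", columns="region", values="percent"
    )
    for region in ("GM", "WM"):
        if region not in wide.columns:
            raise ValueError(f"no {region} stratum present")
    incomplete = wide.index[wide[["GM", "WM"]].isna().any(axis=1)]
    if len(incomplete):
        logger.warning(
            "dropping cases without both regions: %s", list(incomplete)
        )
    wide = wide.dropna(subset=["GM", "WM"])
    if len(wide) < 2:
        raise ValueError("paired comparison needs >= 2 complete cases")
    diffs = (wide["GM"] - wide["WM"]).to_numpy()
    degenerate = bool(np.std(diffs, ddof=1) == 0.0)
    if degenerate and np.allclose(diffs, 0.0):
        t, p, degenerate = 0.0, 1.0, False
    elif degenerate:
        t, p = float("nan"), float("nan")
    else:
        t, p = stats.ttest_rel(wide["GM"], wide["WM"])
    return {
        "t": float(t),
        "df": len(wide) - 1,
        "p": float(p),
        "n_cases": len(wide),
        "mean_diff": float(np.mean(diffs)),
        "sd_diff": float(np.std(diffs, ddof=1)),
        "diffs": dict(zip(wide.index, diffs)),
        "degenerate": degenerate,
    }


def correlate_demographics(
    fractions: pd.DataFrame, cases: pd.DataFrame
) -> pd.DataFrame:
    """Spearman rank correlation (average ranks on ties) of per-case
    percentages against donor age and post-mortem delay, per region."""
    merged = fractions.merge(
        cases[["case_id", "age_years", "pmd_hours"]], on="case_id", how="inner"
    )
    rows = []
    for region, grp in merged.groupby("region", sort=True):
        if len(grp) < 3:
            raise ValueError(f"need >= 3 cases in region {region}")
        for covariate in ("age_years", "pmd_hours"):
            rho, p = stats.spearmanr(grp["percent"], grp[covariate])
            rows.append(
                {
                    "region": region,
                    "covariate": covariate,
                    "n": len(grp),
                    "rho": float(rho),
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows)


def morphology_crosstab(
    cells: pd.DataFrame,
    markers=("hla_dr", "moi"),
    min_count: int = 1,
) -> pd.DataFrame:
    """Counts of marker-positive cells per morphology class, plus an
    ``observed`` flag (>= ``min_count`` positive cells).

    Only Iba1-positive cells are tabulated; unknown morphology labels are
    an error.
    """
    from .simulate import MORPHOLOGIES

    unknown = set(cells["morphology"]) - set(MORPHOLOGIES)
    if unknown:
        raise ValueError(f"unknown morphology labels: {sorted(unknown)}")
    pos = cells[cells["iba1_positive"]] if "iba1_positive" in cells else cells
    rows = []
    for morph in MORPHOLOGIES:
        grp = pos[pos["morphology"] == morph]
        row: dict = {"morphology": morph, "n_cells": len(grp)}
        for marker in markers:
            n = int(grp[f"{marker}_positive"].sum())
            row[f"n_{marker}"] = n
            row[f"{marker}_observed"] = n >= min_count
        rows.append(row)
    return pd.DataFrame(rows).set_index("morphology")
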