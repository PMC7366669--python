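"""Co-labelling analysis of HLA-DR and a marker of interest (MOI).

Two complementary routes quantify whether the two markers rise and fall
together on Iba1-positive cells:

1. *Continuous* — pooled Pearson correlation of the two point intensities,
   repeated on the top decile of either marker and with/without 8-bit
   saturated cells (sensitivity to the 255 ceiling).
2. *Categorical* — each cell is binarised as HLA-DR high/low and MOI
   high/low against per-marker thresholds above background; the resulting
   2x2 table is tested for independence with a chi-square, and the
   conditional proportions (e.g. %MOI-high within HLA-DR-high vs within
   HLA-DR-low, per case) with an unpaired t-test.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import BackgroundEstimate, interpret_correlation, _bg_value

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationReport",
    "FourWayCounts",
    "HighLowThresholds",
    "interpret_correlation",
    "pearson_pooled",
    "top_decile_subset",
    "saturation_sensitivity",
    "categorize_highlow",
    "fourway_counts",
    "chi_square_independence",
    "conditional_proportion_test",
]


@dataclasses.dataclass
class CorrelationReport:
    marker_pair: tuple[str, str]
    n: int
    r: float
    p: float
    band: str
    subset: str = "all"
    undefined: bool = False

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class FourWayCounts:
    """Counts of the HLA-DR^high/low x MOI^high/low populations."""

    n_hh: int
    n_hl: int
    n_lh: int
    n_ll: int
    scope: str = "pooled"

    def __post_init__(self) -> None:
        if min(self.n_hh, self.n_hl, self.n_lh, self.n_ll) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_hh + self.n_hl + self.n_lh + self.n_ll

    def as_table(self) -> np.ndarray:
        """2x2 array [[hh, hl], [lh, ll]]; rows = HLA-DR, cols = MOI."""
        return np.array([[self.n_hh, self.n_hl], [self.n_lh, self.n_ll]])

    def log_odds_ratio(self) -> float:
        t = self.as_table().astype(float)
        if (t == 0).any():
            return float("nan")
        return float(np.log(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0])))


@dataclasses.dataclass
class HighLowThresholds:
    """Per-marker grey values above background required to call 'high'.

    Determined per marker from the original images in practice; the
    default of 40 sits at the top of the positivity range so that 'high'
    is never looser than 'positive'.
    """

    t_high: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"hla_dr": 40.0, "moi": 40.0}
    )
    positivity: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.positivity:
            for marker, t in self.t_high.items():
                tpos = self.positivity.get(marker)
                if tpos is not None and t < tpos:
                    raise ValueError(
                        f"t_high[{marker!r}]={t} below positivity "
                        f"threshold {tpos}"
                    )

    def __getitem__(self, marker: str) -> float:
        if marker not in self.t_high:
            raise KeyError(f"no high/low threshold configured for {marker!r}")
        return self.t_high[marker]


def _correlation(
    x: np.ndarray, y: np.ndarray, pair, subset: str
) -> CorrelationReport:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or x.std() == 0.0 or y.std() == 0.0:
        return CorrelationReport(
            marker_pair=tuple(pair), n=len(x), r=float("nan"), p=float("nan"),
            band="undefined", subset=subset, undefined=True,
        )
    r, p = stats.pearsonr(x, y)
    return CorrelationReport(
        marker_pair=tuple(pair), n=len(x), r=float(r), p=float(p),
        band=interpret_correlation(r), subset=subset,
    )


def pearson_pooled(
    cells: pd.DataFrame, marker_a: str = "hla_dr", marker_b: str = "moi",
    subset: str = "all",
) -> CorrelationReport:
    """Pearson correlation of two point intensities over pooled cells.

    ``cells`` must carry ``pi_<marker>`` columns; pooling across cases is
    implicit (every row participates).  Two-sided p.  Fewer than 3 cells
    or a zero-variance marker yields an undefined-r report.
    """
    return _correlation(
        cells[f"pi_{marker_a}"], cells[f"pi_{marker_b}"],
        (marker_a, marker_b), subset,
    )


def top_decile_subset(
    cells: pd.DataFrame, by_marker: str,
    marker_a: str = "hla_dr", marker_b: str = "moi",
) -> tuple[pd.DataFrame, CorrelationReport]:
    """The ceil(n/10) cells with the highest ``by_marker`` PI (nearest
    rank; ties at the cut all included), plus the correlation on them."""
    if len(cells) < 10:
        raise ValueError("top-decile analysis needs at least 10 cells")
    pi = cells[f"pi_{by_marker}"].to_numpy()
    k = math.ceil(len(cells) / 10)
    cutoff = np.sort(pi)[::-1][k - 1]
    subset = cells[pi >= cutoff]
    report = _correlation(
        subset[f"pi_{marker_a}"], subset[f"pi_{marker_b}"],
        (marker_a, marker_b), f"top10_by_{by_marker}",
    )
    return subset, report


def saturation_sensitivity(
    cells: pd.DataFrame, marker_a: str = "hla_dr", marker_b: str = "moi"
) -> dict:
    """Correlation with all cells vs excluding 8-bit-saturated cells.

    A cell is excluded when *either* PI equals 255 (the pair, not one
    coordinate).  Returns both reports, the count excluded, the r
    difference, and an ``all_saturated`` flag when exclusion empties the
    set.
    """
    with_all = pearson_pooled(cells, marker_a, marker_b, subset="all")
    mask = (cells[f"pi_{marker_a}"] < 255) & (cells[f"pi_{marker_b}"] < 255)
    n_excluded = int((~mask).sum())
    if mask.sum() < 3:
        return {
            "all": with_all,
            "unsaturated": None,
            "n_excluded": n_excluded,
            "delta_r": float("nan"),
            "all_saturated": True,
        }
    without = _correlation(
        cells.loc[mask, f"pi_{marker_a}"], cells.loc[mask, f"pi_{marker_b}"],
        (marker_a, marker_b), "unsaturated_only",
    )
    return {
        "all": with_all,
        "unsaturated": without,
        "n_excluded": n_excluded,
        "delta_r": float(with_all.r - without.r),
        "all_saturated": False,
    }


def categorize_highlow(
    cells: pd.DataFrame,
    backgrounds: dict[str, BackgroundEstimate | float],
    thresholds: HighLowThresholds | None = None,
    markers=("hla_dr", "moi"),
) -> pd.DataFrame:
    """Label each Iba1-positive cell high/low per marker.

    level = high iff PI >= background + t_high.  Returns a copy with
    ``<marker>_level`` columns; non-Iba1-positive rows are dropped (levels
    are defined only on the counted population).
    """
    thresholds = thresholds or HighLowThresholds()
    out = cells[cells["iba1_positive"]].copy() if "iba1_positive" in cells else cells.copy()
    for marker in markers:
        if marker not in backgrounds:
            raise KeyError(f"no background estimate for {marker!r}")
        cut = _bg_value(backgrounds[marker]) + thresholds[marker]
        out[f"{marker}_level"] = np.where(
            out[f"pi_{marker}"] >= cut, "high", "low"
        )
    return out


def fourway_counts(
    categorized: pd.DataFrame, scope: str = "pooled",
    marker_a: str = "hla_dr", marker_b: str = "moi",
) -> FourWayCounts:
    """Collapse per-cell high/low levels into the four-way table."""
    a = categorized[f"{marker_a}_level"] == "high"
    b = categorized[f"{marker_b}_level"] == "high"
    return FourWayCounts(
        n_hh=int((a & b).sum()),
        n_hl=int((a & ~b).sum()),
        n_lh=int((~a & b).sum()),
        n_ll=int((~a & ~b).sum()),
        scope=scope,
    )


def fourway_by_case(categorized: pd.DataFrame) -> dict[str, FourWayCounts]:
    return {
        case_id: fourway_counts(grp, scope="per-case")
        for case_id, grp in categorized.groupby("case_id", sort=True)
    }


def chi_square_independence(
    counts: FourWayCounts, yates: bool = False
) -> dict:
    """Pearson chi-square test of independence on the 2x2 table.

    No continuity correction by default.  Expected counts below 5 trigger
    a warning recommending an exact test (which is *not* performed); an
    expected count of 0 is an error.
    """
    table = counts.as_table()
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / counts.total if counts.total else np.zeros((2, 2))
    if (expected == 0).any():
        raise ValueError("chi-square undefined: an expected count is 0")
    if (expected < 5).any():
        warnings.warn(
            "an expected count is below 5; consider an exact test",
            stacklevel=2,
        )
    chi2, p, df, _ = stats.chi2_contingency(table, correction=yates)
    return {"chi2": float(chi2), "df": int(df), "p": float(p)}


def conditional_proportion_test(
    categorized: pd.DataFrame,
    group_by: str = "hla_dr",
    outcome: str = "moi",
    welch: bool = False,
) -> dict:
    """Per case: % of group-high cells that are outcome-high, and the same
    within group-low; compared across cases with a two-sided unpaired
    t-test (pooled variance by default, Welch optional).

    Cases with an empty high or low group are excluded with a warning.
    """
    rows = []
    for case_id, grp in categorized.groupby("case_id", sort=True):
        high = grp[grp[f"{group_by}_level"] == "high"]
        low = grp[grp[f"{group_by}_level"] == "low"]
        if len(high) == 0 or len(low) == 0:
            logger.warning(
                "case %s excluded: empty %s-%s group",
                case_id, group_by, "high" if len(high) == 0 else "low",
            )
            continue
        rows.append(
            {
                "case_id": case_id,
                "pct_outcome_high_in_group_high":
                    100.0 * (high[f"{outcome}_level"] == "high").mean(),
                "pct_outcome_high_in_group_low":
                    100.0 * (low[f"{outcome}_level"] == "high").mean(),
                "n_group_high": len(high),
                "n_group_low": len(low),
            }
        )
    per_case = pd.DataFrame(rows)
    if len(per_case) < 2:
        raise ValueError("conditional comparison needs >= 2 usable cases")
    a = per_case["pct_outcome_high_in_group_high"].to_numpy()
    b = per_case["pct_outcome_high_in_group_low"].to_numpy()
    if np.std(a, ddof=1) == 0.0 and np.std(b, ddof=1) == 0.0 and np.allclose(a, b):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return {
        "group_by": group_by,
        "outcome": outcome,
        "per_case": per_case,
        "mean_group_high": float(a.mean()),
        "mean_group_low": float(b.mean()),
        "t": float(t),
        "df": (2 * len(per_case) - 2) if not welch else None,
        "p": float(p),
        "n_cases": len(per_case),
        "welch": welch,
    }
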