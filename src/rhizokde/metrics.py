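"""Calibration and per-root colonization statistics.

Fluorescence is converted to cell counts through a linear calibration
(total pixel intensity = slope·cells + intercept, measured on images where
individual cells could be counted).  On top of that sit the cohort-level
summaries: colonization-state classification per root and timepoint,
cell-density profiles along the root (CFU mm⁻¹ of root per distance-from-tip
bin), minimum biofilm-to-tip distances, and the timepoint comparison of
those distances.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: Default calibration line: intensity = 39·cells + 331.
DEFAULT_CALIBRATION_SLOPE = 39.0
DEFAULT_CALIBRATION_INTERCEPT = 331.0


@dataclass
class CalibrationModel:
    """Linear map between cell count and total pixel intensity."""

    slope: float
    intercept: float
    n_points: int = 0
    residual_sd: float = float("nan")
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("calibration slope must be positive")

    def predict(self, cells) -> np.ndarray | float:
        """Total pixel intensity expected for a given cell count."""
        return self.slope * np.asarray(cells, dtype=float) + self.intercept

    def invert(self, total_intensity) -> np.ndarray | float:
        """Cell count for a given total pixel intensity, clamped at 0."""
        cells = (np.asarray(total_intensity, dtype=float) - self.intercept) / self.slope
        return np.maximum(cells, 0.0)


def paper_default_calibration() -> CalibrationModel:
    """The package's default calibration line (slope 39, intercept 331)."""
    return CalibrationModel(DEFAULT_CALIBRATION_SLOPE, DEFAULT_CALIBRATION_INTERCEPT)


def fit_calibration(points) -> CalibrationModel:
    """Ordinary least squares of total intensity on cell count.

    ``points``: iterable of (cell count, total intensity) pairs, or a
    DataFrame with columns ``cells`` and ``total_intensity``.  Requires at
    least two distinct counts.
    """
    if isinstance(points, pd.DataFrame):
        cells = points["cells"].to_numpy(dtype=float)
        intensity = points["total_intensity"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(points), dtype=float)
        cells, intensity = arr[:, 0], arr[:, 1]
    if len(np.unique(cells)) < 2:
        raise ValueError("calibration requires at least two distinct cell counts")
    res = sm.OLS(intensity, sm.add_constant(cells)).fit()
    intercept, slope = res.params
    dof = max(len(cells) - 2, 1)
    resid_sd = float(np.sqrt(np.sum(res.resid ** 2) / dof))
    return CalibrationModel(float(slope), float(intercept),
                            n_points=len(cells), residual_sd=resid_sd,
                            r_squared=float(res.rsquared))


def intensity_to_cells(patches: pd.DataFrame, cal: CalibrationModel,
                       pixel_size_um: float) -> np.ndarray:
    """Calibrated cells per patch.

    The patch's total pixel intensity is its mean intensity times its pixel
    count, ``I_i · A_i / pixel_area``; inverting the calibration line treats
    the intercept as per-patch background and clamps negatives to 0.
    """
    total = (patches["mean_intensity"].to_numpy(dtype=float)
             * patches["area_um2"].to_numpy(dtype=float) / pixel_size_um ** 2)
    return cal.invert(total)


class ColonizationState(enum.Enum):
    NONE = "none"
    MOBILE_ONLY = "mobile_only"
    MOBILE_AND_BIOFILM = "mobile_and_biofilm"
    BIOFILM_ONLY = "biofilm_only"


def colonization_state(classes) -> ColonizationState:
    """State of one root×timepoint from the multiset of patch classes."""
    s = set(classes)
    has_mb = "MB" in s
    has_biofilm = bool(s & {"RB", "PB"})
    if not has_mb and not has_biofilm:
        return ColonizationState.NONE
    if has_mb and not has_biofilm:
        return ColonizationState.MOBILE_ONLY
    if has_biofilm and not has_mb:
        return ColonizationState.BIOFILM_ONLY
    return ColonizationState.MOBILE_AND_BIOFILM


def state_table(patches: pd.DataFrame, roots=None, timepoints=None,
                collapse_biofilm_only: bool = False) -> pd.DataFrame:
    """Per-root×timepoint states plus cohort percentage table.

    Roots/timepoints absent from the patch table count as NONE, so pass the
    full cohort lists to include uncolonized observations.  With
    ``collapse_biofilm_only`` the BIOFILM_ONLY state is folded into
    MOBILE_AND_BIOFILM (three-category presentation).
    """
    if roots is None:
        roots = sorted(patches["root_id"].unique())
    if timepoints is None:
        timepoints = sorted(patches["timepoint_h"].unique())
    rows = []
    for r in roots:
        for t in timepoints:
            sub = patches[(patches["root_id"] == r) & (patches["timepoint_h"] == t)]
            st = colonization_state(sub["class"])
            if collapse_biofilm_only and st is ColonizationState.BIOFILM_ONLY:
                st = ColonizationState.MOBILE_AND_BIOFILM
            rows.append({"root_id": r, "timepoint_h": t, "state": st.value})
    return pd.DataFrame(rows)


def state_percentages(states: pd.DataFrame) -> pd.DataFrame:
    """Percentage of roots in each state per timepoint."""
    tab = (states.groupby(["timepoint_h", "state"]).size()
           .unstack(fill_value=0))
    return tab.div(tab.sum(axis=1), axis=0) * 100.0


@dataclass
class DensityProfile:
    """Cells per mm of root, binned by distance from the tip."""

    class_name: str
    timepoint_h: float
    bin_edges_mm: np.ndarray
    values: np.ndarray          # CFU mm⁻¹ per bin (averaged over R roots)
    roots_per_bin: np.ndarray   # roots long enough to contribute to each bin
    R: int

    def total_cells_per_root(self) -> float:
        widths = np.diff(self.bin_edges_mm)
        valid = ~np.isnan(self.values)
        return float(np.sum(self.values[valid] * widths[valid]))


def density_profile(patches: pd.DataFrame, class_name: str,
                    cal: CalibrationModel, R: int, pixel_size_um: float,
                    timepoint_h: float | None = None,
                    bin_width_mm: float = 0.5, max_da_mm: float = 10.0,
                    root_lengths_mm: dict | None = None) -> DensityProfile:
    """Calibrated cell density along the root for one class (and timepoint).

    Per bin: Σ calibrated cells ÷ (bin width · R), in CFU mm⁻¹.  Bins beyond
    every contributing root's length are masked (NaN) when root lengths are
    supplied.
    """
    if bin_width_mm <= 0:
        raise ValueError("bin width must be positive")
    if R <= 0:
        raise ValueError("R must be positive")
    sub = patches[patches["class"] == class_name]
    if timepoint_h is not None:
        sub = sub[sub["timepoint_h"] == timepoint_h]
    edges = np.arange(0.0, max_da_mm + 1e-9, bin_width_mm)
    cells = intensity_to_cells(sub, cal, pixel_size_um)
    da_mm = sub["da_um"].to_numpy(dtype=float) / 1000.0
    totals, _ = np.histogram(da_mm, bins=edges, weights=cells)
    values = totals / (bin_width_mm * R)
    if root_lengths_mm is not None:
        lengths = np.asarray(list(root_lengths_mm.values()), dtype=float)
        roots_per_bin = np.array([(lengths >= hi).sum() for hi in edges[1:]])
        values = np.where(roots_per_bin > 0, values, np.nan)
    else:
        roots_per_bin = np.full(len(edges) - 1, R)
    return DensityProfile(class_name, timepoint_h, edges, values,
                          roots_per_bin, R)


def min_biofilm_tip_distance(patches: pd.DataFrame) -> float | None:
    """Minimum da (µm) over root-biofilm patches of one root×timepoint."""
    rb = patches[patches["class"] == "RB"]
    if len(rb) == 0:
        return None
    return float(rb["da_um"].min())


def tip_distance_table(patches: pd.DataFrame) -> pd.DataFrame:
    """Per root×timepoint minimum RB-to-tip distance (µm); observations only."""
    rows = []
    for (r, t), sub in patches.groupby(["root_id", "timepoint_h"]):
        d = min_biofilm_tip_distance(sub)
        if d is not None:
            rows.append({"root_id": r, "timepoint_h": t, "min_tip_distance_um": d})
    return pd.DataFrame(rows, columns=["root_id", "timepoint_h",
                                       "min_tip_distance_um"])


def tip_distance_summary(table: pd.DataFrame) -> dict:
    """Cohort mean ± SD of per-root×timepoint minimum tip distances."""
    vals = table["min_tip_distance_um"].to_numpy(dtype=float)
    return {"n": len(vals), "mean_um": float(np.mean(vals)),
            "sd_um": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")}


def compare_tip_distance_groups(values_by_timepoint: dict,
                                reference_timepoint: float = 48.0,
                                method: str = "mannwhitney") -> dict:
    """Are biofilm-free tip zones longer at the reference (last) timepoint?

    Two-sided Mann–Whitney U of the reference-timepoint group against all
    earlier timepoints pooled; the exact null distribution is used when both
    groups have ≤ 20 observations, the normal approximation otherwise.
    ``method="welch"`` substitutes Welch's t-test.
    """
    ref = np.asarray(values_by_timepoint[reference_timepoint], dtype=float)
    other = np.concatenate([np.asarray(v, dtype=float)
                            for t, v in values_by_timepoint.items()
                            if t != reference_timepoint])
    if len(ref) < 2 or len(other) < 2:
        raise ValueError("each group needs at least 2 observations")
    if method == "welch":
        t, p = stats.ttest_ind(ref, other, equal_var=False)
        return {"statistic": float(t), "p_value": float(p),
                "n_reference": len(ref), "n_other": len(other),
                "method": "welch_t"}
    how = "exact" if max(len(ref), len(other)) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(ref, other, alternative="two-sided", method=how)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "n_reference": len(ref), "n_other": len(other),
            "method": f"mannwhitney_{how}"}


def mannwhitney_exact_enumeration(x, y) -> tuple[float, float]:
    """Brute-force two-sided exact Mann–Whitney p by full enumeration.

    Enumerates every C(n+m, n) assignment of the pooled sample to groups and
    counts assignments whose U deviates from its null mean at least as much
    as observed.  Tractable for small groups only; used as an independent
    cross-check of the exact test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n, m = len(x), len(y)
    mean_u = n * m / 2.0

    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - n * (n + 1) / 2.0

    u_obs = u_of(range(n))
    dev = abs(u_obs - mean_u)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n + m), n):
        total += 1
        if abs(u_of(idx) - mean_u) >= dev - 1e-12:
            count += 1
    return float(u_obs), count / total
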