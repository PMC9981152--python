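"""Figure-ground (FGM) and border-ownership (BOM) modulation statistics.

Both indices are normalized differences of zone-mean responses,

    FGM = (R_fig - R_back) / (R_fig + R_back)
    BOM = (R_left - R_right) / (R_left + R_right)

where the zones are sets of figure positions on the session grid:

* ``results`` convention — figure zone is the central 2 x 2 block of grid
  locations (40 trials at 10 repeats), background zone is the leftmost plus
  rightmost columns (160 trials), and the left/right border zones are the
  columns where the figure's border falls over a centrally located RF
  (columns 4 and 12 of the 16-column grid; 80 trials each).
* ``methods`` convention — figure zone is the 2 x 2 block nearest the
  cell's fitted RF center and the background zone is every location farther
  than 1.5 RF widths from the RF center.

Significance is assessed with a trial-shuffle bootstrap (500 shuffles of
zone identity) and the per-cell count of significant conditions is compared
against the Binomial(6, alpha) false-positive expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .rf_mapping import RFFit
from .session import PositionGrid

__all__ = [
    "ZoneSpec", "ModulationResult", "label_trials_by_zone",
    "zone_trial_counts", "compute_fgm", "compute_bom",
    "bootstrap_significance", "modulation_for_cell",
    "count_significant_conditions", "compute_zone_timecourses",
]


@dataclass(frozen=True)
class ZoneSpec:
    """Assignment of grid positions to figure/background/border zones."""

    convention: Literal["results", "methods"] = "results"
    figure_block: int = 2               # side of the central/RF-centered block
    background_distance_rf_widths: float = 1.5   # methods convention
    border_offset_bins: tuple[int, int] = (-4, 4)  # columns 4 and 12 on 16

    def __post_init__(self) -> None:
        if self.figure_block < 1:
            raise ValueError("figure_block must be >= 1")
        if self.convention not in ("results", "methods"):
            raise ValueError(f"unknown convention {self.convention!r}")


@dataclass
class ModulationResult:
    """One modulation index with its ingredients and bootstrap p-value."""

    index_type: Literal["FGM", "BOM"]
    index_value: float
    r_a: float
    r_b: float
    n_a: int
    n_b: int
    p_value: float | None = None
    condition: str | None = None
    variant: int | None = None

    def summary(self) -> str:
        zones = ("fig", "back") if self.index_type == "FGM" else ("left", "right")
        p = "n/a" if self.p_value is None else f"{self.p_value:.4f}"
        return (f"{self.index_type} [{self.condition or '-'}"
                f"/{self.variant or '-'}] = {self.index_value:+.4f} "
                f"(R_{zones[0]}={self.r_a:.4f} over {self.n_a} trials, "
                f"R_{zones[1]}={self.r_b:.4f} over {self.n_b} trials, "
                f"p={p})")


def _central_block(n: int, block: int) -> np.ndarray:
    """1-based indices of the central ``block`` bins along an ``n``-bin axis."""
    lo = (n - block) // 2 + 1
    return np.arange(lo, lo + block)


def label_trials_by_zone(trial_table: pd.DataFrame, grid: PositionGrid,
                         zone: ZoneSpec = ZoneSpec(),
                         rf_fit: RFFit | None = None) -> pd.Series:
    """Label every trial figure / background / left_border / right_border / other.

    ``results`` convention centers the zones on the grid (monitor) center;
    ``methods`` centers them on ``rf_fit`` and requires one.
    """
    az = trial_table["az_bin"].to_numpy()
    el = trial_table["el_bin"].to_numpy()

    if zone.convention == "results":
        fig_cols = _central_block(grid.n_azimuth, zone.figure_block)
        fig_rows = _central_block(grid.n_elevation, zone.figure_block)
        figure = np.isin(az, fig_cols) & np.isin(el, fig_rows)
        background = (az == 1) | (az == grid.n_azimuth)
        anchor_col = grid.n_azimuth // 2
    else:
        if rf_fit is None:
            raise ValueError("methods convention requires an RF fit")
        az_step = grid.azimuth_span_deg / max(grid.n_azimuth - 1, 1)
        el_step = grid.elevation_span_deg / max(grid.n_elevation - 1, 1)
        rf_col = (grid.n_azimuth + 1) / 2.0 + rf_fit.center[0] / az_step
        rf_row = (grid.n_elevation + 1) / 2.0 - rf_fit.center[1] / el_step
        fig_cols = np.round([rf_col - 0.5, rf_col + 0.5]).astype(int)
        fig_rows = np.round([rf_row - 0.5, rf_row + 0.5]).astype(int)
        figure = np.isin(az, fig_cols) & np.isin(el, fig_rows)
        rf_width = 2.0 * float(np.sqrt(rf_fit.widths[0] * rf_fit.widths[1]))
        pos_az = np.asarray(grid.azimuth_of_bin(az))
        pos_el = np.asarray(grid.elevation_of_bin(el))
        dist = np.hypot(pos_az - rf_fit.center[0], pos_el - rf_fit.center[1])
        background = dist > zone.background_distance_rf_widths * rf_width
        anchor_col = int(round(rf_col - 0.5))
    left_col = anchor_col + zone.border_offset_bins[0]
    right_col = anchor_col + zone.border_offset_bins[1]

    labels = np.full(len(trial_table), "other", dtype=object)
    labels[background] = "background"
    labels[(az == left_col) & ~figure] = "left_border"
    labels[(az == right_col) & ~figure] = "right_border"
    labels[figure] = "figure"
    return pd.Series(labels, index=trial_table.index, name="zone")


def zone_trial_counts(labels: pd.Series, trial_table: pd.DataFrame
                      ) -> pd.DataFrame:
    """Trial counts per (condition, variant, zone)."""
    df = trial_table[["condition", "variant"]].copy()
    df["zone"] = labels
    return (df.value_counts(["condition", "variant", "zone"])
              .rename("n_trials").reset_index())


def _normalized_difference(a: float, b: float) -> float:
    if a < 0 or b < 0:
        raise ValueError("zone means must be nonnegative")
    total = a + b
    if total == 0:
        raise ValueError("both zone means are zero; index undefined")
    return (a - b) / total


def compute_fgm(r_fig: float, r_back: float) -> float:
    """Figure-ground modulation index (R_fig - R_back)/(R_fig + R_back)."""
    return _normalized_difference(r_fig, r_back)


def compute_bom(r_left: float, r_right: float) -> float:
    """Border-ownership modulation index (R_left - R_right)/(R_left + R_right)."""
    return _normalized_difference(r_left, r_right)


def bootstrap_significance(responses: np.ndarray, zone_labels: np.ndarray,
                           zone_a: str, zone_b: str, n_shuffles: int = 500,
                           seed: int = 0) -> tuple[float, float]:
    """Two-sided trial-shuffle p-value for a normalized-difference index.

    Zone identity is shuffled among the trials of the two zones; the
    p-value is the small-sample-corrected fraction of shuffles whose
    absolute index reaches the observed one:
    ``p = (1 + #{|shuffled| >= |observed|}) / (n_shuffles + 1)``.

    Returns (observed index, p).
    """
    responses = np.asarray(responses, dtype=float)
    in_a = np.asarray(zone_labels) == zone_a
    in_b = np.asarray(zone_labels) == zone_b
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError("need at least 2 trials per zone")
    ra, rb = responses[in_a].mean(), responses[in_b].mean()
    observed = _normalized_difference(ra, rb)

    pool = np.concatenate([responses[in_a], responses[in_b]])
    n_a = int(in_a.sum())
    rng = np.random.default_rng(seed)
    shuffled = np.tile(pool, (n_shuffles, 1))
    shuffled = rng.permuted(shuffled, axis=1)
    mean_a = shuffled[:, :n_a].mean(axis=1)
    mean_b = shuffled[:, n_a:].mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        null = (mean_a - mean_b) / (mean_a + mean_b)
    null = null[np.isfinite(null)]
    p = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (n_shuffles + 1.0)
    return observed, float(p)


def modulation_for_cell(responses: np.ndarray, labels: pd.Series,
                        trial_table: pd.DataFrame, index_type: str = "FGM",
                        condition: str | None = None,
                        variant: int | None = None,
                        n_shuffles: int = 500, seed: int = 0
                        ) -> ModulationResult:
    """Modulation index for one cell, optionally restricted to a
    condition (pooling variants) or a single condition-variant."""
    zone_a, zone_b = (("figure", "background") if index_type == "FGM"
                      else ("left_border", "right_border"))
    keep = np.ones(len(trial_table), dtype=bool)
    if condition is not None:
        keep &= (trial_table["condition"] == condition).to_numpy()
    if variant is not None:
        keep &= (trial_table["variant"] == variant).to_numpy()
    resp = np.asarray(responses, dtype=float)[keep]
    labs = np.asarray(labels)[keep]
    value, p = bootstrap_significance(resp, labs, zone_a, zone_b,
                                      n_shuffles, seed)
    in_a, in_b = labs == zone_a, labs == zone_b
    return ModulationResult(index_type, value, resp[in_a].mean(),
                            resp[in_b].mean(), int(in_a.sum()),
                            int(in_b.sum()), p, condition, variant)


def count_significant_conditions(p_values: np.ndarray, alpha: float = 0.05
                                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Histogram of per-cell significant-condition counts vs chance.

    ``p_values`` is (n_cells, n_conditions).  Returns (counts per cell,
    histogram over 0..n_conditions as fractions of cells, Binomial(n, alpha)
    chance mass function).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 2:
        raise ValueError("p_values must be (n_cells, n_conditions)")
    n_cond = p.shape[1]
    counts = (p < alpha).sum(axis=1)
    hist = np.bincount(counts, minlength=n_cond + 1) / p.shape[0]
    chance = stats.binom.pmf(np.arange(n_cond + 1), n_cond, alpha)
    return counts, hist, chance


def compute_zone_timecourses(time_responses: np.ndarray, labels: pd.Series,
                             alpha: float = 0.01) -> dict:
    """Zone-resolved response time courses with per-bin figure>ground tests.

    ``time_responses`` is (n_trials, n_bins).  Returns mean and SEM traces
    for the figure, background and border zones plus a one-sided two-sample
    t-test flag per bin for figure > background.
    """
    x = np.asarray(time_responses, dtype=float)
    labs = np.asarray(labels)
    out: dict = {"alpha": alpha}
    for zone in ("figure", "background", "left_border", "right_border"):
        sel = labs == zone
        if sel.sum() == 0:
            continue
        out[zone] = {"mean": x[sel].mean(axis=0),
                     "sem": stats.sem(x[sel], axis=0),
                     "n": int(sel.sum())}
    fig, back = labs == "figure", labs == "background"
    if fig.sum() < 2 or back.sum() < 2:
        raise ValueError("need >= 2 figure and background trials per bin")
    tstat, pvals = stats.ttest_ind(x[fig], x[back], axis=0,
                                   alternative="greater")
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    out["t_statistic"] = tstat
    out["p_values"] = pvals
    out["significant"] = pvals < alpha
    return out
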