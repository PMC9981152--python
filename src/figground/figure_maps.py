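"""Per-neuron figure maps, map consistency, and cross-session cell matching.

A *figure map* is a neuron's mean response as a function of figure position
on the session grid (canonically 16 azimuth x 8 elevation positions).  Maps
are compared with Pearson correlation — across the two pattern variants of
a condition, across all condition pairs, and across recording sessions for
cells matched by spatial-mask overlap (Jaccard index > 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .population import ResponseMatrix
from .session import PositionGrid

__all__ = [
    "FigureMap", "compute_trial_responses", "build_figure_map",
    "correlate_maps", "condition_consistency", "CellMask", "jaccard_index",
    "match_cells_across_sessions", "matched_vs_shuffled",
]


@dataclass
class FigureMap:
    """Mean response per figure position for one neuron and condition."""

    values: np.ndarray            # (n_elevation, n_azimuth)
    n_trials: np.ndarray          # same shape; trials per position
    condition: str
    variant: int | None
    neuron: int | str | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def compute_trial_responses(spike_times: list[np.ndarray] | np.ndarray,
                            trial_table: pd.DataFrame,
                            window_ms: tuple[float, float] = (50.0, 250.0),
                            neurons: pd.DataFrame | None = None
                            ) -> ResponseMatrix:
    """Trial-scalar responses from spike trains or a time-binned recording.

    For spiking data (a list of per-neuron spike-time arrays, seconds) the
    response is the spike count between ``onset + window_ms[0]`` and
    ``onset + window_ms[1]``.  A 2D array input is treated as an already
    trial-aligned (neurons x trials) response matrix and passed through.
    """
    lo, hi = window_ms
    if hi <= lo:
        raise ValueError("window must have positive duration")
    onsets = trial_table["onset_s"].to_numpy()
    if isinstance(spike_times, np.ndarray) and spike_times.ndim == 2:
        resp = np.asarray(spike_times, dtype=float)
        if resp.shape[1] != len(trial_table):
            raise ValueError("response matrix does not match trial table")
    else:
        resp = np.empty((len(spike_times), len(onsets)))
        for i, st in enumerate(spike_times):
            st = np.sort(np.asarray(st, dtype=float))
            starts = np.searchsorted(st, onsets + lo / 1000.0, side="left")
            stops = np.searchsorted(st, onsets + hi / 1000.0, side="right")
            resp[i] = stops - starts
    if neurons is None:
        neurons = pd.DataFrame(index=range(resp.shape[0]))
    return ResponseMatrix(resp, neurons, trial_table.reset_index(drop=True))


def build_figure_map(responses: np.ndarray, trial_table: pd.DataFrame,
                     grid: PositionGrid, condition: str,
                     variant: int | None = None,
                     neuron: int | str | None = None) -> FigureMap:
    """Average one neuron's trial responses into a position map.

    ``variant=None`` pools the condition's variants.  Raises if any grid
    position lacks trials (no silent interpolation).
    """
    responses = np.asarray(responses, dtype=float)
    sel = (trial_table["condition"] == condition).to_numpy()
    if variant is not None:
        sel &= (trial_table["variant"] == variant).to_numpy()
    if not sel.any():
        raise ValueError(f"no trials for condition {condition!r} "
                         f"variant {variant!r}")
    az = trial_table.loc[sel, "az_bin"].to_numpy() - 1
    el = trial_table.loc[sel, "el_bin"].to_numpy() - 1
    total = np.zeros((grid.n_elevation, grid.n_azimuth))
    count = np.zeros_like(total)
    np.add.at(total, (el, az), responses[sel])
    np.add.at(count, (el, az), 1.0)
    if (count == 0).any():
        missing = np.argwhere(count == 0)[:5] + 1
        raise ValueError(f"grid positions without trials, e.g. {missing.tolist()}")
    return FigureMap(total / count, count, condition, variant, neuron)


def correlate_maps(map_a: FigureMap | np.ndarray,
                   map_b: FigureMap | np.ndarray) -> float:
    """Pearson correlation of two equally shaped figure maps."""
    a = (map_a.values if isinstance(map_a, FigureMap) else np.asarray(map_a))
    b = (map_b.values if isinstance(map_b, FigureMap) else np.asarray(map_b))
    if a.shape != b.shape:
        raise ValueError("maps must share dimensions")
    a, b = a.ravel(), b.ravel()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant map: correlation undefined")
    return float(stats.pearsonr(a, b).statistic)


def condition_consistency(maps: list[FigureMap | np.ndarray]) -> float:
    """Mean Pearson correlation over all unordered pairs of maps.

    With the six condition-variant maps of one neuron this is the
    cross-condition consistency; values near zero mean no texture-invariant
    figure representation.
    """
    if len(maps) < 2:
        raise ValueError("need at least two maps")
    rs = [correlate_maps(a, b) for a, b in combinations(maps, 2)]
    return float(np.mean(rs))


@dataclass(frozen=True)
class CellMask:
    """Binary spatial footprint of a cell within one session."""

    pixels: frozenset[tuple[int, int]]
    session_id: str = ""
    cell_id: int = 0

    def __post_init__(self) -> None:
        if len(self.pixels) == 0:
            raise ValueError("mask must be non-empty")

    @classmethod
    def from_array(cls, mask: np.ndarray, session_id: str = "",
                   cell_id: int = 0) -> "CellMask":
        pix = frozenset(map(tuple, np.argwhere(np.asarray(mask) > 0)))
        return cls(pix, session_id, cell_id)


def jaccard_index(a: CellMask, b: CellMask) -> float:
    """Intersection over union of two masks."""
    inter = len(a.pixels & b.pixels)
    union = len(a.pixels | b.pixels)
    return inter / union


def match_cells_across_sessions(masks_a: list[CellMask],
                                masks_b: list[CellMask],
                                threshold: float = 0.5
                                ) -> list[tuple[int, int, float]]:
    """Greedy one-to-one matching of cells by mask overlap.

    Candidate pairs with Jaccard index > ``threshold`` are assigned in
    descending overlap order; each cell participates in at most one match.
    Returns (index into masks_a, index into masks_b, J) triples.
    """
    if not masks_a or not masks_b:
        raise ValueError("both mask sets must be non-empty")
    candidates = [(jaccard_index(a, b), i, j)
                  for i, a in enumerate(masks_a)
                  for j, b in enumerate(masks_b)]
    candidates = [c for c in candidates if c[0] > threshold]
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for jac, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        matches.append((i, j, jac))
        used_a.add(i)
        used_b.add(j)
    return matches


def matched_vs_shuffled(maps_a: list[np.ndarray], maps_b: list[np.ndarray],
                        matches: list[tuple[int, int, float]],
                        n_shuffled: int | None = None, seed: int = 0
                        ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Figure-map correlations for matched vs random non-matched cell pairs.

    Returns (matched correlations, shuffled-pair correlations, KS statistic,
    KS p-value).  A matched-pair distribution shifted right of the shuffled
    one indicates that spatial response maps are a stable cell signature.
    """
    if not matches:
        raise ValueError("no matched pairs")
    matched = np.array([correlate_maps(maps_a[i], maps_b[j])
                        for i, j, _ in matches])
    rng = np.random.default_rng(seed)
    matched_pairs = {(i, j) for i, j, _ in matches}
    n_shuffled = n_shuffled if n_shuffled is not None else 10 * len(matches)
    shuffled = []
    while len(shuffled) < n_shuffled:
        i = int(rng.integers(len(maps_a)))
        j = int(rng.integers(len(maps_b)))
        if (i, j) in matched_pairs:
            continue
        shuffled.append(correlate_maps(maps_a[i], maps_b[j]))
    shuffled = np.asarray(shuffled)
    ks = stats.ks_2samp(matched, shuffled)
    return matched, shuffled, float(ks.statistic), float(ks.pvalue)
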