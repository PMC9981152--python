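"""Figure-map session construction: the 16 x 8 position grid protocol.

One session presents each condition-variant as a block within which the
figure square is flashed at every grid position ``repeats_per_position``
times in pseudo-random order.  Condition blocks are pseudo-randomly
interleaved with the two within-condition variants presented consecutively
(in random order), matching the recording protocol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import CanvasGeometry
from .stimuli import (FigureGroundSpec, StimulusMovie, condition_spec,
                      render_trial_movie)

__all__ = ["PositionGrid", "FigureMapSession", "build_figure_map_session",
           "canonical_condition_specs"]

TRIAL_COLUMNS = ["trial", "condition", "variant", "az_bin", "el_bin",
                 "onset_s", "motion_phase"]


@dataclass(frozen=True)
class PositionGrid:
    """Grid of figure positions (azimuth x elevation bin centers).

    Canonically 16 x 8 positions spanning 45 x 21 degrees (~3 degrees per
    bin), 250 ms dwell, 10 repeats per position.  Bins are 1-based.
    """

    n_azimuth: int = 16
    n_elevation: int = 8
    azimuth_span_deg: float = 45.0
    elevation_span_deg: float = 21.0
    repeats_per_position: int = 10
    dwell_ms: float = 250.0

    def __post_init__(self) -> None:
        if self.n_azimuth < 1 or self.n_elevation < 1:
            raise ValueError("grid must have at least one position")
        if self.repeats_per_position < 1:
            raise ValueError("repeats_per_position must be positive")
        if self.dwell_ms <= 0 or self.azimuth_span_deg <= 0 \
                or self.elevation_span_deg <= 0:
            raise ValueError("grid spans and dwell must be positive")

    @property
    def n_positions(self) -> int:
        return self.n_azimuth * self.n_elevation

    def azimuth_of_bin(self, az_bin: np.ndarray | int) -> np.ndarray | float:
        """Azimuth (deg) of a 1-based azimuth bin center; 0 at grid center."""
        b = np.asarray(az_bin, dtype=float)
        step = self.azimuth_span_deg / (self.n_azimuth - 1) \
            if self.n_azimuth > 1 else 0.0
        out = (b - (self.n_azimuth + 1) / 2.0) * step
        return float(out) if np.isscalar(az_bin) else out

    def elevation_of_bin(self, el_bin: np.ndarray | int) -> np.ndarray | float:
        b = np.asarray(el_bin, dtype=float)
        step = self.elevation_span_deg / (self.n_elevation - 1) \
            if self.n_elevation > 1 else 0.0
        out = ((self.n_elevation + 1) / 2.0 - b) * step
        return float(out) if np.isscalar(el_bin) else out

    def positions(self) -> np.ndarray:
        """(n_positions, 2) array of 1-based (az_bin, el_bin) pairs."""
        az, el = np.meshgrid(np.arange(1, self.n_azimuth + 1),
                             np.arange(1, self.n_elevation + 1))
        return np.column_stack([az.ravel(), el.ravel()])


def canonical_condition_specs(conditions: Sequence[str] = ("Cross", "Iso", "Nat"),
                              variants: Sequence[int] = (1, 2),
                              **kwargs) -> list[FigureGroundSpec]:
    """The six condition-variant stimuli (3 conditions x 2 variants)."""
    return [condition_spec(c, v, **kwargs) for c in conditions for v in variants]


@dataclass
class FigureMapSession:
    """Trial table plus lazy access to each trial's stimulus movie.

    Movies are rendered on demand; the (condition, variant, position) ->
    movie mapping is cached because every repeat of a position shows the
    identical stimulus.
    """

    trials: pd.DataFrame
    grid: PositionGrid
    specs: dict[tuple[str, int], FigureGroundSpec]
    canvas: CanvasGeometry
    frame_rate_hz: float = 56.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self._movie_cache: dict[tuple, StimulusMovie] = {}

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def spec_for(self, condition: str, variant: int, az_bin: int,
                 el_bin: int) -> FigureGroundSpec:
        base = self.specs[(condition, int(variant))]
        return base.at_position(self.grid.azimuth_of_bin(az_bin),
                                self.grid.elevation_of_bin(el_bin))

    def render_unique(self, condition: str, variant: int, az_bin: int,
                      el_bin: int, motion_phase: float = 0.0) -> StimulusMovie:
        key = (condition, int(variant), int(az_bin), int(el_bin),
               round(float(motion_phase), 9))
        if key not in self._movie_cache:
            spec = self.spec_for(*key[:4])
            self._movie_cache[key] = render_trial_movie(
                spec, self.canvas, duration_s=self.grid.dwell_ms / 1000.0,
                frame_rate_hz=self.frame_rate_hz, motion_phase=key[4])
        return self._movie_cache[key]

    def render_trial(self, trial_index: int) -> StimulusMovie:
        row = self.trials.iloc[trial_index]
        return self.render_unique(row["condition"], row["variant"],
                                  row["az_bin"], row["el_bin"],
                                  row.get("motion_phase", 0.0))

    def unique_keys(self) -> list[tuple[str, int, int, int, float]]:
        """All distinct (condition, variant, az_bin, el_bin, phase) stimuli."""
        u = self.trials[["condition", "variant", "az_bin", "el_bin",
                         "motion_phase"]].drop_duplicates()
        return [tuple(r) for r in u.itertuples(index=False)]

    def clear_cache(self) -> None:
        self._movie_cache.clear()


def build_figure_map_session(grid: PositionGrid,
                             conditions: Iterable[FigureGroundSpec] | None = None,
                             seed: int = 0,
                             canvas: CanvasGeometry | None = None,
                             frame_rate_hz: float = 56.0,
                             continuous_motion_phase: bool = True
                             ) -> FigureMapSession:
    """Assemble the pseudo-random trial order for a figure-map session.

    Each condition-variant block contains every grid position exactly
    ``repeats_per_position`` times (shuffled).  Blocks are ordered with
    conditions in random order and the two variants of each condition
    consecutive, their order also randomized.  Deterministic under ``seed``.

    With ``continuous_motion_phase`` (the recording protocol) the
    counterphase oscillation clock runs across trials, so each trial starts
    at motion phase ``2 pi f t_onset`` (four distinct phases for the
    canonical 250-ms dwell and 1 Hz oscillation); repeats of a position then
    sample different displacement branches.  Disabling it starts every
    trial at phase zero.
    """
    if conditions is None:
        conditions = canonical_condition_specs()
    specs = {(s.condition, s.variant): s for s in conditions}
    canvas = canvas if canvas is not None else CanvasGeometry()
    rng = np.random.default_rng(seed)

    cond_names = list(dict.fromkeys(c for c, _ in specs))
    rng.shuffle(cond_names)
    block_order: list[tuple[str, int]] = []
    for c in cond_names:
        variants = sorted(v for cc, v in specs if cc == c)
        rng.shuffle(variants)
        block_order.extend((c, v) for v in variants)

    positions = grid.positions()
    dwell_s = grid.dwell_ms / 1000.0
    rows = []
    t = 0
    for cond, var in block_order:
        order = np.repeat(np.arange(grid.n_positions),
                          grid.repeats_per_position)
        rng.shuffle(order)
        freq = specs[(cond, var)].motion.temporal_freq_hz
        for idx in order:
            az, el = positions[idx]
            onset = t * dwell_s
            # cycle fraction computed before scaling by 2*pi so the phase
            # set stays exactly periodic (no float drift at large t)
            phase = (round(2 * np.pi * ((freq * onset) % 1.0), 9)
                     if continuous_motion_phase else 0.0)
            rows.append((t, cond, var, int(az), int(el), onset, phase))
            t += 1
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return FigureMapSession(trials, grid, specs, canvas, frame_rate_hz, seed)
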