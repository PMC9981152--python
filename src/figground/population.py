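"""Synthetic neural populations: LN Gabor model, divisive surround, noise.

The encoding model is a classic linear-nonlinear simple cell: a Gabor filter

    g(x, y) = exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2)) cos(2 pi x'/lambda + omega)

(x', y' the coordinates rotated by theta) applied to each mean-subtracted
stimulus frame, rectified at zero, and averaged over the frames of a trial.
Parameters are sampled uniformly: theta, omega ~ U(0, pi); sigma ~ U(2, 7)
degrees; spatial frequency 1/lambda ~ U(0.05, 0.3) cpd; gamma = 1.

The surround variant divides the feedforward rate by ``1 + beta * rho``,
where rho is the Pearson correlation between the mean orientation-energy
vectors (over a bank of oriented cell types) inside the receptive field
(< 2 sigma) and in the surround annulus (2-5 sigma).  Matched center and
surround orientation content (Iso figures) gives rho > 0 and suppression;
orthogonal content (Cross figures) gives rho < 0 and facilitation.

Trial-to-trial variability is additive zero-mean Gaussian noise with
variance ``noise_factor * popmean`` (population mean response within the
condition), rectified at zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .geometry import CanvasGeometry
from .session import FigureMapSession
from .stimuli import StimulusMovie

__all__ = [
    "GaborParams", "GaborPopulation", "sample_population", "gabor_image",
    "ln_response", "SurroundParams", "OrientationEnergyBank", "surround_rho",
    "surround_modulate", "NoiseModel", "add_noise", "ResponseMatrix",
    "ArchetypeSpec", "archetype_response", "make_archetype_cells",
    "simulate_session",
]


@dataclass(frozen=True)
class GaborParams:
    """One model simple cell.  Angles in radians, lengths in degrees."""

    theta: float
    sigma: float
    wavelength: float
    gamma: float = 1.0
    omega: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)  # (azimuth, elevation) deg

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.wavelength <= 0:
            raise ValueError("sigma and wavelength must be positive")


def gabor_image(params: GaborParams, canvas: CanvasGeometry,
                truncate_sigma: float = 3.0) -> np.ndarray:
    """Render the Gabor filter on the canvas raster (float32).

    Support is truncated at ``truncate_sigma`` envelope widths (default 3,
    discarding <1% of envelope mass) to bound compute.
    """
    az = canvas.azimuth_of_columns()[None, :] - params.center[0]
    el = canvas.elevation_of_rows()[:, None] - params.center[1]
    x_r = az * np.cos(params.theta) + el * np.sin(params.theta)
    y_r = -az * np.sin(params.theta) + el * np.cos(params.theta)
    r2 = x_r ** 2 + (params.gamma * y_r) ** 2
    env = np.exp(-r2 / (2.0 * params.sigma ** 2))
    g = env * np.cos(2 * np.pi * x_r / params.wavelength + params.omega)
    g[r2 > (truncate_sigma * params.sigma) ** 2] = 0.0
    return g.astype(np.float32)


SIGMA_RANGE = (2.0, 7.0)
FREQ_RANGE_CPD = (0.05, 0.3)


class GaborPopulation:
    """A sampled population of LN model cells with a shared canvas."""

    def __init__(self, params: pd.DataFrame, canvas: CanvasGeometry):
        required = {"theta", "sigma", "wavelength", "gamma", "omega",
                    "x0", "y0"}
        if not required <= set(params.columns):
            raise ValueError(f"params must contain columns {sorted(required)}")
        self.params = params.reset_index(drop=True)
        self.canvas = canvas
        self._filters: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.params)

    def cell(self, i: int) -> GaborParams:
        r = self.params.iloc[i]
        return GaborParams(r.theta, r.sigma, r.wavelength, r.gamma, r.omega,
                           (r.x0, r.y0))

    def filter_matrix(self) -> np.ndarray:
        """(n_cells, n_pixels) stack of flattened unit-norm filters (cached).

        Filters are normalized to unit energy so that responses are in
        stimulus-contrast units, making the mean-scaled noise model
        comparable across cells of different envelope size.
        """
        if self._filters is None:
            h, w = self.canvas.shape
            out = np.empty((len(self), h * w), dtype=np.float32)
            for i in range(len(self)):
                g = gabor_image(self.cell(i), self.canvas).ravel()
                out[i] = g / np.linalg.norm(g)
            self._filters = out
        return self._filters

    def metadata(self) -> pd.DataFrame:
        meta = self.params.copy()
        meta["model"] = "ln_gabor"
        return meta


def sample_population(n_neurons: int,
                      center_extent_deg: tuple[float, float, float, float]
                      = (-22.5, 22.5, -10.5, 10.5),
                      seed: int = 0,
                      canvas: CanvasGeometry | None = None) -> GaborPopulation:
    """Sample model cells i.i.d. from the uniform parameter ranges.

    Centers are uniform over ``center_extent_deg`` (az_min, az_max, el_min,
    el_max), by default the span of the canonical 16 x 8 position grid.
    """
    if n_neurons <= 0:
        raise ValueError("n_neurons must be positive")
    rng = np.random.default_rng(seed)
    az0, az1, el0, el1 = center_extent_deg
    params = pd.DataFrame({
        "theta": rng.uniform(0.0, np.pi, n_neurons),
        "sigma": rng.uniform(*SIGMA_RANGE, n_neurons),
        "wavelength": 1.0 / rng.uniform(*FREQ_RANGE_CPD, n_neurons),
        "gamma": np.ones(n_neurons),
        "omega": rng.uniform(0.0, np.pi, n_neurons),
        "x0": rng.uniform(az0, az1, n_neurons),
        "y0": rng.uniform(el0, el1, n_neurons),
    })
    return GaborPopulation(params, canvas if canvas is not None
                           else CanvasGeometry())


def _frame_matrix(movie: StimulusMovie) -> np.ndarray:
    """(n_pixels, n_frames) mean-subtracted frames."""
    t, h, w = movie.frames.shape
    return (movie.frames.reshape(t, h * w).T - np.float32(0.5))


def ln_response(params: GaborParams, movie: StimulusMovie,
                unit_norm: bool = True) -> float:
    """Feedforward LN rate: rectified filter dot per frame, frame-averaged.

    With ``unit_norm`` (the population convention) the filter is scaled to
    unit energy, putting responses in stimulus-contrast units.
    """
    g = gabor_image(params, movie.canvas).ravel()
    if unit_norm:
        g = g / np.linalg.norm(g)
    drive = g @ _frame_matrix(movie)
    return float(np.maximum(drive, 0.0).mean())


def population_ln_responses(population: GaborPopulation,
                            movie: StimulusMovie,
                            per_frame: bool = False) -> np.ndarray:
    """Vectorized LN rates for all cells; (n_cells,) or (n_cells, n_frames)."""
    drive = population.filter_matrix() @ _frame_matrix(movie)
    rect = np.maximum(drive, 0.0)
    return rect if per_frame else rect.mean(axis=1)


# ---------------------------------------------------------------------------
# Divisive surround
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurroundParams:
    """Divisive center-surround normalization parameters."""

    beta: float = 0.95
    inner_radius_sigma: float = 2.0
    outer_radius_sigma: float = 5.0
    n_cell_types: int = 100
    seed: int = 1234
    #: block size (pixels) for spatially pooling energy maps before the
    #: region averages; the regions are discs several degrees across, so
    #: modest pooling changes rho negligibly while bounding compute
    pool_px: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta < 1.0:
            raise ValueError("beta must lie in [0, 1)")
        if self.inner_radius_sigma >= self.outer_radius_sigma:
            raise ValueError("inner radius must be smaller than outer radius")


class OrientationEnergyBank:
    """Bank of oriented cell types used to measure local orientation energy.

    The 100 types tile orientation and spatial frequency: ``n_orientations``
    evenly spaced on [0, pi) crossed with ``n_frequencies`` log-spaced bands
    over the model frequency range, each a unit-norm Gabor with envelope
    width half its wavelength (about an octave of bandwidth).  Energies are
    the rectified outputs of each kernel correlated with the frame at every
    position.  Matched gain within an orientation ring is what lets the
    center-surround energy correlation pick up orientation (mis)matches
    rather than overall responsiveness differences between cell types.
    """

    def __init__(self, canvas: CanvasGeometry, n_types: int = 100,
                 seed: int = 1234, n_orientations: int | None = None):
        self.canvas = canvas
        self.n_types = n_types
        n_ori = n_orientations if n_orientations is not None \
            else max(n_types // 5, 1)
        n_freq = max(n_types // n_ori, 1)
        self.n_orientations = n_ori
        self.n_frequencies = n_freq
        self.n_types = n_ori * n_freq
        h, w = canvas.shape
        self._kernel_fft = np.empty((self.n_types, h, w // 2 + 1),
                                    dtype=np.complex64)
        freqs = np.logspace(np.log10(FREQ_RANGE_CPD[0]),
                            np.log10(FREQ_RANGE_CPD[1]), n_freq)
        k = 0
        for f in freqs:
            for theta in np.arange(n_ori) * np.pi / n_ori:
                p = GaborParams(theta=theta, sigma=0.5 / f,
                                wavelength=1.0 / f, omega=0.0)
                kern = gabor_image(p, canvas)
                kern /= np.linalg.norm(kern)
                self._kernel_fft[k] = np.conj(
                    np.fft.rfft2(np.fft.ifftshift(kern)))
                k += 1

    def energy_maps(self, frame: np.ndarray) -> np.ndarray:
        """(n_types, H, W) rectified filter outputs at every position."""
        f = np.fft.rfft2(frame - 0.5)
        maps = np.fft.irfft2(f[None, :, :] * self._kernel_fft,
                             s=frame.shape)
        return np.maximum(maps, 0.0)


def _pooled_axes(canvas: CanvasGeometry, pool: int
                 ) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Azimuth/elevation of pooled-block centers and pooled dimensions."""
    h, w = canvas.shape
    hp, wp = h // pool, w // pool
    az = canvas.azimuth_of_columns()[:wp * pool].reshape(wp, pool).mean(axis=1)
    el = canvas.elevation_of_rows()[:hp * pool].reshape(hp, pool).mean(axis=1)
    return az, el, hp, wp


def _pool_maps(maps: np.ndarray, pool: int) -> np.ndarray:
    """Block-average (K, H, W) maps to (K, H//pool * W//pool)."""
    k, h, w = maps.shape
    hp, wp = h // pool, w // pool
    pooled = maps[:, :hp * pool, :wp * pool].reshape(k, hp, pool, wp, pool)
    return pooled.mean(axis=(2, 4)).reshape(k, hp * wp)


def _region_masks(population: GaborPopulation,
                  surround: SurroundParams) -> tuple[sparse.csc_matrix,
                                                     sparse.csc_matrix]:
    """Column-normalized (n_pooled_pixels, n_cells) center/annulus masks."""
    az, el, hp, wp = _pooled_axes(population.canvas, surround.pool_px)
    azg = az[None, :]
    elg = el[:, None]
    x0 = population.params["x0"].to_numpy()
    y0 = population.params["y0"].to_numpy()
    sigma = population.params["sigma"].to_numpy()
    cols_in, cols_out = [], []
    for i in range(len(population)):
        dist = np.hypot(azg - x0[i], elg - y0[i]).ravel()
        inner = dist < surround.inner_radius_sigma * sigma[i]
        outer = (~inner) & (dist < surround.outer_radius_sigma * sigma[i])
        cols_in.append(inner / max(inner.sum(), 1))
        cols_out.append(outer / max(outer.sum(), 1))
    m_in = sparse.csc_matrix(np.column_stack(cols_in))
    m_out = sparse.csc_matrix(np.column_stack(cols_out))
    return m_in, m_out


def _pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation of two (K, N) matrices; NaN where
    either column has zero variance."""
    a = a - a.mean(axis=0, keepdims=True)
    b = b - b.mean(axis=0, keepdims=True)
    num = (a * b).sum(axis=0)
    den = np.sqrt((a ** 2).sum(axis=0) * (b ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = num / den
    rho[den == 0] = np.nan
    return rho


def surround_rho(frame: np.ndarray, population: GaborPopulation,
                 surround: SurroundParams,
                 bank: OrientationEnergyBank | None = None,
                 masks: tuple[sparse.csc_matrix, sparse.csc_matrix] | None = None
                 ) -> np.ndarray:
    """Center-surround orientation-energy correlation per cell (may be NaN)."""
    if bank is None:
        bank = OrientationEnergyBank(population.canvas,
                                     surround.n_cell_types, surround.seed)
    if masks is None:
        masks = _region_masks(population, surround)
    m_in, m_out = masks
    energy = _pool_maps(bank.energy_maps(frame), surround.pool_px)
    v_in = _ring_normalize(np.asarray(energy @ m_in), bank)
    v_out = _ring_normalize(np.asarray(energy @ m_out), bank)
    return _pearson_columns(v_in, v_out)


def _ring_normalize(v: np.ndarray, bank: OrientationEnergyBank) -> np.ndarray:
    """Normalize each frequency ring of energies by its mean per cell.

    Overall energy falls steeply with spatial frequency (1/f input spectra),
    which would let the shared frequency profile dominate the center-surround
    correlation; dividing each ring by its mean leaves the orientation
    profile, which is what rho is meant to compare.
    """
    k, n = v.shape
    rings = v.reshape(bank.n_frequencies, bank.n_orientations, n)
    means = rings.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(means > 0, rings / means, 0.0)
    return out.reshape(k, n)


def surround_modulate(feedforward_rate: np.ndarray | float,
                      frame: np.ndarray,
                      population: GaborPopulation,
                      surround: SurroundParams,
                      bank: OrientationEnergyBank | None = None,
                      masks=None) -> tuple[np.ndarray, np.ndarray]:
    """Divisive surround: rate / (1 + beta * rho).

    Returns (modulated rates, rho).  Cells whose energy vectors have zero
    variance (rho undefined) keep their feedforward rate; their rho is NaN.
    """
    rho = surround_rho(frame, population, surround, bank, masks)
    ff = np.asarray(feedforward_rate, dtype=float)
    denom = 1.0 + surround.beta * np.where(np.isnan(rho), 0.0, rho)
    return ff / denom, rho


# ---------------------------------------------------------------------------
# Noise model and response container
# ---------------------------------------------------------------------------

@dataclass
class ResponseMatrix:
    """neurons x trials response array with aligned metadata tables."""

    responses: np.ndarray
    neurons: pd.DataFrame
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        n, t = self.responses.shape
        if len(self.neurons) != n:
            raise ValueError("neuron metadata length mismatch")
        if len(self.trials) != t:
            raise ValueError("trial table length mismatch")
        if np.any(self.responses < 0):
            raise ValueError("responses must be nonnegative")

    @property
    def n_neurons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_trials(self) -> int:
        return self.responses.shape[1]


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise with variance ``noise_factor * popmean``.

    ``popmean`` is the mean response over all neurons and all trials within
    each condition (``pop_mean_scope='condition'``), or over the whole
    session (``'session'``).
    """

    noise_factor: float = 2.0
    pop_mean_scope: Literal["condition", "session"] = "condition"

    def __post_init__(self) -> None:
        if self.noise_factor < 0:
            raise ValueError("noise_factor must be nonnegative")


def add_noise(responses: ResponseMatrix, model: NoiseModel,
              seed: int = 0) -> ResponseMatrix:
    """Apply the noise model; rectifies at zero.  Identity at factor 0."""
    if model.noise_factor == 0:
        return responses
    rng = np.random.default_rng(seed)
    out = responses.responses.astype(float).copy()
    if model.pop_mean_scope == "condition":
        groups = responses.trials.groupby("condition").indices.items()
    else:
        groups = [("all", np.arange(responses.n_trials))]
    for _, idx in groups:
        idx = np.asarray(idx)
        popmean = out[:, idx].mean()
        sd = np.sqrt(model.noise_factor * max(popmean, 0.0))
        out[:, idx] += rng.normal(0.0, sd, size=(out.shape[0], idx.size))
    np.maximum(out, 0.0, out=out)
    return ResponseMatrix(out, responses.neurons, responses.trials)


# ---------------------------------------------------------------------------
# Ideal-cell archetypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchetypeSpec:
    """Schematic response rules for idealized segmentation cells.

    * ``figure_cell`` — fires iff any part of the figure covers its RF disc.
    * ``border_cell`` — fires iff a figure border of the preferred
      orientation crosses the RF disc with the figure on the preferred side.
    * ``on_simple_cell`` — rectified ON-center Gaussian kernel response
      (phase/texture dependent).
    """

    kind: Literal["figure_cell", "border_cell", "on_simple_cell"]
    rf_center: tuple[float, float] = (0.0, 0.0)
    rf_size: float = 4.0  # disc radius, degrees
    preferred_border_orientation: Literal["vertical", "horizontal"] = "vertical"
    preferred_side: Literal["left", "right", "above", "below"] = "left"

    def __post_init__(self) -> None:
        if self.kind not in ("figure_cell", "border_cell", "on_simple_cell"):
            raise ValueError(f"unknown archetype kind {self.kind!r}")
        if self.rf_size <= 0:
            raise ValueError("rf_size must be positive")


def _segment_point_distance(p: np.ndarray, a: np.ndarray,
                            b: np.ndarray) -> float:
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


def archetype_response(spec: ArchetypeSpec, figure_center: tuple[float, float],
                       figure_size_deg: float,
                       movie: StimulusMovie | None = None) -> float:
    """Response of an archetype cell to a figure at the given position."""
    cx, cy = figure_center
    half = figure_size_deg / 2.0
    p = np.asarray(spec.rf_center, dtype=float)
    if spec.kind == "figure_cell":
        # distance from RF center to the figure rectangle
        dx = max(abs(p[0] - cx) - half, 0.0)
        dy = max(abs(p[1] - cy) - half, 0.0)
        return 1.0 if np.hypot(dx, dy) <= spec.rf_size else 0.0
    if spec.kind == "border_cell":
        corners = {
            "left_edge": (np.array([cx - half, cy - half]),
                          np.array([cx - half, cy + half])),
            "right_edge": (np.array([cx + half, cy - half]),
                           np.array([cx + half, cy + half])),
            "top_edge": (np.array([cx - half, cy + half]),
                         np.array([cx + half, cy + half])),
            "bottom_edge": (np.array([cx - half, cy - half]),
                            np.array([cx + half, cy - half])),
        }
        if spec.preferred_border_orientation == "vertical":
            # the figure is left of its right edge and right of its left edge
            edge = "right_edge" if spec.preferred_side == "left" else "left_edge"
        else:
            edge = "top_edge" if spec.preferred_side == "below" else "bottom_edge"
        a, b = corners[edge]
        return 1.0 if _segment_point_distance(p, a, b) <= spec.rf_size else 0.0
    # on_simple_cell: needs the rendered movie
    if movie is None:
        raise ValueError("on_simple_cell archetypes require the movie")
    canvas = movie.canvas
    az = canvas.azimuth_of_columns()[None, :] - spec.rf_center[0]
    el = canvas.elevation_of_rows()[:, None] - spec.rf_center[1]
    kern = np.exp(-(az ** 2 + el ** 2) / (2.0 * (spec.rf_size / 2.0) ** 2))
    kern = (kern / kern.sum()).astype(np.float32).ravel()
    drive = kern @ _frame_matrix(movie)
    return float(np.maximum(drive, 0.0).mean())


def make_archetype_cells(specs: Sequence[ArchetypeSpec]) -> list[ArchetypeSpec]:
    """Validate a list of archetype specs (validation happens on construction)."""
    return list(specs)


# ---------------------------------------------------------------------------
# Session simulation
# ---------------------------------------------------------------------------

def _representative_frame(movie: StimulusMovie) -> np.ndarray:
    """Frame at maximal figure-background relative displacement.

    rho measures the static center-surround texture relationship, which is
    essentially invariant to the small within-trial displacements, so a
    single frame per trial suffices for the surround term.
    """
    rel = np.abs(movie.relative_disp_deg())
    return movie.frames[int(np.argmax(rel))].astype(float)


def simulate_session(population: GaborPopulation | Sequence[ArchetypeSpec],
                     session: FigureMapSession,
                     surround: SurroundParams | None = None,
                     noise: NoiseModel | None = None,
                     seed: int = 0) -> ResponseMatrix:
    """Run a population through every trial of a figure-map session.

    Responses to the repeats of a (condition, variant, position) stimulus
    are identical before noise; noise (if any) is drawn per trial.
    Deterministic under ``seed``.
    """
    keys = session.unique_keys()
    key_index = {k: i for i, k in enumerate(keys)}
    if isinstance(population, GaborPopulation):
        if population.canvas != session.canvas:
            raise ValueError("population and session use different canvases")
        n = len(population)
        filters = population.filter_matrix()
        bank = masks = None
        if surround is not None:
            bank = OrientationEnergyBank(population.canvas,
                                         surround.n_cell_types, surround.seed)
            masks = _region_masks(population, surround)
        unique = np.empty((n, len(keys)))
        rho_cache: dict[tuple, np.ndarray] = {}
        for j, key in enumerate(keys):
            movie = session.render_unique(*key)
            rates = np.maximum(filters @ _frame_matrix(movie), 0.0).mean(axis=1)
            if surround is not None:
                # rho depends on the texture relationship at maximal
                # figure-ground separation, not on which oscillation branch
                # the trial sampled, so it is shared across phase branches
                stim = key[:4]
                if stim not in rho_cache:
                    rho_cache[stim] = surround_rho(
                        _representative_frame(movie), population, surround,
                        bank, masks)
                rho = rho_cache[stim]
                rates = rates / (1.0 + surround.beta
                                 * np.where(np.isnan(rho), 0.0, rho))
            unique[:, j] = rates
            session.clear_cache()
        neurons = population.metadata()
    else:
        specs = make_archetype_cells(population)
        n = len(specs)
        unique = np.empty((n, len(keys)))
        for j, (cond, var, az, el, phase) in enumerate(keys):
            center = (session.grid.azimuth_of_bin(az),
                      session.grid.elevation_of_bin(el))
            size = session.specs[(cond, var)].figure_size_deg
            movie = None
            if any(s.kind == "on_simple_cell" for s in specs):
                movie = session.render_unique(cond, var, az, el, phase)
            unique[:, j] = [archetype_response(s, center, size, movie)
                            for s in specs]
            session.clear_cache()
        neurons = pd.DataFrame([{
            "model": "archetype", "kind": s.kind, "x0": s.rf_center[0],
            "y0": s.rf_center[1], "rf_size": s.rf_size,
        } for s in specs])

    trial_keys = [key_index[(r.condition, r.variant, r.az_bin, r.el_bin,
                             r.motion_phase)]
                  for r in session.trials.itertuples(index=False)]
    result = ResponseMatrix(unique[:, trial_keys], neurons,
                            session.trials.copy())
    if noise is not None:
        result = add_noise(result, noise, seed)
    return result
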