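"""Figure-ground movie synthesis with opponent (counterphase) motion.

A trial movie contains a square texture *figure* translating over a texture
*background*; by default both move with equal and opposite sinusoidal
displacement (amplitude 3.5 degrees, 1 cycle/s).  Because the figure is an
opaque patch pasted over the background, background texture is revealed at
its trailing edge and hidden at its leading edge (accretion-deletion), the
segmentation cue the five texture conditions manipulate:

* ``Cross`` — figure grating orthogonal to the background grating.
* ``Iso`` — same-orientation grating.  By default the figure patch is cut
  from the background grating itself, so at zero relative displacement the
  figure is invisible and the figure-ground phase difference is created by
  the opponent motion (the construction used for the neural recordings);
  passing ``static_phase_offset`` instead builds the behavioral variant
  whose figure grating carries a fixed phase offset and is visible in
  static frames.
* ``Nat`` — figure cut from the *same* 1/f texture that defines the
  background, so with zero relative displacement the figure is invisible and
  only motion defines it.
* ``CrossTex`` — figure patch is the background texture crop rotated 90
  degrees (texture analogue of Cross).
* ``IsoTex`` — figure patch is a displaced crop of the background texture
  (texture analogue of Iso: same orientation content, offset sample).

Rendering convention: the background, shifted by its displacement, is drawn
first; the figure patch (rigidly carrying its own texture) is pasted over it
at the displaced figure location.  Displacements are rounded to whole canvas
pixels so that the Nat condition is bit-exactly invisible at zero offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .geometry import CanvasGeometry
from .textures import TextureSpec, make_texture

__all__ = [
    "Condition",
    "MotionSpec",
    "FigureGroundSpec",
    "StimulusMovie",
    "condition_spec",
    "render_trial_movie",
    "make_morph_stimulus",
    "make_static_frame",
]

Condition = Literal["Cross", "Iso", "Nat", "CrossTex", "IsoTex"]
CONDITIONS: tuple[str, ...] = ("Cross", "Iso", "Nat", "CrossTex", "IsoTex")

#: Figure square side used throughout the neural experiments (degrees).
DEFAULT_FIGURE_SIZE_DEG = 27.0


@dataclass(frozen=True)
class MotionSpec:
    """Sinusoidal displacement of figure and background.

    ``amplitude_deg`` is the half-range of each trace (3.5 degrees, i.e.
    14 movie pixels, in the source experiments).  With ``counterphase`` the
    background trace is the negative of the figure trace; with
    ``background_static`` only the figure moves.
    """

    amplitude_deg: float = 3.5
    temporal_freq_hz: float = 1.0
    counterphase: bool = True
    background_static: bool = False

    def __post_init__(self) -> None:
        if self.amplitude_deg < 0:
            raise ValueError("amplitude_deg must be nonnegative")
        if self.temporal_freq_hz <= 0:
            raise ValueError("temporal_freq_hz must be positive")
        if self.counterphase and self.background_static:
            raise ValueError("counterphase and background_static are mutually "
                             "exclusive")

    def displacement_traces(self, n_frames: int, frame_rate_hz: float,
                            phase0: float = 0.0
                            ) -> tuple[np.ndarray, np.ndarray]:
        """(figure, background) displacement in degrees at each frame time.

        ``phase0`` (radians) is the oscillation phase at the first frame;
        in a session the oscillation clock runs continuously while the
        figure jumps between positions, so trials start at different phases.
        """
        t = np.arange(n_frames) / frame_rate_hz
        s = self.amplitude_deg * np.sin(
            2 * np.pi * self.temporal_freq_hz * t + phase0)
        if self.background_static:
            return s, np.zeros_like(s)
        if self.counterphase:
            return s, -s
        return s, s


@dataclass(frozen=True)
class FigureGroundSpec:
    """Full description of one figure-ground trial stimulus."""

    condition: str
    variant: int
    figure_center_deg: tuple[float, float]  # (azimuth, elevation)
    figure_size_deg: float = DEFAULT_FIGURE_SIZE_DEG
    background: TextureSpec = field(
        default_factory=lambda: TextureSpec("grating", orientation_deg=45.0))
    figure: TextureSpec | None = None
    motion: MotionSpec = field(default_factory=MotionSpec)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.variant not in (1, 2):
            raise ValueError("variant must be 1 or 2")
        if self.figure_size_deg <= 0:
            raise ValueError("figure_size_deg must be positive")
        if self.condition in ("Nat", "CrossTex", "IsoTex") and self.figure is not None:
            raise ValueError(f"{self.condition} derives the figure patch from "
                             "the background texture; figure must be None")
        if self.condition == "Cross" and self.figure is None:
            raise ValueError("Cross requires an explicit figure texture")

    def at_position(self, azimuth_deg: float,
                    elevation_deg: float) -> "FigureGroundSpec":
        return replace(self, figure_center_deg=(azimuth_deg, elevation_deg))

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)


def condition_spec(condition: str, variant: int,
                   figure_center_deg: tuple[float, float] = (0.0, 0.0),
                   figure_size_deg: float = DEFAULT_FIGURE_SIZE_DEG,
                   motion: MotionSpec | None = None,
                   grating_orientations: tuple[float, float] = (45.0, 135.0),
                   spatial_freq_cpd: float = 0.06,
                   nat_seeds: tuple[int, int] = (11, 23),
                   static_phase_offset: float | None = None) -> FigureGroundSpec:
    """Build the canonical spec for one of the condition-variant stimuli.

    Grating conditions use 0.06 cpd gratings at 45 or 135 degrees (the two
    variants); Nat/CrossTex/IsoTex variants select one of two fixed 1/f
    texture seeds, mirroring the two fixed naturalistic textures used per
    session in the source experiments.  For Iso, ``static_phase_offset``
    (radians) builds the behavioral variant with a fixed figure-ground phase
    offset; the default (None) is the motion-defined pop-out construction.
    """
    if variant not in (1, 2):
        raise ValueError("variant must be 1 or 2")
    motion = motion if motion is not None else MotionSpec()
    if condition in ("Cross", "Iso"):
        bg_ori = grating_orientations[variant - 1]
        background = TextureSpec("grating", orientation_deg=bg_ori,
                                 spatial_freq_cpd=spatial_freq_cpd)
        if condition == "Cross":
            figure = replace(background,
                             orientation_deg=(bg_ori + 90.0) % 180.0)
        elif static_phase_offset is not None:
            figure = replace(background,
                             phase=background.phase + static_phase_offset)
        else:
            figure = None
        return FigureGroundSpec(condition, variant, figure_center_deg,
                                figure_size_deg, background, figure, motion)
    if condition in ("Nat", "CrossTex", "IsoTex"):
        background = TextureSpec("pink_noise", seed=nat_seeds[variant - 1])
        return FigureGroundSpec(condition, variant, figure_center_deg,
                                figure_size_deg, background, None, motion)
    raise ValueError(f"unknown condition {condition!r}")


@dataclass
class StimulusMovie:
    """Rendered movie plus per-frame figure/background displacements.

    ``figure_disp_deg`` / ``background_disp_deg`` are the ideal (continuous)
    traces; ``figure_disp_px`` / ``background_disp_px`` are the integer pixel
    shifts actually rendered.
    """

    frames: np.ndarray  # (T, H, W) float32 in [0, 1]
    frame_rate_hz: float
    figure_disp_deg: np.ndarray
    background_disp_deg: np.ndarray
    figure_disp_px: np.ndarray
    background_disp_px: np.ndarray
    spec: FigureGroundSpec | None
    canvas: CanvasGeometry

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def relative_disp_deg(self) -> np.ndarray:
        return self.figure_disp_deg - self.background_disp_deg


def _figure_patch(condition: str, bg_full: np.ndarray, fig_full: np.ndarray | None,
                  top: int, left: int, side: int) -> np.ndarray:
    """Texture content carried rigidly by the figure."""
    if fig_full is not None:  # Cross, or Iso with a static phase offset
        return fig_full[top:top + side, left:left + side]
    crop = bg_full[top:top + side, left:left + side]
    if condition in ("Nat", "Iso"):
        return crop
    if condition == "CrossTex":
        return np.rot90(crop)
    if condition == "IsoTex":
        # Offset sample of the same texture: same orientation content,
        # different local phase -- texture analogue of the Iso phase offset.
        return bg_full[top + side // 2:top + 3 * side // 2,
                       left:left + side]
    raise ValueError(condition)


def render_trial_movie(spec: FigureGroundSpec, canvas: CanvasGeometry,
                       duration_s: float = 0.25,
                       frame_rate_hz: float = 56.0,
                       background_only: bool = False,
                       motion_phase: float = 0.0) -> StimulusMovie:
    """Render one figure-ground trial.

    The default 0.25 s at 56 Hz yields the 14 frames per trial used for
    model filtering.  With ``background_only`` the figure patch is not
    pasted, giving the no-figure control movie over the *same* texture
    sample (in the Nat condition the two are bit-identical at zero relative
    displacement).  Raises ``ValueError`` if the figure square would leave
    the canvas at any displacement.
    """
    n_frames = max(1, int(round(duration_s * frame_rate_hz)))
    fig_deg, bg_deg = spec.motion.displacement_traces(n_frames, frame_rate_hz,
                                                      motion_phase)
    ppd = canvas.px_per_deg
    fig_px = np.round(fig_deg * ppd).astype(int)
    bg_px = np.round(bg_deg * ppd).astype(int)
    pad = int(np.ceil(spec.motion.amplitude_deg * ppd)) + 1

    h, w = canvas.shape
    side = int(round(spec.figure_size_deg * ppd))
    row_c, col_c = canvas.pixel_of(*spec.figure_center_deg)
    top = int(round(row_c - (side - 1) / 2.0))
    left = int(round(col_c - (side - 1) / 2.0))
    if (top < 0 or left + fig_px.min() < 0 or top + side > h
            or left + side + fig_px.max() > w):
        raise ValueError("figure rectangle leaves the canvas at some "
                         "displacement; enlarge the canvas or move the figure")

    pad_shape = (h + side, w + 2 * pad + side)  # room for IsoTex offset crop
    bg_full = make_texture(spec.background.with_size(pad_shape), canvas)
    fig_full = None
    if spec.figure is not None:
        fig_full = make_texture(spec.figure.with_size(pad_shape), canvas)
    patch = _figure_patch(spec.condition, bg_full, fig_full,
                          top, left + pad, side).astype(np.float32)

    frames = np.empty((n_frames, h, w), dtype=np.float32)
    for k in range(n_frames):
        frame = bg_full[:h, pad - bg_px[k]:pad - bg_px[k] + w].astype(np.float32)
        if not background_only:
            lk = left + fig_px[k]
            frame[top:top + side, lk:lk + side] = patch
        frames[k] = frame
    return StimulusMovie(frames, frame_rate_hz, fig_deg, bg_deg,
                         fig_px, bg_px, spec, canvas)


def make_morph_stimulus(stage: int, grating: TextureSpec, noise: TextureSpec,
                        canvas: CanvasGeometry,
                        figure_size_deg: float = DEFAULT_FIGURE_SIZE_DEG,
                        motion: MotionSpec | None = None,
                        duration_s: float = 1.0, frame_rate_hz: float = 28.0,
                        seed: int = 0) -> StimulusMovie:
    """Grating-to-noise morph used to shape the motion strategy.

    The texture at stage ``s`` is the pixel-wise blend
    ``(1 - s/10) * grating + (s/10) * noise`` (stage 10 is pure noise).  The
    figure patch is the blended texture flipped vertically, and is placed at
    one of three heights (top / middle / down) chosen by ``seed``.
    """
    if not 1 <= stage <= 10:
        raise ValueError("morph stage must lie in 1..10")
    w_noise = stage / 10.0
    motion = motion if motion is not None else MotionSpec()
    rng = np.random.default_rng(seed)
    elevation = float(rng.choice([canvas.height_deg / 4.0, 0.0,
                                  -canvas.height_deg / 4.0]))
    n_frames = max(1, int(round(duration_s * frame_rate_hz)))
    fig_deg, bg_deg = motion.displacement_traces(n_frames, frame_rate_hz)
    ppd = canvas.px_per_deg
    fig_px = np.round(fig_deg * ppd).astype(int)
    bg_px = np.round(bg_deg * ppd).astype(int)
    pad = int(np.ceil(motion.amplitude_deg * ppd)) + 1

    h, w = canvas.shape
    side = int(round(figure_size_deg * ppd))
    row_c, col_c = canvas.pixel_of(0.0, elevation)
    top = int(np.clip(round(row_c - (side - 1) / 2.0), 0, h - side))
    left = int(round(col_c - (side - 1) / 2.0))

    pad_shape = (h, w + 2 * pad)
    g = make_texture(grating.with_size(pad_shape), canvas)
    n = make_texture(noise.with_size(pad_shape), canvas)
    blend = (1.0 - w_noise) * g + w_noise * n
    patch = np.flipud(blend[top:top + side,
                            left + pad:left + pad + side]).astype(np.float32)

    frames = np.empty((n_frames, h, w), dtype=np.float32)
    for k in range(n_frames):
        frame = blend[:, pad - bg_px[k]:pad - bg_px[k] + w].astype(np.float32)
        lk = left + fig_px[k]
        frame[top:top + side, lk:lk + side] = patch
        frames[k] = frame
    spec = None  # morph stimuli are outside the five-condition taxonomy
    return StimulusMovie(frames, frame_rate_hz, fig_deg, bg_deg,
                         fig_px, bg_px, spec, canvas)


def make_static_frame(movie: StimulusMovie) -> np.ndarray:
    """Frame with the largest figure-background phase difference.

    Returns the earliest frame maximizing the absolute relative displacement
    (for a counterphase sine of amplitude A this is the 2A extremum); with
    zero motion amplitude every frame ties and the first is returned.
    """
    if movie.n_frames == 0:
        raise ValueError("empty movie")
    rel = np.abs(movie.relative_disp_deg())
    return movie.frames[int(np.argmax(rel))]
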