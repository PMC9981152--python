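"""Texture synthesis: sinusoidal gratings and 1/f (pink) noise fields.

All textures are luminance images in [0, 1] with mean ~0.5; contrast math is
done in this range and 8-bit quantization happens only on file export.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .geometry import CanvasGeometry

__all__ = ["TextureSpec", "make_texture", "grating_image", "pink_noise_image"]


@dataclass(frozen=True)
class TextureSpec:
    """Parameters of a single texture sample.

    ``orientation_deg`` follows the grating convention that 0 degrees varies
    along azimuth (vertical stripes); orientations live on [0, 180).
    ``spatial_freq_cpd`` is in cycles per degree of visual angle.  For
    ``pink_noise`` only ``seed``, ``size_px`` and ``contrast`` matter; the
    amplitude spectrum is radially proportional to 1/f up to Nyquist.
    """

    kind: Literal["grating", "pink_noise"]
    orientation_deg: float = 0.0
    spatial_freq_cpd: float = 0.06
    phase: float = 0.0
    seed: int = 0
    size_px: tuple[int, int] | None = None
    contrast: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("grating", "pink_noise"):
            raise ValueError(f"unknown texture kind {self.kind!r}")
        if self.spatial_freq_cpd <= 0:
            raise ValueError("spatial_freq_cpd must be positive")
        if not 0.0 <= self.orientation_deg < 180.0:
            raise ValueError("orientation_deg must lie in [0, 180)")
        if not 0.0 < self.contrast <= 1.0:
            raise ValueError("contrast must lie in (0, 1]")

    def with_size(self, size_px: tuple[int, int]) -> "TextureSpec":
        return replace(self, size_px=size_px)


def grating_image(size_px: tuple[int, int], orientation_deg: float,
                  spatial_freq_cpd: float, phase: float,
                  px_per_deg: float, contrast: float = 1.0) -> np.ndarray:
    """Sinusoidal grating, cosine convention.

    Pixel (0, 0) is the image origin; the grating is
    ``0.5 + (contrast/2) cos(2 pi f (x cos(theta) + y sin(theta)) + phase)``
    with x, y in degrees, so orientation 0 and phase 0 gives luminance 1.0
    at x = 0.
    """
    h, w = size_px
    if h <= 0 or w <= 0:
        raise ValueError("texture size must be positive")
    x = np.arange(w) / px_per_deg
    y = np.arange(h) / px_per_deg
    xx, yy = np.meshgrid(x, y)
    theta = np.deg2rad(orientation_deg)
    carrier = np.cos(2 * np.pi * spatial_freq_cpd
                     * (xx * np.cos(theta) + yy * np.sin(theta)) + phase)
    return 0.5 + 0.5 * contrast * carrier


def pink_noise_image(size_px: tuple[int, int], seed: int,
                     contrast: float = 1.0, rms_contrast: float = 0.18,
                     clip_sigma: float = 2.5) -> np.ndarray:
    """Naturalistic noise with radial amplitude spectrum proportional to 1/f.

    The field has an *exact* 1/|f| amplitude spectrum with randomized phases
    (DC set to zero): white Gaussian noise supplies the phases and the
    amplitudes are replaced by the 1/f envelope.  The result is
    standardized, scaled to ``rms_contrast * contrast`` about a 0.5 mean and
    clipped at ``clip_sigma`` standard deviations so values stay inside
    [0, 1] without distorting the spectrum appreciably.
    """
    h, w = size_px
    if h <= 0 or w <= 0:
        raise ValueError("texture size must be positive")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((h, w))
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.hypot(fy, fx)
    envelope = np.zeros_like(f)
    nonzero = f > 0
    envelope[nonzero] = 1.0 / f[nonzero]
    spectrum = np.fft.fft2(white)
    mag = np.abs(spectrum)
    phases = np.divide(spectrum, mag, out=np.ones_like(spectrum),
                       where=mag > 0)
    field = np.fft.ifft2(phases * envelope).real
    field -= field.mean()
    field /= field.std()
    field = np.clip(field, -clip_sigma, clip_sigma)
    img = 0.5 + rms_contrast * contrast * field
    return np.clip(img, 0.0, 1.0)


def make_texture(spec: TextureSpec, geometry: CanvasGeometry) -> np.ndarray:
    """Render a texture sample on the canvas raster.

    Returns an image of ``spec.size_px`` (defaults to the canvas shape) with
    values in [0, 1] and mean ~0.5.
    """
    size = spec.size_px if spec.size_px is not None else geometry.shape
    if spec.kind == "grating":
        return grating_image(size, spec.orientation_deg, spec.spatial_freq_cpd,
                             spec.phase, geometry.px_per_deg, spec.contrast)
    return pink_noise_image(size, spec.seed, spec.contrast)


def spectral_energy_fraction_below(image: np.ndarray, cutoff_cpd: float,
                                   px_per_deg: float,
                                   include_dc: bool = False) -> float:
    """Fraction of spectral power below a spatial-frequency cutoff.

    A diagnostic for acuity arguments (e.g. how much of a texture's energy
    falls under a species' peak contrast-sensitivity frequency).  Power is
    |FFT|^2 integrated radially in 2D; the DC term is excluded by default.
    The result depends on conventions (DC handling, 2D radial vs 1D
    integration), so this is reported, never asserted.
    """
    img = np.asarray(image, dtype=float)
    power = np.abs(np.fft.fft2(img)) ** 2
    h, w = img.shape
    fy = np.fft.fftfreq(h)[:, None] * px_per_deg
    fx = np.fft.fftfreq(w)[None, :] * px_per_deg
    f = np.hypot(fy, fx)
    if not include_dc:
        power = power.copy()
        power[0, 0] = 0.0
    total = power.sum()
    if total == 0:
        raise ValueError("image has no spectral power")
    return float(power[f < cutoff_cpd].sum() / total)


def radial_amplitude_slope(image: np.ndarray, n_bins: int = 20) -> float:
    """Log-log slope of the radially averaged amplitude spectrum.

    A 1/f field should return approximately -1.  Used as a diagnostic and in
    spectral property tests.
    """
    img = image - image.mean()
    amp = np.abs(np.fft.fft2(img))
    h, w = img.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.hypot(fy, fx).ravel()
    a = amp.ravel()
    keep = (f > 0) & (f <= 0.5)
    f, a = f[keep], a[keep]
    edges = np.logspace(np.log10(f.min()), np.log10(0.5), n_bins + 1)
    which = np.digitize(f, edges) - 1
    centers, means = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() >= 4:
            centers.append(np.sqrt(edges[b] * edges[b + 1]))
            means.append(a[sel].mean())
    slope = np.polyfit(np.log10(centers), np.log10(means), 1)[0]
    return float(slope)
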