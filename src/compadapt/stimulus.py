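"""Spatial stimulus synthesis: gratings, plaids, and chevron contours.

All geometry is expressed in degrees of visual angle on a grid centred on
the stimulus centre, with x positive rightward and y positive upward.
Images hold signed contrast values relative to mean luminance, so a value
of 0 renders as mid-gray and +/-1 are the luminance extremes.

Gratings are parametrised by orientation (degrees clockwise from vertical),
spatial frequency (cycles per degree), spatial phase (degrees) and Michelson
contrast.  A plaid is the pointwise sum of two gratings under an isotropic
Gaussian envelope; a contour abuts two obliquely oriented gratings along a
vertical hard edge under an anisotropic envelope, forming a sideways-opening
chevron whose apex angle is configurable.

The rendered images are for export and inspection; the simulation and
analysis pipeline operates on the parametric specs, not on pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GratingSpec",
    "GaussianEnvelope",
    "Raster",
    "StimulusImage",
    "make_grating",
    "make_plaid",
    "make_contour",
    "envelope_extent",
    "contour_component_orientations",
    "jitter_phase",
    "save_png",
]

#: Maximum displayable Michelson contrast.
MAX_CONTRAST = 0.98

#: Default sampling density, pixels per degree of visual angle.
DEFAULT_PIXELS_PER_DEGREE = 32


@dataclass(frozen=True)
class GratingSpec:
    """One sinusoidal luminance grating.

    Parameters
    ----------
    orientation:
        Degrees clockwise from vertical (a 0-deg grating has vertical bars).
    spatial_frequency:
        Cycles per degree of visual angle; must be positive.
    spatial_phase:
        Phase in degrees at the grid centre.
    contrast:
        Michelson contrast in [0, 0.98].
    """

    orientation: float
    spatial_frequency: float
    spatial_phase: float = 0.0
    contrast: float = 0.49

    def __post_init__(self) -> None:
        if not 0.0 <= self.contrast <= MAX_CONTRAST:
            raise ValueError(
                f"contrast must lie in [0, {MAX_CONTRAST}], got {self.contrast}"
            )
        if self.spatial_frequency <= 0:
            raise ValueError("spatial_frequency must be positive")


@dataclass(frozen=True)
class GaussianEnvelope:
    """Gaussian contrast envelope with per-axis standard deviations (degrees).

    ``cutoff_fraction`` is the fraction of peak contrast at which the
    stimulus extent is conventionally reported (1% by default).
    """

    sigma_x: float
    sigma_y: float
    cutoff_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("envelope sigmas must be positive")
        if not 0.0 < self.cutoff_fraction < 1.0:
            raise ValueError("cutoff_fraction must lie strictly in (0, 1)")

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return np.exp(
            -(x**2 / (2.0 * self.sigma_x**2) + y**2 / (2.0 * self.sigma_y**2))
        )


@dataclass(frozen=True)
class Raster:
    """Sampling description: field of view (degrees) and density (px/deg)."""

    width_deg: float
    height_deg: float
    pixels_per_degree: float = DEFAULT_PIXELS_PER_DEGREE

    @classmethod
    def square(
        cls, size_deg: float, pixels_per_degree: float = DEFAULT_PIXELS_PER_DEGREE
    ) -> "Raster":
        return cls(size_deg, size_deg, pixels_per_degree)

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre coordinate mesh, centred on the stimulus centre.

        Pixel centres sit at half-integer offsets so that for an even pixel
        count the grid is exactly mirror-symmetric about both axes and no
        sample falls on the midline.
        """
        nx = int(round(self.width_deg * self.pixels_per_degree))
        ny = int(round(self.height_deg * self.pixels_per_degree))
        x = (np.arange(nx) + 0.5 - nx / 2.0) / self.pixels_per_degree
        y = (np.arange(ny) + 0.5 - ny / 2.0) / self.pixels_per_degree
        # row 0 is the top of the image (largest y)
        return np.meshgrid(x, y[::-1])


@dataclass
class StimulusImage:
    """A rendered stimulus: signed contrast values on a centred grid."""

    values: np.ndarray
    pixels_per_degree: float

    @property
    def extent_deg(self) -> tuple[float, float]:
        """(width, height) of the image in degrees."""
        ny, nx = self.values.shape
        return nx / self.pixels_per_degree, ny / self.pixels_per_degree

    def __post_init__(self) -> None:
        if np.any(np.abs(self.values) > 1.0 + 1e-12):
            raise ValueError("contrast values must lie in [-1, 1]")


def _grating_field(
    spec: GratingSpec, x: np.ndarray, y: np.ndarray
) -> np.ndarray:
    theta = math.radians(spec.orientation)
    # modulation axis is perpendicular to the bars
    u = x * math.cos(theta) - y * math.sin(theta)
    phase = math.radians(spec.spatial_phase)
    return spec.contrast * np.cos(
        2.0 * math.pi * spec.spatial_frequency * u + phase
    )


def make_grating(spec: GratingSpec, raster: Raster) -> StimulusImage:
    """Render a sinusoidal grating; peak absolute value equals the contrast.

    Raises ``ValueError`` if the raster supplies fewer than 4 samples per
    cycle, which would alias the carrier.
    """
    if raster.pixels_per_degree < 4.0 * spec.spatial_frequency:
        raise ValueError(
            f"raster at {raster.pixels_per_degree} px/deg under-samples a "
            f"{spec.spatial_frequency} c/deg grating; need at least "
            f"{4.0 * spec.spatial_frequency} px/deg (4 samples per cycle)"
        )
    x, y = raster.mesh()
    return StimulusImage(_grating_field(spec, x, y), raster.pixels_per_degree)


def make_plaid(
    a: GratingSpec,
    b: GratingSpec,
    env: GaussianEnvelope,
    raster: Raster | None = None,
) -> StimulusImage:
    """Linear combination of two gratings under a Gaussian envelope.

    The combined contrast ``a.contrast + b.contrast`` must not exceed 1,
    otherwise the stimulus would drive luminance out of gamut.
    """
    total = a.contrast + b.contrast
    if total > 1.0 + 1e-12:
        raise ValueError(
            f"combined contrast {total:.3f} exceeds 1 (luminance out of gamut)"
        )
    if raster is None:
        side = envelope_extent(max(env.sigma_x, env.sigma_y), env.cutoff_fraction)
        raster = Raster.square(math.ceil(side))
    x, y = raster.mesh()
    field = (_grating_field(a, x, y) + _grating_field(b, x, y)) * env(x, y)
    return StimulusImage(field, raster.pixels_per_degree)


def contour_component_orientations(apex_angle: float) -> tuple[float, float]:
    """Component orientations (degrees from vertical) for a chevron contour.

    An apex angle ``theta`` maps to component tilts of ``(180 - theta) / 2``
    from horizontal, i.e. ``90 - (180 - theta)/2`` from vertical, mirrored
    across the vertical midline, producing a V that opens sideways.  At
    ``theta = 180`` both components are horizontal and collinear.
    """
    if not 0.0 < apex_angle < 180.0 + 1e-12:
        raise ValueError("apex_angle must lie in (0, 180] degrees")
    tilt = (180.0 - apex_angle) / 2.0
    return 90.0 - tilt, -(90.0 - tilt)


def make_contour(
    a: GratingSpec,
    b: GratingSpec,
    env: GaussianEnvelope,
    apex_angle: float = 140.0,
    raster: Raster | None = None,
) -> StimulusImage:
    """Two abutting oblique gratings forming a chevron contour.

    The left half-plane carries ``a`` and the right half-plane ``b``, joined
    at a vertical hard edge through the centre, then multiplied by the
    (generally anisotropic) Gaussian envelope.  The component orientations
    are derived from ``apex_angle``; the orientations stored in ``a`` and
    ``b`` are ignored and replaced.
    """
    orient_left, orient_right = contour_component_orientations(apex_angle)
    if raster is None:
        w = envelope_extent(env.sigma_x, env.cutoff_fraction)
        h = envelope_extent(env.sigma_y, env.cutoff_fraction)
        raster = Raster(math.ceil(w), math.ceil(h))
    x, y = raster.mesh()
    left = _grating_field(replace(a, orientation=orient_left), x, y)
    right = _grating_field(replace(b, orientation=orient_right), x, y)
    field = np.where(x < 0.0, left, right) * env(x, y)
    return StimulusImage(field, raster.pixels_per_degree)


def envelope_extent(sigma: float, cutoff: float = 0.01) -> float:
    """Diameter (degrees) at which a Gaussian envelope falls to ``cutoff``.

    Closed form: ``2 * sigma * sqrt(2 * ln(1 / cutoff))``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie strictly in (0, 1)")
    return 2.0 * sigma * math.sqrt(2.0 * math.log(1.0 / cutoff))


def jitter_phase(spec: GratingSpec, rng: np.random.Generator) -> GratingSpec:
    """Return ``spec`` with a fresh spatial phase drawn uniformly on [0, 360).

    Mimics the periodic phase randomisation used during adaptation to
    prevent retinal afterimages; all other fields are unchanged.
    """
    return replace(spec, spatial_phase=float(rng.uniform(0.0, 360.0)))


def save_png(image: StimulusImage, path: str) -> None:
    """Export as 8-bit grayscale PNG; mid-gray (128) is zero contrast."""
    from PIL import Image

    gray = np.clip(
        np.round((image.values + 1.0) / 2.0 * 255.0), 0, 255
    ).astype(np.uint8)
    Image.fromarray(gray, mode="L").save(path)
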