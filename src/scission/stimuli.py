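"""Van Lier star stimuli and the transparency-consistency physics.

The inducer is an eight-pointed star built from two interleaved four-pointed
sub-stars in alternating colors, with a gray center patch on a bright
background.  When the star's points are seen as two partially transmissive
colored filters overlapping in the center, the center luminance admits a
transparency interpretation only within a bounded interval: a uniform filter
of transmittance ``T = L_point / L_background`` can darken the points down to
``T * L_point`` at most, and can never make the overlap brighter than the
points themselves.  Those two luminances, ``B1 = L_point**2 / L_background``
and ``B2 = L_point``, bracket the region in which a layered (scission)
interpretation of the scene is physically consistent, and every downstream
prediction in this package keys off that interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from ._color import xyy_to_srgb

__all__ = [
    "CENTER_LUMINANCE_LEVELS",
    "BACKGROUND_LUMINANCE_CDM2",
    "POINT_LUMINANCE_CDM2",
    "ColorSpec",
    "StarStimulus",
    "TransparencyBounds",
    "InvalidLuminanceError",
    "TransparencyDomainError",
    "UnsupportedConfigurationError",
    "transmittance",
    "transparency_bounds",
    "classify_center_luminance",
    "classify_color_configuration",
    "build_star_stimulus",
    "render_stimulus",
    "COLOR_SCHEMES",
]

#: The nine center-patch luminance levels (cd/m^2), approximately log-spaced,
#: indexed by coded level 1-9 in the mixed-model analysis.
CENTER_LUMINANCE_LEVELS: tuple[float, ...] = (
    0.1, 1.5, 8.3, 19.2, 34.1, 54.9, 83.7, 121.4, 169.0,
)

#: White background luminance (cd/m^2).
BACKGROUND_LUMINANCE_CDM2: float = 169.0

#: Nominal luminance of the star's points (cd/m^2).  The red/green settings
#: average to ~83.8; the conventional rounded value 84 is used as the default
#: upper transparency bound and is overridable everywhere it appears.
POINT_LUMINANCE_CDM2: float = 84.0

DEFAULT_DIAMETER_DEG: float = 4.3

ConsistencyLabel = Literal["below", "consistent", "above"]
OutlineTarget = Literal["none", "substar_a", "substar_b"]
RenderMode = Literal["inducer", "outline", "mask"]


class InvalidLuminanceError(ValueError):
    """A luminance argument is negative, zero where positivity is required, or non-finite."""


class TransparencyDomainError(ValueError):
    """The luminance configuration admits no uniform-filter interpretation."""


class UnsupportedConfigurationError(ValueError):
    """The point-color arrangement falls outside the supported stimulus space."""


@dataclass(frozen=True)
class ColorSpec:
    """A display color as CIE xy chromaticity plus luminance in cd/m^2."""

    cie_x: float
    cie_y: float
    luminance: float

    def __post_init__(self) -> None:
        if not (0.0 < self.cie_x < 1.0 and 0.0 < self.cie_y < 1.0):
            raise ValueError(
                f"chromaticity ({self.cie_x}, {self.cie_y}) outside (0, 1)"
            )
        if not math.isfinite(self.luminance) or self.luminance < 0:
            raise InvalidLuminanceError(f"luminance {self.luminance!r} must be >= 0")


# Equiluminance-adjusted inducer colors (group-average settings) and the gray
# center/background chromaticities.
RED = ColorSpec(0.2851, 0.2615, 84.71)
GREEN = ColorSpec(0.2269, 0.2967, 82.9)
BLUE = ColorSpec(0.2287, 0.2289, 93.0)
YELLOW = ColorSpec(0.2618, 0.2912, 94.0)
GRAY_XY = (0.2397, 0.2515)
BACKGROUND = ColorSpec(*GRAY_XY, BACKGROUND_LUMINANCE_CDM2)

#: Point-color pairs / singletons by scheme name.  Two-entry schemes alternate
#: around the star and support a layered interpretation; uniform ones do not.
COLOR_SCHEMES: dict[str, tuple[ColorSpec, ...]] = {
    "red_green": (RED, GREEN),
    "blue_yellow": (BLUE, YELLOW),
    "uniform_red": (RED,),
    "uniform_green": (GREEN,),
    "uniform_blue": (BLUE,),
    "uniform_yellow": (YELLOW,),
}


@dataclass(frozen=True)
class StarStimulus:
    """Parametric description of the star inducer.

    ``point_colors`` holds one entry per point, in order around the star;
    sub-star A owns the even indices and sub-star B the odd ones.
    """

    point_colors: tuple[ColorSpec, ...]
    center: ColorSpec
    background: ColorSpec = BACKGROUND
    diameter_deg: float = DEFAULT_DIAMETER_DEG
    outline_target: OutlineTarget = "none"

    def __post_init__(self) -> None:
        n = self.n_points
        if n < 4 or n % 2 != 0:
            raise ValueError(f"n_points must be even and >= 4, got {n}")
        if len(set(self.point_colors)) not in (1, 2):
            raise UnsupportedConfigurationError(
                "point_colors must contain exactly 1 or 2 distinct colors"
            )
        if self.diameter_deg <= 0:
            raise ValueError("diameter_deg must be positive")

    @property
    def n_points(self) -> int:
        return len(self.point_colors)


@dataclass(frozen=True)
class TransparencyBounds:
    """Luminance interval [lower, upper] admitting a transparency interpretation.

    ``lower = transmittance * upper`` and ``upper`` is the point luminance.
    """

    transmittance: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0.0 < self.transmittance <= 1.0):
            raise ValueError(f"transmittance {self.transmittance} outside (0, 1]")
        if self.lower > self.upper + 1e-9:
            raise ValueError("lower bound exceeds upper bound")
        if abs(self.lower - self.transmittance * self.upper) > 1e-6 * max(1.0, self.upper):
            raise ValueError("lower must equal transmittance * upper")

    def classify(self, l_center: float) -> ConsistencyLabel:
        return classify_center_luminance(l_center, self)


def _check_filter_luminances(l_point: float, l_background: float) -> None:
    if not (math.isfinite(l_point) and math.isfinite(l_background)):
        raise InvalidLuminanceError("luminances must be finite")
    if l_point <= 0 or l_background <= 0:
        raise InvalidLuminanceError(
            f"luminances must be positive, got point={l_point}, background={l_background}"
        )
    if l_point > l_background:
        raise TransparencyDomainError(
            f"points brighter than background ({l_point} > {l_background}): "
            "no uniform filter can increase luminance"
        )


def transmittance(l_point: float, l_background: float) -> float:
    """Transmittance of the inferred filter, ``L_point / L_background``.

    A surface of luminance ``l_background`` seen through a neutral filter of
    transmittance T has luminance ``T * l_background``; observing the points
    at ``l_point`` therefore implies ``T = l_point / l_background``, in (0, 1].
    """
    _check_filter_luminances(l_point, l_background)
    return l_point / l_background


def transparency_bounds(
    l_point: float = POINT_LUMINANCE_CDM2,
    l_background: float = BACKGROUND_LUMINANCE_CDM2,
) -> TransparencyBounds:
    """Center-luminance interval consistent with two overlapping filters.

    The overlap region (center patch) is the background seen through both
    sub-star filters, so its darkest consistent luminance is
    ``T * l_point = l_point**2 / l_background``; its brightest is ``l_point``
    itself (transmittance cannot exceed 1).
    """
    t = transmittance(l_point, l_background)
    return TransparencyBounds(transmittance=t, lower=t * l_point, upper=l_point)


def classify_center_luminance(
    l_center: float, bounds: TransparencyBounds
) -> ConsistencyLabel:
    """Classify a center luminance against transparency bounds.

    The interval is closed: values equal to either bound count as consistent.
    """
    if not math.isfinite(l_center) or l_center < 0:
        raise InvalidLuminanceError(f"center luminance {l_center!r} must be >= 0")
    if l_center < bounds.lower:
        return "below"
    if l_center > bounds.upper:
        return "above"
    return "consistent"


def classify_color_configuration(stimulus: StarStimulus) -> bool:
    """Whether the point coloring supports a layered (two-filter) interpretation.

    True for exactly two distinct colors assigned alternately (two interleaved
    sub-stars, each interpretable as one filter); False for a uniform star.
    """
    distinct = list(dict.fromkeys(stimulus.point_colors))
    if len(distinct) == 1:
        return False
    if len(distinct) != 2:
        raise UnsupportedConfigurationError(
            f"{len(distinct)} distinct point colors; supported: 1 or 2"
        )
    a, b = stimulus.point_colors[0], stimulus.point_colors[1]
    alternating = all(
        c == (a if i % 2 == 0 else b) for i, c in enumerate(stimulus.point_colors)
    )
    if not alternating:
        raise UnsupportedConfigurationError(
            "two point colors must alternate around the star"
        )
    return True


def build_star_stimulus(
    center_level: int | None = None,
    center_luminance_cdm2: float | None = None,
    color_scheme: str = "red_green",
    n_points: int = 8,
    background_luminance_cdm2: float = BACKGROUND_LUMINANCE_CDM2,
    diameter_deg: float = DEFAULT_DIAMETER_DEG,
    outline_target: OutlineTarget = "none",
) -> StarStimulus:
    """Construct a validated star stimulus from named parameters.

    ``center_level`` is the 1-based coded luminance level into
    :data:`CENTER_LUMINANCE_LEVELS`; ``center_luminance_cdm2`` overrides it.
    With no overrides the default geometry is 8 points, 4.3 degrees, on the
    169 cd/m^2 white background.
    """
    if n_points % 2 != 0 or n_points < 4:
        raise ValueError(f"n_points must be even and >= 4, got {n_points}")
    if color_scheme not in COLOR_SCHEMES:
        raise ValueError(
            f"unknown color_scheme {color_scheme!r}; options: {sorted(COLOR_SCHEMES)}"
        )
    if center_luminance_cdm2 is None:
        if center_level is None:
            center_level = 6  # 54.9 cd/m^2, the peak-completion condition
        if not 1 <= center_level <= len(CENTER_LUMINANCE_LEVELS):
            raise ValueError(f"center_level {center_level} outside 1..9")
        center_luminance_cdm2 = CENTER_LUMINANCE_LEVELS[center_level - 1]
    if center_luminance_cdm2 < 0:
        raise InvalidLuminanceError("center luminance must be >= 0")
    if background_luminance_cdm2 <= 0:
        raise InvalidLuminanceError("background luminance must be > 0")

    palette = COLOR_SCHEMES[color_scheme]
    point_colors = tuple(palette[i % len(palette)] for i in range(n_points))
    return StarStimulus(
        point_colors=point_colors,
        center=ColorSpec(*GRAY_XY, center_luminance_cdm2),
        background=ColorSpec(*GRAY_XY, background_luminance_cdm2),
        diameter_deg=diameter_deg,
        outline_target=outline_target,
    )


# ---------------------------------------------------------------------------
# rendering

# Free rendering constants (illustrative only; no statistic depends on them).
PX_PER_DEG_DEFAULT = 60.0
INNER_RADIUS_FRAC = 0.35  # center-octagon radius as fraction of star radius
OUTLINE_LUMINANCE_CDM2 = 0.5  # near-black stroke


def _substar_polygon(
    cx: float, cy: float, r_outer: float, r_inner: float, phase_deg: float
) -> list[tuple[float, float]]:
    """Four-pointed star polygon: outer vertices every 90 deg starting at
    ``phase_deg``, inner vertices midway between them."""
    verts = []
    for k in range(4):
        for ang, r in (
            (phase_deg + 90 * k, r_outer),
            (phase_deg + 90 * k + 45, r_inner),
        ):
            a = math.radians(ang)
            verts.append((cx + r * math.cos(a), cy - r * math.sin(a)))
    return verts


def _center_octagon(cx: float, cy: float, r_inner: float) -> list[tuple[float, float]]:
    return [
        (cx + r_inner * math.cos(math.radians(45 * k + 45)),
         cy - r_inner * math.sin(math.radians(45 * k + 45)))
        for k in range(8)
    ]


def render_stimulus(
    stimulus: StarStimulus,
    resolution_px: int = 512,
    mode: RenderMode = "inducer",
    seed: int = 0,
    px_per_deg: float = PX_PER_DEG_DEFAULT,
) -> np.ndarray:
    """Rasterize a stimulus to an 8-bit RGB array (top-left origin, row-major).

    Modes: ``inducer`` paints both sub-stars and the center patch; ``outline``
    paints only the contour of the targeted sub-star plus the center octagon
    on the background; ``mask`` fills the star's bounding box with a seeded
    random pixel array.  Mask rendering is deterministic given ``seed``;
    inducer and outline rendering ignore it.

    Rendered RGB is an sRGB approximation of the CIE xyY specifications,
    normalized so the brightest scene luminance maps to display white.
    """
    from PIL import Image, ImageDraw

    if resolution_px < 32:
        raise ValueError("resolution_px must be >= 32")
    if mode not in ("inducer", "outline", "mask"):
        raise ValueError(f"unknown render mode {mode!r}")
    if mode == "outline" and stimulus.outline_target == "none":
        raise ValueError("outline mode requires stimulus.outline_target != 'none'")

    colors = list(stimulus.point_colors) + [stimulus.center, stimulus.background]
    y_ref = max(c.luminance for c in colors)
    def rgb(c: ColorSpec) -> tuple[int, int, int]:
        return xyy_to_srgb(c.cie_x, c.cie_y, c.luminance, y_ref)

    img = Image.new("RGB", (resolution_px, resolution_px), rgb(stimulus.background))
    draw = ImageDraw.Draw(img)
    cx = cy = (resolution_px - 1) / 2.0
    r_outer = stimulus.diameter_deg * px_per_deg / 2.0
    r_inner = r_outer * INNER_RADIUS_FRAC

    star_a = _substar_polygon(cx, cy, r_outer, r_inner, phase_deg=90.0)
    star_b = _substar_polygon(cx, cy, r_outer, r_inner, phase_deg=45.0)
    octagon = _center_octagon(cx, cy, r_inner)

    if mode == "mask":
        rng = np.random.default_rng(seed)
        arr = np.asarray(img, dtype=np.uint8).copy()
        half = int(math.ceil(r_outer))
        lo = max(0, int(round(cx)) - half)
        hi = min(resolution_px, int(round(cx)) + half)
        arr[lo:hi, lo:hi, :] = rng.integers(0, 256, size=(hi - lo, hi - lo, 3),
                                            dtype=np.uint8)
        return arr

    if mode == "inducer":
        color_a = rgb(stimulus.point_colors[0])
        color_b = rgb(stimulus.point_colors[1 % stimulus.n_points])
        draw.polygon(star_a, fill=color_a)
        draw.polygon(star_b, fill=color_b)
        draw.polygon(octagon, fill=rgb(stimulus.center))
    else:  # outline
        target = star_a if stimulus.outline_target == "substar_a" else star_b
        stroke = xyy_to_srgb(*GRAY_XY, OUTLINE_LUMINANCE_CDM2, y_ref)
        draw.polygon(target, outline=stroke, width=2)
        draw.polygon(octagon, outline=stroke, width=2)

    return np.asarray(img, dtype=np.uint8)
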