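"""CIE xyY -> sRGB conversion for stimulus rendering.

Rendering is illustrative: luminances are normalized to a scene reference
(white point of the conversion is sRGB D65), linear values are clipped into
gamut, and the standard sRGB transfer curve is applied.
"""

from __future__ import annotations

import numpy as np

# linear sRGB <- XYZ (D65), IEC 61966-2-1
_XYZ_TO_RGB = np.array(
    [
        [3.2406, -1.5372, -0.4986],
        [-0.9689, 1.8758, 0.0415],
        [0.0557, -0.2040, 1.0570],
    ]
)


def xyy_to_srgb(x: float, y: float, luminance: float, y_ref: float) -> tuple[int, int, int]:
    """Map a CIE xyY color to an 8-bit sRGB triple, ``luminance / y_ref`` as Y."""
    if y_ref <= 0:
        raise ValueError("reference luminance must be positive")
    Y = max(0.0, luminance / y_ref)
    if y <= 0:
        raise ValueError("cie_y must be positive")
    X = x * Y / y
    Z = (1.0 - x - y) * Y / y
    lin = _XYZ_TO_RGB @ np.array([X, Y, Z])
    lin = np.clip(lin, 0.0, 1.0)
    srgb = np.where(lin <= 0.0031308, 12.92 * lin, 1.055 * lin ** (1 / 2.4) - 0.055)
    return tuple(int(round(255 * v)) for v in srgb)
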