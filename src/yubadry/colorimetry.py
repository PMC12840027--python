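"""CIELAB colorimetry: sRGB -> L*a*b* conversion, total color difference
(dE, the Euclidean distance in CIELAB), and the yellowness index
YI = 142.86 * b* / L* used to grade the yellow color of dried yuba.

The sRGB conversion assumes the D65 white point and the 2-degree standard
observer, the common choice for camera-derived color in food science.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ColorLab", "delta_e", "yellowness_index", "rgb_to_lab"]

# D65 reference white (2-degree observer), XYZ scaled so Yn = 1.
_D65 = np.array([0.95047, 1.00000, 1.08883])

# linear-RGB -> XYZ matrix for sRGB primaries / D65 (IEC 61966-2-1).
_RGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)


@dataclass(frozen=True)
class ColorLab:
    """A CIELAB color: L* in [0, 100], a* red-green, b* yellow-blue."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.L <= 100.0:
            raise ValueError("L* must lie in [0, 100]")

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b], dtype=float)


def delta_e(c0: ColorLab, c1: ColorLab) -> float:
    """Total color difference: Euclidean distance in L*a*b* space."""
    return float(np.linalg.norm(c0.as_array() - c1.as_array()))


def yellowness_index(L, b):
    """YI = 142.86 * b* / L*; higher means more yellow."""
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0):
        raise ValueError("L* must be positive")
    out = 142.86 * np.asarray(b, dtype=float) / L
    return out.item() if out.ndim == 0 else out


def _srgb_to_linear(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _lab_f(t: np.ndarray) -> np.ndarray:
    delta = 6.0 / 29.0
    return np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)


def rgb_to_lab(r, g, b) -> ColorLab:
    """Convert 8-bit sRGB channel values to CIELAB (D65, 2-degree observer).

    Pipeline: gamma-decode sRGB to linear RGB, linear map to XYZ, then the
    standard f-compression against the D65 white point.
    """
    rgb = np.array([r, g, b], dtype=float)
    if np.any(rgb < 0) or np.any(rgb > 255):
        raise ValueError("RGB channels must lie in [0, 255]")
    linear = _srgb_to_linear(rgb / 255.0)
    xyz = _RGB_TO_XYZ @ linear
    fx, fy, fz = _lab_f(xyz / _D65)
    L = 116.0 * fy - 16.0
    return ColorLab(L=float(np.clip(L, 0.0, 100.0)),
                    a=float(500.0 * (fx - fy)),
                    b=float(200.0 * (fy - fz)))
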