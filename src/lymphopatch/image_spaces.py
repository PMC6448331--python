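"""Image-space transforms: blue-ratio gray space and CIE Lab.

H&E histology carries complementary information in two spaces. The
blue-ratio transform amplifies the hematoxylin (nuclear) signal of an
RGB image into one gray channel::

    BR = 100 * B / (1 + R + G) * 256 / (1 + B + R + G)

The first factor enhances blue-dominated pixels (nuclei), the second
attenuates bright background. CIE Lab separates lightness from the two
chromatic axes (a: green-red, b: blue-yellow), which is where eosin
tint variation lives. RGB is converted to XYZ with the BT.709/D65
linear matrix and then to Lab with the D65 white point
(Xn, Yn, Zn) = (0.950456, 1.0, 1.088754).
"""

from __future__ import annotations

import numpy as np

# Linear RGB -> XYZ, BT.709 primaries, D65 white. Row sums equal the
# white point below, so (1,1,1) maps exactly to the reference white.
RGB_TO_XYZ = np.array(
    [
        [0.412453, 0.357580, 0.180423],
        [0.212671, 0.715160, 0.072169],
        [0.019334, 0.119193, 0.950227],
    ]
)

#: D65 reference white (Xn, Yn, Zn).
WHITE_POINT = np.array([0.950456, 1.0, 1.088754])

_DELTA = 6.0 / 29.0


def _validate_rgb(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"empty image of shape {arr.shape}")
    return arr.astype(np.float64)


def to_blue_ratio(img: np.ndarray) -> np.ndarray:
    """Map an 8-bit RGB image to the blue-ratio gray space.

    Returns an H x W float array; values are >= 0 and finite for every
    8-bit input (both denominators are at least 1).
    """
    arr = _validate_rgb(img)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    return 100.0 * b / (1.0 + r + g) * 256.0 / (1.0 + b + r + g)


def quantize_blue_ratio(br: np.ndarray) -> np.ndarray:
    """Min-max rescale a blue-ratio image to 8-bit gray.

    Rescaling is per image; rounding is round-half-to-even. A constant
    image maps to all zeros.
    """
    arr = np.asarray(br, dtype=np.float64)
    lo = arr.min()
    hi = arr.max()
    if hi <= lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    scaled = (arr - lo) / (hi - lo) * 255.0
    return np.rint(scaled).astype(np.uint8)


def _srgb_to_linear(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _f(t: np.ndarray) -> np.ndarray:
    """Piecewise cube-root of the XYZ->Lab transform."""
    return np.where(t > _DELTA**3, np.cbrt(t), t / (3.0 * _DELTA**2) + 4.0 / 29.0)


def rgb_to_lab(img: np.ndarray, gamma: bool = True) -> np.ndarray:
    """Convert an 8-bit RGB image to CIE Lab.

    Parameters
    ----------
    img : H x W x 3 array of 8-bit intensities.
    gamma : apply the sRGB gamma linearization before the RGB->XYZ
        matrix (standard colorimetry). ``gamma=False`` treats channel
        values as already linear.

    Returns
    -------
    H x W x 3 float array with channels (L, a, b); L in [0, 100].
    """
    arr = _validate_rgb(img) / 255.0
    if gamma:
        arr = _srgb_to_linear(arr)
    xyz = arr @ RGB_TO_XYZ.T
    fxyz = _f(xyz / WHITE_POINT)
    fx, fy, fz = fxyz[..., 0], fxyz[..., 1], fxyz[..., 2]
    lab = np.empty_like(xyz)
    lab[..., 0] = 116.0 * fy - 16.0
    lab[..., 1] = 500.0 * (fx - fy)
    lab[..., 2] = 200.0 * (fy - fz)
    return lab
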