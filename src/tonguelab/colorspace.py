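"""sRGB <-> CIE 1976 (L*, a*, b*) conversion.

Tongue photographs arrive as 8-bit RGB; every downstream stage (segmentation,
exclusion thresholds, color correction, the 2-D color histogram) works in
CIELAB, so this module is the entry point of the pipeline.  The camera standard
is taken to be sRGB with the D65 reference white — the universal default for
consumer and clinical imaging devices when no ICC profile is attached.

The sRGB -> XYZ matrix is the IEC 61966-2-1 matrix with its rows renormalized
so that RGB white (255, 255, 255) maps *exactly* onto the reference white.
Without that normalization the published 6-decimal matrix leaves residuals of
~2e-3 on a*/b* for neutral pixels, which would smear the neutral axis that the
checker-based L* correction relies on.  With it, equal-RGB pixels satisfy
a* = b* = 0 to machine precision and L* is strictly monotone in channel value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FormatError

__all__ = [
    "LabRaster",
    "srgb_to_lab",
    "lab_to_srgb",
    "read_rgb",
    "D65_WHITE",
]

# IEC 61966-2-1 sRGB primaries -> XYZ (D65), 6-decimal published form.
_SRGB_TO_XYZ = np.array(
    [
        [0.412453, 0.357580, 0.180423],
        [0.212671, 0.715160, 0.072169],
        [0.019334, 0.119193, 0.950227],
    ]
)

# Reference white = image of RGB (1,1,1); guarantees an exactly neutral axis.
D65_WHITE = _SRGB_TO_XYZ.sum(axis=1)

_XYZ_TO_SRGB = np.linalg.inv(_SRGB_TO_XYZ)

# CIE L*a*b* constants (exact rational form).
_DELTA = 6.0 / 29.0
_DELTA3 = _DELTA**3
_KAPPA = (29.0 / 6.0) ** 2 / 3.0  # slope of the linear segment of f


@dataclass(frozen=True)
class LabRaster:
    """Per-pixel CIE 1976 (L*, a*, b*) image.

    ``L`` is lightness in [0, 100]; ``a`` the red–green and ``b`` the
    yellow–blue opponent coordinate.  All three arrays share one (H, W) shape.
    """

    L: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        if not (self.L.shape == self.a.shape == self.b.shape):
            raise FormatError("L, a, b planes must share one shape")
        if self.L.ndim != 2 or min(self.L.shape) < 1:
            raise FormatError("LabRaster planes must be 2-D and non-empty")

    @property
    def shape(self) -> tuple[int, int]:
        return self.L.shape

    def stack(self) -> np.ndarray:
        """(H, W, 3) float array in L, a, b order."""
        return np.stack([self.L, self.a, self.b], axis=-1)

    @classmethod
    def from_stack(cls, lab: np.ndarray) -> "LabRaster":
        lab = np.asarray(lab, dtype=float)
        if lab.ndim != 3 or lab.shape[-1] != 3:
            raise FormatError("expected an (H, W, 3) Lab stack")
        return cls(L=lab[..., 0], a=lab[..., 1], b=lab[..., 2])


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        if image.ndim == 3 and image.shape[-1] == 4:
            raise FormatError(
                "alpha channel not supported: flatten to 3-channel RGB first"
            )
        raise FormatError(
            f"expected an (H, W, 3) 8-bit RGB image, got shape {image.shape}"
        )
    if image.dtype != np.uint8:
        if np.issubdtype(image.dtype, np.integer):
            if image.min() < 0 or image.max() > 255:
                raise FormatError("integer RGB values must lie in [0, 255]")
            image = image.astype(np.uint8)
        else:
            raise FormatError("RGB image must be 8-bit integer valued")
    return image


def _f(t: np.ndarray) -> np.ndarray:
    return np.where(t > _DELTA3, np.cbrt(t), _KAPPA * t + 4.0 / 29.0)


def _f_inv(t: np.ndarray) -> np.ndarray:
    return np.where(t > _DELTA, t**3, (t - 4.0 / 29.0) / _KAPPA)


def srgb_to_lab(image: np.ndarray) -> LabRaster:
    """Convert an 8-bit sRGB image to CIE 1976 (L*, a*, b*).

    Parameters
    ----------
    image
        (H, W, 3) uint8 array.  Alpha channels are rejected.

    Returns
    -------
    LabRaster
        Floating-point Lab planes; no quantization is applied.
    """
    image = _validate_rgb(image)
    s = image.astype(float) / 255.0
    linear = np.where(s <= 0.04045, s / 12.92, ((s + 0.055) / 1.055) ** 2.4)
    xyz = linear @ _SRGB_TO_XYZ.T
    xyz_n = xyz / D65_WHITE
    fx, fy, fz = _f(xyz_n[..., 0]), _f(xyz_n[..., 1]), _f(xyz_n[..., 2])
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    return LabRaster(L=L, a=a, b=b)


def lab_to_srgb(lab: LabRaster, *, return_clip_count: bool = False):
    """Render a Lab raster back to 8-bit sRGB (used to draw synthetic images).

    Out-of-gamut values are clipped channel-wise to [0, 255]; the number of
    pixels touched by clipping is available via ``return_clip_count``.
    For in-gamut colors the round trip through :func:`srgb_to_lab` is exact to
    within one 8-bit quantization step per channel.
    """
    fy = (np.asarray(lab.L, dtype=float) + 16.0) / 116.0
    fx = fy + np.asarray(lab.a, dtype=float) / 500.0
    fz = fy - np.asarray(lab.b, dtype=float) / 200.0
    xyz = np.stack([_f_inv(fx), _f_inv(fy), _f_inv(fz)], axis=-1) * D65_WHITE
    linear = xyz @ _XYZ_TO_SRGB.T
    clipped_linear = np.clip(linear, 0.0, 1.0)
    n_clipped = int(np.any(linear != clipped_linear, axis=-1).sum())
    s = np.where(
        clipped_linear <= 0.0031308,
        12.92 * clipped_linear,
        1.055 * clipped_linear ** (1.0 / 2.4) - 0.055,
    )
    rgb = np.clip(np.round(s * 255.0), 0, 255).astype(np.uint8)
    if return_clip_count:
        return rgb, n_clipped
    return rgb


def read_rgb(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG file as an (H, W, 3) uint8 array.

    Grayscale images are rejected (the analysis needs color); images with an
    alpha channel are rejected with an explicit error rather than silently
    dropping transparency.
    """
    from PIL import Image

    with Image.open(path) as im:
        if im.mode == "RGBA" or "A" in im.getbands():
            raise FormatError(f"{path}: alpha channel not supported")
        if im.mode != "RGB":
            raise FormatError(f"{path}: expected 8-bit RGB, got mode {im.mode!r}")
        return np.asarray(im, dtype=np.uint8)
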