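"""Resizing and illumination normalization of fundus photographs.

Every image is first brought to a standard working height of 565 px (the
height of the smallest common fundus dataset), preserving aspect ratio.
Uneven illumination is then corrected on the green channel by a blend of
morphological residues and a large average-filter background estimate:

    Ibt = closing(I, disk θ) − I          (bottom-hat: fills dark thin detail)
    Iop = opening(I, disk σ)
    Ibg = mean filter of I (89×89)
    Ipre1 = I + Ibt − Ibg
    Ipre2 = Iop − Ibg
    Ic   = (Ipre1 + Ipre2) / 2, clipped to [0, 255]

Subtracting the average-filter background removes smooth shading (an
additive background term would instead double it), the bottom-hat term
fills in dark vessels, and large bright structure survives — so the optic
disc stands alone as the brightest region of Ic, which is what the coarse
disc localizer relies on.  Arithmetic is carried out in float64 and
clipped back to the 8-bit range only in Ic; the intermediates are
returned unclipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import color, morphology, transform

from .config import PipelineConfig
from .errors import InvalidInputError

__all__ = [
    "FundusImage",
    "ResizedImage",
    "NormalizedImage",
    "resize_to_standard",
    "channel",
    "normalize_illumination",
]


@dataclass(frozen=True)
class FundusImage:
    """A raw RGB fundus photograph.

    Coordinates throughout the package are x = column, y = row, 0-based,
    origin at the top-left corner.
    """

    pixels: np.ndarray  # H×W×3 uint8
    path: str = "<memory>"

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise InvalidInputError(
                f"{self.path}: expected H×W×3 RGB pixels, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise InvalidInputError(f"{self.path}: zero-sized image")
        object.__setattr__(self, "pixels", px.astype(np.uint8, copy=False))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ResizedImage:
    """An RGB image at the standard working height."""

    pixels: np.ndarray  # h'×w'×3 uint8
    scale_factor: float  # resized height / original height
    path: str = "<memory>"

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class NormalizedImage:
    """Illumination-normalized green channel with all intermediates.

    All grids are float64 with the shape of the resized green channel.
    ``Ic`` is clipped to [0, 255]; the intermediates are unclipped.
    """

    Ic: np.ndarray
    Ipre1: np.ndarray
    Ipre2: np.ndarray
    Ibt: np.ndarray
    Ibg: np.ndarray
    Iop: np.ndarray


def resize_to_standard(img: FundusImage,
                       cfg: PipelineConfig | None = None) -> ResizedImage:
    """Scale an image to the standard working height, preserving aspect.

    The target width is ``round(h' / h × w)`` (at least 1) so the aspect
    ratio survives within rounding.  Bilinear interpolation is used, with
    anti-aliasing when downscaling.
    """
    cfg = cfg or PipelineConfig()
    h_std = cfg.resize.height
    h, w = img.height, img.width
    if h == h_std:
        return ResizedImage(img.pixels.copy(), 1.0, img.path)
    w_new = max(1, int(round(h_std / h * w)))
    out = transform.resize(
        img.pixels, (h_std, w_new, 3), order=1,
        preserve_range=True, anti_aliasing=(h_std < h),
    )
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return ResizedImage(out, h_std / h, img.path)


def channel(img: ResizedImage, which: str) -> np.ndarray:
    """Extract a single-channel uint8 grid: ``red``, ``green`` or ``gray``.

    ``gray`` is the standard luminance combination of R, G, B.
    """
    if which == "red":
        return img.pixels[:, :, 0].copy()
    if which == "green":
        return img.pixels[:, :, 1].copy()
    if which == "gray":
        g = color.rgb2gray(img.pixels) * 255.0
        return np.clip(np.rint(g), 0, 255).astype(np.uint8)
    raise InvalidInputError(f"unknown channel {which!r}; use red, green or gray")


def _fit_filter(size: int, shape: tuple[int, int]) -> int:
    """Largest odd filter size <= requested that fits the grid."""
    limit = min(shape)
    if size <= limit:
        return size
    fitted = limit if limit % 2 == 1 else limit - 1
    fitted = max(1, fitted)
    warnings.warn(
        f"background filter {size}×{size} exceeds grid {shape}; "
        f"reduced to {fitted}×{fitted}",
        stacklevel=3,
    )
    return fitted


def normalize_illumination(green: np.ndarray,
                           cfg: PipelineConfig | None = None) -> NormalizedImage:
    """Flatten uneven illumination on a single-channel grid.

    See the module docstring for the formulas.  Deterministic: identical
    inputs give bitwise-identical outputs.
    """
    cfg = cfg or PipelineConfig()
    I = np.asarray(green, dtype=np.float64)
    if I.ndim != 2:
        raise InvalidInputError("normalize_illumination expects a 2-D grid")

    theta = morphology.disk(cfg.normalize.theta_radius)
    sigma = morphology.disk(cfg.normalize.sigma_radius)

    # bottom-hat: closing minus image (responds to dark thin structures)
    Ibt = morphology.closing(I, theta) - I
    Iop = morphology.opening(I, sigma)
    size = _fit_filter(cfg.normalize.bg_filter, I.shape)
    Ibg = ndi.uniform_filter(I, size=size, mode="nearest")

    Ipre1 = I + Ibt - Ibg
    Ipre2 = Iop - Ibg
    Ic = np.clip((Ipre1 + Ipre2) / 2.0, 0.0, 255.0)
    return NormalizedImage(Ic=Ic, Ipre1=Ipre1, Ipre2=Ipre2,
                           Ibt=Ibt, Ibg=Ibg, Iop=Iop)
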