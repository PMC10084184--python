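"""Collagen quantification of stained liver sections by YCbCr color gating.

Picrosirius red (PSR) and Masson trichrome (MT) both bind collagen fibers;
on the section the stained collagen occupies a compact region of color
space. Each RGB image is converted to YCbCr and a pixel is counted as
collagen iff all three channels fall inside the stain's inclusive gate:

    PSR: Y in [0, 184],  Cb in [121, 144], Cr in [136, 255]
    MT:  Y in [67, 255], Cb in [129, 255], Cr in [119, 159]

The collagen fraction is simply the in-gate pixel percentage — pure
thresholding, no morphological cleanup.

The default conversion is the ITU-R BT.601 studio-swing matrix (Y in
[16, 235], Cb/Cr in [16, 240] for in-gamut inputs), the convention of the
common 8-bit thresholding tools the gates were defined with; a full-swing
JPEG-style conversion is available via ``swing="full"`` for gates defined
under that convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2ycbcr

__all__ = [
    "ColorGate",
    "StainResult",
    "PSR_GATE",
    "MT_GATE",
    "GATE_PRESETS",
    "rgb_to_ycbcr",
    "segment_stain",
]


@dataclass(frozen=True)
class ColorGate:
    """Inclusive per-channel YCbCr intervals defining a stain."""

    y_range: tuple[int, int]
    cb_range: tuple[int, int]
    cr_range: tuple[int, int]

    def __post_init__(self) -> None:
        for name, (lo, hi) in zip(
            ("y_range", "cb_range", "cr_range"),
            (self.y_range, self.cb_range, self.cr_range),
        ):
            if not (0 <= lo <= hi <= 255):
                raise ValueError(f"{name}=({lo}, {hi}) is not a valid 8-bit interval")

    def contains(self, ycbcr: np.ndarray) -> np.ndarray:
        """Boolean mask of pixels inside all three intervals."""
        y, cb, cr = ycbcr[..., 0], ycbcr[..., 1], ycbcr[..., 2]
        return (
            (self.y_range[0] <= y) & (y <= self.y_range[1])
            & (self.cb_range[0] <= cb) & (cb <= self.cb_range[1])
            & (self.cr_range[0] <= cr) & (cr <= self.cr_range[1])
        )


PSR_GATE = ColorGate(y_range=(0, 184), cb_range=(121, 144), cr_range=(136, 255))
MT_GATE = ColorGate(y_range=(67, 255), cb_range=(129, 255), cr_range=(119, 159))
GATE_PRESETS: dict[str, ColorGate] = {"PSR": PSR_GATE, "MT": MT_GATE}


@dataclass
class StainResult:
    """Segmentation mask and in-gate pixel percentage for one image."""

    mask: np.ndarray
    fraction_percent: float


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if image.dtype != np.uint8:
        raise ValueError(f"expected 8-bit (uint8) RGB, got dtype {image.dtype}")
    if image.size == 0:
        raise ValueError("image is empty")
    return image


def rgb_to_ycbcr(image: np.ndarray, swing: str = "studio") -> np.ndarray:
    """Convert an 8-bit RGB image to 8-bit YCbCr.

    ``swing="studio"`` (default) uses the BT.601 studio-swing matrix;
    ``swing="full"`` the JPEG full-swing variant. Channels are rounded to
    the nearest integer (half away from zero) and clipped to [0, 255].
    """
    image = _check_rgb(image)
    if swing == "studio":
        ycc = rgb2ycbcr(image)  # skimage: BT.601, Y in [16,235], chroma [16,240]
    elif swing == "full":
        r, g, b = (image[..., c].astype(float) for c in range(3))
        ycc = np.stack(
            [
                0.299 * r + 0.587 * g + 0.114 * b,
                128.0 - 0.168736 * r - 0.331264 * g + 0.5 * b,
                128.0 + 0.5 * r - 0.418688 * g - 0.081312 * b,
            ],
            axis=-1,
        )
    else:
        raise ValueError(f"swing must be 'studio' or 'full', got {swing!r}")
    return np.clip(np.floor(ycc + 0.5), 0, 255).astype(np.uint8)


def segment_stain(
    image: np.ndarray, gate: ColorGate, swing: str = "studio"
) -> StainResult:
    """Gate every pixel of an RGB image and report the in-gate percentage."""
    ycc = rgb_to_ycbcr(image, swing=swing)
    mask = gate.contains(ycc.astype(np.int16))
    fraction = 100.0 * float(mask.sum()) / mask.size
    return StainResult(mask=mask, fraction_percent=fraction)
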