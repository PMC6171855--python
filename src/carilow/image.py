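"""Core raster containers.

Images are numpy arrays with float values in [0, 1]; grayscale arrays are
2-D ``(H, W)``, RGB arrays are ``(H, W, 3)``.  A :class:`FaceImage` binds the
pixel data to its angular size on the observer's retina, which the blur
simulator needs to convert cycles/degree into pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np

#: Horizontal extent of a displayed face, in degrees of visual angle,
#: for a real person viewed at 54 cm.
DEFAULT_FACE_WIDTH_DEG = 18.11


@dataclass(frozen=True)
class FaceImage:
    """A face raster plus the metadata the low-vision simulators rely on.

    Parameters
    ----------
    pixels:
        Float array in [0, 1]; shape ``(H, W)`` or ``(H, W, 3)``.
    width_deg:
        Degrees of visual angle subtended by the image width.
    colorspace:
        ``"gray"`` or ``"rgb"``; must match the array shape.
    """

    pixels: np.ndarray
    width_deg: float = DEFAULT_FACE_WIDTH_DEG
    colorspace: str = "gray"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim == 2:
            cs = "gray"
        elif px.ndim == 3 and px.shape[2] == 3:
            cs = "rgb"
        else:
            raise ValueError(f"unsupported image shape {px.shape}")
        if cs != self.colorspace:
            raise ValueError(
                f"colorspace {self.colorspace!r} does not match shape {px.shape}"
            )
        if self.width_deg <= 0:
            raise ValueError("width_deg must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def size(self) -> tuple[int, int]:
        """(width, height) in pixels."""
        h, w = self.pixels.shape[:2]
        return (w, h)

    @property
    def pixels_per_degree(self) -> float:
        return self.size[0] / self.width_deg

    def luma(self) -> np.ndarray:
        """Grayscale view (Rec.601 luma for RGB input)."""
        if self.colorspace == "gray":
            return self.pixels
        return self.pixels @ np.array([0.299, 0.587, 0.114])

    def with_pixels(self, pixels: np.ndarray) -> "FaceImage":
        cs = "gray" if np.ndim(pixels) == 2 else "rgb"
        return replace(self, pixels=np.asarray(pixels, dtype=float), colorspace=cs)


@dataclass(frozen=True)
class Stimulus:
    """An image together with the provenance of every processing step.

    ``caricature`` is the strength fraction used (0.0 for veridical),
    ``scheme`` the landmark scheme that drove the warp, ``resolution`` the
    low-vision condition label (``highres`` when untouched) and ``seed`` the
    dropout seed where one was used.
    """

    image: FaceImage
    identity: str
    sex: str
    viewpoint: str
    caricature: float = 0.0
    scheme: Optional[str] = None
    resolution: str = "highres"
    seed: Optional[int] = None
    extra: dict = field(default_factory=dict)

    @property
    def caricature_label(self) -> str:
        if self.caricature == 0.0:
            return "V"
        return {"hand": "C-147p", "auto": "C-68p"}.get(
            self.scheme or "", f"C({self.scheme},{self.caricature:g})"
        )


def save_image(img: FaceImage, path: str | Path) -> None:
    """Write a FaceImage as 8-bit PNG/TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.clip(np.round(img.pixels * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)


def load_image(path: str | Path, width_deg: float = DEFAULT_FACE_WIDTH_DEG) -> FaceImage:
    """Read an 8-bit PNG/TIFF back into a [0, 1]-float FaceImage."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return FaceImage(arr.astype(float) / 255.0, width_deg=width_deg)
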