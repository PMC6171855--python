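"""Low-vision renderings: eccentricity-matched blur and phosphenised vision.

Blur emulates viewing a face in peripheral vision, as in macular degeneration
where central vision is lost.  Acuity falls roughly inverse-linearly with
eccentricity E, so the simulated cutoff spatial frequency is

    f_c(E) = f0 * E2 / (E2 + E)          [cycles/degree]

with foveal cutoff f0 = 30 cpd and half-acuity eccentricity E2 = 2.5 deg by
default.  The image is low-passed with a spatially uniform Gaussian whose
modulation transfer falls to 0.5 at f_c(E); for a Gaussian of spatial s.d.
sigma (degrees) the MTF is exp(-2 pi^2 sigma^2 f^2), so
sigma = sqrt(ln 2 / 2) / (pi f_c).

Phosphenisation emulates a retinal prosthesis: a rows x cols electrode grid
tiles the face box, each functioning electrode samples the nearest-neighbour
pixel under its centre, the sample is quantized to L = 8 levels, and each
level is rendered on black as a circular Gaussian spot whose size and peak
brightness both grow with level.  Random electrode dropout (30% in the DO
conditions) removes a fixed, seed-reproducible subset of sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .image import FaceImage, Stimulus
from .landmark_io import LandmarkSet

DEFAULT_F0_CPD = 30.0
DEFAULT_E2_DEG = 2.5
DEFAULT_LEVELS = 8

#: phosphene radius, in grid-spacing units, at level 0 and its growth to full level
SIGMA_BASE = 0.30
SIGMA_GAIN = 0.10


@dataclass(frozen=True)
class BlurCondition:
    """Peripheral-viewing blur at eccentricity E (deg); E = 0 is passthrough."""

    eccentricity_deg: float
    face_width_deg: float = 18.11
    f0_cpd: float = DEFAULT_F0_CPD
    e2_deg: float = DEFAULT_E2_DEG

    def __post_init__(self) -> None:
        if self.eccentricity_deg < 0:
            raise ValueError("eccentricity must be non-negative")

    @property
    def label(self) -> str:
        e = self.eccentricity_deg
        return "highres" if e == 0 else f"Blur{e:g}"


@dataclass(frozen=True)
class PhospheneCondition:
    """Electrode grid geometry, dropout fraction and render quantization."""

    grid: tuple[int, int]  # (rows, cols)
    dropout_fraction: float = 0.0
    seed: int = 0
    levels: int = DEFAULT_LEVELS

    def __post_init__(self) -> None:
        if not (0 <= self.dropout_fraction < 1):
            raise ValueError("dropout fraction must be in [0, 1)")
        if self.levels < 2:
            raise ValueError("need at least 2 quantization levels")

    @property
    def label(self) -> str:
        tag = "DO" if self.dropout_fraction > 0 else "ND"
        return f"{self.grid[0]}x{self.grid[1]}{tag}"


# ---------------------------------------------------------------------------
# blur
# ---------------------------------------------------------------------------


def cutoff_frequency(
    eccentricity_deg: float, f0_cpd: float = DEFAULT_F0_CPD, e2_deg: float = DEFAULT_E2_DEG
) -> float:
    """Cutoff spatial frequency (cpd) at eccentricity E: f0 * E2 / (E2 + E)."""
    if eccentricity_deg < 0:
        raise ValueError("eccentricity must be non-negative")
    return f0_cpd * e2_deg / (e2_deg + eccentricity_deg)


def blur_sigma_deg(cutoff_cpd: float) -> float:
    """Gaussian s.d. (degrees) whose MTF equals 0.5 at the given cutoff."""
    return np.sqrt(np.log(2.0) / 2.0) / (np.pi * cutoff_cpd)


def blur_image(
    image: FaceImage, cond: BlurCondition, pixels_per_degree: Optional[float] = None
) -> FaceImage:
    """Uniform Gaussian low-pass matched to the condition's eccentricity."""
    if cond.eccentricity_deg == 0:
        return image.with_pixels(image.pixels.copy())
    ppd = pixels_per_degree
    if ppd is None:
        if image.width_deg is None or image.width_deg <= 0:
            raise ValueError("image carries no angular-size metadata")
        ppd = image.pixels_per_degree
    fc = cutoff_frequency(cond.eccentricity_deg, cond.f0_cpd, cond.e2_deg)
    sigma_px = blur_sigma_deg(fc) * ppd
    px = image.pixels
    if px.ndim == 3:
        blurred = np.stack(
            [gaussian_filter(px[:, :, c], sigma_px, mode="reflect") for c in range(3)],
            axis=2,
        )
    else:
        blurred = gaussian_filter(px, sigma_px, mode="reflect")
    return image.with_pixels(blurred)


# ---------------------------------------------------------------------------
# phosphenisation
# ---------------------------------------------------------------------------


def face_bounding_box(landmarks: Optional[LandmarkSet], image: FaceImage) -> tuple[float, float, float, float]:
    """(x0, y0, x1, y1) box the grid tiles: landmark extent, else the frame."""
    if landmarks is None:
        w, h = image.size
        return (0.0, 0.0, float(w), float(h))
    pts = landmarks.points
    return (
        float(pts[:, 0].min()),
        float(pts[:, 1].min()),
        float(pts[:, 0].max()),
        float(pts[:, 1].max()),
    )


def place_phosphene_grid(
    face_box: tuple[float, float, float, float], grid: tuple[int, int]
) -> np.ndarray:
    """Cell-centred rows x cols lattice of site centres spanning the box.

    Returns an (rows*cols, 2) array of (x, y) centres; corner sites sit half a
    cell in from the box edges.
    """
    x0, y0, x1, y1 = face_box
    rows, cols = grid
    dx = (x1 - x0) / cols
    dy = (y1 - y0) / rows
    if dx < 1.0 or dy < 1.0:
        raise ValueError(
            f"face box {face_box} is too small for a {rows}x{cols} grid "
            "(spacing below 1 px)"
        )
    xs = x0 + dx * (np.arange(cols) + 0.5)
    ys = y0 + dy * (np.arange(rows) + 0.5)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def apply_dropout(sites: np.ndarray, dropout_fraction: float, seed: int) -> np.ndarray:
    """Remove round(d*N) sites uniformly at random; reproducible under seed."""
    if not (0 <= dropout_fraction < 1):
        raise ValueError("dropout fraction must be in [0, 1)")
    n = len(sites)
    n_drop = int(round(dropout_fraction * n))
    if n_drop == 0:
        return sites.copy()
    rng = np.random.default_rng(seed)
    drop = rng.choice(n, size=n_drop, replace=False)
    keep = np.ones(n, dtype=bool)
    keep[drop] = False
    return sites[keep]


def sample_and_quantize(image: FaceImage, sites: np.ndarray, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Nearest-neighbour luma under each site, uniformly binned to L levels."""
    luma = image.luma()
    h, w = luma.shape
    xi = np.clip(np.round(sites[:, 0]).astype(int), 0, w - 1)
    yi = np.clip(np.round(sites[:, 1]).astype(int), 0, h - 1)
    vals = np.clip(luma[yi, xi], 0.0, 1.0)
    return np.minimum((vals * levels).astype(int), levels - 1)


def render_phosphenes(
    level_values: np.ndarray,
    sites: np.ndarray,
    image_size: tuple[int, int],
    grid: tuple[int, int],
    face_box: tuple[float, float, float, float],
    levels: int = DEFAULT_LEVELS,
) -> np.ndarray:
    """Sum Gaussian spots on black; size and peak both scale with level.

    A level-l spot has peak amplitude l/(L-1) and s.d.
    sigma = spacing * (SIGMA_BASE + SIGMA_GAIN * l/(L-1)); overlapping spots
    add and the sum is clipped to [0, 1].
    """
    w, h = image_size
    out = np.zeros((h, w), dtype=float)
    x0, y0, x1, y1 = face_box
    spacing = min((x1 - x0) / grid[1], (y1 - y0) / grid[0])
    ys_full, xs_full = np.mgrid[0:h, 0:w]
    for (sx, sy), lev in zip(sites, level_values):
        if lev == 0:
            continue
        frac = lev / (levels - 1)
        sigma = spacing * (SIGMA_BASE + SIGMA_GAIN * frac)
        r = int(np.ceil(4 * sigma))
        xlo, xhi = max(int(sx) - r, 0), min(int(sx) + r + 1, w)
        ylo, yhi = max(int(sy) - r, 0), min(int(sy) + r + 1, h)
        if xlo >= xhi or ylo >= yhi:
            continue
        dx = xs_full[ylo:yhi, xlo:xhi] - sx
        dy = ys_full[ylo:yhi, xlo:xhi] - sy
        out[ylo:yhi, xlo:xhi] += frac * np.exp(-(dx * dx + dy * dy) / (2 * sigma * sigma))
    return np.clip(out, 0.0, 1.0)


def phosphenise(
    image: FaceImage,
    cond: PhospheneCondition,
    landmarks: Optional[LandmarkSet] = None,
    identity: str = "",
    sex: str = "",
    viewpoint: str = "front",
) -> Stimulus:
    """Full prosthetic-vision rendering pipeline with provenance."""
    box = face_bounding_box(landmarks, image)
    sites = place_phosphene_grid(box, cond.grid)
    surviving = apply_dropout(sites, cond.dropout_fraction, cond.seed)
    level_values = sample_and_quantize(image, surviving, cond.levels)
    rendered = render_phosphenes(
        level_values, surviving, image.size, cond.grid, box, cond.levels
    )
    return Stimulus(
        image=image.with_pixels(rendered),
        identity=identity,
        sex=sex,
        viewpoint=viewpoint,
        resolution=cond.label,
        seed=cond.seed,
        extra={"grid": cond.grid, "dropout": cond.dropout_fraction},
    )
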