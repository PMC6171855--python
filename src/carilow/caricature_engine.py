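"""Shape-only face caricaturing.

A caricature exaggerates a face's deviation from a category-matched average:
each landmark v is pushed along the ray from the average landmark a through v,

    p' = v + s * (v - a),

where s is the caricature strength — s = 0 leaves the face veridical and
s = 1 doubles every landmark's distance from the average.  The study regime
is s = 0.6.  Only geometry is exaggerated ("warp not fade"): the veridical
image is warped from its own landmarks to the caricatured landmarks by a
Delaunay-triangulated piecewise-affine warp, and pixel values are never
blended toward or away from the average's texture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import Delaunay

from .image import FaceImage, Stimulus
from .landmark_io import LandmarkSet, SchemeMismatchError, require_compatible

#: strengths above this are refused unless explicitly allowed; larger values
#: were found to introduce morphing artefacts in the source experiments
MAX_DEFAULT_STRENGTH = 1.0


class DegenerateTriangleError(ValueError):
    """A destination triangle collapsed to zero area."""


class CategoryMismatchError(ValueError):
    """Face and average disagree on sex or viewpoint."""


@dataclass(frozen=True)
class CaricatureSpec:
    """Strength s >= 0 of a shape-only caricature (0.6 = 60%)."""

    strength: float
    shape_only: bool = True
    allow_extreme: bool = False

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ValueError("anti-caricatures (s < 0) are out of scope")
        if self.strength > MAX_DEFAULT_STRENGTH and not self.allow_extreme:
            raise ValueError(
                f"strength {self.strength} exceeds the validated regime "
                f"(s <= {MAX_DEFAULT_STRENGTH}); pass allow_extreme=True to override"
            )
        if not self.shape_only:
            raise ValueError("texture ('fade') caricaturing is not supported")


@dataclass(frozen=True)
class AverageFace:
    """Category average: sex x viewpoint, with landmarks and optional render."""

    sex: str
    viewpoint: str
    landmarks: LandmarkSet
    image: Optional[FaceImage] = None

    def __post_init__(self) -> None:
        if self.landmarks.viewpoint != self.viewpoint:
            raise CategoryMismatchError(
                f"average viewpoint {self.viewpoint!r} vs landmark "
                f"viewpoint {self.landmarks.viewpoint!r}"
            )


def caricature_landmarks(
    veridical: LandmarkSet, average: LandmarkSet, strength: float
) -> LandmarkSet:
    """Exaggerate landmark displacements from the average: p' = v + s(v - a)."""
    require_compatible(veridical, average)
    if strength < 0:
        raise ValueError("anti-caricatures (s < 0) are out of scope")
    v = veridical.points
    a = average.points
    return veridical.with_points(v + strength * (v - a))


def build_average_landmarks(sets: Sequence[LandmarkSet]) -> LandmarkSet:
    """Componentwise mean of corresponding landmarks over >= 1 sets."""
    if len(sets) == 0:
        raise ValueError("cannot average an empty list of landmark sets")
    first = sets[0]
    for other in sets[1:]:
        require_compatible(first, other)
    stack = np.stack([s.points for s in sets])
    return first.with_points(stack.mean(axis=0))


# ---------------------------------------------------------------------------
# piecewise-affine warping
# ---------------------------------------------------------------------------


def frame_anchors(size: tuple[int, int]) -> np.ndarray:
    """Fixed control points pinning the image frame: 4 corners + 4 edge midpoints."""
    w, h = size
    x1, y1 = w - 1.0, h - 1.0
    return np.array(
        [
            [0.0, 0.0], [x1, 0.0], [0.0, y1], [x1, y1],
            [x1 / 2, 0.0], [x1 / 2, y1], [0.0, y1 / 2], [x1, y1 / 2],
        ]
    )


def _bilinear(img: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    h, w = img.shape[:2]
    x = np.clip(x, 0.0, w - 1.0)
    y = np.clip(y, 0.0, h - 1.0)
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    fx = (x - x0)[..., None] if img.ndim == 3 else x - x0
    fy = (y - y0)[..., None] if img.ndim == 3 else y - y0
    top = img[y0, x0] * (1 - fx) + img[y0, x1] * fx
    bot = img[y1, x0] * (1 - fx) + img[y1, x1] * fx
    return top * (1 - fy) + bot * fy


def warp_points(image: np.ndarray, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Piecewise-affine backward warp of raw control points (no anchors added).

    The Delaunay triangulation is computed once on the source points and the
    same simplices are applied to the destination points.  Each output pixel
    inside a destination triangle is mapped back through that triangle's
    affine transform and sampled bilinearly; pixels outside every triangle
    pass through unchanged.  A zero-area destination triangle raises
    :class:`DegenerateTriangleError`; an orientation flip (src and dst
    triangle areas of opposite sign) is reported as a warning.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape:
        raise ValueError("src and dst control points must align")
    if np.array_equal(src, dst):  # identity warp is bit-exact
        return image.copy()

    tri = Delaunay(src)
    simplices = tri.simplices
    out = image.copy()
    h, w = image.shape[:2]
    flipped: list[int] = []

    for t_idx, simp in enumerate(simplices):
        d0, d1, d2 = dst[simp]
        s0, s1, s2 = src[simp]
        # barycentric basis in destination space
        m = np.array([[d1[0] - d0[0], d2[0] - d0[0]], [d1[1] - d0[1], d2[1] - d0[1]]])
        det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
        sm = np.array([[s1[0] - s0[0], s2[0] - s0[0]], [s1[1] - s0[1], s2[1] - s0[1]]])
        sdet = sm[0, 0] * sm[1, 1] - sm[0, 1] * sm[1, 0]
        if abs(det) < 1e-12:
            raise DegenerateTriangleError(
                f"destination triangle {t_idx} (vertices {simp.tolist()}) has zero area"
            )
        if det * sdet < 0:
            flipped.append(t_idx)
        minv = np.array([[m[1, 1], -m[0, 1]], [-m[1, 0], m[0, 0]]]) / det

        xlo = max(int(np.floor(min(d0[0], d1[0], d2[0]))), 0)
        xhi = min(int(np.ceil(max(d0[0], d1[0], d2[0]))), w - 1)
        ylo = max(int(np.floor(min(d0[1], d1[1], d2[1]))), 0)
        yhi = min(int(np.ceil(max(d0[1], d1[1], d2[1]))), h - 1)
        if xhi < xlo or yhi < ylo:
            continue
        ys, xs = np.mgrid[ylo : yhi + 1, xlo : xhi + 1]
        rel = np.stack([xs - d0[0], ys - d0[1]])
        lam1 = minv[0, 0] * rel[0] + minv[0, 1] * rel[1]
        lam2 = minv[1, 0] * rel[0] + minv[1, 1] * rel[1]
        lam0 = 1.0 - lam1 - lam2
        eps = 1e-9
        inside = (lam0 >= -eps) & (lam1 >= -eps) & (lam2 >= -eps)
        if not inside.any():
            continue
        sx = lam0 * s0[0] + lam1 * s1[0] + lam2 * s2[0]
        sy = lam0 * s0[1] + lam1 * s1[1] + lam2 * s2[1]
        vals = _bilinear(image, sx[inside], sy[inside])
        out[ys[inside], xs[inside]] = vals
    if flipped:
        warnings.warn(
            f"{len(flipped)} of {len(simplices)} triangles flip orientation "
            f"between source and destination (first: {flipped[:5]}); these are "
            "typically sliver triangles between adjacent contours",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


def warp_image(image: FaceImage, src: LandmarkSet, dst: LandmarkSet) -> FaceImage:
    """Warp a face from its landmarks to target landmarks, frame pinned.

    Control points are the landmarks plus fixed frame anchors (identical in
    source and destination), so the image borders stay in place.
    """
    require_compatible(src, dst)
    w, h = image.size
    if (w, h) != src.image_size:
        raise ValueError(f"image size {(w, h)} does not match landmark frame {src.image_size}")
    anchors = frame_anchors((w, h))
    src_pts = np.vstack([src.points, anchors])
    dst_pts = np.vstack([dst.points, anchors])
    return image.with_pixels(warp_points(image.pixels, src_pts, dst_pts))


def make_caricature(
    image: FaceImage,
    veridical_lms: LandmarkSet,
    average: AverageFace,
    spec: CaricatureSpec,
    identity: str = "",
    sex: str = "",
    annotation: str | None = None,
) -> Stimulus:
    """Full caricature step: exaggerate landmarks, warp the image, tag provenance."""
    if sex and average.sex and sex != average.sex:
        raise CategoryMismatchError(
            f"face sex {sex!r} does not match average category {average.sex!r}"
        )
    if veridical_lms.viewpoint != average.viewpoint:
        raise CategoryMismatchError(
            f"face viewpoint {veridical_lms.viewpoint!r} vs average {average.viewpoint!r}"
        )
    cari = caricature_landmarks(veridical_lms, average.landmarks, spec.strength)
    if spec.strength == 0.0:
        out = image.with_pixels(image.pixels.copy())
    else:
        out = warp_image(image, veridical_lms, cari)
    return Stimulus(
        image=out,
        identity=identity,
        sex=sex or average.sex,
        viewpoint=veridical_lms.viewpoint,
        caricature=spec.strength,
        scheme=annotation,
    )
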