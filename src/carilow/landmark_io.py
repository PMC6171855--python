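"""Landmark schemes and landmark-file I/O.

Two annotation schemes are modelled.  The hand-annotation scheme traces every
facial feature in detail — 147 points on frontal views (S147), dropping to 136
on rotated views where only one ear is visible (S136).  The automatic-detector
scheme is the widely used 68-landmark convention (S68: jawline 17, brows 5+5,
nose 4+5, eyes 6+6, mouth 12+8); it carries no forehead, ear, eyebrow-width or
mid-nose-width points, which is exactly the precision gap the caricature
comparison probes.

Coordinate convention (used everywhere in this package): origin at the
image's top-left corner, x rightward, y downward, 0-based floating-point
pixel units.

Files are plain text: a small ``key value`` header followed by one ``x y``
pair per line, written with shortest round-trip float formatting so that
save → load is bit-exact.  A JSON dialect with the same fields is also
supported (extension ``.json``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

VIEWPOINTS = ("front", "right10", "left10", "left30")

#: yaw (degrees) of each named viewpoint; positive = turn to the model's right
VIEWPOINT_YAW = {"front": 0.0, "right10": 10.0, "left10": -10.0, "left30": -30.0}


class LandmarkError(ValueError):
    """Base class for scheme/landmark validation failures."""


class SchemeMismatchError(LandmarkError):
    pass


class LandmarkValidationError(LandmarkError):
    pass


class LandmarkParseError(LandmarkError):
    pass


# ---------------------------------------------------------------------------
# scheme definitions
# ---------------------------------------------------------------------------

# Ordered (block name, point count) pairs; point order within a file follows
# this block order.  Coarse-region tags drive the covered_regions sets.
_S147_BLOCKS: tuple[tuple[str, int], ...] = (
    ("jaw", 21),
    ("forehead", 16),
    ("ear_right", 11),
    ("ear_left", 11),
    ("brow_right_top", 6),
    ("brow_right_bottom", 6),
    ("brow_left_top", 6),
    ("brow_left_bottom", 6),
    ("eye_right", 10),
    ("eye_left", 10),
    ("nose_bridge", 4),
    ("nose_mid_width", 4),
    ("nose_base", 7),
    ("nose_nostrils", 5),
    ("mouth_outer", 14),
    ("mouth_inner", 10),
)

# S136 = S147 with the occluded ear removed; the single remaining "ear" block
# refers to whichever ear stays visible for the set's viewpoint.
_S136_BLOCKS: tuple[tuple[str, int], ...] = tuple(
    ("ear", n) if name == "ear_right" else (name, n)
    for name, n in _S147_BLOCKS
    if name != "ear_left"
)

_S68_BLOCKS: tuple[tuple[str, int], ...] = (
    ("jaw", 17),
    ("brow_right_top", 5),
    ("brow_left_top", 5),
    ("nose_bridge", 4),
    ("nose_base", 5),
    ("eye_right", 6),
    ("eye_left", 6),
    ("mouth_outer", 12),
    ("mouth_inner", 8),
)

_COARSE_TAG = {
    "jaw": "jaw",
    "forehead": "forehead",
    "ear_right": "ears",
    "ear_left": "ears",
    "ear": "ears",
    "brow_right_top": "eyebrows",
    "brow_left_top": "eyebrows",
    "brow_right_bottom": "eyebrow-width",
    "brow_left_bottom": "eyebrow-width",
    "eye_right": "eyes",
    "eye_left": "eyes",
    "nose_bridge": "nose",
    "nose_base": "nose",
    "nose_mid_width": "mid-nose-width",
    "nose_nostrils": "nostrils",
    "mouth_outer": "mouth",
    "mouth_inner": "mouth",
}


@dataclass(frozen=True)
class LandmarkScheme:
    """An ordered landmark layout: named blocks of points with region tags."""

    name: str
    blocks: tuple[tuple[str, int], ...]

    @property
    def point_count(self) -> int:
        return sum(n for _, n in self.blocks)

    @property
    def region_labels(self) -> tuple[str, ...]:
        """Per-point block label, in point order."""
        labels: list[str] = []
        for name, n in self.blocks:
            labels.extend([name] * n)
        return tuple(labels)

    @property
    def covered_regions(self) -> frozenset[str]:
        return frozenset(_COARSE_TAG[name] for name, _ in self.blocks)

    def block_slice(self, block: str) -> slice:
        """Index range of a named block within the point array."""
        start = 0
        for name, n in self.blocks:
            if name == block:
                return slice(start, start + n)
            start += n
        raise KeyError(f"scheme {self.name} has no block {block!r}")

    def has_block(self, block: str) -> bool:
        return any(name == block for name, _ in self.blocks)


S147 = LandmarkScheme("S147", _S147_BLOCKS)
S136 = LandmarkScheme("S136", _S136_BLOCKS)
S68 = LandmarkScheme("S68", _S68_BLOCKS)

_SCHEMES = {s.name: s for s in (S147, S136, S68)}

assert S147.point_count == 147 and S136.point_count == 136 and S68.point_count == 68


def get_scheme(name: str) -> LandmarkScheme:
    try:
        return _SCHEMES[name]
    except KeyError:
        raise LandmarkError(f"unknown scheme {name!r}; known: {sorted(_SCHEMES)}")


def scheme_for(annotation: str, viewpoint: str) -> LandmarkScheme:
    """Scheme used by an annotation family (``hand``/``auto``) at a viewpoint."""
    if viewpoint not in VIEWPOINTS:
        raise LandmarkError(f"unknown viewpoint {viewpoint!r}; known: {VIEWPOINTS}")
    if annotation == "hand":
        return S147 if viewpoint == "front" else S136
    if annotation == "auto":
        return S68
    raise LandmarkError(f"unknown annotation family {annotation!r} (use 'hand' or 'auto')")


def scheme_point_count(annotation: str, viewpoint: str) -> int:
    """147 for hand/front, 136 for hand non-frontal, 68 for auto anywhere."""
    return scheme_for(annotation, viewpoint).point_count


# ---------------------------------------------------------------------------
# landmark sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LandmarkSet:
    """Ordered 2-D points bound to a scheme, viewpoint and image frame."""

    scheme: LandmarkScheme
    viewpoint: str
    points: np.ndarray  # (n, 2) float, pixel units
    image_size: tuple[int, int]  # (width, height)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise LandmarkValidationError(f"points must be (n, 2); got {pts.shape}")
        if pts.shape[0] != self.scheme.point_count:
            raise LandmarkValidationError(
                f"scheme {self.scheme.name}: expected {self.scheme.point_count} "
                f"points, found {pts.shape[0]}"
            )
        if self.viewpoint not in VIEWPOINTS:
            raise LandmarkValidationError(f"unknown viewpoint {self.viewpoint!r}")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "image_size", tuple(int(v) for v in self.image_size))

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def block(self, name: str) -> np.ndarray:
        return self.points[self.scheme.block_slice(name)]

    def with_points(self, points: np.ndarray) -> "LandmarkSet":
        return LandmarkSet(self.scheme, self.viewpoint, points, self.image_size)

    def validate(self, check_bounds: bool = True) -> None:
        """Raise if the set is inconsistent; optionally check frame bounds."""
        w, h = self.image_size
        if check_bounds:
            x, y = self.points[:, 0], self.points[:, 1]
            bad = (x < 0) | (x >= w) | (y < 0) | (y >= h)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise LandmarkValidationError(
                    f"point {i} at {tuple(self.points[i])} outside frame {w}x{h}"
                )

    def allclose(self, other: "LandmarkSet", tol: float = 0.0) -> bool:
        return (
            self.scheme.name == other.scheme.name
            and self.viewpoint == other.viewpoint
            and self.image_size == other.image_size
            and bool(np.allclose(self.points, other.points, rtol=0, atol=tol))
        )


def require_compatible(a: LandmarkSet, b: LandmarkSet) -> None:
    """Raise unless two sets share scheme, viewpoint and point order."""
    if a.scheme.name != b.scheme.name:
        raise SchemeMismatchError(f"scheme mismatch: {a.scheme.name} vs {b.scheme.name}")
    if a.viewpoint != b.viewpoint:
        raise SchemeMismatchError(f"viewpoint mismatch: {a.viewpoint} vs {b.viewpoint}")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_MAGIC = "# carilow landmarks v1"


def save_landmarks(lms: LandmarkSet, path: str | Path) -> None:
    """Write a landmark set; ``.json`` paths get the JSON dialect."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".json":
        payload = {
            "scheme": lms.scheme.name,
            "viewpoint": lms.viewpoint,
            "image_size": list(lms.image_size),
            "points": [[float(x), float(y)] for x, y in lms.points],
        }
        path.write_text(json.dumps(payload, indent=1))
        return
    lines = [
        _MAGIC,
        f"scheme {lms.scheme.name}",
        f"viewpoint {lms.viewpoint}",
        f"image_size {lms.image_size[0]} {lms.image_size[1]}",
        f"n_points {lms.n_points}",
    ]
    # repr() gives the shortest decimal that round-trips the float exactly
    lines += [f"{float(x)!r} {float(y)!r}" for x, y in lms.points]
    path.write_text("\n".join(lines) + "\n")


def load_landmarks(path: str | Path, scheme: str | LandmarkScheme | None = None) -> LandmarkSet:
    """Read a landmark file; optionally enforce an expected scheme."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    expected = get_scheme(scheme) if isinstance(scheme, str) else scheme
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        lms = LandmarkSet(
            get_scheme(payload["scheme"]),
            payload["viewpoint"],
            np.asarray(payload["points"], dtype=float),
            tuple(payload["image_size"]),
        )
    else:
        lms = _parse_text(path)
    if expected is not None and lms.scheme.name != expected.name:
        raise LandmarkValidationError(
            f"{path}: expected {expected.point_count} points "
            f"({expected.name}), found {lms.n_points} ({lms.scheme.name})"
        )
    lms.validate(check_bounds=False)
    return lms


def _parse_text(path: Path) -> LandmarkSet:
    header: dict[str, str] = {}
    pts: list[tuple[float, float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] in ("scheme", "viewpoint", "image_size", "n_points"):
                header[parts[0]] = " ".join(parts[1:])
                continue
            if len(parts) != 2:
                raise LandmarkParseError(f"{path}:{lineno}: expected 'x y', got {line!r}")
            try:
                pts.append((float(parts[0]), float(parts[1])))
            except ValueError:
                raise LandmarkParseError(f"{path}:{lineno}: non-numeric coordinate {line!r}")
    for key in ("scheme", "viewpoint", "image_size"):
        if key not in header:
            raise LandmarkParseError(f"{path}: missing header field {key!r}")
    scheme = get_scheme(header["scheme"])
    declared = int(header.get("n_points", len(pts)))
    if declared != len(pts) or len(pts) != scheme.point_count:
        raise LandmarkValidationError(
            f"{path}: expected {scheme.point_count}, found {len(pts)}"
        )
    w, h = (int(v) for v in header["image_size"].split())
    return LandmarkSet(scheme, header["viewpoint"], np.asarray(pts), (w, h))
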