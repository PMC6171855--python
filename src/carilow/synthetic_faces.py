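"""Parametric synthetic faces with ground-truth landmarks in both schemes.

The generator emulates the stimulus set of the rating experiments — 26
identities (13 male, 13 female), each seen from four viewpoints (front, 10
deg right, 10 deg left, 30 deg left), plus sex x viewpoint average faces
built from a larger disjoint pool — so the whole caricaturing / low-vision /
rating pipeline runs with no external data.

Faces are schematic, not photorealistic: a sex-specific 147-point template
(every region of the hand-annotation scheme traced: outline, forehead, ears,
brows with width, nose with mid-width, eyes, mouth) is perturbed by a
smooth per-identity displacement field (per-region affine plus small
per-point jitter), projected to a viewpoint by horizontal foreshortening,
and rendered as a smoothly shaded raster so that warps produce visible,
testable pixel changes.  The 68-point annotation is derived deterministically
from the 147-point ground truth by selecting / arc-length-resampling the
regions the automatic detector covers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon

from .caricature_engine import AverageFace, build_average_landmarks
from .image import FaceImage, Stimulus
from .landmark_io import (
    S68,
    S136,
    S147,
    VIEWPOINT_YAW,
    VIEWPOINTS,
    LandmarkSet,
)

DEFAULT_SIZE = (128, 128)

# displacement-field scale knobs (fractions of image width at distinctiveness 1)
_ROT_SD = 0.02          # radians, per-region rotation
_SCALE_SD = 0.05        # per-region, per-axis log-ish scale
_SHIFT_SD = 0.012       # per-region translation
_JITTER_SD = 0.0035     # per-point jitter

# region groups that move together under the per-identity affine
_REGION_GROUPS: tuple[tuple[str, ...], ...] = (
    ("jaw",),
    ("forehead",),
    ("ear_right",),
    ("ear_left",),
    ("brow_right_top", "brow_right_bottom"),
    ("brow_left_top", "brow_left_bottom"),
    ("eye_right",),
    ("eye_left",),
    ("nose_bridge", "nose_mid_width", "nose_base", "nose_nostrils"),
    ("mouth_outer", "mouth_inner"),
)


@dataclass(frozen=True)
class IdentityParams:
    """One synthetic identity: a displacement field off its sex template."""

    id: str
    sex: str
    displacement: np.ndarray  # (147, 2), pixel units at distinctiveness 1
    distinctiveness: float = 1.0


@dataclass
class StimulusSet:
    """A bag of stimuli plus a manifest table describing each one."""

    stimuli: list[Stimulus]
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.stimuli) != len(self.manifest):
            raise ValueError("manifest rows must match stimulus count")


@dataclass
class Cohort:
    """Identities, ground-truth landmarks, veridical renders and averages."""

    identities: list[IdentityParams]
    image_size: tuple[int, int]
    landmarks: dict[tuple[str, str, str], LandmarkSet]  # (id, viewpoint, annotation)
    images: dict[tuple[str, str], FaceImage]  # (id, viewpoint) -> veridical render
    averages: dict[tuple[str, str, str], AverageFace]  # (sex, viewpoint, annotation)

    def ids_by_sex(self, sex: str) -> list[str]:
        return [p.id for p in self.identities if p.sex == sex]


# ---------------------------------------------------------------------------
# template geometry
# ---------------------------------------------------------------------------


def _arc(cx, cy, rx, ry, t0_deg, t1_deg, n, endpoint=True):
    t = np.deg2rad(np.linspace(t0_deg, t1_deg, n, endpoint=endpoint))
    return np.column_stack([cx + rx * np.cos(t), cy + ry * np.sin(t)])


def _template_fractions(sex: str) -> np.ndarray:
    """147 template points in unit-square fractions, y downward."""
    if sex not in ("M", "F"):
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    jaw_rx = 0.270 if sex == "M" else 0.245        # male jaw is wider
    brow_thick = 0.026 if sex == "M" else 0.018
    cx = 0.5

    jaw = _arc(cx, 0.50, jaw_rx, 0.36, -15, 195, 21)
    forehead = _arc(cx, 0.46, 0.24, 0.30, 195, 345, 16)

    ear_cx = cx + jaw_rx + 0.02
    ear_r = _arc(ear_cx, 0.48, 0.035, 0.075, -80, 80, 11)
    ear_l = ear_r * np.array([-1.0, 1.0]) + np.array([2 * cx, 0.0])

    bx, by, bw = cx + 0.12, 0.355, 0.085
    u = np.linspace(-1.0, 1.0, 6)
    brow_r_top = np.column_stack([bx + bw * u, by - 0.020 * (1 - u**2)])
    brow_r_bot = np.column_stack([bx + bw * u[::-1], by - 0.020 * (1 - u**2) + brow_thick])
    brow_l_top = brow_r_top * np.array([-1.0, 1.0]) + np.array([2 * cx, 0.0])
    brow_l_bot = brow_r_bot * np.array([-1.0, 1.0]) + np.array([2 * cx, 0.0])

    eye_r = _arc(cx + 0.115, 0.43, 0.055, 0.028, 0, 360, 10, endpoint=False)
    eye_l = eye_r * np.array([-1.0, 1.0]) + np.array([2 * cx, 0.0])

    nose_bridge = np.column_stack([np.full(4, cx), np.linspace(0.435, 0.535, 4)])
    nose_mid = np.array(
        [[cx - 0.030, 0.500], [cx + 0.030, 0.500], [cx - 0.035, 0.525], [cx + 0.035, 0.525]]
    )
    nose_base = _arc(cx, 0.575, 0.052, 0.020, 180, 0, 7)
    nostrils = np.array(
        [
            [cx - 0.030, 0.565],
            [cx - 0.018, 0.572],
            [cx, 0.555],
            [cx + 0.018, 0.572],
            [cx + 0.030, 0.565],
        ]
    )

    mouth_outer = _arc(cx, 0.655, 0.085, 0.032, 0, 360, 14, endpoint=False)
    mouth_inner = _arc(cx, 0.655, 0.055, 0.014, 0, 360, 10, endpoint=False)

    pts = np.vstack(
        [
            jaw, forehead, ear_r, ear_l,
            brow_r_top, brow_r_bot, brow_l_top, brow_l_bot,
            eye_r, eye_l,
            nose_bridge, nose_mid, nose_base, nostrils,
            mouth_outer, mouth_inner,
        ]
    )
    assert pts.shape == (147, 2)
    return pts


def make_template(sex: str, size: tuple[int, int] = DEFAULT_SIZE) -> LandmarkSet:
    """Deterministic sex-specific 147-point frontal template."""
    w, h = size
    pts = _template_fractions(sex) * np.array([w, h])
    return LandmarkSet(S147, "front", pts, size)


# ---------------------------------------------------------------------------
# identities
# ---------------------------------------------------------------------------


def sample_identity(
    template: LandmarkSet,
    distinctiveness: float,
    seed: int,
    label: str = "id",
    sex: str = "M",
) -> IdentityParams:
    """Draw a smooth random displacement field off the template.

    Each region group gets a small random affine (rotation, per-axis scale,
    translation) about its centroid, plus independent per-point jitter; the
    field is stored at unit scale and multiplied by ``distinctiveness`` when
    landmarks are materialised.
    """
    rng = np.random.default_rng(seed)
    w = template.image_size[0]
    pts = template.points
    disp = np.zeros_like(pts)
    for group in _REGION_GROUPS:
        idx = np.concatenate([np.arange(147)[template.scheme.block_slice(b)] for b in group])
        centroid = pts[idx].mean(axis=0)
        theta = rng.normal(0.0, _ROT_SD)
        sx, sy = 1.0 + rng.normal(0.0, _SCALE_SD, size=2)
        shift = rng.normal(0.0, _SHIFT_SD * w, size=2)
        c, s = math.cos(theta), math.sin(theta)
        rot = np.array([[c, -s], [s, c]])
        local = (pts[idx] - centroid) * np.array([sx, sy])
        moved = local @ rot.T + centroid + shift
        disp[idx] = moved - pts[idx]
    disp += rng.normal(0.0, _JITTER_SD * w, size=disp.shape)
    return IdentityParams(label, sex, disp, float(distinctiveness))


def identity_landmarks(template: LandmarkSet, ident: IdentityParams) -> LandmarkSet:
    """Frontal 147-point landmarks for an identity."""
    return template.with_points(
        template.points + ident.distinctiveness * ident.displacement
    )


# ---------------------------------------------------------------------------
# viewpoints and the 68-point derivation
# ---------------------------------------------------------------------------


def project_viewpoint(landmarks: LandmarkSet, viewpoint: str) -> LandmarkSet:
    """Foreshorten horizontally for a named yaw; drop the occluded ear.

    x -> x_c + (x - x_c) cos(yaw) about the vertical image midline.  Under
    the hand scheme, any non-frontal yaw hides one ear (the left ear for
    rightward turns, the right ear for leftward), taking 147 -> 136 points.
    """
    if viewpoint not in VIEWPOINT_YAW:
        raise ValueError(f"unknown viewpoint {viewpoint!r}")
    yaw = VIEWPOINT_YAW[viewpoint]
    if yaw == 0.0:
        return LandmarkSet(landmarks.scheme, "front", landmarks.points.copy(), landmarks.image_size)
    w = landmarks.image_size[0]
    xc = 0.5 * w
    pts = landmarks.points.copy()
    pts[:, 0] = xc + (pts[:, 0] - xc) * math.cos(math.radians(yaw))
    if landmarks.scheme.name == "S147":
        occluded = "ear_left" if yaw > 0 else "ear_right"
        keep = np.ones(147, dtype=bool)
        keep[landmarks.scheme.block_slice(occluded)] = False
        return LandmarkSet(S136, viewpoint, pts[keep], landmarks.image_size)
    return LandmarkSet(landmarks.scheme, viewpoint, pts, landmarks.image_size)


def resample_polyline(pts: np.ndarray, n: int, closed: bool = False) -> np.ndarray:
    """Evenly respace n points along a polyline by arc length."""
    pts = np.asarray(pts, dtype=float)
    if closed:
        pts = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total == 0:
        return np.repeat(pts[:1], n, axis=0)
    targets = (
        np.linspace(0, total, n, endpoint=False) if closed else np.linspace(0, total, n)
    )
    out = np.empty((n, 2))
    for k, t in enumerate(targets):
        i = min(int(np.searchsorted(cum, t, side="right")) - 1, len(seg) - 1)
        f = (t - cum[i]) / seg[i] if seg[i] > 0 else 0.0
        out[k] = pts[i] + f * (pts[i + 1] - pts[i])
    return out


def derive_68(landmarks: LandmarkSet) -> LandmarkSet:
    """Deterministic 68-point annotation from 147/136-point ground truth.

    Keeps jawline, brow top edges, nose bridge and base, eyes and mouth;
    drops forehead, ears, eyebrow width and mid-nose width — the regions the
    automatic detector does not cover.
    """
    if landmarks.scheme.name not in ("S147", "S136"):
        raise ValueError(f"derive_68 expects hand-scheme input, got {landmarks.scheme.name}")
    lb = landmarks.block
    pts = np.vstack(
        [
            resample_polyline(lb("jaw"), 17),
            resample_polyline(lb("brow_right_top"), 5),
            resample_polyline(lb("brow_left_top"), 5),
            lb("nose_bridge"),
            resample_polyline(lb("nose_base"), 5),
            resample_polyline(lb("eye_right"), 6, closed=True),
            resample_polyline(lb("eye_left"), 6, closed=True),
            resample_polyline(lb("mouth_outer"), 12, closed=True),
            resample_polyline(lb("mouth_inner"), 8, closed=True),
        ]
    )
    return LandmarkSet(S68, landmarks.viewpoint, pts, landmarks.image_size)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _fill(canvas: np.ndarray, poly: np.ndarray, value: float) -> None:
    rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=canvas.shape)
    canvas[rr, cc] = value


def _stroke(canvas: np.ndarray, pts: np.ndarray, value: float, radius: float = 1.2) -> None:
    # dense sampling along the polyline, painting small discs
    dense = resample_polyline(pts, max(4 * len(pts), 32))
    h, w = canvas.shape
    r = int(np.ceil(radius))
    for x, y in dense:
        xlo, xhi = max(int(x) - r, 0), min(int(x) + r + 1, w)
        ylo, yhi = max(int(y) - r, 0), min(int(y) + r + 1, h)
        if xlo >= xhi or ylo >= yhi:
            continue
        ys, xs = np.mgrid[ylo:yhi, xlo:xhi]
        mask = (xs - x) ** 2 + (ys - y) ** 2 <= radius**2
        canvas[ylo:yhi, xlo:xhi][mask] = value


def render_face(landmarks: LandmarkSet, size: tuple[int, int] | None = None) -> FaceImage:
    """Smooth shaded grayscale render of a landmark set.

    Every drawn element is derived from the landmark positions, so rendering
    deformed landmarks approximates warping the rendered original.  Output is
    deterministic for identical input.
    """
    if landmarks.scheme.name not in ("S147", "S136"):
        raise ValueError("render_face expects hand-scheme landmarks")
    size = size or landmarks.image_size
    w, h = size
    img = np.full((h, w), 0.12)
    lb = landmarks.block

    ear_blocks = [b for b in ("ear_right", "ear_left", "ear") if landmarks.scheme.has_block(b)]
    for b in ear_blocks:
        _fill(img, lb(b), 0.62)

    outline = np.vstack([lb("jaw"), lb("forehead")])
    _fill(img, outline, 0.75)

    # radial shading off the face centroid makes the skin a smooth gradient
    centroid = outline.mean(axis=0)
    ys, xs = np.mgrid[0:h, 0:w]
    r2 = ((xs - centroid[0]) ** 2 + (ys - centroid[1]) ** 2) / (0.55 * w) ** 2
    face_mask = img > 0.5
    img[face_mask] = (0.82 - 0.30 * np.clip(r2, 0, 1.4))[face_mask]

    for b in ("brow_right_top", "brow_left_top"):
        bot = b.replace("_top", "_bottom")
        if landmarks.scheme.has_block(bot):
            _fill(img, np.vstack([lb(b), lb(bot)]), 0.25)
        else:
            _stroke(img, lb(b), 0.25, radius=1.4)

    for b in ("eye_right", "eye_left"):
        eye = lb(b)
        _fill(img, eye, 0.95)
        c = eye.mean(axis=0)
        pr = 0.38 * (eye[:, 0].max() - eye[:, 0].min()) / 2
        _stroke(img, np.array([c, c]), 0.08, radius=max(pr, 1.0))

    _stroke(img, lb("nose_bridge"), 0.88, radius=1.2)
    _stroke(img, lb("nose_base"), 0.35, radius=1.0)
    if landmarks.scheme.has_block("nose_nostrils"):
        for p in lb("nose_nostrils"):
            _stroke(img, np.array([p, p]), 0.20, radius=1.0)

    _fill(img, lb("mouth_outer"), 0.45)
    _fill(img, lb("mouth_inner"), 0.22)

    img = gaussian_filter(img, 0.8, mode="nearest")
    return FaceImage(np.clip(img, 0.0, 1.0))


# ---------------------------------------------------------------------------
# cohorts and averages
# ---------------------------------------------------------------------------


def _sample_pool(
    template: LandmarkSet, sex: str, n: int, seed: int, distinctiveness: float, prefix: str
) -> list[IdentityParams]:
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    return [
        sample_identity(template, distinctiveness, int(s), label=f"{prefix}{i:02d}", sex=sex)
        for i, s in enumerate(seeds)
    ]


def make_cohort(
    n_male: int = 13,
    n_female: int = 13,
    viewpoints: Sequence[str] = VIEWPOINTS,
    seed: int = 0,
    size: tuple[int, int] = DEFAULT_SIZE,
    distinctiveness: float = 1.0,
    pool_size: int = 50,
    centre: bool = True,
    render: bool = True,
) -> Cohort:
    """Full synthetic stimulus base: identities, landmarks, renders, averages.

    Averages are built per sex x viewpoint from a seeded pool (default 50 per
    sex) disjoint from the test identities, mirroring category averages taken
    over a large number of individuals.  With ``centre=True`` the cohort's
    displacement fields are mean-centred within sex, so the cohort average
    coincides with the sex template.
    """
    templates = {s: make_template(s, size) for s in ("M", "F")}
    identities: list[IdentityParams] = []
    for sex, n, sub in (("M", n_male, 0), ("F", n_female, 1)):
        cohort_raw = _sample_pool(
            templates[sex], sex, n, seed * 4 + sub, distinctiveness, prefix=f"{sex}"
        )
        if centre and n > 0:
            mean_disp = np.mean([p.displacement for p in cohort_raw], axis=0)
            cohort_raw = [
                IdentityParams(p.id, p.sex, p.displacement - mean_disp, p.distinctiveness)
                for p in cohort_raw
            ]
        identities.extend(cohort_raw)

    landmarks: dict[tuple[str, str, str], LandmarkSet] = {}
    images: dict[tuple[str, str], FaceImage] = {}
    for ident in identities:
        frontal = identity_landmarks(templates[ident.sex], ident)
        for vp in viewpoints:
            hand = project_viewpoint(frontal, vp)
            landmarks[(ident.id, vp, "hand")] = hand
            landmarks[(ident.id, vp, "auto")] = derive_68(hand)
            if render:
                images[(ident.id, vp)] = render_face(hand)

    averages: dict[tuple[str, str, str], AverageFace] = {}
    for sex, sub in (("M", 2), ("F", 3)):
        pool = _sample_pool(
            templates[sex], sex, pool_size, seed * 4 + sub, distinctiveness, prefix=f"p{sex}"
        )
        pool_frontal = [identity_landmarks(templates[sex], p) for p in pool]
        for vp in viewpoints:
            hand_sets = [project_viewpoint(f, vp) for f in pool_frontal]
            avg_hand = build_average_landmarks(hand_sets)
            avg_auto = build_average_landmarks([derive_68(s) for s in hand_sets])
            avg_img = render_face(avg_hand) if render else None
            averages[(sex, vp, "hand")] = AverageFace(sex, vp, avg_hand, avg_img)
            averages[(sex, vp, "auto")] = AverageFace(sex, vp, avg_auto, avg_img)

    return Cohort(identities, size, landmarks, images, averages)


def build_caricature_inventory(cohort: Cohort, strength: float = 0.6) -> StimulusSet:
    """Veridical + 68-point + 147-point caricatures for every identity x view.

    For the default 26-identity, 4-viewpoint cohort this yields 312 stimuli:
    104 veridical, 104 C-68p, 104 C-147p.
    """
    from .caricature_engine import CaricatureSpec, make_caricature

    spec = CaricatureSpec(strength)
    stimuli: list[Stimulus] = []
    rows = []
    vps = sorted({vp for (_, vp, _) in cohort.landmarks})
    vps = [v for v in VIEWPOINTS if v in vps]
    for ident in cohort.identities:
        for vp in vps:
            img = cohort.images[(ident.id, vp)]
            for annotation, label in ((None, "V"), ("auto", "C-68p"), ("hand", "C-147p")):
                if annotation is None:
                    stim = Stimulus(
                        image=img, identity=ident.id, sex=ident.sex, viewpoint=vp,
                        caricature=0.0,
                    )
                else:
                    lms = cohort.landmarks[(ident.id, vp, annotation)]
                    avg = cohort.averages[(ident.sex, vp, annotation)]
                    stim = make_caricature(
                        img, lms, avg, spec,
                        identity=ident.id, sex=ident.sex, annotation=annotation,
                    )
                stimuli.append(stim)
                rows.append(
                    {
                        "identity": ident.id,
                        "sex": ident.sex,
                        "viewpoint": vp,
                        "caricature": label,
                        "strength": 0.0 if annotation is None else strength,
                        "resolution": "highres",
                    }
                )
    manifest = pd.DataFrame(rows)
    return StimulusSet(stimuli, manifest)
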