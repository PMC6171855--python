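"""Caricature algebra and piecewise-affine warping."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from carilow.caricature_engine import (
    CaricatureSpec,
    DegenerateTriangleError,
    CategoryMismatchError,
    AverageFace,
    build_average_landmarks,
    caricature_landmarks,
    frame_anchors,
    make_caricature,
    warp_image,
    warp_points,
)
from carilow.image import FaceImage
from carilow.landmark_io import S68, LandmarkSet, SchemeMismatchError


def _set(points, scheme=S68, size=(200, 200), viewpoint="front"):
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] != scheme.point_count:  # pad with a fixed lattice
        extra = scheme.point_count - pts.shape[0]
        grid = np.column_stack(
            [20 + 10 * (np.arange(extra) % 10), 20 + 10 * (np.arange(extra) // 10)]
        ).astype(float)
        pts = np.vstack([pts, grid])
    return LandmarkSet(scheme, viewpoint, pts, size)


# ---------------------------------------------------------------------------
# landmark algebra
# ---------------------------------------------------------------------------


def test_strength_one_doubles_distance_from_average():
    v = _set([[110.0, 100.0]])
    a = _set([[100.0, 100.0]], size=v.image_size)
    a = a.with_points(np.where([[True, True]] * 68, a.points, a.points))
    # make averages differ only at point 0 so the example is isolated
    a = v.with_points(np.vstack([[100.0, 100.0], v.points[1:]]))
    out = caricature_landmarks(v, a, 1.0)
    assert np.allclose(out.points[0], [120.0, 100.0])
    assert np.array_equal(out.points[1:], v.points[1:])


def test_zero_strength_and_zero_displacement_are_identities(rng):
    v = _set(rng.uniform(10, 190, size=(68, 2)))
    a = _set(rng.uniform(10, 190, size=(68, 2)))
    assert np.array_equal(caricature_landmarks(v, a, 0.0).points, v.points)
    assert np.array_equal(caricature_landmarks(v, v, 0.7).points, v.points)


@given(s=st.floats(0.0, 3.0), seed=st.integers(0, 2**16))
def test_collinearity_and_distance_scaling(s, seed):
    rng = np.random.default_rng(seed)
    v = _set(rng.uniform(10, 190, size=(68, 2)))
    a = _set(rng.uniform(10, 190, size=(68, 2)))
    out = caricature_landmarks(v, a, s)
    want = (1 + s) * np.linalg.norm(v.points - a.points, axis=1)
    got = np.linalg.norm(out.points - a.points, axis=1)
    assert np.allclose(got, want, rtol=1e-9, atol=0)
    # p' - a is parallel to v - a (zero cross product)
    u1, u2 = out.points - a.points, v.points - a.points
    cross = u1[:, 0] * u2[:, 1] - u1[:, 1] * u2[:, 0]
    scale = np.linalg.norm(v.points - a.points, axis=1) ** 2
    assert np.allclose(cross, 0.0, atol=1e-6 * scale.max())


@given(s1=st.floats(0.0, 1.0), s2=st.floats(0.0, 1.0), seed=st.integers(0, 2**16))
def test_caricature_composition_identity(s1, s2, seed):
    rng = np.random.default_rng(seed)
    v = _set(rng.uniform(10, 190, size=(68, 2)))
    a = _set(rng.uniform(10, 190, size=(68, 2)))
    step = caricature_landmarks(caricature_landmarks(v, a, s1), a, s2)
    combined = caricature_landmarks(v, a, s1 + s2 + s1 * s2)
    assert np.allclose(step.points, combined.points, rtol=1e-9, atol=1e-9)


def test_negative_strength_and_scheme_mismatch_rejected(rng, template_m):
    v = _set(rng.uniform(10, 190, size=(68, 2)))
    a = _set(rng.uniform(10, 190, size=(68, 2)))
    with pytest.raises(ValueError, match="anti-caricature"):
        caricature_landmarks(v, a, -0.2)
    with pytest.raises(SchemeMismatchError):
        caricature_landmarks(template_m, a, 0.5)


def test_spec_caps_extreme_strengths():
    with pytest.raises(ValueError, match="allow_extreme"):
        CaricatureSpec(1.5)
    assert CaricatureSpec(1.5, allow_extreme=True).strength == 1.5
    with pytest.raises(ValueError):
        CaricatureSpec(-0.1)


def test_average_landmarks_match_loop_oracle(rng):
    sets = [_set(rng.uniform(10, 190, size=(68, 2))) for _ in range(20)]
    avg = build_average_landmarks(sets)
    # independent oracle: explicit per-coordinate accumulation
    acc = np.zeros((68, 2))
    for s in sets:
        for i in range(68):
            acc[i, 0] += s.points[i, 0]
            acc[i, 1] += s.points[i, 1]
    assert np.allclose(avg.points, acc / len(sets), rtol=1e-12)
    # n identical sets average to themselves
    same = build_average_landmarks([sets[0]] * 5)
    assert np.allclose(same.points, sets[0].points, rtol=1e-14)


def test_average_of_empty_list_rejected():
    with pytest.raises(ValueError):
        build_average_landmarks([])


# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------


def test_identity_warp_is_bit_exact(rng):
    img = rng.uniform(size=(60, 60))
    pts = rng.uniform(5, 55, size=(12, 2))
    out = warp_points(img, pts, pts)
    assert np.array_equal(out, img)


def test_translation_warp_matches_direct_resampling(rng):
    img = rng.uniform(size=(80, 80))
    base = np.array(
        [[0, 0], [79, 0], [0, 79], [79, 79], [40, 0], [40, 79], [0, 40], [79, 40],
         [25, 30], [55, 30], [40, 60]],
        dtype=float,
    )
    t = 6.0
    out = warp_points(img, base, base + np.array([t, 0.0]))
    # oracle: direct affine resampling x_src = x_dst - t (interior only)
    ys, xs = np.mgrid[10:70, 20:70]
    expect = img[ys, (xs - int(t))]
    assert np.allclose(out[10:70, 20:70], expect, atol=1e-9)


def test_single_triangle_matches_closed_form_affine(rng):
    img = rng.uniform(size=(60, 60))
    src = np.array([[5.0, 5.0], [55.0, 8.0], [20.0, 55.0], [55.0, 55.0]])
    dst = np.array([[8.0, 7.0], [52.0, 10.0], [25.0, 50.0], [55.0, 55.0]])
    out = warp_points(img, src, dst)
    # hand-solved affine for the triangle formed by points {0, 1, 2}
    A = np.vstack([dst[:3].T, np.ones(3)]).T
    coef_x = np.linalg.solve(A, src[:3, 0])
    coef_y = np.linalg.solve(A, src[:3, 1])
    # probe strictly interior pixels of that destination triangle
    probes = []
    for lam in ([0.4, 0.35, 0.25], [0.2, 0.3, 0.5], [0.6, 0.2, 0.2]):
        p = lam @ dst[:3]
        probes.append(p)
    for px, py in probes:
        xi, yi = int(round(px)), int(round(py))
        sx = coef_x @ [xi, yi, 1.0]
        sy = coef_y @ [xi, yi, 1.0]
        x0, y0 = int(np.floor(sx)), int(np.floor(sy))
        fx, fy = sx - x0, sy - y0
        expect = (
            img[y0, x0] * (1 - fx) * (1 - fy)
            + img[y0, x0 + 1] * fx * (1 - fy)
            + img[y0 + 1, x0] * (1 - fx) * fy
            + img[y0 + 1, x0 + 1] * fx * fy
        )
        assert out[yi, xi] == pytest.approx(expect, abs=1e-6)


def test_degenerate_destination_triangle_raises(rng):
    img = rng.uniform(size=(40, 40))
    src = np.array([[5.0, 5.0], [35.0, 5.0], [20.0, 35.0]])
    dst = np.array([[5.0, 5.0], [35.0, 5.0], [20.0, 5.0]])  # collapsed onto a line
    with pytest.raises(DegenerateTriangleError):
        warp_points(img, src, dst)


def test_warp_preserves_size_and_value_range(rng, template_m):
    from carilow.synthetic_faces import render_face, identity_landmarks, sample_identity

    ident = sample_identity(template_m, 1.0, 3, sex="M")
    v = identity_landmarks(template_m, ident)
    img = render_face(v)
    moved = v.with_points(v.points + [1.5, -1.0])
    out = warp_image(img, v, moved)
    assert out.size == img.size
    assert out.pixels.min() >= img.pixels.min() - 1e-12
    assert out.pixels.max() <= img.pixels.max() + 1e-12


def test_moving_one_point_changes_only_its_neighbourhood(rng):
    img = rng.uniform(size=(100, 100))
    pts = np.vstack([frame_anchors((100, 100)), [[30.0, 30.0], [70.0, 30.0], [50.0, 70.0]]])
    dst = pts.copy()
    dst[8] += [4.0, 3.0]  # move one interior landmark
    out = warp_points(img, pts, dst)
    changed = np.argwhere(out != img)
    if len(changed):
        dists = np.hypot(changed[:, 1] - 30.0, changed[:, 0] - 30.0)
        # influence is bounded by the incident triangles, all within the frame
        assert dists.max() < 100


def test_make_caricature_provenance_and_category_check(small_cohort_rendered):
    from carilow.caricature_engine import CaricatureSpec

    cohort = small_cohort_rendered
    ident = cohort.identities[0]
    lms = cohort.landmarks[(ident.id, "front", "hand")]
    avg = cohort.averages[(ident.sex, "front", "hand")]
    img = cohort.images[(ident.id, "front")]
    stim = make_caricature(img, lms, avg, CaricatureSpec(0.0), identity=ident.id, sex=ident.sex)
    assert np.array_equal(stim.image.pixels, img.pixels)
    assert stim.caricature == 0.0

    other_sex = "F" if ident.sex == "M" else "M"
    wrong_avg = cohort.averages[(other_sex, "front", "hand")]
    with pytest.raises(CategoryMismatchError):
        make_caricature(img, lms, wrong_avg, CaricatureSpec(0.6), sex=ident.sex)
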