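"""Sliding semilandmarks, GPA, Procrustes distances, and mirroring."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import special_ortho_group

from morphopatch import (
    Configuration,
    CurveDefinition,
    SlidingSpec,
    find_mean_spec,
    gpa,
    midline_variance_fraction,
    mirror_fill,
    procrustes_distance,
    slide,
    tangent_structures,
)
from morphopatch.fixtures import make_bilateral_dataset

from conftest import make_landmark_config


def curve_config(sid, xs, extra_landmarks=True):
    """Config with one straight curve along x plus non-coplanar landmarks."""
    rows = [
        {"label": "A", "class": "landmark", "x": 0.0, "y": 0.0, "z": 0.0},
        {"label": "B", "class": "landmark", "x": 4.0, "y": 0.0, "z": 0.0},
    ]
    if extra_landmarks:
        rows += [
            {"label": "C", "class": "landmark", "x": 2.0, "y": 3.0, "z": 0.0},
            {"label": "D", "class": "landmark", "x": 2.0, "y": 1.0, "z": 2.0},
            {"label": "E", "class": "landmark", "x": 1.0, "y": -2.0, "z": 1.0},
        ]
    for i, x in enumerate(xs):
        rows.append({"label": f"c{i}", "class": "curve", "curve_id": "cv",
                     "ordinal": i, "x": x, "y": 0.0, "z": 0.0})
    return Configuration(sid, pd.DataFrame(rows))


CURVES = [CurveDefinition("cv", "A", "B", 5)]


# ---------------------------------------------------------------------------
# Tangent structures
# ---------------------------------------------------------------------------


def test_straight_curve_tangents():
    cfg = curve_config("s", [1.0, 2.0, 3.0])
    bases = tangent_structures(cfg, CURVES, None)
    for i in (5, 6, 7):
        assert np.allclose(np.abs(bases[i]), [[1, 0, 0]])
    for i in range(5):  # landmarks never slide
        assert bases[i].shape == (0, 3)


def test_surface_tangent_plane_on_sphere(hemisphere_atlas):
    cfg = hemisphere_atlas.config
    bases = tangent_structures(cfg, hemisphere_atlas.curves,
                               hemisphere_atlas.mesh)
    df = cfg.points
    surf = np.nonzero(df["class"].to_numpy() == "surface")[0]
    coords = cfg.coords
    for i in surf:
        basis = bases[i]
        assert basis.shape == (2, 3)
        # orthonormal pair
        assert np.allclose(basis @ basis.T, np.eye(2), atol=1e-9)
        # approximately perpendicular to the radial direction (mesh faceting)
        r = coords[i] / np.linalg.norm(coords[i])
        assert np.abs(basis @ r).max() < 0.15


def test_tangent_bases_orthonormal(hemisphere_atlas):
    bases = tangent_structures(hemisphere_atlas.config,
                               hemisphere_atlas.curves,
                               hemisphere_atlas.mesh)
    for b in bases:
        if len(b):
            assert np.allclose(b @ b.T, np.eye(len(b)), atol=1e-9)


# ---------------------------------------------------------------------------
# Sliding
# ---------------------------------------------------------------------------


def test_slide_noop_at_reference():
    ref = curve_config("ref", [1.0, 2.0, 3.0])
    spec = SlidingSpec(stepsize=1.0, reference_mode="fixed_reference")
    out = slide([ref], spec, CURVES, None, reference=ref)
    assert np.allclose(out[0].coords, ref.coords, atol=1e-9)


def test_slide_stepsize_zero_is_identity():
    ref = curve_config("ref", [1.0, 2.0, 3.0])
    bad = curve_config("s", [1.0, 2.7, 3.0])
    spec = SlidingSpec(stepsize=0.0, reference_mode="fixed_reference")
    out = slide([bad], spec, CURVES, None, reference=ref)
    assert np.allclose(out[0].coords, bad.coords, atol=1e-12)


def test_slide_recovers_planted_displacement():
    """A curve point pushed along its own straight curve slides back to the
    reference position, with monotonically decreasing bending energy."""
    ref = curve_config("ref", [1.0, 2.0, 3.0])
    bad = curve_config("s", [1.0, 2.7, 3.0])
    spec = SlidingSpec(criterion="bending_energy", stepsize=1.0,
                       max_iterations=30, tolerance=1e-12,
                       reference_mode="fixed_reference")
    out, trace = slide([bad], spec, CURVES, None, reference=ref,
                       return_trace=True)
    assert np.abs(out[0].coords[6] - [2.0, 0.0, 0.0]).max() < 1e-6
    pre = trace["pre"]
    assert all(b <= a + 1e-12 for a, b in zip(pre, pre[1:]))


def test_slide_objective_nonincreasing_prestep(rng):
    """With stepsize 1, the solved configuration never has a higher
    criterion value than the pre-step configuration."""
    ref = curve_config("ref", [1.0, 2.0, 3.0])
    configs = []
    for i in range(4):
        xs = np.sort(rng.uniform(0.5, 3.5, size=3))
        configs.append(curve_config(f"s{i}", xs))
    spec = SlidingSpec(criterion="bending_energy", stepsize=1.0,
                       max_iterations=10)
    _, trace = slide(configs, spec, CURVES, None, return_trace=True)
    for pre, post in zip(trace["pre"], trace["post"]):
        assert post <= pre + 1e-10


def test_high_stepsize_leaves_curve_more(rng):
    """Undamped steps push curve points off a curved polyline before
    re-projection; stepsize 0.1 keeps them close."""
    theta = np.linspace(0, np.pi / 2, 30)
    arc = np.column_stack([2 * np.cos(theta), 2 * np.sin(theta), 0 * theta])

    def arc_config(sid, jitter):
        rows = [
            {"label": "A", "class": "landmark", "x": 2.0, "y": 0.0, "z": 0.0},
            {"label": "B", "class": "landmark", "x": 0.0, "y": 2.0, "z": 0.0},
            {"label": "C", "class": "landmark", "x": 0.0, "y": 0.0, "z": 1.0},
            {"label": "D", "class": "landmark", "x": 1.0, "y": 1.0, "z": -1.0},
            {"label": "E", "class": "landmark", "x": -1.0, "y": 0.5, "z": 0.5},
        ]
        ts = np.clip(np.linspace(0.15, np.pi / 2 - 0.15, 5) + jitter, 0.05,
                     np.pi / 2 - 0.05)
        for i, t in enumerate(ts):
            rows.append({"label": f"c{i}", "class": "curve", "curve_id": "cv",
                         "ordinal": i, "x": 2 * np.cos(t), "y": 2 * np.sin(t),
                         "z": 0.0})
        return Configuration(sid, pd.DataFrame(rows))

    curves = [CurveDefinition("cv", "A", "B", 7)]
    ref = arc_config("ref", np.zeros(5))
    moved = arc_config("s", rng.normal(scale=0.12, size=5))

    def max_departure(stepsize):
        spec = SlidingSpec(criterion="bending_energy", stepsize=stepsize,
                           max_iterations=1,
                           reference_mode="fixed_reference")
        # measure the pre-projection departure from the arc after one step
        out, trace = slide([moved], spec, curves, None, reference=ref,
                           return_trace=True)
        # reconstruct pre-projection positions: one undamped solve
        from morphopatch.sliding import _solve_step, tangent_structures
        from morphopatch.tps import bending_energy_matrix

        bases = tangent_structures(moved, curves, None)
        bmat = bending_energy_matrix(ref.coords)
        up = _solve_step("bending_energy", ref.coords, moved.coords, bmat,
                         bases, [5, 6, 7, 8, 9])
        y = moved.coords + stepsize * up
        r = np.linalg.norm(y[5:, :2], axis=1)
        return np.abs(r - 2).max() + np.abs(y[5:, 2]).max()

    assert max_departure(2.0) > max_departure(0.1)


# ---------------------------------------------------------------------------
# GPA
# ---------------------------------------------------------------------------


def test_gpa_removes_similarity_transform(rng):
    base = rng.normal(size=(9, 3))
    R = special_ortho_group.rvs(3, random_state=3)
    a = make_landmark_config("a", base)
    b = make_landmark_config("b", 2.5 * base @ R.T + [1, 2, 3])
    res = gpa([a, b])
    assert procrustes_distance(res.aligned[0], res.aligned[1]) < 1e-7


def test_gpa_unit_size_and_centering(rng):
    configs = [make_landmark_config(f"s{i}", rng.normal(size=(7, 3)))
               for i in range(5)]
    res = gpa(configs)
    for cfg in res.aligned:
        x = cfg.coords
        assert np.abs(x.mean(axis=0)).max() < 1e-9
        assert np.sqrt((x**2).sum()) == pytest.approx(1.0, abs=1e-9)
    assert res.mean_shape.centroid_size() == pytest.approx(1.0, abs=1e-9)


def test_gpa_objective_nonincreasing(rng):
    configs = [make_landmark_config(f"s{i}", rng.normal(size=(8, 3)))
               for i in range(6)]
    res = gpa(configs)
    tr = res.objective_trace
    assert all(b <= a + 1e-12 for a, b in zip(tr, tr[1:]))


def test_gpa_rotation_equivariance(rng):
    configs = [make_landmark_config(f"s{i}", rng.normal(size=(6, 3)))
               for i in range(4)]
    R = special_ortho_group.rvs(3, random_state=11)
    rotated = [c.with_coords(c.coords @ R.T) for c in configs]
    res1, res2 = gpa(configs), gpa(rotated)
    for a, b in zip(res1.aligned, res2.aligned):
        assert procrustes_distance(a, b) < 1e-8
    assert np.allclose(res1.eigenvalues, res2.eigenvalues, atol=1e-10)


def test_gpa_pca_eigenvalues(rng):
    configs = [make_landmark_config(f"s{i}", rng.normal(size=(10, 3)))
               for i in range(8)]
    res = gpa(configs)
    assert np.all(res.eigenvalues >= 0)
    flat = res.aligned_array().reshape(8, -1)
    total = ((flat - flat.mean(0)) ** 2).sum() / 7
    assert res.eigenvalues.sum() == pytest.approx(total, rel=1e-9)


def test_gpa_too_few_points_errors():
    a = make_landmark_config("a", np.array([[0.0, 0, 0], [1, 0, 0]]))
    with pytest.raises(ValueError, match="3 points"):
        gpa([a, a.with_id("b")])


# ---------------------------------------------------------------------------
# Procrustes distance / mean specimen
# ---------------------------------------------------------------------------


def test_procrustes_distance_properties(rng):
    for _ in range(10):
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        dab = procrustes_distance(a, b)
        dba = procrustes_distance(b, a)
        assert dab == pytest.approx(dba, abs=1e-12)
        assert dab >= 0
    assert procrustes_distance(a, 3.0 * a + 5.0) == pytest.approx(0, abs=1e-7)


def test_procrustes_triangle_inequality_small_variation(rng):
    base = rng.normal(size=(10, 3))
    for _ in range(20):
        a = base + rng.normal(scale=0.02, size=base.shape)
        b = base + rng.normal(scale=0.02, size=base.shape)
        c = base + rng.normal(scale=0.02, size=base.shape)
        assert (procrustes_distance(a, c)
                <= procrustes_distance(a, b) + procrustes_distance(b, c) + 1e-9)


def test_find_mean_spec_planted(rng):
    base = rng.normal(size=(8, 3))
    configs = [make_landmark_config("mean_twin", base)]
    for i in range(4):
        configs.append(make_landmark_config(
            f"s{i}", base + rng.normal(scale=0.3, size=base.shape)
        ))
    res = gpa(configs)
    # exhaustive check: argmin of distances to the mean
    dists = {c.specimen_id: procrustes_distance(c, res.mean_shape)
             for c in res.aligned}
    expected = min(sorted(dists), key=lambda k: (dists[k], k))
    assert find_mean_spec(res) == expected


def test_find_mean_spec_single():
    cfg = make_landmark_config("only", np.eye(3) * 2)
    assert find_mean_spec(gpa([cfg])) == "only"


# ---------------------------------------------------------------------------
# Mirroring
# ---------------------------------------------------------------------------


def _bilateral_config(rng, n_pairs=5, n_mid=9):
    # midline points spread in two in-plane directions so the least-squares
    # plane is well conditioned under noise
    xs = np.linspace(-1.5, 1.5, n_mid)
    mid = np.column_stack([xs, np.zeros(n_mid), 1.2 - 0.5 * xs**2])
    right = rng.normal(size=(n_pairs, 3))
    right[:, 1] = -np.abs(right[:, 1]) - 0.1
    left = right * [1, -1, 1]
    rows = []
    for i, p in enumerate(mid):
        rows.append({"label": f"m{i}", "class": "landmark",
                     "x": p[0], "y": p[1], "z": p[2]})
    for i in range(n_pairs):
        for side, p in (("r", right[i]), ("l", left[i])):
            rows.append({"label": f"{side}{i}", "class": "landmark",
                         "x": p[0], "y": p[1], "z": p[2]})
    return Configuration("s", pd.DataFrame(rows))


def test_mirror_fill_exact_on_symmetric_data(rng):
    cfg = _bilateral_config(rng)
    gone = cfg.coords.copy()
    left_idx = cfg.index_of([f"l{i}" for i in range(5)])
    gone[left_idx] = np.nan
    filled = mirror_fill(cfg.with_coords(gone),
                         [(f"l{i}", f"r{i}") for i in range(5)],
                         [f"m{i}" for i in range(9)])
    assert np.allclose(filled.coords, cfg.coords, atol=1e-12)


def test_mirror_fill_involution(rng):
    cfg = _bilateral_config(rng)
    pairs = [(f"l{i}", f"r{i}") for i in range(5)]
    mids = [f"m{i}" for i in range(9)]
    gone = cfg.coords.copy()
    gone[cfg.index_of([p[0] for p in pairs])] = np.nan
    once = mirror_fill(cfg.with_coords(gone), pairs, mids)
    again = once.coords.copy()
    again[cfg.index_of([p[0] for p in pairs])] = np.nan
    twice = mirror_fill(once.with_coords(again), pairs, mids)
    assert np.allclose(once.coords, twice.coords, atol=1e-12)


def test_mirror_midline_fixed(rng):
    cfg = _bilateral_config(rng)
    gone = cfg.coords.copy()
    gone[cfg.index_of(["l0"])] = np.nan
    filled = mirror_fill(cfg.with_coords(gone), [("l0", "r0")],
                         [f"m{i}" for i in range(9)])
    mids = cfg.index_of([f"m{i}" for i in range(9)])
    assert np.allclose(filled.coords[mids], cfg.coords[mids])


def test_mirror_collinear_midline_errors(rng):
    cfg = _bilateral_config(rng)
    c = cfg.coords.copy()
    mids = cfg.index_of([f"m{i}" for i in range(9)])
    c[mids, 2] = 0.0  # midline on the x axis only
    c[mids, 1] = 0.0
    c[cfg.index_of(["l0"])] = np.nan
    with pytest.raises(ValueError, match="collinear"):
        mirror_fill(cfg.with_coords(c), [("l0", "r0")],
                    [f"m{i}" for i in range(9)])


def test_mirror_noise_recovery_scale(rng):
    """Imputed positions deviate from truth on the order of the noise."""
    errs = []
    for _ in range(100):
        cfg = _bilateral_config(rng)
        noisy = cfg.with_coords(
            cfg.coords + rng.normal(scale=0.01, size=cfg.coords.shape)
        )
        gone = noisy.coords.copy()
        left_idx = cfg.index_of([f"l{i}" for i in range(5)])
        truth = noisy.coords[left_idx]
        gone[left_idx] = np.nan
        filled = mirror_fill(noisy.with_coords(gone),
                             [(f"l{i}", f"r{i}") for i in range(5)],
                             [f"m{i}" for i in range(9)])
        errs.append(np.sqrt(((filled.coords[left_idx] - truth) ** 2).mean()))
    rms = np.mean(errs)
    assert rms < 2 * 0.01 * np.sqrt(2) * 2  # within x2 of the noise scale


# ---------------------------------------------------------------------------
# Midline variance fraction
# ---------------------------------------------------------------------------


def test_midline_fraction_bounds_and_errors(rng):
    ds = make_bilateral_dataset(n_specimens=10, seed=3)
    res = gpa(ds["fully_mirrored"])
    frac = midline_variance_fraction(res, ds["midline_labels"],
                                     ds["right_labels"])
    assert frac > 0
    with pytest.raises(ValueError, match="empty"):
        midline_variance_fraction(res, [])


def test_one_sided_alignment_inflates_midline_variance():
    """The mirroring artifact: aligning one-sided data exaggerates shape
    variation along the midline relative to fully mirrored data."""
    wins = 0
    for seed in range(10):
        ds = make_bilateral_dataset(n_specimens=15, seed=seed)
        right = [l for l in ds["right_labels"]]
        f_one = midline_variance_fraction(
            gpa(ds["right_only"]), ds["midline_labels"], right)
        f_mir = midline_variance_fraction(
            gpa(ds["fully_mirrored"]), ds["midline_labels"], right)
        wins += f_one > f_mir
    assert wins >= 9
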