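"""Template patching: atlas validation, projection, piecemeal operation,
and the negligible-region / negligible-hole procedures."""

import numpy as np
import pandas as pd
import pytest

from morphopatch import (
    Configuration,
    build_atlas,
    drop_points,
    gpa,
    load_atlas,
    make_negligible_hole,
    make_negligible_region,
    nearest_point_on_mesh,
    piecemeal_patch,
    place_patch,
    save_atlas,
)
from morphopatch.fixtures import make_hemisphere_template


# ---------------------------------------------------------------------------
# build_atlas
# ---------------------------------------------------------------------------


def test_build_atlas_hemisphere(hemisphere_atlas):
    atlas = hemisphere_atlas
    assert len(atlas.surface_labels) == 18
    assert set(atlas.region_map) == {"dome"}
    assert sorted(atlas.region_map["dome"]) == sorted(atlas.surface_labels)


def test_build_atlas_rejects_floating_point(hemisphere_atlas):
    cfg = hemisphere_atlas.config
    coords = cfg.coords.copy()
    i = cfg.index_of(["s0"])[0]
    coords[i] *= 1.10  # 10% of the radius off the surface
    with pytest.raises(ValueError, match="s0"):
        build_atlas(hemisphere_atlas.mesh, cfg.with_coords(coords),
                    hemisphere_atlas.curves)


def test_build_atlas_region_map_must_cover_surface(hemisphere_atlas):
    with pytest.raises(ValueError, match="region_map"):
        build_atlas(hemisphere_atlas.mesh, hemisphere_atlas.config,
                    hemisphere_atlas.curves,
                    region_map={"dome": hemisphere_atlas.surface_labels[:-1]})


# ---------------------------------------------------------------------------
# place_patch
# ---------------------------------------------------------------------------


def test_identity_transfer(hemisphere_atlas):
    """The template patched against itself returns its own surface points."""
    atlas = hemisphere_atlas
    fixed = atlas.config.subset(atlas.fixed_labels)
    res = place_patch(atlas, atlas.mesh, fixed, inflate=0.0)
    assert not res.failed
    got = res.config.subset(atlas.surface_labels).coords
    want = atlas.config.subset(atlas.surface_labels).coords
    scale = atlas.config.centroid_size()
    assert np.abs(got - want).max() < 1e-6 * scale
    assert res.config.labels == atlas.config.labels


def test_placed_points_on_surface(hemisphere_atlas, pyramid):
    """Patching a different convex specimen puts every surface point on the
    specimen mesh with outward normal agreement (convex fixture)."""
    atlas = hemisphere_atlas
    # specimen: the same hemisphere stretched anisotropically
    stretch = np.array([1.3, 0.9, 1.1])
    mesh = atlas.mesh.with_vertices(atlas.mesh.vertices * stretch)
    fixed = atlas.config.subset(atlas.fixed_labels)
    fixed = fixed.with_coords(fixed.coords * stretch).with_id("spec")
    for inflate in (0.0, 0.1, 0.5):
        res = place_patch(atlas, mesh, fixed, inflate=inflate)
        assert not res.failed
        cs = res.config.centroid_size()
        assert res.diagnostics["distance_to_surface"].max() < 1e-6 * cs
        assert (res.diagnostics["normal_sign"] > 0).all()
        assert not res.diagnostics["off_region"].any()


def test_floating_fixed_points_fail_gracefully(hemisphere_atlas):
    atlas = hemisphere_atlas
    fixed = atlas.config.subset(atlas.fixed_labels)
    coords = fixed.coords.copy()
    i = fixed.index_of(["rim0"])[0]
    coords[i] *= 1.5
    res = place_patch(atlas, atlas.mesh, fixed.with_coords(coords))
    assert res.failed
    assert "rim0" in res.reason
    assert res.config is None


def test_label_mismatch_raises(hemisphere_atlas):
    atlas = hemisphere_atlas
    fixed = atlas.config.subset(atlas.fixed_labels[:-1])
    with pytest.raises(ValueError, match="difference"):
        place_patch(atlas, atlas.mesh, fixed)


def test_thin_shell_face_inversion_detected():
    """On a thin double-walled shell, insufficient inflate lands points on
    the internal surface: negative normal agreement is reported."""
    atlas = make_hemisphere_template(radius=1.0, target_faces=700,
                                     surface_grid=(3, 6), n_curve_points=5)
    # specimen: the same dome plus an inner wall at 96% radius
    outer = atlas.mesh
    inner = outer.with_vertices(outer.vertices * 0.96)
    shell_v = np.vstack([outer.vertices, inner.vertices])
    inner_faces = inner.faces[:, ::-1] + outer.n_vertices  # flip winding
    shell_f = np.vstack([outer.faces, inner_faces])
    from morphopatch import TriMesh

    shell = TriMesh(shell_v, shell_f, fix_winding=False)
    fixed = atlas.config.subset(atlas.fixed_labels)
    # inflate below the wall separation: points can catch the inner wall
    res_low = place_patch(atlas, shell, fixed, inflate=-0.02)
    assert not res_low.failed
    assert (res_low.diagnostics["normal_sign"] < 0).sum() > 0
    # adequate inflate: everything lands on the outer surface
    res_ok = place_patch(atlas, shell, fixed, inflate=0.1)
    assert (res_ok.diagnostics["normal_sign"] > 0).all()


# ---------------------------------------------------------------------------
# piecemeal patching
# ---------------------------------------------------------------------------


def _split_atlas_by_halves(atlas):
    """Split the hemisphere atlas's surface points into two 'regions'."""
    df = atlas.config.points.copy()
    surface = df["class"] == "surface"
    east = surface & (df["y"] > 0)
    west = surface & (df["y"] <= 0)
    regions = {}
    for name, mask in (("east", east), ("west", west)):
        sub = df[~surface | mask].copy()
        sub.loc[mask, "region"] = name
        cfg = Configuration(atlas.config.specimen_id, sub)
        regions[name] = build_atlas(atlas.mesh, cfg, atlas.curves)
    return regions


def test_piecemeal_matches_joint_with_shared_anchors(hemisphere_atlas):
    atlas = hemisphere_atlas
    regions = _split_atlas_by_halves(atlas)
    stretch = np.array([1.2, 1.0, 0.9])
    mesh = atlas.mesh.with_vertices(atlas.mesh.vertices * stretch)
    fixed = atlas.config.subset(atlas.fixed_labels)
    fixed = fixed.with_coords(fixed.coords * stretch).with_id("spec")
    joint = place_patch(atlas, mesh, fixed, inflate=0.05)
    pieces = piecemeal_patch(regions, mesh, fixed, inflate_per_region=0.05)
    assert not pieces.failed
    # identical anchors (both regions use all fixed points) -> same warp
    for lab in atlas.surface_labels:
        a = joint.config.subset([lab]).coords
        b = pieces.config.subset([lab]).coords
        assert np.abs(a - b).max() < 1e-6


def test_piecemeal_rejects_overlapping_surface_labels(hemisphere_atlas):
    regions = _split_atlas_by_halves(hemisphere_atlas)
    regions["east2"] = regions["east"]
    fixed = hemisphere_atlas.config.subset(hemisphere_atlas.fixed_labels)
    with pytest.raises(ValueError, match="more than one region"):
        piecemeal_patch(regions, hemisphere_atlas.mesh, fixed)


def test_piecemeal_merge_preserves_order(hemisphere_atlas):
    atlas = hemisphere_atlas
    regions = _split_atlas_by_halves(atlas)
    fixed = atlas.config.subset(atlas.fixed_labels)
    res = piecemeal_patch(regions, atlas.mesh, fixed)
    expected = fixed.labels + [
        lab for r in regions.values() for lab in r.surface_labels
    ]
    assert res.config.labels == expected


# ---------------------------------------------------------------------------
# negligible region
# ---------------------------------------------------------------------------


def test_negligible_region_rows():
    rows = make_negligible_region((1.0, 2.0, 3.0), 4,
                                  [f"n{i}" for i in range(4)], region="pt")
    assert len(rows) == 4
    assert (rows[["x", "y", "z"]].to_numpy() == [1.0, 2.0, 3.0]).all()
    cfg = Configuration("s", rows)
    assert cfg.centroid_size() == 0.0


def test_negligible_region_single_point_legal():
    rows = make_negligible_region((0, 0, 0), 1, ["n0"])
    assert len(rows) == 1


def test_negligible_region_label_count_mismatch():
    with pytest.raises(ValueError, match="labels"):
        make_negligible_region((0, 0, 0), 3, ["a", "b"])


def test_negligible_region_stays_small_after_gpa(rng):
    """After joint alignment the replicated region remains near zero size."""
    base = rng.normal(size=(10, 3))
    configs = []
    for i in range(6):
        coords = base + rng.normal(scale=0.05, size=base.shape)
        main = pd.DataFrame({
            "label": [f"p{j}" for j in range(10)], "class": "landmark",
            "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
        })
        region = make_negligible_region(coords[0] + 0.05, 4,
                                        [f"n{j}" for j in range(4)],
                                        region="missing")
        configs.append(Configuration(f"s{i}",
                                     pd.concat([main, region],
                                               ignore_index=True)))
    res = gpa(configs)
    for cfg in res.aligned:
        region_cs = cfg.subset([f"n{j}" for j in range(4)]).centroid_size()
        assert region_cs < 1e-3 * cfg.centroid_size()


# ---------------------------------------------------------------------------
# negligible hole
# ---------------------------------------------------------------------------


def test_negligible_hole_fence_geometry(pyramid):
    mesh, cfg, _ = pyramid
    pos = np.array([0.0, -0.4, 0.4])  # on lateral face 0
    curve, rows = make_negligible_hole(mesh, pos, surface_point_spacing=0.08)
    assert curve.closed
    fence = rows[rows["class"] == "curve"]
    pts = fence[["x", "y", "z"]].to_numpy()
    # diameter within [0.5, 1.5] x spacing
    from scipy.spatial.distance import pdist

    diam = pdist(pts).max()
    assert 0.5 * 0.08 <= diam <= 1.5 * 0.08
    # on-surface and valid bookkeeping
    _, _, d = nearest_point_on_mesh(mesh, pts)
    assert np.max(d) < 1e-6
    ords = np.sort(fence["ordinal"].to_numpy())
    assert np.array_equal(ords, np.arange(len(fence)))
    Configuration("s", rows)  # validates


def test_negligible_hole_requires_positive_spacing(pyramid):
    mesh, _, _ = pyramid
    with pytest.raises(ValueError, match="positive"):
        make_negligible_hole(mesh, np.zeros(3), 0.0)


# ---------------------------------------------------------------------------
# atlas bundle I/O
# ---------------------------------------------------------------------------


def test_atlas_bundle_round_trip(hemisphere_atlas, tmp_path):
    save_atlas(hemisphere_atlas, tmp_path / "atlas")
    back = load_atlas(tmp_path / "atlas")
    assert back.mesh.n_faces == hemisphere_atlas.mesh.n_faces
    assert back.config.labels == hemisphere_atlas.config.labels
    assert np.allclose(back.config.coords, hemisphere_atlas.config.coords)
    assert len(back.curves) == len(hemisphere_atlas.curves)
    assert back.region_map == hemisphere_atlas.region_map
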