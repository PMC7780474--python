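"""Seeded synthetic geometry and datasets for testing the whole pipeline.

Real semilandmark studies run on museum-specimen scans; everything here is
deliberately minimal geometry that still exercises each pipeline stage:

* pyramids of varying proportions, optionally bearing a circular fossa
  (a spherical-cap depression) fenced by a closed curve — the test bed for
  the negligible-hole method;
* hemispherical template meshes with systematic rows of surface points,
  the template shape that works well for vertebrate skulls;
* bilaterally symmetric point configurations for the mirroring experiment;
* a two-group deformation dataset for comparing global vs piecemeal sliding.

All generators are deterministic under a fixed seed and record their
parameters in a manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .mesh import TriMesh, nearest_point_on_mesh
from .patching import Atlas, build_atlas, place_patch
from .points import Configuration, CurveDefinition, drop_points, resample_curve
from .sliding import gpa, mirror_fill
from .tps import fit_tps, warp_points

__all__ = [
    "PyramidSpec",
    "make_pyramid",
    "make_hemisphere_template",
    "make_pyramid_experiment",
    "run_pyramid_experiment",
    "make_bilateral_dataset",
    "make_two_group_dataset",
]


# ---------------------------------------------------------------------------
# Pyramid fixtures
# ---------------------------------------------------------------------------


@dataclass
class PyramidSpec:
    """Shape parameters of one synthetic pyramid.

    The base is a parallelogram (``corner_skew`` shears the far edge,
    varying the base corner angles); the apex sits over the base centroid at
    ``height``.  ``fossa`` is (face_id, (u, v), radius): a circular
    spherical-cap depression of depth 0.3 x radius centered at barycentric
    position (u, v) of lateral face ``face_id``, rimmed by a fence circle.
    ``seed`` drives only optional vertex jitter (default amplitude 0 —
    geometry is deterministic).
    """

    base_width: float = 1.0
    base_depth: float = 1.0
    height: float = 1.0
    corner_skew: float = 0.0
    fossa: Optional[tuple[int, tuple[float, float], float]] = None
    mesh_resolution: int = 2400
    jitter: float = 0.0
    seed: int = 0


def _subdivide_triangle(p0, p1, p2, m):
    """Barycentric grid subdivision of one triangle into m^2 triangles."""
    verts = []
    index = {}
    for i in range(m + 1):
        for j in range(m + 1 - i):
            index[(i, j)] = len(verts)
            verts.append(p0 + (p1 - p0) * (i / m) + (p2 - p0) * (j / m))
    faces = []
    for i in range(m):
        for j in range(m - i):
            a, b, c = index[(i, j)], index[(i + 1, j)], index[(i, j + 1)]
            faces.append([a, b, c])
            if j < m - i - 1:
                d = index[(i + 1, j + 1)]
                faces.append([b, d, c])
    return np.array(verts), np.array(faces)


def _weld_exact(vertices, faces, decimals=9):
    key = np.round(vertices, decimals)
    _, first, inverse = np.unique(
        key, axis=0, return_index=True, return_inverse=True
    )
    return vertices[first], inverse[faces]


def _pyramid_corners(spec: PyramidSpec):
    w, d, h = spec.base_width, spec.base_depth, spec.height
    s = spec.corner_skew * w
    c0 = np.array([-w / 2, -d / 2, 0.0])
    c1 = np.array([w / 2, -d / 2, 0.0])
    c2 = np.array([w / 2 + s, d / 2, 0.0])
    c3 = np.array([-w / 2 + s, d / 2, 0.0])
    apex = np.array([s / 2, 0.0, h])
    return c0, c1, c2, c3, apex


def _lateral_faces(c0, c1, c2, c3, apex):
    return [(c0, c1, apex), (c1, c2, apex), (c2, c3, apex), (c3, c0, apex)]


def _face_frame(p0, p1, p2):
    """(origin, in-plane e1/e2, outward normal approx) of a lateral face."""
    e1 = p1 - p0
    n = np.cross(e1, p2 - p0)
    n = n / np.linalg.norm(n)
    e1u = e1 / np.linalg.norm(e1)
    e2u = np.cross(n, e1u)
    return p0, e1u, e2u, n


def _circle_in_face(p0, p1, p2, uv, radius, n_points):
    """Points of a circle of ``radius`` around barycentric (u, v) in a face."""
    center = p0 + uv[0] * (p1 - p0) + uv[1] * (p2 - p0)
    _, e1u, e2u, n = _face_frame(p0, p1, p2)
    theta = np.linspace(0.0, 2 * np.pi, n_points + 1)[:-1]
    pts = center + radius * (
        np.outer(np.cos(theta), e1u) + np.outer(np.sin(theta), e2u)
    )
    return center, pts, n


def _dist_point_to_edges(c, tri):
    """Min distance from an interior point to the triangle's edges (2D-safe)."""
    d = []
    for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
        ab = b - a
        t = np.clip((c - a) @ ab / (ab @ ab), 0, 1)
        d.append(np.linalg.norm(c - (a + t * ab)))
    return min(d)


def make_pyramid(
    spec: PyramidSpec,
    n_curve_points: int = 7,
    fence_points: int = 24,
    fence_curve_id: str = "fossa",
    fence_anchor_label: str = "fossa_anchor",
):
    """Triangulated pyramid with 5 vertex landmarks and 8 edge curves.

    Returns ``(mesh, config, curves)``.  When ``spec.fossa`` is set, a
    spherical-cap depression is carved into the named lateral face and its
    rim is fenced by a closed curve of ``fence_points`` points (anchor
    landmark + fence curve points), all snapped onto the mesh surface.
    """
    if min(spec.base_width, spec.base_depth, spec.height) <= 0:
        raise ValueError("pyramid dimensions must be positive")
    c0, c1, c2, c3, apex = _pyramid_corners(spec)
    laterals = _lateral_faces(c0, c1, c2, c3, apex)
    m = max(2, int(round(np.sqrt(spec.mesh_resolution / 6))))
    all_v, all_f = [], []
    offset = 0
    patches = laterals + [(c0, c2, c1), (c0, c3, c2)]  # base, facing down
    for (p0, p1, p2) in patches:
        v, f = _subdivide_triangle(
            np.asarray(p0, float), np.asarray(p1, float), np.asarray(p2, float), m
        )
        all_v.append(v)
        all_f.append(f + offset)
        offset += len(v)
    vertices = np.vstack(all_v)
    faces = np.vstack(all_f)
    vertices, faces = _weld_exact(vertices, faces)

    fence_rows = None
    fence_curve = None
    if spec.fossa is not None:
        face_id, uv, radius = spec.fossa
        tri = [np.asarray(p, float) for p in laterals[face_id]]
        center, rim, n = _circle_in_face(*tri, uv, radius, fence_points)
        if _dist_point_to_edges(center, tri) <= radius:
            raise ValueError("fossa circle does not fit inside its face")
        depth = 0.3 * radius
        # displace in-plane vertices within the rim inward along the normal
        d_plane = np.abs((vertices - tri[0]) @ n)
        rho = np.linalg.norm(
            vertices - center - ((vertices - center) @ n)[:, None] * n, axis=1
        )
        mask = (d_plane < 1e-9) & (rho < radius)
        vertices = vertices.copy()
        vertices[mask] -= (
            depth * (1.0 - (rho[mask] / radius) ** 2)
        )[:, None] * n
        mesh = TriMesh(vertices, faces, fix_winding=True)
        snapped, _, _ = nearest_point_on_mesh(mesh, rim)
        fence_rows = [{
            "label": fence_anchor_label, "class": "landmark", "region": f"face{face_id}",
            "curve_id": None, "ordinal": np.nan, "side": "none",
            "x": snapped[0, 0], "y": snapped[0, 1], "z": snapped[0, 2],
        }]
        for i in range(1, fence_points):
            fence_rows.append({
                "label": f"{fence_curve_id}_{i - 1}", "class": "curve",
                "region": f"face{face_id}", "curve_id": fence_curve_id,
                "ordinal": i - 1, "side": "none",
                "x": snapped[i, 0], "y": snapped[i, 1], "z": snapped[i, 2],
            })
        fence_curve = CurveDefinition(
            fence_curve_id, fence_anchor_label, fence_anchor_label,
            n_points=fence_points, closed=True,
        )
    else:
        mesh = TriMesh(vertices, faces, fix_winding=True)

    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        mesh = mesh.with_vertices(
            mesh.vertices + rng.normal(scale=spec.jitter, size=mesh.vertices.shape)
        )

    # landmarks at the 5 pyramid vertices, curves along the 8 edges
    corner_pts = {"c0": c0, "c1": c1, "c2": c2, "c3": c3, "apex": apex}
    rows = []
    for lab, p in corner_pts.items():
        rows.append({
            "label": lab, "class": "landmark", "region": "",
            "curve_id": None, "ordinal": np.nan, "side": "none",
            "x": p[0], "y": p[1], "z": p[2],
        })
    edges = [
        ("b0", "c0", "c1"), ("b1", "c1", "c2"),
        ("b2", "c2", "c3"), ("b3", "c3", "c0"),
        ("l0", "c0", "apex"), ("l1", "c1", "apex"),
        ("l2", "c2", "apex"), ("l3", "c3", "apex"),
    ]
    curves = []
    lateral_edge_region = {"b0": "face0", "l0": "face0", "l1": "face0"}
    for cid, a, b in edges:
        pts = resample_curve(
            np.vstack([corner_pts[a], corner_pts[b]]), n_curve_points
        )
        region = lateral_edge_region.get(cid, "")
        for i, p in enumerate(pts[1:-1]):
            rows.append({
                "label": f"{cid}_{i}", "class": "curve", "region": region,
                "curve_id": cid, "ordinal": i, "side": "none",
                "x": p[0], "y": p[1], "z": p[2],
            })
        curves.append(CurveDefinition(cid, a, b, n_points=n_curve_points))
    if fence_rows is not None:
        rows.extend(fence_rows)
        curves.append(fence_curve)
    # boundary landmarks of face 0 carry its region tag for diagnostics
    for r in rows:
        if r["label"] in ("c0", "c1", "apex"):
            r["region"] = "face0"
    config = Configuration("pyramid", pd.DataFrame(rows))
    return mesh, config, curves


def _pyramid_face_point(spec: PyramidSpec, face_id: int, u: float, v: float):
    c0, c1, c2, c3, apex = _pyramid_corners(spec)
    p0, p1, p2 = _lateral_faces(c0, c1, c2, c3, apex)[face_id]
    return p0 + u * (p1 - p0) + v * (p2 - p0)


def _surface_grid_on_face(spec: PyramidSpec, face_id: int, rows: int, cols: int):
    """rows x cols points in rows parallel to the base edge of a face."""
    pts = []
    for r in range(rows):
        v = 0.06 + 0.80 * (r / (rows - 1)) if rows > 1 else 0.4
        for c in range(cols):
            u = (0.06 + 0.88 * ((c + 0.5) / cols)) * (1.0 - v)
            pts.append(_pyramid_face_point(spec, face_id, u, v))
    return np.array(pts)


_FOSSA_UV = (0.50, 0.27)     # barycentric fence/fossa center on face 0
_FENCE_SPACING = 0.10        # negligible-hole diameter ~ one surface point


def make_pyramid_experiment(seed: int = 0) -> dict:
    """Inputs of the negligible-hole pyramid experiment.

    10 pyramid specimens of seeded varying proportions (base aspect ratio
    0.6–1.6, height 0.5–2.0, corner skew ±0.15), the first 4 bearing a
    circular fossa on lateral face 0; a template pyramid carrying 90 surface
    points (9 rows x 10 columns) on that face plus a negligible-size fence
    at the fossa position; and, for the 6 fossa-free specimens, fixed
    configurations both with a negligible-hole fence and without any fence
    (for re-patching with the fence-free template).
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(10):
        specs.append(PyramidSpec(
            base_width=1.0,
            base_depth=float(rng.uniform(0.6, 1.6)),
            height=float(rng.uniform(0.5, 2.0)),
            corner_skew=float(rng.uniform(-0.15, 0.15)),
            fossa=(0, _FOSSA_UV, float(rng.uniform(0.07, 0.13))) if i < 4 else None,
            mesh_resolution=2400,
        ))
    specimens = []
    for i, sp in enumerate(specs):
        if sp.fossa is not None:
            mesh, cfg, curves = make_pyramid(sp)
            specimens.append({
                "id": f"pyr{i}_hole", "mesh": mesh,
                "fixed": cfg.with_id(f"pyr{i}_hole"), "curves": curves,
                "has_fossa": True, "spec": sp,
            })
        else:
            mesh, cfg, curves = make_pyramid(sp)
            # negligible-hole fence: zero-depth circle on the flat face
            c0, c1, c2, c3, apex = _pyramid_corners(sp)
            tri = [np.asarray(p, float)
                   for p in _lateral_faces(c0, c1, c2, c3, apex)[0]]
            _, rim, _ = _circle_in_face(*tri, _FOSSA_UV, _FENCE_SPACING / 2, 24)
            snapped, _, _ = nearest_point_on_mesh(mesh, rim)
            fence_rows = [{
                "label": "fossa_anchor", "class": "landmark", "region": "face0",
                "curve_id": None, "ordinal": np.nan, "side": "none",
                "x": snapped[0, 0], "y": snapped[0, 1], "z": snapped[0, 2],
            }] + [{
                "label": f"fossa_{j - 1}", "class": "curve", "region": "face0",
                "curve_id": "fossa", "ordinal": j - 1, "side": "none",
                "x": snapped[j, 0], "y": snapped[j, 1], "z": snapped[j, 2],
            } for j in range(1, 24)]
            fenced = Configuration(
                f"pyr{i}_hole",
                pd.concat([cfg.points, pd.DataFrame(fence_rows)],
                          ignore_index=True),
            )
            curves_f = curves + [CurveDefinition(
                "fossa", "fossa_anchor", "fossa_anchor", 24, closed=True
            )]
            specimens.append({
                "id": f"pyr{i}_hole", "mesh": mesh, "fixed": fenced,
                "curves": curves_f, "has_fossa": False, "spec": sp,
                "fixed_nohole": cfg.with_id(f"pyr{i}_nohole"),
                "curves_nohole": curves,
            })

    # template: near-median proportions, fence of negligible size, 90 points
    tpl_spec = PyramidSpec(base_width=1.0, base_depth=1.1, height=1.2,
                           corner_skew=0.0,
                           fossa=(0, _FOSSA_UV, _FENCE_SPACING / 2),
                           mesh_resolution=2400)
    tpl_mesh, tpl_cfg, tpl_curves = make_pyramid(tpl_spec)
    grid = _surface_grid_on_face(tpl_spec, 0, 9, 10)
    snapped, _, _ = nearest_point_on_mesh(tpl_mesh, grid)
    surf_rows = [{
        "label": f"s{j}", "class": "surface", "region": "face0",
        "curve_id": None, "ordinal": np.nan, "side": "none",
        "x": p[0], "y": p[1], "z": p[2],
    } for j, p in enumerate(snapped)]
    tpl_full = Configuration(
        "template",
        pd.concat([tpl_cfg.points, pd.DataFrame(surf_rows)], ignore_index=True),
    )
    atlas_with_fence = build_atlas(tpl_mesh, tpl_full, tpl_curves)
    fence_labels = ["fossa_anchor"] + [f"fossa_{j}" for j in range(23)]
    tpl_nohole = drop_points(tpl_full, fence_labels)
    curves_nohole = [c for c in tpl_curves if c.curve_id != "fossa"]
    atlas_no_fence = build_atlas(tpl_mesh, tpl_nohole, curves_nohole)

    manifest = {
        "seed": seed,
        "n_specimens": 10,
        "n_with_fossa": 4,
        "n_surface_points": 90,
        "fence_labels": fence_labels,
        "fossa_uv": _FOSSA_UV,
        "fence_spacing": _FENCE_SPACING,
        "specs": [sp.__dict__ for sp in specs],
    }
    return {
        "specimens": specimens,
        "atlas": atlas_with_fence,
        "atlas_nohole": atlas_no_fence,
        "fence_labels": fence_labels,
        "manifest": manifest,
    }


def run_pyramid_experiment(seed: int = 0, inflate: float = 0.05) -> dict:
    """Patch, align, and analyze the 16-configuration pyramid experiment.

    All 10 specimens are patched with the fence-bearing template (the 6
    fossa-free ones through their negligible-hole fences); the 6 fossa-free
    specimens are then re-patched without any fence using the fence-free
    template.  Fence landmarks and curves are dropped, the 16 configurations
    are jointly Procrustes aligned, and a PCA is run.  Returns the alignment
    plus the cumulative percent variance of PC1–PC4 and the twin pairs.
    """
    bundle = make_pyramid_experiment(seed)
    fence_labels = bundle["fence_labels"]
    patched = []
    for spec in bundle["specimens"]:
        res = place_patch(bundle["atlas"], spec["mesh"], spec["fixed"],
                          inflate=inflate)
        if res.failed:
            raise RuntimeError(
                f"patching failed for {spec['id']}: {res.reason}"
            )
        patched.append(drop_points(res.config, fence_labels))
    for spec in bundle["specimens"]:
        if spec["has_fossa"]:
            continue
        res = place_patch(bundle["atlas_nohole"], spec["mesh"],
                          spec["fixed_nohole"], inflate=inflate)
        if res.failed:
            raise RuntimeError(
                f"re-patching failed for {spec['fixed_nohole'].specimen_id}: "
                f"{res.reason}"
            )
        patched.append(res.config)
    result = gpa(patched)
    cum4 = float(result.variance_explained()[:4].sum() * 100.0)
    pairs = [
        (s["id"], s["fixed_nohole"].specimen_id)
        for s in bundle["specimens"] if not s["has_fossa"]
    ]
    return {
        "alignment": result,
        "configs": patched,
        "cumulative_pc1_4_percent": cum4,
        "twin_pairs": pairs,
        "bundle": bundle,
    }


# ---------------------------------------------------------------------------
# Hemisphere template
# ---------------------------------------------------------------------------


def make_hemisphere_template(
    radius: float = 1.0,
    target_faces: int = 18_000,
    surface_grid: tuple[int, int] = (6, 12),
    n_curve_points: int = 7,
) -> Atlas:
    """Hemispherical template atlas with systematic surface-point rows.

    Flat base; landmarks at the pole and at four rim positions; curves along
    the four rim arcs and four meridians; ``surface_grid`` rows x cols of
    surface points between them, in rows parallel to the rim.  Face count
    lands within ~10% of ``target_faces``.
    """
    if target_faces < 100:
        raise ValueError("target_faces must be >= 100")
    ntheta = max(3, int(round(np.sqrt(target_faces / 4.0))))
    nphi = max(8, int(round(target_faces / (2.0 * ntheta) / 4.0)) * 4)
    thetas = np.linspace(0.0, np.pi / 2, ntheta + 1)  # pole -> equator
    verts = [np.array([0.0, 0.0, radius])]
    ring_index = []
    for t in thetas[1:]:
        ring = []
        for j in range(nphi):
            phi = 2 * np.pi * j / nphi
            ring.append(len(verts))
            verts.append(radius * np.array([
                np.sin(t) * np.cos(phi), np.sin(t) * np.sin(phi), np.cos(t)
            ]))
        ring_index.append(ring)
    faces = []
    for j in range(nphi):
        faces.append([0, ring_index[0][j], ring_index[0][(j + 1) % nphi]])
    for r in range(len(ring_index) - 1):
        a, b = ring_index[r], ring_index[r + 1]
        for j in range(nphi):
            j2 = (j + 1) % nphi
            faces.append([a[j], b[j], b[j2]])
            faces.append([a[j], b[j2], a[j2]])
    base_center = len(verts)
    verts.append(np.array([0.0, 0.0, 0.0]))
    eq = ring_index[-1]
    for j in range(nphi):
        faces.append([base_center, eq[(j + 1) % nphi], eq[j]])
    mesh = TriMesh(np.array(verts), np.array(faces), fix_winding=True)

    # landmarks: pole + 4 rim positions (phi = 0, 90, 180, 270)
    rim_ids = [eq[0], eq[nphi // 4], eq[nphi // 2], eq[3 * nphi // 4]]
    rows = [{
        "label": "pole", "class": "landmark", "region": "dome",
        "curve_id": None, "ordinal": np.nan, "side": "none",
        "x": 0.0, "y": 0.0, "z": radius,
    }]
    for i, vid in enumerate(rim_ids):
        p = mesh.vertices[vid]
        rows.append({
            "label": f"rim{i}", "class": "landmark", "region": "dome",
            "curve_id": None, "ordinal": np.nan, "side": "none",
            "x": p[0], "y": p[1], "z": p[2],
        })
    curves = []
    # rim arcs between consecutive rim landmarks, along equator vertices
    quarter = nphi // 4
    for i in range(4):
        ids = [eq[(i * quarter + j) % nphi] for j in range(quarter + 1)]
        pl = mesh.vertices[ids]
        pts = resample_curve(pl, n_curve_points)
        for k, p in enumerate(pts[1:-1]):
            rows.append({
                "label": f"rimarc{i}_{k}", "class": "curve", "region": "dome",
                "curve_id": f"rimarc{i}", "ordinal": k, "side": "none",
                "x": p[0], "y": p[1], "z": p[2],
            })
        curves.append(CurveDefinition(
            f"rimarc{i}", f"rim{i}", f"rim{(i + 1) % 4}", n_curve_points
        ))
    # meridians from each rim landmark to the pole
    for i in range(4):
        j = i * quarter
        ids = [ring_index[r][j] for r in range(len(ring_index) - 1, -1, -1)]
        pl = np.vstack([mesh.vertices[ids], [[0.0, 0.0, radius]]])
        pts = resample_curve(pl, n_curve_points)
        for k, p in enumerate(pts[1:-1]):
            rows.append({
                "label": f"mer{i}_{k}", "class": "curve", "region": "dome",
                "curve_id": f"mer{i}", "ordinal": k, "side": "none",
                "x": p[0], "y": p[1], "z": p[2],
            })
        curves.append(CurveDefinition(
            f"mer{i}", f"rim{i}", "pole", n_curve_points
        ))
    # surface points: rows parallel to the rim, columns between meridians
    r_rows, r_cols = surface_grid
    pts = []
    for a in range(r_rows):
        t = (a + 1) / (r_rows + 1) * (np.pi / 2) * 0.92
        for b in range(r_cols):
            phi = 2 * np.pi * (b + 0.5) / r_cols
            pts.append(radius * np.array([
                np.sin(t) * np.cos(phi), np.sin(t) * np.sin(phi), np.cos(t)
            ]))
    snapped, _, _ = nearest_point_on_mesh(mesh, np.array(pts))
    for j, p in enumerate(snapped):
        rows.append({
            "label": f"s{j}", "class": "surface", "region": "dome",
            "curve_id": None, "ordinal": np.nan, "side": "none",
            "x": p[0], "y": p[1], "z": p[2],
        })
    cfg = Configuration("hemisphere_template", pd.DataFrame(rows))
    return build_atlas(mesh, cfg, curves)


# ---------------------------------------------------------------------------
# Bilateral dataset (mirroring experiment)
# ---------------------------------------------------------------------------


def _bilateral_base(n_pairs: int, n_midline: int):
    """Deterministic symmetric base shape (midline plane y = 0)."""
    rows = []
    for i in range(n_midline):
        x = -1.0 + 2.0 * i / max(n_midline - 1, 1)
        rows.append((f"m{i}", "landmark", "midline", x, 0.0, 0.45 - 0.35 * x * x))
    golden = 0.6180339887498949
    for p in range(n_pairs):
        x = -0.9 + 1.8 * (p + 0.5) / n_pairs
        y = 0.25 + 0.55 * ((p * golden) % 1.0)
        z = 0.05 + 0.35 * ((p * 0.37 + 0.13) % 1.0)
        if p < max(3, n_pairs // 3):
            cls, cid, ordn = "landmark", None, np.nan
        elif p < max(3, n_pairs // 3) + max(3, n_pairs // 3):
            cls = "curve"
            cid = "cv"
            ordn = p - max(3, n_pairs // 3)
        else:
            cls, cid, ordn = "surface", None, np.nan
        rows.append((f"r{p}", cls, "right", x, -y, z, cid, ordn))
        rows.append((f"l{p}", cls, "left", x, y, z, cid, ordn))
    return rows


def make_bilateral_dataset(
    n_specimens: int = 20,
    n_pairs: int = 12,
    n_midline: int = 5,
    noise_sd: float = 0.01,
    asymmetry_sd: float = 0.0,
    shape_sd: float = 0.05,
    seed: int = 0,
) -> dict:
    """Bilaterally symmetric sample with four one-sided/mirrored variants.

    Each specimen is the symmetric base shape deformed by a random symmetric
    smooth field (scale ``shape_sd``), plus optional directional asymmetry
    (``asymmetry_sd``) and isotropic digitization noise (``noise_sd``).
    Exported variants per specimen: (1) right side + midline only;
    (2) plus true left landmarks; (3) plus mirrored left curve points;
    (4) plus mirrored left curve and surface points (full bilateral).
    """
    rng = np.random.default_rng(seed)
    base_rows = _bilateral_base(n_pairs, n_midline)

    labels, classes, sides, xyz, cids, ords = [], [], [], [], [], []
    for r in base_rows:
        if len(r) == 6:
            lab, cls, side, x, y, z = r
            cid, ordn = None, np.nan
        else:
            lab, cls, side, x, y, z, cid, ordn = r
        labels.append(lab); classes.append(cls); sides.append(side)
        xyz.append((x, y, z)); cids.append(cid); ords.append(ordn)
    xyz = np.array(xyz)
    # curve ordinals must be consecutive per side-specific curve id
    side_cids = []
    per_curve_counter: dict[str, int] = {}
    for cid, side in zip(cids, sides):
        if cid is None:
            side_cids.append(None)
        else:
            scid = f"{cid}_{side[0]}"
            side_cids.append(scid)
    # recompute ordinals consecutively per curve
    new_ords = []
    for scid in side_cids:
        if scid is None:
            new_ords.append(np.nan)
        else:
            k = per_curve_counter.get(scid, 0)
            new_ords.append(k)
            per_curve_counter[scid] = k + 1

    df_base = pd.DataFrame({
        "label": labels, "class": classes, "region": "",
        "curve_id": side_cids, "ordinal": new_ords, "side": sides,
        "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
    })
    pairs = [(f"l{p}", f"r{p}") for p in range(n_pairs)]
    midline_labels = [f"m{i}" for i in range(n_midline)]
    lab_idx = {l: i for i, l in enumerate(labels)}

    def symmetric_field(rng):
        """Random smooth displacement, mirrored exactly across y = 0."""
        A = rng.normal(scale=shape_sd, size=(3, 3))
        b = rng.normal(scale=shape_sd, size=3)
        Q = rng.normal(scale=shape_sd * 0.5, size=(3, 3, 3))

        def f(p):
            lin = p @ A.T + b
            quad = np.einsum("ijk,nj,nk->ni", Q, p, p)
            return lin + quad

        def apply_sym(points):
            disp = f(points)
            # mirror the displacement field: S f(S p), S = diag(1,-1,1)
            S = np.array([1.0, -1.0, 1.0])
            disp_m = f(points * S) * S
            return 0.5 * (disp + disp_m)

        return apply_sym

    full, v1, v2, v3, v4 = [], [], [], [], []
    right_plus_mid = [l for l, s in zip(labels, sides) if s != "left"]
    left_landmarks = [
        l for l, s, c in zip(labels, sides, classes)
        if s == "left" and c == "landmark"
    ]
    left_curves = [
        l for l, s, c in zip(labels, sides, classes)
        if s == "left" and c == "curve"
    ]
    left_surfaces = [
        l for l, s, c in zip(labels, sides, classes)
        if s == "left" and c == "surface"
    ]
    for i in range(n_specimens):
        apply_sym = symmetric_field(rng)
        coords = xyz + apply_sym(xyz)
        coords[[lab_idx[m] for m in midline_labels], 1] = 0.0
        if asymmetry_sd > 0:
            coords = coords + rng.normal(scale=asymmetry_sd, size=coords.shape)
        if noise_sd > 0:
            coords = coords + rng.normal(scale=noise_sd, size=coords.shape)
        cfg = Configuration(f"spec{i}", df_base).with_coords(coords)
        full.append(cfg)
        v1.append(cfg.subset(right_plus_mid))
        v2.append(cfg.subset(right_plus_mid + left_landmarks))
        # variants 3/4: left curve (and surface) points imputed by mirroring
        def mirrored(extra):
            keep = right_plus_mid + left_landmarks + extra
            sub = cfg.subset(keep)
            c = sub.coords.copy()
            c[sub.index_of(extra)] = np.nan
            mirror_pairs = [(lab, "r" + lab[1:]) for lab in extra]
            return mirror_fill(sub.with_coords(c), mirror_pairs, midline_labels)
        v3.append(mirrored(left_curves))
        v4.append(mirrored(left_curves + left_surfaces))
    return {
        "full": full, "right_only": v1, "plus_left_landmarks": v2,
        "plus_mirrored_curves": v3, "fully_mirrored": v4,
        "pairs": pairs, "midline_labels": midline_labels,
        "right_labels": [l for l, s in zip(labels, sides) if s == "right"],
        "manifest": {
            "n_specimens": n_specimens, "n_pairs": n_pairs,
            "n_midline": n_midline, "noise_sd": noise_sd,
            "asymmetry_sd": asymmetry_sd, "shape_sd": shape_sd, "seed": seed,
        },
    }


# ---------------------------------------------------------------------------
# Two-group dataset (piecemeal-sliding experiment)
# ---------------------------------------------------------------------------


def make_two_group_dataset(
    n_a: int = 30,
    n_b: int = 10,
    seed: int = 0,
    deformation_sd: float = 0.05,
    group_offset_sd: float = 0.08,
    target_faces: int = 800,
    surface_grid: tuple[int, int] = (4, 8),
) -> dict:
    """Two groups of smoothly deformed hemispheres with on-mesh configurations.

    Each specimen is the hemisphere template warped by a random smooth TPS
    (control points on a box around the dome, displacements of scale
    ``deformation_sd`` x radius); group B adds a group-level mean
    deformation of scale ``group_offset_sd`` x radius.  The same warp is
    applied to mesh and configuration, so every point stays on its mesh.
    """
    rng = np.random.default_rng(seed)
    atlas = make_hemisphere_template(
        radius=1.0, target_faces=target_faces, surface_grid=surface_grid,
        n_curve_points=6,
    )
    ctrl = np.array([
        [x, y, z]
        for x in (-1.3, 1.3) for y in (-1.3, 1.3) for z in (-0.3, 1.3)
    ] + [[0.0, 0.0, 0.6]])
    group_disp = rng.normal(scale=group_offset_sd, size=ctrl.shape)
    configs, meshes, groups = [], [], []
    for i in range(n_a + n_b):
        grp = "A" if i < n_a else "B"
        disp = rng.normal(scale=deformation_sd, size=ctrl.shape)
        if grp == "B":
            disp = disp + group_disp
        model = fit_tps(ctrl, ctrl + disp)
        mesh = atlas.mesh.with_vertices(warp_points(model, atlas.mesh.vertices))
        warped = warp_points(model, atlas.config.coords)
        # the warp is nonlinear: re-snap points onto the faceted warped mesh
        snapped, _, _ = nearest_point_on_mesh(mesh, warped)
        cfg = atlas.config.with_coords(snapped).with_id(f"{grp}{i}")
        configs.append(cfg)
        meshes.append(mesh)
        groups.append(grp)
    return {
        "configs": configs, "meshes": meshes, "groups": groups,
        "curves": atlas.curves, "atlas": atlas,
        "manifest": {
            "n_a": n_a, "n_b": n_b, "seed": seed,
            "deformation_sd": deformation_sd,
            "group_offset_sd": group_offset_sd,
            "target_faces": target_faces, "surface_grid": surface_grid,
        },
    }
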