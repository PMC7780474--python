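"""Template-based surface-point projection ("patching").

Surface semilandmarks are digitized once, on a template mesh, and
transferred to each specimen semi-automatically: the template is warped to
the specimen by a thin-plate spline fitted through the fixed points they
share (landmarks + resampled curve points), the warped surface points are
inflated outward along the warped template's normals — preventing capture by
internal surfaces — and then deflated along those normals until they contact
the specimen mesh.

Also here: the procedures for variably present structures.  A structure
absent in some specimens can be represented as a *negligible region* (its
surface-point count replicated at one anchor coordinate, a zero-size
region), and a region that only sometimes bears a hole can be patched with a
shared template by fencing off a *negligibly-sized hole* — a closed curve
about the size of one surface point — on the specimens that lack it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point as _ShapelyPoint, Polygon as _ShapelyPolygon

from .mesh import TriMesh, nearest_point_on_mesh, ray_mesh_intersections
from .points import Configuration, CurveDefinition
from .sliding import SlidingSpec, slide
from .tps import fit_tps, warp_points

log = logging.getLogger(__name__)

__all__ = [
    "Atlas",
    "PatchResult",
    "build_atlas",
    "place_patch",
    "piecemeal_patch",
    "make_negligible_region",
    "make_negligible_hole",
]

_MIN_TEMPLATE_FACES = 10_000  # ~18,000 faces is the proven working range


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------


@dataclass
class Atlas:
    """A template mesh bound to its full point configuration.

    ``config`` holds the template's landmarks, resampled curve points, and
    surface points; ``region_map`` assigns every surface-point label to a
    region.  The fixed points (landmarks + curve points) must be in
    one-to-one label correspondence with every specimen patched with this
    atlas.
    """

    mesh: TriMesh
    config: Configuration
    curves: list[CurveDefinition]
    region_map: dict[str, list[str]] = field(default_factory=dict)

    @property
    def fixed_labels(self) -> list[str]:
        df = self.config.points
        return df.loc[df["class"] != "surface", "label"].tolist()

    @property
    def surface_labels(self) -> list[str]:
        df = self.config.points
        return df.loc[df["class"] == "surface", "label"].tolist()


def build_atlas(
    mesh: TriMesh,
    config: Configuration,
    curves: list[CurveDefinition],
    region_map: dict[str, list[str]] | None = None,
    tol: float | None = None,
) -> Atlas:
    """Validate and bind a template mesh to its point sets.

    Every configuration point must lie on the mesh surface within ``tol``
    (default 5e-3 x bounding-box diagonal); floating points are listed in
    the error.  Surface points not covered by ``region_map`` are assigned to
    their row's region.
    """
    if tol is None:
        tol = 5e-3 * mesh.bbox_diagonal
    _, _, dist = nearest_point_on_mesh(mesh, config.coords)
    floating = np.asarray(dist) > tol
    if np.any(floating):
        labs = [l for l, f in zip(config.labels, floating) if f]
        raise ValueError(
            f"template points off the mesh surface (tol={tol:.3g}): {labs}"
        )
    if mesh.n_faces < _MIN_TEMPLATE_FACES:
        log.warning(
            "template mesh has %d faces; fewer than %d limits how smoothly "
            "it can deform (around 18,000 faces is the proven range)",
            mesh.n_faces, _MIN_TEMPLATE_FACES,
        )
    df = config.points
    if region_map is None:
        region_map = {}
        for _, row in df[df["class"] == "surface"].iterrows():
            region_map.setdefault(row["region"] or "default", []).append(
                row["label"]
            )
    mapped = [l for labs in region_map.values() for l in labs]
    surface = set(df.loc[df["class"] == "surface", "label"])
    if set(mapped) != surface:
        raise ValueError(
            "region_map must cover exactly the surface-point labels; "
            f"difference: {sorted(set(mapped) ^ surface)}"
        )
    if len(mapped) != len(set(mapped)):
        raise ValueError("region_map assigns a label to several regions")
    return Atlas(mesh=mesh, config=config, curves=curves, region_map=region_map)


# ---------------------------------------------------------------------------
# Patching
# ---------------------------------------------------------------------------


@dataclass
class PatchResult:
    """Outcome of patching one specimen.

    Patch failure is a value, not an exception, so batch runs complete and
    report.  ``diagnostics`` has one row per surface point: distance of the
    placed point to the specimen surface, the sign of agreement between the
    warped-template normal and the face normal at the landing face (negative
    means placement on the reverse side of the polygons — face inversion),
    the projection route taken, and the off-region flag.
    """

    config: Configuration | None
    diagnostics: pd.DataFrame
    failed: bool = False
    reason: str = ""


def _surface_normal_at(mesh: TriMesh, points: np.ndarray):
    _, fidx, dist = nearest_point_on_mesh(mesh, points)
    return mesh.face_normals[np.asarray(fidx, dtype=int)], np.asarray(dist)


def place_patch(
    atlas: Atlas,
    specimen_mesh: TriMesh,
    specimen_fixed: Configuration,
    inflate: float = 0.0,
    relax_to_atlas: bool = False,
    stepsize: float = 0.1,
    inflate_relative: bool = False,
    fixed_tol: float | None = None,
) -> PatchResult:
    """Project the atlas's surface points onto one specimen.

    Pipeline: fit a TPS from the atlas fixed points to the specimen fixed
    points; warp the atlas surface points and mesh (the intermediate model);
    push each warped surface point outward by ``inflate`` along its
    warped-template normal (``inflate_relative`` scales by the specimen's
    fixed-point centroid size); cast a ray back along the negative normal
    and take the hit with the smallest absolute signed distance (ties broken
    toward the outward side), falling back to the globally nearest surface
    point when the ray misses; optionally relax the placed points toward the
    atlas configuration by tangent-plane bending-energy sliding.

    Specimen fixed points farther than ``fixed_tol`` from the specimen mesh
    (floating curve points are the leading cause of patching failure) yield
    ``failed=True`` with the offending labels in ``reason``.
    """
    fixed_labels = atlas.fixed_labels
    spec_labels = specimen_fixed.labels
    if sorted(spec_labels) != sorted(fixed_labels):
        diff = sorted(set(spec_labels) ^ set(fixed_labels))
        raise ValueError(
            f"specimen fixed labels do not match the atlas; difference: {diff}"
        )
    if fixed_tol is None:
        fixed_tol = 5e-3 * specimen_mesh.bbox_diagonal
    spec_fixed = specimen_fixed.subset(fixed_labels)
    # reorder specimen rows into atlas fixed order
    order = spec_fixed.index_of(fixed_labels)
    spec_fixed_coords = spec_fixed.coords[order]
    _, _, d_fixed = nearest_point_on_mesh(specimen_mesh, spec_fixed_coords)
    floating = np.asarray(d_fixed) > fixed_tol
    if np.any(floating):
        labs = [l for l, f in zip(fixed_labels, floating) if f]
        return PatchResult(
            config=None,
            diagnostics=pd.DataFrame(),
            failed=True,
            reason=f"floating fixed points (not on the specimen surface): {labs}",
        )

    atlas_df = atlas.config.points
    atlas_fixed_coords = atlas.config.subset(fixed_labels).coords[
        atlas.config.subset(fixed_labels).index_of(fixed_labels)
    ]
    surf_labels = atlas.surface_labels
    atlas_surface = atlas.config.subset(surf_labels).coords

    model = fit_tps(atlas_fixed_coords, spec_fixed_coords, lam=0.0)
    warped_surface = warp_points(model, atlas_surface)
    intermediate = atlas.mesh.with_vertices(
        warp_points(model, atlas.mesh.vertices)
    )
    normals, _ = _surface_normal_at(intermediate, warped_surface)

    scale = spec_fixed.centroid_size()
    amount = inflate * scale if inflate_relative else inflate
    inflated = warped_surface + amount * normals

    placed = np.empty_like(warped_surface)
    route = []
    normal_sign = np.zeros(len(warped_surface), dtype=int)
    for i, (p, nrm) in enumerate(zip(inflated, normals)):
        hits = ray_mesh_intersections(specimen_mesh, p, -nrm)
        if hits:
            # smallest |signed distance|; ties toward the outward side
            best = min(hits, key=lambda h: (abs(h[2]), h[2] < 0))
            placed[i] = best[0]
            # outward-facing landing: specimen face normal along the warped
            # template normal
            fsign = np.sign(specimen_mesh.face_normals[best[1]] @ nrm)
            normal_sign[i] = int(fsign)
            route.append("ray")
        else:
            q, fidx, _ = nearest_point_on_mesh(specimen_mesh, p)
            placed[i] = q
            normal_sign[i] = int(
                np.sign(specimen_mesh.face_normals[fidx] @ nrm)
            )
            route.append("nearest")

    # assemble output configuration in canonical atlas order
    out = atlas.config.points.copy()
    fixed_pos = {lab: i for i, lab in enumerate(fixed_labels)}
    surf_pos = {lab: i for i, lab in enumerate(surf_labels)}
    coords = np.empty((len(out), 3))
    for r, row in enumerate(out.itertuples(index=False)):
        if row.label in fixed_pos:
            coords[r] = spec_fixed_coords[fixed_pos[row.label]]
        else:
            coords[r] = placed[surf_pos[row.label]]
    result_cfg = Configuration(
        specimen_fixed.specimen_id, out
    ).with_coords(coords)

    if relax_to_atlas:
        sspec = SlidingSpec(
            criterion="bending_energy",
            stepsize=stepsize,
            max_iterations=5,
            reference_mode="fixed_reference",
            slide_curves=False,
        )
        result_cfg = slide(
            [result_cfg], sspec, atlas.curves, [specimen_mesh],
            reference=atlas.config,
        )[0]
        placed = result_cfg.subset(surf_labels).coords

    _, dist_after = _surface_normal_at(specimen_mesh, placed)
    off_region = _off_region_flags(
        atlas, model, surf_labels, placed
    )
    diag = pd.DataFrame({
        "label": surf_labels,
        "distance_to_surface": dist_after,
        "normal_sign": normal_sign,
        "route": route,
        "off_region": off_region,
    })
    return PatchResult(config=result_cfg, diagnostics=diag, failed=False)


def _off_region_flags(atlas, model, surf_labels, placed) -> np.ndarray:
    """Planar-proxy containment test in the warped-template frame.

    For each region whose boundary (the fixed points labeled with that
    region) has >= 3 points, the boundary is warped to the specimen, both
    boundary and placed points are projected onto the boundary's best-fit
    plane, and a point is flagged when it falls outside the boundary's
    convex hull by more than 5% of the region scale.  Regions without a
    usable boundary are never flagged.
    """
    flags = np.zeros(len(surf_labels), dtype=bool)
    df = atlas.config.points
    label_to_i = {l: i for i, l in enumerate(surf_labels)}
    for region, labels in atlas.region_map.items():
        boundary = df[(df["class"] != "surface") & (df["region"] == region)]
        if len(boundary) < 3:
            continue
        b_src = boundary[["x", "y", "z"]].to_numpy(dtype=float)
        b = warp_points(model, b_src)
        c = b.mean(axis=0)
        _, s, vt = np.linalg.svd(b - c)
        if s[1] <= 1e-12 * max(s[0], 1e-300):
            continue
        basis = vt[:2]
        b2 = (b - c) @ basis.T
        try:
            hull = _ShapelyPolygon(b2).convex_hull
        except Exception:
            continue
        scale = np.sqrt(((b2) ** 2).sum(axis=1)).max()
        tol = 0.05 * scale
        for lab in labels:
            i = label_to_i[lab]
            p2 = (placed[i] - c) @ basis.T
            pt = _ShapelyPoint(p2)
            if not hull.buffer(tol).contains(pt):
                flags[i] = True
    return flags


def piecemeal_patch(
    atlas_per_region: dict[str, Atlas],
    specimen_mesh: TriMesh,
    specimen_fixed: Configuration,
    inflate_per_region: dict[str, float] | float = 0.0,
    anchor_labels_per_region: dict[str, list[str]] | None = None,
    **kwargs,
) -> PatchResult:
    """Patch each region with its own atlas and merge the results.

    ``anchor_labels_per_region`` adds neighboring regions' fixed points as
    extra warp anchors for a region without patching them — the remedy for
    face inversion when a region alone under-constrains the warp.  Surface
    point labels must not overlap across regions; the merged configuration
    lists the specimen's fixed points first (in their given order), then
    each region's surface points in region order.
    """
    anchor_labels_per_region = anchor_labels_per_region or {}
    all_surface: list[str] = []
    for region, atlas in atlas_per_region.items():
        for lab in atlas.surface_labels:
            if lab in all_surface:
                raise ValueError(
                    f"surface label {lab!r} appears in more than one region"
                )
            all_surface.append(lab)
    frames = []
    diags = []
    for region, atlas in atlas_per_region.items():
        wanted = set(atlas.fixed_labels) | set(
            anchor_labels_per_region.get(region, [])
        )
        sub_fixed = specimen_fixed.subset(
            [l for l in specimen_fixed.labels if l in wanted]
        )
        inflate = (
            inflate_per_region.get(region, 0.0)
            if isinstance(inflate_per_region, dict)
            else inflate_per_region
        )
        res = place_patch(atlas, specimen_mesh, sub_fixed, inflate=inflate,
                          **kwargs)
        if res.failed:
            return PatchResult(
                config=None, diagnostics=res.diagnostics, failed=True,
                reason=f"region {region!r}: {res.reason}",
            )
        surf = res.config.subset(atlas.surface_labels)
        frames.append(surf.points)
        d = res.diagnostics.copy()
        d.insert(0, "region", region)
        diags.append(d)
    merged = pd.concat(
        [specimen_fixed.points] + frames, ignore_index=True
    )
    cfg = Configuration(specimen_fixed.specimen_id, merged)
    return PatchResult(
        config=cfg, diagnostics=pd.concat(diags, ignore_index=True),
        failed=False,
    )


# ---------------------------------------------------------------------------
# Variably present structures
# ---------------------------------------------------------------------------


def make_negligible_region(
    anchor: np.ndarray,
    n: int,
    labels: list[str],
    region: str = "",
    side: str = "none",
) -> pd.DataFrame:
    """Surface-point rows for an absent structure: ``n`` copies of ``anchor``.

    The replicated coordinates give the region zero centroid size while
    retaining positional information; the rows are inserted in canonical
    order for specimens lacking the structure (and the structure's landmarks
    and curves are dropped from all specimens before joint alignment).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(labels) != n:
        raise ValueError(
            f"{len(labels)} labels supplied for a region of {n} surface points"
        )
    anchor = np.asarray(anchor, dtype=float).reshape(3)
    return pd.DataFrame({
        "label": labels,
        "class": "surface",
        "region": region,
        "curve_id": None,
        "ordinal": np.nan,
        "side": side,
        "x": anchor[0], "y": anchor[1], "z": anchor[2],
    })


def make_negligible_hole(
    mesh: TriMesh,
    position: np.ndarray,
    surface_point_spacing: float,
    curve_id: str = "hole",
    anchor_label: str = "hole_anchor",
    n_fence_points: int = 24,
    region: str = "",
) -> tuple[CurveDefinition, pd.DataFrame]:
    """A minute closed fence standing in for an absent hole.

    Specimens lacking a fossa/foramen get the same fence labels as the
    hole-bearing specimens, but enclosing an area about the size of one
    surface point (fence diameter = ``surface_point_spacing``), so one atlas
    can patch both.  The fence is a circle in the local tangent plane,
    snapped onto the mesh; it returns the closed curve definition plus rows
    for the anchor landmark and fence curve points (removable after patching
    via ``drop_points``).
    """
    if surface_point_spacing <= 0:
        raise ValueError("surface_point_spacing must be positive")
    center, fidx, _ = nearest_point_on_mesh(
        mesh, np.asarray(position, dtype=float).reshape(3)
    )
    n = mesh.face_normals[fidx]
    a = np.array([1.0, 0.0, 0.0])
    if abs(n @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(n, a)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    radius = surface_point_spacing / 2.0
    theta = np.linspace(0.0, 2 * np.pi, n_fence_points + 1)[:-1]
    circle = center + radius * (
        np.outer(np.cos(theta), t1) + np.outer(np.sin(theta), t2)
    )
    snapped, _, _ = nearest_point_on_mesh(mesh, circle)
    rows = [{
        "label": anchor_label, "class": "landmark", "region": region,
        "curve_id": None, "ordinal": np.nan, "side": "none",
        "x": snapped[0, 0], "y": snapped[0, 1], "z": snapped[0, 2],
    }]
    for i in range(1, n_fence_points):
        rows.append({
            "label": f"{curve_id}_{i - 1}", "class": "curve",
            "region": region, "curve_id": curve_id, "ordinal": i - 1,
            "side": "none",
            "x": snapped[i, 0], "y": snapped[i, 1], "z": snapped[i, 2],
        })
    curve = CurveDefinition(
        curve_id=curve_id,
        start_landmark=anchor_label,
        end_landmark=anchor_label,
        n_points=n_fence_points,
        closed=True,
    )
    return curve, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Atlas bundle I/O
# ---------------------------------------------------------------------------


def save_atlas(atlas: Atlas, directory) -> None:
    """Write an atlas bundle: template PLY + configuration CSV + curves CSV +
    JSON manifest (region map, version)."""
    import json
    from pathlib import Path

    from . import __version__
    from .mesh import write_mesh
    from .points import write_configurations, write_curves

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_mesh(atlas.mesh, d / "template.ply", "ply_ascii")
    write_configurations([atlas.config], d / "config.csv")
    write_curves(atlas.curves, d / "curves.csv")
    (d / "manifest.json").write_text(json.dumps({
        "region_map": atlas.region_map,
        "version": __version__,
        "n_faces": atlas.mesh.n_faces,
        "n_points": len(atlas.config),
    }, indent=2))


def load_atlas(directory) -> Atlas:
    """Read an atlas bundle written by :func:`save_atlas`."""
    import json
    from pathlib import Path

    from .mesh import read_mesh
    from .points import read_configurations, read_curves

    d = Path(directory)
    mesh = read_mesh(d / "template.ply")
    config = read_configurations(d / "config.csv")[0]
    curves = read_curves(d / "curves.csv")
    manifest = json.loads((d / "manifest.json").read_text())
    return build_atlas(mesh, config, curves,
                       region_map=manifest.get("region_map") or None)
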