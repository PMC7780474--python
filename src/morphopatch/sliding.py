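"""Sliding semilandmarks, generalized Procrustes alignment, and mirroring.

After patching, curve points are slid along their curve tangents and surface
points within their mesh tangent planes, minimizing either the bending
energy of the thin-plate spline from a reference shape (the default
criterion) or the Procrustes distance to it.  Tangential displacements are
solved exactly as a generalized least-squares problem, damped by a stepsize
factor (default 0.1 — large steps let curve points leave their digitized
curves), and re-projected onto the specimen geometry after every step.

Generalized Procrustes analysis (GPA) removes position, scale, and rotation
across a sample, producing aligned shapes, the mean shape, centroid sizes,
and a PCA of the aligned coordinates.  Bilateral structures digitized on one
side only can be completed by mirroring across the least-squares midline
plane before alignment; aligning one-sided data inflates apparent shape
variation along the midline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .mesh import TriMesh, nearest_point_on_mesh
from .points import Configuration, CurveDefinition
from .tps import bending_energy_matrix

log = logging.getLogger(__name__)

__all__ = [
    "SlidingSpec",
    "AlignmentResult",
    "tangent_structures",
    "slide",
    "gpa",
    "procrustes_distance",
    "find_mean_spec",
    "mirror_fill",
    "midline_variance_fraction",
]


# ---------------------------------------------------------------------------
# Superimposition primitives
# ---------------------------------------------------------------------------


def _center_scale(x: np.ndarray):
    c = x.mean(axis=0)
    y = x - c
    s = np.sqrt((y**2).sum())
    if s == 0:
        raise ValueError("degenerate configuration with zero centroid size")
    return y / s, c, s


def _optimal_rotation(a: np.ndarray, b: np.ndarray, allow_reflection: bool = False):
    """Rotation R minimizing ||a @ R - b||_F (det(R) = +1 unless allowed)."""
    u, _, vt = np.linalg.svd(a.T @ b)
    if not allow_reflection and np.linalg.det(u @ vt) < 0:
        u = u.copy()
        u[:, -1] *= -1
    return u @ vt


def procrustes_distance(
    a, b, allow_reflection: bool = False
) -> float:
    """Full Procrustes distance: RMS residual after optimal translation,
    scaling, and rotation.  Symmetric; zero iff the shapes are similar."""
    xa = a.coords if isinstance(a, Configuration) else np.asarray(a, float)
    xb = b.coords if isinstance(b, Configuration) else np.asarray(b, float)
    if xa.shape != xb.shape:
        raise ValueError("configurations have different point counts")
    za, *_ = _center_scale(xa)
    zb, *_ = _center_scale(xb)
    r = _optimal_rotation(za, zb, allow_reflection)
    # optimal scale between unit-size shapes is trace(S); the symmetric form
    d2 = 1.0 - min(1.0, float(np.sum(za @ r * zb))) ** 2
    return float(np.sqrt(max(d2, 0.0)))


def _superimpose_similarity(src: np.ndarray, dst: np.ndarray,
                            allow_reflection: bool = False) -> np.ndarray:
    """Map src onto dst by the least-squares similarity transform."""
    zs, cs, ss = _center_scale(src)
    zd, cd, sd = _center_scale(dst)
    r = _optimal_rotation(zs, zd, allow_reflection)
    beta = float(np.sum(zs @ r * zd))  # optimal scale for unit shapes
    return (zs @ r) * beta * sd + cd


# ---------------------------------------------------------------------------
# Generalized Procrustes analysis
# ---------------------------------------------------------------------------


@dataclass
class AlignmentResult:
    """Procrustes-aligned sample with mean shape and PCA.

    ``aligned`` configurations are centered, unit centroid size, and
    optimally rotated; ``eigenvalues`` sum to the total aligned variance and
    ``scores[i, j]`` is specimen i on PC j (covariance scaled by 1/(n-1)).
    """

    aligned: list[Configuration]
    mean_shape: Configuration
    centroid_sizes: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # (n_components, 3k)
    scores: np.ndarray        # (n, n_components)
    objective_trace: list[float] = field(default_factory=list)

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.aligned]

    def aligned_array(self) -> np.ndarray:
        return np.stack([c.coords for c in self.aligned])

    def variance_explained(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        return self.eigenvalues / tot if tot > 0 else self.eigenvalues

    def covariance(self) -> np.ndarray:
        """(3k, 3k) covariance of the flattened aligned coordinates."""
        flat = self.aligned_array().reshape(len(self.aligned), -1)
        return np.cov(flat, rowvar=False, ddof=1)


def gpa(
    configs: list[Configuration],
    allow_reflection: bool = False,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> AlignmentResult:
    """Generalized Procrustes analysis with PCA of the aligned shapes.

    Each configuration is centered and scaled to unit centroid size, then
    iteratively rotated to the evolving mean until the mean stabilizes; the
    summed squared distance to the mean is non-increasing over iterations
    (recorded in ``objective_trace``).
    """
    if len(configs) < 1:
        raise ValueError("need at least one configuration")
    k = len(configs[0])
    if k < 3:
        raise ValueError("need at least 3 points")
    for c in configs[1:]:
        if len(c) != k:
            raise ValueError("configurations have different point counts")
    shapes, sizes = [], []
    for c in configs:
        z, _, s = _center_scale(c.coords)
        shapes.append(z)
        sizes.append(s)
    shapes = np.stack(shapes)
    n = len(shapes)
    ref = shapes[0].copy()
    trace = []
    for _ in range(max_iter):
        for i in range(n):
            r = _optimal_rotation(shapes[i], ref, allow_reflection)
            shapes[i] = shapes[i] @ r
        mean = shapes.mean(axis=0)
        mean /= np.sqrt((mean**2).sum())
        trace.append(float(((shapes - mean) ** 2).sum()))
        if np.sqrt(((mean - ref) ** 2).sum()) < tol:
            ref = mean
            break
        ref = mean
    aligned = [c.with_coords(shapes[i]) for i, c in enumerate(configs)]
    mean_cfg = configs[0].with_coords(ref).with_id("mean")
    flat = shapes.reshape(n, -1)
    centered = flat - flat.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    ncomp = min(n - 1, centered.shape[1]) if n > 1 else 0
    eigenvalues = (s[:ncomp] ** 2) / (n - 1) if n > 1 else np.zeros(0)
    return AlignmentResult(
        aligned=aligned,
        mean_shape=mean_cfg,
        centroid_sizes=np.asarray(sizes),
        eigenvalues=eigenvalues,
        eigenvectors=vt[:ncomp],
        scores=(u[:, :ncomp] * s[:ncomp]) if n > 1 else np.zeros((n, 0)),
        objective_trace=trace,
    )


def find_mean_spec(result: AlignmentResult) -> str:
    """Specimen closest to the mean shape (the natural template choice).

    Ties broken lexicographically by specimen id.
    """
    best = None
    for cfg in result.aligned:
        d = procrustes_distance(cfg, result.mean_shape)
        key = (d, cfg.specimen_id)
        if best is None or key < best:
            best = key
    return best[1]


# ---------------------------------------------------------------------------
# Tangent structures
# ---------------------------------------------------------------------------


def tangent_structures(
    config: Configuration,
    curves: list[CurveDefinition],
    mesh: TriMesh | None,
) -> list[np.ndarray]:
    """Per-point sliding basis: (d_i, 3) orthonormal rows.

    Landmarks never slide (empty basis).  Curve points get the unit tangent
    from the central difference of their neighbors along the curve (anchors
    included, so points adjacent to a landmark get a one-sided-weighted
    tangent).  Surface points get an orthonormal pair spanning the tangent
    plane of the nearest mesh face.  Degenerate tangents demote the point to
    fixed with a warning.
    """
    k = len(config)
    bases: list[np.ndarray] = [np.zeros((0, 3)) for _ in range(k)]
    coords = config.coords
    label_idx = {lab: i for i, lab in enumerate(config.labels)}
    df = config.points
    for curve in curves:
        sel = df[(df["class"] == "curve") & (df["curve_id"] == curve.curve_id)]
        if sel.empty:
            continue
        sel = sel.sort_values("ordinal")
        idx = [label_idx[l] for l in sel["label"]]
        chain = [label_idx[curve.start_landmark], *idx]
        if curve.closed:
            seq = np.array(chain + [chain[0]])
        else:
            seq = np.array(chain + [label_idx[curve.end_landmark]])
        for pos in range(1, len(seq) - 1):
            i = seq[pos]
            t = coords[seq[pos + 1]] - coords[seq[pos - 1]]
            nt = np.linalg.norm(t)
            if nt == 0:
                log.warning(
                    "zero tangent at curve point %s; treating as fixed",
                    config.labels[i],
                )
                continue
            bases[i] = (t / nt).reshape(1, 3)
    surf = np.nonzero(df["class"].to_numpy() == "surface")[0]
    if len(surf):
        if mesh is None:
            raise ValueError("surface points present but no mesh supplied")
        _, fidx, _ = nearest_point_on_mesh(mesh, coords[surf])
        normals = mesh.face_normals[fidx]
        for j, i in enumerate(surf):
            n = normals[j]
            if np.linalg.norm(n) == 0:
                log.warning(
                    "degenerate normal at surface point %s; treating as fixed",
                    config.labels[i],
                )
                continue
            a = np.array([1.0, 0.0, 0.0])
            if abs(n @ a) > 0.9:
                a = np.array([0.0, 1.0, 0.0])
            t1 = np.cross(n, a)
            t1 /= np.linalg.norm(t1)
            t2 = np.cross(n, t1)
            t2 /= np.linalg.norm(t2)
            bases[i] = np.vstack([t1, t2])
    return bases


# ---------------------------------------------------------------------------
# Sliding
# ---------------------------------------------------------------------------


@dataclass
class SlidingSpec:
    """Parameters of the sliding scheme.

    stepsize damps each solved displacement (default 0.1: larger values let
    curve points stray from their digitized curves before re-projection);
    the loop stops when the relative change in mean Procrustes distance to
    the reference drops below ``tolerance`` or after ``max_iterations``.
    """

    criterion: str = "bending_energy"  # or "procrustes_distance"
    stepsize: float = 0.1
    max_iterations: int = 50
    tolerance: float = 1e-6
    reference_mode: str = "sample_mean"  # or "fixed_reference"
    slide_curves: bool = True
    slide_surfaces: bool = True

    def __post_init__(self):
        if self.stepsize < 0:
            raise ValueError("stepsize must be >= 0")
        if self.stepsize > 1:
            log.warning(
                "stepsize %.3g > 1: undamped steps overshoot and let curve "
                "points leave their curves before re-projection",
                self.stepsize,
            )
        if self.criterion not in ("bending_energy", "procrustes_distance"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.reference_mode not in ("sample_mean", "fixed_reference"):
            raise ValueError(f"unknown reference_mode {self.reference_mode!r}")


def _criterion_value(crit, ref, y, bmat):
    if crit == "bending_energy":
        return float(np.trace(y.T @ bmat @ y))
    aligned_ref = _superimpose_similarity(ref, y)
    return float(((aligned_ref - y) ** 2).sum())


def _solve_step(crit, ref, y, bmat, bases, active):
    """Exact tangential minimizer of the criterion; returns (k, 3) update."""
    dofs = []  # (point index, direction)
    for i in active:
        for d in bases[i]:
            dofs.append((i, d))
    if not dofs:
        return np.zeros_like(y)
    p = np.array([i for i, _ in dofs])
    D = np.stack([d for _, d in dofs])
    if crit == "bending_energy":
        M = bmat[np.ix_(p, p)] * (D @ D.T)
        g = np.einsum("ij,ij->i", (bmat @ y)[p], D)
        try:
            t = scipy.linalg.solve(M, -g, assume_a="sym")
            if not np.all(np.isfinite(t)):
                raise scipy.linalg.LinAlgError("non-finite solution")
        except (scipy.linalg.LinAlgError, ValueError):
            lam = 1e-8 * (np.trace(M) / len(M) if np.trace(M) > 0 else 1.0)
            log.warning("singular sliding system; ridge fallback lambda=%g", lam)
            t = scipy.linalg.solve(M + lam * np.eye(len(M)), -g, assume_a="sym")
    else:
        aligned_ref = _superimpose_similarity(ref, y)
        delta = aligned_ref - y
        t = np.einsum("ij,ij->i", delta[p], D)
    update = np.zeros_like(y)
    np.add.at(update, p, t[:, None] * D)
    return update


def _project_polyline(point: np.ndarray, pl: np.ndarray) -> np.ndarray:
    """Nearest point on a polyline (segment-wise closed-form)."""
    a, b = pl[:-1], pl[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    t = np.clip(np.einsum("ij,ij->i", point - a, ab) / denom, 0.0, 1.0)
    cand = a + t[:, None] * ab
    return cand[np.argmin(((cand - point) ** 2).sum(axis=1))]


def slide(
    configs: list[Configuration],
    spec: SlidingSpec,
    curves: list[CurveDefinition],
    meshes: list[TriMesh] | None,
    reference: Configuration | None = None,
    return_trace: bool = False,
):
    """Slide curve and surface semilandmarks across a sample.

    Each outer iteration: (a) the reference is the GPA mean
    (``sample_mean``) or the supplied fixed reference; (b) per specimen the
    tangential displacements minimizing the criterion are solved exactly;
    (c) the step is damped by ``spec.stepsize``; (d) slid curve points are
    re-projected onto their specimen's digitized polyline and surface points
    onto the specimen mesh; (e) repeat to convergence.  With stepsize 1 and
    before re-projection, the solved configuration's criterion value never
    exceeds the pre-step value.

    Returns the slid configurations (and, with ``return_trace``, a dict with
    per-iteration pre/post criterion values summed over specimens).
    """
    n = len(configs)
    if n == 0:
        raise ValueError("no configurations")
    if spec.reference_mode == "fixed_reference" and reference is None:
        raise ValueError("fixed_reference mode needs a reference")
    if meshes is not None and len(meshes) != n:
        raise ValueError("need one mesh per configuration")
    # digitized geometry captured once: these are the constraint curves
    polylines = [
        {cv.curve_id: cfg.curve_polyline(cv) for cv in curves}
        for cfg in configs
    ]
    current = [c.coords.copy() for c in configs]
    classes = configs[0].classes
    trace = {"pre": [], "post": []}
    prev_mean_d = None
    for _it in range(spec.max_iterations):
        if spec.reference_mode == "sample_mean":
            res = gpa([c.with_coords(x) for c, x in zip(configs, current)])
            ref = res.mean_shape.coords
        else:
            ref = reference.coords
        bmat = (
            bending_energy_matrix(ref)
            if spec.criterion == "bending_energy"
            else None
        )
        pre_total = post_total = 0.0
        for i in range(n):
            cfg_now = configs[i].with_coords(current[i])
            bases = tangent_structures(
                cfg_now, curves, meshes[i] if meshes is not None else None
            )
            active = [
                j for j in range(len(classes))
                if (classes[j] == "curve" and spec.slide_curves)
                or (classes[j] == "surface" and spec.slide_surfaces)
            ]
            y = current[i]
            pre_total += _criterion_value(spec.criterion, ref, y, bmat)
            update = _solve_step(spec.criterion, ref, y, bmat, bases, active)
            y_full = y + update
            post_total += _criterion_value(spec.criterion, ref, y_full, bmat)
            y_new = y + spec.stepsize * update
            # re-projection: curves back onto their digitized polylines,
            # surfaces back onto the mesh
            df = configs[i].points
            for j in active:
                if classes[j] == "curve":
                    cid = df.iloc[j]["curve_id"]
                    pl = polylines[i][cid]
                    cv = next(c for c in curves if c.curve_id == cid)
                    if cv.closed and not np.allclose(pl[0], pl[-1]):
                        pl = np.vstack([pl, pl[0]])
                    y_new[j] = _project_polyline(y_new[j], pl)
            surf_active = [j for j in active if classes[j] == "surface"]
            if surf_active and meshes is not None:
                pts, _, _ = nearest_point_on_mesh(
                    meshes[i], y_new[surf_active]
                )
                y_new[surf_active] = pts
            current[i] = y_new
        trace["pre"].append(pre_total)
        trace["post"].append(post_total)
        mean_d = float(np.mean([
            procrustes_distance(configs[i].with_coords(current[i]),
                                configs[0].with_coords(ref))
            for i in range(n)
        ]))
        if prev_mean_d is not None:
            denom = max(prev_mean_d, 1e-300)
            if abs(mean_d - prev_mean_d) / denom < spec.tolerance:
                prev_mean_d = mean_d
                break
        prev_mean_d = mean_d
        if spec.stepsize == 0:
            break
    out = [c.with_coords(x) for c, x in zip(configs, current)]
    if return_trace:
        return out, trace
    return out


# ---------------------------------------------------------------------------
# Mirroring
# ---------------------------------------------------------------------------


def mirror_fill(
    config: Configuration,
    pairs: list[tuple[str, str]],
    midline_labels: list[str],
) -> Configuration:
    """Impute a missing bilateral side by reflection across the midline plane.

    The midline plane is the least-squares plane through ``midline_labels``
    (>= 3 non-collinear points).  For each (left, right) pair exactly one
    member must be present (non-NaN); the other is filled with the present
    member's reflection.  Midline points are unchanged; on perfectly
    symmetric data the operation is an exact involution.
    """
    coords = config.coords
    mid_idx = config.index_of(midline_labels)
    mid = coords[mid_idx]
    if len(mid) < 3:
        raise ValueError("need at least 3 midline points")
    c = mid.mean(axis=0)
    _, s, vt = np.linalg.svd(mid - c)
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise ValueError("midline points are collinear; plane undefined")
    normal = vt[2]
    new = coords.copy()
    for left, right in pairs:
        il, ir = config.index_of([left])[0], config.index_of([right])[0]
        left_ok = not np.isnan(coords[il]).any()
        right_ok = not np.isnan(coords[ir]).any()
        if left_ok == right_ok:
            raise ValueError(
                f"pair ({left!r}, {right!r}) must have exactly one present side"
            )
        src, dst = (il, ir) if left_ok else (ir, il)
        p = coords[src]
        new[dst] = p - 2.0 * ((p - c) @ normal) * normal
    return config.with_coords(new)


def midline_variance_fraction(
    result: AlignmentResult,
    midline_labels: list[str],
    reference_labels: list[str] | None = None,
) -> float:
    """Variance along the midline relative to a reference point set.

    Sum of per-coordinate variances (across specimens, after alignment) over
    the midline points, divided by the same sum over ``reference_labels``
    (default: every non-midline point).  One-sided alignment inflates this
    fraction; mirroring before alignment deflates it.
    """
    if not midline_labels:
        raise ValueError("empty midline label set")
    arr = result.aligned_array()  # (n, k, 3)
    cfg = result.aligned[0]
    mid_idx = cfg.index_of(midline_labels)
    if reference_labels is None:
        ref_idx = np.array(
            [i for i in range(arr.shape[1]) if i not in set(mid_idx)]
        )
    else:
        ref_idx = cfg.index_of(reference_labels)
    var = arr.var(axis=0, ddof=1)  # (k, 3)
    num = float(var[mid_idx].sum())
    den = float(var[ref_idx].sum())
    if den == 0:
        raise ValueError("reference point set has zero variance")
    return num / den
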