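"""Triangle-mesh data model, PLY/STL I/O, and geometric queries.

The mesh is the substrate for every later step: specimen surfaces are read
from PLY or STL files, centered, and queried during surface-point projection
(nearest point on surface, ray casting along point normals).

ASCII PLY is parsed and written natively so that coordinates survive a
write/read round trip exactly (float64 text, full repr) and so that malformed
headers and truncated bodies produce errors naming the offending line.
Binary PLY (either endianness) and STL are handled through :mod:`trimesh`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh
from trimesh.proximity import closest_point_naive

log = logging.getLogger(__name__)

__all__ = [
    "TriMesh",
    "MeshIOError",
    "read_mesh",
    "write_mesh",
    "center_mesh",
    "nearest_point_on_mesh",
    "ray_mesh_intersections",
    "extract_submesh",
]


class MeshIOError(ValueError):
    """Raised for unreadable, malformed, or unsupported mesh files."""


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


@dataclass
class TriMesh:
    """Triangle mesh: vertices, faces, derived area-weighted vertex normals.

    Face winding is made globally consistent at construction when the mesh is
    orientable; ``orientable`` records whether that succeeded.  Indexing is
    0-based throughout.

    Parameters
    ----------
    vertices : (n, 3) float array, mesh units.
    faces : (m, 3) int array of vertex indices; each face has 3 distinct
        vertices.
    source_dialect : dialect the mesh was read from, if any
        (``ply_ascii``, ``ply_binary_little_endian``, ``ply_binary_big_endian``,
        ``stl_ascii``, ``stl_binary``).
    """

    vertices: np.ndarray
    faces: np.ndarray
    source_dialect: str | None = None
    fix_winding: bool = True
    orientable: bool = field(default=True, init=True)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.vertices) == 0:
            raise ValueError("mesh has no vertices")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face index out of range")
            degenerate = (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            )
            if degenerate.any():
                raise ValueError(
                    f"{int(degenerate.sum())} faces have repeated vertex indices"
                )
        self._cache: dict = {}
        if self.fix_winding and len(self.faces) > 1:
            tm = self._tm()
            if not tm.is_winding_consistent:
                _trimesh.repair.fix_normals(tm)
                if tm.is_winding_consistent:
                    self.faces = np.asarray(tm.faces, dtype=np.int64)
                    self._cache = {}
                else:
                    self.orientable = False
                    log.warning(
                        "mesh is not orientable; winding left as loaded"
                    )

    # -- derived quantities -------------------------------------------------

    def _tm(self) -> _trimesh.Trimesh:
        if "tm" not in self._cache:
            self._cache["tm"] = _trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
        return self._cache["tm"]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def centroid(self) -> np.ndarray:
        """Mean of the vertex coordinates."""
        return self.vertices.mean(axis=0)

    @property
    def bbox_diagonal(self) -> float:
        ext = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(ext))

    @property
    def face_normals(self) -> np.ndarray:
        """(m, 3) unit normals; zero vector for degenerate faces."""
        if "fn" not in self._cache:
            tri = self.vertices[self.faces]
            n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
            norm = np.linalg.norm(n, axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                unit = np.where(norm > 0, n / norm, 0.0)
            self._cache["fn"] = unit
            self._cache["fa"] = 0.5 * norm.ravel()
        return self._cache["fn"]

    @property
    def face_areas(self) -> np.ndarray:
        self.face_normals
        return self._cache["fa"]

    @property
    def vertex_normals(self) -> np.ndarray:
        """(n, 3) area-weighted unit vertex normals.

        A vertex belonging to no face gets the zero vector.
        """
        if "vn" not in self._cache:
            acc = np.zeros_like(self.vertices)
            weighted = self.face_normals * self.face_areas[:, None]
            for c in range(3):
                np.add.at(acc, self.faces[:, c], weighted)
            norm = np.linalg.norm(acc, axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                self._cache["vn"] = np.where(norm > 0, acc / norm, 0.0)
        return self._cache["vn"]

    def copy(self) -> "TriMesh":
        return TriMesh(
            self.vertices.copy(),
            self.faces.copy(),
            source_dialect=self.source_dialect,
            fix_winding=False,
            orientable=self.orientable,
        )

    def with_vertices(self, vertices: np.ndarray) -> "TriMesh":
        """Same connectivity, new vertex coordinates (winding untouched)."""
        return TriMesh(
            np.asarray(vertices, dtype=float),
            self.faces.copy(),
            source_dialect=self.source_dialect,
            fix_winding=False,
            orientable=self.orientable,
        )


# ---------------------------------------------------------------------------
# PLY (ASCII) parsing
# ---------------------------------------------------------------------------

_PLY_SCALARS = {
    "char", "int8", "uchar", "uint8", "short", "int16", "ushort", "uint16",
    "int", "int32", "uint", "uint32", "float", "float32", "double", "float64",
}


def _parse_ply_header(lines: list[str]):
    """Parse a PLY header into (format, elements, n_header_lines).

    ``elements`` is a list of (name, count, [property specs]).  Raises
    MeshIOError naming the offending 1-based line for anything malformed.
    """
    if not lines or lines[0].strip() != "ply":
        raise MeshIOError("line 1: not a PLY file (missing 'ply' magic)")
    fmt = None
    elements: list[tuple[str, int, list]] = []
    for i, raw in enumerate(lines[1:], start=2):
        tok = raw.strip().split()
        if not tok or tok[0] == "comment" or tok[0] == "obj_info":
            continue
        if tok[0] == "format":
            if len(tok) != 3 or tok[1] not in (
                "ascii", "binary_little_endian", "binary_big_endian"
            ):
                raise MeshIOError(f"line {i}: malformed format line {raw!r}")
            fmt = tok[1]
        elif tok[0] == "element":
            if len(tok) != 3:
                raise MeshIOError(f"line {i}: malformed element line {raw!r}")
            try:
                count = int(tok[2])
            except ValueError:
                raise MeshIOError(
                    f"line {i}: element count is not an integer: {raw!r}"
                ) from None
            elements.append((tok[1], count, []))
        elif tok[0] == "property":
            if not elements:
                raise MeshIOError(f"line {i}: property before any element")
            if tok[1] == "list":
                if len(tok) != 5:
                    raise MeshIOError(
                        f"line {i}: malformed list property {raw!r}"
                    )
                elements[-1][2].append(("list", tok[4]))
            else:
                if len(tok) != 3 or tok[1] not in _PLY_SCALARS:
                    raise MeshIOError(
                        f"line {i}: malformed property line {raw!r}"
                    )
                elements[-1][2].append(("scalar", tok[2]))
        elif tok[0] == "end_header":
            if fmt is None:
                raise MeshIOError(f"line {i}: end_header before format line")
            return fmt, elements, i
        else:
            raise MeshIOError(f"line {i}: unrecognized header keyword {tok[0]!r}")
    raise MeshIOError("header has no end_header line")


def _read_ply_ascii(text: str, path: str) -> TriMesh:
    lines = text.splitlines()
    fmt, elements, n_head = _parse_ply_header(lines)
    assert fmt == "ascii"
    body = [ln for ln in lines[n_head:] if ln.strip()]
    cursor = 0
    vertices = faces = None
    for name, count, props in elements:
        if len(body) - cursor < count:
            raise MeshIOError(
                f"{path}: element '{name}' declares {count} rows but only "
                f"{len(body) - cursor} remain after line {n_head + cursor}"
            )
        rows = body[cursor : cursor + count]
        cursor += count
        if name == "vertex":
            names = [p[1] for p in props if p[0] == "scalar"]
            try:
                ix, iy, iz = names.index("x"), names.index("y"), names.index("z")
            except ValueError:
                raise MeshIOError(
                    f"{path}: vertex element lacks x/y/z properties"
                ) from None
            try:
                arr = np.array(
                    [[float(t) for t in r.split()] for r in rows], dtype=float
                )
            except ValueError as e:
                raise MeshIOError(f"{path}: bad vertex row: {e}") from None
            if arr.ndim != 2 or arr.shape[1] < len(names):
                raise MeshIOError(f"{path}: vertex rows have too few columns")
            vertices = arr[:, [ix, iy, iz]]
        elif name == "face":
            out = []
            for r in rows:
                t = r.split()
                n = int(t[0])
                if n != 3:
                    raise MeshIOError(
                        f"{path}: face with {n} vertices; triangulate the mesh "
                        "upstream before loading"
                    )
                if len(t) < 4:
                    raise MeshIOError(f"{path}: truncated face row {r!r}")
                out.append([int(t[1]), int(t[2]), int(t[3])])
            faces = np.array(out, dtype=np.int64).reshape(-1, 3)
    if vertices is None:
        raise MeshIOError(f"{path}: no vertex element")
    if faces is None:
        faces = np.zeros((0, 3), dtype=np.int64)
    return TriMesh(vertices, faces, source_dialect="ply_ascii")


def _write_ply_ascii(mesh: TriMesh, path: Path) -> None:
    # full-precision repr so that read(write(m)) is bit-exact for coordinates
    with open(path, "w", encoding="ascii") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


# ---------------------------------------------------------------------------
# read / write
# ---------------------------------------------------------------------------


def _sniff_format(head: bytes, suffix: str, hint: str | None) -> str:
    if hint:
        return hint.lower()
    if head.startswith(b"ply"):
        return "ply"
    if suffix in (".ply", ".stl"):
        return suffix[1:]
    if head.startswith(b"solid"):
        return "stl"
    return "stl" if suffix == ".stl" else "ply"


def read_mesh(path, format_hint: str | None = None) -> TriMesh:
    """Read a PLY (ASCII or binary) or STL (ASCII or binary) mesh.

    Geometry is identical regardless of dialect (binary PLY stores float32, so
    coordinates agree within float32 representation error).  STL stores no
    connectivity, so duplicate vertices are welded within ``1e-8 x`` the
    bounding-box diagonal; patching and normals need shared vertices.
    """
    path = Path(path)
    if not path.exists():
        raise MeshIOError(f"mesh file not found: {path}")
    raw = path.read_bytes()
    fmt = _sniff_format(raw[:16], path.suffix.lower(), format_hint)
    if fmt == "ply":
        header_end = raw.find(b"end_header")
        if header_end < 0:
            raise MeshIOError(f"{path}: header has no end_header line")
        header_text = raw[: header_end + len(b"end_header")].decode(
            "ascii", errors="replace"
        )
        ply_fmt, elements, _ = _parse_ply_header(header_text.splitlines())
        if ply_fmt == "ascii":
            return _read_ply_ascii(raw.decode("ascii", errors="replace"), str(path))
        # binary: delegate body parsing to trimesh, then validate counts
        try:
            tm = _trimesh.load(
                _bytes_io(raw), file_type="ply", process=False
            )
        except Exception as e:  # trimesh raises a zoo of types
            raise MeshIOError(f"{path}: failed to parse binary PLY: {e}") from e
        declared = {name: count for name, count, _ in elements}
        if len(tm.vertices) != declared.get("vertex", len(tm.vertices)):
            raise MeshIOError(
                f"{path}: header declares {declared['vertex']} vertices but "
                f"{len(tm.vertices)} were read"
            )
        if "face" in declared and len(tm.faces) != declared["face"]:
            raise MeshIOError(
                f"{path}: header declares {declared['face']} faces but "
                f"{len(tm.faces)} triangles were read; non-triangular faces "
                "must be triangulated upstream"
            )
        dialect = "ply_" + ply_fmt
        return TriMesh(
            np.asarray(tm.vertices, dtype=float),
            np.asarray(tm.faces, dtype=np.int64),
            source_dialect=dialect,
        )
    if fmt == "stl":
        try:
            tm = _trimesh.load(_bytes_io(raw), file_type="stl", process=False)
        except Exception as e:
            raise MeshIOError(f"{path}: failed to parse STL: {e}") from e
        v = np.asarray(tm.vertices, dtype=float)
        f = np.asarray(tm.faces, dtype=np.int64)
        v, f = _weld(v, f)
        dialect = "stl_ascii" if raw.lstrip()[:5] == b"solid" and b"\x00" not in raw[:512] else "stl_binary"
        return TriMesh(v, f, source_dialect=dialect)
    raise MeshIOError(f"unsupported mesh format {fmt!r}")


def _bytes_io(raw: bytes):
    import io

    return io.BytesIO(raw)


def _weld(vertices: np.ndarray, faces: np.ndarray):
    """Merge vertices closer than 1e-8 x bbox diagonal (STL import)."""
    if len(vertices) == 0:
        return vertices, faces
    diag = np.linalg.norm(vertices.max(axis=0) - vertices.min(axis=0))
    tol = 1e-8 * diag
    if tol == 0:
        key = vertices
    else:
        key = np.round(vertices / tol)
    _, first, inverse = np.unique(
        key, axis=0, return_index=True, return_inverse=True
    )
    new_v = vertices[first]
    new_f = inverse[faces]
    keep = (
        (new_f[:, 0] != new_f[:, 1])
        & (new_f[:, 1] != new_f[:, 2])
        & (new_f[:, 0] != new_f[:, 2])
    )
    return new_v, new_f[keep]


def write_mesh(mesh: TriMesh, path, dialect: str = "ply_ascii") -> None:
    """Write ``mesh`` as ``ply_ascii``, ``ply_binary`` (little-endian) or ``stl``.

    ``ply_ascii`` writes full-precision float text, so a write/read round trip
    reproduces vertices and faces exactly.
    """
    path = Path(path)
    if dialect == "ply_ascii":
        _write_ply_ascii(mesh, path)
        return
    tm = _trimesh.Trimesh(
        vertices=mesh.vertices, faces=mesh.faces, process=False
    )
    if dialect == "ply_binary":
        data = _trimesh.exchange.ply.export_ply(
            tm, encoding="binary_little_endian"
        )
    elif dialect == "stl":
        data = _trimesh.exchange.stl.export_stl(tm)
    else:
        raise ValueError(
            f"unknown dialect {dialect!r}; use ply_ascii, ply_binary or stl"
        )
    path.write_bytes(data)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def center_mesh(mesh: TriMesh) -> TriMesh:
    """Translate so the vertex centroid sits at the origin.

    Idempotent; shape unchanged.
    """
    return mesh.with_vertices(mesh.vertices - mesh.centroid)


def nearest_point_on_mesh(mesh: TriMesh, query: np.ndarray):
    """Globally nearest surface point to ``query``.

    Returns ``(point, face_index, distance)``; for a (q, 3) array of queries,
    returns arrays.  Brute force over all faces (exact).
    """
    q = np.atleast_2d(np.asarray(query, dtype=float))
    if mesh.n_faces == 0:
        raise ValueError("mesh has no faces")
    pts, dist, tri = closest_point_naive(mesh._tm(), q)
    if np.ndim(query) == 1:
        return pts[0], int(tri[0]), float(dist[0])
    return pts, tri.astype(int), dist


def ray_mesh_intersections(
    mesh: TriMesh, origin: np.ndarray, direction: np.ndarray, eps: float = 1e-12
):
    """All intersections of the line through ``origin`` along ``direction``.

    Möller–Trumbore over every face.  Returns a list of
    ``(point, face_index, signed_distance, normal_sign)`` sorted by
    ``|signed_distance|``; ``signed_distance`` is positive along ``direction``
    and negative behind the origin.  ``normal_sign`` is the sign of
    ``face_normal . direction`` (−1 means the face opposes the ray, i.e. the
    ray hits its front side — the face-inversion diagnostic).
    """
    origin = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    nd = np.linalg.norm(d)
    if not np.isclose(nd, 1.0, atol=1e-6):
        raise ValueError("direction must be a unit vector")
    tri = mesh.vertices[mesh.faces]
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    p = np.cross(d[None, :], e2)
    det = np.einsum("ij,ij->i", e1, p)
    ok = np.abs(det) > eps
    inv = np.zeros_like(det)
    inv[ok] = 1.0 / det[ok]
    t_vec = origin[None, :] - v0
    u = np.einsum("ij,ij->i", t_vec, p) * inv
    q = np.cross(t_vec, e1)
    v = q @ d * inv
    t = np.einsum("ij,ij->i", e2, q) * inv
    bary_eps = 1e-10
    hit = ok & (u >= -bary_eps) & (v >= -bary_eps) & (u + v <= 1 + bary_eps)
    idx = np.nonzero(hit)[0]
    if idx.size == 0:
        return []
    ts = t[idx]
    order = np.argsort(np.abs(ts), kind="stable")
    results = []
    seen_t: list[float] = []
    scale = max(mesh.bbox_diagonal, 1.0)
    fn = mesh.face_normals
    for j in order:
        fi = int(idx[j])
        tj = float(ts[j])
        # drop duplicate hits where the line crosses a shared edge
        if any(abs(tj - s) < 1e-9 * scale for s in seen_t):
            continue
        seen_t.append(tj)
        point = origin + tj * d
        nsign = int(np.sign(fn[fi] @ d)) or 0
        results.append((point, fi, tj, nsign))
    return results


def extract_submesh(mesh: TriMesh, keep_faces) -> TriMesh:
    """Compact submesh of the faces selected by an index set or predicate.

    ``keep_faces`` may be a boolean mask, an integer index array, or a
    predicate called with the (m, 3, 3) face-coordinate array returning a
    mask.  The returned mesh carries ``original_faces`` mapping its faces back
    to indices in ``mesh`` — used to delete interfering surfaces (e.g. teeth)
    before patching and restore the full mesh for sliding.
    """
    if callable(keep_faces):
        mask = np.asarray(keep_faces(mesh.vertices[mesh.faces]), dtype=bool)
    else:
        arr = np.asarray(keep_faces)
        if arr.dtype == bool:
            mask = arr
        else:
            mask = np.zeros(mesh.n_faces, dtype=bool)
            mask[arr] = True
    if mask.shape != (mesh.n_faces,):
        raise ValueError("face selection has wrong length")
    if not mask.any():
        raise ValueError("empty face selection")
    face_idx = np.nonzero(mask)[0]
    old_faces = mesh.faces[face_idx]
    used = np.unique(old_faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    sub = TriMesh(
        mesh.vertices[used], remap[old_faces], fix_winding=False,
        orientable=mesh.orientable,
    )
    sub.original_faces = face_idx  # type: ignore[attr-defined]
    sub.original_vertices = used  # type: ignore[attr-defined]
    return sub
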