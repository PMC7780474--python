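"""Point configurations: the landmark / curve-point / surface-point data model.

A :class:`Configuration` is the ordered 3D point set digitized on one
specimen.  Every point carries a class — ``landmark`` (fixed, anatomically
homologous), ``curve`` (sliding semilandmark constrained to an outline
between two landmarks), or ``surface`` (semilandmark sliding in its tangent
plane) — plus a region, a side, and, for curve points, the curve it belongs
to and its ordinal position along that curve.

The canonical interchange format is a UTF-8 CSV with the exact header
``specimen,label,class,region,curve_id,ordinal,side,x,y,z``; a read-only
importer for Landmark-Editor-style ``.pts`` files is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "POINT_CLASSES",
    "SIDES",
    "Configuration",
    "CurveDefinition",
    "read_configurations",
    "write_configurations",
    "read_pts",
    "resample_curve",
    "resample_configuration_curves",
    "allocate_curve_points",
    "allocate_by_spacing",
    "drop_points",
]

POINT_CLASSES = ("landmark", "curve", "surface")
SIDES = ("left", "right", "midline", "none")

_COLUMNS = [
    "label", "class", "region", "curve_id", "ordinal", "side", "x", "y", "z",
]


@dataclass(frozen=True)
class CurveDefinition:
    """A semilandmark curve anchored by two fixed landmarks.

    ``n_points`` is the resampling budget counting both anchors; for a closed
    curve (a hole "fence") the start and end anchor coincide and the
    duplicate endpoint is stored once.
    """

    curve_id: str
    start_landmark: str
    end_landmark: str
    n_points: int = 2
    closed: bool = False

    def __post_init__(self):
        if not self.closed and self.n_points < 2:
            raise ValueError("open curves need n_points >= 2")


@dataclass
class Configuration:
    """Ordered, labeled 3D point set for one specimen.

    ``points`` is a DataFrame with columns label, class, region, curve_id,
    ordinal, side, x, y, z.  Point order (labels and classes) must be
    identical across all configurations entering a joint analysis.
    """

    specimen_id: str
    points: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.points.copy().reset_index(drop=True)
        for col in _COLUMNS:
            if col not in df.columns:
                if col in ("curve_id",):
                    df[col] = None
                elif col == "ordinal":
                    df[col] = np.nan
                elif col == "side":
                    df[col] = "none"
                elif col == "region":
                    df[col] = ""
                else:
                    raise ValueError(f"points table lacks column {col!r}")
        df = df[_COLUMNS]
        bad_class = ~df["class"].isin(POINT_CLASSES)
        if bad_class.any():
            raise ValueError(
                f"unknown point classes: {sorted(df.loc[bad_class, 'class'].unique())}"
            )
        if df["label"].duplicated().any():
            dup = df.loc[df["label"].duplicated(), "label"].tolist()
            raise ValueError(f"duplicate point labels: {dup}")
        is_curve = df["class"] == "curve"
        missing = is_curve & (df["curve_id"].isna() | df["ordinal"].isna())
        if missing.any():
            raise ValueError(
                "curve points lacking curve_id/ordinal: "
                f"{df.loc[missing, 'label'].tolist()}"
            )
        extra = ~is_curve & df["curve_id"].notna()
        if extra.any():
            raise ValueError(
                "non-curve points carry a curve_id: "
                f"{df.loc[extra, 'label'].tolist()}"
            )
        for cid, grp in df[is_curve].groupby("curve_id"):
            ords = np.sort(grp["ordinal"].astype(int).to_numpy())
            if not np.array_equal(ords, np.arange(len(ords))):
                raise ValueError(
                    f"curve {cid!r}: ordinals must be consecutive from 0, "
                    f"got {ords.tolist()}"
                )
        self.points = df

    # -- basic accessors ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.points)

    @property
    def labels(self) -> list[str]:
        return self.points["label"].tolist()

    @property
    def classes(self) -> np.ndarray:
        return self.points["class"].to_numpy()

    @property
    def coords(self) -> np.ndarray:
        """(k, 3) float coordinates in canonical point order."""
        return self.points[["x", "y", "z"]].to_numpy(dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Configuration":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self), 3):
            raise ValueError("coordinate array has wrong shape")
        df = self.points.copy()
        df[["x", "y", "z"]] = coords
        return Configuration(self.specimen_id, df)

    def with_id(self, specimen_id: str) -> "Configuration":
        return Configuration(specimen_id, self.points.copy())

    def centroid_size(self) -> float:
        """Root summed squared distances of points to their centroid."""
        x = self.coords
        return float(np.sqrt(((x - x.mean(axis=0)) ** 2).sum()))

    def index_of(self, labels) -> np.ndarray:
        lookup = {lab: i for i, lab in enumerate(self.labels)}
        try:
            return np.array([lookup[l] for l in labels], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown point label {e.args[0]!r}") from None

    def subset(self, labels) -> "Configuration":
        """Rows for ``labels`` in canonical (stored) order."""
        idx = np.sort(self.index_of(labels))
        return Configuration(self.specimen_id, self.points.iloc[idx])

    def curve_polyline(self, curve: CurveDefinition) -> np.ndarray:
        """Anchor-to-anchor polyline of a curve: start landmark, curve points
        in ordinal order, end landmark (start again if closed)."""
        df = self.points
        sel = df[(df["class"] == "curve") & (df["curve_id"] == curve.curve_id)]
        sel = sel.sort_values("ordinal")
        start = df[df["label"] == curve.start_landmark][["x", "y", "z"]].to_numpy()
        end = df[df["label"] == curve.end_landmark][["x", "y", "z"]].to_numpy()
        if len(start) != 1 or len(end) != 1:
            raise ValueError(
                f"curve {curve.curve_id!r}: anchors "
                f"{curve.start_landmark!r}/{curve.end_landmark!r} not found"
            )
        mid = sel[["x", "y", "z"]].to_numpy(dtype=float)
        return np.vstack([start, mid, end]).astype(float)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_HEADER = "specimen,label,class,region,curve_id,ordinal,side,x,y,z"


def read_configurations(path) -> list[Configuration]:
    """Read the canonical configuration CSV, one row per point per specimen.

    Specimens are grouped in file order; every specimen's point order (labels
    and classes) is validated against the first.
    """
    df = pd.read_csv(path, dtype={"specimen": str, "label": str,
                                  "curve_id": str, "region": str, "side": str})
    expected = _HEADER.split(",")
    if list(df.columns) != expected:
        raise ValueError(
            f"configuration table must have header {_HEADER!r}, "
            f"got {','.join(df.columns)!r}"
        )
    df["region"] = df["region"].fillna("")
    df["side"] = df["side"].fillna("none")
    configs = []
    reference: list[tuple[str, str]] | None = None
    for spec_id, grp in df.groupby("specimen", sort=False):
        cfg = Configuration(str(spec_id), grp.drop(columns=["specimen"]))
        key = list(zip(cfg.labels, cfg.classes))
        if reference is None:
            reference = key
        elif key != reference:
            a = {k[0] for k in reference}
            b = {k[0] for k in key}
            diff = sorted(a.symmetric_difference(b))
            raise ValueError(
                f"specimen {spec_id!r} has a different point set than "
                f"{configs[0].specimen_id!r}; label symmetric difference: {diff}"
                if diff else
                f"specimen {spec_id!r} has the same labels but different "
                "order or classes"
            )
        configs.append(cfg)
    if not configs:
        raise ValueError("configuration table is empty")
    return configs


def write_configurations(configs, path) -> None:
    frames = []
    for cfg in configs:
        df = cfg.points.copy()
        df.insert(0, "specimen", cfg.specimen_id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False)


def read_pts(path, point_class: str = "landmark", region: str = "") -> Configuration:
    """Read a Landmark-Editor-style ``.pts`` file: ``label x y z`` per line."""
    rows = []
    text = Path(path).read_text()
    for line in text.splitlines():
        tok = line.split()
        if not tok or tok[0].startswith("#"):
            continue
        if len(tok) != 4:
            raise ValueError(f"malformed .pts line: {line!r}")
        rows.append((tok[0], float(tok[1]), float(tok[2]), float(tok[3])))
    if not rows:
        raise ValueError(f"{path}: no points")
    df = pd.DataFrame(rows, columns=["label", "x", "y", "z"])
    df["class"] = point_class
    df["region"] = region
    return Configuration(Path(path).stem, df)


# ---------------------------------------------------------------------------
# Curve resampling
# ---------------------------------------------------------------------------


def resample_curve(polyline: np.ndarray, n: int, closed: bool = False) -> np.ndarray:
    """Resample a polyline to ``n`` points with equal chord-length spacing.

    Points lie exactly on the input polyline; the first and last output
    points coincide with the polyline endpoints (landmark anchors never
    move).  For ``closed=True`` the polyline is treated as a loop starting
    and ending at its first point, and ``n`` points are returned covering
    [0, L) — the duplicate endpoint is not repeated.
    """
    pl = np.asarray(polyline, dtype=float).reshape(-1, 3)
    if len(pl) < 2:
        raise ValueError("polyline needs at least 2 points")
    if closed and not np.allclose(pl[0], pl[-1]):
        pl = np.vstack([pl, pl[0]])
    seg = np.linalg.norm(np.diff(pl, axis=0), axis=1)
    length = seg.sum()
    if length == 0:
        raise ValueError("zero-length polyline")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if closed:
        targets = np.linspace(0.0, length, n, endpoint=False)
    else:
        if n < 2:
            raise ValueError("n must be >= 2 for open curves")
        targets = np.linspace(0.0, length, n)
    out = np.column_stack(
        [np.interp(targets, s, pl[:, c]) for c in range(3)]
    )
    if not closed:
        out[0], out[-1] = pl[0], pl[-1]
    return out


def resample_configuration_curves(
    config: Configuration, curves: list[CurveDefinition]
) -> Configuration:
    """Replace each curve's points by an even resampling of its polyline.

    The budget is each curve's ``n_points`` (counting anchors for open
    curves).  Point count per curve may change; labels are regenerated as
    ``{curve_id}_{ordinal}`` when counts change, otherwise kept.
    """
    df = config.points.copy()
    out_frames = []
    consumed = set()
    for curve in curves:
        pl = config.curve_polyline(curve)
        if curve.closed:
            # the start anchor is sample 0; everything after it is a curve
            # point, and the duplicate endpoint is stored once
            interior = resample_curve(pl, curve.n_points, closed=True)[1:]
        else:
            interior = resample_curve(pl, curve.n_points)[1:-1]
        old = df[(df["class"] == "curve") & (df["curve_id"] == curve.curve_id)]
        old = old.sort_values("ordinal")
        consumed.update(old.index)
        proto = old.iloc[0] if len(old) else None
        rows = []
        for i, xyz in enumerate(interior):
            if len(old) == len(interior):
                lab = old.iloc[i]["label"]
            else:
                lab = f"{curve.curve_id}_{i}"
            rows.append({
                "label": lab, "class": "curve",
                "region": proto["region"] if proto is not None else "",
                "curve_id": curve.curve_id, "ordinal": i,
                "side": proto["side"] if proto is not None else "none",
                "x": xyz[0], "y": xyz[1], "z": xyz[2],
            })
        out_frames.append(rows)
    # fixed points keep their order; resampled curves follow in curve order
    keep = df.drop(index=list(consumed))
    result = pd.concat(
        [keep] + [pd.DataFrame(rows) for rows in out_frames],
        ignore_index=True,
    )
    return Configuration(config.specimen_id, result)


def allocate_curve_points(
    curve_lengths,
    total_budget: int,
    min_per_curve: int = 5,
    max_per_curve: int = 30,
):
    """Split a point budget across curves proportionally to their lengths.

    Largest-remainder rounding; counts clipped to
    [``min_per_curve``, ``max_per_curve``] with clipped surplus
    re-distributed among unclipped curves.  The default cap of 30 follows
    the field guidance of limiting curves to roughly 20–30 points; the
    budget is conserved exactly whenever the caps make it feasible.
    """
    lengths = np.asarray(curve_lengths, dtype=float)
    if (lengths < 0).any() or lengths.sum() == 0:
        raise ValueError("curve lengths must be non-negative with positive sum")
    m = len(lengths)
    if total_budget < m * min_per_curve:
        raise ValueError(
            f"budget {total_budget} below the minimum {m * min_per_curve} "
            f"({m} curves x {min_per_curve})"
        )
    counts = np.full(m, -1, dtype=int)  # -1 = not yet fixed
    free = np.ones(m, dtype=bool)
    budget = total_budget
    while True:
        quota = lengths[free] / lengths[free].sum() * budget
        lo = quota < min_per_curve
        hi = quota > max_per_curve
        if not lo.any() and not hi.any():
            break
        free_idx = np.nonzero(free)[0]
        counts[free_idx[lo]] = min_per_curve
        counts[free_idx[hi]] = max_per_curve
        free[free_idx[lo]] = False
        free[free_idx[hi]] = False
        budget = total_budget - counts[~free].sum()
        if not free.any():
            return counts.tolist()
        if budget < free.sum() * min_per_curve:
            counts[free] = min_per_curve
            return counts.tolist()
    quota = lengths[free] / lengths[free].sum() * budget
    base = np.floor(quota).astype(int)
    rem = quota - base
    short = budget - base.sum()
    order = np.argsort(-rem, kind="stable")
    base[order[:short]] += 1
    counts[free] = np.clip(base, min_per_curve, max_per_curve)
    return counts.tolist()


def allocate_by_spacing(curve_lengths, spacing: float,
                        min_per_curve: int = 5, max_per_curve: int = 30):
    """Point counts giving approximately ``spacing`` between curve points.

    Implements the guidance that curve-point density should match
    surface-point density; ``spacing`` would typically be the template's
    surface-point spacing.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    lengths = np.asarray(curve_lengths, dtype=float)
    counts = np.rint(lengths / spacing).astype(int) + 1
    return np.clip(counts, min_per_curve, max_per_curve).tolist()


def drop_points(config: Configuration, labels_or_predicate) -> Configuration:
    """Remove points by label list or by predicate on the point rows.

    Order of surviving points is preserved.  This is the workhorse for
    removing non-comparable landmarks and curves before joint alignment
    (negligible regions, negligible holes, multi-template workflows).
    """
    df = config.points
    if callable(labels_or_predicate):
        mask = df.apply(labels_or_predicate, axis=1).to_numpy(dtype=bool)
    else:
        labels = list(labels_or_predicate)
        unknown = sorted(set(labels) - set(config.labels))
        if unknown:
            raise KeyError(f"unknown point labels: {unknown}")
        mask = df["label"].isin(labels).to_numpy()
    survivors = df[~mask]
    if len(survivors) == 0:
        raise ValueError("drop would leave an empty configuration")
    return Configuration(config.specimen_id, survivors)


def read_curves(path) -> list[CurveDefinition]:
    """Read curve definitions from CSV: curve_id,start_landmark,end_landmark,
    n_points,closed."""
    df = pd.read_csv(path, dtype={"curve_id": str})
    needed = ["curve_id", "start_landmark", "end_landmark", "n_points", "closed"]
    if list(df.columns) != needed:
        raise ValueError(f"curves table must have columns {needed}")
    out = []
    for row in df.itertuples(index=False):
        out.append(CurveDefinition(
            str(row.curve_id), str(row.start_landmark), str(row.end_landmark),
            int(row.n_points), bool(row.closed),
        ))
    return out


def write_curves(curves: list[CurveDefinition], path) -> None:
    pd.DataFrame([{
        "curve_id": c.curve_id, "start_landmark": c.start_landmark,
        "end_landmark": c.end_landmark, "n_points": c.n_points,
        "closed": c.closed,
    } for c in curves]).to_csv(path, index=False)
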