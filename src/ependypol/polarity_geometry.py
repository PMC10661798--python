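"""Per-cell polarity measurements for multiciliated epithelia.

Quantifies the polarity of the basal-body (BB) patch of each cell in an
epithelial sheet, the way ependymal planar-cell-polarity studies do:

* translational polarity — the displacement of the BB patch centroid (BC)
  from the cell centroid (C), reported as the translational distance TD
  (and TD normalized by the cell's equivalent radius) and the BB patch
  angle TA (direction of C -> BC);
* patch orientation — the Feret (longest-caliper) diameter LD of the BB
  point set and its axial Feret angle FA in [0, 180);
* rotational polarity — vectors from each basal-foot marker point to its
  nearest basal-body point, whose common direction reports the beat
  orientation of the cilia.

Angle convention: angles are measured counterclockwise from the +x axis
in a y-up frame.  Image coordinates have y pointing down, so directions
are computed as ``atan2(-dy_image, dx)``; the same convention is used for
TA, FA, rotational vectors and flow directions throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull
from scipy.spatial.distance import cdist
from shapely.geometry import Polygon

from .circular_stats import AngleSample, circular_mean_R, rayleigh_test

__all__ = [
    "CellRecord",
    "BasalBodyPatch",
    "PolarityMeasurement",
    "RotationalVector",
    "GeometryError",
    "polygon_centroid",
    "translational_distance",
    "bb_patch_angle",
    "ferets_angle",
    "measure_patch",
    "rotational_vectors",
    "cells_from_label_image",
    "measure_cells",
    "summarize_cells",
]


class GeometryError(ValueError):
    """Raised for degenerate geometric input (zero-area polygon, <2 points)."""


def direction_deg(dx: float | np.ndarray, dy_image: float | np.ndarray):
    """Direction of an image-coordinate displacement, in degrees [0, 360).

    Counterclockwise from +x in a y-up frame: the image y axis points
    down, so dy is negated before atan2.
    """
    return np.mod(np.rad2deg(np.arctan2(-np.asarray(dy_image),
                                        np.asarray(dx))), 360.0)


@dataclass(frozen=True)
class CellRecord:
    cell_id: int
    boundary: np.ndarray        # (k, 2) closed polygon vertices, pixel coords
    centroid: tuple[float, float]
    area: float
    equivalent_radius: float    # radius of the equal-area circle
    touches_border: bool = False


@dataclass(frozen=True)
class BasalBodyPatch:
    cell_id: int
    points: np.ndarray          # (n, 2) basal-body coordinates
    centroid: tuple[float, float]
    longest_diameter: float
    feret_angle: float          # degrees in [0, 180); NaN when LD == 0


@dataclass(frozen=True)
class PolarityMeasurement:
    cell_id: int
    td: float
    td_norm: float
    ta: float                   # NaN when TD == 0 (undefined direction)


@dataclass(frozen=True)
class RotationalVector:
    foot_point: tuple[float, float]
    bb_point: tuple[float, float]
    angle: float                # direction foot -> bb, degrees [0, 360)
    length: float
    cell_id: int | None = None


# ---------------------------------------------------------------------------
# elementary measurements
# ---------------------------------------------------------------------------

def polygon_centroid(boundary: np.ndarray) -> tuple[float, float]:
    """Area-weighted centroid of a simple closed polygon (shoelace formula).

    The result does not depend on vertex orientation or starting vertex.
    """
    poly = Polygon(np.asarray(boundary, dtype=float))
    if not poly.is_valid or poly.area <= 0:
        raise GeometryError("degenerate polygon (zero area or self-intersecting)")
    c = poly.centroid
    return float(c.x), float(c.y)


def translational_distance(c: tuple[float, float],
                           bc: tuple[float, float]) -> float:
    """Euclidean distance between cell centroid C and BB patch centroid BC."""
    c = np.asarray(c, dtype=float)
    bc = np.asarray(bc, dtype=float)
    if not (np.all(np.isfinite(c)) and np.all(np.isfinite(bc))):
        raise GeometryError("non-finite centroid coordinates")
    return float(np.linalg.norm(bc - c))


def bb_patch_angle(c: tuple[float, float],
                   bc: tuple[float, float]) -> float:
    """BB patch angle TA: direction of the vector C -> BC, degrees [0, 360).

    Returns NaN (undefined, not an error) when C == BC.
    """
    dx = bc[0] - c[0]
    dy = bc[1] - c[1]
    if dx == 0.0 and dy == 0.0:
        return float("nan")
    return float(direction_deg(dx, dy))


def ferets_angle(points: np.ndarray) -> tuple[float, float]:
    """Longest (Feret) diameter LD and its axial angle FA of a point set.

    LD is the maximum pairwise distance, computed over convex-hull
    vertices; FA is the direction of a maximizing pair folded into
    [0, 180).  When several pairs attain LD (within 1e-9 relative), the
    smallest FA is reported so the output is deterministic.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise GeometryError("Feret diameter needs >= 2 distinct points")
    if pts.shape[0] > 3:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except Exception:
            pass  # collinear sets: fall through to all-pairs on raw points
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    ld = float(d.max())
    ii, jj = np.nonzero(d >= ld * (1.0 - 1e-9))
    angles = direction_deg(diff[ii, jj, 0], diff[ii, jj, 1]) % 180.0
    # fold near-180 roundoff back to 0 before taking the minimum
    angles = np.where(angles > 180.0 - 1e-9, 0.0, angles)
    return ld, float(angles.min())


def measure_patch(cell_id: int, points: np.ndarray) -> BasalBodyPatch:
    """Summarize a cell's basal-body point set.

    The patch centroid is the unweighted mean of the BB points.  A
    single-point patch has LD = 0 and an undefined (NaN) Feret angle.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 1:
        raise GeometryError("patch needs >= 1 basal body")
    bc = (float(pts[:, 0].mean()), float(pts[:, 1].mean()))
    if np.unique(pts, axis=0).shape[0] < 2:
        return BasalBodyPatch(cell_id, pts, bc, 0.0, float("nan"))
    ld, fa = ferets_angle(pts)
    return BasalBodyPatch(cell_id, pts, bc, ld, fa)


# ---------------------------------------------------------------------------
# rotational polarity
# ---------------------------------------------------------------------------

def rotational_vectors(
    foot_points: np.ndarray,
    bb_points: np.ndarray,
    max_gate: float | None = None,
    cell_ids=None,
) -> tuple[list[RotationalVector], list[int]]:
    """Pair each basal-foot point with its nearest basal-body point.

    Pairing is one-to-one and greedy by ascending distance, gated at
    ``max_gate`` (default: twice the median foot-to-nearest-bb spacing)
    to stop many feet collapsing onto one basal body.  Distance ties are
    broken by lower point index.  Returns the vectors plus the indices of
    feet left unmatched by the gate or by exhaustion of basal bodies.
    """
    feet = np.asarray(foot_points, dtype=float).reshape(-1, 2)
    bbs = np.asarray(bb_points, dtype=float).reshape(-1, 2)
    if feet.shape[0] == 0 or bbs.shape[0] == 0:
        raise ValueError("foot_points and bb_points must be nonempty")
    d = cdist(feet, bbs)
    if max_gate is None:
        max_gate = 2.0 * float(np.median(d.min(axis=1)))
    if max_gate <= 0:
        raise ValueError("max_gate must be > 0")

    fi, bi = np.nonzero(d <= max_gate)
    order = np.lexsort((bi, fi, d[fi, bi]))  # distance, then index tie-break
    foot_used = np.zeros(feet.shape[0], dtype=bool)
    bb_used = np.zeros(bbs.shape[0], dtype=bool)
    vectors: list[RotationalVector] = []
    for k in order:
        f, b = fi[k], bi[k]
        if foot_used[f] or bb_used[b]:
            continue
        foot_used[f] = bb_used[b] = True
        dx = bbs[b, 0] - feet[f, 0]
        dy = bbs[b, 1] - feet[f, 1]
        length = float(np.hypot(dx, dy))
        if length == 0.0:
            continue  # coincident points carry no direction
        vectors.append(RotationalVector(
            foot_point=(float(feet[f, 0]), float(feet[f, 1])),
            bb_point=(float(bbs[b, 0]), float(bbs[b, 1])),
            angle=float(direction_deg(dx, dy)),
            length=length,
            cell_id=None if cell_ids is None else int(cell_ids[f]),
        ))
    unmatched = np.flatnonzero(~foot_used).tolist()
    return vectors, unmatched


# ---------------------------------------------------------------------------
# whole-image measurement
# ---------------------------------------------------------------------------

def cells_from_label_image(labels: np.ndarray) -> list[CellRecord]:
    """Extract CellRecords from an integer label image (background 0).

    Cell boundaries are traced with marching squares on each cell's mask;
    centroid/area come from the label-region pixel statistics, which is
    what matters for TD (the traced polygon is kept for plotting and
    containment checks).  Cells touching the image border are flagged.
    """
    from skimage import measure

    labels = np.asarray(labels)
    records: list[CellRecord] = []
    h, w = labels.shape
    for region in measure.regionprops(labels):
        cy, cx = region.centroid
        area = float(region.area)
        minr, minc, maxr, maxc = region.bbox
        touches = minr == 0 or minc == 0 or maxr == h or maxc == w
        mask = np.pad(region.image, 1)
        contours = measure.find_contours(mask.astype(float), 0.5)
        boundary = np.empty((0, 2))
        if contours:
            c = max(contours, key=len)
            # (row, col) in padded-mask frame -> (x, y) in image frame
            boundary = np.column_stack([c[:, 1] - 1 + minc,
                                        c[:, 0] - 1 + minr])
        records.append(CellRecord(
            cell_id=int(region.label), boundary=boundary,
            centroid=(float(cx), float(cy)), area=area,
            equivalent_radius=float(np.sqrt(area / np.pi)),
            touches_border=bool(touches)))
    return records


def measure_cells(cells: list[CellRecord],
                  bb_table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell polarity measurements from cells and a BB point table.

    ``bb_table`` needs columns ``cell_id, x, y``.  Returns a DataFrame
    with columns ``cell_id, TD, TD_norm, TA, FA, LD, n_bb,
    touches_border``; cells without basal bodies are omitted.
    """
    rows = []
    by_cell = dict(tuple(bb_table.groupby("cell_id")))
    for cell in cells:
        grp = by_cell.get(cell.cell_id)
        if grp is None or len(grp) == 0:
            continue
        patch = measure_patch(cell.cell_id, grp[["x", "y"]].to_numpy())
        td = translational_distance(cell.centroid, patch.centroid)
        ta = bb_patch_angle(cell.centroid, patch.centroid)
        rows.append({
            "cell_id": cell.cell_id,
            "TD": td,
            "TD_norm": td / cell.equivalent_radius,
            "TA": ta,
            "FA": patch.feret_angle,
            "LD": patch.longest_diameter,
            "n_bb": patch.points.shape[0],
            "touches_border": cell.touches_border,
        })
    return pd.DataFrame(rows)


def summarize_cells(measurements: pd.DataFrame,
                    group_col: str = "group",
                    exclude_border: bool = True) -> dict:
    """Group-level summary of polarity measurements.

    For each group: n, mean +/- SEM of TD and TD_norm, circular mean and
    resultant length of TA (directional) and FA (axial), and the Rayleigh
    uniformity p for TA.  With exactly two groups, a two-tailed t-test on
    TD is reported (t, df, p).  Border-touching cells are excluded by
    default because their polygons are truncated.
    """
    df = measurements
    if exclude_border and "touches_border" in df.columns:
        df = df[~df["touches_border"]]
    if group_col not in df.columns:
        df = df.assign(**{group_col: "all"})

    summary: dict = {"groups": {}, "t_test": None}
    for name, grp in df.groupby(group_col):
        entry: dict = {"n": int(len(grp))}
        if len(grp) < 2:
            entry["statistics_available"] = False
            summary["groups"][str(name)] = entry
            continue
        entry["statistics_available"] = True
        for col in ("TD", "TD_norm"):
            vals = grp[col].to_numpy()
            entry[f"{col}_mean"] = float(np.mean(vals))
            entry[f"{col}_sem"] = float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
        ta = grp["TA"].dropna().to_numpy()
        if ta.size >= 1:
            s = AngleSample(str(name), ta, period=360)
            mean, R = circular_mean_R(s)
            entry["TA_circ_mean"] = mean
            entry["TA_R"] = R
            if ta.size >= 5:
                entry["TA_rayleigh_p"] = rayleigh_test(s).p_value
        fa = grp["FA"].dropna().to_numpy()
        if fa.size >= 1:
            mean, R = circular_mean_R(AngleSample(str(name), fa, period=180))
            entry["FA_circ_mean"] = mean
            entry["FA_R"] = R
        summary["groups"][str(name)] = entry

    usable = [g for g, e in summary["groups"].items()
              if e.get("statistics_available")]
    if len(usable) == 2:
        g1, g2 = usable
        x = df[df[group_col].astype(str) == g1]["TD"].to_numpy()
        y = df[df[group_col].astype(str) == g2]["TD"].to_numpy()
        t, p = stats.ttest_ind(x, y)
        summary["t_test"] = {
            "groups": (g1, g2), "t": float(t),
            "df": int(len(x) + len(y) - 2), "p": float(p)}
    elif len(usable) > 2:
        warnings.warn("more than two groups: pairwise t-test not reported",
                      stacklevel=2)
    return summary
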