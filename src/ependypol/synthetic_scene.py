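"""Ground-truthed synthetic epithelium and near-wall flow generator.

Emulates the two kinds of raw data the polarity/flow analyses consume,
with every sampled quantity recorded as ground truth:

* an epithelial mosaic — a Voronoi tessellation of Poisson-disk seeds
  (one Lloyd relaxation step) in which each cell carries a basal-body
  patch whose centroid offset direction, elongation axis, and per-basal-
  body basal-foot direction are drawn from von Mises distributions
  around a global polarity direction ``mu_global``.  High concentration
  kappa emulates the coordinated wild-type-like tissue; kappa = 0 gives
  the uniformly random mutant-like tissue.
* a microsphere flow video — Gaussian spots advected by either a
  coherent unidirectional field (wild-type-like) or a smooth spatially
  varying vortex field spanning all directions (mutant-like, turbulent),
  plus Brownian jitter.

Point tables are the authoritative representation; label images and
frame stacks are derived rasterizations.  A single integer seed expands
into independent per-component substreams, so adding one component never
perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely import STRtree
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import nearest_points, voronoi_diagram

from .polarity_geometry import direction_deg

__all__ = [
    "SceneConfig",
    "FlowConfig",
    "GroundTruth",
    "sample_von_mises",
    "sample_axial_von_mises",
    "generate_mosaic",
    "generate_flow_video",
]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic epithelium.

    Angles are degrees; kappa values are von Mises concentrations
    (kappa = 0 means circular uniform).  ``offset_frac`` places each
    cell's patch centroid at C + offset_frac * R_eq in a direction drawn
    from vonMises(mu_global, kappa_trans).
    """

    n_cells: int = 200
    domain_size: tuple[int, int] = (512, 512)  # (width, height) px
    mu_global: float = 40.0
    kappa_trans: float = 8.0
    kappa_rot: float = 8.0
    kappa_feret: float = 8.0
    offset_frac: float = 0.35
    bb_per_patch: int = 10
    foot_offset_px: float = 1.2
    # basal bodies keep at least this spacing inside the patch; it must
    # comfortably exceed foot_offset_px or "nearest basal body" becomes
    # ambiguous between a parent and a neighboring basal body
    bb_min_separation: float = 3.0
    seed: int = 0
    # ellipse semi-axes of the BB scatter as fractions of R_eq
    patch_major_frac: float = 0.40
    patch_minor_frac: float = 0.20

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        if min(self.kappa_trans, self.kappa_rot, self.kappa_feret) < 0:
            raise ValueError("kappa values must be >= 0")
        if not 0 <= self.offset_frac < 1:
            raise ValueError("offset_frac must be in [0, 1)")
        if self.bb_per_patch < 1:
            raise ValueError("bb_per_patch must be positive")
        if self.foot_offset_px <= 0:
            raise ValueError("foot_offset_px must be positive")

    @classmethod
    def wildtype(cls, seed: int = 0, **kw) -> "SceneConfig":
        """Coordinated tissue: patches displaced toward mu_global with
        tightly aligned feet and elongation axes."""
        return cls(seed=seed, **kw)

    @classmethod
    def mutant(cls, seed: int = 0, **kw) -> "SceneConfig":
        """Disorganized tissue: nearly centered patches, all angular
        structure uniform (kappa = 0)."""
        kw.setdefault("offset_frac", 0.10)
        kw.setdefault("kappa_trans", 0.0)
        kw.setdefault("kappa_rot", 0.0)
        kw.setdefault("kappa_feret", 0.0)
        return cls(seed=seed, **kw)


@dataclass(frozen=True)
class FlowConfig:
    """Parameters of the microsphere flow simulation."""

    regime: str = "coherent"            # "coherent" | "disorganized"
    mean_direction: float = 45.0        # degrees; used by coherent regime
    speed_px_per_frame: float = 2.0
    diffusion_px: float = 0.5
    n_particles: int = 100
    n_frames: int = 50
    seed: int = 0
    frame_size: tuple[int, int] = (256, 256)  # (width, height)
    spot_sigma: float = 1.5
    min_separation: float = 10.0        # initial spacing between particles

    def __post_init__(self):
        if self.regime not in ("coherent", "disorganized"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.n_particles < 1 or self.n_frames < 1:
            raise ValueError("n_particles and n_frames must be positive")
        if self.speed_px_per_frame <= 0:
            raise ValueError("speed_px_per_frame must be positive")
        if self.diffusion_px < 0:
            raise ValueError("diffusion_px must be >= 0")


@dataclass
class GroundTruth:
    """Sampled truth for every generated entity.

    ``cells`` — one row per cell: centroid, R_eq, true patch-offset
    direction and TD, true Feret axis, clipping flag.
    ``feet`` — one row per basal body: true basal-foot direction.
    ``particles`` — per-frame true particle positions.
    ``directions`` — per-particle true net movement direction.
    """

    cells: pd.DataFrame | None = None
    feet: pd.DataFrame | None = None
    particles: pd.DataFrame | None = None
    directions: pd.DataFrame | None = None
    config: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# circular sampling
# ---------------------------------------------------------------------------

def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def sample_von_mises(mu: float, kappa: float, n: int, seed=None) -> np.ndarray:
    """n draws from vonMises(mu, kappa), in degrees [0, 360).

    kappa = 0 gives the circular uniform distribution.  The same
    (mu, kappa, n, seed) always reproduces the same draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    rng = _rng(seed)
    if kappa == 0:
        return rng.uniform(0.0, 360.0, size=n)
    draws = rng.vonmises(np.deg2rad(mu), kappa, size=n)
    return np.mod(np.rad2deg(draws), 360.0)


def sample_axial_von_mises(mu: float, kappa: float, n: int,
                           seed=None) -> np.ndarray:
    """Axial von Mises draws in degrees [0, 180).

    Standard axial construction: draw on the doubled circle around
    2*mu, then halve.
    """
    doubled = sample_von_mises(2.0 * mu, kappa, n, seed)
    return np.mod(doubled / 2.0, 180.0)


def _unit_image(theta_deg):
    """Unit vector of a y-up angle expressed in image (y-down) coordinates."""
    t = np.deg2rad(np.asarray(theta_deg, dtype=float))
    return np.stack([np.cos(t), -np.sin(t)], axis=-1)


# ---------------------------------------------------------------------------
# epithelial mosaic
# ---------------------------------------------------------------------------

def _poisson_disk(n: int, width: float, height: float,
                  rng: np.random.Generator) -> np.ndarray:
    """n seed points with a blue-noise minimum spacing, by dart throwing.

    The target spacing starts near the hexagonal-packing value and is
    relaxed geometrically if the darts cannot fit, so the request always
    succeeds for any density the domain can hold.
    """
    r_min = 0.7 * np.sqrt(width * height / n)
    for _ in range(12):
        accepted: list[np.ndarray] = []
        misses = 0
        while len(accepted) < n and misses < 300 * n:
            p = rng.uniform([0, 0], [width, height])
            if accepted:
                d = np.linalg.norm(np.asarray(accepted) - p, axis=1)
                if d.min() < r_min:
                    misses += 1
                    continue
            accepted.append(p)
        if len(accepted) == n:
            return np.asarray(accepted)
        r_min *= 0.8
    raise ValueError(
        f"could not place {n} Poisson-disk seeds in a "
        f"{width}x{height} domain")


def _rasterize_labels(seeds: np.ndarray, width: int, height: int) -> np.ndarray:
    """Nearest-seed pixel assignment = rasterized Voronoi partition.

    Every pixel belongs to exactly one cell, labels 1..n (uint16)."""
    # pixel centers sit at integer coordinates (skimage convention)
    yy, xx = np.mgrid[0:height, 0:width]
    pix = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    _, idx = cKDTree(seeds).query(pix)
    return (idx.reshape(height, width) + 1).astype(np.uint16)


def _lloyd_step(seeds: np.ndarray, width: int, height: int) -> np.ndarray:
    """One Lloyd relaxation: move each seed to the pixel-mass centroid of
    its Voronoi cell."""
    labels = _rasterize_labels(seeds, width, height)
    flat = labels.ravel() - 1
    yy, xx = np.mgrid[0:height, 0:width]
    counts = np.bincount(flat, minlength=len(seeds)).astype(float)
    sx = np.bincount(flat, weights=xx.ravel().astype(float),
                     minlength=len(seeds))
    sy = np.bincount(flat, weights=yy.ravel().astype(float),
                     minlength=len(seeds))
    out = seeds.copy()
    nonzero = counts > 0
    out[nonzero] = np.column_stack([sx[nonzero] / counts[nonzero],
                                    sy[nonzero] / counts[nonzero]])
    return out


def _voronoi_polygons(seeds: np.ndarray, width: float, height: float) -> list:
    """Shapely Voronoi cells clipped to the domain box, ordered by seed."""
    domain = box(0, 0, width, height)
    cells = voronoi_diagram(MultiPoint(seeds.tolist()), envelope=domain)
    polys = [g.intersection(domain) for g in cells.geoms]
    tree = STRtree(polys)
    ordered = []
    for s in seeds:
        pt = Point(s)
        hit = None
        for j in tree.query(pt):
            if polys[j].distance(pt) < 1e-9:
                hit = polys[j]
                break
        if hit is None:  # numeric edge case: take nearest polygon
            hit = min(polys, key=lambda g: g.distance(pt))
        ordered.append(hit)
    return ordered


_MAX_PATCH_RETRIES = 8


def _scatter_in_ellipse(center, major, minor, axis_deg, n, min_sep,
                        rng: np.random.Generator) -> np.ndarray:
    """Blue-noise scatter inside an ellipse elongated along axis_deg.

    Points keep a minimum spacing (relaxed geometrically if the ellipse
    is too small for it) so each basal body stays resolvable from its
    neighbors' basal feet.  The empirical centroid is recentred exactly
    onto ``center`` so patch centroids carry no sampling offset."""
    e1 = _unit_image(axis_deg)
    e2 = np.array([-e1[1], e1[0]])
    sep = min_sep
    pts = None
    for _ in range(10):
        accepted: list[np.ndarray] = []
        misses = 0
        while len(accepted) < n and misses < 100 * n:
            r = np.sqrt(rng.uniform())
            alpha = rng.uniform(0, 2 * np.pi)
            p = (major * r * np.cos(alpha)) * e1 \
                + (minor * r * np.sin(alpha)) * e2
            if accepted and np.linalg.norm(
                    np.asarray(accepted) - p, axis=1).min() < sep:
                misses += 1
                continue
            accepted.append(p)
        if len(accepted) == n:
            pts = np.asarray(accepted)
            break
        sep *= 0.75
    if pts is None:  # ellipse far too small: fall back to plain uniform
        r = np.sqrt(rng.uniform(size=n))
        alpha = rng.uniform(0, 2 * np.pi, size=n)
        pts = (major * r * np.cos(alpha))[:, None] * e1[None, :] \
            + (minor * r * np.sin(alpha))[:, None] * e2[None, :]
    pts = pts - pts.mean(axis=0)
    return np.asarray(center) + pts


def generate_mosaic(config: SceneConfig):
    """Generate a labeled epithelial mosaic with BB and basal-foot points.

    Returns
    -------
    (label_image, bb_table, foot_table, truth)
        ``label_image`` — uint16, cells 1..n tiling the domain;
        ``bb_table`` / ``foot_table`` — DataFrames with columns
        ``cell_id, x, y, kind``; ``truth`` — a :class:`GroundTruth`.

    Patch ellipses that cannot be placed inside their cell after a
    bounded number of scatter retries (with geometric shrinking) are
    clipped to the cell polygon and flagged in the ground truth.
    """
    width, height = config.domain_size
    root = np.random.SeedSequence(config.seed)
    rng_place, rng_psi, rng_feret, rng_scatter, rng_rot = \
        (np.random.default_rng(s) for s in root.spawn(5))

    seeds = _poisson_disk(config.n_cells, width, height, rng_place)
    seeds = _lloyd_step(seeds, width, height)
    labels = _rasterize_labels(seeds, width, height)
    polys = _voronoi_polygons(seeds, width, height)

    n = config.n_cells
    psi = sample_von_mises(config.mu_global, config.kappa_trans, n, rng_psi)
    feret_axis = sample_axial_von_mises(
        config.mu_global, config.kappa_feret, n, rng_feret)

    cell_rows, bb_rows, foot_rows, foot_truth_rows = [], [], [], []
    for i, poly in enumerate(polys):
        cell_id = i + 1
        cx, cy = poly.centroid.x, poly.centroid.y
        r_eq = np.sqrt(poly.area / np.pi)
        td_true = config.offset_frac * r_eq
        patch_center = np.array([cx, cy]) + td_true * _unit_image(psi[i])

        inner = poly.buffer(-0.5)  # half-pixel margin for rasterization
        if inner.is_empty:
            inner = poly
        major = config.patch_major_frac * r_eq
        minor = config.patch_minor_frac * r_eq
        clipped = False
        pts = None
        for attempt in range(_MAX_PATCH_RETRIES):
            shrink = 0.85 ** attempt
            cand = _scatter_in_ellipse(
                patch_center, major * shrink, minor * shrink,
                feret_axis[i], config.bb_per_patch,
                config.bb_min_separation * shrink, rng_scatter)
            if all(inner.covers(Point(p)) for p in cand):
                pts = cand
                break
        if pts is None:
            cand = _scatter_in_ellipse(
                patch_center, major, minor, feret_axis[i],
                config.bb_per_patch, config.bb_min_separation, rng_scatter)
            pts = np.array([
                p if inner.covers(Point(p))
                else np.asarray(nearest_points(inner, Point(p))[0].coords[0])
                for p in cand])
            clipped = True

        foot_angles = sample_von_mises(
            config.mu_global, config.kappa_rot, config.bb_per_patch, rng_rot)
        feet = pts - config.foot_offset_px * _unit_image(foot_angles)

        touches = poly.exterior.distance(box(0, 0, width, height).exterior) \
            < 1e-9 if not poly.is_empty else True
        cell_rows.append({
            "cell_id": cell_id, "cx": cx, "cy": cy, "r_eq": r_eq,
            "psi_true": psi[i], "td_true": td_true,
            "td_norm_true": config.offset_frac,
            "feret_axis_true": feret_axis[i],
            "clipped": clipped, "touches_border": bool(touches)})
        for j in range(config.bb_per_patch):
            bb_rows.append({"cell_id": cell_id, "x": pts[j, 0],
                            "y": pts[j, 1], "kind": "bb"})
            foot_rows.append({"cell_id": cell_id, "x": feet[j, 0],
                              "y": feet[j, 1], "kind": "foot"})
            foot_truth_rows.append({"cell_id": cell_id, "bb_index": j,
                                    "foot_angle_true": foot_angles[j]})

    truth = GroundTruth(
        cells=pd.DataFrame(cell_rows),
        feet=pd.DataFrame(foot_truth_rows),
        config=asdict(config))
    return labels, pd.DataFrame(bb_rows), pd.DataFrame(foot_rows), truth


# ---------------------------------------------------------------------------
# microsphere flow video
# ---------------------------------------------------------------------------

def _field_direction(pos: np.ndarray, config: FlowConfig) -> np.ndarray:
    """Direction (degrees) of the flow field at each position.

    Coherent: a single global direction.  Disorganized: a smooth vortex
    around the frame center whose tangential directions span the full
    circle — a stand-in for turbulent near-wall flow.
    """
    if config.regime == "coherent":
        return np.full(pos.shape[0], config.mean_direction, dtype=float)
    w, h = config.frame_size
    center = np.array([w / 2.0, h / 2.0])
    rel = pos - center
    radial = direction_deg(rel[:, 0], rel[:, 1])
    return np.mod(radial + 90.0, 360.0)


def _render_frame(pos: np.ndarray, config: FlowConfig) -> np.ndarray:
    w, h = config.frame_size
    frame = np.zeros((h, w), dtype=np.float64)
    s = config.spot_sigma
    half = int(np.ceil(4 * s))
    for x, y in pos:
        x0, y0 = int(round(x)), int(round(y))
        xs = np.arange(max(0, x0 - half), min(w, x0 + half + 1))
        ys = np.arange(max(0, y0 - half), min(h, y0 + half + 1))
        if xs.size == 0 or ys.size == 0:
            continue
        gx = np.exp(-0.5 * ((xs - x) / s) ** 2)
        gy = np.exp(-0.5 * ((ys - y) / s) ** 2)
        frame[np.ix_(ys, xs)] += gy[:, None] * gx[None, :]
    return (np.clip(frame, 0, 6.5535) * 10000).astype(np.uint16)


def generate_flow_video(config: FlowConfig):
    """Simulate microsphere motion and render it as a frame stack.

    Particles advance each frame by ``speed * field_direction`` plus an
    isotropic Gaussian step of scale ``diffusion_px``; particles leaving
    the frame are dropped from subsequent frames.  Returns
    ``(frames, truth)`` where ``frames`` is a (n_frames, H, W) uint16
    stack and ``truth`` holds per-frame positions and per-particle net
    directions (first -> last position, y-up angle convention).
    """
    w, h = config.frame_size
    root = np.random.SeedSequence(config.seed)
    rng_init, rng_step = (np.random.default_rng(s) for s in root.spawn(2))

    # start particles well inside the frame: spots closer than ~3 sigma
    # to the border are truncated, so a generous margin keeps every
    # particle resolvable for several frames before it can exit
    margin = 8.0 * config.spot_sigma
    pos = _poisson_disk_flow(config.n_particles, w, h, margin,
                             config.min_separation, rng_init)
    active = np.ones(config.n_particles, dtype=bool)
    frames = np.zeros((config.n_frames, h, w), dtype=np.uint16)
    records = []
    for f in range(config.n_frames):
        frames[f] = _render_frame(pos[active], config)
        for pid in np.flatnonzero(active):
            records.append({"particle": pid, "frame": f,
                            "x": pos[pid, 0], "y": pos[pid, 1]})
        theta = _field_direction(pos, config)
        step = config.speed_px_per_frame * _unit_image(theta)
        noise = rng_step.normal(0.0, config.diffusion_px, size=pos.shape) \
            if config.diffusion_px > 0 else 0.0
        pos = pos + step + noise
        inside = ((pos[:, 0] >= 0) & (pos[:, 0] < w)
                  & (pos[:, 1] >= 0) & (pos[:, 1] < h))
        active &= inside

    particles = pd.DataFrame(records)
    dirs = []
    for pid, grp in particles.groupby("particle"):
        grp = grp.sort_values("frame")
        dx = grp["x"].iloc[-1] - grp["x"].iloc[0]
        dy = grp["y"].iloc[-1] - grp["y"].iloc[0]
        disp = float(np.hypot(dx, dy))
        dirs.append({
            "particle": pid, "n_frames": len(grp),
            "net_displacement": disp,
            "direction_true": float(direction_deg(dx, dy))
            if disp > 0 else np.nan})
    truth = GroundTruth(particles=particles,
                        directions=pd.DataFrame(dirs),
                        config=asdict(config))
    return frames, truth


def _poisson_disk_flow(n, w, h, margin, min_sep, rng):
    """Initial particle positions with a minimum spacing (keeps rendered
    spots resolvable), relaxing the spacing if the frame is too crowded."""
    lo = np.array([margin, margin])
    hi = np.array([w - margin, h - margin])
    sep = min_sep
    for _ in range(12):
        accepted: list[np.ndarray] = []
        misses = 0
        while len(accepted) < n and misses < 200 * n:
            p = rng.uniform(lo, hi)
            if accepted:
                d = np.linalg.norm(np.asarray(accepted) - p, axis=1)
                if d.min() < sep:
                    misses += 1
                    continue
            accepted.append(p)
        if len(accepted) == n:
            return np.asarray(accepted)
        sep *= 0.8
    raise ValueError(f"could not place {n} particles in a {w}x{h} frame")
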