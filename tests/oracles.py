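"""Independent reference implementations used only as test oracles.

Each function here deliberately uses a naive, direct formulation
(explicit loops, brute-force enumeration) so it shares no code path with
the package implementation it checks.
"""

import numpy as np


def watson_u2_naive(a_deg, b_deg) -> float:
    """Two-sample U2 by direct summation over the combined sorted sample,
    with tied values resolved by averaging the CDF-difference within each
    tied block (average-rank convention)."""
    a = [float(x) for x in a_deg]
    b = [float(x) for x in b_deg]
    n, m = len(a), len(b)
    N = n + m
    combined = sorted(a + b)
    d = []
    for x in combined:
        fa = sum(1 for v in a if v <= x) / n
        fb = sum(1 for v in b if v <= x) / m
        d.append(fa - fb)
    out = []
    i = 0
    while i < N:
        j = i
        while j < N and combined[j] == combined[i]:
            j += 1
        block = d[i:j]
        out.extend([sum(block) / len(block)] * len(block))
        i = j
    s1 = sum(v * v for v in out)
    s2 = sum(out)
    return (n * m / N**2) * (s1 - s2 * s2 / N)


def circular_mean_naive(angles_deg) -> tuple[float, float]:
    """Mean direction and resultant length by explicit unit-vector sum."""
    s = sum(np.sin(np.deg2rad(a)) for a in angles_deg)
    c = sum(np.cos(np.deg2rad(a)) for a in angles_deg)
    n = len(angles_deg)
    R = np.sqrt(s * s + c * c) / n
    return float(np.rad2deg(np.arctan2(s, c)) % 360.0), float(R)


def feret_all_pairs(points) -> tuple[float, float]:
    """Longest diameter and its axial angle by O(n^2) enumeration over
    ALL points (no hull), smallest-angle tie-break."""
    pts = np.asarray(points, dtype=float)
    best_d = -1.0
    best_angles = []
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            dx = pts[j, 0] - pts[i, 0]
            dy = pts[j, 1] - pts[i, 1]
            d = float(np.hypot(dx, dy))
            ang = np.rad2deg(np.arctan2(-dy, dx)) % 180.0
            if ang > 180.0 - 1e-9:
                ang = 0.0
            if d > best_d * (1 + 1e-12):
                best_d, best_angles = d, [ang]
            elif d >= best_d * (1 - 1e-9):
                best_angles.append(ang)
    return best_d, min(best_angles)


def rasterized_centroid(boundary, h: float) -> tuple[float, float]:
    """Pixel-mass centroid of a polygon on a dense grid of spacing h."""
    from shapely import contains_xy
    from shapely.geometry import Polygon

    poly = Polygon(boundary)
    x0, y0, x1, y1 = poly.bounds
    xs = np.arange(x0 + h / 2, x1, h)
    ys = np.arange(y0 + h / 2, y1, h)
    xx, yy = np.meshgrid(xs, ys)
    inside = contains_xy(poly, xx.ravel(), yy.ravel())
    return (float(xx.ravel()[inside].mean()),
            float(yy.ravel()[inside].mean()))


def yates_chi2_naive(a, b, c, d) -> float:
    """Textbook per-cell continuity-corrected chi-square for a 2x2 table:
    sum over cells of (|obs - exp| - 0.5)^2 / exp, corrections floored
    at zero."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    N = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / N
    adj = np.maximum(np.abs(obs - exp) - 0.5, 0.0)
    return float((adj**2 / exp).sum())
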