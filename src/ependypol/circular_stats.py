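"""Circular statistics for directional and axial angle samples.

Angles are degrees everywhere at the API surface; radians are used only
internally.  Directional data live on a 360-degree circle; axial data
(orientations defined only up to a half-turn, such as Feret angles) use a
180-degree period and are analyzed with the standard angle-doubling
transform: double, compute the circular statistic, halve.

The module provides the mean direction and resultant length, the Rayleigh
test of uniformity, Watson's two-sample U-squared test of homogeneity
(permutation and asymptotic p-values), and rose-plot binning.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AngleSample",
    "RayleighResult",
    "WatsonResult",
    "circular_mean_R",
    "rayleigh_test",
    "watson_u2",
    "watson_u2_pvalue",
    "bin_angles",
]

#: Resultant lengths below this are treated as "no preferred direction";
#: the mean direction is then reported as NaN.
_R_UNDEFINED = 1e-12

#: Large-sample critical points of the two-sample U2 null distribution.
_U2_CRITICAL = [(0.152, 0.10), (0.187, 0.05), (0.268, 0.01), (0.385, 0.001)]


@dataclass(frozen=True)
class AngleSample:
    """A labeled collection of angles with a declared period.

    Parameters
    ----------
    label : str
        Group name carried through summaries and tests.
    angles : array-like of float
        Angles in degrees.  They are wrapped into ``[0, period)`` on
        construction.
    period : {360, 180}
        360 for directional data, 180 for axial data.
    """

    label: str
    angles: np.ndarray
    period: int = 360

    def __post_init__(self):
        if self.period not in (360, 180):
            raise ValueError(f"period must be 360 or 180, got {self.period}")
        a = np.asarray(self.angles, dtype=float)
        if a.ndim != 1 or a.size < 1:
            raise ValueError("angles must be a nonempty 1-D array")
        if not np.all(np.isfinite(a)):
            raise ValueError("angles must be finite")
        object.__setattr__(self, "angles", np.mod(a, self.period))

    @property
    def n(self) -> int:
        return self.angles.size


@dataclass(frozen=True)
class RayleighResult:
    z: float
    p_value: float
    n: int
    small_sample_warning: bool = False


@dataclass(frozen=True)
class WatsonResult:
    """Result of Watson's two-sample U2 homogeneity test."""

    u2: float
    n: int
    m: int
    p_value: float
    method: str
    n_permutations: int = 0
    seed: int | None = None
    p_lower: float | None = None  # asymptotic bracket from critical points
    p_upper: float | None = None
    small_sample_warning: bool = False
    labels: tuple[str, str] = ("a", "b")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _as_directional_radians(sample: AngleSample) -> np.ndarray:
    """Map angles to radians, doubling axial data so both periods share
    one circular machinery."""
    a = np.deg2rad(sample.angles)
    return 2.0 * a if sample.period == 180 else a


def circular_mean_R(sample: AngleSample) -> tuple[float, float]:
    """Mean direction and mean resultant length of an angle sample.

    Axial samples are doubled before averaging and halved after, so the
    returned mean lies in ``[0, period)``.

    Returns
    -------
    (mean_deg, R)
        ``mean_deg`` is NaN when R falls below 1e-12 (no preferred
        direction, e.g. perfectly symmetric data).
    """
    rad = _as_directional_radians(sample)
    C = np.mean(np.cos(rad))
    S = np.mean(np.sin(rad))
    R = float(np.hypot(C, S))
    if R < _R_UNDEFINED:
        return float("nan"), 0.0
    mean = np.rad2deg(np.arctan2(S, C)) % 360.0
    if sample.period == 180:
        mean /= 2.0
    return float(mean), R


def rayleigh_test(sample: AngleSample) -> RayleighResult:
    """Rayleigh test of circular uniformity.

    Z = n R^2; the p-value uses the standard series approximation, which
    is reliable for n >= 5 (smaller samples are flagged, not refused).
    """
    n = sample.n
    _, R = circular_mean_R(sample)
    Z = n * R * R
    # series expansion of the Rayleigh null tail probability
    p = np.exp(-Z) * (
        1.0
        + (2.0 * Z - Z * Z) / (4.0 * n)
        - (24.0 * Z - 132.0 * Z**2 + 76.0 * Z**3 - 9.0 * Z**4) / (288.0 * n * n)
    )
    p = float(np.clip(p, 0.0, 1.0))
    warn = n < 5
    if warn:
        warnings.warn("Rayleigh p-value unreliable for n < 5", stacklevel=2)
    return RayleighResult(z=float(Z), p_value=p, n=n, small_sample_warning=warn)


# ---------------------------------------------------------------------------
# Watson's two-sample U2
# ---------------------------------------------------------------------------

def _u2_from_labels(values_sorted: np.ndarray, tie_starts: np.ndarray,
                    tie_sizes: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    """U2 for one or many labelings of a fixed combined sorted sample.

    ``is_a`` has shape (..., N) with entries 1 where the observation at
    that sorted position belongs to sample a.  Ties (equal combined
    values) are resolved by evaluating both empirical CDFs at the tied
    value itself, so every member of a tied block carries the same
    d_k = F_a(x) - F_b(x); the statistic is then independent of the
    arbitrary within-block ordering.
    """
    is_a = np.atleast_2d(is_a).astype(float)
    n = is_a.sum(axis=1, keepdims=True)
    N = is_a.shape[1]
    m = N - n
    Fa = np.cumsum(is_a, axis=1) / n
    Fb = np.cumsum(1.0 - is_a, axis=1) / m
    d = Fa - Fb
    if tie_sizes.max() > 1:
        # broadcast each tied block's final (full-mass) d over the block
        block_end = d[:, tie_starts + tie_sizes - 1]
        d = np.repeat(block_end, tie_sizes, axis=1)
    dbar = d.mean(axis=1, keepdims=True)
    u2 = (n.ravel() * m.ravel() / N**2) * np.sum((d - dbar) ** 2, axis=1)
    return u2


def _prepare_combined(a: AngleSample, b: AngleSample):
    if a.period != b.period:
        raise ValueError(
            f"samples have different periods ({a.period} vs {b.period})")
    combined = np.concatenate([a.angles, b.angles])
    labels = np.concatenate([np.ones(a.n), np.zeros(b.n)])
    order = np.argsort(combined, kind="stable")
    values = combined[order]
    is_a = labels[order]
    # tied blocks of exactly equal angle values
    boundaries = np.flatnonzero(np.diff(values) != 0) + 1
    tie_starts = np.concatenate([[0], boundaries])
    tie_sizes = np.diff(np.concatenate([tie_starts, [values.size]]))
    return values, tie_starts, tie_sizes, is_a


def watson_u2(a: AngleSample, b: AngleSample) -> float:
    """Watson's two-sample U2 statistic.

    U2 = (n m / N^2) [ sum d_k^2 - (sum d_k)^2 / N ] where d_k is the
    difference of the two empirical CDF fractions at the k-th combined
    order statistic.  The statistic is invariant to a joint rotation of
    both samples and symmetric in its arguments; tied values are
    resolved by evaluating both empirical CDFs at the tied value.
    """
    values, tie_starts, tie_sizes, is_a = _prepare_combined(a, b)
    return float(_u2_from_labels(values, tie_starts, tie_sizes, is_a)[0])


def _u2_asymptotic_p(u2: float) -> float:
    """Large-sample tail probability P(U2 > u2), by the alternating series
    2 * sum_{k>=1} (-1)^(k-1) exp(-2 k^2 pi^2 u2)."""
    if u2 <= 0:
        return 1.0
    k = np.arange(1, 51)
    terms = (-1.0) ** (k - 1) * np.exp(-2.0 * k**2 * np.pi**2 * u2)
    return float(np.clip(2.0 * terms.sum(), 0.0, 1.0))


def watson_u2_pvalue(
    a: AngleSample,
    b: AngleSample,
    method: str = "permutation",
    n_permutations: int = 999,
    seed: int | None = None,
) -> WatsonResult:
    """Watson's two-sample U2 test with a permutation or asymptotic p-value.

    The permutation p-value randomly relabels the combined sample
    ``n_permutations`` times and reports
    ``(1 + #{U2_perm >= U2_obs}) / (n_permutations + 1)``; it is valid at
    any sample size and is the default.  The asymptotic method evaluates
    the large-sample null series and also reports the bracket implied by
    the standard critical points (0.187 at alpha=0.05, 0.268 at
    alpha=0.01); it is flagged when min(n, m) < 8.
    """
    values, tie_starts, tie_sizes, is_a = _prepare_combined(a, b)
    observed = float(_u2_from_labels(values, tie_starts, tie_sizes, is_a)[0])
    n, m = a.n, b.n
    N = n + m

    if method == "permutation":
        if n_permutations < 999:
            raise ValueError("n_permutations must be >= 999")
        rng = np.random.default_rng(seed)
        # permute labels over sorted positions: each row is one relabeling
        perm_labels = np.zeros((n_permutations, N))
        idx = np.argsort(rng.random((n_permutations, N)), axis=1)[:, :n]
        np.put_along_axis(perm_labels, idx, 1.0, axis=1)
        perm_u2 = _u2_from_labels(values, tie_starts, tie_sizes, perm_labels)
        p = (1.0 + np.count_nonzero(perm_u2 >= observed - 1e-12)) / (
            n_permutations + 1.0)
        return WatsonResult(
            u2=observed, n=n, m=m, p_value=float(p), method="permutation",
            n_permutations=n_permutations, seed=seed,
            labels=(a.label, b.label))
    if method == "asymptotic":
        warn = min(n, m) < 8
        if warn:
            warnings.warn(
                "asymptotic Watson U2 p-value unreliable for min(n, m) < 8",
                stacklevel=2)
        p = _u2_asymptotic_p(observed)
        p_lower, p_upper = 0.0, 1.0
        for crit, alpha in _U2_CRITICAL:
            if observed > crit:
                p_upper = alpha
            else:
                p_lower = alpha
                break
        return WatsonResult(
            u2=observed, n=n, m=m, p_value=p, method="asymptotic",
            p_lower=p_lower, p_upper=p_upper, small_sample_warning=warn,
            labels=(a.label, b.label))
    raise ValueError(f"unknown method {method!r}")


def bin_angles(sample: AngleSample, n_bins: int = 24) -> np.ndarray:
    """Counts per half-open bin [k*w, (k+1)*w) covering the sample period.

    Used to produce circular bar (rose) plot data; counts always sum to n.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    width = sample.period / n_bins
    idx = np.floor(sample.angles / width).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)  # guard float roundoff at period
    return np.bincount(idx, minlength=n_bins)
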