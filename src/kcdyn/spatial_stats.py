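"""3D point-pattern inference for Ki67-cluster (KC) centroid maps.

Implements the nearest-neighbor distance function G(r) with Monte-Carlo
complete-spatial-randomness (CSR) envelopes, Moran's I with permutation
nulls, Fisher pooling of per-specimen p values, and the distance-to-nearest-KC
rank-sum comparison used to ask whether new activation events avoid existing
foci.

Inference is envelope-based throughout: the empirical G estimator carries no
edge correction, and validity comes from applying the *identical* estimator to
the data and to null simulations drawn in the identical region. Monte-Carlo
p values use the exchangeable rank construction p = (k + 1) / (n_sim + 1) and
therefore never report 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .regions import RegionMask


@dataclass
class PointPattern3D:
    """A marked or unmarked 3D point pattern inside an observation window.

    Parameters
    ----------
    points
        ``(n, 3)`` coordinates in micrometres.
    region
        The observation window the points live in (used for CSR nulls).
    marks
        Optional per-point values (numeric or categorical), aligned 1:1.
    """

    points: np.ndarray
    region: RegionMask
    marks: np.ndarray | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, float).reshape(-1, 3)
        if not np.all(np.isfinite(pts)):
            raise ValueError("point coordinates must be finite")
        if len(pts) and not np.all(self.region.contains(pts)):
            raise ValueError("all points must lie inside the region mask")
        self.points = pts
        if self.marks is not None:
            marks = np.asarray(self.marks)
            if len(marks) != len(pts):
                raise ValueError("marks must align 1:1 with points")
            self.marks = marks

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class EnvelopeResult:
    """CSR envelope test output for the G function."""

    r: np.ndarray
    g_obs: np.ndarray
    g_null_mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    p_value: float
    n_sim: int
    statistic: str = "integrated-absolute-deviation"


@dataclass
class MoranResult:
    """Moran's I with its permutation null."""

    i: float
    p_value: float
    n_points: int
    weight_scheme: str
    null_mean: float
    null_sd: float
    expected_i: float  # -1/(n-1), the permutation-null expectation
    n_perm: int
    alternative: str = "two-sided"
    null_values: np.ndarray = field(default=None, repr=False)


def nn_distances(pattern: PointPattern3D) -> tuple[np.ndarray, float]:
    """Per-point nearest-neighbor distances and their mean.

    Coincident points yield a zero distance; these are reported with a warning
    rather than silently kept, since downstream G-function inference assumes
    distinct cell centroids.
    """
    pts = pattern.points
    if len(pts) < 2:
        raise ValueError("nearest-neighbor distances need at least 2 points")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    d = d[:, 1]
    if np.any(d == 0):
        warnings.warn(f"{int((d == 0).sum())} coincident point(s) detected", stacklevel=2)
    return d, float(d.mean())


def g_function(pattern: PointPattern3D, r_grid: np.ndarray) -> np.ndarray:
    """Empirical nearest-neighbor CDF: Ĝ(r) = fraction of NN distances ≤ r.

    No edge correction is applied (see module docstring).
    """
    r_grid = np.asarray(r_grid, float)
    if r_grid.ndim != 1 or len(r_grid) < 1 or np.any(np.diff(r_grid) <= 0):
        raise ValueError("r_grid must be strictly increasing")
    d, _ = nn_distances(pattern)
    return np.searchsorted(np.sort(d), r_grid, side="right") / len(d)


def _default_r_grid(pattern: PointPattern3D, n_r: int = 100) -> np.ndarray:
    """Grid from 0+ to twice the mean NN distance — the range where G carries
    its information for patterns at this intensity."""
    _, mean_nn = nn_distances(pattern)
    return np.linspace(1e-9, 3.0 * mean_nn, n_r)


def csr_envelope(
    pattern: PointPattern3D,
    n_sim: int = 999,
    seed: int | np.random.Generator | None = None,
    r_grid: np.ndarray | None = None,
    statistic: str = "integrated-absolute-deviation",
) -> EnvelopeResult:
    """Monte-Carlo CSR test of a point pattern via the G function.

    Simulates ``n_sim`` CSR patterns with the same number of points in the
    same region, forms pointwise min/max envelopes, and computes one global
    p value from the rank of a summary deviation statistic. The deviation of
    each pattern (observed or simulated) is measured against the mean G of the
    *other* patterns, which makes the observed and simulated statistics
    exchangeable under H0 and the Monte-Carlo p exactly uniform on its grid.

    Parameters
    ----------
    statistic
        ``integrated-absolute-deviation`` (default; trapezoidal integral of
        \\|Ĝ - Ḡ_null\\| over r) or ``max-deviation`` (sup norm).
    """
    if n_sim < 19:
        raise ValueError("n_sim < 19 gives too coarse a p-value grid; refused")
    if len(pattern) < 2:
        raise ValueError("CSR envelope test needs at least 2 points")
    if statistic not in ("integrated-absolute-deviation", "max-deviation"):
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(seed)
    if r_grid is None:
        r_grid = _default_r_grid(pattern)
    r_grid = np.asarray(r_grid, float)

    n = len(pattern)
    g_all = np.empty((n_sim + 1, len(r_grid)))
    g_all[0] = g_function(pattern, r_grid)
    for i in range(n_sim):
        sim = PointPattern3D(pattern.region.sample_uniform(n, rng), pattern.region)
        g_all[i + 1] = g_function(sim, r_grid)

    total = g_all.sum(axis=0)
    # leave-one-out null mean per pattern → exchangeability under H0
    loo_mean = (total[None, :] - g_all) / n_sim
    dev = np.abs(g_all - loo_mean)
    if statistic == "integrated-absolute-deviation":
        t = np.trapezoid(dev, r_grid, axis=1)
    else:
        t = dev.max(axis=1)
    k = int(np.sum(t[1:] >= t[0]))
    p = (k + 1) / (n_sim + 1)

    g_sims = g_all[1:]
    return EnvelopeResult(
        r=r_grid,
        g_obs=g_all[0],
        g_null_mean=g_sims.mean(axis=0),
        lower=g_sims.min(axis=0),
        upper=g_sims.max(axis=0),
        p_value=float(p),
        n_sim=n_sim,
        statistic=statistic,
    )


def _weight_matrix(
    points: np.ndarray,
    scheme: str,
    k: int | None,
    cutoff: float | None,
) -> tuple[np.ndarray, str]:
    """Row-standardized spatial weights. Returns (W, descriptor)."""
    n = len(points)
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    if scheme == "knn":
        kk = k if k is not None else min(6, n - 1)
        if not 1 <= kk <= n - 1:
            raise ValueError("knn weights need 1 <= k <= n-1")
        w = np.zeros((n, n))
        nbr = np.argsort(d, axis=1)[:, :kk]
        rows = np.repeat(np.arange(n), kk)
        w[rows, nbr.ravel()] = 1.0
        desc = f"knn(k={kk}), row-standardized"
    elif scheme == "inverse-distance":
        if cutoff is None:
            # default: 2x mean NN distance
            cutoff = 2.0 * d.min(axis=1).mean()
        with np.errstate(divide="ignore"):
            w = np.where(d <= cutoff, 1.0 / d, 0.0)
        w[~np.isfinite(w)] = 0.0
        desc = f"inverse-distance(cutoff={cutoff:.3g} um), row-standardized"
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    return w, desc


def morans_i(
    pattern: PointPattern3D,
    marks: np.ndarray | None = None,
    weights: str = "inverse-distance",
    k: int | None = None,
    cutoff: float | None = None,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    alternative: str = "two-sided",
) -> MoranResult:
    """Global Moran's I with a random-permutation null.

    I = (n/ΣW) · Σᵢⱼ wᵢⱼ (xᵢ-x̄)(xⱼ-x̄) / Σᵢ (xᵢ-x̄)².

    Binary marks (e.g. pmNB association, coded 0/1) are handled by the same
    statistic — the join-count equivalent. Points isolated under a cutoff
    weight scheme contribute a zero weight row; they are dropped from the
    statistic with a warning. Two-sided p values use equal-tail doubling of
    the permutation tail probability, capped at 1.
    """
    x = np.asarray(pattern.marks if marks is None else marks, float)
    pts = pattern.points
    if len(pts) < 3:
        raise ValueError("Moran's I needs n >= 3 points")
    if len(x) != len(pts):
        raise ValueError("marks must align with points")
    if np.ptp(x) == 0:
        raise ValueError("marks are constant: Moran's I is undefined (zero variance)")

    w, desc = _weight_matrix(pts, weights, k, cutoff)
    isolated = w.sum(axis=1) == 0
    if isolated.any():
        warnings.warn(
            f"{int(isolated.sum())} isolated point(s) under {desc}; dropped from Moran's I",
            stacklevel=2,
        )
        keep = ~isolated
        pts, x, w = pts[keep], x[keep], w[np.ix_(keep, keep)]
        if len(pts) < 3 or np.ptp(x) == 0:
            raise ValueError("too few non-isolated points (or constant marks) after dropping")
    w = w / w.sum(axis=1, keepdims=True)

    n = len(x)
    rng = np.random.default_rng(seed)

    def _i(vals: np.ndarray) -> float:
        z = vals - vals.mean()
        return float(n / w.sum() * (z @ w @ z) / (z @ z))

    i_obs = _i(x)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = _i(rng.permutation(x))

    if alternative == "greater":
        p = (1 + np.sum(null >= i_obs)) / (n_perm + 1)
    elif alternative == "less":
        p = (1 + np.sum(null <= i_obs)) / (n_perm + 1)
    elif alternative == "two-sided":
        p_hi = (1 + np.sum(null >= i_obs)) / (n_perm + 1)
        p_lo = (1 + np.sum(null <= i_obs)) / (n_perm + 1)
        p = min(1.0, 2.0 * min(p_hi, p_lo))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")

    return MoranResult(
        i=i_obs,
        p_value=float(p),
        n_points=n,
        weight_scheme=desc,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        expected_i=-1.0 / (n - 1),
        n_perm=n_perm,
        alternative=alternative,
        null_values=null,
    )


def pool_pvalues(p_values, method: str = "fisher") -> float:
    """Combine independent per-specimen p values (Fisher's method).

    Fisher's statistic −2 Σ ln pᵢ is referred to χ² with 2k degrees of
    freedom. Exact zeros are refused: a Monte-Carlo test can never produce
    p = 0, so a zero indicates an upstream error; use the Monte-Carlo lower
    bound 1/(n_sim+1) instead.
    """
    p = np.asarray(p_values, float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("need a non-empty 1D list of p values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must lie in (0, 1]; replace exact zeros by the MC lower bound")
    stat, pooled = stats.combine_pvalues(p, method=method)
    return float(pooled)


def distance_to_nearest_kc_test(
    query_points: np.ndarray,
    kc_pattern: PointPattern3D,
    alternative: str = "greater",
    seed: int | None = None,
) -> dict:
    """Are query points (e.g. single/pair/trio Ki67+ groups) farther from
    their nearest KC than KCs are from each other?

    One-sided Wilcoxon rank-sum comparing query→nearest-KC distances against
    the KC→KC nearest-neighbor distances. ``alternative='greater'`` tests the
    hypothesis that queries sit farther away (new activations avoid existing
    foci). The rank-sum p is exact/asymptotic and needs no randomness; ``seed``
    is accepted for interface uniformity and ignored.
    """
    q = np.atleast_2d(np.asarray(query_points, float))
    if len(q) < 1:
        raise ValueError("need at least one query point")
    if len(kc_pattern) < 2:
        raise ValueError("need at least two KCs")
    tree = cKDTree(kc_pattern.points)
    d_query, _ = tree.query(q, k=1)
    d_kc, _ = nn_distances(kc_pattern)
    res = stats.mannwhitneyu(d_query, d_kc, alternative=alternative)
    return {
        "query_distances": np.asarray(d_query, float),
        "kc_nn_distances": d_kc,
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "alternative": alternative,
    }


def plot_envelope(result: EnvelopeResult, ax=None):
    """Plot observed G, null mean, and pointwise envelopes (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.fill_between(result.r, result.lower, result.upper, color="0.8", label="envelope")
    ax.plot(result.r, result.g_null_mean, "k--", label="G(H0, mean)")
    ax.plot(result.r, result.g_obs, "r-", label="G(obs)")
    ax.set_xlabel("r (um)")
    ax.set_ylabel("G(r)")
    ax.legend()
    ax.set_title(f"CSR envelope test, p = {result.p_value:.3g} ({result.n_sim} sims)")
    return ax
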