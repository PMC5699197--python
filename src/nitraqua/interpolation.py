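"""Spatial interpolators for scattered groundwater observations.

Four point interpolators built from first principles over planar
Euclidean coordinates:

* ordinary kriging driven by a fitted semivariogram (spherical,
  exponential or gaussian), solved with a Lagrange multiplier so the
  weights sum to one;
* inverse-distance weighting with configurable power and optional
  k-nearest neighbourhood;
* thin-plate spline (radial kernel r^2 log r plus an affine trend),
  an exact interpolator at tension 0;
* Sibson natural-neighbour interpolation, with weights computed as the
  Voronoi areas the inserted target cell "steals" from its neighbours.

All four reproduce a constant field exactly and are translation
invariant. IDW and natural neighbour are convex combinations of the
observations; natural neighbour returns NaN outside the convex hull,
where the Sibson weights are undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import Delaunay, cKDTree
from scipy.spatial.distance import cdist, pdist, squareform

from .data_model import SampleTable, Surface, DEFAULT_NODATA

VARIOGRAM_KINDS = ("spherical", "exponential", "gaussian")
METHODS = ("idw", "kriging", "natural_neighbor", "spline")

# Targets closer than this (metres) to a sample coincide with it.
COINCIDENCE_TOL = 1e-9


@dataclass(frozen=True)
class VariogramModel:
    """Parametric semivariogram gamma(h).

    nugget and partial_sill in (mg/L)^2, range_m in metres. The
    exponential and gaussian kinds use the practical-range convention
    (gamma reaches ~95% of the sill at h = range_m).
    """

    kind: str
    nugget: float
    partial_sill: float
    range_m: float

    def __post_init__(self) -> None:
        if self.kind not in VARIOGRAM_KINDS:
            raise ValueError(f"unknown variogram kind {self.kind!r}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial_sill must be >= 0")
        if self.range_m <= 0:
            raise ValueError("range_m must be > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def correlation(self, h: np.ndarray) -> np.ndarray:
        """Normalized correlogram rho(h) of the structured component."""
        h = np.asarray(h, dtype=float)
        a = self.range_m
        if self.kind == "spherical":
            hr = np.minimum(h / a, 1.0)
            return 1.0 - (1.5 * hr - 0.5 * hr**3)
        if self.kind == "exponential":
            return np.exp(-3.0 * h / a)
        return np.exp(-3.0 * (h / a) ** 2)

    def gamma(self, h: np.ndarray | float) -> np.ndarray:
        """Semivariance at lag h; gamma(0) = 0 exactly."""
        h = np.asarray(h, dtype=float)
        g = self.partial_sill * (1.0 - self.correlation(h))
        out = np.where(h > 0, self.nugget + g, 0.0)
        return out


@dataclass(frozen=True)
class EmpiricalVariogram:
    """Binned Matheron estimates: lag centres (m), gamma ((mg/L)^2), pair counts.

    Empty bins carry count 0 and gamma NaN.
    """

    lags: np.ndarray
    gammas: np.ndarray
    counts: np.ndarray


@dataclass(frozen=True)
class InterpolatorSpec:
    """Configuration of one interpolation method.

    ``idw_neighbors=None`` uses all points. ``variogram=None`` for
    kriging means fit one from the data (kind ``variogram_kind``).
    """

    method: str
    idw_power: float = 2.0
    idw_neighbors: Optional[int] = None
    variogram: Optional[VariogramModel] = None
    variogram_kind: str = "spherical"
    n_bins: int = 12
    max_lag: Optional[float] = None
    spline_tension: float = 0.0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.idw_power <= 0:
            raise ValueError("idw_power must be > 0")
        if self.spline_tension < 0:
            raise ValueError("spline_tension must be >= 0")


# ---------------------------------------------------------------------------
# semivariogram estimation and fitting


def empirical_semivariogram(
    samples: SampleTable, n_bins: int = 12, max_lag: Optional[float] = None
) -> EmpiricalVariogram:
    """Binned Matheron semivariogram estimator.

    gamma(h) = (1 / 2N(h)) * sum over pairs in the bin of (z_i - z_j)^2,
    pairs binned by separation distance into ``n_bins`` equal-width bins
    over (0, max_lag]. Default max_lag is half the maximum pairwise
    distance, the conventional reliable-lag rule.
    """
    xy = samples.xy
    z = samples.nitrate
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    d = pdist(xy)
    if np.all(d < COINCIDENCE_TOL):
        raise ValueError("all points coincident; semivariogram undefined")
    if max_lag is None:
        max_lag = float(d.max()) / 2.0
    if max_lag <= 0:
        raise ValueError("max_lag must be > 0")
    sq = pdist(z[:, None], metric="sqeuclidean")
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    idx = np.digitize(d, edges) - 1  # bin index; outside [0, n_bins) ignored
    keep = (idx >= 0) & (idx < n_bins)
    counts = np.bincount(idx[keep], minlength=n_bins)
    sums = np.bincount(idx[keep], weights=sq[keep], minlength=n_bins)
    gammas = np.full(n_bins, np.nan)
    nz = counts > 0
    gammas[nz] = sums[nz] / (2.0 * counts[nz])
    centres = 0.5 * (edges[:-1] + edges[1:])
    return EmpiricalVariogram(centres, gammas, counts.astype(int))


def fit_variogram_model(
    lags: np.ndarray,
    gammas: np.ndarray,
    counts: np.ndarray,
    kind: str = "spherical",
) -> VariogramModel:
    """Weighted least-squares fit of a parametric semivariogram.

    Weights are the pair counts. A fixed, deterministic multi-start grid
    of range and nugget initialisations guards against local minima, so
    repeated fits are bit-stable. If the optimal range falls below the
    smallest informative lag the structured component is observationally
    indistinguishable from nugget and is folded into it (pure-nugget
    limit).
    """
    lags = np.asarray(lags, dtype=float)
    gammas = np.asarray(gammas, dtype=float)
    counts = np.asarray(counts, dtype=float)
    usable = (counts > 0) & np.isfinite(gammas)
    if usable.sum() < 3:
        raise ValueError("need >= 3 non-empty bins to fit a variogram")
    h = lags[usable]
    g = gammas[usable]
    w = np.sqrt(counts[usable])

    gmax = float(g.max())
    hmax = float(h.max())
    if gmax == 0.0:
        return VariogramModel(kind, 0.0, 0.0, hmax)

    def resid(p: np.ndarray) -> np.ndarray:
        m = VariogramModel(kind, max(p[0], 0.0), max(p[1], 0.0), max(p[2], 1e-12))
        return w * (m.gamma(h) - g)

    best: tuple[float, np.ndarray] | None = None
    for r0 in (0.15, 0.35, 0.6, 0.9):
        for n0 in (0.0, 0.5):
            x0 = np.array([n0 * gmax, max(gmax - n0 * gmax, 1e-6 * gmax), r0 * hmax])
            sol = least_squares(
                resid,
                x0,
                bounds=([0.0, 0.0, 1e-9 * hmax], [np.inf, np.inf, 100.0 * hmax]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
            if best is None or sol.cost < best[0] - 1e-15 * (1 + best[0]):
                best = (sol.cost, sol.x)
    assert best is not None
    nugget, psill, rng = best[1]
    hmin = float(h.min())
    if rng < hmin:  # flat over all observed lags: pure-nugget limit
        m_flat = VariogramModel(kind, nugget + psill, 0.0, hmax)
        if float(np.sum((w * (m_flat.gamma(h) - g)) ** 2)) <= 2.0 * best[0] + 1e-12:
            return m_flat
    return VariogramModel(kind, float(nugget), float(psill), float(rng))


def fit_variogram(
    samples: SampleTable,
    kind: str = "spherical",
    n_bins: int = 12,
    max_lag: Optional[float] = None,
) -> VariogramModel:
    """Convenience: empirical estimation followed by WLS model fitting."""
    emp = empirical_semivariogram(samples, n_bins=n_bins, max_lag=max_lag)
    return fit_variogram_model(emp.lags, emp.gammas, emp.counts, kind=kind)


# ---------------------------------------------------------------------------
# ordinary kriging


def _dedupe(xy: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average observations at coincident locations (within tolerance)."""
    if len(xy) < 2:
        return xy, z
    order = np.lexsort((xy[:, 1], xy[:, 0]))
    xs, zs = xy[order], z[order]
    groups: list[list[int]] = [[0]]
    for i in range(1, len(xs)):
        if np.hypot(*(xs[i] - xs[groups[-1][0]])) < COINCIDENCE_TOL:
            groups[-1].append(i)
        else:
            groups.append([i])
    if len(groups) == len(xs):
        return xy, z
    uxy = np.array([xs[g[0]] for g in groups])
    uz = np.array([zs[g].mean() for g in groups])
    return uxy, uz


class OrdinaryKriging:
    """Ordinary-kriging predictor with a factorized system matrix.

    The (n+1)x(n+1) system [[Gamma, 1], [1^T, 0]] is LU-factorized once;
    each prediction solves for the weights and the Lagrange multiplier.
    Duplicate locations are pre-averaged (the system would otherwise be
    singular).
    """

    def __init__(self, xy: np.ndarray, z: np.ndarray, variogram: VariogramModel):
        xy = np.asarray(xy, dtype=float)
        z = np.asarray(z, dtype=float)
        if len(xy) < 1:
            raise ValueError("need at least one sample")
        self.xy, self.z = _dedupe(xy, z)
        self.variogram = variogram
        n = len(self.xy)
        A = np.empty((n + 1, n + 1))
        A[:n, :n] = variogram.gamma(squareform(pdist(self.xy))) if n > 1 else 0.0
        A[:n, n] = 1.0
        A[n, :n] = 1.0
        A[n, n] = 0.0
        from scipy.linalg import lu_factor

        try:
            self._lu = lu_factor(A)
        except Exception as exc:  # singular after dedupe: degenerate geometry
            raise ValueError(f"singular kriging system: {exc}") from exc

    def weights(self, target: Sequence[float]) -> tuple[np.ndarray, float]:
        """Kriging weights (summing to 1) and the Lagrange multiplier."""
        from scipy.linalg import lu_solve

        n = len(self.xy)
        b = np.empty(n + 1)
        d = np.hypot(self.xy[:, 0] - target[0], self.xy[:, 1] - target[1])
        b[:n] = self.variogram.gamma(d)
        b[n] = 1.0
        sol = lu_solve(self._lu, b)
        return sol[:n], float(sol[n])

    def predict(self, target: Sequence[float]) -> tuple[float, float]:
        """Prediction (mg/L) and kriging variance ((mg/L)^2) at a point."""
        w, mu = self.weights(target)
        d = np.hypot(self.xy[:, 0] - target[0], self.xy[:, 1] - target[1])
        var = float(w @ self.variogram.gamma(d) + mu)
        return float(w @ self.z), max(var, 0.0)


def krige_ordinary(
    samples: SampleTable, variogram: VariogramModel, target: Sequence[float]
) -> tuple[float, float]:
    """One-shot ordinary kriging at a single target location."""
    ok = OrdinaryKriging(samples.xy, samples.nitrate, variogram)
    return ok.predict(target)


# ---------------------------------------------------------------------------
# inverse-distance weighting


def idw_predict(
    samples: SampleTable,
    power: float = 2.0,
    target: Sequence[float] = (0.0, 0.0),
    n_neighbors: Optional[int] = None,
) -> float:
    """Inverse-distance-weighted prediction: sum of w_i z_i with
    w_i proportional to d_i^(-power), normalized.

    A target within the coincidence tolerance of a sample returns that
    sample's value exactly. ``n_neighbors`` restricts the average to the
    k nearest points (default: all points).
    """
    if power <= 0:
        raise ValueError("power must be > 0")
    xy = samples.xy
    z = samples.nitrate
    d = np.hypot(xy[:, 0] - target[0], xy[:, 1] - target[1])
    hit = d < COINCIDENCE_TOL
    if np.any(hit):
        return float(z[np.argmax(hit)])
    if n_neighbors is not None and n_neighbors < len(d):
        keep = np.argsort(d, kind="stable")[:n_neighbors]
        d, z = d[keep], z[keep]
    w = d ** (-power)
    return float(w @ z / w.sum())


# ---------------------------------------------------------------------------
# thin-plate spline


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r, with U(0) = 0 by continuity."""
    out = np.zeros_like(r)
    pos = r > 0
    out[pos] = r[pos] ** 2 * np.log(r[pos])
    return out


class ThinPlateSpline:
    """Exact thin-plate spline interpolant with an affine trend.

    Solves [[K + tension*I, P], [P^T, 0]] [lambda; a] = [z; 0] where
    K_ij = U(|x_i - x_j|) and P = [1, x, y]. tension > 0 relaxes exact
    interpolation into smoothing (a ridge on the radial coefficients).
    Requires >= 3 non-collinear points so the affine part is determined.
    """

    def __init__(self, xy: np.ndarray, z: np.ndarray, tension: float = 0.0):
        xy = np.asarray(xy, dtype=float)
        z = np.asarray(z, dtype=float)
        n = len(xy)
        if n < 3:
            raise ValueError("thin-plate spline needs >= 3 points")
        P = np.column_stack([np.ones(n), xy])
        if np.linalg.matrix_rank(P) < 3:
            raise ValueError("points are collinear; affine trend is underdetermined")
        dup = pdist(xy)
        if np.any(dup < COINCIDENCE_TOL):
            raise ValueError("duplicate locations make the spline system singular")
        K = _tps_kernel(squareform(dup))
        A = np.zeros((n + 3, n + 3))
        A[:n, :n] = K + tension * np.eye(n)
        A[:n, n:] = P
        A[n:, :n] = P.T
        b = np.concatenate([z, np.zeros(3)])
        try:
            coef = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"degenerate spline configuration: {exc}") from exc
        self.xy = xy
        self.lam = coef[:n]
        self.affine = coef[n:]

    def predict(self, target: Sequence[float]) -> float:
        r = np.hypot(self.xy[:, 0] - target[0], self.xy[:, 1] - target[1])
        a0, ax, ay = self.affine
        return float(self.lam @ _tps_kernel(r) + a0 + ax * target[0] + ay * target[1])


def spline_tps_predict(
    samples: SampleTable, tension: float = 0.0, target: Sequence[float] = (0.0, 0.0)
) -> float:
    """One-shot thin-plate-spline prediction at a single target."""
    tps = ThinPlateSpline(samples.xy, samples.nitrate, tension)
    return tps.predict(target)


# ---------------------------------------------------------------------------
# Sibson natural neighbour


def _clip_halfplane(poly: np.ndarray, a: np.ndarray, c: float) -> np.ndarray:
    """Sutherland–Hodgman clip of a convex polygon to {x : a.x <= c}."""
    if len(poly) == 0:
        return poly
    vals = poly @ a - c
    out: list[np.ndarray] = []
    n = len(poly)
    for i in range(n):
        p, q = poly[i], poly[(i + 1) % n]
        vp, vq = vals[i], vals[(i + 1) % n]
        if vp <= 0:
            out.append(p)
        if (vp < 0 < vq) or (vq < 0 < vp):
            t = vp / (vp - vq)
            out.append(p + t * (q - p))
    return np.array(out) if out else np.empty((0, 2))


def _poly_area(poly: np.ndarray) -> float:
    """Shoelace area of a (convex) polygon."""
    if len(poly) < 3:
        return 0.0
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _voronoi_cell(site: np.ndarray, others: np.ndarray, bbox: np.ndarray) -> np.ndarray:
    """Voronoi cell of ``site`` against ``others``, clipped to the bbox
    polygon, built by successive bisector half-plane clipping."""
    poly = bbox
    for q in others:
        diff = q - site
        nrm = float(np.hypot(*diff))
        if nrm < COINCIDENCE_TOL:
            continue
        mid = 0.5 * (site + q)
        poly = _clip_halfplane(poly, diff, float(diff @ mid))
        if len(poly) == 0:
            break
    return poly


def _convex_intersection(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Intersection of two convex polygons: clip P by each edge of Q."""
    if len(P) < 3 or len(Q) < 3:
        return np.empty((0, 2))
    # orient Q counter-clockwise
    u, v = Q[1] - Q[0], Q[2] - Q[0]
    if u[0] * v[1] - u[1] * v[0] < 0:
        Q = Q[::-1]
    poly = P
    m = len(Q)
    for i in range(m):
        e0, e1 = Q[i], Q[(i + 1) % m]
        edge = e1 - e0
        # inside is to the left of the edge: normal pointing right
        a = np.array([edge[1], -edge[0]])
        poly = _clip_halfplane(poly, a, float(a @ e0))
        if len(poly) == 0:
            break
    return poly


def natural_neighbor_weights(
    samples: SampleTable, target: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Sibson weights of a target point over the sample set.

    Returns (indices, weights) with weights > 0 summing to 1. The weight
    of sample i is the area its Voronoi cell cedes to the cell of the
    inserted target, normalized. Raises outside the convex hull (the
    inserted cell would be unbounded) and on degenerate geometry.
    """
    xy = samples.xy
    tgt = np.asarray(target, dtype=float)
    d = np.hypot(xy[:, 0] - tgt[0], xy[:, 1] - tgt[1])
    hit = d < COINCIDENCE_TOL
    if np.any(hit):
        i = int(np.argmax(hit))
        return np.array([i]), np.array([1.0])
    try:
        tri = Delaunay(xy)
    except Exception as exc:
        raise ValueError(f"degenerate sample geometry: {exc}") from exc
    if tri.find_simplex(tgt) < 0:
        raise _OutsideHull()
    lo = xy.min(axis=0)
    hi = xy.max(axis=0)
    span = max(float(np.max(hi - lo)), 1.0)
    pad = 10.0 * span
    bbox = np.array(
        [
            [lo[0] - pad, lo[1] - pad],
            [hi[0] + pad, lo[1] - pad],
            [hi[0] + pad, hi[1] + pad],
            [lo[0] - pad, hi[1] + pad],
        ]
    )
    tcell = _voronoi_cell(tgt, xy, bbox)
    if _poly_area(tcell) <= 0:
        raise ValueError("degenerate inserted Voronoi cell")
    aug = Delaunay(np.vstack([xy, tgt[None, :]]))
    indptr, indices = aug.vertex_neighbor_vertices
    t_idx = len(xy)
    nbrs = indices[indptr[t_idx]: indptr[t_idx + 1]]
    nbrs = nbrs[nbrs < len(xy)]
    stolen = np.zeros(len(nbrs))
    for k, i in enumerate(nbrs):
        others = np.delete(xy, i, axis=0)
        old = _voronoi_cell(xy[i], others, bbox)
        stolen[k] = _poly_area(_convex_intersection(old, tcell))
    total = stolen.sum()
    if total <= 0:
        raise ValueError("Sibson weights degenerate (zero stolen area)")
    keep = stolen > 0
    return nbrs[keep], stolen[keep] / total


class _OutsideHull(Exception):
    """Target lies outside the convex hull of the samples."""


def natural_neighbor_predict(
    samples: SampleTable, target: Sequence[float]
) -> float:
    """Sibson natural-neighbour prediction; NaN outside the convex hull."""
    if len(samples) < 3:
        raise ValueError("natural neighbour needs >= 3 non-collinear samples")
    try:
        idx, w = natural_neighbor_weights(samples, target)
    except _OutsideHull:
        return float("nan")
    return float(w @ samples.nitrate[idx])


# ---------------------------------------------------------------------------
# unified interface and gridding


def make_interpolator(
    samples: SampleTable, spec: InterpolatorSpec
) -> Callable[[Sequence[float]], float]:
    """Build a point-prediction callable for the chosen method.

    Shared state (kriging factorization, spline coefficients) is built
    once so gridding and cross-validation stay cheap. The callable
    returns NaN where the method is undefined (natural neighbour outside
    the hull).
    """
    if spec.method == "idw":
        return lambda t: idw_predict(samples, spec.idw_power, t, spec.idw_neighbors)
    if spec.method == "kriging":
        vg = spec.variogram
        if vg is None:
            vg = fit_variogram(
                samples, kind=spec.variogram_kind, n_bins=spec.n_bins, max_lag=spec.max_lag
            )
        ok = OrdinaryKriging(samples.xy, samples.nitrate, vg)
        return lambda t: ok.predict(t)[0]
    if spec.method == "spline":
        tps = ThinPlateSpline(samples.xy, samples.nitrate, spec.spline_tension)
        return tps.predict
    return lambda t: natural_neighbor_predict(samples, t)


def predict_grid(
    samples: SampleTable,
    spec: InterpolatorSpec,
    ncols: int,
    nrows: int,
    xll: float,
    yll: float,
    cellsize: float,
    nodata: float = DEFAULT_NODATA,
) -> Surface:
    """Apply an interpolator at every cell centre of a regular grid.

    Cells where the method is undefined (natural-neighbour cells outside
    the convex hull) receive the nodata sentinel.
    """
    if ncols <= 0 or nrows <= 0 or cellsize <= 0:
        raise ValueError("grid geometry must be positive")
    predict = make_interpolator(samples, spec)
    values = np.full((nrows, ncols), nodata, dtype=float)
    surface = Surface(ncols, nrows, xll, yll, cellsize, values, nodata)
    X, Y = surface.cell_centers()
    for r in range(nrows):
        for c in range(ncols):
            v = predict((X[r, c], Y[r, c]))
            values[r, c] = v if math.isfinite(v) else nodata
    surface.values = values
    return surface


def grid_geometry_for(
    samples: SampleTable, cellsize: float, pad_cells: int = 1
) -> tuple[int, int, float, float]:
    """(ncols, nrows, xll, yll) of a grid covering the sample bounding box."""
    xy = samples.xy
    lo = xy.min(axis=0) - pad_cells * cellsize
    hi = xy.max(axis=0) + pad_cells * cellsize
    ncols = max(int(math.ceil((hi[0] - lo[0]) / cellsize)), 1)
    nrows = max(int(math.ceil((hi[1] - lo[1]) / cellsize)), 1)
    return ncols, nrows, float(lo[0]), float(lo[1])
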