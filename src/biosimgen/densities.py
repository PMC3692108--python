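"""One-dimensional density fitting and inverse-CDF sampling.

The simulator models every scalar characteristic of the input data (sequence
lengths, per-symbol composition fractions, numerical features) with a smooth
1-D density of the log-spline family, then samples new values from it.

The log-spline fit here uses Lindsey's method: the data are binned and the
bin counts modelled by a Poisson regression on a cubic B-spline basis of the
bin centres, so the fitted log-density is a cubic spline whose coefficients
are maximum-likelihood estimates.  The number of interior knots is chosen by
BIC over a small candidate grid.  For small or degenerate inputs the fit
falls back to a boundary-reflected Gaussian KDE or to the empirical
quantile function; in every case the result is represented the same way — a
monotone (x, CDF) grid inverted by linear interpolation at sampling time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, stats
from scipy.special import gammaln

logger = logging.getLogger(__name__)

GRID_SIZE = 2048
#: interior-knot candidates scanned by BIC for the log-spline fit
KNOT_CANDIDATES = (3, 5, 8, 12)


@dataclass
class FittedDensity:
    """A fitted 1-D law represented by an invertible CDF grid.

    ``x_grid``/``cdf_grid`` is a monotone grid running from ~0 to ~1 used for
    inversion sampling; ``pdf_grid`` (when available) is the normalized
    density on the same grid.
    """

    kind: str  # logspline | kde | empirical | pointmass
    support: tuple[float, float]
    x_grid: np.ndarray
    cdf_grid: np.ndarray
    pdf_grid: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x_grid = np.asarray(self.x_grid, dtype=float)
        self.cdf_grid = np.asarray(self.cdf_grid, dtype=float)
        if np.any(np.diff(self.cdf_grid) < -1e-12):
            raise ValueError("CDF grid must be nondecreasing")

    def cdf(self, x) -> np.ndarray:
        return np.interp(x, self.x_grid, self.cdf_grid, left=0.0, right=1.0)

    def quantile(self, u) -> np.ndarray:
        """Inverse CDF by linear interpolation on the grid."""
        return np.interp(u, self.cdf_grid, self.x_grid)

    def to_dict(self) -> dict:
        """Plain-text-serializable form (reproducibility record)."""
        return {
            "kind": self.kind,
            "support": list(self.support),
            "x_grid": self.x_grid.tolist(),
            "cdf_grid": self.cdf_grid.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedDensity":
        return cls(kind=d["kind"], support=tuple(d["support"]),
                   x_grid=np.array(d["x_grid"]), cdf_grid=np.array(d["cdf_grid"]))


def _grid_for(values: np.ndarray, bounds) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    pad = 0.01 * (hi - lo) if hi > lo else max(abs(lo) * 0.01, 1e-9)
    glo, ghi = lo - pad, hi + pad
    if bounds is not None:
        if bounds[0] is not None:
            glo = max(glo, float(bounds[0]))
        if bounds[1] is not None:
            ghi = min(ghi, float(bounds[1]))
    return np.linspace(glo, ghi, GRID_SIZE)


def _density_from_pdf(kind: str, grid: np.ndarray, pdf: np.ndarray,
                      meta: dict | None = None) -> FittedDensity:
    pdf = np.clip(pdf, 0.0, None)
    area = np.trapezoid(pdf, grid)
    if area <= 0:
        raise ValueError("degenerate density (zero mass)")
    pdf = pdf / area
    cdf = np.concatenate([[0.0], np.cumsum(
        0.5 * (pdf[1:] + pdf[:-1]) * np.diff(grid))])
    cdf = np.clip(cdf / cdf[-1], 0.0, 1.0)
    return FittedDensity(kind, (float(grid[0]), float(grid[-1])),
                         grid, cdf, pdf, meta or {})


def _fit_logspline(values: np.ndarray, grid: np.ndarray) -> FittedDensity:
    """Lindsey's method: Poisson fit of binned counts on a B-spline basis."""
    n = values.size
    nbins = int(np.clip(n // 4, 30, 150))
    edges = np.linspace(grid[0], grid[-1], nbins + 1)
    counts, _ = np.histogram(values, bins=edges)
    centres = 0.5 * (edges[:-1] + edges[1:])

    def basis(x: np.ndarray, n_interior: int) -> np.ndarray:
        interior = np.quantile(values, np.linspace(0, 1, n_interior + 2)[1:-1])
        interior = np.unique(np.clip(interior, grid[0], grid[-1]))
        knots = np.concatenate([[grid[0]] * 4, interior, [grid[-1]] * 4])
        k = len(knots) - 4
        mat = np.empty((x.size, k))
        for j in range(k):
            coef = np.zeros(k)
            coef[j] = 1.0
            mat[:, j] = interpolate.BSpline(knots, coef, 3, extrapolate=False)(x)
        return np.nan_to_num(mat)

    def poisson_fit(X: np.ndarray, y: np.ndarray):
        # IRLS for log-linear Poisson regression with a tiny ridge for stability
        beta = np.zeros(X.shape[1])
        beta[0] = np.log(max(y.mean(), 1e-3))
        for _ in range(100):
            eta = np.clip(X @ beta, -30, 30)
            mu = np.exp(eta)
            W = mu
            z = eta + (y - mu) / np.maximum(mu, 1e-10)
            XtW = X.T * W
            H = XtW @ X + 1e-8 * np.eye(X.shape[1])
            new = np.linalg.solve(H, XtW @ z)
            if np.max(np.abs(new - beta)) < 1e-8:
                beta = new
                break
            beta = new
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        llf = float(np.sum(y * eta - mu - gammaln(y + 1)))
        return beta, llf

    best = None
    for n_interior in KNOT_CANDIDATES:
        try:
            X = basis(centres, n_interior)
            if np.linalg.matrix_rank(X) < X.shape[1]:
                continue
            beta, llf = poisson_fit(X, counts.astype(float))
            bic = -2 * llf + X.shape[1] * np.log(nbins)
        except np.linalg.LinAlgError:
            continue
        if best is None or bic < best[0]:
            best = (bic, n_interior, beta)
    if best is None:
        raise np.linalg.LinAlgError("no stable spline basis")
    _, n_interior, beta = best
    Xg = basis(grid, n_interior)
    pdf = np.exp(np.clip(Xg @ beta, -30, 30))
    return _density_from_pdf("logspline", grid, pdf,
                             {"interior_knots": n_interior, "n": n})


def _fit_kde(values: np.ndarray, grid: np.ndarray, bounds) -> FittedDensity:
    kde = stats.gaussian_kde(values, bw_method="silverman")
    pdf = kde(grid)
    # boundary reflection keeps mass from leaking past finite bounds
    if bounds is not None:
        if bounds[0] is not None:
            pdf = pdf + kde(2.0 * float(bounds[0]) - grid)
        if bounds[1] is not None:
            pdf = pdf + kde(2.0 * float(bounds[1]) - grid)
    return _density_from_pdf("kde", grid, pdf, {"n": values.size})


def _fit_empirical(values: np.ndarray) -> FittedDensity:
    """Quantile-function representation; exact for point masses."""
    q = np.linspace(0.0, 1.0, GRID_SIZE)
    x = np.quantile(values, q, method="linear")
    return FittedDensity("empirical", (float(x[0]), float(x[-1])), x, q,
                         meta={"n": values.size})


def fit_density(values, bounds=None, kind: str = "auto") -> FittedDensity:
    """Fit a 1-D density to ``values``.

    Parameters
    ----------
    values : array-like of float
    bounds : optional (lower, upper); either end may be None.  The fitted
        density is zero outside, enforced by grid clamping and reflection.
    kind : 'auto' | 'logspline' | 'kde' | 'empirical'.  'auto' prefers the
        log-spline fit, falling back to KDE and finally to the empirical
        quantile function when the data are too small or the fit unstable.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("need at least 2 values to fit a density")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values")
    distinct = np.unique(values)
    if distinct.size == 1:
        logger.warning("all values identical (%g): returning point mass", distinct[0])
        x = np.full(2, distinct[0])
        return FittedDensity("pointmass", (distinct[0], distinct[0]),
                             x, np.array([0.0, 1.0]))

    if kind == "empirical":
        return _fit_empirical(values)
    if distinct.size < 10 and kind == "auto":
        logger.info("only %d distinct values: empirical fallback", distinct.size)
        return _fit_empirical(values)

    grid = _grid_for(values, bounds)
    if kind in ("auto", "logspline"):
        try:
            fit = _fit_logspline(values, grid)
            if kind == "logspline":
                return fit
            # goodness-of-fit guard: boundary-piled data can make the
            # exponential spline spike; fall back when the fitted CDF leaves
            # the KS band around the empirical CDF
            xs = np.sort(values)
            ecdf = np.arange(1, xs.size + 1) / xs.size
            gof = np.max(np.abs(fit.cdf(xs) - ecdf))
            if gof < max(0.05, 1.36 / np.sqrt(xs.size)):
                return fit
            logger.info("logspline misfit (sup-distance %.3f); KDE fallback", gof)
        except (np.linalg.LinAlgError, ValueError) as exc:
            if kind == "logspline":
                raise
            logger.info("logspline fit failed (%s); KDE fallback", exc)
    try:
        return _fit_kde(values, grid, bounds)
    except np.linalg.LinAlgError:
        if kind == "kde":
            raise
        return _fit_empirical(values)


def sample_density(density: FittedDensity, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` values by inverse-CDF sampling; deterministic given the rng state."""
    if n < 1:
        raise ValueError("n must be >= 1")
    u = rng.random(n)
    return density.quantile(u)


def ks_distance(a, b) -> float:
    """Two-sample Kolmogorov–Smirnov sup-distance between empirical CDFs."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.ks_2samp(a, b, method="asymp").statistic)
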