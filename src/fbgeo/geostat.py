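"""Geostatistics: Matérn variograms, ML fitting, ordinary kriging, LOO-CV.

The spatial model is a second-order stationary Gaussian process with
unknown constant mean, Matérn correlation with range parameter ``a`` and
smoothness ``nu``, partial sill ``c`` and nugget ``c0``:

    C(h) = c * rho_Matern(h; a, nu) + c0 * 1{h = 0}
    gamma(h) = c0 + c * (1 - rho_Matern(h; a, nu))      for h > 0

Fitting maximises the Gaussian likelihood with the mean profiled out in
closed form and the total sill profiled out as well, leaving a 2-D
numerical search over (log range, correlated-fraction); the smoothness
``nu`` is optimised over a discrete candidate grid because the continuous
likelihood in ``nu`` is extremely flat.  Distances are Euclidean on
planar projected coordinates in km — lon/lat must be projected upstream.

Prediction uses ordinary kriging (weights constrained to sum to one) on
a local neighborhood of nearest samples, and model quality is assessed
by leave-one-out cross-validation through standardized squared
prediction errors, which are approximately chi-square(1) under a
well-specified model (mean 1, median 0.455).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

NU_GRID_DEFAULT = (0.5, 1.5, 2.5)
NEIGHBORHOOD_DEFAULT = 64
#: fraction of the sill defining the practical (effective) range
PRACTICAL_FRACTION = 0.95
#: correlated fraction below which a fit is flagged pure nugget
PURE_NUGGET_FRACTION = 0.05


class GeostatError(ValueError):
    pass


class FitConvergenceError(GeostatError):
    """ML optimiser failed; carries the scipy diagnostics message."""


# ---------------------------------------------------------------------------
# Matérn correlation and semivariance
# ---------------------------------------------------------------------------

def matern_correlation(h: np.ndarray, range_param: float, nu: float) -> np.ndarray:
    """Matérn correlation rho(h) = 2^(1-nu)/Gamma(nu) * (h/a)^nu * K_nu(h/a).

    Half-integer smoothness uses the closed forms (nu=0.5 exponential,
    nu=1.5, nu=2.5); other nu go through the modified Bessel function.
    rho(0) = 1.
    """
    h = np.asarray(h, dtype=float)
    if range_param <= 0:
        raise GeostatError("range parameter must be positive")
    u = h / range_param
    if nu == 0.5:
        return np.exp(-u)
    if nu == 1.5:
        return (1.0 + u) * np.exp(-u)
    if nu == 2.5:
        return (1.0 + u + u * u / 3.0) * np.exp(-u)
    out = np.ones_like(u)
    pos = u > 0
    up = u[pos]
    out[pos] = (2.0 ** (1.0 - nu) / special.gamma(nu)) * up**nu * special.kv(nu, up)
    return out


@dataclass(frozen=True)
class VariogramModel:
    """Nugget + Matérn structure; semivariance saturates at nugget + partial_sill."""

    nugget: float
    partial_sill: float
    range_param: float  # km
    nu: float
    neg_loglik: float | None = None
    pure_nugget: bool = False

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def covariance(self, h: np.ndarray) -> np.ndarray:
        """C(h) for h > 0; the nugget contributes only at h = 0 exactly."""
        h = np.asarray(h, dtype=float)
        cov = self.partial_sill * matern_correlation(h, self.range_param, self.nu)
        return np.where(h == 0.0, self.sill, cov)

    def to_dict(self) -> dict:
        return {
            "nugget": self.nugget,
            "partial_sill": self.partial_sill,
            "range_km": self.range_param,
            "nu": self.nu,
            "effective_range_km": effective_range(self),
            "neg_loglik": self.neg_loglik,
            "pure_nugget": self.pure_nugget,
        }


def matern_semivariance(h: np.ndarray | float, model: VariogramModel) -> np.ndarray | float:
    """gamma(h); 0 at h = 0 by convention, jumping to the nugget at 0+."""
    h_arr = np.asarray(h, dtype=float)
    if np.any(h_arr < 0):
        raise GeostatError("lag distances must be non-negative")
    gamma = model.nugget + model.partial_sill * (
        1.0 - matern_correlation(h_arr, model.range_param, model.nu)
    )
    gamma = np.where(h_arr == 0.0, 0.0, gamma)
    return float(gamma) if np.isscalar(h) else gamma


def effective_range(model: VariogramModel, fraction: float = PRACTICAL_FRACTION) -> float | None:
    """Smallest h with gamma(h) >= nugget + fraction * partial_sill.

    For the exponential model (nu = 0.5) this is -a*log(1-fraction),
    i.e. about 3a at the conventional 95% level.  Undefined (None) for a
    pure-nugget model.
    """
    if model.partial_sill <= 0 or model.pure_nugget:
        return None

    def gap(h: float) -> float:
        return matern_correlation(np.array(h), model.range_param, model.nu) - (1.0 - fraction)

    hi = model.range_param
    while gap(hi) > 0:
        hi *= 2.0
        if hi > 1e9 * model.range_param:  # pragma: no cover - pathological nu
            return None
    return float(optimize.brentq(gap, 1e-12 * model.range_param, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# Empirical variogram
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmpiricalVariogram:
    lag_centers: np.ndarray  # km
    semivariances: np.ndarray
    pair_counts: np.ndarray


def _coords_values(samples: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    xy = samples[["x_km", "y_km"]].to_numpy(float)
    z = samples["value"].to_numpy(float)
    if not np.all(np.isfinite(xy)):
        raise GeostatError("non-finite coordinates")
    if not np.all(np.isfinite(z)):
        raise GeostatError("non-finite sample values")
    return xy, z


def empirical_variogram(
    samples: pd.DataFrame, lag_width: float = 10.0, max_dist: float | None = None
) -> EmpiricalVariogram:
    """Matheron estimator binned by distance.

    gamma_hat(bin) = sum over pairs (z_i - z_j)^2 / (2 N(bin)).  Default
    ``max_dist`` is one-third of the bounding-box diagonal; empty bins
    are dropped.  This is a diagnostic — model fitting is by ML, not by
    least squares on these bins.
    """
    if lag_width <= 0:
        raise GeostatError("lag_width must be positive")
    xy, z = _coords_values(samples)
    if len(z) < 2:
        raise GeostatError("need at least two samples")
    if max_dist is None:
        span = xy.max(axis=0) - xy.min(axis=0)
        max_dist = float(np.hypot(*span)) / 3.0
        if max_dist <= 0:
            max_dist = lag_width
    d = pdist(xy)
    dz2 = pdist(z[:, None], metric="sqeuclidean")
    keep = d <= max_dist
    if not keep.any():
        raise GeostatError("all sample pairs lie beyond max_dist")
    d, dz2 = d[keep], dz2[keep]
    edges = np.arange(0.0, max_dist + lag_width, lag_width)
    idx = np.clip(np.digitize(d, edges) - 1, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    sums = np.bincount(idx, weights=dz2, minlength=len(edges) - 1)
    nonempty = counts > 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    return EmpiricalVariogram(
        lag_centers=centers[nonempty],
        semivariances=sums[nonempty] / (2.0 * counts[nonempty]),
        pair_counts=counts[nonempty],
    )


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _profile_negloglik(
    dist: np.ndarray, z: np.ndarray, log_a: float, logit_rho: float, nu: float
) -> float:
    """Negative log-likelihood with constant mean and total sill profiled out.

    Parameterisation: correlation matrix K = rho*R(a) + (1-rho)*I where
    rho = c / (c0 + c); the total sill has closed-form MLE
    sigma2_hat = (z - mu_hat)' K^-1 (z - mu_hat) / n.
    """
    n = len(z)
    a = math.exp(log_a)
    rho = 1.0 / (1.0 + math.exp(-logit_rho))
    K = rho * matern_correlation(dist, a, nu)
    np.fill_diagonal(K, 1.0)
    try:
        L = np.linalg.cholesky(K)
    except np.linalg.LinAlgError:
        return 1e300
    logdet = 2.0 * float(np.sum(np.log(np.diagonal(L))))
    # solve L y = [z, 1] once
    rhs = np.column_stack([z, np.ones(n)])
    y = np.linalg.solve(L, rhs)
    zKz = float(y[:, 0] @ y[:, 0])
    oKo = float(y[:, 1] @ y[:, 1])
    zKo = float(y[:, 0] @ y[:, 1])
    mu = zKo / oKo
    quad = zKz - 2.0 * mu * zKo + mu * mu * oKo
    if quad <= 0:
        return 1e300
    sigma2 = quad / n
    return 0.5 * (n * math.log(sigma2) + logdet + n * (1.0 + math.log(2.0 * math.pi)))


def _init_from_empirical(samples: pd.DataFrame) -> tuple[float, float]:
    """Crude (log a, logit rho) start from the binned empirical variogram."""
    xy, z = _coords_values(samples)
    span = xy.max(axis=0) - xy.min(axis=0)
    diag = float(np.hypot(*span))
    try:
        ev = empirical_variogram(samples, lag_width=max(diag / 30.0, 1e-6))
        sill = float(np.var(z))
        if sill > 0 and len(ev.lag_centers) >= 3:
            target = ev.semivariances[0]
            rho0 = float(np.clip(1.0 - target / sill, 0.05, 0.95))
            # first lag where gamma reaches 95% of its plateau ~ effective range
            plateau = np.median(ev.semivariances[len(ev.semivariances) // 2 :])
            reach = ev.lag_centers[np.argmax(ev.semivariances >= 0.95 * plateau)]
            a0 = max(float(reach) / 3.0, diag / 100.0)
            return math.log(a0), math.log(rho0 / (1.0 - rho0))
    except GeostatError:
        pass
    return math.log(max(diag / 10.0, 1e-3)), 0.8


def fit_variogram_ml(
    samples: pd.DataFrame,
    nu_candidates: tuple[float, ...] = NU_GRID_DEFAULT,
    init: tuple[float, float] | None = None,
    maxfev: int = 200,
) -> VariogramModel:
    """Fit nugget, partial sill and range by maximum likelihood.

    One 2-D Nelder-Mead search per candidate smoothness; the model with
    the smallest negative log-likelihood wins.  ``init`` optionally
    supplies a (range_km, correlated_fraction) starting point.  A fit
    whose correlated fraction collapses below 5% of the variance is
    returned flagged ``pure_nugget``.
    """
    xy, z = _coords_values(samples)
    n = len(z)
    if n < 3:
        raise GeostatError("need at least three samples to fit a variogram")
    dist = squareform(pdist(xy))
    if init is not None:
        a0, rho0 = init
        rho0 = min(max(rho0, 1e-3), 1.0 - 1e-3)
        x0 = (math.log(a0), math.log(rho0 / (1.0 - rho0)))
    else:
        x0 = _init_from_empirical(samples)

    best: VariogramModel | None = None
    for nu in nu_candidates:
        res = optimize.minimize(
            lambda p: _profile_negloglik(dist, z, p[0], p[1], nu),
            x0=np.array(x0),
            method="Nelder-Mead",
            options={"xatol": 5e-3, "fatol": 1e-4, "maxfev": maxfev},
        )
        if not np.isfinite(res.fun) or res.fun >= 1e299:
            raise FitConvergenceError(f"ML fit failed for nu={nu}: {res.message}")
        log_a, logit_rho = res.x
        a = math.exp(log_a)
        rho = 1.0 / (1.0 + math.exp(-logit_rho))
        # recover the profiled total sill at the optimum
        K = rho * matern_correlation(dist, a, nu)
        np.fill_diagonal(K, 1.0)
        L = np.linalg.cholesky(K)
        rhs = np.column_stack([z, np.ones(n)])
        y = np.linalg.solve(L, rhs)
        mu = float(y[:, 0] @ y[:, 1]) / float(y[:, 1] @ y[:, 1])
        resid = y[:, 0] - mu * y[:, 1]
        sigma2 = float(resid @ resid) / n
        model = VariogramModel(
            nugget=(1.0 - rho) * sigma2,
            partial_sill=rho * sigma2,
            range_param=a,
            nu=nu,
            neg_loglik=float(res.fun),
            pure_nugget=rho < PURE_NUGGET_FRACTION,
        )
        # identifiability guard: if the fit beats the closed-form white-noise
        # likelihood by less than ~2 units, the correlated component is not
        # supported by the data — fold it into the nugget and flag
        s2_white = float(np.mean((z - z.mean()) ** 2))
        nll_white = 0.5 * n * (math.log(s2_white) + 1.0 + math.log(2.0 * math.pi))
        if res.fun > nll_white - 2.0:
            model = VariogramModel(
                nugget=s2_white,
                partial_sill=0.0,
                range_param=a,
                nu=nu,
                neg_loglik=min(float(res.fun), nll_white),
                pure_nugget=True,
            )
        if best is None or model.neg_loglik < best.neg_loglik:
            best = model
    assert best is not None
    if best.pure_nugget:
        logger.warning("variogram fit degenerated to a pure-nugget model")
    return best


# ---------------------------------------------------------------------------
# Ordinary kriging
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KrigingPrediction:
    x: float
    y: float
    estimate: float
    kriging_variance: float


DUPLICATE_JITTER = 1e-6


def _prepare_sample_arrays(
    model: VariogramModel, samples: pd.DataFrame, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    xy, z = _coords_values(samples)
    if model.nugget == 0.0:
        # duplicate coordinates make the covariance singular without a nugget
        _, inverse, counts = np.unique(
            xy.round(9), axis=0, return_inverse=True, return_counts=True
        )
        if (counts > 1).any():
            logger.info("jittering duplicate coordinates (no nugget to absorb them)")
            rng = rng or np.random.default_rng(0)
            dup = counts[inverse] > 1
            xy = xy.copy()
            xy[dup] += rng.uniform(-DUPLICATE_JITTER, DUPLICATE_JITTER, (int(dup.sum()), 2))
    return xy, z


def _ok_solve(
    model: VariogramModel,
    xy: np.ndarray,
    z: np.ndarray,
    targets: np.ndarray,
    neighborhood_size: int | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve the OK system per target; returns estimates, variances, weight-sum."""
    n = len(z)
    k_neigh = n if neighborhood_size is None else min(neighborhood_size, n)
    tree = cKDTree(xy)
    dists, idxs = tree.query(targets, k=k_neigh)
    if k_neigh == 1:
        dists, idxs = dists[:, None], idxs[:, None]
    estimates = np.empty(len(targets))
    variances = np.empty(len(targets))
    wsums = np.empty(len(targets))
    sill = model.sill
    for t in range(len(targets)):
        ind = idxs[t]
        sub_xy = xy[ind]
        m = len(ind)
        Dn = squareform(pdist(sub_xy)) if m > 1 else np.zeros((1, 1))
        C = model.covariance(Dn)
        np.fill_diagonal(C, sill)
        c0_vec = model.covariance(dists[t])
        A = np.empty((m + 1, m + 1))
        A[:m, :m] = C
        A[:m, m] = 1.0
        A[m, :m] = 1.0
        A[m, m] = 0.0
        b = np.empty(m + 1)
        b[:m] = c0_vec
        b[m] = 1.0
        try:
            sol = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise GeostatError(
                "singular kriging matrix; add a nugget or jitter duplicate points"
            ) from exc
        w, lam = sol[:m], sol[m]
        estimates[t] = float(w @ z[ind])
        variances[t] = max(float(sill - w @ c0_vec - lam), 0.0)
        wsums[t] = float(w.sum())
    return estimates, variances, wsums


def ordinary_kriging(
    model: VariogramModel,
    samples: pd.DataFrame,
    targets: np.ndarray | pd.DataFrame,
    neighborhood_size: int | None = NEIGHBORHOOD_DEFAULT,
) -> pd.DataFrame:
    """Predict at target locations from the nearest ``neighborhood_size`` samples.

    Returns a frame with x, y, estimate and kriging variance; weights sum
    to one by construction of the constrained system, and predictions at
    sample locations reproduce the data exactly (with zero variance when
    the nugget is zero).
    """
    if isinstance(targets, pd.DataFrame):
        tgt = targets[["x_km", "y_km"]].to_numpy(float)
    else:
        tgt = np.atleast_2d(np.asarray(targets, dtype=float))
    xy, z = _prepare_sample_arrays(model, samples)
    if neighborhood_size is not None and neighborhood_size < 1:
        raise GeostatError("neighborhood_size must be >= 1")
    est, var, _ = _ok_solve(model, xy, z, tgt, neighborhood_size)
    return pd.DataFrame(
        {"x_km": tgt[:, 0], "y_km": tgt[:, 1], "estimate": est, "kriging_variance": var}
    )


@dataclass
class CrossValidationReport:
    table: pd.DataFrame  # site_id, observed, predicted, kriging_variance, sspe
    mean_sspe: float
    median_sspe: float
    r_squared: float  # squared correlation observed vs LOO-predicted

    def to_dict(self) -> dict:
        return {
            "mean_sspe": self.mean_sspe,
            "median_sspe": self.median_sspe,
            "r_squared": self.r_squared,
            "n": int(len(self.table)),
        }


def loo_cross_validation(
    model: VariogramModel,
    samples: pd.DataFrame,
    neighborhood_size: int | None = NEIGHBORHOOD_DEFAULT,
) -> CrossValidationReport:
    """Leave-one-out kriging with a fixed fitted model.

    Each site is predicted from all others; the standardized squared
    prediction error theta_i = (z_i - zhat_i)^2 / sigma2_k,i should have
    mean ~1 and median ~0.455 (chi-square with 1 df) when the model is
    well specified.
    """
    xy, z = _prepare_sample_arrays(model, samples)
    n = len(z)
    if n < 3:
        raise GeostatError("need at least three samples for cross-validation")
    k_neigh = (n - 1) if neighborhood_size is None else min(neighborhood_size, n - 1)
    tree = cKDTree(xy)
    # query k+1 and drop self
    dists, idxs = tree.query(xy, k=k_neigh + 1)
    preds = np.empty(n)
    kvars = np.empty(n)
    for i in range(n):
        mask = idxs[i] != i
        ind = idxs[i][mask][:k_neigh]
        di = dists[i][mask][:k_neigh]
        sub_xy = xy[ind]
        C = model.covariance(squareform(pdist(sub_xy))) if len(ind) > 1 else np.zeros((1, 1))
        np.fill_diagonal(C, model.sill)
        c0_vec = model.covariance(di)
        m = len(ind)
        A = np.empty((m + 1, m + 1))
        A[:m, :m] = C
        A[:m, m] = 1.0
        A[m, :m] = 1.0
        A[m, m] = 0.0
        b = np.concatenate([c0_vec, [1.0]])
        sol = np.linalg.solve(A, b)
        w, lam = sol[:m], sol[m]
        preds[i] = w @ z[ind]
        kvars[i] = max(float(model.sill - w @ c0_vec - lam), 1e-300)
    sspe = (z - preds) ** 2 / kvars
    if np.std(preds) > 0 and np.std(z) > 0:
        r2 = float(np.corrcoef(z, preds)[0, 1] ** 2)
    else:
        r2 = 0.0
    site_ids = (
        samples["site_id"].to_numpy() if "site_id" in samples.columns else np.arange(n)
    )
    table = pd.DataFrame(
        {
            "site_id": site_ids,
            "observed": z,
            "predicted": preds,
            "kriging_variance": kvars,
            "sspe": sspe,
        }
    )
    return CrossValidationReport(
        table=table,
        mean_sspe=float(np.mean(sspe)),
        median_sspe=float(np.median(sspe)),
        r_squared=r2,
    )


def map_grid(
    model: VariogramModel,
    samples: pd.DataFrame,
    bbox: tuple[float, float, float, float] | None = None,
    resolution_km: float = 16.0,
    neighborhood_size: int | None = NEIGHBORHOOD_DEFAULT,
    mask=None,
) -> pd.DataFrame:
    """Krige every node of a regular grid covering ``bbox`` (xmin, ymin, xmax, ymax).

    ``mask``, if given, is a callable mask(x, y) -> bool array selecting
    nodes to keep (e.g. a territory polygon test).  Default bbox is the
    sample bounding box.
    """
    xy, _ = _coords_values(samples)
    if bbox is None:
        bbox = (xy[:, 0].min(), xy[:, 1].min(), xy[:, 0].max(), xy[:, 1].max())
    xmin, ymin, xmax, ymax = bbox
    if not (xmin <= xy[:, 0].min() and xmax >= xy[:, 0].max()):
        logger.warning("bbox does not contain all samples in x")
    xs = np.arange(xmin, xmax + resolution_km / 2, resolution_km)
    ys = np.arange(ymin, ymax + resolution_km / 2, resolution_km)
    gx, gy = np.meshgrid(xs, ys)
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    if mask is not None:
        keep = np.asarray(mask(nodes[:, 0], nodes[:, 1]), dtype=bool)
        nodes = nodes[keep]
    return ordinary_kriging(model, samples, nodes, neighborhood_size)
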