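"""Peak-based extraction: half-maximum density region + two-Gaussian EM.

When the joint density of (social weight, log estimate) splits into a peak
of resisting subjects (low ws) and a peak of conforming subjects (high ws),
the resisting peak's central estimate is an alternative to the omega-sweep.
The procedure:

1. smooth the points into a joint density (``density.smooth_2d``);
2. keep the points whose exact kernel density is at least half the grid
   maximum (the high-density zone);
3. fit a two-component bivariate Gaussian mixture to the kept points by EM,
   in coordinates standardized by the kernel bandwidths so both axes carry
   comparable scale;
4. hard-assign points to components, label the component with the smaller
   mean social weight "low-ws", and report each cluster's geometric mean of
   raw estimates plus a 95% probability ellipse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .core import DegenerateDataError, InvalidInputError, geometric_mean
from .density import DensityConfig, DensityGrid, smooth_2d

__all__ = ["MixtureModel", "Ellipse", "ClusterSummary",
           "high_density_points", "fit_two_gaussian_mixture",
           "cluster_summaries", "cluster_analysis"]

_LOG2PI = np.log(2 * np.pi)
_RIDGE = 1e-6
_DET_FLOOR = 1e-12


def high_density_points(grid: DensityGrid, points: np.ndarray) -> np.ndarray:
    """Boolean mask of points in the half-maximum density zone.

    Density is evaluated exactly via the kernel sum at each point (never by
    grid interpolation); the threshold is half the maximum over the grid.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 2:
        raise InvalidInputError("points must be (n, 2): (ws, y)")
    dens = grid.evaluate(pts[:, 0], pts[:, 1])
    return dens >= 0.5 * grid.max_density


@dataclass
class MixtureModel:
    """Two-component bivariate Gaussian mixture (maximum likelihood)."""

    means: np.ndarray          # (2, 2): component x (ws, y)
    covariances: np.ndarray    # (2, 2, 2)
    weights: np.ndarray        # (2,), sums to 1
    responsibilities: np.ndarray  # (n, 2), rows sum to 1
    log_likelihood: float
    log_likelihood_trace: np.ndarray
    n_iter: int
    converged: bool

    def hard_assignment(self) -> np.ndarray:
        return np.argmax(self.responsibilities, axis=1)


def _component_logpdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    cov = cov.copy()
    if np.linalg.det(cov) < _DET_FLOOR:
        warnings.warn("near-singular component covariance; adding ridge",
                      stacklevel=3)
        cov[np.diag_indices_from(cov)] += _RIDGE
    chol = np.linalg.cholesky(cov)
    diff = x - mean
    sol = np.linalg.solve(chol, diff.T).T
    maha = np.sum(sol * sol, axis=1)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (maha + logdet + 2 * _LOG2PI)


def _em_run(x: np.ndarray, rng: np.random.Generator,
            tol: float, max_iter: int) -> MixtureModel:
    n = x.shape[0]
    # initialize from two random points with the pooled covariance
    idx = rng.choice(n, size=2, replace=False)
    means = x[idx].copy()
    base_cov = np.cov(x, rowvar=False) + _RIDGE * np.eye(2)
    covs = np.stack([base_cov, base_cov])
    w = np.array([0.5, 0.5])
    trace = []
    prev_ll = -np.inf
    converged = False
    resp = np.full((n, 2), 0.5)
    for it in range(max_iter):
        # E step
        log_p = np.stack([np.log(w[c]) + _component_logpdf(x, means[c], covs[c])
                          for c in range(2)], axis=1)
        m = log_p.max(axis=1, keepdims=True)
        log_norm = m[:, 0] + np.log(np.exp(log_p - m).sum(axis=1))
        resp = np.exp(log_p - log_norm[:, None])
        ll = float(log_norm.sum())
        trace.append(ll)
        if ll - prev_ll < tol and it > 0:
            converged = True
            break
        prev_ll = ll
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        means = (resp.T @ x) / nk[:, None]
        for c in range(2):
            d = x - means[c]
            cov = (resp[:, c][:, None] * d).T @ d / nk[c]
            if np.linalg.det(cov) < _DET_FLOOR:
                warnings.warn("degenerate covariance in M step; adding ridge",
                              stacklevel=3)
                cov[np.diag_indices_from(cov)] += _RIDGE
            covs[c] = cov
    return MixtureModel(means=means, covariances=covs, weights=w,
                        responsibilities=resp, log_likelihood=trace[-1],
                        log_likelihood_trace=np.asarray(trace),
                        n_iter=len(trace), converged=converged)


def fit_two_gaussian_mixture(points, seed=0, n_init: int = 10,
                             tol: float = 1e-8,
                             max_iter: int = 500) -> MixtureModel:
    """Maximum-likelihood two-component Gaussian mixture by EM.

    Best of ``n_init`` random initializations (two random points as means,
    pooled covariance).  The log-likelihood is non-decreasing across EM
    iterations; near-singular covariances get a small diagonal ridge.
    """
    x = np.atleast_2d(np.asarray(points, dtype=float))
    if x.shape[0] < 4 or x.shape[1] != 2:
        raise InvalidInputError("need at least 4 bivariate points")
    if np.linalg.matrix_rank(x - x.mean(axis=0)) < 2:
        raise DegenerateDataError("points are collinear")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        model = _em_run(x, rng, tol=tol, max_iter=max_iter)
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    return best


@dataclass(frozen=True)
class Ellipse:
    """95% probability ellipse of a bivariate Gaussian component."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]   # major, minor
    angle: float                     # radians, major axis vs ws axis


def _ellipse(mean: np.ndarray, cov: np.ndarray, level: float = 0.95) -> Ellipse:
    q = chi2.ppf(level, df=2)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    axes = np.sqrt(np.maximum(evals, 0) * q)
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return Ellipse(center=(float(mean[0]), float(mean[1])),
                   semi_axes=(float(axes[0]), float(axes[1])), angle=angle)


@dataclass
class ClusterSummary:
    """One mixture component after hard assignment."""

    label: str                  # "low-ws" or "high-ws"
    members: tuple
    geometric_mean: float       # of members' raw estimates
    peak_value: float           # exp of the component's y mean
    ws_mean: float
    ws_sd: float
    ellipse: Ellipse
    mixing_proportion: float

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "members": list(self.members),
            "geometric_mean": self.geometric_mean,
            "peak_value": self.peak_value,
            "ws_mean": self.ws_mean,
            "ws_sd": self.ws_sd,
            "mixing_proportion": self.mixing_proportion,
            "ellipse": {"center": list(self.ellipse.center),
                        "semi_axes": list(self.ellipse.semi_axes),
                        "angle": self.ellipse.angle},
        }


def cluster_summaries(model: MixtureModel, points, estimates,
                      member_ids=None) -> tuple[ClusterSummary, ClusterSummary]:
    """(low-ws, high-ws) summaries after hard assignment.

    Points go to their maximum-responsibility component; the component with
    the smaller mean social weight is "low-ws" (ties broken by the smaller
    mean log estimate).  The cluster's central estimate is the geometric
    mean of its members' raw estimates; the exponentiated component mean of
    the log-estimate axis is reported alongside as ``peak_value``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    est = np.ravel(np.asarray(estimates, dtype=float))
    if member_ids is None:
        member_ids = np.arange(pts.shape[0], dtype=object)
    member_ids = np.asarray(member_ids, dtype=object)
    assign = model.hard_assignment()
    order = sorted(range(2), key=lambda c: (model.means[c, 0], model.means[c, 1]))
    out = []
    for rank, c in enumerate(order):
        mask = assign == c
        if not mask.any():
            raise DegenerateDataError("empty cluster after hard assignment")
        out.append(ClusterSummary(
            label="low-ws" if rank == 0 else "high-ws",
            members=tuple(member_ids[mask]),
            geometric_mean=geometric_mean(est[mask]),
            peak_value=float(np.exp(model.means[c, 1])),
            ws_mean=float(pts[mask, 0].mean()),
            ws_sd=float(pts[mask, 0].std(ddof=1)) if mask.sum() > 1 else 0.0,
            ellipse=_ellipse(model.means[c], model.covariances[c]),
            mixing_proportion=float(model.weights[c]),
        ))
    return out[0], out[1]


def cluster_analysis(weights, estimates, member_ids=None,
                     config: DensityConfig | None = None,
                     gamma_ws: float | None = None, seed=0,
                     n_init: int = 10) -> dict:
    """Full peak-based pipeline for one question.

    ``weights`` are social weights (array-like), ``estimates`` the matching
    raw round-1 estimates.  EM runs in bandwidth-standardized coordinates so
    the half-max zone and the mixture see the same geometry; all reported
    quantities are in raw coordinates.
    """
    config = config or DensityConfig()
    ws = np.ravel(np.asarray(weights, dtype=float))
    est = np.ravel(np.asarray(estimates, dtype=float))
    if np.any(est <= 0):
        raise InvalidInputError("estimates must be positive")
    y = np.log(est)
    if member_ids is None:
        member_ids = np.arange(ws.size, dtype=object)
    member_ids = np.asarray(member_ids, dtype=object)
    grid = smooth_2d(ws, y, config=config, gamma_ws=gamma_ws)
    pts = np.column_stack([ws, y])
    mask = high_density_points(grid, pts)
    sel = pts[mask]
    scale = np.array([grid.sigma_ws, grid.sigma_y])
    model_std = fit_two_gaussian_mixture(sel / scale, seed=seed, n_init=n_init)
    # de-standardize for reporting
    model = MixtureModel(
        means=model_std.means * scale,
        covariances=model_std.covariances * np.outer(scale, scale),
        weights=model_std.weights,
        responsibilities=model_std.responsibilities,
        log_likelihood=model_std.log_likelihood,
        log_likelihood_trace=model_std.log_likelihood_trace,
        n_iter=model_std.n_iter,
        converged=model_std.converged,
    )
    low, high = cluster_summaries(model, sel, est[mask],
                                  member_ids=member_ids[mask])
    return {"grid": grid, "selected_mask": mask, "model": model,
            "low": low, "high": high}
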