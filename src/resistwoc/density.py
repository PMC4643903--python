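"""Gaussian kernel smoothing with the resolution-coefficient bandwidth rule.

Both the 1D distribution of social weights and the joint density of
(social weight, log estimate) are smoothed with fixed-bandwidth Gaussian
kernels.  The bandwidth on each axis is

    sigma = sigma_hat * n**(-1/gamma)

with ``sigma_hat`` the sample SD of that coordinate and ``gamma`` the
*resolution coefficient*: larger gamma shrinks the bandwidth and reveals
finer structure (peaks of resisting vs conforming subjects).  For the 1D
social-weight density the SD entering the rule is computed after discarding
points outside an open trim interval (default (-1, 2)) so that extreme
outliers do not inflate the bandwidth; all points still contribute kernel
mass.  The 2D density uses an axis-aligned product kernel with an
independent bandwidth per axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DegenerateDataError, InvalidInputError

__all__ = ["DensityConfig", "Density1D", "DensityGrid",
           "bandwidth", "smooth_1d", "smooth_2d"]


@dataclass(frozen=True)
class DensityConfig:
    """Smoothing settings.

    gamma_y : resolution coefficient for the log-estimate axis (optimal 6).
    gamma_ws : resolution coefficient for the social-weight axis; the
        interesting range is 2 (coarse peaks) to 6 (fine).
    gamma_1d : coefficient for the 1D social-weight density (half the
        optimal value, 5/2, keeps only the main structure visible).
    trim_interval : open interval outside which points are ignored when
        estimating the 1D bandwidth SD.
    sigma_floor : lower bound on the sample SD so degenerate (constant)
        samples still get a positive bandwidth.
    grid_points : grid resolution per axis.
    grid_pad : grid extension beyond the data range, in bandwidths.
    """

    gamma_y: float = 6.0
    gamma_ws: float = 4.0
    gamma_1d: float = 2.5
    trim_interval: tuple[float, float] = (-1.0, 2.0)
    sigma_floor: float = 1e-6
    grid_points: int = 256
    grid_pad: float = 3.0

    def __post_init__(self) -> None:
        if min(self.gamma_y, self.gamma_ws, self.gamma_1d) <= 0:
            raise InvalidInputError("resolution coefficients must be positive")


def bandwidth(sample_sd: float, n: int, gamma: float) -> float:
    """Kernel bandwidth sigma_hat * n**(-1/gamma)."""
    if n < 2:
        raise InvalidInputError("need n >= 2 for a bandwidth")
    if gamma <= 0:
        raise InvalidInputError("gamma must be positive")
    if sample_sd <= 0:
        raise DegenerateDataError("sample SD must be positive")
    return float(sample_sd * n ** (-1.0 / gamma))


def _gauss_outer(grid: np.ndarray, data: np.ndarray, sigma: float) -> np.ndarray:
    """Matrix exp(-(grid_a - data_i)^2 / 2 sigma^2), shape (len(grid), n)."""
    d = (grid[:, None] - data[None, :]) / sigma
    return np.exp(-0.5 * d * d)


@dataclass
class Density1D:
    """Equal-weight Gaussian kernel density on a grid."""

    grid: np.ndarray
    f: np.ndarray
    sigma: float
    data: np.ndarray

    def evaluate(self, x) -> np.ndarray:
        """Exact kernel-sum density at arbitrary points."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        n = self.data.size
        k = _gauss_outer(x, self.data, self.sigma)
        return k.sum(axis=1) / (np.sqrt(2 * np.pi) * self.sigma * n)


def smooth_1d(values, config: DensityConfig | None = None,
              sigma: float | None = None) -> Density1D:
    """1D kernel density of social weights.

    The bandwidth comes from the SD of the values inside the open trim
    interval (tail values would otherwise dominate it) unless ``sigma``
    overrides it.  Every value, trimmed or not, contributes a kernel.
    """
    config = config or DensityConfig()
    data = np.ravel(np.asarray(values, dtype=float))
    if data.size < 2:
        raise InvalidInputError("need at least 2 values")
    if sigma is None:
        lo, hi = config.trim_interval
        trimmed = data[(data > lo) & (data < hi)]
        if trimmed.size < 2:
            raise DegenerateDataError(
                "fewer than 2 values inside the bandwidth trim interval")
        sd = max(float(trimmed.std(ddof=1)), config.sigma_floor)
        sigma = bandwidth(sd, data.size, config.gamma_1d)
    lo, hi = data.min() - config.grid_pad * sigma, data.max() + config.grid_pad * sigma
    grid = np.linspace(lo, hi, config.grid_points)
    dens = Density1D(grid=grid, f=np.empty(0), sigma=float(sigma), data=data)
    dens.f = dens.evaluate(grid)
    return dens


@dataclass
class DensityGrid:
    """Joint kernel density of (social weight, log estimate) on a grid.

    ``f[i, j]`` is the density at (ws_axis[i], y_axis[j]).  The original
    points and bandwidths are kept so the density can be evaluated exactly
    (kernel sum) at arbitrary locations, e.g. at the data points themselves
    for half-maximum selection.
    """

    ws_axis: np.ndarray
    y_axis: np.ndarray
    f: np.ndarray
    sigma_ws: float
    sigma_y: float
    ws_data: np.ndarray = field(repr=False, default=None)
    y_data: np.ndarray = field(repr=False, default=None)

    @property
    def max_density(self) -> float:
        return float(self.f.max())

    def evaluate(self, ws, y) -> np.ndarray:
        """Exact product-kernel density at points (ws, y)."""
        ws = np.atleast_1d(np.asarray(ws, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        n = self.ws_data.size
        dw = (ws[:, None] - self.ws_data[None, :]) / self.sigma_ws
        dy = (y[:, None] - self.y_data[None, :]) / self.sigma_y
        k = np.exp(-0.5 * (dw * dw + dy * dy)).sum(axis=1)
        return k / (2 * np.pi * self.sigma_ws * self.sigma_y * n)

    def to_frame(self):
        """Long-format (ws, y, f) table for export."""
        import pandas as pd
        w, y = np.meshgrid(self.ws_axis, self.y_axis, indexing="ij")
        return pd.DataFrame({"ws": w.ravel(), "y": y.ravel(), "f": self.f.ravel()})


def smooth_2d(ws_values, y_values,
              config: DensityConfig | None = None,
              gamma_ws: float | None = None) -> DensityGrid:
    """Joint density of social weight and log estimate.

    Product Gaussian kernel with independent bandwidths per axis, each from
    the full-sample SD of that coordinate (no trimming in 2D).  ``gamma_ws``
    overrides the config's social-weight resolution, which is the knob swept
    when looking for separate peaks.
    """
    config = config or DensityConfig()
    ws = np.ravel(np.asarray(ws_values, dtype=float))
    y = np.ravel(np.asarray(y_values, dtype=float))
    if ws.size != y.size:
        raise InvalidInputError("ws and y must have the same length")
    if ws.size < 2:
        raise InvalidInputError("need at least 2 points")
    n = ws.size
    g_ws = config.gamma_ws if gamma_ws is None else gamma_ws
    sd_ws = max(float(ws.std(ddof=1)), config.sigma_floor)
    sd_y = max(float(y.std(ddof=1)), config.sigma_floor)
    s_ws = bandwidth(sd_ws, n, g_ws)
    s_y = bandwidth(sd_y, n, config.gamma_y)
    pad = config.grid_pad
    ws_axis = np.linspace(ws.min() - pad * s_ws, ws.max() + pad * s_ws, config.grid_points)
    y_axis = np.linspace(y.min() - pad * s_y, y.max() + pad * s_y, config.grid_points)
    # separable kernel: f = Gw @ Gy.T up to the normalizing constant
    gw = _gauss_outer(ws_axis, ws, s_ws)
    gy = _gauss_outer(y_axis, y, s_y)
    f = gw @ gy.T / (2 * np.pi * s_ws * s_y * n)
    return DensityGrid(ws_axis=ws_axis, y_axis=y_axis, f=f,
                       sigma_ws=s_ws, sigma_y=s_y, ws_data=ws, y_data=y)
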