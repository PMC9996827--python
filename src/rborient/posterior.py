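"""Posterior summaries: toroidal KDE, HPD regions, intervals and bands.

Orientation samples live on a 2-torus in (theta, phi); densities are
estimated on a regular periodic grid by diffusing the sample histogram
with a wrapped Gaussian kernel (heat-kernel smoothing via FFT), which is
exactly periodic and mass-conserving.  Highest-posterior-density regions
are super-level sets found by sorting grid cells by density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .inference import MCMCChain, wrap_angle

__all__ = ["OrientationDensity", "HPDRegionSet", "kde_torus", "histogram2d",
           "hpd_regions", "univariate_interval", "profile_bands",
           "density_at", "region_contains"]

PERIOD = 360.0


@dataclass
class OrientationDensity:
    """A normalized probability density on the (theta, phi) torus.

    ``density[i, j]`` is the density (deg^-2) at
    ``(theta_centers[i], phi_centers[j])``; cells are square with area
    ``cell_area`` deg^2 and the density integrates to 1.
    """

    theta_centers: np.ndarray
    phi_centers: np.ndarray
    density: np.ndarray

    @property
    def cell_area(self) -> float:
        step = self.theta_centers[1] - self.theta_centers[0]
        return float(step * step)

    def total_mass(self) -> float:
        return float(self.density.sum() * self.cell_area)


@dataclass
class HPDRegionSet:
    """Nested highest-posterior-density regions at several levels."""

    levels: tuple[float, ...]
    masks: dict[float, np.ndarray]
    areas: dict[float, float]  # deg^2
    masses: dict[float, float]
    theta_centers: np.ndarray
    phi_centers: np.ndarray


def _grid_centers(grid_deg: float) -> np.ndarray:
    n = int(round(PERIOD / grid_deg))
    if abs(n * grid_deg - PERIOD) > 1e-9:
        raise ValueError("grid_deg must divide 360")
    return -PERIOD / 2 + grid_deg * (np.arange(n) + 0.5)


def _bin_periodic(values: np.ndarray, grid_deg: float) -> np.ndarray:
    n = int(round(PERIOD / grid_deg))
    idx = np.floor((wrap_angle(values) + PERIOD / 2) / grid_deg).astype(int)
    return np.clip(idx, 0, n - 1)


def _circular_std(samples_deg: np.ndarray) -> float:
    ang = np.radians(samples_deg)
    r = np.hypot(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
    r = min(max(r, 1e-12), 1.0 - 1e-12)
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))


def kde_torus(samples: np.ndarray, grid_deg: float = 1.0,
              bandwidth: tuple[float, float] | None = None) -> OrientationDensity:
    """Kernel density estimate of (theta, phi) samples on the torus.

    The sample histogram on a fine periodic grid is evolved under the
    heat equation (wrapped-Gaussian convolution via FFT) to a diffusion
    time set per axis by a plug-in bandwidth: Silverman's rule on the
    circular standard deviation, ``h = sigma_c * n^(-1/6)`` for a 2D
    estimate.  Pass ``bandwidth=(h_theta, h_phi)`` in degrees to
    override.  Requires at least 100 samples for a stable bandwidth.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 2:
        raise ValueError("samples must be an (n, 2) array of (theta, phi)")
    n_samples = len(samples)
    if n_samples < 100:
        raise ValueError("need >= 100 samples for a reliable bandwidth")
    centers = _grid_centers(grid_deg)
    n = len(centers)
    hist = np.zeros((n, n))
    it = _bin_periodic(samples[:, 0], grid_deg)
    ip = _bin_periodic(samples[:, 1], grid_deg)
    np.add.at(hist, (it, ip), 1.0)
    if bandwidth is None:
        h_t = max(_circular_std(samples[:, 0]) * n_samples ** (-1 / 6), grid_deg)
        h_p = max(_circular_std(samples[:, 1]) * n_samples ** (-1 / 6), grid_deg)
    else:
        h_t, h_p = bandwidth
    freqs = np.fft.fftfreq(n, d=grid_deg)
    kern_t = np.exp(-2.0 * (np.pi * freqs * h_t) ** 2)
    kern_p = np.exp(-2.0 * (np.pi * freqs * h_p) ** 2)
    smoothed = np.fft.ifft2(np.fft.fft2(hist) * np.outer(kern_t, kern_p)).real
    smoothed = np.clip(smoothed, 0.0, None)
    cell_area = grid_deg * grid_deg
    smoothed /= smoothed.sum() * cell_area
    return OrientationDensity(theta_centers=centers, phi_centers=centers,
                              density=smoothed)


def histogram2d(samples: np.ndarray, bin_width: float = 5.0):
    """Periodic 2D histogram of (theta, phi) samples.

    ``bin_width`` must divide 360; a sample at exactly -180 falls in the
    first bin (half-open convention).  Returns ``(edges, counts)``.
    """
    if abs(round(PERIOD / bin_width) * bin_width - PERIOD) > 1e-9:
        raise ValueError("bin_width must divide 360")
    samples = np.asarray(samples, dtype=float)
    n = int(round(PERIOD / bin_width))
    counts = np.zeros((n, n))
    it = _bin_periodic(samples[:, 0], bin_width)
    ip = _bin_periodic(samples[:, 1], bin_width)
    np.add.at(counts, (it, ip), 1.0)
    edges = -PERIOD / 2 + bin_width * np.arange(n + 1)
    return edges, counts


def hpd_regions(density: OrientationDensity,
                levels: tuple[float, ...] = (0.25, 0.65, 0.95)) -> HPDRegionSet:
    """Highest-posterior-density regions of a gridded density.

    For each level the density is thresholded at the smallest value
    whose super-level set encloses at least that much mass: grid cells
    are sorted by density (descending, ties broken by cell index) and
    accumulated.  Regions are nested across levels by construction.
    """
    if abs(density.total_mass() - 1.0) > 1e-6:
        raise ValueError("density must be normalized to unit mass")
    flat = density.density.ravel()
    order = np.argsort(-flat, kind="stable")
    cum = np.cumsum(flat[order]) * density.cell_area
    masks, areas, masses = {}, {}, {}
    for level in sorted(levels):
        if not 0.0 < level < 1.0:
            raise ValueError("levels must lie in (0, 1)")
        k = int(np.searchsorted(cum, level)) + 1
        mask = np.zeros(flat.shape, dtype=bool)
        mask[order[:k]] = True
        masks[level] = mask.reshape(density.density.shape)
        areas[level] = float(k * density.cell_area)
        masses[level] = float(cum[k - 1])
    return HPDRegionSet(levels=tuple(sorted(levels)), masks=masks, areas=areas,
                        masses=masses, theta_centers=density.theta_centers,
                        phi_centers=density.phi_centers)


def density_at(density: OrientationDensity, theta: float, phi: float) -> float:
    """Density value at an arbitrary (theta, phi), nearest-cell lookup."""
    step = density.theta_centers[1] - density.theta_centers[0]
    it = _bin_periodic(np.array([theta]), step)[0]
    ip = _bin_periodic(np.array([phi]), step)[0]
    return float(density.density[it, ip])


def region_contains(regions: HPDRegionSet, level: float,
                    theta: float, phi: float) -> bool:
    """Whether the HPD region at a level covers the cell of (theta, phi)."""
    step = regions.theta_centers[1] - regions.theta_centers[0]
    it = _bin_periodic(np.array([theta]), step)[0]
    ip = _bin_periodic(np.array([phi]), step)[0]
    return bool(regions.masks[level][it, ip])


def region_boundary_points(regions: HPDRegionSet, level: float) -> np.ndarray:
    """(theta, phi) coordinates of the cells on a region's boundary.

    Boundary cells are mask cells with at least one (periodic) neighbour
    outside the mask; suitable for plotting region outlines.
    """
    mask = regions.masks[level]
    inside_all = np.ones_like(mask)
    for shift in (1, -1):
        for axis in (0, 1):
            inside_all &= np.roll(mask, shift, axis=axis)
    boundary = mask & ~inside_all
    it, ip = np.nonzero(boundary)
    return np.column_stack([regions.theta_centers[it],
                            regions.phi_centers[ip]])


def univariate_interval(samples: np.ndarray) -> tuple[float, float]:
    """Mean +- standard deviation summary of a scalar marginal.

    Used for the roughly Gaussian Gamma and penetration marginals; warns
    on a constant chain (zero-width interval).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples")
    std = float(samples.std(ddof=1))
    if std == 0.0:
        warnings.warn("constant chain: zero-width interval", stacklevel=2)
    return float(samples.mean()), std


def profile_bands(chain: MCMCChain, evaluator, abscissa: np.ndarray,
                  n_draws: int = 3000, level: float = 0.65,
                  rng: np.random.Generator | None = None):
    """Pointwise credible band of a curve over posterior draws.

    Draws ``n_draws`` post-burn-in states, evaluates
    ``evaluator(params) -> y(abscissa)`` for each and returns
    ``(lower, upper)`` envelopes covering the central ``level`` mass at
    every abscissa via interpolated percentiles.  States on which the
    evaluator fails are dropped with a warning, never silently replaced.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    post = chain.posterior
    if len(post) < n_draws:
        raise ValueError("post-burn-in chain shorter than n_draws")
    idx = rng.choice(len(post), size=n_draws, replace=False)
    curves, n_failed = [], 0
    for i in idx:
        try:
            curves.append(np.asarray(evaluator(post[i])))
        except Exception:  # noqa: BLE001 - evaluator failures are reported
            n_failed += 1
    if n_failed:
        warnings.warn(f"{n_failed}/{n_draws} posterior draws failed evaluation "
                      "and were dropped", stacklevel=2)
    if not curves:
        raise ValueError("all posterior draws failed evaluation")
    stack = np.vstack(curves)
    half = 100.0 * level / 2.0
    lower = np.percentile(stack, 50.0 - half, axis=0)
    upper = np.percentile(stack, 50.0 + half, axis=0)
    return lower, upper
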