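"""Molecular footprint areas of an oriented protein at the interface.

The footprint is the area the rotated protein projects onto the
interfacial (x, y) plane: a convex-hull estimate, a concave alpha-shape
estimate for molecules with reentrant outlines, and the area per
molecule implied by the measured surface excess Gamma,
``APM = MWT / (N_A * Gamma)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError, cKDTree
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

from .scattering import AVOGADRO
from .slabs import AdsorptionState, rotate_model
from .structure import ProteinModel

__all__ = ["FootprintResult", "convex_footprint", "concave_footprint",
           "apm_from_gamma", "footprint", "footprint_sweep",
           "FragmentedShapeError", "default_alpha"]


class FragmentedShapeError(ValueError):
    """The alpha-shape broke into disconnected fragments."""


@dataclass(frozen=True)
class FootprintResult:
    """Footprint areas (A^2) for one oriented state."""

    apm_convex: float
    apm_concave: float
    apm_gamma: float
    coverage: float  # projected (concave) area / Gamma-implied area


def _projected(model: ProteinModel, state: AdsorptionState | None) -> np.ndarray:
    if state is None:
        return model.positions[:, :2]
    return rotate_model(model, state.orientation)[:, :2]


def convex_footprint(model: ProteinModel,
                     state: AdsorptionState | None = None) -> float:
    """Area (A^2) of the convex hull of the xy-projected residues."""
    points = _projected(model, state)
    try:
        hull = ConvexHull(points)
    except QhullError as exc:
        raise ValueError("projected beads are collinear; no 2D hull") from exc
    return float(hull.volume)  # in 2D, .volume is the enclosed area


def default_alpha(points_2d: np.ndarray) -> float:
    """Probe radius: twice the median nearest-neighbour distance."""
    tree = cKDTree(points_2d)
    dists, _ = tree.query(points_2d, k=2)
    return 2.0 * float(np.median(dists[:, 1]))


def concave_footprint(model: ProteinModel, alpha: float | None = None,
                      state: AdsorptionState | None = None) -> float:
    """Area (A^2) enclosed by the alpha-shape of the projected residues.

    Delaunay triangles with circumradius below ``alpha`` are kept and
    their union taken; as ``alpha`` grows the result converges to the
    convex hull.  An alpha small enough to fragment the shape raises
    :class:`FragmentedShapeError` reporting the fragment count.
    """
    points = _projected(model, state)
    if len(points) < 3:
        raise ValueError("need at least 3 beads for a footprint")
    if alpha is None:
        alpha = default_alpha(points)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    try:
        tri = Delaunay(points)
    except QhullError as exc:
        raise ValueError("projected beads are collinear; no triangulation") from exc
    a, b, c = (points[tri.simplices[:, k]] for k in range(3))
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    cross = np.abs((b - a)[:, 0] * (c - a)[:, 1] - (b - a)[:, 1] * (c - a)[:, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        circumradius = np.where(cross > 0, la * lb * lc / (2.0 * cross), np.inf)
    keep = tri.simplices[circumradius < alpha]
    if len(keep) == 0:
        raise FragmentedShapeError("alpha too small: no triangles survive")
    shape = unary_union([Polygon(points[s]) for s in keep])
    if isinstance(shape, MultiPolygon):
        raise FragmentedShapeError(
            f"alpha too small: shape fragments into {len(shape.geoms)} parts")
    return float(shape.area)


def apm_from_gamma(mwt: float, gamma: float) -> float:
    """Area per molecule (A^2) from MWT (Da) and Gamma (mg/m^2)."""
    if mwt <= 0:
        raise ValueError("molecular weight must be positive")
    if gamma <= 0:
        raise ValueError("gamma must be positive (zero implies infinite area)")
    gamma_g_per_cm2 = gamma * 1e-7
    return mwt / (AVOGADRO * gamma_g_per_cm2) * 1e16


def footprint(model: ProteinModel, state: AdsorptionState,
              alpha: float | None = None) -> FootprintResult:
    """All three footprint measures for one adsorbed state."""
    convex = convex_footprint(model, state)
    concave = concave_footprint(model, alpha=alpha, state=state)
    apm_g = apm_from_gamma(model.mwt, state.gamma)
    return FootprintResult(apm_convex=convex, apm_concave=concave,
                           apm_gamma=apm_g, coverage=concave / apm_g)


def footprint_sweep(model: ProteinModel, thetas: np.ndarray, phis: np.ndarray,
                    alpha: float | None = None) -> np.ndarray:
    """Footprint areas over an orientation grid.

    Returns a structured array with columns
    (theta, phi, apm_convex, apm_concave) for CSV export.
    """
    from .slabs import Orientation

    rows = []
    for theta in thetas:
        for phi in phis:
            st = AdsorptionState(orientation=Orientation(theta, phi), gamma=1.0)
            try:
                concave = concave_footprint(model, alpha=alpha, state=st)
            except FragmentedShapeError:
                concave = np.nan
            rows.append((theta, phi, convex_footprint(model, st), concave))
    return np.array(rows, dtype=[("theta", float), ("phi", float),
                                 ("apm_convex", float), ("apm_concave", float)])
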