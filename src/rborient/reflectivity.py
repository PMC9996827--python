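"""Specular reflectivity from slab profiles and multi-contrast chi-squared.

The kernel is the standard characteristic-matrix (Abeles) recursion for
a stack of uniform slabs between two semi-infinite media.  SLD inputs
are in 1e-6 A^-2, momentum transfer Q in A^-1.  The neutron arrives
through the substrate-side medium, matching the interfacial-adsorption
geometry where air or oil is the fronting phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scattering import SolventSpec
from .slabs import AdsorptionState, SlabProfile, SliceConfig, assemble_profile

__all__ = [
    "ReflectivityCurve", "ContrastDefinition", "abeles",
    "reflectivity_from_profile", "fresnel_reflectivity",
    "simulate_contrast", "chi_squared", "load_curve", "save_curve",
]


@dataclass
class ReflectivityCurve:
    """One contrast's reflectivity data: (Q, R, dR[, dQ])."""

    q: np.ndarray
    r: np.ndarray
    dr: np.ndarray | None = None
    dq: np.ndarray | None = None
    contrast_name: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if np.any(np.diff(self.q) <= 0) or np.any(self.q <= 0):
            raise ValueError("q must be positive and strictly increasing")
        if self.dr is not None:
            self.dr = np.asarray(self.dr, dtype=float)
            if np.any(self.dr[np.isfinite(self.dr)] <= 0):
                raise ValueError("dr must be positive where present")
        if self.dq is not None:
            self.dq = np.asarray(self.dq, dtype=float)


@dataclass
class ContrastDefinition:
    """Measurement conditions for one isotopic contrast."""

    name: str
    solvent: SolventSpec
    substrate_sld: float = 0.0  # 1e-6 A^-2; 0 for air
    q_grid: np.ndarray = field(default_factory=lambda: np.geomspace(0.012, 0.4, 60))
    dq_over_q: float = 0.0  # Gaussian resolution sigma(Q)/Q
    scale: float = 1.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.background < 0:
            raise ValueError("background must be >= 0")


def _abeles_kernel(q: np.ndarray, layer_slds: np.ndarray,
                   d: np.ndarray) -> np.ndarray:
    """Characteristic-matrix recursion; scalar loop suitable for JIT."""
    nq = q.shape[0]
    n_layers = layer_slds.shape[0]
    out = np.empty(nq)
    for iq in range(nq):
        kz0_sq = (q[iq] / 2.0) ** 2 + 0j
        kz_j = np.sqrt(kz0_sq)
        m00 = 1.0 + 0j
        m01 = 0j
        m10 = 0j
        m11 = 1.0 + 0j
        for j in range(n_layers - 1):
            kz_next = np.sqrt(kz0_sq - 4.0 * np.pi * (layer_slds[j + 1] - layer_slds[0]))
            denom = kz_j + kz_next
            rj = (kz_j - kz_next) / denom if abs(denom) > 0 else 0j
            beta = kz_j * d[j]
            ep = np.exp(1j * beta)
            em = np.exp(-1j * beta)
            a01 = rj * ep
            a10 = rj * em
            m00, m01, m10, m11 = (m00 * ep + m01 * a10, m00 * a01 + m01 * em,
                                  m10 * ep + m11 * a10, m10 * a01 + m11 * em)
            kz_j = kz_next
        out[iq] = abs(m10 / m00) ** 2 if abs(m00) > 0 else 1.0
    return out


try:  # JIT-compile the hot loop when numba is present
    from numba import njit

    _abeles_kernel = njit(cache=False, fastmath=False)(_abeles_kernel)
except ImportError:  # pragma: no cover - numba is an optional accelerator
    pass


def abeles(q: np.ndarray, slds: np.ndarray, thicknesses: np.ndarray,
           sld_fronting: float, sld_backing: float) -> np.ndarray:
    """Specular reflectivity of a slab stack via the optical matrix method.

    Parameters are in 1e-6 A^-2 (SLDs) and A (thicknesses); ``slds`` may
    be complex to include absorption.  The wavevector in each layer is
    referenced to the fronting medium through which the beam arrives.
    Returns R(q) in [0, 1].
    """
    q = np.ascontiguousarray(q, dtype=float)
    layer_slds = np.concatenate(
        ([sld_fronting], np.atleast_1d(slds), [sld_backing])).astype(complex) * 1e-6
    d = np.concatenate(([0.0], np.atleast_1d(thicknesses), [0.0]))
    refl = _abeles_kernel(q, layer_slds, d)
    return np.clip(np.nan_to_num(refl, nan=1.0), 0.0, 1.0)


def fresnel_reflectivity(q: np.ndarray, sld_fronting: float,
                         sld_backing: float) -> np.ndarray:
    """Closed-form Fresnel reflectivity of a single sharp interface."""
    q = np.asarray(q, dtype=float)
    kz0 = (q / 2.0).astype(complex)
    kz1 = np.sqrt(kz0 ** 2 - 4.0 * np.pi * (sld_backing - sld_fronting) * 1e-6)
    return np.abs((kz0 - kz1) / (kz0 + kz1)) ** 2


def reflectivity_from_profile(profile: SlabProfile, q: np.ndarray,
                              dq: np.ndarray | None = None,
                              n_gauss: int = 17, gauss_width: float = 3.5) -> np.ndarray:
    """Reflectivity of a slab profile, optionally Gaussian-smeared in Q.

    ``dq`` is the 1-sigma resolution width per point; smearing uses a
    fixed-node Gaussian quadrature over ``+- gauss_width`` sigma.
    """
    q = np.asarray(q, dtype=float)
    if np.any(np.diff(q) <= 0):
        raise ValueError("q grid must be strictly increasing")
    thicknesses = np.full(profile.n_slices, profile.thickness)

    def kernel(qv: np.ndarray) -> np.ndarray:
        return abeles(qv, profile.sld_slice, thicknesses,
                      profile.sld_substrate, profile.sld_solvent)

    if dq is None or np.all(np.asarray(dq) == 0):
        return kernel(q)
    dq = np.broadcast_to(np.asarray(dq, dtype=float), q.shape)
    x = np.linspace(-gauss_width, gauss_width, n_gauss)
    w = np.exp(-0.5 * x ** 2)
    w /= w.sum()
    q_samples = np.clip(q[:, None] + dq[:, None] * x[None, :], 1e-6, None)
    r_samples = kernel(q_samples.ravel()).reshape(q_samples.shape)
    return r_samples @ w


def simulate_contrast(model, state: AdsorptionState,
                      contrast: ContrastDefinition,
                      config: SliceConfig = SliceConfig(),
                      extra_rotation: np.ndarray | None = None) -> ReflectivityCurve:
    """Forward-model one contrast: profile -> reflectivity -> scale/background."""
    profile = assemble_profile(model, state, config, contrast.solvent,
                               contrast.substrate_sld,
                               extra_rotation=extra_rotation)
    q = contrast.q_grid
    dq = contrast.dq_over_q * q if contrast.dq_over_q > 0 else None
    r = reflectivity_from_profile(profile, q, dq)
    scale = contrast.scale * state.scale
    background = contrast.background + state.background
    return ReflectivityCurve(q=q, r=scale * r + background, dq=dq,
                             contrast_name=contrast.name)


def chi_squared(simulated, observed) -> float:
    """Summed chi-squared over one or more contrasts.

    ``simulated`` and ``observed`` are matching curves or lists of
    curves; each observed point must carry ``dr > 0`` and grids must
    agree exactly (no implicit interpolation).
    """
    if isinstance(simulated, ReflectivityCurve):
        simulated, observed = [simulated], [observed]
    total = 0.0
    for sim, obs in zip(simulated, observed, strict=True):
        if obs.dr is None:
            raise ValueError("observed curve lacks uncertainties dr")
        if len(sim.q) != len(obs.q) or not np.allclose(sim.q, obs.q):
            raise ValueError("q grids differ; resample before chi_squared")
        total += float(np.sum(((sim.r - obs.r) / obs.dr) ** 2))
    return total


def load_curve(path, contrast_name: str = "") -> ReflectivityCurve:
    """Read 3/4-column (Q, R, dR[, dQ]) whitespace text.

    Lines starting with '#' are comments; ORSO ``.ort`` header blocks are
    skipped the same way.
    """
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 3:
        raise ValueError(f"{path}: expected at least 3 columns (Q, R, dR)")
    return ReflectivityCurve(
        q=data[:, 0], r=data[:, 1], dr=data[:, 2],
        dq=data[:, 3] if data.shape[1] > 3 else None,
        contrast_name=contrast_name)


def save_curve(curve: ReflectivityCurve, path) -> None:
    """Write a curve in the 4-column (Q, R, dR, dQ) text dialect."""
    dr = curve.dr if curve.dr is not None else np.zeros_like(curve.q)
    dq = curve.dq if curve.dq is not None else np.zeros_like(curve.q)
    header = f"contrast: {curve.contrast_name}\nQ_A^-1 R dR dQ_A^-1"
    np.savetxt(path, np.column_stack([curve.q, curve.r, dr, dq]), header=header)
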