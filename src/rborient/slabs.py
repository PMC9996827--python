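"""Rigid-body rotation and slab SLD profiles.

The canonicalized protein is rotated by two Euler angles, boxed by its
coordinate extents, and cut along z into equal slices.  Each residue is
binned wholly into the slice containing its representative z coordinate.
Slice SLDs mix the protein contribution with the bulk (solvent above the
interface, substrate below it), with the overall protein volume fraction
tied to the surface excess Gamma.

Coordinate convention: +z points from the substrate (air or oil) into
the aqueous solvent.  The interface plane sits at
``z_interface = min_z(protein) + z_pen``, so ``z_pen = 0`` leaves the
protein entirely immersed in the solvent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .scattering import SolventSpec, protein_density
from .structure import ProteinModel

__all__ = [
    "Orientation", "AdsorptionState", "SliceConfig", "SlabProfile",
    "PackingError", "rotation_matrix", "rotate_model", "slice_protein",
    "bulk_sld", "rho_total_from_gamma", "assemble_profile",
    "penetrated_fraction", "profile_sld_at", "profile_to_text",
]

BOX_PAD = 2.0  # A per side on the in-plane box extents


class PackingError(ValueError):
    """Gamma implies per-slice protein occupancy above unity."""


@dataclass(frozen=True)
class Orientation:
    """Two-angle rigid-body orientation (degrees).

    In the primary ``XY`` mode the protein is actively rotated by theta
    about the x-axis and then by phi about the y-axis (right-handed); the
    composite matrix is ``R_y(phi) @ R_x(theta)``.  The alternative
    ``ZY`` mode rotates first about z, then about y.
    """

    theta: float = 0.0
    phi: float = 0.0
    mode: str = "XY"

    def __post_init__(self) -> None:
        if self.mode not in ("XY", "ZY"):
            raise ValueError("mode must be 'XY' or 'ZY'")
        if not (np.isfinite(self.theta) and np.isfinite(self.phi)):
            raise ValueError("angles must be finite")


@dataclass
class AdsorptionState:
    """The fitted description of an adsorbed rigid protein."""

    orientation: Orientation = field(default_factory=Orientation)
    z_pen: float = 0.0  # A, penetration past the interface into the substrate
    gamma: float = 0.0  # mg/m^2, adsorbed mass per unit area
    scale: float = 1.0  # per-contrast reflectivity multiplier
    background: float = 0.0  # per-contrast additive reflectivity

    def __post_init__(self) -> None:
        if self.z_pen < 0:
            raise ValueError("z_pen must be >= 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")

    def symmetric_image(self) -> "AdsorptionState":
        """The 180-degree rotated partner state (theta+180, phi+180).

        For proteins with a mirror-symmetric mass distribution this
        produces the same z-profile; for real proteins it is the
        near-degenerate "flipped" orientation.
        """
        from .inference import wrap_angle
        o = self.orientation
        return replace(self, orientation=Orientation(
            wrap_angle(o.theta + 180.0), wrap_angle(o.phi + 180.0), o.mode))

    def gauge_image(self) -> "AdsorptionState":
        """The exactly z-profile-equivalent state (theta+180, 180-phi).

        In the XY rotation system the projection of any point onto z is
        unchanged by this map, so the two parameter points describe the
        identical physical profile: the parametrization double-covers
        profile space.
        """
        from .inference import wrap_angle
        o = self.orientation
        return replace(self, orientation=Orientation(
            wrap_angle(o.theta + 180.0), wrap_angle(180.0 - o.phi), o.mode))


@dataclass(frozen=True)
class SliceConfig:
    """Slicing of the bounding box along z."""

    n_slices: int = 50

    def __post_init__(self) -> None:
        if self.n_slices < 2:
            raise ValueError("n_slices must be >= 2")


@dataclass
class SlabProfile:
    """An ordered stack of equal-thickness slices with per-slice SLD.

    Slices run from low z (substrate side) to high z (solvent side);
    SLDs are in 1e-6 A^-2.  ``sld_slice`` is the hydrated total SLD that
    feeds the reflectivity kernel; the semi-infinite bounding media are
    the substrate below and the solvent above.
    """

    z_edges: np.ndarray  # (n+1,)
    v_slice_prot: np.ndarray  # (n,) A^3
    sld_slice_prot: np.ndarray  # (n,) 1e-6 A^-2, 0 for empty slices
    rho_slice: np.ndarray  # (n,) box-volume fraction of protein
    sld_bulk: np.ndarray  # (n,) 1e-6 A^-2
    sld_slice: np.ndarray  # (n,) 1e-6 A^-2
    rho_box: float
    rho_total: float
    rho_norm: float
    area: float  # A^2, padded box cross-section
    sld_solvent: float
    sld_substrate: float
    z_interface: float

    @property
    def thickness(self) -> float:
        return float(self.z_edges[1] - self.z_edges[0])

    @property
    def n_slices(self) -> int:
        return len(self.v_slice_prot)

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])


def rotation_matrix(orientation: Orientation) -> np.ndarray:
    """Composite active rotation matrix for a two-angle orientation."""
    t = np.radians(orientation.theta)
    p = np.radians(orientation.phi)
    ct, st = np.cos(t), np.sin(t)
    cp, sp = np.cos(p), np.sin(p)
    r_y = np.array([[cp, 0.0, sp], [0.0, 1.0, 0.0], [-sp, 0.0, cp]])
    if orientation.mode == "XY":
        r_first = np.array([[1.0, 0.0, 0.0], [0.0, ct, -st], [0.0, st, ct]])
    else:  # ZY
        r_first = np.array([[ct, -st, 0.0], [st, ct, 0.0], [0.0, 0.0, 1.0]])
    return r_y @ r_first


def rotate_model(model: ProteinModel, orientation: Orientation,
                 extra_rotation: np.ndarray | None = None) -> np.ndarray:
    """Rotated bead positions; ``extra_rotation`` composes on the left."""
    rot = rotation_matrix(orientation)
    if extra_rotation is not None:
        rot = np.asarray(extra_rotation) @ rot
    return model.positions @ rot.T


def _slice_edges(z: np.ndarray, n_slices: int) -> np.ndarray:
    z_min, z_max = float(z.min()), float(z.max())
    if z_max - z_min < 1e-9:  # degenerate flat cloud: pad the box
        z_min -= 0.5
        z_max += 0.5
    return np.linspace(z_min, z_max, n_slices + 1)


def slice_protein(z: np.ndarray, volumes: np.ndarray, b_eff: np.ndarray,
                  config: SliceConfig,
                  z_edges: np.ndarray | None = None):
    """Bin residues into equal-thickness z slices.

    Each residue contributes its whole volume and scattering length to
    the slice containing its representative z (half-open intervals
    ``[lo, hi)``, the top slice closed).  Returns
    ``(z_edges, v_slice, sld_slice_prot)`` with SLD in 1e-6 A^-2 and
    empty slices carrying ``V = 0`` and SLD 0.
    """
    if z_edges is None:
        z_edges = _slice_edges(z, config.n_slices)
    n = len(z_edges) - 1
    idx = np.clip(np.searchsorted(z_edges, z, side="right") - 1, 0, n - 1)
    v_slice = np.bincount(idx, weights=volumes, minlength=n)
    b_slice = np.bincount(idx, weights=b_eff, minlength=n)
    sld = np.divide(b_slice, v_slice, out=np.zeros(n), where=v_slice > 0) * 1e6
    return z_edges, v_slice, sld


def bulk_sld(z_edges: np.ndarray, z_interface: float,
             sld_solvent: float, sld_substrate: float) -> np.ndarray:
    """Per-slice bulk SLD given the interface position.

    Slices entirely above the interface are solvent, entirely below are
    substrate; the straddling slice mixes the two by the solvent-side
    fraction ``B`` of its z extent.
    """
    lo, hi = np.asarray(z_edges[:-1]), np.asarray(z_edges[1:])
    if np.any(hi <= lo):
        raise ValueError("slice bounds must be strictly increasing")
    b = np.clip((hi - z_interface) / (hi - lo), 0.0, 1.0)
    return b * sld_solvent + (1.0 - b) * sld_substrate


def rho_total_from_gamma(gamma: float, d_prot: float, layer_extent: float) -> float:
    """Total protein volume fraction of the layer from the surface excess.

    ``gamma`` in mg/m^2, ``d_prot`` in g/cm^3, ``layer_extent`` in A.
    The conversion collapses to ``rho = 10 * gamma / (d_prot * extent)``.
    """
    if d_prot <= 0 or layer_extent <= 0:
        raise ValueError("density and layer extent must be positive")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    return 10.0 * gamma / (d_prot * layer_extent)


def assemble_profile(model: ProteinModel, state: AdsorptionState,
                     config: SliceConfig, solvent: SolventSpec,
                     substrate_sld: float,
                     exchange_fraction: float = 1.0,
                     extra_rotation: np.ndarray | None = None) -> SlabProfile:
    """Build the hydrated slab SLD profile for one contrast.

    The per-slice SLD is
    ``rho_norm * rho_slice * SLD_prot + (1 - rho_norm * rho_slice) * SLD_bulk``
    where ``rho_norm = rho_total / rho_box`` rescales the arbitrary box
    hydration to the Gamma-implied layer hydration.  Raises
    :class:`PackingError` if any slice occupancy exceeds unity.
    """
    pos = rotate_model(model, state.orientation, extra_rotation)
    z = pos[:, 2]
    volumes = model.volumes
    b_eff = model.effective_b(solvent.h_fraction, exchange_fraction=exchange_fraction)
    z_edges, v_slice, sld_prot = slice_protein(z, volumes, b_eff, config)
    d = z_edges[1] - z_edges[0]
    extent = z_edges[-1] - z_edges[0]
    x_ext = pos[:, 0].max() - pos[:, 0].min()
    y_ext = pos[:, 1].max() - pos[:, 1].min()
    area = (x_ext + 2 * BOX_PAD) * (y_ext + 2 * BOX_PAD)
    rho_slice = v_slice / (area * d)
    rho_box = volumes.sum() / (area * extent)
    d_prot = protein_density(model.mwt / 1000.0)
    rho_total = rho_total_from_gamma(state.gamma, d_prot, extent)
    rho_norm = rho_total / rho_box
    occupancy = rho_norm * rho_slice
    if np.any(occupancy > 1.0 + 1e-9):
        worst = int(np.argmax(occupancy))
        raise PackingError(
            f"slice {worst}: protein occupancy {occupancy[worst]:.3f} > 1 "
            f"(gamma={state.gamma} too high for this orientation)")
    z_interface = z_edges[0] + state.z_pen if z.max() > z.min() else z.min() + state.z_pen
    bulk = bulk_sld(z_edges, z_interface, solvent.sld, substrate_sld)
    sld_slice = occupancy * sld_prot + (1.0 - occupancy) * bulk
    return SlabProfile(
        z_edges=z_edges, v_slice_prot=v_slice, sld_slice_prot=sld_prot,
        rho_slice=rho_slice, sld_bulk=bulk, sld_slice=sld_slice,
        rho_box=float(rho_box), rho_total=float(rho_total),
        rho_norm=float(rho_norm), area=float(area),
        sld_solvent=solvent.sld, sld_substrate=substrate_sld,
        z_interface=float(z_interface))


def penetrated_fraction(model: ProteinModel, state: AdsorptionState,
                        extra_rotation: np.ndarray | None = None) -> float:
    """Fraction of residues past the interface into the substrate phase."""
    z = rotate_model(model, state.orientation, extra_rotation)[:, 2]
    z_interface = z.min() + state.z_pen
    return float(np.mean(z < z_interface))


def profile_sld_at(profile: SlabProfile, z: np.ndarray) -> np.ndarray:
    """Piecewise-constant SLD of the full stack evaluated at z points."""
    z = np.asarray(z, dtype=float)
    out = np.where(z < profile.z_interface, profile.sld_substrate,
                   profile.sld_solvent).astype(float)
    inside = (z >= profile.z_edges[0]) & (z < profile.z_edges[-1])
    idx = np.clip(np.searchsorted(profile.z_edges, z[inside], side="right") - 1,
                  0, profile.n_slices - 1)
    out[inside] = profile.sld_slice[idx]
    return out


def profile_to_text(profiles: dict[str, SlabProfile], path) -> None:
    """Export per-contrast profiles as columnar text (z, volfrac, SLDs)."""
    names = list(profiles)
    first = profiles[names[0]]
    occ = first.rho_norm * first.rho_slice
    cols = [first.z_centers, occ] + [profiles[n].sld_slice for n in names]
    header = "z_A\tprotein_volume_fraction\t" + "\t".join(
        f"sld_{n}_1e-6_A^-2" for n in names)
    np.savetxt(path, np.column_stack(cols), header=header, delimiter="\t")
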