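"""Neutron scattering parameters for residues, solvents and proteins.

Scattering lengths are stored in Angstrom (1 fm = 1e-5 A) and scattering
length densities (SLD) are quoted in the customary units of 1e-6 A^-2.
The residue table ships with the package as a columnar text file; each
residue carries a fully protonated scattering length ``b_h``, a fully
exchanged scattering length ``b_d`` (all labile H replaced by D), an
empirical volume and the count of exchangeable hydrogens.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "AVOGADRO",
    "COHERENT_B_FM",
    "ResidueKind",
    "SolventSpec",
    "load_residue_table",
    "residue_effective_b",
    "water_sld",
    "h2o_fraction_for_sld",
    "protein_density",
    "protein_mean_sld",
    "match_point",
    "solvent_presets",
]

AVOGADRO = 6.02214076e23  # mol^-1

# Coherent neutron scattering lengths, fm (Sears tabulation).
COHERENT_B_FM = {
    "H": -3.7390,
    "D": 6.6710,
    "C": 6.6460,
    "N": 9.3600,
    "O": 5.8030,
    "S": 2.8470,
}

FM_TO_ANGSTROM = 1e-5

# Pure-water mass densities at 20 C, g/cm^3.
H2O_DENSITY = 0.998
D2O_DENSITY = 1.105
H2O_MOLAR_MASS = 18.015
D2O_MOLAR_MASS = 20.028


@dataclass(frozen=True)
class ResidueKind:
    """Scattering parameters of one amino-acid residue unit."""

    code: str
    b_h: float  # A, all H protonated
    b_d: float  # A, labile H exchanged to D
    volume: float  # A^3
    n_labile: int
    mass: float  # Da
    formula: str = ""

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"{self.code}: residue volume must be positive")
        if self.n_labile < 0:
            raise ValueError(f"{self.code}: n_labile must be >= 0")
        if self.b_d < self.b_h:
            raise ValueError(f"{self.code}: b_d must be >= b_h")


@dataclass(frozen=True)
class SolventSpec:
    """An aqueous solvent contrast.

    ``sld`` is in 1e-6 A^-2 and ``h_fraction`` is the volume fraction of
    light water; the two are linked through the linear H2O/D2O mix.
    """

    name: str
    sld: float
    h_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.h_fraction <= 1.0:
            raise ValueError("h_fraction must lie in [0, 1]")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style formula like ``C4H6N2O2`` into element counts."""
    counts: dict[str, int] = {}
    for element, num in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
        if element:
            counts[element] = counts.get(element, 0) + (int(num) if num else 1)
    return counts


@lru_cache(maxsize=1)
def load_residue_table() -> dict[str, ResidueKind]:
    """Load the packaged residue parameter table.

    Returns a mapping from 3-letter residue code to :class:`ResidueKind`.
    """
    text = (resources.files("rborient.data") / "residues.tsv").read_text()
    table: dict[str, ResidueKind] = {}
    header: list[str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if header is None:
            header = line.split("\t")
            continue
        row = dict(zip(header, line.split("\t")))
        kind = ResidueKind(
            code=row["code"],
            b_h=float(row["b_h"]),
            b_d=float(row["b_d"]),
            volume=float(row["volume"]),
            n_labile=int(row["n_labile"]),
            mass=float(row["mass"]),
            formula=row.get("formula", ""),
        )
        table[kind.code] = kind
    return table


def residue_effective_b(kind: ResidueKind, h_fraction: float,
                        exchange_fraction: float = 1.0) -> float:
    """Effective scattering length (A) of a residue in mixed H2O/D2O.

    Labile hydrogens are assumed to exchange with the solvent: in pure
    H2O (``h_fraction=1``) the residue scatters as ``b_h``, in pure D2O
    as ``b_d``, and linearly in between.  ``exchange_fraction`` scales
    the labile-H exchange globally (1.0 = full exchange) for sensitivity
    analyses.
    """
    if not 0.0 <= h_fraction <= 1.0:
        raise ValueError("h_fraction must lie in [0, 1]")
    if not 0.0 <= exchange_fraction <= 1.0:
        raise ValueError("exchange_fraction must lie in [0, 1]")
    b_d_eff = kind.b_h + exchange_fraction * (kind.b_d - kind.b_h)
    return h_fraction * kind.b_h + (1.0 - h_fraction) * b_d_eff


def _pure_water_sld(molecule_b_fm: float, density: float, molar_mass: float) -> float:
    """SLD of a pure molecular liquid in 1e-6 A^-2."""
    number_density = density * AVOGADRO / molar_mass * 1e-24  # molecules / A^3
    return molecule_b_fm * FM_TO_ANGSTROM * number_density * 1e6


def water_sld(d2o_volume_fraction: float) -> float:
    """SLD (1e-6 A^-2) of an H2O/D2O mixture by D2O volume fraction."""
    if not 0.0 <= d2o_volume_fraction <= 1.0:
        raise ValueError("d2o_volume_fraction must lie in [0, 1]")
    b_h2o = 2 * COHERENT_B_FM["H"] + COHERENT_B_FM["O"]
    b_d2o = 2 * COHERENT_B_FM["D"] + COHERENT_B_FM["O"]
    sld_h2o = _pure_water_sld(b_h2o, H2O_DENSITY, H2O_MOLAR_MASS)
    sld_d2o = _pure_water_sld(b_d2o, D2O_DENSITY, D2O_MOLAR_MASS)
    f = d2o_volume_fraction
    return f * sld_d2o + (1.0 - f) * sld_h2o


def h2o_fraction_for_sld(sld: float) -> float:
    """H2O volume fraction of the water mixture with the given SLD."""
    lo, hi = water_sld(0.0), water_sld(1.0)
    if not lo <= sld <= hi:
        raise ValueError(f"SLD {sld} outside the pure-water range [{lo:.2f}, {hi:.2f}]")
    f_d2o = (sld - lo) / (hi - lo)
    return 1.0 - f_d2o


def protein_density(mw_kda: float) -> float:
    """Protein mass density (g/cm^3) from molecular weight in kDa.

    Uses the empirical exponential dependence of globular-protein density
    on molecular weight: rho(M) = 1.410 + 0.145 exp(-M / 13), M in kDa.
    """
    if mw_kda <= 0:
        raise ValueError("molecular weight must be positive")
    return 1.410 + 0.145 * np.exp(-mw_kda / 13.0)


def protein_mean_sld(model, h_fraction: float, exchange_fraction: float = 1.0) -> float:
    """Volume-averaged protein SLD (1e-6 A^-2) in a given solvent.

    ``model`` is a :class:`~rborient.structure.ProteinModel`; the mean is
    the sum of effective residue scattering lengths over the sum of
    residue volumes.
    """
    if len(model) == 0:
        raise ValueError("model has no residues")
    b = model.effective_b(h_fraction, exchange_fraction=exchange_fraction)
    return float(b.sum() / model.volumes.sum() * 1e6)


def match_point(model, exchange_fraction: float = 1.0) -> tuple[float, float]:
    """Contrast match point of a protein against water mixtures.

    Solves ``water_sld(f_d2o) == protein_mean_sld(model, h=1-f_d2o)`` and
    returns ``(d2o_volume_fraction, sld)``.  Both sides are linear in the
    D2O fraction so the root is unique when it exists.
    """
    def gap(f_d2o: float) -> float:
        return water_sld(f_d2o) - protein_mean_sld(
            model, 1.0 - f_d2o, exchange_fraction=exchange_fraction)

    if gap(0.0) * gap(1.0) > 0:
        raise ValueError("protein cannot be matched by any pure-water mixture")
    f = brentq(gap, 0.0, 1.0, xtol=1e-10)
    return f, water_sld(f)


def solvent_presets() -> dict[str, SolventSpec]:
    """Standard solvent contrasts used in interfacial protein work."""
    def spec(name: str, sld: float) -> SolventSpec:
        return SolventSpec(name=name, sld=sld, h_fraction=h2o_fraction_for_sld(sld))

    return {
        "H2O": spec("H2O", water_sld(0.0)),
        "NRW": spec("NRW", 0.0),
        "CM2.56": spec("CM2.56", 2.56),
        "CM4.5": spec("CM4.5", 4.5),
        "CMSapphire": spec("CMSapphire", 5.65),
        "D2O": spec("D2O", water_sld(1.0)),
    }
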