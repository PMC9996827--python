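"""Residue-bead protein models: PDB I/O and canonical orientation.

Structures are coarse-grained to one bead per residue at the heavy-atom
centroid (switchable to C-alpha).  The canonical orientation centres the
bead cloud on the origin with its principal axes sorted by extent and
aligned to (y, x, z) = (major, semi-major, minor), which defines the
(theta=0, phi=0) reference state for rigid-body rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .scattering import ResidueKind, load_residue_table

__all__ = ["ResidueBead", "ProteinModel", "read_structure", "write_structure",
           "canonicalize_orientation", "UnknownResidueError"]

WATER_MASS = 18.015  # Da, added back for the terminal H/OH


class UnknownResidueError(KeyError):
    """A residue code absent from the scattering-parameter table."""


@dataclass(frozen=True)
class ResidueBead:
    """One coarse-grained residue."""

    kind: ResidueKind
    position: tuple[float, float, float]
    chain_id: str = "A"
    index: int = 0


@dataclass
class ProteinModel:
    """A protein as an ordered collection of residue beads.

    Positions, volumes and scattering lengths are exposed as numpy arrays
    for vectorised slicing; ``mwt`` is bookkept from residue masses plus
    one water for the termini.
    """

    kinds: list[ResidueKind]
    positions: np.ndarray  # (n, 3) A
    chain_ids: list[str] = field(default_factory=list)
    name: str = "protein"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if len(self.kinds) != len(self.positions):
            raise ValueError("kinds and positions length mismatch")
        if len(self.kinds) == 0:
            raise ValueError("model must contain at least one residue")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if not self.chain_ids:
            self.chain_ids = ["A"] * len(self.kinds)
        self._volumes = np.array([k.volume for k in self.kinds])
        self._b_h = np.array([k.b_h for k in self.kinds])
        self._b_d = np.array([k.b_d for k in self.kinds])
        self._mwt = float(sum(k.mass for k in self.kinds) + WATER_MASS)

    def __len__(self) -> int:
        return len(self.kinds)

    @property
    def volumes(self) -> np.ndarray:
        return self._volumes

    @property
    def b_h(self) -> np.ndarray:
        return self._b_h

    @property
    def b_d(self) -> np.ndarray:
        return self._b_d

    @property
    def mwt(self) -> float:
        """Molecular weight in Da."""
        return self._mwt

    def effective_b(self, h_fraction: float, exchange_fraction: float = 1.0) -> np.ndarray:
        """Per-residue effective scattering length (A) in mixed water."""
        if not 0.0 <= h_fraction <= 1.0:
            raise ValueError("h_fraction must lie in [0, 1]")
        b_d_eff = self._b_h + exchange_fraction * (self._b_d - self._b_h)
        return h_fraction * self._b_h + (1.0 - h_fraction) * b_d_eff

    def total_volume(self) -> float:
        return float(self.volumes.sum())

    def with_positions(self, positions: np.ndarray) -> "ProteinModel":
        return ProteinModel(kinds=self.kinds, positions=positions,
                            chain_ids=list(self.chain_ids), name=self.name)


def read_structure(path, *, representative: str = "centroid",
                   on_unknown: str = "error") -> ProteinModel:
    """Read a PDB file into a residue-bead model.

    One bead per amino-acid residue is placed at the heavy-atom centroid
    (``representative="centroid"``) or at the C-alpha position
    (``representative="ca"``).  Hydrogens and HETATM water/ligands are
    ignored; only the first model and the first altloc are used.

    ``on_unknown`` controls residues missing from the parameter table:
    ``"error"`` raises :class:`UnknownResidueError`, ``"skip"`` drops them.
    """
    if representative not in ("centroid", "ca"):
        raise ValueError("representative must be 'centroid' or 'ca'")
    if on_unknown not in ("error", "skip"):
        raise ValueError("on_unknown must be 'error' or 'skip'")
    table = load_residue_table()
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models in structure")
    kinds: list[ResidueKind] = []
    coords: list[np.ndarray] = []
    chains: list[str] = []
    model = st[0]
    for chain in model:
        for residue in chain:
            if residue.het_flag == "H" and residue.name not in table:
                continue  # solvent / ligand HETATM
            if residue.name not in table:
                if residue.het_flag == "A" and on_unknown == "error":
                    raise UnknownResidueError(
                        f"{path}: residue {residue.name} not in parameter table")
                continue
            pos = _representative_position(residue, representative)
            if pos is None:
                continue
            kinds.append(table[residue.name])
            coords.append(pos)
            chains.append(chain.name)
    if not kinds:
        raise ValueError(f"{path}: no amino-acid residues found")
    return ProteinModel(kinds=kinds, positions=np.array(coords),
                        chain_ids=chains, name=st.name or "protein")


def _representative_position(residue, representative: str) -> np.ndarray | None:
    if representative == "ca":
        atom = residue.find_atom("CA", "*")
        if atom is None:
            return None
        return np.array([atom.pos.x, atom.pos.y, atom.pos.z])
    acc = []
    seen = set()
    for atom in residue:
        if atom.is_hydrogen():
            continue
        if atom.name in seen:  # keep first altloc only
            continue
        seen.add(atom.name)
        acc.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not acc:
        return None
    return np.mean(acc, axis=0)


def write_structure(model: ProteinModel, path) -> None:
    """Write a bead model as a PDB file with one CA pseudo-atom per bead.

    Round-trips through :func:`read_structure` (with
    ``representative="ca"``) to within PDB coordinate precision (1e-3 A).
    """
    st = gemmi.Structure()
    st.name = model.name
    gm = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    counters: dict[str, int] = {}
    for kind, pos, cid in zip(model.kinds, model.positions, model.chain_ids):
        if cid not in chain_map:
            chain_map[cid] = gemmi.Chain(cid)
            counters[cid] = 0
        counters[cid] += 1
        res = gemmi.Residue()
        res.name = kind.code
        res.seqid = gemmi.SeqId(counters[cid], " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*pos)
        atom.occ = 1.0
        res.add_atom(atom)
        chain_map[cid].add_residue(res)
    for chain in chain_map.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.write_pdb(str(path))


def canonicalize_orientation(model: ProteinModel) -> ProteinModel:
    """Rotate/translate a model into the canonical reference orientation.

    The centroid moves to the origin and the principal axes of the bead
    cloud (eigenvectors of the position covariance) are aligned so that
    the major axis lies along y, the semi-major along x and the minor
    along z.  Axis signs are fixed deterministically: the bead farthest
    from the origin along y gets y > 0, then likewise for x.
    """
    pos = model.positions - model.positions.mean(axis=0)
    cov = pos.T @ pos / len(pos)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] < 1e-9 * max(evals[2], 1.0):
        raise ValueError("degenerate (collinear) bead cloud")
    # eigh returns ascending eigenvalues: [minor, semi-major, major]
    minor, semi, major = evecs[:, 0], evecs[:, 1], evecs[:, 2]
    # target axes: major -> y, semi-major -> x, minor -> z
    rot = np.vstack([semi, major, minor])  # rows: new x, y, z in old frame
    if np.linalg.det(rot) < 0:
        rot[2] *= -1.0
    out = pos @ rot.T
    # deterministic sign convention
    iy = int(np.argmax(np.abs(out[:, 1])))
    if out[iy, 1] < 0:
        out[:, 1] *= -1.0
        out[:, 2] *= -1.0  # keep determinant +1
    ix = int(np.argmax(np.abs(out[:, 0])))
    if out[ix, 0] < 0:
        out[:, 0] *= -1.0
        out[:, 2] *= -1.0
    return model.with_positions(out)
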