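"""Fixed-length atomic-environment representations.

Two families are provided.  ``coulomb`` encodes an atom as its row of the
molecular Coulomb matrix (2-body information only): the self-term
0.5·Z_i^2.4 first, then the off-diagonal terms Z_i·Z_j/r_ij (r in Bohr)
sorted by descending magnitude and zero-padded to a fixed ``max_atoms``.
``local_mbr`` is a local many-body representation carrying the same 2- and
3-body information content as the aSLATM/FCHL family: per-element
Gaussian-smeared radial densities of neighbours inside a smooth cosine
cutoff, concatenated with per-element-pair Gaussian-smeared angle
distributions weighted by the cutoff functions of both arms.

Both are invariant to rigid motions (they depend on interatomic distances
and angles only), and their length is fixed by the parameters alone, never
by molecule size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .structures import ATOMIC_NUMBERS, Dataset, Structure

__all__ = [
    "ANGSTROM_TO_BOHR",
    "RepParams",
    "AtomicRep",
    "PairRep",
    "coulomb_row",
    "local_mbr",
    "atomic_rep",
    "structure_reps",
    "represent_dataset",
    "rep_for_label",
]

#: Å → Bohr conversion used in the Coulomb matrix (atomic units).
ANGSTROM_TO_BOHR = 1.8897261


@dataclass(frozen=True)
class RepParams:
    """Hyperparameters fixing a representation family and its dimension.

    Parameters
    ----------
    family:
        ``"coulomb"`` or ``"local_mbr"``.
    max_atoms:
        Padding size for Coulomb rows; must be ≥ the largest molecule.
    r_cut:
        Neighbourhood cutoff in Å for ``local_mbr``; contributions vanish
        exactly at and beyond the cutoff.
    n_radial, n_angular:
        Grid sizes of the radial ((0, r_cut]) and angular ([0, π]) blocks.
    gaussian_width:
        Radial smearing width in Å.
    angular_width:
        Angular smearing width in radians.
    element_set:
        Ordered element symbols defining the block layout; must cover every
        element in the dataset.
    """

    family: str = "local_mbr"
    max_atoms: int = 64
    r_cut: float = 5.0
    n_radial: int = 48
    n_angular: int = 12
    gaussian_width: float = 0.1
    angular_width: float = 0.2
    element_set: tuple[str, ...] = ("H", "C", "N", "O", "F")

    def __post_init__(self):
        if self.family not in ("coulomb", "local_mbr"):
            raise ValueError(f"unknown representation family {self.family!r}")
        if self.r_cut <= 0 or self.gaussian_width <= 0 or self.angular_width <= 0:
            raise ValueError("cutoff and smearing widths must be positive")
        if self.max_atoms < 1 or self.n_radial < 1 or self.n_angular < 1:
            raise ValueError("sizes must be positive")
        object.__setattr__(self, "element_set", tuple(self.element_set))

    @property
    def length(self) -> int:
        """Vector length — a function of the parameters only."""
        if self.family == "coulomb":
            return self.max_atoms
        n_e = len(self.element_set)
        n_pairs = n_e * (n_e + 1) // 2
        return n_e * self.n_radial + n_pairs * self.n_angular

    @property
    def element_pairs(self) -> list[tuple[str, str]]:
        es = self.element_set
        return [(es[a], es[b]) for a in range(len(es)) for b in range(a, len(es))]


@dataclass(frozen=True)
class AtomicRep:
    """A fixed-length feature vector for one atomic environment."""

    structure_id: str
    atom_index: int
    element: str
    vector: np.ndarray
    params: RepParams

    def __post_init__(self):
        v = np.asarray(self.vector, dtype=float)
        object.__setattr__(self, "vector", v)
        if v.shape != (self.params.length,):
            raise ValueError(
                f"vector length {v.shape} inconsistent with params ({self.params.length})"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite entry in representation vector")


@dataclass(frozen=True)
class PairRep:
    """An ordered (carbon-env, hydrogen-env) pair for coupling targets.

    The ordering is a contract: constructing a pair whose first member is
    not a carbon environment or second member not a hydrogen environment
    raises.
    """

    carbon: AtomicRep
    hydrogen: AtomicRep

    def __post_init__(self):
        if self.carbon.element != "C" or self.hydrogen.element != "H":
            raise ValueError(
                "PairRep must be ordered (carbon-env, hydrogen-env); got "
                f"({self.carbon.element}, {self.hydrogen.element})"
            )
        if self.carbon.params != self.hydrogen.params:
            raise ValueError("pair members built with different RepParams")

    @property
    def params(self) -> RepParams:
        return self.carbon.params


def _smooth_cutoff(r: np.ndarray, r_cut: float) -> np.ndarray:
    """Cosine cutoff f(r) = 0.5·(cos(πr/r_cut)+1) for r < r_cut, exactly 0 beyond."""
    r = np.asarray(r, dtype=float)
    out = 0.5 * (np.cos(np.pi * r / r_cut) + 1.0)
    return np.where(r < r_cut, out, 0.0)


def coulomb_row(s: Structure, i: int, p: RepParams) -> AtomicRep:
    """Atom-i row of the sorted Coulomb matrix.

    M_ii = 0.5·Z_i^2.4; M_ij = Z_i·Z_j / r_ij with r in Bohr.  Off-diagonal
    entries are sorted by descending magnitude (ties broken by neighbour
    distance, then atomic number), the self-term is appended first, and the
    vector is zero-padded to ``max_atoms``.
    """
    if p.family != "coulomb":
        raise ValueError("coulomb_row requires params.family == 'coulomb'")
    if s.n_atoms > p.max_atoms:
        raise ValueError(
            f"{s.id}: {s.n_atoms} atoms exceeds max_atoms={p.max_atoms}"
        )
    z = s.atomic_numbers
    diff = s.coords - s.coords[i]
    r_ang = np.sqrt((diff * diff).sum(axis=1))
    r_bohr = r_ang * ANGSTROM_TO_BOHR
    others = [j for j in range(s.n_atoms) if j != i]
    vals = {j: z[i] * z[j] / r_bohr[j] for j in others}
    order = sorted(others, key=lambda j: (-abs(vals[j]), r_ang[j], z[j]))
    vec = np.zeros(p.max_atoms)
    vec[0] = 0.5 * z[i] ** 2.4
    for k, j in enumerate(order, start=1):
        vec[k] = vals[j]
    return AtomicRep(s.id, i, s.elements[i], vec, p)


def local_mbr(s: Structure, i: int, p: RepParams) -> AtomicRep:
    """Local 2-/3-body many-body representation of atom i.

    2-body blocks (one per element in ``element_set``): the Gaussian-smeared
    radial density of same-element neighbours on ``n_radial`` points over
    (0, r_cut], each neighbour weighted by the smooth cosine cutoff.
    3-body blocks (one per unordered element pair): the Gaussian-smeared
    distribution of angles j–i–k on ``n_angular`` points over [0, π],
    weighted by f(r_ij)·f(r_ik).  Absent elements contribute zero blocks.
    """
    if p.family != "local_mbr":
        raise ValueError("local_mbr requires params.family == 'local_mbr'")
    missing = set(s.elements) - set(p.element_set)
    if missing:
        raise ValueError(f"{s.id}: element(s) {sorted(missing)} not in element_set")

    diff = s.coords - s.coords[i]
    r = np.sqrt((diff * diff).sum(axis=1))
    neigh = [j for j in range(s.n_atoms) if j != i and r[j] < p.r_cut]
    fcut = _smooth_cutoff(r, p.r_cut)

    r_grid = p.r_cut * np.arange(1, p.n_radial + 1) / p.n_radial
    a_grid = np.linspace(0.0, np.pi, p.n_angular)

    blocks: list[np.ndarray] = []
    for el in p.element_set:
        block = np.zeros(p.n_radial)
        for j in neigh:
            if s.elements[j] == el:
                block += fcut[j] * np.exp(-((r_grid - r[j]) ** 2) / (2 * p.gaussian_width**2))
        blocks.append(block)

    # Precompute unit vectors for angle evaluation.
    units = {j: diff[j] / r[j] for j in neigh}
    for el_a, el_b in p.element_pairs:
        block = np.zeros(p.n_angular)
        for a_pos, j in enumerate(neigh):
            for k in neigh[a_pos + 1:]:
                pair = tuple(sorted((s.elements[j], s.elements[k])))
                if pair != tuple(sorted((el_a, el_b))):
                    continue
                cosang = float(np.clip(units[j] @ units[k], -1.0, 1.0))
                theta = np.arccos(cosang)
                w = fcut[j] * fcut[k]
                block += w * np.exp(-((a_grid - theta) ** 2) / (2 * p.angular_width**2))
        blocks.append(block)

    return AtomicRep(s.id, i, s.elements[i], np.concatenate(blocks), p)


def atomic_rep(s: Structure, i: int, p: RepParams) -> AtomicRep:
    """Dispatch to the family selected by ``p``."""
    if p.family == "coulomb":
        return coulomb_row(s, i, p)
    return local_mbr(s, i, p)


def structure_reps(s: Structure, atoms: Iterable[int], p: RepParams) -> dict[int, AtomicRep]:
    return {i: atomic_rep(s, i, p) for i in sorted(set(atoms))}


def represent_dataset(d: Dataset, p: RepParams) -> dict[tuple[str, int], AtomicRep]:
    """One AtomicRep per (structure, atom) referenced by any label, deduplicated.

    Deterministic: iteration follows structure insertion order and ascending
    atom index.
    """
    needed: dict[str, set[int]] = {}
    for rec in d.labels:
        needed.setdefault(rec.structure_id, set()).update(rec.atoms)
    cache: dict[tuple[str, int], AtomicRep] = {}
    for sid in d.structures:
        if sid not in needed:
            continue
        for i, rep in structure_reps(d.structures[sid], needed[sid], p).items():
            cache[(sid, i)] = rep
    return cache


def rep_for_label(rec, cache: dict[tuple[str, int], AtomicRep]):
    """The kernel input for one label: an AtomicRep (shifts) or PairRep (couplings)."""
    if rec.param == "j1_CH":
        c_idx, h_idx = rec.atoms
        return PairRep(cache[(rec.structure_id, c_idx)], cache[(rec.structure_id, h_idx)])
    return cache[(rec.structure_id, rec.atoms[0])]
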