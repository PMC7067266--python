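"""Molecular structures, NMR label tables, and the on-disk dataset contract.

Geometries travel as (multi-frame) XYZ files with coordinates in Å; labels
and predictions travel as delimited text tables with a fixed header.  Atom
indices are 0-based everywhere, on disk and in memory.  Values are stored in
the parameter's natural unit (ppm for shifts/shieldings, Hz for couplings)
and are never normalised on disk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

__all__ = [
    "PARAMS",
    "SHIFT_PARAMS",
    "CORE_ELEMENTS",
    "ATOMIC_NUMBERS",
    "Structure",
    "LabelRecord",
    "Dataset",
    "PredictionRow",
    "ParseError",
    "ValidationError",
    "read_xyz",
    "write_xyz",
    "read_sdf",
    "read_labels",
    "write_labels",
    "read_predictions",
    "write_predictions",
]

#: NMR parameters handled by the package.
PARAMS = ("shift_1H", "shift_13C", "j1_CH")
SHIFT_PARAMS = ("shift_1H", "shift_13C")

#: Elements the method was designed for; others trigger a warning.
CORE_ELEMENTS = frozenset({"H", "C", "N", "O", "F"})

_SYMBOLS = (
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca "
    "Sc Ti V Cr Mn Fe Co Ni Cu Zn Ga Ge As Se Br Kr "
    "Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I Xe"
).split()
#: Element symbol -> atomic number, H..Xe.
ATOMIC_NUMBERS = {s: z for z, s in enumerate(_SYMBOLS, start=1)}

#: Hard floor on interatomic distances (Å); closer atoms are unphysical.
MIN_INTERATOMIC_DIST = 0.5

#: Element of the first/second atom index of each parameter kind.
PARAM_ELEMENTS = {"shift_1H": ("H",), "shift_13C": ("C",), "j1_CH": ("C", "H")}


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """A structure, label, or dataset violates an invariant."""


@dataclass(frozen=True)
class Structure:
    """One molecule: element symbols plus Cartesian coordinates in Å.

    Atom order is meaningful (labels index into it) and is never permuted
    by I/O.
    """

    id: str
    elements: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3), Å

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "elements", tuple(self.elements))
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValidationError(f"{self.id}: coords must be (n, 3), got {coords.shape}")
        if len(self.elements) != len(coords) or len(coords) < 1:
            raise ValidationError(
                f"{self.id}: {len(self.elements)} elements vs {len(coords)} coordinates"
            )
        if not np.all(np.isfinite(coords)):
            raise ValidationError(f"{self.id}: non-finite coordinate")
        unknown = [e for e in self.elements if e not in ATOMIC_NUMBERS]
        if unknown:
            raise ValidationError(f"{self.id}: unknown element symbol(s) {sorted(set(unknown))}")
        exotic = sorted(set(self.elements) - CORE_ELEMENTS)
        if exotic:
            warnings.warn(
                f"structure {self.id!r} contains elements outside H/C/N/O/F: {exotic}",
                stacklevel=2,
            )
        if len(coords) > 1 and pdist(coords).min() < MIN_INTERATOMIC_DIST:
            raise ValidationError(
                f"{self.id}: atoms closer than {MIN_INTERATOMIC_DIST} Å"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBERS[e] for e in self.elements], dtype=float)

    def distance_matrix(self) -> np.ndarray:
        d = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((d * d).sum(axis=-1))


@dataclass(frozen=True)
class LabelRecord:
    """One NMR target value bound to atom index/indices of a structure.

    ``atoms`` holds one 0-based index for shifts and an ordered
    (carbon, hydrogen) pair for one-bond couplings.  ``value`` is in ppm
    (shifts / raw shieldings) or Hz (couplings) and may be NaN for
    prediction targets whose reference value is unknown.
    """

    structure_id: str
    param: str
    atoms: tuple[int, ...]
    value: float = float("nan")

    def __post_init__(self):
        if self.param not in PARAMS:
            raise ValidationError(f"unknown param {self.param!r}; expected one of {PARAMS}")
        atoms = tuple(int(a) for a in self.atoms)
        object.__setattr__(self, "atoms", atoms)
        want = len(PARAM_ELEMENTS[self.param])
        if len(atoms) != want:
            raise ValidationError(f"{self.param} needs {want} atom index(es), got {atoms}")
        if any(a < 0 for a in atoms):
            raise ValidationError(f"negative atom index in {atoms}")

    @property
    def key(self) -> tuple[str, str, tuple[int, ...]]:
        return (self.structure_id, self.param, self.atoms)


@dataclass
class Dataset:
    """Structures keyed by id plus the labels that reference them."""

    structures: dict[str, Structure] = field(default_factory=dict)
    labels: list[LabelRecord] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        seen: set[tuple] = set()
        for rec in self.labels:
            s = self.structures.get(rec.structure_id)
            if s is None:
                raise ValidationError(f"label references unknown structure {rec.structure_id!r}")
            if rec.key in seen:
                raise ValidationError(f"duplicate label key {rec.key}")
            seen.add(rec.key)
            for idx, want_elem in zip(rec.atoms, PARAM_ELEMENTS[rec.param]):
                if idx >= s.n_atoms:
                    raise ValidationError(
                        f"label {rec.key}: atom index {idx} out of range for "
                        f"{s.id} ({s.n_atoms} atoms)"
                    )
                if s.elements[idx] != want_elem:
                    raise ValidationError(
                        f"label {rec.key}: atom {idx} is {s.elements[idx]}, "
                        f"expected {want_elem} for {rec.param}"
                    )

    def labels_for(self, param: str, structure_ids: Iterable[str] | None = None) -> list[LabelRecord]:
        ids = None if structure_ids is None else set(structure_ids)
        return [
            r for r in self.labels
            if r.param == param and (ids is None or r.structure_id in ids)
        ]

    def structure_ids_with(self, param: str) -> list[str]:
        """Ids of structures carrying at least one label for ``param``, in insertion order."""
        with_param = {r.structure_id for r in self.labels if r.param == param}
        return [sid for sid in self.structures if sid in with_param]

    def subset(self, structure_ids: Iterable[str]) -> "Dataset":
        ids = list(structure_ids)
        idset = set(ids)
        missing = idset - self.structures.keys()
        if missing:
            raise ValidationError(f"subset references unknown structures {sorted(missing)}")
        return Dataset(
            structures={sid: self.structures[sid] for sid in ids},
            labels=[r for r in self.labels if r.structure_id in idset],
        )

    @property
    def n_structures(self) -> int:
        return len(self.structures)


# ---------------------------------------------------------------------------
# XYZ geometry I/O


def read_xyz(path: str | Path) -> list[Structure]:
    """Read a (possibly multi-frame) XYZ file into Structures.

    The frame id is the first whitespace-delimited token of the comment
    line, or ``frame_<k>`` when the comment is blank.  Coordinates are
    preserved at full printed precision.  Malformed atom counts,
    non-numeric coordinates and unknown element symbols raise
    :class:`ParseError` naming the offending line.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    structures: list[Structure] = []
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():  # tolerate trailing blank lines
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"{path}:{i + 1}: expected atom count, got {lines[i]!r}")
        if n < 1 or i + 1 + n > len(lines):
            raise ParseError(f"{path}:{i + 1}: atom count {n} exceeds remaining file")
        comment = lines[i + 1].strip() if i + 1 < len(lines) else ""
        sid = comment.split()[0] if comment else f"frame_{frame}"
        elements: list[str] = []
        coords: list[list[float]] = []
        for k in range(n):
            lineno = i + 2 + k
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno + 1}: expected 'El x y z', got {lines[lineno]!r}")
            el = parts[0]
            if el not in ATOMIC_NUMBERS:
                raise ParseError(f"{path}:{lineno + 1}: unknown element symbol {el!r}")
            try:
                xyz = [float(v) for v in parts[1:4]]
            except ValueError:
                raise ParseError(f"{path}:{lineno + 1}: non-numeric coordinate in {lines[lineno]!r}")
            elements.append(el)
            coords.append(xyz)
        try:
            structures.append(Structure(sid, tuple(elements), np.array(coords)))
        except ValidationError as exc:
            raise ParseError(f"{path}: frame {frame} ({sid}): {exc}") from exc
        i += 2 + n
        frame += 1
    return structures


def write_xyz(structures: Sequence[Structure], path: str | Path) -> None:
    """Write structures as concatenated XYZ frames (id on the comment line)."""
    out = []
    for s in structures:
        out.append(str(s.n_atoms))
        out.append(s.id)
        for el, (x, y, z) in zip(s.elements, s.coords):
            out.append(f"{el} {x:.10f} {y:.10f} {z:.10f}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def read_sdf(path: str | Path) -> list[Structure]:
    """Read an SDF/MOL file via rdkit, keeping only elements and coordinates.

    Bond blocks are discarded: the method is geometry-only.  Requires rdkit,
    which is an optional import.
    """
    from rdkit import Chem  # deferred: optional dependency

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    structures = []
    for k, mol in enumerate(supplier):
        if mol is None:
            raise ParseError(f"{path}: molecule {k} could not be parsed")
        name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        sid = name.split()[0] if name else f"mol_{k}"
        conf = mol.GetConformer()
        elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
        coords = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                            conf.GetAtomPosition(i).z] for i in range(mol.GetNumAtoms())])
        structures.append(Structure(sid, elements, coords))
    return structures


# ---------------------------------------------------------------------------
# Label and prediction tables

_LABEL_COLUMNS = ["structure_id", "param", "atom1", "atom2", "value"]


def _atoms_to_cols(rec_atoms: tuple[int, ...]) -> tuple[int, float | int]:
    if len(rec_atoms) == 1:
        return rec_atoms[0], np.nan
    return rec_atoms[0], rec_atoms[1]


def _cols_to_atoms(param: str, atom1, atom2) -> tuple[int, ...]:
    if param == "j1_CH":
        if pd.isna(atom2):
            raise ParseError(f"j1_CH row missing atom2 (atom1={atom1})")
        return (int(atom1), int(atom2))
    return (int(atom1),)


def read_labels(path: str | Path) -> list[LabelRecord]:
    """Read a delimited label table (columns structure_id,param,atom1,atom2,value).

    Duplicate (structure_id, param, atoms) keys are rejected; atom-index
    range checks happen later, at Dataset assembly.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    records: list[LabelRecord] = []
    seen: set[tuple] = set()
    for row in df.itertuples(index=False):
        rec = LabelRecord(
            structure_id=str(row.structure_id),
            param=str(row.param),
            atoms=_cols_to_atoms(str(row.param), row.atom1, row.atom2),
            value=float(row.value),
        )
        if rec.key in seen:
            raise ParseError(f"{path}: duplicate label key {rec.key}")
        seen.add(rec.key)
        records.append(rec)
    return records


def write_labels(records: Sequence[LabelRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        a1, a2 = _atoms_to_cols(r.atoms)
        rows.append((r.structure_id, r.param, a1, a2, r.value))
    df = pd.DataFrame(rows, columns=_LABEL_COLUMNS)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# atom indices are 0-based\n")
        df.to_csv(fh, index=False, float_format="%.8g")


@dataclass(frozen=True)
class PredictionRow:
    """One predicted target: key, predicted value, across-fold spread, kept flag."""

    structure_id: str
    param: str
    atoms: tuple[int, ...]
    value: float
    spread: float = float("nan")
    kept: bool | None = None


_PRED_COLUMNS = ["structure_id", "param", "atom1", "atom2", "value", "spread", "kept"]


def write_predictions(rows: Sequence[PredictionRow], path: str | Path) -> None:
    """Write a prediction table; round-trips through :func:`read_predictions`
    without loss at 6 significant digits (an empty list yields a header-only file)."""
    out = []
    for r in rows:
        a1, a2 = _atoms_to_cols(tuple(r.atoms))
        kept = "" if r.kept is None else str(bool(r.kept)).lower()
        out.append((r.structure_id, r.param, a1, a2, r.value, r.spread, kept))
    df = pd.DataFrame(out, columns=_PRED_COLUMNS)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# atom indices are 0-based\n")
        df.to_csv(fh, index=False, float_format="%.8g")


def read_predictions(path: str | Path) -> list[PredictionRow]:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _PRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    rows = []
    for r in df.itertuples(index=False):
        kept = None
        if isinstance(r.kept, (bool, np.bool_)):
            kept = bool(r.kept)
        elif isinstance(r.kept, str):
            kept = r.kept.strip().lower() == "true"
        rows.append(PredictionRow(
            structure_id=str(r.structure_id),
            param=str(r.param),
            atoms=_cols_to_atoms(str(r.param), r.atom1, r.atom2),
            value=float(r.value),
            spread=float(r.spread),
            kept=kept,
        ))
    return rows
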