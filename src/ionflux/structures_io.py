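"""Multi-model PDB reading/writing, atom role classification, and selections.

Coordinates are Angstrom throughout.  Atoms are indexed 0-based internally;
the 1-based PDB serial is preserved on each :class:`AtomRecord` for
reporting.  Frame times default to the frame index in nanoseconds when the
file carries no time metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "Role",
    "AtomRole",
    "SelectionQuery",
    "PDBFormatError",
    "read_pdb",
    "write_pdb",
    "classify_atoms",
    "select_atoms",
    "select_frames",
    "write_tsv",
    "write_json",
    "DEFAULT_LIPID_NAMES",
    "DEFAULT_ION_NAMES",
    "DEFAULT_WATER_NAMES",
]

DEFAULT_LIPID_NAMES = frozenset({"POPE", "POPG", "POPC", "DPPC"})
DEFAULT_ION_NAMES = frozenset({"NA", "SOD", "CL", "CLA", "K", "POT", "MG", "CAL"})
DEFAULT_WATER_NAMES = frozenset({"HOH", "WAT", "TIP3", "TIP", "SOL", "SPC"})

#: residues for which a bare two-letter atom name denotes a monoatomic species
_MONOATOMIC_ELEMENTS = {
    "NA": "NA",
    "SOD": "NA",
    "CL": "CL",
    "CLA": "CL",
    "K": "K",
    "POT": "K",
    "MG": "MG",
    "CAL": "CA",
    "ZN": "ZN",
    "FE": "FE",
    "MN": "MN",
}


class PDBFormatError(ValueError):
    """Raised for structurally invalid PDB input (carries location info)."""


@dataclass(frozen=True)
class AtomRecord:
    """One topology atom; ``position_index`` indexes frame coordinate rows."""

    serial: int
    name: str
    residue_name: str
    residue_number: int
    chain_id: str
    element: str
    position_index: int


@dataclass
class Frame:
    """Coordinates for one trajectory snapshot; ``time`` in ns."""

    coordinates: np.ndarray
    time: float

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("frame coordinates must be an (n_atoms, 3) array")
        if self.time < 0:
            raise ValueError("frame time must be non-negative")


@dataclass
class Trajectory:
    """Topology plus ordered frames.

    ``z_positive_periplasm`` records the membrane-normal sign convention:
    the normal is +z with the periplasmic side at positive z by default.
    """

    topology: Sequence[AtomRecord]
    frames: Sequence[Frame]
    z_positive_periplasm: bool = True

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a trajectory needs at least one frame")
        n = len(self.topology)
        for i, fr in enumerate(self.frames):
            if fr.coordinates.shape[0] != n:
                raise ValueError(
                    f"frame {i} has {fr.coordinates.shape[0]} coordinates "
                    f"for {n} topology atoms"
                )
        times = self.times
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames], dtype=float)

    def coords(self, frame_index: int) -> np.ndarray:
        return self.frames[frame_index].coordinates

    def stacked(self) -> np.ndarray:
        """All coordinates as an (n_frames, n_atoms, 3) array."""
        return np.stack([fr.coordinates for fr in self.frames])

    def flipped_z(self) -> "Trajectory":
        """Return a copy with the z axis negated and the convention toggled."""
        frames = [
            Frame(fr.coordinates * np.array([1.0, 1.0, -1.0]), fr.time)
            for fr in self.frames
        ]
        return Trajectory(self.topology, frames, not self.z_positive_periplasm)


class Role(str, Enum):
    PROTEIN = "protein"
    LIPID = "lipid"
    WATER = "water"
    ION = "ion"
    OTHER = "other"


@dataclass(frozen=True)
class AtomRole:
    role: Role
    is_polar: bool
    is_hydrogen: bool

    def __post_init__(self) -> None:
        if self.is_polar and self.is_hydrogen:
            raise ValueError("is_polar and is_hydrogen are mutually exclusive")


# ---------------------------------------------------------------------------
# PDB parsing (fixed-column, MODEL/ENDMDL multi-model dialect)
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int):
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        residue_name = line[17:21].strip()
        chain_id = line[21:22].strip() or " "
        residue_number = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(
            f"line {lineno}: unparseable fixed-width ATOM/HETATM record: "
            f"{line.rstrip()!r}"
        ) from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    return serial, name, residue_name, residue_number, chain_id, element, (x, y, z)


def read_pdb(path, times: Sequence[float] | None = None) -> Trajectory:
    """Read a (possibly multi-model) PDB file into a :class:`Trajectory`.

    One frame per MODEL record, or a single frame if the file has none.
    Topology is taken from the first model; later models must carry the
    same atom count.  ``times`` overrides the default 0, 1, 2, ... ns
    frame times.
    """
    path = Path(path)
    models: list[list] = []
    current: list | None = None

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if current:
                    models.append(current)
                current = []
            elif rec == "ENDMDL":
                if current is not None:
                    models.append(current)
                current = None
            elif rec in ("ATOM  ", "HETATM"):
                if current is None:
                    current = []
                current.append(_parse_atom_line(line, lineno))
    if current:
        models.append(current)
    if not models or not models[0]:
        raise PDBFormatError(f"{path}: no ATOM/HETATM records found")

    first = models[0]
    topology = tuple(
        AtomRecord(
            serial=a[0],
            name=a[1],
            residue_name=a[2],
            residue_number=a[3],
            chain_id=a[4],
            element=a[5],
            position_index=i,
        )
        for i, a in enumerate(first)
    )
    n_atoms = len(topology)
    for model_i, atoms in enumerate(models, start=1):
        if len(atoms) != n_atoms:
            raise PDBFormatError(
                f"{path}: MODEL {model_i} has {len(atoms)} atoms, "
                f"expected {n_atoms} (from MODEL 1)"
            )
    if times is None:
        times = [float(i) for i in range(len(models))]
    elif len(times) != len(models):
        raise ValueError("times length must match number of models")

    frames = [
        Frame(np.array([a[6] for a in atoms], dtype=float), t)
        for atoms, t in zip(models, times)
    ]
    return Trajectory(topology, frames)


def write_pdb(traj: Trajectory, path,
              hetatm_residues: Iterable[str] = ()) -> None:
    """Write a trajectory as a multi-model PDB (single frame: no MODEL)."""
    path = Path(path)
    het = set(hetatm_residues)
    multi = traj.n_frames > 1
    with path.open("w") as fh:
        for i, fr in enumerate(traj.frames, start=1):
            if multi:
                fh.write(f"MODEL     {i:4d}\n")
            for atom in traj.topology:
                x, y, z = fr.coordinates[atom.position_index]
                record = "HETATM" if atom.residue_name in het else "ATOM  "
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                fh.write(
                    f"{record}{atom.serial % 100000:5d} {name:<4s} "
                    f"{atom.residue_name:<4s}"
                    f"{atom.chain_id:1s}{atom.residue_number % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          "
                    f"{atom.element:>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def infer_element(name: str, residue_name: str) -> str:
    """Infer the element from an atom name (no element column available).

    Strip digits, take the first alphabetic character; monoatomic-ion
    residues resolve through a fixed two-letter lookup.
    """
    residue = residue_name.strip().upper()
    if residue in _MONOATOMIC_ELEMENTS:
        return _MONOATOMIC_ELEMENTS[residue]
    stripped = "".join(ch for ch in name if ch.isalpha())
    if not stripped:
        return "X"
    return stripped[0].upper()


def classify_atoms(
    traj: Trajectory,
    lipid_names: Iterable[str] = DEFAULT_LIPID_NAMES,
    ion_names: Iterable[str] = DEFAULT_ION_NAMES,
    water_names: Iterable[str] = DEFAULT_WATER_NAMES,
) -> list[AtomRole]:
    """Assign every atom a role plus polarity/hydrogen flags.

    The three residue-name sets must be disjoint.  Residues matching none
    of them and none of the standard amino acids get role ``other``.
    """
    lipid = {s.upper() for s in lipid_names}
    ion = {s.upper() for s in ion_names}
    water = {s.upper() for s in water_names}
    if (lipid & ion) or (lipid & water) or (ion & water):
        raise ValueError("lipid/ion/water residue-name sets must be disjoint")

    roles: list[AtomRole] = []
    for atom in traj.topology:
        res = atom.residue_name.upper()
        element = (atom.element or infer_element(atom.name, atom.residue_name)).upper()
        if res in water:
            role = Role.WATER
        elif res in ion:
            role = Role.ION
        elif res in lipid:
            role = Role.LIPID
        elif res in _AMINO_ACIDS:
            role = Role.PROTEIN
        else:
            role = Role.OTHER
        is_h = element == "H"
        is_polar = (not is_h) and element in {"O", "N", "S"}
        roles.append(AtomRole(role=role, is_polar=is_polar, is_hydrogen=is_h))
    return roles


_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS HSD HSE HSP ILE LEU LYS MET PHE "
    "PRO SER THR TRP TYR VAL".split()
)


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

_RECORD_FIELDS = {
    "serial", "name", "residue_name", "residue_number", "chain_id", "element",
}
_ROLE_FIELDS = {"role", "is_polar", "is_hydrogen"}


@dataclass(frozen=True)
class SelectionQuery:
    """Conjunction of equality / membership / range tests on atom fields.

    Each clause is ``(field, op, value)`` with op one of ``"eq"``, ``"in"``,
    ``"range"`` (inclusive bounds).  Role fields require roles to be passed
    to :func:`select_atoms`.
    """

    clauses: tuple = field(default_factory=tuple)

    @classmethod
    def where(cls, **kwargs) -> "SelectionQuery":
        """Build from keyword equality/membership tests.

        Iterable (non-string) values become membership tests.
        """
        clauses = []
        for key, value in kwargs.items():
            if isinstance(value, (set, frozenset, list, tuple)):
                clauses.append((key, "in", tuple(value)))
            else:
                clauses.append((key, "eq", value))
        return cls(tuple(clauses))

    def and_(self, field_name: str, op: str, value) -> "SelectionQuery":
        return SelectionQuery(self.clauses + ((field_name, op, value),))


def _clause_matches(clause, atom: AtomRecord, role: AtomRole | None) -> bool:
    field_name, op, value = clause
    if field_name in _RECORD_FIELDS:
        actual = getattr(atom, field_name)
        if field_name == "element" and not actual:
            actual = infer_element(atom.name, atom.residue_name)
    elif field_name in _ROLE_FIELDS:
        if role is None:
            raise ValueError(
                f"query references role field {field_name!r} but no roles given"
            )
        actual = getattr(role, field_name)
        if field_name == "role":
            actual = actual.value
            value = value.value if isinstance(value, Role) else value
    else:
        raise ValueError(f"unknown selection field: {field_name!r}")
    if op == "eq":
        return actual == value
    if op == "in":
        return actual in value
    if op == "range":
        lo, hi = value
        return lo <= actual <= hi
    raise ValueError(f"unknown selection operator: {op!r}")


def select_atoms(
    traj: Trajectory,
    query: SelectionQuery,
    roles: Sequence[AtomRole] | None = None,
) -> np.ndarray:
    """Evaluate a query; returns 0-based atom indices sorted ascending."""
    out = []
    for i, atom in enumerate(traj.topology):
        role = roles[i] if roles is not None else None
        if all(_clause_matches(c, atom, role) for c in query.clauses):
            out.append(i)
    return np.array(out, dtype=int)


def select_frames(traj: Trajectory, start_time: float, stride: float = 1.0,
                  tol: float = 1e-9) -> Trajectory:
    """Frames with time >= start_time, at the given stride (ns).

    The stride is measured from the first retained frame.  An empty result
    is an error: analysis over zero frames is undefined.
    """
    if stride <= 0:
        raise ValueError("stride must be positive")
    kept: list[Frame] = []
    t0 = None
    for fr in traj.frames:
        if fr.time + tol < start_time:
            continue
        if t0 is None:
            t0 = fr.time
        k = (fr.time - t0) / stride
        if abs(k - round(k)) <= tol * max(1.0, abs(fr.time)):
            kept.append(fr)
    if not kept:
        raise ValueError(
            f"no frames at or after t={start_time} ns with stride {stride} ns"
        )
    return Trajectory(traj.topology, kept, traj.z_positive_periplasm)


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def write_tsv(path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def write_json(path, obj: Mapping) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
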