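"""Per-frame geometric statistics over trajectories.

Contact-fraction maps, ion coordination numbers, nearest-ion distance
series, inter-residue distances, membrane hydrophobic thickness, backbone
dihedral helix assignment, and Kabsch superposition RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .structures_io import AtomRole, Frame, Role, Trajectory

__all__ = [
    "ContactMap",
    "DistanceSeries",
    "ThicknessResult",
    "HelixAssignment",
    "contact_fraction",
    "coordination_number",
    "nearest_ion_distance",
    "residue_pair_distance",
    "hydrophobic_thickness",
    "helix_assignment",
    "kabsch_rmsd",
]

CONTACT_CUTOFF = 3.5   # A, residue heavy atom to probe
COORDINATION_CUTOFF = 2.5  # A, polar atom to ion


@dataclass
class ContactMap:
    """Fraction of frames each residue contacts the probe species."""

    fractions: dict  # (chain_id, residue_number, residue_name) -> float
    probe: str
    cutoff: float
    n_frames: int

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for key, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction out of [0,1] for residue {key}")

    def rows(self):
        for (chain, num, name), frac in sorted(self.fractions.items()):
            yield chain, num, name, frac


@dataclass
class DistanceSeries:
    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class ThicknessResult:
    mean: float
    sd: float
    definition: str  # "phosphorus" or "ester_carbon"
    per_frame: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class HelixAssignment:
    """Per-residue helical flags plus contiguous runs of length >= 4."""

    residues: list          # ordered (chain_id, residue_number) keys
    helical: dict           # key -> bool (unassessed residues absent)
    runs: list              # (chain_id, start_residue, end_residue)


# ---------------------------------------------------------------------------

def _residue_atom_indices(traj: Trajectory) -> dict:
    groups: dict = {}
    for i, atom in enumerate(traj.topology):
        key = (atom.chain_id, atom.residue_number, atom.residue_name)
        groups.setdefault(key, []).append(i)
    return groups


def contact_fraction(
    traj: Trajectory,
    residues: Iterable,
    probe_atoms: Sequence[int],
    roles: Sequence[AtomRole],
    cutoff: float = CONTACT_CUTOFF,
    probe: str = "ion",
) -> ContactMap:
    """Fraction of frames each residue has a heavy atom within ``cutoff``
    of any probe atom.

    ``residues`` are (chain_id, residue_number) pairs; hydrogens are
    excluded from the residue side via ``roles``.  The frame set is exactly
    the supplied trajectory (pre-filter with ``select_frames``).
    """
    probe_atoms = np.asarray(probe_atoms, dtype=int)
    if probe_atoms.size == 0:
        raise ValueError("probe_atoms must be non-empty")
    wanted = set(tuple(r) for r in residues)
    if not wanted:
        raise ValueError("residues must be non-empty")

    groups = {}
    for (chain, num, name), idx in _residue_atom_indices(traj).items():
        if (chain, num) in wanted:
            heavy = [i for i in idx if not roles[i].is_hydrogen]
            if not heavy:
                raise ValueError(
                    f"residue {chain}:{num} has no non-hydrogen atoms"
                )
            groups[(chain, num, name)] = np.array(heavy, dtype=int)
    missing = wanted - {(c, n) for (c, n, _) in groups}
    if missing:
        raise ValueError(f"residues not in topology: {sorted(missing)}")

    counts = {key: 0 for key in groups}
    for fr in traj.frames:
        probe_xyz = fr.coordinates[probe_atoms]
        for key, idx in groups.items():
            dmin = cdist(fr.coordinates[idx], probe_xyz).min()
            if dmin <= cutoff:
                counts[key] += 1
    n = traj.n_frames
    fractions = {key: c / n for key, c in counts.items()}
    return ContactMap(fractions=fractions, probe=probe, cutoff=cutoff, n_frames=n)


def coordination_number(
    frame: Frame,
    ion_index: int,
    roles: Sequence[AtomRole],
    cutoff: float = COORDINATION_CUTOFF,
    species: str = "both",
) -> int:
    """Count polar atoms (O/N/S of protein or water) within ``cutoff`` of
    the ion.  The ion itself and hydrogens never count.

    ``species`` restricts the partners: "protein", "water", or "both".
    """
    if species not in ("protein", "water", "both"):
        raise ValueError("species must be 'protein', 'water' or 'both'")
    allowed = {Role.PROTEIN, Role.WATER} if species == "both" else {Role(species)}
    xyz = frame.coordinates
    ion_pos = xyz[ion_index]
    count = 0
    for i, role in enumerate(roles):
        if i == ion_index or not role.is_polar or role.role not in allowed:
            continue
        if np.linalg.norm(xyz[i] - ion_pos) <= cutoff:
            count += 1
    return count


def nearest_ion_distance(
    traj: Trajectory, atom: int, ion_indices: Sequence[int], label: str = ""
) -> DistanceSeries:
    """Per-frame minimum distance from ``atom`` to any listed ion."""
    ion_indices = np.asarray(ion_indices, dtype=int)
    if ion_indices.size == 0:
        raise ValueError("ion_indices must be non-empty")
    values = np.array([
        np.linalg.norm(fr.coordinates[ion_indices] - fr.coordinates[atom], axis=1).min()
        for fr in traj.frames
    ])
    return DistanceSeries(traj.times, values, label=label)


def residue_pair_distance(
    traj: Trajectory, atom_a: int, atom_b: int, label: str = ""
) -> DistanceSeries:
    """Per-frame Euclidean distance between two atoms."""
    if atom_a == atom_b:
        raise ValueError("atom indices must be distinct")
    values = np.array([
        np.linalg.norm(fr.coordinates[atom_a] - fr.coordinates[atom_b])
        for fr in traj.frames
    ])
    return DistanceSeries(traj.times, values, label=label)


def hydrophobic_thickness(
    traj: Trajectory,
    markers: Sequence[int] | None = None,
    top: Sequence[int] | None = None,
    bottom: Sequence[int] | None = None,
    definition: str = "phosphorus",
) -> ThicknessResult:
    """Membrane thickness as mean(z_top) - mean(z_bottom) of marker atoms.

    Pass explicit ``top``/``bottom`` index sets, or a single ``markers``
    set to have leaflets assigned per frame by the sign of z about the
    median marker z.
    """
    if definition not in ("phosphorus", "ester_carbon"):
        raise ValueError("definition must be 'phosphorus' or 'ester_carbon'")
    explicit = top is not None or bottom is not None
    if explicit and (top is None or bottom is None or len(top) == 0 or len(bottom) == 0):
        raise ValueError("both top and bottom marker sets must be non-empty")
    if not explicit and (markers is None or len(markers) == 0):
        raise ValueError("markers must be non-empty")

    per_frame = []
    for fr in traj.frames:
        if explicit:
            z_top = fr.coordinates[np.asarray(top, dtype=int), 2]
            z_bot = fr.coordinates[np.asarray(bottom, dtype=int), 2]
        else:
            z = fr.coordinates[np.asarray(markers, dtype=int), 2]
            mid = np.median(z)
            z_top = z[z > mid]
            z_bot = z[z <= mid]
            if z_top.size == 0 or z_bot.size == 0:
                raise ValueError("leaflet empty after median-z assignment")
        per_frame.append(z_top.mean() - z_bot.mean())
    per_frame = np.asarray(per_frame)
    sd = float(per_frame.std(ddof=1)) if per_frame.size > 1 else 0.0
    return ThicknessResult(
        mean=float(per_frame.mean()), sd=sd,
        definition=definition, per_frame=per_frame,
    )


# ---------------------------------------------------------------------------
# helix assignment from backbone dihedrals
# ---------------------------------------------------------------------------

PHI_WINDOW = (-100.0, -30.0)
PSI_WINDOW = (-80.0, 5.0)
MIN_RUN = 4


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees for four points."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def helix_assignment(frame: Frame, topology) -> HelixAssignment:
    """Flag residues helical when phi/psi fall in the canonical alpha
    window and belong to a run of >= 4 consecutive such residues.

    Residues missing any backbone atom (N, CA, C) or lacking a neighbour
    needed for the dihedral are unassessed and excluded from runs.
    """
    backbone: dict = {}
    order: list = []
    for atom in topology:
        key = (atom.chain_id, atom.residue_number)
        if key not in backbone:
            backbone[key] = {}
            order.append(key)
        if atom.name in ("N", "CA", "C"):
            backbone[key][atom.name] = frame.coordinates[atom.position_index]

    helical: dict = {}
    for i, key in enumerate(order):
        chain = key[0]
        prev_key = order[i - 1] if i > 0 and order[i - 1][0] == chain else None
        next_key = (
            order[i + 1] if i + 1 < len(order) and order[i + 1][0] == chain else None
        )
        res = backbone[key]
        if not all(k in res for k in ("N", "CA", "C")):
            continue  # unassessed
        if prev_key is None or "C" not in backbone.get(prev_key, {}):
            continue
        if next_key is None or "N" not in backbone.get(next_key, {}):
            continue
        phi = dihedral(backbone[prev_key]["C"], res["N"], res["CA"], res["C"])
        psi = dihedral(res["N"], res["CA"], res["C"], backbone[next_key]["N"])
        helical[key] = (
            PHI_WINDOW[0] <= phi <= PHI_WINDOW[1]
            and PSI_WINDOW[0] <= psi <= PSI_WINDOW[1]
        )

    runs = []
    run: list = []
    for key in order + [None]:
        if key is not None and helical.get(key, False):
            if run and (key[0] != run[-1][0] or key[1] != run[-1][1] + 1):
                if len(run) >= MIN_RUN:
                    runs.append((run[0][0], run[0][1], run[-1][1]))
                run = []
            run.append(key)
        else:
            if len(run) >= MIN_RUN:
                runs.append((run[0][0], run[0][1], run[-1][1]))
            run = []

    # residues helical only when inside a qualifying run
    in_run = set()
    for chain, start, end in runs:
        for num in range(start, end + 1):
            in_run.add((chain, num))
    final = {key: (key in in_run) for key in helical}
    return HelixAssignment(residues=order, helical=final, runs=runs)


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimal RMSD between two point sets over all rigid superpositions."""
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate arrays must share an (N, 3) shape")
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = A @ R.T - B
    return float(np.sqrt((diff ** 2).sum() / A.shape[0]))
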