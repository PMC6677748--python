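"""Constant-velocity pulling (steered-MD) force-profile analysis.

Parses per-trial force logs, pools trials, smooths force-vs-position and
coordination-vs-position curves, extracts peaks, forms mutant/wild-type
peak ratios, and quantifies convergence with trial count.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .structures_io import AtomRole, Trajectory
from .trajectory_metrics import coordination_number

__all__ = [
    "SMDSchedule",
    "ForceLog",
    "AggregatedProfile",
    "PeakStats",
    "parse_force_log",
    "write_force_log",
    "aggregate_trials",
    "moving_average",
    "profile",
    "peak_stats",
    "peak_ratio",
    "coordination_vs_z",
    "convergence_curve",
    "FORCE_WINDOW",
    "COORDINATION_WINDOW",
]

FORCE_WINDOW = 501          # centered points, self included
COORDINATION_WINDOW = 101

LOG_HEADER = ("time_ps", "z_A", "force_kcal_mol_A")


@dataclass(frozen=True)
class SMDSchedule:
    """Constant-velocity pulling schedule.

    Units: kcal/mol/A^2 for spring constants, A/ps for velocity, ps for
    duration, A for pull distance.  The anchor travels exactly
    ``velocity * duration``.
    """

    spring_k: float = 6.16
    velocity: float = 0.05
    lateral_k: float = 1.0
    duration: float = 1000.0
    pull_distance: float = 50.0

    def __post_init__(self) -> None:
        for name in ("spring_k", "velocity", "lateral_k", "duration",
                     "pull_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        expected = self.velocity * self.duration
        if abs(self.pull_distance - expected) > 1e-9 * max(1.0, expected):
            raise ValueError(
                f"pull_distance {self.pull_distance} != velocity*duration "
                f"{expected}"
            )

    def anchor_displacement(self) -> float:
        """Total anchor travel over the full schedule (A)."""
        return self.velocity * self.duration


@dataclass
class ForceLog:
    """One pulling trial: time (ps), ion z (A), applied spring force."""

    trial_id: int
    time: np.ndarray
    z: np.ndarray
    force: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if not (self.time.shape == self.z.shape == self.force.shape):
            raise ValueError("time, z, force must have equal length")
        if self.time.size < 2:
            raise ValueError("a force log needs at least 2 records")
        bad = np.nonzero(np.diff(self.time) <= 0)[0]
        if bad.size:
            raise ValueError(
                f"time not strictly increasing at record {int(bad[0]) + 1}"
            )

    @property
    def n_records(self) -> int:
        return self.time.size


@dataclass
class AggregatedProfile:
    """Pooled, z-sorted, moving-average-smoothed profile."""

    z: np.ndarray
    values: np.ndarray
    smoothing_window: int
    source_trials: int
    kind: str  # "force" or "coordination"
    raw_values: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.z) < 0):
            raise ValueError("profile z must be non-decreasing")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")
        if self.kind not in ("force", "coordination"):
            raise ValueError("kind must be 'force' or 'coordination'")


@dataclass
class PeakStats:
    max_value: float
    z_at_max: float
    peaks: list  # (z, value) local maxima above the prominence threshold


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def parse_force_log(path, trial_id: int | None = None) -> ForceLog:
    """Read a whitespace/TSV force log with columns time_ps, z_A, force.

    Lines starting with ``#`` are comments; ``# trial: N`` sets the trial
    id, as do trailing digits in the file name.  Non-monotone time is an
    error naming the offending record.
    """
    path = Path(path)
    times, zs, forces = [], [], []
    header_trial = None
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.search(r"trial\s*[:=]\s*(\d+)", line)
            if m:
                header_trial = int(m.group(1))
            continue
        parts = line.split()
        try:
            t, z, f = float(parts[0]), float(parts[1]), float(parts[2])
        except (ValueError, IndexError):
            if not times and any(c.isalpha() for c in line):
                continue  # column header row
            raise ValueError(f"{path}: unparseable record: {line!r}")
        times.append(t)
        zs.append(z)
        forces.append(f)
    if trial_id is None:
        if header_trial is not None:
            trial_id = header_trial
        else:
            m = re.search(r"(\d+)\D*$", path.stem)
            trial_id = int(m.group(1)) if m else 0
    return ForceLog(trial_id=trial_id, time=times, z=zs, force=forces)


def write_force_log(log: ForceLog, path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"# trial: {log.trial_id}\n")
        fh.write("\t".join(LOG_HEADER) + "\n")
        for t, z, f in zip(log.time, log.z, log.force):
            fh.write(f"{t:.6g}\t{z:.6f}\t{f:.6f}\n")


# ---------------------------------------------------------------------------
# pooling and smoothing
# ---------------------------------------------------------------------------

def aggregate_trials(logs: Sequence[ForceLog]):
    """Concatenate all trials, sorted by z ascending with a stable
    (trial_id, time) tie-break.  Returns (z, values) arrays."""
    if not logs:
        raise ValueError("at least one force log required")
    z = np.concatenate([lg.z for lg in logs])
    v = np.concatenate([lg.force for lg in logs])
    trial = np.concatenate([np.full(lg.n_records, lg.trial_id) for lg in logs])
    time = np.concatenate([lg.time for lg in logs])
    order = np.lexsort((time, trial, z))
    return z[order], v[order]


def moving_average(values, window: int) -> np.ndarray:
    """Centered moving average, truncated at the edges.

    ``window`` is the total centered width (self plus surroundings); even
    values are normalized up to the next odd number.  Output length equals
    input length; each point averages the in-window points available.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if window % 2 == 0:
        window += 1
    values = np.asarray(values, dtype=float)
    n = values.size
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half + 1)
    return (csum[hi] - csum[lo]) / (hi - lo)


def profile(
    logs: Sequence[ForceLog],
    kind: str = "force",
    window: int | None = None,
) -> AggregatedProfile:
    """Pool trials and smooth the z-sorted values with a centered window.

    Window defaults: 501 points for force, 101 for coordination.
    """
    if window is None:
        window = FORCE_WINDOW if kind == "force" else COORDINATION_WINDOW
    if window % 2 == 0:
        window += 1
    z, raw = aggregate_trials(logs)
    smooth = moving_average(raw, window)
    return AggregatedProfile(
        z=z, values=smooth, smoothing_window=window,
        source_trials=len(logs), kind=kind, raw_values=raw,
    )


def peak_stats(prof: AggregatedProfile, prominence_frac: float = 0.05) -> PeakStats:
    """Global maximum plus local maxima above a prominence threshold
    (fraction of the profile's value range)."""
    if prof.values.size < 3:
        raise ValueError("profile needs at least 3 points")
    i_max = int(np.argmax(prof.values))
    rng = float(prof.values.max() - prof.values.min())
    prominence = prominence_frac * rng if rng > 0 else None
    if prominence:
        idx, _ = find_peaks(prof.values, prominence=prominence)
    else:
        idx = np.array([], dtype=int)
    peaks = [(float(prof.z[i]), float(prof.values[i])) for i in idx]
    return PeakStats(
        max_value=float(prof.values[i_max]),
        z_at_max=float(prof.z[i_max]),
        peaks=peaks,
    )


def peak_ratio(profile_mut: AggregatedProfile, profile_wt: AggregatedProfile) -> float:
    """max(mutant) / max(wild-type) of the smoothed profiles."""
    if profile_mut.kind != profile_wt.kind:
        raise ValueError("profiles must share a kind")
    wt_max = float(profile_wt.values.max())
    if wt_max <= 0:
        raise ValueError("wild-type profile maximum must be positive")
    return float(profile_mut.values.max()) / wt_max


def coordination_vs_z(
    traj: Trajectory,
    ion_index: int,
    roles: Sequence[AtomRole],
    cutoff: float = 2.5,
    window: int = COORDINATION_WINDOW,
    species: str = "both",
) -> AggregatedProfile:
    """Per-frame (ion z, coordination number), z-sorted and smoothed.

    ``species`` selects protein-only, water-only, or both partner sets.
    """
    zs = np.array([fr.coordinates[ion_index, 2] for fr in traj.frames])
    counts = np.array([
        coordination_number(fr, ion_index, roles, cutoff=cutoff, species=species)
        for fr in traj.frames
    ], dtype=float)
    order = np.argsort(zs, kind="stable")
    z_sorted, raw = zs[order], counts[order]
    if window % 2 == 0:
        window += 1
    smooth = moving_average(raw, window)
    return AggregatedProfile(
        z=z_sorted, values=smooth, smoothing_window=window,
        source_trials=1, kind="coordination", raw_values=raw,
    )


def convergence_curve(
    logs: Sequence[ForceLog],
    subset_sizes: Sequence[int] = (1, 2, 3, 5, 8, 10),
    window: int = FORCE_WINDOW,
) -> list[float]:
    """Mean absolute deviation of each k-trial profile from the all-trial
    profile, compared on a common uniform z grid by linear interpolation."""
    full = profile(logs, kind="force", window=window)
    grid = np.linspace(full.z[0], full.z[-1], 500)
    full_on_grid = np.interp(grid, full.z, full.values)
    out = []
    for k in subset_sizes:
        if k > len(logs):
            raise ValueError(f"subset size {k} exceeds {len(logs)} logs")
        sub = profile(logs[:k], kind="force", window=window)
        sub_on_grid = np.interp(grid, sub.z, sub.values)
        out.append(float(np.abs(sub_on_grid - full_on_grid).mean()))
    return out
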