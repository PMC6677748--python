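"""Synthetic input generators with known ground truth.

Every generator returns a ``(data, ground_truth)`` pair and draws all of
its randomness from one explicit seed, so downstream recovery tests can
close the loop exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ftir import NACL_SERIES_MM, Spectrum, default_grid
from .smd_profile import ForceLog, SMDSchedule
from .structures_io import AtomRecord, Frame, Trajectory

__all__ = [
    "BindingScript",
    "ScriptEntry",
    "PotentialSpec",
    "GaussianFeature",
    "Band",
    "FTIRModel",
    "build_membrane_system",
    "generate_binding_trajectory",
    "simulate_smd_1d",
    "generate_ftir_dataset",
    "default_ftir_model",
    "KCAL_MOL_K",
]

KCAL_MOL_K = 0.0019872041  # Boltzmann constant, kcal/mol/K


# ---------------------------------------------------------------------------
# membrane pseudo-system
# ---------------------------------------------------------------------------

def build_membrane_system(
    n_pope: int = 324,
    n_popg: int = 108,
    thickness: float = 38.2,
    area: float | None = None,
    n_frames: int = 1,
    jitter_sd: float = 0.5,
    seed: int = 0,
):
    """Pseudo-lipid bilayer: per lipid a phosphorus marker at z = +-t/2
    (with seeded Gaussian jitter) and ester-carbon markers 4 A inward.

    Species are split evenly between leaflets.  Returns
    ``(Trajectory, ground_truth)`` where the truth records the noise-free
    thickness and composition.
    """
    if n_pope <= 0 or n_popg <= 0:
        raise ValueError("lipid counts must be positive")
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    n_lipids = n_pope + n_popg
    if area is None:
        area = 65.0 * n_lipids / 2  # ~65 A^2 per lipid per leaflet
    side = math.sqrt(area)
    per_leaflet = (n_lipids + 1) // 2
    n_grid = math.ceil(math.sqrt(per_leaflet))
    spacing = side / n_grid

    rng = np.random.default_rng(seed)
    names = ["POPE"] * n_pope + ["POPG"] * n_popg
    # alternate leaflets within each species so both stay balanced
    leaflets = [1 if i % 2 == 0 else -1 for i in range(n_pope)]
    leaflets += [1 if i % 2 == 0 else -1 for i in range(n_popg)]

    topology = []
    base_xy = []
    serial = 1
    pos = 0
    slot = {1: 0, -1: 0}
    for res_i, (res_name, leaf) in enumerate(zip(names, leaflets), start=1):
        k = slot[leaf]
        slot[leaf] += 1
        x = (k % n_grid + 0.5) * spacing
        y = (k // n_grid + 0.5) * spacing
        for atom_name, element in (("P", "P"), ("C21", "C"), ("C31", "C")):
            topology.append(AtomRecord(
                serial=serial, name=atom_name, residue_name=res_name,
                residue_number=res_i, chain_id="M", element=element,
                position_index=pos,
            ))
            base_xy.append((x, y, leaf, atom_name))
            serial += 1
            pos += 1

    half = thickness / 2.0
    frames = []
    for t in range(n_frames):
        coords = np.empty((len(topology), 3))
        for i, (x, y, leaf, atom_name) in enumerate(base_xy):
            z0 = leaf * half
            if atom_name != "P":
                z0 -= leaf * 4.0  # ester carbons sit 4 A inward
            jitter = rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0
            coords[i] = (x, y, z0 + jitter)
        frames.append(Frame(coords, float(t)))

    traj = Trajectory(topology, frames)
    truth = {
        "n_pope": n_pope,
        "n_popg": n_popg,
        "n_lipids": n_lipids,
        "pope_popg_ratio": n_pope / n_popg,
        "thickness_phosphorus": thickness,
        "thickness_ester_carbon": thickness - 8.0,
        "jitter_sd": jitter_sd,
    }
    return traj, truth


# ---------------------------------------------------------------------------
# scripted ion-binding trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScriptEntry:
    """Frame intervals (half-open, [start, end)) during which the probe
    contacts this residue."""

    chain_id: str
    residue_number: int
    residue_name: str = "ASP"
    intervals: tuple = ()


@dataclass
class BindingScript:
    entries: Sequence[ScriptEntry]

    def validate(self, n_frames: int) -> None:
        occupied = []
        for entry in self.entries:
            for start, end in entry.intervals:
                if not (0 <= start < end <= n_frames):
                    raise ValueError(
                        f"interval ({start}, {end}) outside [0, {n_frames})"
                    )
                occupied.append((start, end, entry))
        occupied.sort(key=lambda x: x[0])
        for (s1, e1, _), (s2, e2, _) in zip(occupied, occupied[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping script intervals ({s1},{e1}) and ({s2},{e2})"
                )

    def fraction(self, entry: ScriptEntry, n_frames: int) -> float:
        return sum(e - s for s, e in entry.intervals) / n_frames


CONTACT_DISTANCE = 2.0   # A, probe-to-residue distance during an interval
APART_DISTANCE = 10.0    # minimum separation outside intervals
_RESIDUE_SPACING = 50.0  # residues far apart so contacts are exclusive


def generate_binding_trajectory(script: BindingScript, n_frames: int,
                                seed: int = 0):
    """Trajectory in which the probe ion sits 2 A from a scripted residue
    atom during its intervals and >= 10 A from every residue otherwise.

    Contact-fraction analysis on the output recovers each entry's scripted
    fraction exactly.  Returns ``(Trajectory, ground_truth)``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    script.validate(n_frames)
    rng = np.random.default_rng(seed)

    topology = []
    residue_pos = {}
    serial = 1
    for i, entry in enumerate(script.entries):
        x = i * _RESIDUE_SPACING
        residue_pos[i] = np.array([x, 0.0, 0.0])
        topology.append(AtomRecord(
            serial=serial, name="OD1", residue_name=entry.residue_name,
            residue_number=entry.residue_number, chain_id=entry.chain_id,
            element="O", position_index=i,
        ))
        serial += 1
    probe_index = len(topology)
    topology.append(AtomRecord(
        serial=serial, name="NA", residue_name="NA",
        residue_number=9999, chain_id="I", element="NA",
        position_index=probe_index,
    ))

    rest = np.array([-_RESIDUE_SPACING, 0.0, 500.0])  # far from everything
    frame_owner = {}
    for i, entry in enumerate(script.entries):
        for start, end in entry.intervals:
            for f in range(start, end):
                frame_owner[f] = i

    frames = []
    for f in range(n_frames):
        coords = np.empty((len(topology), 3))
        for i in residue_pos:
            coords[i] = residue_pos[i]
        if f in frame_owner:
            owner = frame_owner[f]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            coords[probe_index] = residue_pos[owner] + CONTACT_DISTANCE * direction
        else:
            coords[probe_index] = rest
        frames.append(Frame(coords, float(f)))

    traj = Trajectory(topology, frames)
    truth = {
        "probe_index": probe_index,
        "fractions": {
            (e.chain_id, e.residue_number): script.fraction(e, n_frames)
            for e in script.entries
        },
    }
    return traj, truth


# ---------------------------------------------------------------------------
# 1D overdamped Langevin pulling surrogate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianFeature:
    """One Gaussian barrier (height > 0) or well (height < 0)."""

    center: float  # A
    height: float  # kcal/mol
    width: float   # A (Gaussian sigma)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("feature width must be positive")


@dataclass
class PotentialSpec:
    features: Sequence[GaussianFeature] = field(default_factory=tuple)

    def energy(self, z):
        z = np.asarray(z, dtype=float)
        u = np.zeros_like(z)
        for f in self.features:
            u += f.height * np.exp(-((z - f.center) ** 2) / (2 * f.width ** 2))
        return u

    def gradient(self, z):
        """dU/dz."""
        z = np.asarray(z, dtype=float)
        g = np.zeros_like(z)
        for f in self.features:
            g += (
                -f.height * (z - f.center) / f.width ** 2
                * np.exp(-((z - f.center) ** 2) / (2 * f.width ** 2))
            )
        return g

    def max_curvature(self, z_lo: float, z_hi: float, n: int = 2001) -> float:
        z = np.linspace(z_lo, z_hi, n)
        if not self.features:
            return 0.0
        eps = 1e-4
        d2 = (self.gradient(z + eps) - self.gradient(z - eps)) / (2 * eps)
        return float(np.abs(d2).max())

    def scaled(self, factor: float) -> "PotentialSpec":
        return PotentialSpec(tuple(
            GaussianFeature(f.center, f.height * factor, f.width)
            for f in self.features
        ))


#: default friction: drag force ~ 1 kcal/mol/A at the default 0.05 A/ps
DEFAULT_FRICTION = 20.0  # kcal/mol * ps / A^2


def simulate_smd_1d(
    potential: PotentialSpec,
    schedule: SMDSchedule | None = None,
    friction: float = DEFAULT_FRICTION,
    temperature: float = 300.0,
    dt: float = 0.01,
    seed: int = 0,
    z_start: float = 0.0,
    record_stride: int = 1,
    trial_id: int = 0,
) -> ForceLog:
    """Overdamped Langevin pulling of a particle through a 1D potential.

    The spring anchor moves as z0 + v*t; the recorded force is
    spring_k * (z_anchor - z).  Stability requires
    dt < friction / (spring_k + max|U''|); violations raise before
    integration, divergence raises during it.
    """
    schedule = schedule or SMDSchedule()
    if friction <= 0 or dt <= 0:
        raise ValueError("friction and dt must be positive")
    k_max = schedule.spring_k + potential.max_curvature(
        z_start - 5.0, z_start + schedule.pull_distance + 5.0
    )
    if dt >= friction / k_max:
        raise ValueError(
            f"dt={dt} unstable: require dt < friction/(k_spring + max|U''|) "
            f"= {friction / k_max:.4g} ps"
        )
    rng = np.random.default_rng(seed)
    n_steps = int(round(schedule.duration / dt))
    noise_sd = math.sqrt(2.0 * KCAL_MOL_K * max(temperature, 0.0) * dt / friction)
    xi = rng.normal(0.0, 1.0, size=n_steps) if noise_sd > 0 else np.zeros(n_steps)

    z = z_start
    times, zs, forces = [], [], []
    bound = schedule.pull_distance + 50.0
    for step in range(n_steps):
        t = step * dt
        anchor = z_start + schedule.velocity * t
        f_spring = schedule.spring_k * (anchor - z)
        if step % record_stride == 0:
            times.append(t)
            zs.append(z)
            forces.append(f_spring)
        f_total = f_spring - float(potential.gradient(z))
        z = z + (f_total / friction) * dt + noise_sd * xi[step]
        if not np.isfinite(z) or abs(z - anchor) > bound:
            raise RuntimeError(
                f"pulling simulation diverged at t={t:.3f} ps; use a smaller dt"
            )
    return ForceLog(trial_id=trial_id, time=times, z=zs, force=forces)


# ---------------------------------------------------------------------------
# FTIR spectrum generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Band:
    """One Gaussian difference band.

    ``selective`` bands respond to the selective cation (Na) only, with a
    Hill-shaped concentration dependence; non-selective bands respond to
    every cation with a concentration-independent amplitude (any C > 0).
    """

    center: float      # cm^-1
    sign: int          # +1 or -1
    width: float       # cm^-1 (sigma)
    amplitude: float   # saturating (Hill) or constant amplitude
    selective: bool = True
    kd: float = 3.5    # mM, used when selective
    n: float = 0.9

    def response(self, conc: float, cation: str, selective_cation: str) -> float:
        if conc <= 0:
            return 0.0
        if self.selective:
            if cation != selective_cation:
                return 0.0
            return self.amplitude * conc ** self.n / (self.kd ** self.n + conc ** self.n)
        return self.amplitude


@dataclass
class FTIRModel:
    bands: Sequence[Band]
    drift_slope: float = 0.0        # absorbance per cm^-1, linear drift
    drift_offset: float = 0.0
    noise_sd: float = 0.0
    selective_cation: str = "Na"
    grid: np.ndarray = field(default_factory=default_grid)


def default_ftir_model(noise_sd: float = 0.0, drift_slope: float = 0.0,
                       drift_offset: float = 0.0) -> FTIRModel:
    """Band inventory mirroring the observed difference features: amide-I
    pair 1662(+)/1648(-) with Kd 3.5 mM / n 0.9, Thr sidechain pair
    1115(+)/1061(-) with Kd 6.5 mM / n 0.7, plus non-selective bands."""
    bands = (
        Band(1662.0, +1, 4.0, 0.5, selective=True, kd=3.5, n=0.9),
        Band(1648.0, -1, 4.0, 0.5, selective=True, kd=3.5, n=0.9),
        Band(1631.0, +1, 4.0, 0.2, selective=True, kd=3.5, n=0.9),
        Band(1115.0, +1, 5.0, 0.3, selective=True, kd=6.5, n=0.7),
        Band(1061.0, -1, 5.0, 0.3, selective=True, kd=6.5, n=0.7),
        # non-selective cation response in the amide II / nu_s regions
        Band(1554.0, -1, 5.0, 0.15, selective=False),
        Band(1417.0, -1, 5.0, 0.1, selective=False),
    )
    return FTIRModel(
        bands=bands, noise_sd=noise_sd,
        drift_slope=drift_slope, drift_offset=drift_offset,
    )


def generate_ftir_dataset(
    model: FTIRModel,
    concentrations: Sequence[float] = NACL_SERIES_MM,
    cations: Sequence[str] = ("Na", "K"),
    seed: int = 0,
    solvent: str = "H2O",
):
    """Spectra for every (cation, concentration) plus the shared 0-mM
    reference per cation.

    Each spectrum is the band sum at that condition plus linear drift and
    seeded Gaussian noise.  Returns ``(spectra, ground_truth)`` with
    ``spectra[(cation, conc)]`` a :class:`Spectrum`.
    """
    rng = np.random.default_rng(seed)
    wn = model.grid
    mid = wn.mean()
    spectra = {}
    for cation in cations:
        for conc in [0.0] + [float(c) for c in concentrations]:
            values = model.drift_offset + model.drift_slope * (wn - mid)
            for band in model.bands:
                amp = band.sign * band.response(conc, cation, model.selective_cation)
                if amp != 0.0:
                    values = values + amp * np.exp(
                        -((wn - band.center) ** 2) / (2 * band.width ** 2)
                    )
            if model.noise_sd > 0:
                values = values + rng.normal(0.0, model.noise_sd, size=wn.size)
            spectra[(cation, conc)] = Spectrum(
                wavenumbers=wn.copy(), absorbance=values,
                condition={"cation": cation, "conc_mM": conc, "solvent": solvent},
            )
    truth = {
        "bands": [
            {
                "center": b.center, "sign": b.sign, "width": b.width,
                "amplitude": b.amplitude, "selective": b.selective,
                "kd": b.kd if b.selective else None,
                "n": b.n if b.selective else None,
            }
            for b in model.bands
        ],
        "selective_cation": model.selective_cation,
        "noise_sd": model.noise_sd,
    }
    return spectra, truth
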