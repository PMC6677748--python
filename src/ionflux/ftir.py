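"""ATR-FTIR difference-spectroscopy processing.

On-minus-off difference spectra, cycle averaging, baseline-drift removal,
cation double differences, band-pair intensities, Hill binding fits, and
carboxylate stretch-separation coordination-mode calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Spectrum",
    "DifferenceSpectrum",
    "BandPair",
    "BindingCurve",
    "HillFit",
    "HillFitError",
    "CoordinationModeCall",
    "default_grid",
    "difference_spectrum",
    "average_cycles",
    "subtract_baseline",
    "double_difference",
    "band_intensity",
    "binding_curve",
    "hill",
    "fit_hill",
    "nu_separations",
    "classify_coordination",
    "NACL_SERIES_MM",
    "AMIDE_BAND_PAIR",
    "THR_BAND_PAIR",
    "DEFAULT_ANCHOR_REGIONS",
]

#: NaCl titration series used for binding curves (mM)
NACL_SERIES_MM = (0.5, 2.0, 10.0, 20.0, 50.0, 100.0)

DEFAULT_ANCHOR_REGIONS = ((1780.0, 1750.0), (1010.0, 1000.0))


def default_grid(start: float = 1800.0, stop: float = 1000.0,
                 step: float = 2.0) -> np.ndarray:
    """Strictly descending uniform wavenumber grid (cm^-1)."""
    if start <= stop or step <= 0:
        raise ValueError("grid must descend: start > stop, step > 0")
    n = int(round((start - stop) / step)) + 1
    return start - step * np.arange(n)


def _check_grid(wn: np.ndarray) -> np.ndarray:
    wn = np.asarray(wn, dtype=float)
    d = np.diff(wn)
    if wn.size < 2 or np.any(d >= 0):
        raise ValueError("wavenumber grid must be strictly descending")
    if not np.allclose(d, d[0], rtol=0, atol=1e-6):
        raise ValueError("wavenumber grid must be uniform")
    return wn


@dataclass
class Spectrum:
    """Absorbance on a descending uniform wavenumber grid."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    condition: dict = field(default_factory=dict)  # cation, conc_mM, solvent

    def __post_init__(self) -> None:
        self.wavenumbers = _check_grid(self.wavenumbers)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.shape != self.wavenumbers.shape:
            raise ValueError("absorbance length must match grid")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")


@dataclass
class DifferenceSpectrum:
    wavenumbers: np.ndarray
    values: np.ndarray
    on_condition: dict = field(default_factory=dict)
    off_condition: dict = field(default_factory=dict)
    n_cycles: int = 1

    def __post_init__(self) -> None:
        self.wavenumbers = _check_grid(self.wavenumbers)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.wavenumbers.shape:
            raise ValueError("values length must match grid")


@dataclass(frozen=True)
class BandPair:
    """Positive-lobe / negative-lobe wavenumber pair (cm^-1)."""

    peak_wavenumber: float
    trough_wavenumber: float


#: 1662(+)/1648(-) amide-I pair and 1115(+)/1061(-) Thr sidechain pair
AMIDE_BAND_PAIR = BandPair(1662.0, 1648.0)
THR_BAND_PAIR = BandPair(1115.0, 1061.0)


@dataclass
class BindingCurve:
    concentrations: np.ndarray  # mM, ascending
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.concentrations.shape != self.intensities.shape:
            raise ValueError("concentrations and intensities must match")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")
        if np.unique(self.concentrations).size != self.concentrations.size:
            raise ValueError("concentrations must be distinct")
        order = np.argsort(self.concentrations)
        self.concentrations = self.concentrations[order]
        self.intensities = self.intensities[order]


@dataclass
class HillFit:
    amplitude: float
    kd: float       # mM
    n_hill: float
    residual_rms: float

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.n_hill <= 0:
            raise ValueError("kd and n_hill must be positive")


class HillFitError(RuntimeError):
    """Fit failed to converge; carries the best parameters seen so far."""

    def __init__(self, message: str, best: HillFit | None = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class CoordinationModeCall:
    delta: float  # nu_as - nu_s, cm^-1
    call: str     # bidentate_or_pseudobridged | less_bidentate | indeterminate


# ---------------------------------------------------------------------------
# spectral arithmetic
# ---------------------------------------------------------------------------

def _require_matching_grids(a, b) -> None:
    if a.wavenumbers.shape != b.wavenumbers.shape or not np.allclose(
        a.wavenumbers, b.wavenumbers, rtol=0, atol=1e-9
    ):
        raise ValueError("wavenumber grids do not match")


def difference_spectrum(on: Spectrum, off: Spectrum) -> DifferenceSpectrum:
    """Pointwise on - off (ligand-on minus ligand-off)."""
    _require_matching_grids(on, off)
    if on.condition.get("solvent") != off.condition.get("solvent"):
        raise ValueError("on/off spectra must share a solvent")
    return DifferenceSpectrum(
        wavenumbers=on.wavenumbers.copy(),
        values=on.absorbance - off.absorbance,
        on_condition=dict(on.condition),
        off_condition=dict(off.condition),
    )


def average_cycles(diffs: Sequence[DifferenceSpectrum]) -> DifferenceSpectrum:
    """Pointwise mean over forward/backward measurement cycles."""
    if not diffs:
        raise ValueError("at least one cycle required")
    first = diffs[0]
    for d in diffs[1:]:
        _require_matching_grids(first, d)
    mean = np.mean([d.values for d in diffs], axis=0)
    return DifferenceSpectrum(
        wavenumbers=first.wavenumbers.copy(),
        values=mean,
        on_condition=dict(first.on_condition),
        off_condition=dict(first.off_condition),
        n_cycles=len(diffs),
    )


def subtract_baseline(
    diff: DifferenceSpectrum,
    model: str = "linear",
    anchor_regions: Iterable = DEFAULT_ANCHOR_REGIONS,
    order: int | None = None,
) -> DifferenceSpectrum:
    """Remove a drift baseline fitted by least squares over band-free
    anchor windows.

    ``model``: "none", "linear", or "polynomial" (with ``order``).
    """
    if model == "none":
        return replace(diff, values=diff.values.copy())
    if model == "linear":
        deg = 1
    elif model == "polynomial":
        if order is None or order < 0:
            raise ValueError("polynomial model requires a non-negative order")
        deg = order
    else:
        raise ValueError(f"unknown baseline model: {model!r}")

    wn = diff.wavenumbers
    mask = np.zeros(wn.size, dtype=bool)
    for hi, lo in anchor_regions:
        hi, lo = max(hi, lo), min(hi, lo)
        if hi > wn[0] or lo < wn[-1]:
            raise ValueError(f"anchor region ({hi}, {lo}) outside grid")
        mask |= (wn <= hi) & (wn >= lo)
    n_anchor = int(mask.sum())
    if deg + 1 > n_anchor:
        raise ValueError(
            f"polynomial order {deg} needs more than {n_anchor} anchor points"
        )
    # center the abscissa for conditioning
    x0 = wn.mean()
    coef = np.polyfit(wn[mask] - x0, diff.values[mask], deg)
    baseline = np.polyval(coef, wn - x0)
    return replace(diff, values=diff.values - baseline)


def double_difference(
    na_diff: DifferenceSpectrum, k_diff: DifferenceSpectrum
) -> DifferenceSpectrum:
    """Cation double difference: (Na on-off) minus (K on-off)."""
    _require_matching_grids(na_diff, k_diff)
    return DifferenceSpectrum(
        wavenumbers=na_diff.wavenumbers.copy(),
        values=na_diff.values - k_diff.values,
        on_condition=dict(na_diff.on_condition),
        off_condition=dict(k_diff.on_condition),
        n_cycles=min(na_diff.n_cycles, k_diff.n_cycles),
    )


def _snap_index(wn: np.ndarray, target: float) -> int:
    step = abs(wn[1] - wn[0])
    if target > wn[0] + step / 2 or target < wn[-1] - step / 2:
        raise ValueError(f"wavenumber {target} outside grid "
                         f"[{wn[-1]}, {wn[0]}]")
    return int(np.argmin(np.abs(wn - target)))


def band_intensity(diff: DifferenceSpectrum, pair: BandPair) -> float:
    """Peak-minus-trough amplitude at the pair's (grid-snapped) positions."""
    i_peak = _snap_index(diff.wavenumbers, pair.peak_wavenumber)
    i_trough = _snap_index(diff.wavenumbers, pair.trough_wavenumber)
    return float(diff.values[i_peak] - diff.values[i_trough])


def binding_curve(
    diffs_by_conc: dict, pair: BandPair
) -> BindingCurve:
    """Band-pair intensity at each concentration (mM -> DifferenceSpectrum)."""
    concs = sorted(diffs_by_conc)
    intensities = [band_intensity(diffs_by_conc[c], pair) for c in concs]
    return BindingCurve(np.array(concs, dtype=float), np.array(intensities))


# ---------------------------------------------------------------------------
# Hill fitting
# ---------------------------------------------------------------------------

def hill(conc, amplitude, kd, n):
    """I(C) = A C^n / (Kd^n + C^n)."""
    conc = np.asarray(conc, dtype=float)
    cn = np.power(conc, n, where=conc > 0, out=np.zeros_like(conc))
    return amplitude * cn / (kd ** n + cn)


def fit_hill(curve: BindingCurve, max_restarts: int = 3,
             seed: int = 0) -> HillFit:
    """Least-squares Hill fit with jittered-multistart fallback.

    Initialization: amplitude at the max intensity, Kd at the concentration
    nearest half-max, n = 1.  Bounds: Kd in (0, 1e3] mM, n in (0, 10].
    """
    if curve.concentrations.size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    c = curve.concentrations
    y = curve.intensities
    a0 = float(y.max()) if y.max() > 0 else 1.0
    kd0 = float(c[np.argmin(np.abs(y - a0 / 2))])
    kd0 = max(kd0, 1e-6)
    lower = [1e-12, 1e-9, 1e-3]
    upper = [np.inf, 1e3, 10.0]

    rng = np.random.default_rng(seed)
    best = None
    best_rms = np.inf
    last_err = None
    for attempt in range(max_restarts):
        if attempt == 0:
            p0 = [a0, kd0, 1.0]
        else:
            p0 = [
                a0 * rng.uniform(0.5, 2.0),
                np.clip(kd0 * rng.uniform(0.2, 5.0), lower[1], upper[1]),
                rng.uniform(0.3, 3.0),
            ]
        try:
            popt, _ = curve_fit(
                hill, c, y, p0=p0, bounds=(lower, upper), maxfev=20000
            )
        except (RuntimeError, ValueError) as exc:
            last_err = exc
            continue
        rms = float(np.sqrt(np.mean((hill(c, *popt) - y) ** 2)))
        if rms < best_rms:
            best_rms = rms
            best = HillFit(
                amplitude=float(popt[0]), kd=float(popt[1]),
                n_hill=float(popt[2]), residual_rms=rms,
            )
        scale = max(abs(y).max(), 1e-12)
        if rms <= 1e-8 * scale or attempt == 0:
            # first attempt converging is accepted; restarts only refine
            break
    if best is None:
        raise HillFitError(f"Hill fit failed to converge: {last_err}", best=None)
    return best


# ---------------------------------------------------------------------------
# carboxylate stretch separations
# ---------------------------------------------------------------------------

#: default thresholds separating the bidentate/pseudobridged range
#: (<= 140 cm^-1) from the less-bidentate range (>= 150 cm^-1)
BIDENTATE_MAX = 140.0
LESS_BIDENTATE_MIN = 150.0


def nu_separations(
    nu_as_candidates: Iterable[float], nu_s_candidates: Iterable[float]
) -> list:
    """All cross pairs (nu_as, nu_s) with delta = nu_as - nu_s >= 0."""
    nu_as = sorted(set(float(v) for v in nu_as_candidates))
    nu_s = sorted(set(float(v) for v in nu_s_candidates))
    if not nu_as or not nu_s:
        raise ValueError("candidate sets must be non-empty")
    if any(v <= 0 for v in nu_as + nu_s):
        raise ValueError("wavenumbers must be positive")
    out = []
    for a in nu_as:
        for s in nu_s:
            delta = a - s
            if delta >= 0:
                out.append(((a, s), delta))
    return out


def classify_coordination(
    delta: float,
    bidentate_max: float = BIDENTATE_MAX,
    less_bidentate_min: float = LESS_BIDENTATE_MIN,
) -> CoordinationModeCall:
    """Call the carboxylate coordination mode from the nu_as - nu_s split."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if delta <= bidentate_max:
        call = "bidentate_or_pseudobridged"
    elif delta >= less_bidentate_min:
        call = "less_bidentate"
    else:
        call = "indeterminate"
    return CoordinationModeCall(delta=float(delta), call=call)
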