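"""SEC-MALS molar-mass determination via Debye plots.

For each chromatographic slice, the excess Rayleigh ratio recorded at
multiple detector angles is combined with the refractive-index-derived
concentration into a Debye plot, ``K C / R_theta`` versus
``sin^2(theta / 2)``.  In the dilute limit the intercept of a linear fit
is ``1 / Mw`` and the initial slope carries the z-average radius of
gyration through the low-angle form-factor expansion
``P(theta)^-1 ~ 1 + (16 pi^2 / 3 lambda^2) Rg^2 sin^2(theta/2)``.
Per-slice masses are averaged over a peak window, weighted by
concentration, and the observed mass range is mapped onto an oligomer
ladder (monomer / dimer / tetramer / octamer by default) to produce the
"oligomer status" label used to describe self-associating complexes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

#: default in-vacuo laser wavelength for the Rg estimate (Angstrom)
DEFAULT_WAVELENGTH = 6580.0

#: allowed oligomer ladder: dimer-of-dimers steps
DEFAULT_ALLOWED_STATES = (1, 2, 4, 8)

_STATE_STEMS = {1: "Monomer", 2: "Di", 4: "Tet", 8: "Oct"}
_STATE_NAMES = {1: "Monomer", 2: "Dimer", 4: "Tetramer", 8: "Octamer"}


@dataclass
class Chromatogram:
    """Multi-angle light-scattering + concentration traces."""

    time: np.ndarray
    concentration: np.ndarray  # g/mL
    angles_deg: np.ndarray
    rayleigh: np.ndarray  # (n_slices, n_angles) excess Rayleigh ratio
    optical_constant: float  # K, houses lambda, dn/dc, n0
    buffer_region: Optional[np.ndarray] = None  # boolean mask of buffer slices

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.rayleigh = np.atleast_2d(np.asarray(self.rayleigh, dtype=float))
        n = len(self.time)
        if self.concentration.shape != (n,) or self.rayleigh.shape[0] != n:
            raise ValueError("all channels must share the slice count")
        if len(self.angles_deg) < 3:
            raise ValueError("need at least 3 detector angles")
        if self.rayleigh.shape[1] != len(self.angles_deg):
            raise ValueError("Rayleigh channel count must match angle count")
        if np.any(self.concentration < -1e-12):
            # tolerate tiny negative baseline noise but not negative signal
            if np.any(self.concentration < -0.1 * np.abs(self.concentration).max()):
                raise ValueError("concentration trace is substantially negative")

    @property
    def n_slices(self) -> int:
        return len(self.time)

    def noise_sigma(self) -> float:
        """Baseline concentration noise, estimated from the annotated buffer
        region (falls back to the lowest-decile slices)."""
        if self.buffer_region is not None and self.buffer_region.any():
            base = self.concentration[self.buffer_region]
        else:
            k = max(self.n_slices // 10, 2)
            base = np.sort(np.abs(self.concentration))[:k]
        sigma = float(np.std(base))
        return sigma if sigma > 0 else 1e-12


@dataclass
class SliceMass:
    time: float
    mw: Optional[float]  # Da; None when the slice is invalid
    rg: Optional[float]  # A; None when unreliable
    valid: bool
    rg_reliable: bool = False


@dataclass
class MassProfile:
    slices: List[SliceMass]

    def valid_masses(self) -> np.ndarray:
        return np.array([s.mw for s in self.slices if s.valid], dtype=float)


@dataclass
class OligomerAssignment:
    protomer_mass: float
    n_low: int
    n_high: int
    label: str


def debye_slice_mass(
    concentration: float,
    rayleigh: Sequence[float],
    angles_deg: Sequence[float],
    optical_constant: float,
    *,
    concentration_threshold: float = 0.0,
    wavelength: float = DEFAULT_WAVELENGTH,
    time: float = 0.0,
) -> SliceMass:
    """Debye-plot mass for one slice: regress ``K C / R_theta`` on
    ``sin^2(theta/2)``; the intercept gives ``1 / Mw``.

    Slices below the concentration threshold are flagged invalid rather
    than raising.  The slope-derived Rg estimate is flagged unreliable
    when the slope is non-positive or the particle is too small for the
    angular dependence to be measured.
    """
    angles = np.asarray(angles_deg, dtype=float)
    r = np.asarray(rayleigh, dtype=float)
    if len(angles) < 3:
        raise ValueError("need at least 3 angles")
    if concentration <= concentration_threshold or np.any(r <= 0):
        return SliceMass(time, None, None, valid=False)
    x = np.sin(np.radians(angles) / 2.0) ** 2
    y = optical_constant * concentration / r
    slope, intercept = np.polyfit(x, y, 1)
    if intercept <= 0:
        return SliceMass(time, None, None, valid=False)
    mw = 1.0 / intercept
    rg = None
    reliable = False
    if slope > 0:
        rg2 = 3.0 * wavelength**2 / (16.0 * math.pi**2) * slope / intercept
        rg = math.sqrt(rg2)
        # angular decay below ~1% of the intercept is indistinguishable
        # from noise for small particles
        reliable = slope * x.max() > 0.01 * intercept
    return SliceMass(time, float(mw), rg, valid=True, rg_reliable=reliable)


def mass_profile(
    chrom: Chromatogram,
    *,
    noise_multiple: float = 3.0,
    wavelength: float = DEFAULT_WAVELENGTH,
) -> MassProfile:
    """Per-slice Debye-plot masses across a chromatogram.

    The slice-validity threshold is ``noise_multiple`` times the baseline
    concentration noise estimated from the buffer region.
    """
    thresh = noise_multiple * chrom.noise_sigma()
    out = []
    for k in range(chrom.n_slices):
        out.append(
            debye_slice_mass(
                float(chrom.concentration[k]),
                chrom.rayleigh[k],
                chrom.angles_deg,
                chrom.optical_constant,
                concentration_threshold=thresh,
                wavelength=wavelength,
                time=float(chrom.time[k]),
            )
        )
    return MassProfile(out)


def peak_average_mass(
    profile: MassProfile,
    chrom: Chromatogram,
    peak_window: Tuple[float, float],
) -> Tuple[float, Tuple[float, float]]:
    """Concentration-weighted average mass over a time window, plus the
    observed (min, max) across valid slices."""
    t0, t1 = peak_window
    num = den = 0.0
    masses = []
    for k, s in enumerate(profile.slices):
        if not (t0 <= s.time <= t1) or not s.valid:
            continue
        c = float(chrom.concentration[k])
        num += c * s.mw
        den += c
        masses.append(s.mw)
    if not masses or den <= 0:
        raise ValueError("peak window contains no valid slices")
    return num / den, (min(masses), max(masses))


def _round_to_allowed(ratio: float, allowed: Sequence[int]) -> int:
    # nearest ladder state in log space (symmetric for mass ratios)
    allowed = sorted(allowed)
    ratio = max(ratio, 1e-12)
    return min(allowed, key=lambda n: abs(math.log(ratio / n)))


def assign_oligomer_range(
    mw_min: float,
    mw_max: float,
    protomer_mass: float,
    allowed_states: Sequence[int] = DEFAULT_ALLOWED_STATES,
    plus_tolerance: float = 0.10,
) -> OligomerAssignment:
    """Map an observed mass range onto the oligomer ladder.

    ``n_low``/``n_high`` are the allowed states nearest (in log space) to
    ``mw_min / protomer`` and ``mw_max / protomer``; a ``+`` is appended
    when the maximum exceeds the largest allowed state by more than
    ``plus_tolerance`` (the species ladder evidently continues upward).
    """
    if protomer_mass <= 0:
        raise ValueError("protomer mass must be positive")
    if mw_min <= 0 or mw_max <= 0 or mw_max < mw_min:
        raise ValueError("mass range must be positive with mw_min <= mw_max")
    n_low = _round_to_allowed(mw_min / protomer_mass, allowed_states)
    n_high = _round_to_allowed(mw_max / protomer_mass, allowed_states)
    top = max(allowed_states)
    plus = mw_max > (1.0 + plus_tolerance) * top * protomer_mass
    if n_low == n_high:
        label = _STATE_NAMES.get(n_low, f"{n_low}-mer")
    else:
        label = (
            f"{_STATE_STEMS.get(n_low, str(n_low))}-"
            f"{_STATE_STEMS.get(n_high, str(n_high))}"
        )
    if plus:
        label += "+"
    return OligomerAssignment(protomer_mass, n_low, n_high, label)
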