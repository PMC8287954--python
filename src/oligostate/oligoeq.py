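"""Mass-action equilibria of a dimer-of-dimers oligomer ladder.

The protomer is the basal heterodimeric unit of a self-associating
complex (for SMN, one SMN-Gemin2 pair); species are its n-mers with
n restricted by default to the dimer-of-dimers ladder {1, 2, 4, 8}.
Association proceeds stepwise -- two monomers form a dimer, two dimers a
tetramer, two tetramers an octamer -- each step governed by a
dissociation constant

    Kd_step(T) = exp(dG_step(T) / RT),
    dG(T) = dH0 + dCp (T - T0) - T [dS0 + dCp ln(T / T0)],

the integrated Gibbs-Helmholtz form with a constant heat-capacity change.
Hydrophobically driven association (entropic, dCp < 0) weakens on
cooling over the 0-40 C range, which reproduces the experimental shift of
tetramer-octamer mixtures toward smaller species at 4 C.

Given total protomer concentration the speciation follows from mass
action; the free-protomer concentration is found by bisection on the
strictly monotone conservation function.  Helpers predict the
weight-average molar mass, a trend-level weight-average sedimentation
coefficient (s_n = s1 n^(2/3) for quasi-globular growth), and the
probability that an untagged protomer co-purifies with a tagged one when
the two assort randomly into n-mers (the mixed-oligomer pulldown
readout; a monomeric mutant never co-purifies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

R_GAS = 8.31446261815324e-3  # kJ mol^-1 K^-1
T_REF = 298.15  # K

DEFAULT_SPECIES = (1, 2, 4, 8)


@dataclass
class StepThermo:
    """Thermodynamics of one association step (two half-species -> species).

    ``kd_ref`` is the dissociation constant (molar) at ``t_ref``;
    ``dh0`` (kJ/mol) and ``dcp`` (kJ/mol/K) complete the temperature
    dependence; ``ds0`` is derived from the three.
    """

    kd_ref: float
    dh0: float = 0.0
    dcp: float = 0.0
    t_ref: float = T_REF

    def dg(self, temperature: float) -> float:
        """Association standard free energy (kJ/mol) at ``temperature``."""
        dg_ref = R_GAS * self.t_ref * math.log(self.kd_ref)
        ds0 = (self.dh0 - dg_ref) / self.t_ref
        t = temperature
        return (
            self.dh0
            + self.dcp * (t - self.t_ref)
            - t * (ds0 + self.dcp * math.log(t / self.t_ref))
        )

    def kd(self, temperature: float) -> float:
        return math.exp(self.dg(temperature) / (R_GAS * temperature))


#: hydrophobic defaults: entropy-driven association with a negative
#: heat-capacity change, so the higher-order steps weaken on cooling.
#: Dimerization is tight (metazoan complexes show few free monomers);
#: the tetramer step echoes the ~1 uM dissociation scale reported for a
#: fungal tetramer, the octamer step is somewhat weaker.
DEFAULT_STEPS: Dict[int, StepThermo] = {
    2: StepThermo(kd_ref=1e-10, dh0=10.0, dcp=-1.0),
    4: StepThermo(kd_ref=1e-6, dh0=20.0, dcp=-2.5),
    8: StepThermo(kd_ref=5e-6, dh0=20.0, dcp=-2.5),
}


@dataclass
class EquilibriumModel:
    """Stepwise association model over an oligomer ladder."""

    species: Tuple[int, ...] = DEFAULT_SPECIES
    steps: Dict[int, StepThermo] = field(default_factory=lambda: dict(DEFAULT_STEPS))
    protomer_mass: float = 1.0  # Da per protomer; 1.0 -> masses in protomer units

    def __post_init__(self) -> None:
        self.species = tuple(sorted(self.species))
        if self.species[0] != 1:
            raise ValueError("ladder must include the free protomer (n = 1)")
        for lo, hi in zip(self.species, self.species[1:]):
            if hi != 2 * lo:
                raise ValueError("ladder must double at each step (dimer-of-dimers)")
            if hi not in self.steps:
                raise ValueError(f"missing thermodynamics for the {lo}->{hi} step")

    def kds(self, temperature: float) -> Dict[int, float]:
        return {n: self.steps[n].kd(temperature) for n in self.species[1:]}


@dataclass
class SpeciesDistribution:
    species: Tuple[int, ...]
    concentrations: np.ndarray  # molar, per species
    total_protomer: float
    protomer_mass: float

    @property
    def molar_fractions(self) -> np.ndarray:
        tot = self.concentrations.sum()
        return self.concentrations / tot if tot > 0 else self.concentrations

    @property
    def mass_fractions(self) -> np.ndarray:
        """Fraction of protomer units residing in each species."""
        units = np.array(self.species) * self.concentrations
        return units / self.total_protomer

    @property
    def weight_average_n(self) -> float:
        units = np.array(self.species) * self.concentrations
        return float((units * np.array(self.species)).sum() / units.sum())

    @property
    def weight_average_mass(self) -> float:
        return self.weight_average_n * self.protomer_mass

    def conservation_residual(self) -> float:
        units = float((np.array(self.species) * self.concentrations).sum())
        return abs(units - self.total_protomer) / self.total_protomer


def _species_conc(x1: float, species: Sequence[int], kds: Dict[int, float]) -> np.ndarray:
    conc = {1: x1}
    for n in species[1:]:
        half = conc[n // 2]
        kd = kds[n]
        conc[n] = (half * half / kd) if kd > 0 else math.inf
    return np.array([conc[n] for n in species])


def solve_equilibrium(
    model: EquilibriumModel,
    total_protomer: float,
    temperature: float = T_REF,
    rel_tol: float = 1e-12,
    max_iter: int = 500,
) -> SpeciesDistribution:
    """Speciation at one total protomer concentration and temperature.

    Bisection on the free-protomer concentration: the conserved total
    ``sum_n n [X_n]`` is strictly increasing in ``[X_1]``, so the bracket
    ``(0, total]`` always contains exactly one root.
    """
    if total_protomer <= 0:
        raise ValueError("total protomer concentration must be positive")
    kds = model.kds(temperature)
    ns = np.array(model.species, dtype=float)

    def total_of(x1: float) -> float:
        return float((ns * _species_conc(x1, model.species, kds)).sum())

    # bisection on log [X1]: relative precision on the free protomer keeps
    # the conservation residual tight even when monomers are scarce
    log_lo, log_hi = math.log(total_protomer) - 80.0, math.log(total_protomer)
    for _ in range(max_iter):
        log_x1 = 0.5 * (log_lo + log_hi)
        if total_of(math.exp(log_x1)) > total_protomer:
            log_hi = log_x1
        else:
            log_lo = log_x1
        if log_hi - log_lo <= rel_tol:
            break
    else:
        raise RuntimeError(
            "equilibrium bisection did not converge: bracket "
            f"[{math.exp(log_lo):g}, {math.exp(log_hi):g}]"
        )
    x1 = math.exp(0.5 * (log_lo + log_hi))
    conc = _species_conc(x1, model.species, kds)
    return SpeciesDistribution(model.species, conc, total_protomer, model.protomer_mass)


def temperature_profile(
    model: EquilibriumModel,
    total_protomer: float,
    temperatures_c: Sequence[float],
) -> List[Tuple[float, float]]:
    """Weight-average mass versus temperature (deg C)."""
    out = []
    for tc in temperatures_c:
        dist = solve_equilibrium(model, total_protomer, tc + 273.15)
        out.append((tc, dist.weight_average_mass))
    return out


@dataclass
class HydroParams:
    """Trend-level hydrodynamic scaling: s_n = s1 * n^exponent."""

    s1: float  # Svedberg, protomer
    exponent: float = 2.0 / 3.0  # quasi-globular mass scaling
    frictional_ratio: float = 1.2

    def __post_init__(self) -> None:
        if self.s1 <= 0:
            raise ValueError("s1 must be positive")
        if not 0 < self.exponent <= 1:
            raise ValueError("exponent must lie in (0, 1]")

    def s_of(self, n: int) -> float:
        return self.s1 * n**self.exponent


def predict_sbar(distribution: SpeciesDistribution, hydro: HydroParams) -> float:
    """Signal(mass)-weighted average sedimentation coefficient."""
    weights = distribution.mass_fractions
    s_vals = np.array([hydro.s_of(n) for n in distribution.species])
    return float((weights * s_vals).sum())


def predict_capture(n: int, tagged_fraction: float) -> float:
    """Probability that an untagged protomer co-purifies with tagged bait
    under independent random assortment into n-mers:
    ``1 - (1 - p)^(n - 1)``.  Monomers (n = 1) never co-purify."""
    if n < 1:
        raise ValueError("n must be >= 1")
    p = tagged_fraction
    if not 0.0 <= p <= 1.0:
        raise ValueError("tagged fraction must lie in [0, 1]")
    return 1.0 - (1.0 - p) ** (n - 1)


def simulate_capture(
    n: int, tagged_fraction: float, n_trials: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo assortment oracle for :func:`predict_capture`."""
    if n == 1:
        return 0.0
    partners = rng.random((n_trials, n - 1)) < tagged_fraction
    return float(partners.any(axis=1).mean())


def fit_kds(
    model: EquilibriumModel,
    totals: Sequence[float],
    observed_mw: Sequence[float],
    temperature: float = T_REF,
) -> Dict[int, float]:
    """Fit the step dissociation constants to weight-average mass versus
    total-concentration data (log-space least squares)."""
    steps = sorted(model.steps)
    x0 = np.array([math.log10(model.steps[n].kd_ref) for n in steps])

    def residuals(logkds: np.ndarray) -> np.ndarray:
        trial = EquilibriumModel(
            species=model.species,
            steps={
                n: StepThermo(10.0 ** lk, model.steps[n].dh0, model.steps[n].dcp)
                for n, lk in zip(steps, logkds)
            },
            protomer_mass=model.protomer_mass,
        )
        pred = [
            solve_equilibrium(trial, t, temperature).weight_average_mass
            for t in totals
        ]
        return np.log(np.array(pred)) - np.log(np.asarray(observed_mw, dtype=float))

    fit = least_squares(residuals, x0, method="lm", xtol=1e-12)
    return {n: 10.0**lk for n, lk in zip(steps, fit.x)}
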