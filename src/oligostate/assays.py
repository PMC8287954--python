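"""Small assay arithmetic: developmental viability percentages, locomotion
normalization and crosslink gel quantitation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np


@dataclass(frozen=True)
class ViabilityCount:
    """Counts from one developmental-viability vial.

    Ordering violations (more pupae than larvae, etc.) warn rather than
    fail: censusing gaps occur in practice.
    """

    n_initial_larvae: int
    n_pupae: int
    n_adults: int

    def __post_init__(self) -> None:
        for v in (self.n_initial_larvae, self.n_pupae, self.n_adults):
            if v < 0:
                raise ValueError("counts must be non-negative")
        if not self.n_adults <= self.n_pupae <= self.n_initial_larvae:
            warnings.warn(
                "count ordering violated (adults <= pupae <= larvae expected)",
                stacklevel=2,
            )


def percent_pupation(v: ViabilityCount) -> float:
    """Percent of initial larvae reaching pupation: 100 * pupae / larvae."""
    if v.n_initial_larvae == 0:
        raise ValueError("no initial larvae counted")
    return 100.0 * v.n_pupae / v.n_initial_larvae


def percent_eclosion(v: ViabilityCount) -> float:
    """Percent of initial larvae eclosing as adults: 100 * adults / larvae."""
    if v.n_initial_larvae == 0:
        raise ValueError("no initial larvae counted")
    return 100.0 * v.n_adults / v.n_initial_larvae


def blps(avg_speed: float, body_length: float) -> float:
    """Crawling speed normalized to larval size: body lengths per second."""
    if body_length <= 0:
        raise ValueError("body length must be positive")
    return avg_speed / body_length


@dataclass(frozen=True)
class GelQuant:
    """Band intensities from one non-reducing SDS-PAGE lane."""

    monomer: float
    dimer: float

    def __post_init__(self) -> None:
        if self.monomer < 0 or self.dimer < 0:
            raise ValueError("band intensities must be non-negative")
        if self.monomer + self.dimer == 0:
            raise ValueError("at least one band must be non-zero")


def fraction_dimer(g: GelQuant) -> float:
    """Fraction of material crosslinked into dimers: D / (M + D)."""
    return g.dimer / (g.monomer + g.dimer)


def aggregate_fractions(fractions: Sequence[float]) -> Tuple[float, float]:
    """Replicate mean and sample standard deviation of dimer fractions."""
    arr = np.asarray(fractions, dtype=float)
    if arr.size == 0:
        raise ValueError("no replicates")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd
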