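"""Synthetic inputs with the statistical structure the analyses assume.

Everything the analysis modules consume can be generated here under a
fixed seed: ortholog families that preserve the step-4 motif register
while diverging elsewhere; SEC-MALS chromatograms whose light scattering
is proportional to ``c * M`` and whose concentration trace follows the
refractive index; SEC-SAXS frame stacks built as overlapping elutions of
bead-model components; and coarse bead models of dimers, tetramers and
octamers (optionally decorated with a partner-protein blob per helix to
mimic the full heterodimer-unit envelope).

Noise models: Gaussian fractional noise on the MALS channels, and
variance-scaled (Poisson-like) Gaussian noise on SAXS frames --
the regimes of refractometer/light-scattering electronics and photon
counting, respectively.  Elution peaks are truncated Gaussians (compact
support), so each component has a well-defined entry and exit frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import helixmodel as hx
from . import saxs as sx
from .mals import Chromatogram
from .seqmotif import AA_ALPHABET, OrthologSequence

#: default template: the synthetic human-numbered YG-box stand-in used by
#: the bundled alignment (s-motif 262/266/270/274, Y 268/272/276,
#: G 271/275/279)
DEFAULT_TEMPLATE = OrthologSequence(
    "template", "EMLAEIELLQSMEISWYMSGYHTGYYMGFRQNQKEGRCSHSLN", 252
)
DEFAULT_MOTIF_POSITIONS = tuple(
    sorted({262, 266, 270, 274, 268, 272, 276, 271, 275, 279})
)


@dataclass
class SynthConfig:
    """Bundle of generator settings (every stochastic output needs a seed)."""

    seed: int
    mals_noise_frac: float = 0.01
    saxs_noise_frac: float = 0.01
    elution_truncation: float = 2.5  # peak support, in units of sigma

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# ortholog families

def gen_ortholog_family(
    template: OrthologSequence = DEFAULT_TEMPLATE,
    motif_positions: Sequence[int] = DEFAULT_MOTIF_POSITIONS,
    n_species: int = 6,
    divergence: float = 0.2,
    mutations: Sequence[Tuple[int, int, str]] = (),
    seed: int = 0,
) -> List[OrthologSequence]:
    """Generate a family of ortholog-like sequences.

    Non-motif positions mutate independently with probability
    ``divergence``; the motif register is held fixed.  ``mutations`` are
    (species_index, residue_number, new_letter) point substitutions
    applied after divergence (e.g. engineered Y->C or G->S alleles).
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    first = template.first_residue_number
    protected = {p - first for p in motif_positions}
    for off in protected:
        if not 0 <= off < len(template.residues):
            raise ValueError("motif position outside the template")
    alphabet = sorted(AA_ALPHABET)
    out = []
    for s in range(n_species):
        res = list(template.residues)
        for i in range(len(res)):
            if i in protected:
                continue
            if rng.random() < divergence:
                choices = [a for a in alphabet if a != res[i]]
                res[i] = choices[rng.integers(len(choices))]
        out.append(OrthologSequence(f"synth{s}", "".join(res), first))
    for species_idx, pos, letter in mutations:
        if not 0 <= species_idx < len(out):
            raise ValueError(f"no generated species with index {species_idx}")
        off = pos - first
        if not 0 <= off < len(template.residues):
            raise ValueError(f"mutation position {pos} undefined in the template")
        seq = out[species_idx]
        res = list(seq.residues)
        res[off] = letter.upper()
        out[species_idx] = OrthologSequence(seq.species_id, "".join(res), first)
    return out


# ---------------------------------------------------------------------------
# SEC-MALS chromatograms

@dataclass
class ElutingSpecies:
    """One Gaussian elution peak of a species with molar mass ``mass`` (Da)."""

    mass: float
    center: float  # slice time of the peak
    width: float  # Gaussian sigma, in time units
    peak_concentration: float  # g/mL at the peak


def gen_chromatogram(
    species: Sequence[ElutingSpecies],
    *,
    n_slices: int = 300,
    angles_deg: Sequence[float] = tuple(np.linspace(15.0, 160.0, 16)),
    optical_constant: float = 1.0e-7,
    noise_frac: float = 0.01,
    buffer_fraction: float = 0.1,
    seed: int = 0,
) -> Chromatogram:
    """Simulate a SEC-MALS run of a species mixture.

    The concentration trace is a sum of Gaussian peaks; light scattering
    at every angle is ``K * sum_s c_s(t) * M_s`` (form factor ~ 1 at
    these particle sizes), plus fractional Gaussian noise with a small
    baseline floor on every channel.  The first ``buffer_fraction`` of
    slices is annotated as buffer.
    """
    if not species:
        raise ValueError("need at least one species")
    rng = np.random.default_rng(seed)
    t = np.arange(n_slices, dtype=float)
    angles = np.asarray(angles_deg, dtype=float)
    conc = np.zeros(n_slices)
    signal = np.zeros(n_slices)  # sum c * M
    for sp in species:
        c = sp.peak_concentration * np.exp(-0.5 * ((t - sp.center) / sp.width) ** 2)
        conc += c
        signal += c * sp.mass
    cmax = conc.max()
    floor = 0.02 * cmax
    c_noisy = conc + rng.normal(0.0, noise_frac * (conc + floor))
    rayleigh = np.empty((n_slices, len(angles)))
    r_clean = optical_constant * signal
    r_floor = 0.02 * r_clean.max()
    for j in range(len(angles)):
        rayleigh[:, j] = r_clean + rng.normal(0.0, noise_frac * (r_clean + r_floor))
    buffer_mask = t < buffer_fraction * n_slices
    return Chromatogram(
        time=t,
        concentration=c_noisy,
        angles_deg=angles,
        rayleigh=rayleigh,
        optical_constant=optical_constant,
        buffer_region=buffer_mask,
    )


# ---------------------------------------------------------------------------
# SEC-SAXS frame stacks

@dataclass
class ElutingComponent:
    """A bead-model component with its (truncated Gaussian) elution."""

    coords: np.ndarray
    weights: Optional[np.ndarray]
    center: float
    width: float
    amplitude: float = 1.0

    def concentration(self, frames: np.ndarray, truncation: float = 2.5) -> np.ndarray:
        c = self.amplitude * np.exp(-0.5 * ((frames - self.center) / self.width) ** 2)
        c[np.abs(frames - self.center) > truncation * self.width] = 0.0
        return c


def gen_secsaxs_frames(
    components: Sequence[ElutingComponent],
    q_grid: Optional[np.ndarray] = None,
    *,
    n_frames: int = 80,
    noise_frac: float = 0.01,
    truncation: float = 2.5,
    seed: int = 0,
) -> Tuple[sx.FrameMatrix, List[np.ndarray], List[np.ndarray]]:
    """Simulate a buffer-subtracted SEC-SAXS frame stack.

    Each frame is ``sum_s c_s(f) I_s(q)`` with the component profiles
    from the Debye sum of its bead model, plus variance-scaled Gaussian
    noise (sigma proportional to sqrt of the mean frame intensity, scaled
    so the rms noise is ``noise_frac`` of the rms signal).  Returns the
    stack together with the true component profiles and concentrations.
    """
    if not components:
        raise ValueError("need at least one component")
    rng = np.random.default_rng(seed)
    if q_grid is None:
        q_grid = np.linspace(1e-3, 0.3, 150)
    frames = np.arange(n_frames, dtype=float)
    profiles = []
    concs = []
    m = np.zeros((n_frames, len(q_grid)))
    for comp in components:
        prof = sx.debye_profile(comp.coords, comp.weights, q_grid)
        # normalize profiles to unit forward scatter so amplitudes are
        # comparable between components of different bead counts
        i0 = prof.intensity[0] if prof.intensity[0] > 0 else 1.0
        intensity = prof.intensity / i0
        c = comp.concentration(frames, truncation)
        m += np.outer(c, intensity)
        profiles.append(intensity)
        concs.append(c)
    rms = float(np.sqrt(np.mean(m**2))) or 1.0
    shape = np.sqrt(np.maximum(m, 0.0) + 0.1 * rms)
    sigma = noise_frac * rms * shape / float(np.sqrt(np.mean(shape**2)))
    m_noisy = m + rng.normal(0.0, sigma)
    return sx.FrameMatrix(m_noisy, np.asarray(q_grid, dtype=float)), profiles, concs


# ---------------------------------------------------------------------------
# bead models

def gen_bead_model(
    level: str = "tetramer",
    mode: str = "parallel",
    sequence: OrthologSequence = DEFAULT_TEMPLATE,
    *,
    gemin2_weight: float = 0.0,
    gemin2_offset: float = 18.0,
    **assembly_kwargs,
) -> Tuple[np.ndarray, np.ndarray]:
    """Coarse bead model (coords, weights) of a zipper assembly.

    ``level`` is ``dimer``, ``tetramer`` or ``octamer`` (two tetramers
    stacked end to end).  With ``gemin2_weight > 0`` each helix gains one
    heavy bead displaced ``gemin2_offset`` Angstrom radially outward from
    its midpoint, mimicking the globular partner protein carried by every
    protomer of the heterodimeric unit.
    """
    dimer = hx.assemble_dimer(sequence)
    if level == "dimer":
        bundles = [dimer]
    elif level == "tetramer":
        bundles = [hx.assemble_tetramer(dimer, mode, **assembly_kwargs)]
    elif level == "octamer":
        tet = hx.assemble_tetramer(dimer, mode, **assembly_kwargs)
        span = tet.coords()[:, 2].max() - tet.coords()[:, 2].min()
        shifted = hx.BundleModel(
            helices=[
                h.transformed(np.eye(3), np.array([14.0, 0.0, span + 4.0]))
                for h in tet.helices
            ],
            level="tetramer",
            mode=mode,
            facing_positions=tet.facing_positions,
        )
        bundles = [tet, shifted]
    else:
        raise ValueError(f"unknown level {level!r}")
    coords = [b.coords() for b in bundles]
    weights = [np.ones(len(c)) for c in coords]
    if gemin2_weight > 0:
        for b in bundles:
            for h in b.helices:
                mid = h.ca.mean(axis=0)
                axis_mid = h.axis_point + h.axis_direction * (
                    (mid - h.axis_point) @ h.axis_direction
                )
                radial = mid - axis_mid
                nrm = np.linalg.norm(radial)
                radial = radial / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
                coords.append((mid + gemin2_offset * radial)[None, :])
                weights.append(np.array([gemin2_weight]))
    return np.vstack(coords), np.concatenate(weights)


def gen_sphere_beads(
    radius: float, spacing: float = 3.0, center=(0.0, 0.0, 0.0)
) -> np.ndarray:
    """Deterministic cubic-lattice filling of a solid sphere (for Guinier
    and P(r) oracles: Rg -> sqrt(3/5) R, Dmax -> 2R)."""
    if radius <= 0 or spacing <= 0:
        raise ValueError("radius and spacing must be positive")
    grid = np.arange(-radius, radius + spacing / 2, spacing)
    xx, yy, zz = np.meshgrid(grid, grid, grid, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    pts = pts[np.sum(pts**2, axis=1) <= radius**2]
    return pts + np.asarray(center, dtype=float)
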