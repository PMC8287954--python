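# Methods

This note records the models implemented in `oligostate`, their
assumptions and defaults, the synthetic data they are validated against,
and the numerical choices that were genuinely open.

## Motif model (`seqmotif`)

A motif hit is a maximal run of ≥3 same-class residues spaced exactly 4
apart (pattern `XxxxXxxxX` and extensions).  Class alphabets: Y-motif
`{Y}`, G-motif `{G}`, s-motif `{G, A, S, T, C}` — the small-residue class
is taken in full generality rather than only Ser/Ala/Thr, on the grounds
that Cys and Gly are sterically equivalent for helix-face packing; the
alphabets are a parameter.  Runs in different step-4 phases may overlap
and are reported separately.  The scanner is verified against exhaustive
enumeration of all step-4 runs on random sequences.

With the ideal α-helix twist of 100°/residue (3.6 residues per turn,
configurable), a step of 4 residues advances the azimuth by only 40°, so
a step-4 motif decorates one helical face; `helix_face_angle` exposes
this arithmetic, and a "face" is defined as a ±50° sector by default.

Cross-species residue mapping is alignment-based and purely positional:
two residues are equivalent when they occupy the same alignment column;
gapped columns yield an explicit no-equivalent outcome.  The bundled
alignment (`data/synthetic_yg_alignment.fasta`) is a **synthetic
stand-in**, not real ortholog sequences: it encodes the documented
human/fly/yeast residue correspondences of the SMN YG box (offsets −69
and −136 from human numbering over the conserved core) and the motif
registers (human s-motif 262/266/270/274, Y-motif 268/272/276, G-motif
271/275/279).  Real ortholog sequences and alignments are user inputs.

Conservation profiles classify residues with priority
glycine > small > hydrophobic > polar (the hydrophobic set is
`AVLIMFWYC`), and report per-column class frequencies over non-gap
residues.

## Coordinate models (`helixmodel`)

Helices are ideal: rise 1.5 Å, twist 100°, Cα radius 2.3 Å, plus a Cβ
pseudo-atom displaced 1.5 Å radially outward.  No side-chain rotamers are
modelled; everything downstream that depends on side-chain geometry
(crosslink scoring in particular) therefore works in distance bands, not
exact contact geometry.

**Dimer.**  Two helices with parallel axes 7.5 Å apart.  The azimuthal
phase points the circular mean of the facing positions (by default the
glycine-zipper motif found by the scanner) at the partner helix, offset
by 10° so the facing residues interdigitate; with the 100° twist the
azimuth lattice has 20° pitch, and a 10° stagger is the unique offset
that maximises the minimum cross-helix approach (3.07 Å, just above the
3.0 Å Cα clash floor) while keeping the closest contact at a facing
glycine.  The two helices are related by an exact 2-fold: about the
bundle axis for parallel polarity (the default — the package does not
assert which polarity the real dimer has; it is a parameter), or
perpendicular to it for antiparallel polarity.  Antiparallel packing
needs a slightly wider axis separation (≥ ~7.6 Å) because the mirror
symmetry defeats the azimuthal stagger.

**Tetramer (dimer of dimers).**  Construction steps: roll the dimer
about its interface-helix axis by a docking azimuth; tilt by half the
crossing angle about the docking direction; place the interface-helix
axis a set distance from the 2-fold axis at a chosen contact height; and
generate the partner dimer by the exact 2-fold (about the bundle axis
for the parallel mode, perpendicular for the antiparallel mode, which
additionally stacks the dimers head-to-tail with an axial register
offset).  Defaults, frozen before the validation runs and chosen to
realise the two published classes of model:

| parameter | parallel | antiparallel |
|---|---|---|
| crossing angle | 35° right-handed | 20° left-handed |
| docking azimuth (from the anti-zipper face) | −50° | 0° |
| interface axis separation | 7.0 Å | 7.5 Å |
| contact residue | last facing glycine − 1 | first facing glycine − 4 |
| axial register | 0 (exact 2-fold) | head-to-tail, 2× contact offset |

The parallel defaults dock the C-terminal stripe flanking the
small-residue face (the 273…277 region in human numbering) against its
symmetry mate in a right-handed cross, which is how the published
parallel tetramer model was constructed (superposing the 269–277 window
onto a membrane-protein small-residue helix pair); the antiparallel
defaults centre a head-to-tail stack on the s-motif core near position
267, mirroring the stacked-dimer lattice of the yeast fusion crystal
form.  Exact crossing angles and separations for the real assemblies are
unknown; these are construction parameters, not structural claims.

**Crosslink scoring.**  For a candidate position the minimum Cβ–Cβ
distance between the two dimers is converted to a propensity by a
logistic with midpoint 6.0 Å and width 1.0 Å.  Rigid disulfides need
~3.5–4.6 Å, but interface breathing tolerates more; the coarse Cβ
placement (and the fiction of a Cβ on glycine) makes anything sharper
than a band meaningless.  The score is monotone non-increasing in
distance by construction, so only the *ranking* of positions carries
information.  On the default geometries the parallel model ranks
274/277 closest and 266/270 farthest, the antiparallel model the
reverse — reproducing the measured crosslink ladder's discrimination
between the two docking modes.

## Scattering analysis (`saxs`)

**Debye sum.**  `I(q) = Σᵢⱼ wᵢwⱼ sinc(q rᵢⱼ)` over bead models, with the
`i = j` and `q → 0` limits taken analytically.  Uniform-contrast point
beads only: no atomic form factors, hydration layer or absolute scale.

**Guinier.**  Iterated linear fit of ln I on q² until the window
satisfies `q·Rg ≤ 1.3`; non-decaying profiles raise a fit error.

**P(r) inversion.**  Piecewise-linear P(r) on a uniform 101-node grid
over [0, Dmax], endpoints pinned to zero, second-difference smoothness
penalty, and by default a non-negativity constraint solved as
regularized NNLS.  Weighting uses 1/σ when uncertainties are present and
fractional (1/I) weighting otherwise, keeping χ² scale-free.  When no
regularization weight is given it is set by a discrepancy knee: the
largest λ (over a log sweep) whose misfit stays within 10% of the best
achievable.

**Dmax scan.**  For each candidate Dmax the inversion reports reduced
χ², the relative negative excursion of P(r), and the "tail pileup" (mean
|p| over the last tenth of the grid relative to the peak).  χ² falls
steeply while Dmax is truncated and then plateaus; within the χ²
plateau (5% tolerance) the non-negative inversion stops piling mass
against the cutoff once Dmax is sufficient, so the scan returns the
smallest candidate whose tail pileup has dropped below 5% of the peak.
A combined scalar criterion (weights: χ² 1.0, negativity 10.0, tail 1.0)
is also reported per candidate for inspection, and a fixed light
λ = 10⁻⁴ is used across the scan so candidates are comparable.  On
synthetic solid spheres and helical-bundle bead models at 1% noise this
recovers the true maximum dimension to within ~3–6%; the residual
uncertainty is informational, not numerical — the tail of P(r) holds
very little scattering mass.

**Parallel-axis theorem.**  `L = sqrt((Rg² − f1·R1g² − f2·R2g²)/(f1·f2))`
with scattering-weight fractions defaulting to mass fractions
(`f1 = f2 = 0.5` for two identical dimers).  A negative radicand beyond
rounding raises an "inconsistent inputs" error.  The identity is exact
for point-weighted bodies and is verified against direct centre-of-mass
distances of bead clouds at 10⁻⁹ relative.

**SVD-EFA.**  Buffer frames are dropped; forward and backward evolving
singular-value traces locate each component's entry and exit frame at a
threshold of 3× the noise floor.  The noise floor is the singular value
at the 25%-rank position rather than the median of the trailing values:
variance-scaled (Poisson-like) detector noise gives a *sloped* noise
spectrum for which the trailing median badly underestimates the leading
noise singular values.  This assumes fewer genuine components than a
quarter of the frame count.  Rotation into component space is a
deterministic alternating least squares with non-negativity and
window-support constraints, initialized from Gaussian masks over the
detected windows.  On overlapping two-component synthetic stacks the
recovered profiles reach cosine similarity > 0.999 and windows match the
true compact elution supports within 2 frames.

## SEC-MALS (`mals`)

Debye plots only: `KC/Rθ` regressed on `sin²(θ/2)`; the intercept gives
1/Mw.  The second virial coefficient is neglected (dilute eluant) and no
Zimm double extrapolation is attempted.  The slope yields a z-average Rg
through the low-angle form-factor expansion with the 658 nm wavelength
default; it is flagged unreliable when the slope is non-positive or the
angular decay is below 1% of the intercept (particles ≲ 10–20 nm give no
measurable MALS angular dependence, which is the regime of these
complexes — the synthetic generator accordingly uses form factor ≈ 1).
Slices with concentration below 3× the baseline noise (estimated from
the annotated buffer region) are marked invalid rather than erroring.
Peak averages are concentration-weighted over valid slices.

Oligomer assignment maps the observed min–max mass range onto the ladder
{1, 2, 4, 8} (configurable) by nearest state in log space — symmetric
for mass ratios — and appends `+` when the maximum exceeds the largest
state by more than 10%.  Protomer masses are user inputs.

## Equilibria (`oligoeq`)

Stepwise mass action over the dimer-of-dimers ladder: [X₂] = [X₁]²/Kd₂,
[X₄] = [X₂]²/Kd₄, [X₈] = [X₄]²/Kd₈; odd intermediates are excluded (the
ladder is configurable but must double at each step).  Free protomer is
found by bisection on log[X₁] — the conservation function is strictly
monotone — to 10⁻¹² relative, giving conservation residuals ≈ 10⁻¹².

Temperature dependence uses the integrated Gibbs–Helmholtz form with
constant ΔCp:
`ΔG(T) = ΔH₀ + ΔCp(T−T₀) − T[ΔS₀ + ΔCp ln(T/T₀)]`, `Kd = exp(ΔG/RT)`.
Defaults are illustrative, not fitted to any dataset: a tight
dimerization step (Kd 10⁻¹⁰ M — metazoan complexes show few free
monomers), a ~10⁻⁶ M tetramer step echoing the micromolar scale reported
for a fungal tetramer, a somewhat weaker octamer step, and
entropy-driven association (ΔH₀ > 0, ΔCp < 0, i.e. hydrophobic) so that
association weakens on cooling over 0–40 °C and a tetramer–octamer
mixture shifts toward smaller species at 4 °C.  Fits of the step Kd
values to user titrations (`fit_kds`, log-space Levenberg–Marquardt) are
the supported path to real numbers; on synthetic titrations spanning all
three transitions with 5% noise, log-Kd is recovered within 0.1–0.2
units.  Titrations that do not reach below a transition leave that step
unidentifiable — the recovery guarantee assumes the concentration range
brackets the ladder.

Sedimentation prediction is a trend tool only: `sₙ = s₁·n^(2/3)`
(quasi-globular growth), mass-fraction-weighted.  No Lamm-equation
machinery.

The pulldown capture model assumes tagged and untagged protomers assort
independently into n-mers: the probability an untagged protomer
co-purifies is `1 − (1−p)^(n−1)`, hence exactly 0 for a monomeric
mutant — the logic by which a non-co-purifying mutant is read as
monomeric.  A Monte-Carlo assortment simulation serves as the oracle.

## Synthetic data (`synthgen`)

Every generator is deterministic given its seed.  Defaults represent the
benchmark conditions used throughout the tests:

* **Ortholog families** preserve the template's motif positions exactly
  and mutate other positions independently (default divergence 0.2 —
  the observed non-motif divergence of YG boxes across phyla is of this
  order); engineered point substitutions are injected afterwards.
* **Chromatograms**: Gaussian elution peaks; concentration in g/mL;
  light scattering `K·Σ c·M` identical across angles (form factor ≈ 1,
  see above); 1% fractional Gaussian noise with a 2%-of-peak baseline
  floor on every channel; the first 10% of slices annotated as buffer.
  1% matches routine refractometer/MALS channel noise.
* **SEC-SAXS stacks**: frames are `Σ c_s(f)·I_s(q)` with component
  profiles from the Debye sum, normalized to unit forward scatter;
  truncated-Gaussian elutions (support ±2.5σ) give every component a
  well-defined entry/exit frame; variance-scaled Gaussian noise at 1%
  rms of the signal approximates photon-counting statistics.
* **Bead models** are the Cα sets of `helixmodel` assemblies; an octamer
  is two tetramers stacked end-to-end; an optional single heavy bead per
  helix, offset 18 Å radially, mimics the globular partner protein of
  each protomer unit.  A deterministic cubic-lattice sphere
  (`gen_sphere_beads`) provides the closed-form oracles
  (Rg = √(3/5)·R, Dmax = 2R).

What the generators deliberately do **not** emulate: inter-detector
calibration and band broadening in MALS, inter-frame buffer drift and
capillary fouling in SEC-SAXS, compositional heterogeneity, and any
kinetics.  Passing the synthetic round trips therefore demonstrates the
estimators' correctness under the stated noise models, not robustness to
instrument systematics.

## Validation against published experimental numbers

Two checks in `tests/test_acceptance.py` operate on experimental inputs
that cannot be bundled: the inter-dimer distance of the wild-type yeast
tetramer via the parallel-axis theorem (expected 106 Å from the
supplementary dimer/tetramer Rg values with f1 = f2 = 0.5), and the
P(r) maximum dimensions of the deposited tetramer and obligate-dimer
SEC-SAXS profiles (276 Å and 233 Å).  They document the file layout
(`data/experimental/`) needed to run them and fail with instructions
until the files are supplied.

## Known limitations

* Coordinate models are ideal-helix caricatures: no rotamers, no
  backbone relaxation, glycines carry a fictitious Cβ.  Crosslink output
  is a ranking, not a rate prediction.
* The tetramer geometries are parametric constructions of the two
  published model classes; the discrimination result says which class is
  consistent with a crosslink ladder, not what the structure is.
* P(r) inversion assumes a dilute, monodisperse, uniform-contrast
  particle; the Dmax scan inherits the intrinsic insensitivity of I(q)
  to the thin tail of P(r).
* The equilibrium defaults are order-of-magnitude placeholders pending
  user fits; only the fitted path should be quoted.
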