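"""Small-angle scattering analysis.

Covers the solution-scattering workflow used to size oligomeric protein
complexes:

* Debye-sum theoretical profiles from coarse bead models,
  ``I(q) = sum_ij w_i w_j sin(q r_ij)/(q r_ij)``;
* Guinier fits, ``ln I = ln I0 - q^2 Rg^2 / 3`` over a self-consistent
  ``q * Rg <= limit`` window;
* regularized indirect inversion of I(q) into the pair-distance
  distribution P(r) with endpoint-zero constraints, plus a Dmax scan that
  balances fit quality against negativity and tail oscillation of P(r);
* the parallel-axis theorem ``Rg^2 = f1 R1g^2 + f2 R2g^2 + f1 f2 L^2``
  linking component and complex radii of gyration to the distance L
  between the two bodies' centres of mass;
* SVD with evolving factor analysis (EFA) to deconvolve the overlapping
  elution components of a SEC-SAXS frame stack into per-component
  scattering profiles and concentration profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import pdist


class FitError(RuntimeError):
    """Raised when a fit has no valid window or an unphysical solution."""


@dataclass
class SAXSProfile:
    """A 1-D scattering curve I(q) with optional uncertainties."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise ValueError("q and I must be 1-D arrays of equal length")
        if np.any(self.q < 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be non-negative and strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape or np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive and match q")

    def __len__(self) -> int:
        return len(self.q)


@dataclass
class GuinierFit:
    rg: float
    i0: float
    q_window: Tuple[float, float]
    n_points: int
    r_squared: float


@dataclass
class PofR:
    """Pair-distance distribution with its derived invariants."""

    r: np.ndarray
    p: np.ndarray
    dmax: float
    rg: float
    i0: float
    chi2: float  # reduced chi^2 of the regularized fit to I(q)
    quality: float  # combined Dmax-scan criterion (lower is better)
    regularization: float = 0.0
    negativity: float = 0.0  # relative negative excursion of p(r)
    tail_pileup: float = 0.0  # relative mass piled against the cutoff

    def forward(self, q: np.ndarray) -> np.ndarray:
        """Re-transform P(r) to I(q)."""
        a = _design_matrix(np.asarray(q, dtype=float), self.r)
        return a @ self.p


@dataclass
class ParallelAxisInput:
    rg_complex: float
    r1g: float
    r2g: float
    f1: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.f1 < 1.0:
            raise ValueError("f1 must lie in (0, 1)")
        for v in (self.rg_complex, self.r1g, self.r2g):
            if v < 0:
                raise ValueError("radii of gyration must be non-negative")

    @property
    def f2(self) -> float:
        return 1.0 - self.f1


@dataclass
class FrameMatrix:
    """SEC-SAXS frame stack: rows are frames, columns the q grid."""

    intensities: np.ndarray  # (n_frames, n_q)
    q: np.ndarray
    frame_index: Optional[np.ndarray] = None
    buffer_frames: Optional[np.ndarray] = None  # boolean mask over frames

    def __post_init__(self) -> None:
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.q = np.asarray(self.q, dtype=float)
        if self.intensities.shape[1] != len(self.q):
            raise ValueError("frame width must match q grid")
        if self.frame_index is None:
            self.frame_index = np.arange(self.intensities.shape[0])
        if self.buffer_frames is not None:
            self.buffer_frames = np.asarray(self.buffer_frames, dtype=bool)
            if self.buffer_frames.shape[0] != self.intensities.shape[0]:
                raise ValueError("buffer mask must match frame count")

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[0]


@dataclass
class EFAComponent:
    entry_frame: int
    exit_frame: int
    profile: np.ndarray  # I(q)
    concentration: np.ndarray  # per frame, arbitrary units


@dataclass
class EFAResult:
    n_components: int
    components: List[EFAComponent]
    singular_values: np.ndarray
    forward_trace: np.ndarray  # (n_frames, n_components) evolving SVs
    backward_trace: np.ndarray
    residual: float  # rms reconstruction residual


# ---------------------------------------------------------------------------
# Debye sum

def debye_profile(
    coords: np.ndarray,
    weights: Optional[np.ndarray] = None,
    q_grid: Optional[np.ndarray] = None,
) -> SAXSProfile:
    """Theoretical scattering of a bead model by the Debye double sum.

    The ``i = j`` and ``q -> 0`` limits are taken analytically
    (``sinc -> 1``), never by division.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = coords.shape[0]
    if n < 1:
        raise ValueError("need at least one bead")
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if q_grid is None:
        q_grid = np.linspace(0.0, 0.5, 201)
    q_grid = np.asarray(q_grid, dtype=float)

    self_term = float(np.sum(weights**2))
    if n == 1:
        return SAXSProfile(q_grid, np.full_like(q_grid, self_term))
    rij = pdist(coords)
    iu, ju = np.triu_indices(n, k=1)
    wij = weights[iu] * weights[ju]
    # np.sinc(x) = sin(pi x)/(pi x) with sinc(0) = 1; chunk q to bound memory
    cross = np.empty_like(q_grid)
    chunk = max(1, int(2e7 // max(len(rij), 1)))
    for s in range(0, len(q_grid), chunk):
        qs = q_grid[s : s + chunk]
        cross[s : s + chunk] = 2.0 * (
            wij[None, :] * np.sinc(np.outer(qs, rij) / np.pi)
        ).sum(axis=1)
    return SAXSProfile(q_grid, self_term + cross)


# ---------------------------------------------------------------------------
# Guinier analysis

def guinier_fit(
    profile: SAXSProfile,
    qrg_limit: float = 1.3,
    min_points: int = 5,
    max_iter: int = 50,
) -> GuinierFit:
    """Fit ``ln I`` linearly on ``q^2`` over a self-consistent low-q window.

    Starting from the full positive-intensity low-q range, the window is
    iterated until ``q_max * Rg <= qrg_limit`` holds for the fitted Rg.
    """
    q, i = profile.q, profile.intensity
    usable = i > 0
    if q[0] == 0.0:
        pass  # q = 0 point is fine in a Guinier fit
    q, i = q[usable], i[usable]
    if len(q) < min_points:
        raise FitError("too few positive-intensity points for a Guinier fit")
    hi = len(q)
    rg = None
    for _ in range(max_iter):
        x, y = q[:hi] ** 2, np.log(i[:hi])
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            if hi > min_points:
                hi -= 1
                continue
            raise FitError("non-negative Guinier slope: no decaying low-q region")
        rg = math.sqrt(-3.0 * slope)
        new_hi = int(np.searchsorted(q, qrg_limit / rg, side="right"))
        new_hi = max(min_points, min(new_hi, len(q)))
        if new_hi == hi:
            break
        hi = new_hi
    if rg is None:
        raise FitError("Guinier fit did not converge to a valid window")
    x, y = q[:hi] ** 2, np.log(i[:hi])
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        raise FitError("non-negative Guinier slope in final window")
    rg = math.sqrt(-3.0 * slope)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return GuinierFit(
        rg=rg,
        i0=float(np.exp(intercept)),
        q_window=(float(q[0]), float(q[hi - 1])),
        n_points=hi,
        r_squared=r2,
    )


# ---------------------------------------------------------------------------
# P(r) inversion

def _design_matrix(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """I(q) = 4 pi * integral p(r) sinc(qr) dr, trapezoidal on the r grid."""
    dr = np.gradient(r)
    sinc = np.sinc(np.outer(q, r) / np.pi)
    return 4.0 * math.pi * sinc * dr[None, :]


def pr_invert(
    profile: SAXSProfile,
    dmax: float,
    regularization: Optional[float] = None,
    n_r: int = 101,
    non_negative: bool = True,
) -> PofR:
    """Invert I(q) to P(r) on [0, Dmax] under a second-difference smoothness
    penalty with p(0) = p(Dmax) = 0, and (by default) p(r) >= 0.

    The non-negativity constraint (solved as regularized NNLS) sharpens
    the misfit response to a wrong Dmax; pass ``non_negative=False`` for
    the unconstrained linear solution.

    When ``regularization`` is not given, it is chosen as the largest
    value whose misfit stays within 10% of the best achievable over a
    log-spaced sweep (a discrepancy-principle knee).
    """
    if dmax <= 0:
        raise ValueError("Dmax must be positive")
    q, i = profile.q, profile.intensity
    if profile.sigma is not None:
        w = 1.0 / profile.sigma
    else:
        # fractional weighting keeps chi^2 scale-free for noiseless input
        w = 1.0 / np.maximum(np.abs(i), 1e-12 * float(np.abs(i).max() or 1.0))
    r = np.linspace(0.0, dmax, n_r)
    a_full = _design_matrix(q, r)
    # endpoint-zero constraint: solve for interior nodes only
    a = a_full[:, 1:-1] * w[:, None]
    y = i * w
    m = a.shape[1]
    d2 = np.zeros((m - 2, m))
    for k in range(m - 2):
        d2[k, k : k + 3] = (1.0, -2.0, 1.0)
    scale = float(np.trace(a.T @ a) / max(np.trace(d2.T @ d2), 1e-300))

    def solve(lam: float) -> np.ndarray:
        if non_negative:
            from scipy.optimize import nnls

            aug = np.vstack([a, math.sqrt(max(lam, 0.0) * scale) * d2])
            rhs = np.concatenate([y, np.zeros(m - 2)])
            return nnls(aug, rhs)[0]
        lhs = a.T @ a + lam * scale * (d2.T @ d2)
        try:
            return np.linalg.solve(lhs, a.T @ y)
        except np.linalg.LinAlgError as exc:
            raise FitError(
                f"singular P(r) system: regularization {lam:g} too small"
            ) from exc

    if regularization is None:
        # discrepancy knee: the largest lambda whose misfit stays within
        # 50% of the best achievable over a log-spaced sweep -- as much
        # smoothing as the data tolerate, no more
        lams = np.logspace(-8, 2, 21)
        resids = []
        for lam in lams:
            p_in = solve(lam)
            resids.append(float(np.sum((a @ p_in - y) ** 2)))
        best = min(resids)
        tol = 1.1 * best + 1e-15
        regularization = float(max(l for l, r in zip(lams, resids) if r <= tol))
    p_in = solve(regularization)
    p = np.concatenate([[0.0], p_in, [0.0]])

    fit = a_full @ p
    dof = max(len(q) - m, 1)
    chi2 = float(np.sum(((fit - i) * w) ** 2) / dof)

    dr = np.gradient(r)
    norm = float(np.sum(p * dr))
    if norm <= 0:
        rg = float("nan")
    else:
        rg = math.sqrt(max(float(np.sum(p * r**2 * dr)) / (2.0 * norm), 0.0))
    i0 = 4.0 * math.pi * norm
    quality, negativity, tail = _pr_quality(p, chi2)
    return PofR(r=r, p=p, dmax=float(dmax), rg=rg, i0=i0, chi2=chi2,
                quality=quality, regularization=float(regularization),
                negativity=negativity, tail_pileup=tail)


#: weights of the combined Dmax-scan criterion
PR_CRITERION_WEIGHTS = {"chi2": 1.0, "negativity": 10.0, "tail": 1.0}


def _pr_quality(p: np.ndarray, chi2: float) -> Tuple[float, float, float]:
    """Combined criterion plus its negativity and tail-pileup components."""
    total = float(np.abs(p).sum()) or 1.0
    negativity = float(-p[p < 0].sum()) / total
    # mass piled up against the cutoff signals a truncated distribution
    k = max(len(p) // 10, 2)
    peak = float(np.abs(p).max()) or 1.0
    tail_mass = float(np.mean(np.abs(p[-k:-1]))) / peak
    w = PR_CRITERION_WEIGHTS
    quality = w["chi2"] * chi2 + w["negativity"] * negativity + w["tail"] * tail_mass
    return quality, negativity, tail_mass


def scan_dmax(
    profile: SAXSProfile,
    dmax_range: Tuple[float, float],
    step: float = 2.0,
    regularization: Optional[float] = None,
    n_r: int = 101,
    plateau_tolerance: float = 0.05,
    tail_threshold: float = 0.05,
) -> Tuple[float, PofR, List[Tuple[float, float]]]:
    """Scan candidate Dmax values, returning the best Dmax, its P(r), and
    the full (Dmax, criterion) trace.

    The criterion combines the reduced chi^2 of the fit, a penalty for
    negative excursions of P(r), and a penalty for sign oscillation of the
    tail (weights in :data:`PR_CRITERION_WEIGHTS`); lower is better.
    """
    lo, hi = dmax_range
    if step <= 0 or hi <= lo or lo <= 0:
        raise ValueError("invalid Dmax range or step")
    if regularization is None:
        # during a scan the non-negativity constraint stabilizes the
        # inversion; keep the smoothness term light and fixed so the
        # criterion is comparable across candidate Dmax values
        regularization = 1e-4
    trace: List[Tuple[float, float]] = []
    results: List[PofR] = []
    d = lo
    while d <= hi + 1e-9:
        pofr = pr_invert(profile, d, regularization=regularization, n_r=n_r)
        trace.append((d, pofr.quality))
        results.append(pofr)
        d += step
    # chi^2 falls steeply while Dmax is too small, then plateaus; among
    # plateau candidates the non-negative inversion stops piling mass
    # against the cutoff once Dmax is large enough, so prefer the
    # smallest candidate whose tail pileup has vanished
    chi2s = np.array([p.chi2 for p in results])
    cmin = float(chi2s.min())
    on_plateau = chi2s <= cmin * (1.0 + plateau_tolerance) + 1e-30
    for k, pofr in enumerate(results):
        if on_plateau[k] and pofr.negativity <= 1e-6 and pofr.tail_pileup <= tail_threshold:
            return trace[k][0], results[k], trace
    qualities = np.array([t[1] for t in trace])
    qmin = float(qualities.min())
    ok = qualities <= qmin * (1.0 + plateau_tolerance) + 1e-30
    idx = int(np.argmax(ok))
    return trace[idx][0], results[idx], trace


# ---------------------------------------------------------------------------
# parallel-axis theorem

def parallel_axis_distance(inp: ParallelAxisInput) -> float:
    """Distance between the centres of mass of two bodies from their
    individual and joint radii of gyration:
    ``L = sqrt((Rg^2 - f1 R1g^2 - f2 R2g^2) / (f1 f2))``."""
    f1, f2 = inp.f1, inp.f2
    rad = inp.rg_complex**2 - f1 * inp.r1g**2 - f2 * inp.r2g**2
    if rad < -1e-9 * max(inp.rg_complex**2, 1.0):
        raise ValueError(
            "inconsistent inputs: complex Rg smaller than the weighted "
            "component Rg values (imaginary distance)"
        )
    return math.sqrt(max(rad, 0.0) / (f1 * f2))


def combined_rg(r1g: float, r2g: float, distance: float, f1: float = 0.5) -> float:
    """Forward form of the parallel-axis theorem."""
    f2 = 1.0 - f1
    return math.sqrt(f1 * r1g**2 + f2 * r2g**2 + f1 * f2 * distance**2)


# ---------------------------------------------------------------------------
# SVD-EFA deconvolution

def _evolving_traces(m: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    n_frames = m.shape[0]
    fwd = np.zeros((n_frames, k))
    bwd = np.zeros((n_frames, k))
    for f in range(n_frames):
        sv = np.linalg.svd(m[: f + 1], compute_uv=False)
        fwd[f, : min(k, len(sv))] = sv[:k]
        sv = np.linalg.svd(m[f:], compute_uv=False)
        bwd[f, : min(k, len(sv))] = sv[:k]
    return fwd, bwd


def _noise_floor(sv: np.ndarray) -> float:
    """Reference noise singular value: the SV at the 25%-rank position.

    Variance-scaled (Poisson-like) detector noise yields a sloped noise
    floor, so a high-rank noise SV is a more robust reference than the
    median of the trailing values; this assumes fewer than a quarter of
    the frames' worth of genuine components.
    """
    return float(sv[max(len(sv) // 4, 1)]) if len(sv) > 1 else 0.0


def detect_rank(singular_values: np.ndarray, noise_factor: float = 3.0) -> int:
    """Number of singular values above ``noise_factor`` times the noise
    floor (see :func:`_noise_floor`)."""
    sv = np.asarray(singular_values, dtype=float)
    if len(sv) == 0 or sv[0] == 0.0:
        return 0
    noise = _noise_floor(sv)
    if noise == 0.0:
        return int(np.sum(sv > 1e-12 * sv[0]))
    return int(np.sum(sv > noise_factor * noise))


def svd_efa(
    frames: FrameMatrix,
    n_components: Optional[int] = None,
    noise_factor: float = 3.0,
    n_iter: int = 500,
) -> EFAResult:
    """Deconvolve a (buffer-subtracted) SEC-SAXS frame stack.

    Forward/backward evolving-factor traces locate each component's entry
    and exit frame; the SVD basis is then rotated into non-negative
    concentration profiles constrained to live inside those windows
    (alternating least squares under the sequential-elution constraint),
    yielding per-component scattering and concentration profiles.
    """
    m = frames.intensities
    if frames.buffer_frames is not None:
        keep = ~frames.buffer_frames
        m = m[keep]
    n_frames = m.shape[0]
    sv_all = np.linalg.svd(m, compute_uv=False)
    rank = detect_rank(sv_all, noise_factor)
    if n_components is None:
        n_components = rank
    if n_components == 0:
        return EFAResult(0, [], sv_all, np.zeros((n_frames, 0)), np.zeros((n_frames, 0)), 0.0)
    if n_components > rank:
        raise ValueError(
            f"requested {n_components} components but only {rank} detectable "
            f"above the noise floor"
        )
    k = n_components
    fwd, bwd = _evolving_traces(m, k)
    noise = _noise_floor(sv_all)
    thresh = noise_factor * noise if noise > 0 else 1e-12 * sv_all[0]

    # component j enters when the (j+1)-th forward SV rises above the noise,
    # and exits when the (j+1)-th backward SV (counting from the back) falls
    entries = []
    exits = []
    for j in range(k):
        above = np.nonzero(fwd[:, j] > thresh)[0]
        entries.append(int(above[0]) if len(above) else 0)
        above = np.nonzero(bwd[:, k - 1 - j] > thresh)[0]
        exits.append(int(above[-1]) if len(above) else n_frames - 1)
    order = np.argsort(entries)
    entries = [entries[j] for j in order]
    exits_sorted = sorted(exits)
    windows = list(zip(entries, exits_sorted))

    # rotation into concentration space: alternating least squares with
    # non-negativity and window support (deterministic)
    conc = np.zeros((k, n_frames))
    for j, (e, x) in enumerate(windows):
        span = max(x - e, 1)
        idx = np.arange(n_frames)
        conc[j] = np.exp(-0.5 * ((idx - (e + x) / 2.0) / (span / 4.0)) ** 2)
        conc[j, :e] = 0.0
        conc[j, x + 1 :] = 0.0
    profiles = np.zeros((k, m.shape[1]))
    for _ in range(n_iter):
        profiles = np.linalg.lstsq(conc.T, m, rcond=None)[0]
        conc_new = np.linalg.lstsq(profiles.T, m.T, rcond=None)[0]
        for j, (e, x) in enumerate(windows):
            conc_new[j, :e] = 0.0
            conc_new[j, x + 1 :] = 0.0
        conc_new = np.clip(conc_new, 0.0, None)
        if np.allclose(conc_new, conc, rtol=1e-10, atol=1e-12):
            conc = conc_new
            break
        conc = conc_new
    profiles = np.linalg.lstsq(conc.T, m, rcond=None)[0]

    # normalize: unit peak concentration per component
    for j in range(k):
        peak = conc[j].max()
        if peak > 0:
            conc[j] /= peak
            profiles[j] *= peak
    residual = float(np.sqrt(np.mean((conc.T @ profiles - m) ** 2)))
    components = [
        EFAComponent(e, x, profiles[j], conc[j]) for j, (e, x) in enumerate(windows)
    ]
    return EFAResult(k, components, sv_all, fwd, bwd, residual)
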