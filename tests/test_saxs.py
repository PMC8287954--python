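"""Debye profiles, Guinier fits, P(r) inversion, parallel-axis theorem, EFA."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oligostate import saxs, synthgen
from oligostate.helixmodel import compute_dmax, compute_rg
from oligostate.saxs import (
    FitError,
    FrameMatrix,
    ParallelAxisInput,
    SAXSProfile,
    combined_rg,
    debye_profile,
    guinier_fit,
    parallel_axis_distance,
    pr_invert,
    scan_dmax,
    svd_efa,
)


@pytest.fixture(scope="module")
def sphere25_profile():
    beads = synthgen.gen_sphere_beads(25.0, spacing=3.5)
    q = np.linspace(1e-3, 0.3, 120)
    return debye_profile(beads, q_grid=q)


@pytest.fixture(scope="module")
def sphere30_profile():
    beads = synthgen.gen_sphere_beads(30.0, spacing=3.5)
    q = np.linspace(1e-3, 0.06, 60)
    return debye_profile(beads, q_grid=q)


@pytest.fixture(scope="module")
def sphere30_scan_profile():
    beads = synthgen.gen_sphere_beads(30.0, spacing=3.5)
    q = np.linspace(1e-3, 0.25, 150)
    return debye_profile(beads, q_grid=q)


class TestDebyeProfile:
    def test_single_bead_is_flat(self):
        prof = debye_profile(np.zeros((1, 3)), np.array([2.5]), np.linspace(0, 0.5, 50))
        assert np.allclose(prof.intensity, 2.5**2)

    def test_two_bead_closed_form(self):
        d, f = 20.0, 1.5
        q = np.linspace(0.0, 0.5, 101)
        prof = debye_profile(np.array([[0, 0, 0], [0, 0, d]]), np.array([f, f]), q)
        expect = 2 * f**2 * (1 + np.sinc(q * d / np.pi))
        assert np.allclose(prof.intensity, expect, rtol=1e-12)
        assert prof.intensity[0] == pytest.approx(4 * f**2)  # q -> 0 handled

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(50, 3)) * 15
        q = np.linspace(0, 0.4, 60)
        base = debye_profile(pts, q_grid=q).intensity
        rot, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = pts @ rot.T + np.array([100.0, -30.0, 5.0])
        assert np.allclose(debye_profile(moved, q_grid=q).intensity, base, rtol=1e-9)

    def test_guinier_limit_matches_real_space_rg(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(120, 3)) * 12
        true_rg = compute_rg(pts)
        q = np.linspace(1e-4, 1.3 / true_rg, 80)
        fit = guinier_fit(debye_profile(pts, q_grid=q))
        assert fit.rg == pytest.approx(true_rg, rel=0.01)


class TestGuinier:
    def test_exact_gaussian_recovery(self):
        rg, i0 = 28.0, 250.0
        q = np.linspace(1e-4, 0.2, 400)
        prof = SAXSProfile(q, i0 * np.exp(-((q * rg) ** 2) / 3.0))
        fit = guinier_fit(prof)
        assert fit.rg == pytest.approx(rg, abs=1e-6)
        assert fit.i0 == pytest.approx(i0, rel=1e-6)

    def test_sphere_closed_form(self, sphere30_profile):
        fit = guinier_fit(sphere30_profile)
        assert fit.rg == pytest.approx(math.sqrt(3.0 / 5.0) * 30.0, rel=0.02)

    def test_flat_profile_is_fit_error(self):
        q = np.linspace(1e-3, 0.1, 60)
        with pytest.raises(FitError):
            guinier_fit(SAXSProfile(q, np.ones_like(q)))

    def test_window_respects_qrg_limit(self):
        rg = 40.0
        q = np.linspace(1e-4, 0.3, 600)
        prof = SAXSProfile(q, np.exp(-((q * rg) ** 2) / 3.0))
        fit = guinier_fit(prof, qrg_limit=1.3)
        assert fit.q_window[1] * fit.rg <= 1.3 + 1e-6


class TestPofR:
    def test_two_bead_mass_at_separation(self):
        d = 25.0
        q = np.linspace(1e-3, 0.6, 300)
        prof = debye_profile(np.array([[0, 0, 0], [0, 0, d]]), q_grid=q)
        pofr = pr_invert(prof, 35.0)
        off_origin = pofr.r > 5.0
        peak_r = pofr.r[off_origin][np.argmax(pofr.p[off_origin])]
        assert peak_r == pytest.approx(d, abs=1.5)

    def test_forward_transform_consistency(self, sphere25_profile):
        prof = sphere25_profile
        q = prof.q
        pofr = pr_invert(prof, 55.0)
        back = pofr.forward(q)
        # agreement within the regularization-consistent residual
        assert np.linalg.norm(back - prof.intensity) / np.linalg.norm(prof.intensity) < 0.01

    def test_pr_rg_matches_guinier(self, sphere25_profile):
        g = guinier_fit(sphere25_profile)
        pofr = pr_invert(sphere25_profile, 55.0)
        assert pofr.rg == pytest.approx(g.rg, rel=0.03)

    def test_truncated_dmax_fits_worse(self, sphere25_profile):
        prof = sphere25_profile
        lam = pr_invert(prof, 50.0).regularization
        good = pr_invert(prof, 50.0, regularization=lam)
        bad = pr_invert(prof, 28.0, regularization=lam)
        assert bad.quality > good.quality

    def test_invalid_inputs(self):
        q = np.linspace(1e-3, 0.3, 50)
        prof = SAXSProfile(q, np.exp(-q))
        with pytest.raises(ValueError):
            pr_invert(prof, -5.0)


class TestDmaxScan:
    def test_sphere_optimum_near_diameter(self, sphere30_scan_profile):
        radius = 30.0
        clean = sphere30_scan_profile
        q = clean.q
        rng = np.random.default_rng(0)
        sigma = 0.01 * clean.intensity + 1e-4 * clean.intensity[0]
        prof = SAXSProfile(q, clean.intensity + rng.normal(0, sigma), sigma)
        best, _, trace = scan_dmax(prof, (40.0, 90.0), step=2.0)
        assert best == pytest.approx(2 * radius, rel=0.05)
        assert len(trace) == 26

    def test_criterion_monotone_below_optimum(self, sphere25_profile):
        prof = sphere25_profile
        lam = pr_invert(prof, 50.0).regularization
        quals = [pr_invert(prof, d, regularization=lam).quality for d in (26, 30, 34)]
        assert quals[0] > quals[1] > quals[2]

    def test_deterministic(self):
        beads = synthgen.gen_sphere_beads(20.0, spacing=3.5)
        q = np.linspace(1e-3, 0.3, 100)
        prof = debye_profile(beads, q_grid=q)
        out1 = scan_dmax(prof, (30.0, 60.0), step=5.0)
        out2 = scan_dmax(prof, (30.0, 60.0), step=5.0)
        assert out1[0] == out2[0]
        assert out1[2] == out2[2]

    def test_empty_range_rejected(self):
        prof = SAXSProfile(np.linspace(1e-3, 0.3, 50), np.exp(-np.linspace(1e-3, 0.3, 50)))
        with pytest.raises(ValueError):
            scan_dmax(prof, (50.0, 40.0), step=2.0)


class TestParallelAxis:
    def test_identical_bodies_zero_distance(self):
        assert parallel_axis_distance(ParallelAxisInput(20.0, 20.0, 20.0, 0.5)) == 0.0

    def test_point_bodies(self):
        rg = 17.0
        assert parallel_axis_distance(ParallelAxisInput(rg, 0.0, 0.0, 0.5)) == pytest.approx(2 * rg)

    @given(
        st.floats(1.0, 50.0),
        st.floats(1.0, 50.0),
        st.floats(0.0, 200.0),
        st.floats(0.05, 0.95),
    )
    def test_algebraic_inverse(self, r1, r2, dist, f1):
        rg = combined_rg(r1, r2, dist, f1)
        back = parallel_axis_distance(ParallelAxisInput(rg, r1, r2, f1))
        # sqrt amplifies rounding near dist = 0, hence the sqrt(eps) floor
        assert back == pytest.approx(dist, rel=1e-9, abs=2e-6)

    def test_bead_cloud_oracle(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=(300, 3)) * 8
        b = rng.normal(size=(300, 3)) * 12 + np.array([60.0, -25.0, 10.0])
        union = np.vstack([a, b])
        true_l = float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))
        inp = ParallelAxisInput(compute_rg(union), compute_rg(a), compute_rg(b), 0.5)
        assert parallel_axis_distance(inp) == pytest.approx(true_l, rel=1e-9)

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError):
            parallel_axis_distance(ParallelAxisInput(5.0, 30.0, 30.0, 0.5))
        with pytest.raises(ValueError):
            ParallelAxisInput(10.0, 5.0, 5.0, 1.5)


class TestEFA:
    def test_rank_one_stack(self):
        q = np.linspace(1e-3, 0.3, 120)
        p = np.exp(-((q * 30) ** 2) / 3.0)
        frames = np.arange(60, dtype=float)
        c = np.exp(-0.5 * ((frames - 25) / 5.0) ** 2)
        rng = np.random.default_rng(1)
        m = np.outer(c, p) + rng.normal(0, 1e-4, (60, 120))
        res = svd_efa(FrameMatrix(m, q), 1)
        assert res.n_components == 1
        got = res.components[0].profile
        cos = np.dot(got, p) / np.linalg.norm(got) / np.linalg.norm(p)
        assert cos >= 0.999

    def test_two_overlapping_components_recovered(self):
        fm, profiles, concs = _two_component_stack(seed=3)
        res = svd_efa(fm, 2)
        for comp, truth_p, truth_c in zip(res.components, profiles, concs):
            cos = np.dot(comp.profile, truth_p) / (
                np.linalg.norm(comp.profile) * np.linalg.norm(truth_p)
            )
            assert cos >= 0.99
            support = np.nonzero(truth_c)[0]
            assert abs(comp.entry_frame - support[0]) <= 2
            assert abs(comp.exit_frame - support[-1]) <= 2

    def test_zero_matrix_has_no_components(self):
        fm = FrameMatrix(np.zeros((20, 30)), np.linspace(1e-3, 0.3, 30))
        assert svd_efa(fm).n_components == 0

    def test_overasking_components_raises(self):
        fm, _, _ = _two_component_stack(seed=5)
        with pytest.raises(ValueError, match="detectable"):
            svd_efa(fm, 10)

    def test_concentrations_non_negative(self):
        fm, _, _ = _two_component_stack(seed=7)
        res = svd_efa(fm, 2)
        for comp in res.components:
            assert np.all(comp.concentration >= 0)


def _two_component_stack(seed: int):
    tet_xyz, tet_w = synthgen.gen_bead_model("tetramer")
    oct_xyz, oct_w = synthgen.gen_bead_model("octamer")
    return synthgen.gen_secsaxs_frames(
        [
            synthgen.ElutingComponent(oct_xyz, oct_w, 30.0, 6.0, 1.0),
            synthgen.ElutingComponent(tet_xyz, tet_w, 45.0, 7.0, 0.8),
        ],
        n_frames=80,
        seed=seed,
    )
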