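import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecospectra as es
from ecospectra.cavity import MomentInputs

from conftest import rel_l2


def lv_residual(mf, m):
    """Residual of the resolvent self-consistency 1/r = -EAii + i w - r c EAijAji."""
    w = -m.EAii + 1j * mf.omegas
    return np.abs(1.0 / mf.r - (w - mf.r * m.c * m.EAijAji))


class TestResolvent:
    def test_uncorrelated_limit_is_bare_resolvent(self):
        m = MomentInputs(EAii=-0.7, EBii=1.0, EAij2=0.3, EAijAji=0.0, EAijBij=0.0, c=5.0)
        for om in (0.0, 1.3):
            assert es.resolvent_mean_field(om, m) == pytest.approx(1 / (0.7 + 1j * om))

    def test_self_consistency_residual_on_grid(self):
        p = es.LVParams(N=1000, c=20, sigma2=1 / 80, gamma=-1.0, b=0.2)
        m = es.lv_moment_map(p)
        omegas = np.linspace(0, 2, 512)
        mf = es.psd_mean_field(omegas, m)
        assert np.max(lv_residual(mf, m)) < 1e-10

    def test_reality_symmetry(self):
        p = es.LVParams(N=100, c=20, sigma2=1 / 80, gamma=-1.0, b=0.2)
        m = es.lv_moment_map(p)
        r_pos = es.resolvent_mean_field(0.7, m)
        r_neg = es.resolvent_mean_field(-0.7, m)
        assert abs(np.conj(r_neg) - r_pos) < 1e-12

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        b=st.floats(0.1, 5.0),
        cs2=st.floats(1e-4, 2.0),
        gamma=st.floats(-1.0, 1.0),
        omega=st.floats(0.0, 20.0),
    )
    def test_physical_branch_everywhere_in_stable_region(self, b, cs2, gamma, omega):
        # stay strictly inside the stability region
        if es.stability_edge(b, cs2, gamma) >= -0.05:
            return
        m = MomentInputs(
            EAii=-b, EBii=1.0, EAij2=cs2, EAijAji=gamma * cs2, EAijBij=0.0, c=1.0
        )
        r = es.resolvent_mean_field(float(omega), m)
        assert r.real > 0  # resolvent of a stable matrix
        w = b + 1j * omega
        # residual in the multiplied-through (well-conditioned) form
        assert abs(1.0 - r * (w - r * gamma * cs2)) < 1e-9


class TestMeanFieldPsd:
    def test_gamma_zero_matches_closed_form_pointwise(self):
        p = es.LVParams(N=1000, c=50, sigma2=0.5, gamma=0.0, b=7.0)
        omegas = np.linspace(0, 30, 512)
        mf = es.psd_mean_field(omegas, es.lv_moment_map(p))
        cf = es.closed_form_psd("gamma_zero", omegas, p)
        assert np.max(np.abs(mf.phi - cf)) < 1e-10

    def test_mixed_community_zero_frequency_value(self):
        p = es.LVParams(N=1000, c=50, sigma2=0.5, gamma=0.0, b=7.0)
        mf = es.psd_mean_field(np.array([0.0]), es.lv_moment_map(p))
        assert mf.phi[0] == pytest.approx(1.75873, abs=1e-4)

    def test_instability_flagged_not_silent(self):
        # gamma=0 with b^2 < c sigma^2: beyond the stability boundary
        m = MomentInputs(EAii=-1.0, EBii=2.0, EAij2=2.0, EAijAji=0.0, EAijBij=0.0, c=1.0)
        mf = es.psd_mean_field(np.array([0.0, 0.5]), m)
        assert not mf.converged[0]
        assert np.isinf(mf.phi[0])

    def test_oracle_agreement_improves_with_system_size(self):
        kw = dict(c=50, sigma2=1 / 200, gamma=-1.0, b=0.05)
        omegas = np.linspace(0, 1.5, 128)
        errs = []
        for N in (200, 1000):
            mf = es.psd_mean_field(omegas, es.lv_moment_map(es.LVParams(N=N, **kw)))
            acc = np.zeros_like(omegas)
            for seed in range(3):
                com = es.sample_lv_community(es.LVParams(N=N, **kw, seed=seed))
                acc += es.mean_psd_exact(com.A, com.B, omegas).values
            errs.append(rel_l2(acc / 3, mf.phi))
        assert errs[-1] < errs[0]


class TestMomentMap:
    def test_no_interactions(self):
        m = es.lv_moment_map(es.LVParams(N=10, c=0, sigma2=0.5, gamma=0.0, b=1.0))
        assert m.EBii == pytest.approx(2.0)

    def test_half_normal_mean_consistency(self):
        p = es.LVParams(N=10, c=7, sigma2=0.37, gamma=0.1, b=1.0)
        m = es.lv_moment_map(p)
        assert m.EBii - 2 * p.b == pytest.approx(
            7 * math.sqrt(0.37) * math.sqrt(2 / math.pi), abs=1e-12
        )

    def test_pure_predation_resolvent_discriminant(self):
        # gamma = -1: the square root becomes sqrt((b + i w)^2 + 4 c sigma^2)
        p = es.LVParams(N=100, c=20, sigma2=0.0125, gamma=-1.0, b=0.2)
        m = es.lv_moment_map(p)
        om = 0.4
        r = es.resolvent_mean_field(om, m)
        w = p.b + 1j * om
        cs2 = p.c * p.sigma2
        expected = (w - np.sqrt(w * w + 4 * cs2)) / (-2 * cs2)
        assert abs(r - expected) < 1e-12


class TestClosedForms:
    def test_quarter_circle_value_at_zero(self):
        p = es.LVParams(N=1000, c=50, sigma2=0.005, gamma=-1.0, b=0.05)
        assert es.closed_form_psd("quarter_circle", 0.0, p) == pytest.approx(
            111.20, abs=0.01
        )

    def test_weak_interaction_lorentzian(self):
        p = es.LVParams(N=100, c=50, sigma2=1e-8, gamma=0.5, b=1.0)
        om = np.linspace(0, 5, 64)
        weak = es.closed_form_psd("weak", om, p)
        full = es.psd_mean_field(om, es.lv_moment_map(p)).phi
        assert np.max(np.abs(full - weak) / weak) < 1e-4

    def test_quarter_circle_band_precondition(self):
        p = es.LVParams(N=100, c=50, sigma2=0.005, gamma=-1.0, b=0.05)
        with pytest.raises(ValueError, match="band"):
            es.closed_form_psd("quarter_circle", 1.1, p)
        p_wrong = es.LVParams(N=100, c=50, sigma2=0.005, gamma=0.0, b=0.05)
        with pytest.raises(ValueError, match="gamma"):
            es.closed_form_psd("quarter_circle", 0.0, p_wrong)

    def test_symmetric_margin_high_frequency_tail(self):
        c, s2 = 50, 0.5
        p = es.LVParams(N=100, c=c, sigma2=s2, gamma=1.0, b=math.sqrt(4 * c * s2))
        for om in (50.0, 100.0):
            ratio = es.closed_form_psd("gamma_one_margin", 2 * om, p) / es.closed_form_psd(
                "gamma_one_margin", om, p
            )
            assert ratio == pytest.approx(0.25, rel=0.04)

    def test_quarter_circle_is_small_b_limit_of_cavity(self):
        sub = np.linspace(0.0, 0.8, 100)  # compact sub-band of omega^2 < 4 c sigma^2 = 1
        sups = []
        for b in (0.05, 0.025, 0.0125):
            p = es.LVParams(N=100, c=50, sigma2=0.005, gamma=-1.0, b=b)
            mf = es.psd_mean_field(sub, es.lv_moment_map(p))
            cf = es.closed_form_psd("quarter_circle", sub, p)
            sups.append(np.max(np.abs(mf.phi - cf)))
        ratios = [sups[k] / sups[k + 1] for k in range(2)]
        # halving b halves the sup deviation: O(b) convergence
        assert all(1.7 < r < 2.3 for r in ratios)


class TestLowFrequencyExponents:
    def test_mixed_near_instability_inverse_square(self):
        c, s2 = 50, 0.5
        b = math.sqrt(c * s2 * (1 + 1e-4))
        p = es.LVParams(N=100, c=c, sigma2=s2, gamma=0.0, b=b)
        om = np.logspace(-0.5, 0.5, 50)  # decade well above sqrt(eps c s2) ~ 0.05
        phi = es.psd_mean_field(om, es.lv_moment_map(p)).phi
        slope = np.polyfit(np.log(om), np.log(phi), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.1)

    def test_symmetric_at_margin_inverse_sqrt(self):
        c, s2 = 50, 0.5
        p = es.LVParams(N=100, c=c, sigma2=s2, gamma=1.0, b=math.sqrt(4 * c * s2))
        om = np.logspace(-6, -5, 50)
        phi = es.psd_mean_field(om, es.lv_moment_map(p)).phi
        slope = np.polyfit(np.log(om), np.log(phi), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)


class TestSingleDefect:
    def test_isolated_species_is_bare_lorentzian(self):
        com = es.sample_lv_community(
            es.LVParams(N=50, c=5, sigma2=0.02, gamma=0.0, b=1.0, seed=8)
        )
        # disconnect species 0 by hand
        com.A[0, 1:] = 0.0
        com.A[1:, 0] = 0.0
        com.B[0, 1:] = 0.0
        com.B[1:, 0] = 0.0
        com.B[0, 0] = 2.0
        omegas = np.linspace(0, 5, 32)
        mf = es.psd_mean_field(omegas, es.lv_moment_map(com.params))
        phi0 = es.psd_single_defect(0, com, mf)
        assert np.allclose(phi0, 2.0 / (1.0 + omegas**2), rtol=1e-12)

    def test_average_local_sums_collapse_to_mean_field(self):
        # craft a species whose local sums equal c times the ensemble moments:
        # its single-defect spectrum must reproduce the mean field exactly
        c, s2, b = 2.0, 0.02, 1.0
        mu = math.sqrt(2 * s2 / math.pi)
        cmu = c * mu
        cs2 = c * s2
        # r1 + r2 = c mu and r1^2 + r2^2 = c sigma^2 (both rates positive)
        disc = math.sqrt(2 * cs2 - cmu**2)
        r1, r2 = (cmu + disc) / 2, (cmu - disc) / 2
        params = es.LVParams(N=3, c=c, sigma2=s2, gamma=1.0, b=b)
        A = np.array([[-b, r1, r2], [r1, -b, 0.0], [r2, 0.0, -b]])
        B = np.diag([2 * b + r1 + r2, 2 * b + r1, 2 * b + r2])
        com = es.LVCommunity(params=params, A=A, B=B, x_star=np.ones(3))
        omegas = np.linspace(0, 6, 64)
        mf = es.psd_mean_field(omegas, es.lv_moment_map(params))
        phi0 = es.psd_single_defect(0, com, mf)
        assert np.max(np.abs(phi0 - mf.phi)) < 1e-10

    def test_index_out_of_range(self):
        com = es.sample_lv_community(es.LVParams(N=5, c=2, sigma2=0.01, gamma=0.0, b=1.0))
        mf = es.psd_mean_field(np.linspace(0, 1, 8), es.lv_moment_map(com.params))
        with pytest.raises(IndexError):
            es.psd_single_defect(7, com, mf)

    def test_vectorised_matches_per_species(self):
        com = es.sample_lv_community(
            es.LVParams(N=40, c=8, sigma2=0.01, gamma=-1.0, b=0.5, seed=2)
        )
        omegas = np.linspace(0, 3, 16)
        mf = es.psd_mean_field(omegas, es.lv_moment_map(com.params))
        allspec = es.psd_single_defect_all(com, mf)
        for i in (0, 17, 39):
            assert np.allclose(allspec.values[:, i], es.psd_single_defect(i, com, mf))


class TestCriticalFrequencies:
    def test_direct_evaluation(self):
        lo, hi = es.critical_frequencies(1.0, 1.0, 20, 10)
        assert lo == pytest.approx(0.0926, abs=1e-4)
        assert hi == pytest.approx(0.5398, abs=1e-4)

    def test_equal_degrees_close_the_gap(self):
        lo, hi = es.critical_frequencies(2.0, 0.5, 12, 12)
        assert lo == 0.0
        assert hi > 0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        b=st.floats(0.1, 5.0), d=st.floats(0.1, 5.0),
        cx=st.integers(1, 40), cy=st.integers(1, 40),
    )
    def test_rate_scaling(self, b, d, cx, cy):
        lo, hi = es.critical_frequencies(b, d, cx, cy)
        # omega_+- scales as sqrt(b d): doubling both rates doubles the band
        lo2, hi2 = es.critical_frequencies(2 * b, 2 * d, cx, cy)
        assert lo2 == pytest.approx(2 * lo, rel=1e-12, abs=1e-12)
        assert hi2 == pytest.approx(2 * hi, rel=1e-12)
        assert 0 <= lo <= hi


class TestRepresentativePair:
    def test_trace_identity_for_complex_pair(self, fig_trophic_params):
        ev1, ev2 = es.representative_2d_eigenvalues(fig_trophic_params)
        x, y = es.trophic_fixed_point(fig_trophic_params)
        assert ev1.real == pytest.approx(-(x + y) / 2, rel=1e-12)

    def test_determinant_identity(self, fig_trophic_params):
        ev1, ev2 = es.representative_2d_eigenvalues(fig_trophic_params)
        p = fig_trophic_params
        x, y = es.trophic_fixed_point(p)
        det = (ev1 * ev2).real
        assert det == pytest.approx(x * y * (1 + p.cx * p.cy * p.alpha**2), rel=1e-12)


@pytest.fixture(scope="module")
def solution(fig_trophic_params):
    omegas = np.linspace(1e-3, 1.5, 300)
    return es.solve_bipartite_mean_field(fig_trophic_params, omegas)


class TestBipartiteSolver:

    def test_all_frequencies_converged(self, solution):
        assert solution.converged.all()

    def test_self_consistency_residual(self, solution, fig_trophic_params):
        p = fig_trophic_params
        x, y = es.trophic_fixed_point(p)
        kx = p.alpha**2 * p.cx * x * y
        ky = p.alpha**2 * p.cy * x * y
        z = 1j * solution.omegas
        res_x = np.abs(1 / solution.r_x - (x + z + kx * solution.r_y))
        res_y = np.abs(1 / solution.r_y - (y + z + ky * solution.r_x))
        assert np.max(res_x) < 1e-6 and np.max(res_y) < 1e-6

    def test_high_frequency_tail_decays(self, solution):
        tail = solution.phi_x[solution.omegas > 1.0]
        assert np.all(np.diff(tail) < 0)
        assert tail[-1] < 0.05 * np.max(solution.phi_x)

    def test_matches_exact_oracle_in_band(self, solution, fig_trophic_community):
        # finite degrees (cy = 10) put O(1/c) corrections near the band edges;
        # agreement inside the band is ~12% at this size, tighter in the core
        com = fig_trophic_community
        sd = es.psd_diag_exact(com.A, com.B, solution.omegas)
        pred = sd.values[:, : com.params.Nx].mean(axis=1)
        lo, hi = solution.band
        inband = (solution.omegas >= lo) & (solution.omegas <= hi)
        core = (solution.omegas >= 1.1 * lo) & (solution.omegas <= 0.9 * hi)
        assert rel_l2(solution.phi_x[inband], pred[inband]) < 0.15
        assert rel_l2(solution.phi_x[core], pred[core]) < 0.10

    def test_zero_frequency_floor_agrees_with_oracle(self, solution, fig_trophic_community):
        com = fig_trophic_community
        d0 = np.diag(es.psd_direct(com.A, com.B, solution.omegas[0]))
        assert solution.phi_x[0] == pytest.approx(
            float(d0[: com.params.Nx].real.mean()), rel=0.05
        )
        assert solution.phi_y[0] == pytest.approx(
            float(d0[com.params.Nx :].real.mean()), rel=0.05
        )

    def test_tail_side_suppression_exceeds_two_decades(self, solution):
        # beyond twice the upper critical frequency the predator spectrum is
        # down by more than 10^2 from its in-band maximum
        lo, hi = solution.band
        inband = (solution.omegas >= lo) & (solution.omegas <= hi)
        tail = solution.omegas >= 2 * hi
        assert np.max(solution.phi_x[inband]) / np.max(solution.phi_x[tail]) > 1e2
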