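"""Closed-form stability theory vs numeric-spectrum oracles."""
import numpy as np
import pytest

from bcmdyn.model import PlasticityRule, meanfield_system
from bcmdyn.numerics import numeric_jacobian, system_jacobian
from bcmdyn.stability import (
    NetworkStabilityParams,
    TwoStimulusParams,
    block_eigen_split,
    charpoly_z1,
    charpoly_z2,
    fixed_points_two_stimuli,
    hopf_tau_z1,
    hopf_tau_z2,
    inhibition_matrix,
    inhibition_steady_state,
    jacobian_z1,
    network_hopf_taus,
    origin_escape_slope,
    partial_equilibrium_is_saddle,
    selective_equilibrium_stable,
    stability_report,
    symmetric_network_jacobian,
)

from conftest import random_noncollinear_pair


def _params_for(ens, tau, selected):
    return TwoStimulusParams.from_ensemble(ens, tau, selected=selected)


class TestFixedPoints:
    def test_equal_probability_points(self):
        pts = fixed_points_two_stimuli(0.5)
        assert np.allclose(pts["z1"], [2.0, 0.0, 2.0])
        assert np.allclose(pts["z2"], [0.0, 2.0, 2.0])

    def test_origin_and_symmetric_always_present(self):
        for rho in (0.1, 0.5, 0.9):
            pts = fixed_points_two_stimuli(rho)
            assert np.allclose(pts["origin"], 0.0)
            assert np.allclose(pts["symmetric11"], 1.0)

    def test_invalid_rho(self):
        with pytest.raises(ValueError):
            fixed_points_two_stimuli(1.0)

    def test_each_point_zeroes_mean_field(self, rng):
        for _ in range(50):
            ens = random_noncollinear_pair(rng)
            system = meanfield_system(ens, PlasticityRule(1.0, 1.0))
            for v in fixed_points_two_stimuli(float(ens.probs[0])).values():
                assert np.max(np.abs(system.f(0.0, v))) < 1e-10


class TestCharacteristicPolynomials:
    def test_coefficients_match_numeric_jacobian(self, rng):
        """Closed-form A coefficients vs the numerically built Jacobian
        of the actual mean field, at both selective equilibria (100 draws)."""
        for _ in range(100):
            ens = random_noncollinear_pair(rng)
            tau = rng.uniform(0.2, 3.0)
            system = meanfield_system(ens, PlasticityRule(1.0, tau))
            pts = fixed_points_two_stimuli(float(ens.probs[0]))
            for which, fn in (("z1", charpoly_z1), ("z2", charpoly_z2)):
                p = _params_for(ens, tau, 0 if which == "z1" else 1)
                A0, A1, A2 = fn(p)
                J = system_jacobian(system, pts[which])
                poly = np.poly(J)  # (1, A2, A1, A0)
                assert np.allclose([A2, A1, A0], poly[1:], atol=1e-8)

    def test_standard_case_substitution(self):
        p = TwoStimulusParams(a=1.0, b=0.3, c=1.0, tau=0.7)
        A0, A1, A2 = charpoly_z1(p)
        assert A2 == pytest.approx(1.0 / 0.7)
        assert A0 == pytest.approx((1.0 - 0.09) / 0.7)

    def test_constant_coefficient_always_positive(self, rng):
        """No zero-eigenvalue bifurcation: A10, A20 > 0 whenever a > b^2."""
        for _ in range(200):
            a = rng.uniform(0.3, 4.0)
            b = rng.uniform(-0.95, 0.95) * np.sqrt(a)
            c = rng.uniform(0.1, 5.0)
            tau = rng.uniform(0.1, 5.0)
            p = TwoStimulusParams(a=a, b=b, c=c, tau=tau)
            assert charpoly_z1(p)[0] > 0
            assert charpoly_z2(p)[0] > 0

    def test_printed_jacobian_at_z1(self, rng):
        """The (a, b, c)-form Jacobian matches the numeric mean-field
        Jacobian at z1 row by row (with the per-equilibrium c convention)."""
        for _ in range(20):
            ens = random_noncollinear_pair(rng)
            tau = rng.uniform(0.3, 2.0)
            p = _params_for(ens, tau, selected=0)
            system = meanfield_system(ens, PlasticityRule(1.0, tau))
            z1 = fixed_points_two_stimuli(float(ens.probs[0]))["z1"]
            Jn = numeric_jacobian(lambda y: system.f(0.0, y), z1)
            assert np.allclose(jacobian_z1(p), Jn, atol=1e-6)


class TestHopfTau:
    def test_standard_closed_form(self):
        """Equal amplitudes and probabilities: tau_c = 1/(1 - b**2)."""
        b = np.cos(1.0)
        tau = hopf_tau_z1(1.0, b, 1.0)
        assert tau == pytest.approx(1.0 / (1.0 - b * b), abs=1e-12)
        assert tau == pytest.approx(1.412, abs=5e-4)
        assert hopf_tau_z2(1.0, b, 1.0) == pytest.approx(tau, abs=1e-12)

    def test_amplified_second_stimulus(self):
        """A = 1.5: the two selective equilibria destabilize at different tau."""
        a, b = 2.25, 1.5 * np.cos(1.0)
        assert hopf_tau_z1(a, b, 1.0) == pytest.approx(1.52, abs=5e-3)
        assert hopf_tau_z2(a, b, 1.0) == pytest.approx(0.52, abs=5e-3)

    def test_orthogonal_stimuli(self):
        assert hopf_tau_z1(1.0, 0.0, 1.0) == pytest.approx(1.0)

    def test_degenerate_linear_cases(self):
        # c = 1/a kills the tau^2 coefficient of the z1 quadratic
        a, b, c = 2.0, 0.4, 0.5
        tau = hopf_tau_z1(a, b, c)
        q2 = c * (a - b * b) * (1 - a * c)
        assert abs(q2) < 1e-12 and tau is not None and tau > 0
        # c = a kills the tau^2 coefficient of the z2 quadratic
        tau2 = hopf_tau_z2(a, b, a)
        assert tau2 is not None and tau2 > 0

    def test_hopf_tau_certified_by_spectrum(self, rng):
        """At the predicted tau the numeric Jacobian has an imaginary pair."""
        for _ in range(20):
            ens = random_noncollinear_pair(rng)
            for which, sel in (("z1", 0), ("z2", 1)):
                p0 = _params_for(ens, 1.0, sel)
                fn = hopf_tau_z1 if which == "z1" else hopf_tau_z2
                tau_c = fn(p0.a, p0.b, p0.c)
                if tau_c is None or tau_c > 50:
                    continue
                system = meanfield_system(ens, PlasticityRule(1.0, tau_c))
                z = fixed_points_two_stimuli(float(ens.probs[0]))[which]
                ev = np.linalg.eigvals(system_jacobian(system, z))
                pair = ev[np.abs(ev.imag) > 1e-8]
                assert pair.size == 2
                assert np.max(np.abs(pair.real)) < 1e-6


class TestStabilityCriterion:
    def test_equal_case_threshold(self):
        b = 0.6
        tau_c = 1.0 / (1.0 - b * b)
        assert selective_equilibrium_stable("z1", 1.0, b, 1.0, 0.9 * tau_c)
        assert selective_equilibrium_stable("z2", 1.0, b, 1.0, 0.9 * tau_c)
        assert not selective_equilibrium_stable("z1", 1.0, b, 1.0, 1.1 * tau_c)

    def test_small_tau_always_stable(self, rng):
        for _ in range(20):
            a = rng.uniform(0.3, 4.0)
            b = rng.uniform(-0.9, 0.9) * np.sqrt(a)
            c = rng.uniform(0.2, 4.0)
            assert selective_equilibrium_stable("z1", a, b, c, 1e-3)
            assert selective_equilibrium_stable("z2", a, b, c, 1e-3)

    def test_flag_matches_eigenvalue_oracle(self, rng):
        """200 random draws: closed-form verdict vs sign of the numeric
        spectrum, skipping draws within 1e-6 of the stability boundary."""
        checked = 0
        while checked < 200:
            ens = random_noncollinear_pair(rng)
            tau = rng.uniform(0.1, 4.0)
            system = meanfield_system(ens, PlasticityRule(1.0, tau))
            pts = fixed_points_two_stimuli(float(ens.probs[0]))
            for which, sel in (("z1", 0), ("z2", 1)):
                p = _params_for(ens, tau, sel)
                ev = np.linalg.eigvals(system_jacobian(system, pts[which]))
                margin = np.max(ev.real)
                if abs(margin) < 1e-6:
                    continue
                flag = selective_equilibrium_stable(which, p.a, p.b, p.c, tau)
                assert flag == (margin < 0), (which, p, margin)
                checked += 1

    def test_report_structure(self, standard_pair):
        reports = {r.label: r for r in stability_report(standard_pair, 1.0)}
        assert not reports["origin"].stable
        assert not reports["symmetric11"].stable
        assert reports["z1"].stable and reports["z2"].stable
        assert reports["z1"].hopf_tau == pytest.approx(1.412, abs=5e-4)


class TestOriginEscapeSlope:
    def test_ray_slope_solves_fixed_point(self):
        b, c, a = 0.5, 1.0, 1.0
        K = origin_escape_slope(b, c, a)
        H = (c + b * K * K) / (c * b + a * K * K)
        assert H == pytest.approx(1.0 / K, rel=1e-8)
        assert K > 0


class TestNetworkAlgebra:
    def test_gamma_zero_reduces_to_single_neuron(self):
        alpha = 0.7709
        ts, ta = network_hopf_taus(0.0, alpha)
        single = 1.0 / (1.0 - np.cos(alpha) ** 2)
        assert ts == pytest.approx(single) and ta == pytest.approx(single)

    def test_symmetric_threshold_linear_in_gamma(self):
        alpha = 0.7709
        gammas = np.linspace(0.05, 0.9, 8)
        vals = [network_hopf_taus(g, alpha)[0] for g in gammas]
        slopes = np.diff(vals) / np.diff(gammas)
        assert np.allclose(slopes, slopes[0])
        assert slopes[0] < 0

    def test_thresholds_match_6x6_spectrum_bisection(self):
        """Closed forms vs the tau at which the full linearization's leading
        pair crosses the imaginary axis (bisection to 1e-4)."""
        gamma, alpha = 0.25, 0.7709

        def lead(tau):
            ev = np.linalg.eigvals(symmetric_network_jacobian(gamma, alpha, tau))
            return np.max(ev.real)

        ts_exact, _ = network_hopf_taus(gamma, alpha)
        lo, hi = 0.5 * ts_exact, 2.0 * ts_exact
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if lead(mid) < 0:
                lo = mid
            else:
                hi = mid
        assert 0.5 * (lo + hi) == pytest.approx(ts_exact, abs=1e-4)

    def test_block_union_equals_full_spectrum(self, rng):
        for _ in range(50):
            gamma = rng.uniform(0.0, 0.9)
            alpha = rng.uniform(0.2, np.pi - 0.2)
            tau = rng.uniform(0.2, 4.0)
            e1, e2 = block_eigen_split(gamma, alpha, tau)
            full = np.linalg.eigvals(symmetric_network_jacobian(gamma, alpha, tau))
            got = np.sort_complex(np.concatenate([e1, e2]))
            assert np.allclose(got, np.sort_complex(full), atol=1e-8)

    def test_instability_enters_through_a2_block(self):
        """Just above the symmetric Hopf the a2 (symmetry-breaking) block is
        unstable while the a1 block is not."""
        gamma, alpha = 0.3, 0.7709
        ts, _ = network_hopf_taus(gamma, alpha)
        e1, e2 = block_eigen_split(gamma, alpha, 1.02 * ts)
        assert np.max(e2.real) > 0
        assert np.max(e1.real) < 0

    def test_gamma_zero_blocks_coincide(self):
        e1, e2 = block_eigen_split(0.0, 1.0, 1.3)
        assert np.allclose(np.sort_complex(e1), np.sort_complex(e2))

    def test_partial_saddle_always(self, rng):
        for _ in range(100):
            gamma = rng.uniform(0.0, 0.9)
            alpha = rng.uniform(0.2, np.pi - 0.2)
            tau = rng.uniform(0.2, 4.0)
            saddle, a0 = partial_equilibrium_is_saddle(gamma, alpha, tau)
            assert saddle and a0 < 0

    def test_partial_saddle_matches_numeric_charpoly(self):
        """a0 equals the constant coefficient of the numeric characteristic
        polynomial at the partial equilibrium (1, 1, 1, 2, 0, 2)."""
        from bcmdyn.model import StimulusEnsemble
        from bcmdyn.network import NetworkParams, network_system

        gamma, alpha, tau = 0.3, 0.7709, 1.4
        ens = StimulusEnsemble.angled_pair(alpha)
        params = NetworkParams(gamma, ens, PlasticityRule(1.0, tau))
        system = network_system(params)
        x = np.array([1.0, 1.0, 1.0, 2.0, 0.0, 2.0])
        assert np.max(np.abs(system.f(0.0, x))) < 1e-12
        poly = np.poly(system_jacobian(system, x))
        _, a0 = partial_equilibrium_is_saddle(gamma, alpha, tau)
        assert poly[-1] == pytest.approx(a0, rel=1e-8)

    def test_partial_saddle_uncoupled_formula(self):
        _, a0 = partial_equilibrium_is_saddle(0.0, 1.0, 1.5)
        beta = np.cos(1.0)
        assert a0 == pytest.approx(-((1 - beta**2) ** 2) / (4 * 1.5**2))


class TestInhibitionSteadyState:
    def test_no_inhibition_identity(self, rng):
        s = rng.standard_normal(4)
        assert np.allclose(inhibition_steady_state(s, 0.0), s)

    def test_two_neuron_closed_form(self, rng):
        s = rng.standard_normal(2)
        gamma = 0.3
        v = inhibition_steady_state(s, gamma)
        assert v[0] == pytest.approx((s[0] - gamma * s[1]) / (1 - gamma**2))
        assert v[1] == pytest.approx((s[1] - gamma * s[0]) / (1 - gamma**2))

    def test_matches_direct_solve(self, rng):
        s = rng.standard_normal(7)
        gamma = 0.3
        v = inhibition_steady_state(s, gamma)
        direct = np.linalg.solve(inhibition_matrix(gamma, 7), s)
        assert np.allclose(v, direct, atol=1e-10)

    def test_singular_gamma_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            inhibition_steady_state(np.ones(3), 1.0)
        with pytest.raises(ValueError, match="singular"):
            inhibition_steady_state(np.ones(3), -0.5)

    def test_relaxation_eigenvalues(self):
        """The inhibition relaxation Jacobian -G has eigenvalue gamma - 1
        with multiplicity N-1 and -(1 + (N-1) gamma) along the ones vector,
        both negative for 0 < gamma < 1."""
        N, gamma = 5, 0.3
        M = -inhibition_matrix(gamma, N)
        ones_eig = (M @ np.ones(N)) / np.ones(N)
        assert np.allclose(ones_eig, -(1 + (N - 1) * gamma))
        ev = np.sort(np.linalg.eigvalsh(M))
        assert ev[0] == pytest.approx(-(1 + (N - 1) * gamma))
        assert np.allclose(ev[1:], gamma - 1.0)
        assert np.all(ev < 0)


class TestParamValidation:
    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            TwoStimulusParams(a=1.0, b=1.0, c=1.0, tau=1.0)

    def test_network_params_invariants(self):
        p = NetworkStabilityParams(gamma=0.4, alpha=1.0)
        assert p.a2 > p.a1 > 0
        assert p.g == pytest.approx(1 / (1 - 0.16))
        with pytest.raises(ValueError):
            NetworkStabilityParams(gamma=1.0, alpha=1.0)


class TestInhibitionPropertyBased:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        gamma=st.floats(0.01, 0.95),
        N=st.integers(2, 9),
        seed=st.integers(0, 2**16),
    )
    def test_closed_form_inverts_coupling_matrix(self, gamma, N, seed):
        """The closed-form steady state solves s = G v for any admissible
        inhibition strength and network size."""
        s = np.random.default_rng(seed).standard_normal(N)
        v = inhibition_steady_state(s, gamma, N)
        assert np.allclose(inhibition_matrix(gamma, N) @ v, s, atol=1e-9)
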