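"""Fixed points, stability classification, scans, synchrony and spectra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import bisect

from izhmass.dynamics import (
    dominant_period,
    find_fixed_points,
    jacobian,
    jacobian_eigenvalues,
    kuramoto_order,
    periodogram_psd,
    scan_parameter,
)
from izhmass.meanfield import MeanFieldModel, MeanFieldState, simulate_mean_field
from izhmass.params import SynapseChannel


@pytest.fixture(scope="module")
def uncoupled_model(case1):
    """Case-1 neuron constants with all synapses silent and b = 0:
    the equilibrium reduces to a scalar equation solvable by bisection."""
    import dataclasses
    p = dataclasses.replace(case1.dimless.with_eta(0.5), b=0.0)
    return MeanFieldModel(p, fit=case1.fit)


def _scalar_equilibrium(p):
    """Brute-force oracle: eliminate r and u, bisect the v equation."""
    def h(v):
        r = p.Delta / (np.pi * (p.alpha - 2 * v))
        u = p.u_jump * r / p.a
        return v * (v - p.alpha) - u + p.eta_bar + p.I - np.pi ** 2 * r ** 2
    v_star = bisect(h, -2.0, p.alpha / 2 - 1e-6, xtol=1e-14)
    r_star = p.Delta / (np.pi * (p.alpha - 2 * v_star))
    return r_star, v_star


class TestFindFixedPoints:
    def test_matches_scalar_bisection_oracle(self, uncoupled_model):
        p = uncoupled_model.params
        r_star, v_star = _scalar_equilibrium(p)
        fps = find_fixed_points(uncoupled_model)
        assert len(fps) >= 1
        fp = min(fps, key=lambda f: abs(f.state.v - v_star))
        assert fp.state.r == pytest.approx(r_star, rel=1e-8)
        assert fp.state.v == pytest.approx(v_star, abs=1e-8)
        assert fp.state.u == pytest.approx(p.u_jump * r_star / p.a, rel=1e-8)

    def test_residuals_below_tolerance(self, case1):
        p = case1.dimless.with_eta(1.5).with_couplings(A={"J_rec": 6.0})
        model = MeanFieldModel(p, fit=case1.fit)
        for fp in find_fixed_points(model):
            assert fp.residual < 1e-9

    def test_conductances_satisfy_equilibrium_relation(self, case1):
        p = case1.dimless.with_eta(0.01).with_couplings(
            A={"J_rec": 6.0, "J_input": 6.0}, N={"J_input": 3.0})
        model = MeanFieldModel(p, fit=case1.fit)
        for fp in find_fixed_points(model, r_input=0.06):
            s = fp.state
            assert s.g_A == pytest.approx(6 * s.r + 6 * 0.06, rel=1e-9)
            assert s.g_N == pytest.approx(3 * 0.06, rel=1e-9)

    def test_no_convergence_returns_empty_list(self, case1):
        import dataclasses
        # an (unphysical) huge-Delta system whose residual tolerance
        # cannot be met from wild seeds within the iteration budget
        p = dataclasses.replace(case1.dimless, Delta=1e12)
        model = MeanFieldModel(p, fit=case1.fit)
        result = find_fixed_points(model, n_random_seeds=0,
                                   seeds=[(1e-12, -1e6)])
        assert isinstance(result, list)


class TestJacobian:
    def test_matches_analytic_reduced_system(self, uncoupled_model):
        """Finite differences agree with the hand-derived Jacobian of the
        synapse-free, b = 0 system in its (r, v, u) block."""
        p = uncoupled_model.params
        r, v = _scalar_equilibrium(p)
        u = p.u_jump * r / p.a
        state = MeanFieldState(r=r, v=v, u=u)
        J = jacobian(uncoupled_model, state)
        analytic = np.array([
            [-p.alpha + 2 * v, 2 * r, 0.0],
            [-2 * np.pi ** 2 * r, 2 * v - p.alpha, -1.0],
            [p.u_jump, 0.0, -p.a],
        ])
        assert np.allclose(J[:3, :3], analytic, atol=1e-4)

    def test_stable_point_has_negative_spectrum(self, case1):
        p = case1.dimless.with_eta(1.5).with_couplings(A={"J_rec": 6.0})
        model = MeanFieldModel(p, fit=case1.fit)
        fp = next(f for f in find_fixed_points(model) if f.is_stable)
        assert np.all(fp.eigenvalues.real < 0)

    def test_classification_agrees_with_perturbed_simulation(self, case1):
        """1e-3 perturbations decay at a stable point and grow at an
        unstable one."""
        base = case1.dimless.with_couplings(A={"J_rec": 6.0})
        for eta, expect_stable in ((1.5, True), (0.2, False)):
            model = MeanFieldModel(base.with_eta(eta), fit=case1.fit)
            fps = find_fixed_points(model)
            fp = fps[0]
            assert fp.is_stable == expect_stable
            y0 = fp.state.to_array()
            delta0 = 1e-3
            y0[1] += delta0
            horizon = 800.0 if expect_stable else 400.0
            traj = simulate_mean_field(
                model, MeanFieldState.from_array(np.maximum(y0, 0) * 0 + y0),
                T=horizon, dt=1.0)
            delta_end = np.linalg.norm(traj.y[:, -1] - fp.state.to_array())
            if expect_stable:
                assert delta_end < delta0 / 10
            else:
                assert delta_end > delta0 * 10


class TestScan:
    def test_no_sign_change_means_no_transitions(self, case1):
        p = case1.dimless.with_couplings(A={"J_rec": 6.0})
        model = MeanFieldModel(p, fit=case1.fit)
        scan = scan_parameter(model, "eta", np.linspace(1.0, 2.0, 6))
        assert scan.transitions == []
        assert all(fp is not None and fp.is_stable for fp in scan.branch)

    def test_transitions_only_at_bracketed_sign_changes(self, case1):
        p = case1.dimless.with_couplings(A={"J_rec": 6.0})
        model = MeanFieldModel(p, fit=case1.fit)
        grid = np.linspace(-0.02, 1.2, 26)
        scan = scan_parameter(model, "eta", grid)
        lead = np.array([fp.leading.real for fp in scan.branch])
        changes = np.nonzero(np.sign(lead[:-1]) != np.sign(lead[1:]))[0]
        assert len(scan.transitions) == len(changes)
        for tr, idx in zip(scan.transitions, changes):
            assert grid[idx] <= tr.lower <= tr.upper <= grid[idx + 1]
            assert tr.upper - tr.lower <= 1e-4

    def test_hopf_label_requires_complex_pair(self, case1):
        p = case1.dimless.with_couplings(A={"J_rec": 6.0})
        model = MeanFieldModel(p, fit=case1.fit)
        scan = scan_parameter(model, "eta", np.linspace(-0.02, 0.2, 12))
        assert len(scan.transitions) == 1
        assert scan.transitions[0].kind == "hopf"

    def test_monotone_grid_required(self, case1):
        model = MeanFieldModel(case1.dimless, fit=case1.fit)
        with pytest.raises(ValueError):
            scan_parameter(model, "eta", np.array([0.2, 0.1]))
        with pytest.raises(ValueError):
            scan_parameter(model, "voltage", np.array([0.1, 0.2]))


class TestKuramoto:
    def test_point_mass_at_rest_is_fully_synchronized(self):
        R, _ = kuramoto_order(0.0, 0.0)
        assert R == pytest.approx(1.0)

    def test_center_of_disk_is_fully_asynchronous(self):
        R, _ = kuramoto_order(1.0 / np.pi, 0.0)
        assert R == pytest.approx(0.0, abs=1e-15)

    @given(st.floats(1e-6, 5.0), st.floats(-5.0, 5.0))
    @settings(max_examples=200, deadline=None)
    def test_magnitude_inside_unit_disk_for_positive_rate(self, r, v):
        R, _ = kuramoto_order(r, v)
        assert 0.0 <= R < 1.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            kuramoto_order(-0.1, 0.0)

    def test_matches_network_phase_average(self, case1):
        """Mean-field R agrees with the direct phase average
        |N^-1 sum exp(2 i arctan v_j)| of a matched network run."""
        p = case1.dimless.with_eta(1.5).with_couplings(A={"J_rec": 6.0})
        from izhmass.network import NetworkConfig, simulate_network
        model = MeanFieldModel(p, fit=case1.fit)
        fp = find_fixed_points(model)[0]
        cfg = NetworkConfig(params=p, N=2000, dt=1e-3, T=150.0, seed=11,
                            u_init=fp.state.u, v_init=(fp.state.v, 0.3),
                            record_raster=False)
        _, trace = simulate_network(cfg)
        R_net = np.abs(trace.kuramoto[trace.t > 75]).mean()
        R_mf, _ = kuramoto_order(fp.state.r, fp.state.v)
        assert R_net == pytest.approx(R_mf, abs=0.1)


class TestPeriodogram:
    def test_pure_tone_yields_single_dominant_bin(self):
        dt, f0 = 0.1, 0.25
        t = np.arange(0, 204.8, dt)
        psd = periodogram_psd(np.sin(2 * np.pi * f0 * t), dt)
        fpeak, _ = psd.dominant()
        assert fpeak == pytest.approx(f0, abs=psd.freq[1] - psd.freq[0])

    def test_parseval_identity(self, rng):
        x = rng.normal(size=4096)
        psd = periodogram_psd(x, 0.05)
        df = psd.freq[1] - psd.freq[0]
        assert psd.power.sum() * df == pytest.approx(np.var(x), rel=1e-9)

    def test_hz_conversion_uses_time_scale(self):
        x = np.sin(np.linspace(0, 100, 512))
        psd = periodogram_psd(x, 0.1, time_scale=3.3064)
        assert np.allclose(psd.freq_hz, psd.freq * 3306.4)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            periodogram_psd(np.zeros(100), 0.1)

    def test_dominant_period_of_known_tone(self):
        dt = 0.1
        t = np.arange(0, 400, dt)
        x = np.sin(2 * np.pi * t / 25.0)
        assert dominant_period(x, dt) == pytest.approx(25.0, rel=0.02)
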