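"""Unit and property tests of the EPG operators and forward simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from ssfp_motion import (
    InvalidParameterError,
    PhaseGraph,
    SequenceParams,
    SignalTimeseries,
    apply_tr,
    diffusion_operator,
    motion_operator,
    reference_sequence,
    reference_tissue,
    rf_operator,
    simulate_timeseries,
    steady_state_tr,
)
from ssfp_motion.epg import _run_epg
from ssfp_motion.motion import impulse_trace


class TestRfOperator:
    def test_zero_flip_is_identity(self):
        assert np.allclose(rf_operator(0.0, 0.3), np.eye(3))

    def test_inversion_exchanges_transverse_and_negates_z(self):
        T = rf_operator(np.pi, 0.0)
        assert np.allclose(T, [[0, 1, 0], [1, 0, 0], [0, 0, -1]], atol=1e-15)

    def test_90_degree_excitation_of_equilibrium(self):
        # brute-force rotation of a unit z-vector about an in-plane axis
        T = rf_operator(np.pi / 2, 0.0)
        state = T @ np.array([0.0, 0.0, 1.0])
        assert abs(abs(state[0]) - 1.0) < 1e-12

    def test_non_finite_angle_rejected(self):
        with pytest.raises(InvalidParameterError):
            rf_operator(np.nan, 0.0)

    @given(
        a=st.floats(0.01, np.pi - 0.01),
        p=st.floats(-np.pi, np.pi),
    )
    @settings(max_examples=50, deadline=None)
    def test_magnetisation_norm_conserved(self, a, p):
        # an RF pulse is a rotation: |Mxy|^2 + Mz^2 is invariant for a
        # physical (F, conj(F), Z) triple
        T = rf_operator(a, p)
        mxy, mz = 0.3 + 0.4j, 0.5
        out = T @ np.array([mxy, np.conj(mxy), mz])
        assert np.isclose(abs(out[0]) ** 2 + out[2].real ** 2, abs(mxy) ** 2 + mz**2)


class TestDiffusionOperator:
    def test_zero_d_no_attenuation(self, seq200):
        assert diffusion_operator(3, 4, 0.0, seq200) == (1.0, 1.0, 1.0)

    def test_constant_order_collapses_to_single_exponential(self, seq200):
        k, D = 2, 1e-3
        f, _, _ = diffusion_operator(k, k, D, seq200)
        assert np.isclose(f, np.exp(-(k**2) * seq200.q**2 * seq200.TR * D))

    def test_first_order_transition_matches_b_value_integral(self, seq200):
        # numerically integrate the instantaneous dephasing trajectory
        # b = int k(t)^2 dt with k ramping 0 -> q during the gradient
        D = 1e-3
        q, delta, TR = seq200.q, seq200.delta, seq200.TR
        b_ramp, _ = quad(lambda t: (q * t / delta) ** 2, 0, delta)
        b_flat = q**2 * (TR - delta)
        f, _, _ = diffusion_operator(0, 1, D, seq200)
        assert np.isclose(f, np.exp(-(b_ramp + b_flat) * D), rtol=1e-10)
        assert np.isclose(f, np.exp(-(q**2) * D * (delta / 3 + TR - delta)))

    def test_negative_d_rejected(self, seq200):
        with pytest.raises(InvalidParameterError):
            diffusion_operator(0, 1, -1e-3, seq200)

    def test_factors_in_unit_interval(self, seq200):
        for k in range(0, 5):
            fac = diffusion_operator(k, k + 1, 2e-3, seq200)
            assert all(0 < f <= 1 for f in fac)


class TestMotionOperator:
    def test_stationary_tissue_unity(self, seq200):
        assert motion_operator(2, 3, 0.0, seq200) == (1.0, 1.0, 1.0)

    def test_zero_order_carries_no_phase(self, seq200):
        assert motion_operator(0, 0, 1.3, seq200) == (1.0, 1.0, 1.0)

    def test_velocity_sign_flip_conjugates(self, seq200):
        fp, fm, z = motion_operator(1, 2, 0.7, seq200)
        fp2, fm2, z2 = motion_operator(1, 2, -0.7, seq200)
        assert np.isclose(fp2, np.conj(fp))
        assert np.isclose(fm2, np.conj(fm))
        assert np.isclose(z2, np.conj(z))

    @given(
        k1=st.integers(-20, 20),
        v=st.floats(-5, 5),
        G=st.floats(1.0, 80.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_unit_magnitude(self, k1, v, G):
        seq = SequenceParams(G=G, delta=6.5e-3, TR=40e-3, alpha=0.5)
        for f in motion_operator(k1, k1 + 1, v, seq):
            assert abs(abs(f) - 1.0) < 1e-12


class TestApplyTr:
    def test_no_attenuation_channels_conserve_population(self):
        # alpha=90deg, D=0, V=0, T1/T2 huge: all operators are unit magnitude
        seq = SequenceParams(G=40.0, delta=6.5e-3, TR=40e-3, alpha=np.pi / 2)
        tis = reference_tissue(D=0.0).with_(T1=1e9, T2=1e8)
        state = PhaseGraph.equilibrium(k_max=30, unit_q=seq.q)
        pops = []
        for _ in range(20):
            state = apply_tr(state, seq, tis, 0.0)
            pop = (
                np.sum(np.abs(state.F_plus[1:]) ** 2)
                + np.sum(np.abs(state.F_minus[1:]) ** 2)
                + np.abs(state.F_plus[0]) ** 2  # k=0 counted once
                + np.abs(state.Z[0]) ** 2
                + 2 * np.sum(np.abs(state.Z[1:]) ** 2)
            )
            pops.append(pop)
        # population in this bookkeeping never grows
        assert all(p2 <= p1 + 1e-9 for p1, p2 in zip(pops, pops[1:]))

    def test_population_never_exceeds_equilibrium(self, seq200, tissue):
        state = PhaseGraph.equilibrium(k_max=60, unit_q=seq200.q)
        for _ in range(50):
            state = apply_tr(state, seq200, tissue, 0.5)
            assert np.max(np.abs(state.as_stack())) <= 1.0 + 1e-6

    def test_invalid_velocity_rejected(self, seq200, tissue):
        state = PhaseGraph.equilibrium(k_max=10, unit_q=seq200.q)
        with pytest.raises(InvalidParameterError):
            apply_tr(state, seq200, tissue, np.inf)

    def test_matches_run_epg(self, seq200, tissue):
        """Stepping apply_tr reproduces the vectorised recursion."""
        rng = np.random.default_rng(3)
        V = rng.uniform(-1, 1, 40)
        seq = seq200.with_(n_tr=40)
        sig_fast, _ = _run_epg(seq, tissue, V)
        state = PhaseGraph.equilibrium(k_max=42, unit_q=seq.q)
        sig_slow = []
        for n in range(40):
            state = apply_tr(state, seq, tissue, V[n])
            sig_slow.append(state.F_plus[0])
        assert np.allclose(sig_slow, sig_fast, atol=1e-14)


class TestSimulateTimeseries:
    def test_flat_steady_state_tail(self, seq200, tissue):
        series = simulate_timeseries(seq200, tissue)
        mags = np.abs(series.values[-50:])
        assert np.std(mags) / np.mean(mags) < 1e-6

    def test_impulse_dips_then_recovers_within_a_second(self, seq200, tissue):
        trace = impulse_trace(1.5, 100, seq200.n_tr)
        series = simulate_timeseries(seq200, tissue, trace)
        mags = np.abs(series.values)
        ss = mags[99]
        assert mags[100:110].min() < 0.95 * ss  # visible dip
        recover_tr = 100 + int(np.ceil(1.2 / seq200.TR))  # ~1 s later
        assert abs(mags[recover_tr] - ss) / ss < 0.01

    def test_global_phase_and_amplitude(self, seq200, tissue):
        base = simulate_timeseries(seq200, tissue)
        scaled = simulate_timeseries(seq200, tissue, global_phase=0.5, amplitude=2.0)
        assert np.allclose(scaled.values, 2.0 * np.exp(0.5j) * base.values)

    def test_length_mismatch_rejected(self, seq200, tissue):
        with pytest.raises(InvalidParameterError):
            simulate_timeseries(seq200, tissue, np.zeros(seq200.n_tr - 1))

    def test_rf_phase_offset_is_global_phase_only(self, seq200, tissue):
        """With V = 0 the steady-state magnitude is independent of phi_rf."""
        a = simulate_timeseries(seq200, tissue)
        b = simulate_timeseries(seq200.with_(phi_rf=1.1), tissue)
        assert np.allclose(np.abs(a.values), np.abs(b.values), rtol=1e-10)

    def test_monotone_attenuation_in_d(self, seq200):
        mags = [
            abs(simulate_timeseries(seq200, reference_tissue(D=d)).values[-1])
            for d in (0.5e-3, 1e-3, 2e-3, 3e-3)
        ]
        assert all(m2 < m1 for m1, m2 in zip(mags, mags[1:]))

    def test_higher_d_reduces_motion_sensitivity(self, seq200):
        """The motion-induced relative magnitude and phase changes shrink as
        D grows (stronger attenuation of high-order pathways)."""
        trace = np.full(seq200.n_tr, 0.2)
        rel_mag, rel_phase = [], []
        for d in (0.5e-3, 1.5e-3, 3e-3):
            tis = reference_tissue(D=d)
            still = simulate_timeseries(seq200, tis).values[-1]
            moving = simulate_timeseries(seq200, tis, trace).values[-1]
            rel_mag.append(abs(abs(moving) - abs(still)) / abs(still))
            rel_phase.append(abs(np.angle(moving / still)))
        assert rel_mag[0] > rel_mag[1] > rel_mag[2]
        assert rel_phase[0] > rel_phase[1] > rel_phase[2]

    def test_truncation_safety(self, seq200, tissue, pulsatile_trace200):
        a = simulate_timeseries(seq200, tissue, pulsatile_trace200, k_max=seq200.n_tr + 2)
        b = simulate_timeseries(seq200, tissue, pulsatile_trace200, k_max=2 * (seq200.n_tr + 2))
        assert np.max(np.abs(a.values - b.values)) / np.max(np.abs(a.values)) < 1e-9


class TestSteadyStateTr:
    def test_constant_series(self):
        s = SignalTimeseries(values=np.ones(20), times=np.arange(20.0))
        assert steady_state_tr(s, 0.01) == 0

    def test_geometric_series_closed_form(self):
        n = np.arange(30)
        s = SignalTimeseries(values=1.0 - 0.5**n + 0j, times=n.astype(float))
        # |S[m+1]-S[m]| = 0.5^(m+1) < 0.01 first holds at m = 6
        assert steady_state_tr(s, 0.01) == 6

    def test_never_converged_flagged(self):
        v = np.ones(10, dtype=complex)
        v[-1] = 5.0  # last step jumps
        s = SignalTimeseries(values=v, times=np.arange(10.0))
        assert steady_state_tr(s, 0.01) == -1

    def test_reference_sequence_settles_by_tr_50(self, seq200, tissue):
        series = simulate_timeseries(seq200, tissue)
        assert 0 < steady_state_tr(series, 0.01) <= 50
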