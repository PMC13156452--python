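"""Tests of image synthesis, segmented readout, DW-SE reference signal and
tensor reconstruction."""

import numpy as np
import pytest
from scipy.integrate import quad

from ssfp_motion import (
    InvalidParameterError,
    PhantomMap,
    brain_phantom,
    dwse_signal,
    icosahedral_directions,
    pulsatility_trace,
    reference_sequence,
    reference_tissue,
    segmented_readout,
    simulate_timeseries,
    spatial_velocity_map,
    synthesize_image_series,
    tensor_from_adc,
)
from ssfp_motion.motion import PulsatilityModel


@pytest.fixture(scope="module")
def tiny_phantom():
    return brain_phantom((12, 12), voxel_size=6.0)


@pytest.fixture(scope="module")
def seq30():
    return reference_sequence(n_tr=30)


class TestSynthesizeImageSeries:
    def test_matches_single_voxel_simulation(self, seq30):
        ph = PhantomMap(D_map=np.array([[1e-3]]), T1=0.832, T2=0.110, B1=1.0,
                        mask=np.array([[True]]), voxel_size=6.0)
        v = np.zeros((1, 1, seq30.n_tr))
        v[0, 0, 10] = 1.5
        stack = synthesize_image_series(ph, seq30, v)
        ref = simulate_timeseries(seq30, reference_tissue(), v[0, 0])
        assert np.allclose(stack[:, 0, 0], ref.values, atol=1e-12)

    def test_zero_motion_temporally_constant_after_convergence(self, tiny_phantom,
                                                               seq30):
        seq = seq30.with_(n_tr=150)
        stack = synthesize_image_series(tiny_phantom, seq, None)
        tail = stack[-10:]
        assert np.allclose(tail, tail[0], rtol=1e-4, atol=1e-7)
        assert np.all(stack[:, ~tiny_phantom.mask] == 0)

    def test_voxel_independence(self, seq30):
        """Masking away voxels does not change the remaining ones."""
        ph = brain_phantom((8, 8))
        full = synthesize_image_series(ph, seq30, None)
        mask2 = ph.mask.copy()
        mask2[4:, :] = False
        ph2 = PhantomMap(D_map=ph.D_map, T1=ph.T1, T2=ph.T2, B1=ph.B1,
                         mask=mask2, voxel_size=ph.voxel_size)
        part = synthesize_image_series(ph2, seq30, None)
        assert np.allclose(part[:, mask2], full[:, mask2], atol=1e-14)

    def test_pulsatile_loss_follows_velocity_map(self, seq30):
        """Voxels with larger relative pulsatile velocity lose more signal."""
        seq = seq30.with_(n_tr=150)
        ny = nx = 9
        ph = PhantomMap(D_map=np.full((ny, nx), 1e-3), T1=0.832, T2=0.110,
                        B1=1.0, mask=np.ones((ny, nx), bool), voxel_size=40.0)
        rel = spatial_velocity_map((ny, nx), voxel_size=40.0, c=175.0)
        base = pulsatility_trace(PulsatilityModel(v_card=0.4), 1.0, seq.TR, seq.n_tr)
        stack = synthesize_image_series(ph, seq, rel[..., None] * base)
        frame = np.abs(stack[145])
        # systolic frame: centre (rel ~ 1) darker than the corner (rel ~ 0)
        still = np.abs(synthesize_image_series(ph, seq, None)[145])
        loss = (still - frame) / still
        assert loss[4, 4] > loss[0, 0]

    def test_higher_d_reduces_motion_phase_contrast(self, seq30):
        """Two-region phantom: the high-D region shows a smaller
        motion-induced phase deviation."""
        seq = seq30.with_(n_tr=120)
        ph = PhantomMap(D_map=np.array([[0.7e-3, 3.0e-3]]), T1=0.832, T2=0.110,
                        B1=1.0, mask=np.ones((1, 2), bool), voxel_size=6.0)
        v = np.broadcast_to(np.full(seq.n_tr, 0.2), (1, 2, seq.n_tr))
        moving = synthesize_image_series(ph, seq, np.array(v))
        still = synthesize_image_series(ph, seq, None)
        dphi = np.angle(moving[-1] / still[-1])
        assert abs(dphi[0, 0]) > abs(dphi[0, 1])


class TestSegmentedReadout:
    def test_static_stack_lossless(self, rng):
        img = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        stack = np.broadcast_to(img, (8, 16, 16))
        rec = segmented_readout(stack, lines_per_tr=2)
        assert np.allclose(rec, img, atol=1e-12)

    def test_single_tr_full_readout_is_instantaneous_image(self, rng):
        stack = rng.standard_normal((3, 8, 8)) + 1j * rng.standard_normal((3, 8, 8))
        rec = segmented_readout(stack, lines_per_tr=8, start_tr=1)
        assert np.allclose(rec, stack[1], atol=1e-12)

    def test_linearity(self, rng):
        a = rng.standard_normal((4, 8, 8)) + 1j * rng.standard_normal((4, 8, 8))
        b = rng.standard_normal((4, 8, 8)) + 1j * rng.standard_normal((4, 8, 8))
        ra = segmented_readout(a, 2)
        rb = segmented_readout(b, 2)
        rab = segmented_readout(a + 2 * b, 2)
        assert np.allclose(rab, ra + 2 * rb, atol=1e-12)

    def test_insufficient_trs_rejected(self, rng):
        stack = np.zeros((2, 8, 8), dtype=complex)
        with pytest.raises(InvalidParameterError):
            segmented_readout(stack, lines_per_tr=2)

    def test_noise_reproducible_with_seed(self, rng):
        stack = np.ones((4, 8, 8), dtype=complex)
        a = segmented_readout(stack, 2, noise_snr=20, rng=5)
        b = segmented_readout(stack, 2, noise_snr=20, rng=5)
        assert np.array_equal(a, b)


class TestDwseSignal:
    def test_stationary_real_positive(self, seq30, tissue):
        s = dwse_signal(tissue, seq30, Delta=40e-3)
        assert s.imag == 0
        assert s.real > 0

    def test_b_value_against_quadrature(self, seq30, tissue):
        """b from the printed closed form equals the integral of k(t)^2 over
        the dephase-rephase trajectory of the gradient pair."""
        q, delta = seq30.q, seq30.delta
        Delta = 40e-3

        def k(t):  # rad/mm
            if t < delta:
                return q * t / delta  # dephasing ramp
            if t < Delta:
                return q  # fully dephased
            return q * (1 - (t - Delta) / delta)  # rephasing ramp

        b_num = quad(lambda t: k(t) ** 2, 0, Delta + delta, limit=500)[0]
        b_closed = q**2 * (Delta - delta / 3)
        assert np.isclose(b_num, b_closed, rtol=1e-8)
        s = dwse_signal(tissue, seq30, Delta)
        relax = np.exp(-(Delta + delta) / tissue.T2)
        assert np.isclose(abs(s), relax * np.exp(-b_closed * tissue.D))

    def test_motion_changes_phase_not_magnitude(self, seq30, tissue):
        still = dwse_signal(tissue, seq30, Delta=40e-3, V_trace=0.0)
        moving = dwse_signal(tissue, seq30, Delta=40e-3, V_trace=1.5)
        assert np.isclose(abs(moving), abs(still))
        assert abs(np.angle(moving)) > 1e-3


class TestTensorFromAdc:
    def test_isotropic(self):
        dirs = icosahedral_directions()
        res = tensor_from_adc(np.full(12, 0.8e-3), dirs)
        assert np.allclose(res.tensor, 0.8e-3 * np.eye(3), atol=1e-15)
        assert np.isclose(res.MD, 0.8e-3)
        assert abs(res.FA) < 1e-12

    def test_anisotropic_round_trip_exact(self):
        dirs = icosahedral_directions()
        rng = np.random.default_rng(4)
        A = rng.standard_normal((3, 3))
        T = A @ A.T * 1e-4  # SPD tensor
        adc = np.einsum("ij,jk,ik->i", dirs, T, dirs)
        res = tensor_from_adc(adc, dirs)
        assert np.allclose(res.tensor, T, atol=1e-12)
        evals = np.sort(np.linalg.eigvalsh(T))[::-1]
        assert np.allclose([res.L1, res.L2, res.L3], evals)
        assert res.L1 >= res.L2 >= res.L3
        assert 0 <= res.FA <= 1

    def test_inverse_variance_downweights_corrupted_direction(self):
        dirs = icosahedral_directions()
        T = np.diag([1.5e-3, 0.5e-3, 0.5e-3])
        adc = np.einsum("ij,jk,ik->i", dirs, T, dirs)
        bad = adc.copy()
        bad[3] = 5e-3  # corrupted direction
        w = np.ones(12)
        w[3] = 1e-6
        res_w = tensor_from_adc(bad, dirs, weights=w)
        res_11 = tensor_from_adc(np.delete(bad, 3), np.delete(dirs, 3, axis=0))
        assert np.allclose(res_w.tensor, res_11.tensor, atol=1e-8)

    def test_map_input_shapes(self):
        dirs = icosahedral_directions()
        adc = np.full((12, 4, 5), 1e-3)
        res = tensor_from_adc(adc, dirs)
        assert res.MD.shape == (4, 5)
        assert res.V1.shape == (4, 5, 3)
        assert np.allclose(res.FA, 0.0, atol=1e-10)

    def test_rank_deficient_rejected(self):
        dirs = np.tile([[1.0, 0, 0]], (6, 1))
        with pytest.raises(InvalidParameterError):
            tensor_from_adc(np.ones(6), dirs)

    def test_too_few_directions_rejected(self):
        dirs = icosahedral_directions()[:5]
        with pytest.raises(InvalidParameterError):
            tensor_from_adc(np.ones(5), dirs)
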