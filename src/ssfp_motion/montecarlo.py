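"""Independent isochromat Monte-Carlo simulator of the DW-SSFP signal.

Serves as the validation oracle for the EPG forward model: each isochromat
carries a 3-vector magnetisation and a position trajectory combining a
Gaussian random walk (free diffusion) with the deterministic bulk motion of
the voxel, discretised at ``steps_per_tr`` timesteps per TR.  Per TR the RF
pulse is applied instantaneously, gradient phase is accrued by trapezoidal
integration of the along-gradient position over the gradient interval, and
the complex mean transverse magnetisation is sampled at the end of the TR.

Two exact reductions keep the default configuration (1e5 spins, 100 steps
per TR, 200 TRs) tractable on one CPU:

* Relaxation commutes with phase accrual between RF pulses, so the
  per-timestep relaxation recursion is applied in its closed per-TR form
  (mathematically identical for instantaneous RF).
* For isotropic diffusion the rotation of accumulated diffusive
  displacements leaves their distribution unchanged, so every scenario
  reduces to a shared deterministic bulk trajectory plus independent 1D
  Brownian walks along the gradient axis.  (The sub-micron diffusive offset
  contributes negligibly to rotation-induced velocity compared with the
  ~100 mm lever arm of the bulk position.)

Initial along-gradient offsets are stratified uniformly over one dephasing
period 2*pi/q, so that configuration orders k != 0 cancel exactly in the
ensemble average and the mean transverse magnetisation estimates F~_0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epg import SignalTimeseries, rf_operator
from .motion import (
    PulsatilityModel,
    RigidBodyMotion,
    pulsatility_waveform,
    rotation_matrix,
)
from .params import GAMMA, InvalidParameterError, SequenceParams, TissueParams, _require

__all__ = ["McConfig", "generate_trajectories", "simulate_mc_signal"]


@dataclass
class McConfig:
    """Configuration of one Monte-Carlo run."""

    seq: SequenceParams
    tissue: TissueParams
    motion: RigidBodyMotion | PulsatilityModel | None = None
    n_spins: int = 100_000
    steps_per_tr: int = 100
    seed: int = 0
    #: spins are laid out on an (offsets x walks) grid: initial positions are
    #: stratified over one dephasing period and each Brownian walk is shared
    #: across the whole offset comb, so configuration orders k != 0 cancel
    #: exactly in the ensemble mean for every walk realisation.  The comb
    #: size must exceed the highest order carrying non-negligible amplitude
    #: (diffusion attenuates order k by exp(-k^2 q^2 TR D) per TR; at the
    #: reference sequence with D = 1e-3 mm^2/s, order 8 is already below
    #: 1e-5 relative).  Increase for very low diffusivities.
    n_offsets: int = 8
    #: pair each Brownian walk with its mirror image (antithetic variates);
    #: each walk remains exactly Gaussian and the ensemble mean is unbiased,
    #: while odd-order sampling error cancels within pairs.
    antithetic: bool = True

    def __post_init__(self) -> None:
        _require(int(self.n_spins) >= 1, "n_spins must be >= 1")
        _require(int(self.steps_per_tr) >= 1, "steps_per_tr must be >= 1")
        _require(int(self.n_offsets) >= 1, "n_offsets must be >= 1")
        self.n_spins = int(self.n_spins)
        self.steps_per_tr = int(self.steps_per_tr)
        # grow the comb until the first aliased order (k = n_offsets) is
        # attenuated below 1e-4 by a single TR of diffusion; without
        # diffusion every order survives and the comb must cover all n_tr
        # reachable orders
        a = self.seq.q**2 * self.seq.TR * self.tissue.D
        needed = self.seq.n_tr + 1 if a <= 0 else int(np.ceil(np.sqrt(9.3 / a))) + 1
        self.n_offsets = min(
            max(int(self.n_offsets), min(needed, self.seq.n_tr + 1)), self.n_spins
        )
        # round the spin count to a full offsets x walks grid
        group = self.n_offsets * (2 if self.antithetic else 1)
        self.n_walks = max(self.n_spins // group, 1) * (2 if self.antithetic else 1)
        self.n_spins = self.n_offsets * self.n_walks

    @property
    def dt(self) -> float:
        return self.seq.TR / self.steps_per_tr

    @property
    def n_steps(self) -> int:
        return self.seq.n_tr * self.steps_per_tr


def _bulk_positions(cfg: McConfig) -> np.ndarray:
    """Deterministic 3D bulk position at every timestep boundary, shape
    (n_steps+1, 3), in absolute mm."""
    seq, dt = cfg.seq, cfg.dt
    n = cfg.n_steps
    x = np.zeros((n + 1, 3))
    if cfg.motion is None:
        return x
    if isinstance(cfg.motion, PulsatilityModel):
        # pulsatile displacement along g_hat: per-step box-averaged waveform
        t_mid = (np.arange(n) + 0.5) * dt
        disp = np.concatenate([[0.0], np.cumsum(pulsatility_waveform(cfg.motion, t_mid) * dt)])
        return x + disp[:, None] * seq.g_hat
    m: RigidBodyMotion = cfg.motion
    v = m.per_tr("v", seq.n_tr)
    omega = np.deg2rad(m.per_tr("omega", seq.n_tr))
    pos = m.X0.copy()
    x[0] = pos
    same_omega = np.allclose(omega, omega[0])
    R = rotation_matrix(omega[0] * dt) if same_omega else None
    for j in range(n):
        tr = j // cfg.steps_per_tr
        Rj = R if same_omega else rotation_matrix(omega[tr] * dt)
        pos = Rj @ pos + v[tr] * dt
        x[j + 1] = pos
    return x


def generate_trajectories(cfg: McConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-spin 3D position time-series, shape (n_spins, n_steps+1, 3), mm.

    Per-axis diffusive increments are Normal(0, sqrt(2*D*dt)) added to the
    deterministic bulk trajectory.  Intended for modest sizes (the array
    holds n_spins * (n_steps+1) * 3 doubles); the signal simulator streams
    the walk instead of materialising it.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sigma = np.sqrt(2.0 * cfg.tissue.D * cfg.dt)
    steps = rng.standard_normal((cfg.n_spins, cfg.n_steps, 3)) * sigma
    walk = np.concatenate(
        [np.zeros((cfg.n_spins, 1, 3)), np.cumsum(steps, axis=1)], axis=1
    )
    return walk + _bulk_positions(cfg)[None, :, :]


def _gradient_weights(steps: int, dt: float, delta: float) -> np.ndarray:
    """Trapezoid weights over timestep boundaries integrating f(t) dt on
    [0, delta] within one TR, with the (possibly fractional) end handled by
    linear interpolation."""
    w = np.zeros(steps + 1)
    j_full = min(int(np.floor(delta / dt + 1e-12)), steps)
    for j in range(j_full):
        w[j] += dt / 2.0
        w[j + 1] += dt / 2.0
    lam = delta - j_full * dt
    if lam > 1e-15 and j_full < steps:
        w[j_full] += lam * (1.0 - lam / (2.0 * dt))
        w[j_full + 1] += lam**2 / (2.0 * dt)
    return w


def simulate_mc_signal(cfg: McConfig) -> SignalTimeseries:
    """Monte-Carlo DW-SSFP signal, sampled at the end of each TR."""
    seq, tissue = cfg.seq, cfg.tissue
    steps, dt = cfg.steps_per_tr, cfg.dt
    n_u, n_w = cfg.n_offsets, cfg.n_walks
    rng = np.random.default_rng(cfg.seed)

    g_T_per_mm = seq.G * 1e-6
    q = seq.q
    bulk = _bulk_positions(cfg) @ seq.g_hat
    bulk -= bulk[0]
    w = _gradient_weights(steps, dt, seq.delta)

    # stratified static offsets over one dephasing period
    if q > 0:
        u = (np.arange(n_u) + 0.5) / n_u * (2.0 * np.pi / q)
    else:
        u = np.zeros(n_u)
    # static-offset phase per TR (the gradient advances the phase of Mxy in
    # proportion to the along-gradient position; with this sign a positive
    # velocity yields a negative motion phase on positive orders, matching
    # the EPG motion-operator convention)
    pu = np.exp(1j * GAMMA * g_T_per_mm * u * seq.delta)

    sigma = np.sqrt(2.0 * tissue.D * dt)
    E1 = np.exp(-seq.TR / tissue.T1)
    E2 = np.exp(-seq.TR / tissue.T2)
    T = rf_operator(tissue.B1 * seq.alpha, seq.phi_rf)

    Mxy = np.zeros((n_u, n_w), dtype=complex)
    Mz = np.ones((n_u, n_w))
    walk = np.zeros(n_w)
    signal = np.empty(seq.n_tr, dtype=complex)

    for n in range(seq.n_tr):
        # RF pulse (instantaneous), same mixing convention as the EPG operator
        Mxy_new = T[0, 0] * Mxy + T[0, 1] * np.conj(Mxy) + T[0, 2] * Mz
        Mz = (T[2, 0] * Mxy + T[2, 1] * np.conj(Mxy) + T[2, 2] * Mz).real
        Mxy = Mxy_new
        # Brownian boundary positions within this TR (one walk per column,
        # shared across the offset comb; antithetic pairing of walks)
        if sigma > 0:
            if cfg.antithetic:
                half = rng.standard_normal((steps, n_w // 2)) * sigma
                incr = np.concatenate([half, -half], axis=1)
            else:
                incr = rng.standard_normal((steps, n_w)) * sigma
            bounds = np.empty((steps + 1, n_w))
            bounds[0] = walk
            np.cumsum(incr, axis=0, out=bounds[1:])
            bounds[1:] += walk
            walk = bounds[-1].copy()
            walk_int = w @ bounds
        else:
            walk_int = walk * seq.delta  # stationary spins
        s0 = n * steps
        bulk_int = float(w @ bulk[s0 : s0 + steps + 1])
        pw = np.exp(1j * GAMMA * g_T_per_mm * (bulk_int + walk_int))
        Mxy *= (E2 * pu)[:, None] * pw[None, :]
        Mz = 1.0 + (Mz - 1.0) * E1
        signal[n] = Mxy.mean()

    times = seq.TR * np.arange(1, seq.n_tr + 1)
    return SignalTimeseries(values=signal, times=times, b_label="mc")
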