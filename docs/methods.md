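# Methods

## The signal model

Diffusion-weighted steady-state free precession (DW-SSFP) applies one RF
pulse (flip angle α, phase φ) and one diffusion gradient (amplitude G,
duration δ, orientation ĝ) in every repetition time TR.  Because transverse
magnetisation survives from TR to TR, the steady-state signal is a
superposition of magnetisation pathways whose diffusion weighting — and
motion sensitivity — depends on their dephasing history.

The package represents a voxel with extended phase graphs (EPG):
configuration states F̃_k (transverse) and Z̃_k (longitudinal) of integer
dephasing order k, where one unit of k corresponds to the gradient's
q-value, q = γGδ (rad/mm; γ = 2.6752218744e8 rad s⁻¹ T⁻¹; lengths in mm,
times in s).  Each TR applies, in this order:

1. **RF mixing** at effective flip B1·α with phase φ — the standard 3×3 EPG
   mixing matrix acting on (F̃_k, conj(F̃_₋k), Z̃_k) identically at every k.
2. **Relaxation** E2 = exp(−TR/T2) on F states, E1 = exp(−TR/T1) on Z.
3. **Diffusion attenuation** for a state whose order ramps k₁ → k₂ = k₁+1
   during the gradient:
   exp(−[(k₁+Δk/2)² + Δk²/12]·q²δD) · exp(−k₂²·q²(TR−δ)D) on F,
   exp(−k₁²·q²·TR·D) on Z.
4. **Motion phase** for the per-TR velocity component V_n along ĝ:
   exp(−i·(k₁+k₂)/2·qδV_n) · exp(−i·k₂·q(TR−δ)V_n) on F⁺ (conjugate on F⁻),
   exp(−i·k₁·q·TR·V_n) on Z.  These factors have unit magnitude: motion
   corrupts the phase of each pathway, and magnitude loss arises only from
   interference between pathways with different motion histories.
5. **Ladder shift** of transverse orders by +1 and longitudinal recovery
   M0(1−E1) into Z̃_0.

The reported signal is F̃_0 at the end of each TR, matching the sampling
point of the Monte-Carlo oracle.  An entire motion profile is summarised by
one scalar velocity per TR, V(t); rigid-body motion maps onto it via
V_n = v⃗_n·ĝ + (ĝ×ω⃗_n)·X⃗ with the position advanced once per TR,
X⃗_{n+1} = R_z R_y R_x(ω⃗_n TR)·X⃗_n + v⃗_n TR.  The rotational term is
evaluated at the TR-midpoint position (half a step from X⃗_n): a single
per-TR velocity best represents the continuously moving spins when sampled
mid-interval, which halves the discretisation gap against the Monte-Carlo
oracle relative to start-of-TR evaluation.

Truncation: the ladder holds k_max+1 orders, k_max = n_tr + 2 by default
(each TR raises the maximum populated order by at most one).  Diffusion
suppresses order k by exp(−k²q²TR·D) per TR, so far smaller ladders are
exact to machine noise in practice; the fitting routine uses k_max = 80 by
default and doubling it changes no signal by more than 1e-9 relative.

## The pulsatility model

Brain-tissue pulsatile velocity is modelled per cardiac cycle (heart rate
HR, default 50 bpm) as a systolic lobe A·sin⁴(4π·HR·t/60) spanning the
first quarter of the cycle, followed by a constant diastolic return
velocity over the remaining three quarters.  The diastolic value is fixed
by requiring zero net displacement per cycle; since sin⁴ averages 3/8 over
its lobe, the plateau is exactly −A/8.  The waveform is box-averaged over
each TR (100 samples per TR; halving the step changes no V_n by more than
1e-6 mm/s).  A spatial amplitude map ((c−r)³/c³ clipped to [0,1], c = 175
mm, r = distance from the map centre in mm) scales the waveform per voxel.

## The Monte-Carlo oracle

An independent isochromat simulator validates the EPG model: spins carry a
3-vector magnetisation and a position trajectory, discretised at 100
timesteps per TR.  Free diffusion contributes Gaussian per-step
displacements (sd √(2DΔt) per axis); bulk motion contributes the
deterministic trajectory of the voxel (per-timestep rotation/translation
recursion, or the integrated pulsatile waveform).  Gradient phase is the
trapezoidal integral of the along-gradient position over the gradient
interval (the fractional last timestep of the 6.5 ms gradient is handled by
linear interpolation); RF is applied instantaneously with the same mixing
convention as the EPG operator, so the deterministic limit (D = 0, V = 0)
agrees with EPG to ~1e-13.

Design choices that keep the estimator exact but cheap:

* Relaxation commutes with phase accrual between RF pulses, so the
  per-timestep relaxation recursion is applied in its algebraically
  identical per-TR closed form.
* For isotropic diffusion, rotating the accumulated diffusive offset leaves
  its distribution unchanged, and its contribution to rotation-induced
  velocity (µm lever arm vs. the ~100 mm bulk position) is negligible, so
  positions decompose into the shared bulk trajectory plus an independent
  1D Brownian walk along ĝ.
* Initial along-gradient offsets are stratified over one dephasing period
  2π/q, and each Brownian walk is shared across the whole offset comb:
  configuration orders k ≠ 0 then cancel *exactly* in the ensemble mean for
  every walk realisation, so the mean transverse magnetisation estimates
  F̃_0 with sampling noise set by the number of independent walks.  Walks
  are antithetic (each paired with its mirror image).  The comb size grows
  automatically until the first aliased order is attenuated below 1e-4 per
  TR (covering all orders when D = 0).

At the reference configuration (1e5 spins, 200 TRs) the EPG and
Monte-Carlo signals agree to ~1.5% (pulsatility) and ~1.3% (rigid body)
relative L2; this residual is stable across seeds and reflects the genuine
discretisation difference between one velocity per TR (EPG) and 100
timesteps per TR (Monte Carlo), which the comparison is designed to expose.

## Parameter estimation

`fit_voxel` embeds the forward model in a bounded trust-region-reflective
least-squares problem on the concatenated real and imaginary residuals
(complex Gaussian noise on both channels makes this the natural embedding,
and it sidesteps phase wrapping).  The simulated window is burn-in (100
TRs, no motion parameters) + dummy (25 TRs, velocities estimated but
excluded from the cost) + measured (75 TRs by default; 384 for
experimental-length series).  Dummy measurements matter because motion
effects persist over many TRs: they let the modelled signal carry a
realistic motion history into the first measured TR.  Two b-shells can be
fitted simultaneously, sharing one D (and S0) with per-shell phase offsets
and velocity traces.  No smoothness prior or regularisation is placed on
V(t).

Defaults (all overridable): D init 1.0e-3 mm²/s, bounds [0.05e-3, 4e-3];
V init 0, bounds ±2 mm/s; φ init = phase of the first measured sample
relative to the motion-free model prediction (the forward model carries an
intrinsic steady-state phase), bounds ±π; S0 fitted only on request (init =
data magnitude relative to the model prediction).  The Jacobian is analytic
in S0 (model/S0), φ (i·model) and every V_n — derivative states are
propagated forward through the linear EPG recursion, seeded by the motion
operator's derivative −i·(phase slope)·J at the corresponding TR — and
central-finite-difference in D.  Agreement with finite differences is
better than 1e-5 per column.

Two deliberate safeguards address structural features of this inverse
problem:

* **Phase wrapping in V.**  The motion phase of the dominant 0→1 pathway is
  periodic in V_n with spacing 2π/(q(δ/2+TR−δ)) ≈ 2.46 mm/s at the
  reference sequence, so near-degenerate wrapped solutions exist.  The ±2
  mm/s default bounds (physiological: peak pulsatile brain-tissue velocity
  is ~1.5 mm/s) exclude most aliases; a deterministic repair pass shifts
  suspicious estimates (bound-pinned, or more than ~0.35 spacing from zero)
  by one spacing and re-solves, keeping the repair only when the cost
  strictly decreases.
* **The D–V(t) confound.**  Per-TR velocity jitter dephases pathways by the
  same mechanism as diffusion, so on low-motion, noisy data the joint fit
  has a shallow degenerate valley along which D falls while V(t) absorbs
  noise.  With 2·75 residuals and ~102 parameters the global minimum
  overfits; the estimate therefore relies on the locality of the
  trust-region iteration started at V = 0.  Jacobian-norm scaling
  (`x_scale='jac'`) and a default budget of 100 function evaluations act as
  the implicit regulariser; a solution whose D lands on its lower physical
  bound is flagged as non-converged (that configuration is the signature of
  the degenerate mode and carries no information).  The residual
  few-percent downward bias of D on motion-free data at low SNR is a known
  property of this estimator class, growing as SNR falls.  A second start
  seeded from temporally unwrapped data-phase increments is tried whenever
  the first solution contains velocities beyond half a wrap spacing, and
  the lower-cost solution kept.

The conventional (motion-free) fit estimates only (D, φ) per shell; its
two-parameter cost can be multimodal on motion-corrupted data, so it is
restarted from three spread-out D values and the best cost kept.

## Synthetic data and study conditions

Scenario builders reproduce the reference simulation conditions: G = 40
mT/m, δ = 6.5 ms, TR = 40 ms, α = 30°, φ = 0, T1 = 832 ms, T2 = 110 ms,
D = 1e-3 mm²/s, 200 TRs; impulse motion of 1.5 mm/s for one TR (0.06 mm
displacement); rigid-body motion v = (3/20, −1/10, 1/20) mm/s, ω =
(1, −2/3, 1/3) °/s, X₀ = (−100,−100,−100) mm with ĝ decoded as the
normalised (3/10, 2/5, 1/(2√2)); pulsatility with peak 0.4 mm/s along ĝ at
50 bpm.  SNR is defined as (motion-free steady-state magnitude)/(per-channel
noise sd); noise is complex Gaussian, re-drawn per repeat from recorded
seeds.  Every scenario regenerates bit-exactly from (name, seed).

The generator emulates the magnetisation-distribution component of motion
corruption under an instantaneous readout.  It does not model coil noise
correlation, Rician magnitude statistics, off-resonance banding,
eddy currents, within-voxel anisotropy, or k-space segmentation during
fitting (segmented readouts are synthesised for illustration only), so
passing tests demonstrate correctness of the model and estimator under
those idealisations, not performance on raw scanner data.

## Known limitations

* The pulsatile bias of the *uncorrected* fit depends strongly on the exact
  waveform shape; with the analytic sin⁴ profile the uncorrected estimate
  at 0.4 mm/s peak velocity is ≈1.6e-3 mm²/s for a true 1e-3 (see the
  bias-grid output), while steeper experimental-derived profiles can double
  the apparent D.
* Velocity estimation during systole degrades above ~1.2 mm/s, where the
  per-TR phase increment exceeds the unambiguous range; D remains
  accurate (the repair pass recovers the branch in the noise-free limit).
* Voxels are simulated independently; there is no spatial coupling or
  through-plane motion.

## Problem sizes used by the test suite and acceptance script

Oracle comparisons run at the reference size (1e5 spins, 100 steps per TR,
200 TRs).  Recovery studies use 10 noise repeats; the velocity × SNR bias
grid uses 6 velocities × 4 SNR levels × 3 repeats (noise-free cells once),
a deliberate scale-down of the 10-repeat grid that leaves cell means within
the repeat scatter.
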