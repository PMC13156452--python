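# ssfp-motion

Modelling and retrospective correction of motion-corrupted
diffusion-weighted steady-state free precession (DW-SSFP) MRI signals.

DW-SSFP applies a single RF pulse and a single diffusion gradient per short
TR and accumulates diffusion contrast over many repetitions, which makes it
exceptionally SNR-efficient — and exceptionally motion sensitive: tissue
velocity along the diffusion gradient corrupts not only the phase but,
through interference of magnetisation pathways with different motion
histories, also the *magnitude* of the steady-state signal, and a single
disturbed TR contaminates the signal for seconds afterwards.  This package
is for researchers who want to simulate that corruption, validate the
model, and recover diffusion coefficients from motion-corrupted complex
time-series data.

It provides:

* **`ssfp_motion.epg`** — an extended-phase-graph (EPG) forward model: the
  voxel is a ladder of configuration states F̃_k, Z̃_k of dephasing order k
  (one unit = q = γGδ), evolved per TR by RF mixing, relaxation, the
  diffusion attenuation operator and a unit-magnitude **motion operator**
  exp(−i·(k₁+k₂)/2·qδV)·exp(−i·k₂·q(TR−δ)V) driven by one scalar velocity
  V_n (mm/s) along the gradient per TR.
* **`ssfp_motion.motion`** — rigid-body (translation + rotation with
  cumulative position update X⃗_{n+1} = R(ω⃗TR)X⃗_n + v⃗TR) and cardiac
  pulsatility (sin⁴ systolic lobe, zero net displacement per cycle)
  velocity-trace generators.
* **`ssfp_motion.montecarlo`** — an independent isochromat Bloch simulator
  (Gaussian random-walk diffusion + deterministic bulk motion, 100
  timesteps per TR) used as a validation oracle for the EPG model.
* **`ssfp_motion.fitting`** — bounded trust-region-reflective least squares
  recovering (D, S0, φ, V(t)) from complex per-TR samples, with an
  analytic/finite-difference hybrid Jacobian, a dummy-measurement window
  that lets the modelled signal carry motion history into the measured
  region, and a velocity x SNR bias-grid study.
* **`ssfp_motion.imaging`** — voxelwise image-series synthesis, segmented
  Cartesian readout emulation, a DW spin-echo reference signal, and
  diffusion-tensor reconstruction (MD, FA, V1) from per-direction ADCs.
* **`ssfp_motion.synthetic`** — reproducible scenario builders and noise
  injection at stated SNR.

See `docs/methods.md` for the model, assumptions, parameter defaults and
known limitations.

## Worked example

Simulate the reference sequence (G = 40 mT/m, δ = 6.5 ms, TR = 40 ms,
α = 30°, brain-like tissue T1 = 832 ms, T2 = 110 ms, D = 1e-3 mm²/s) with
cardiac pulsatility, validate against the Monte-Carlo oracle, add noise,
and recover D and the velocity trace:

```python
import numpy as np
from ssfp_motion import (
    FitConfig, McConfig, PulsatilityModel, add_noise, fit_voxel,
    pulsatility_trace, reference_sequence, reference_tissue,
    simulate_mc_signal, simulate_timeseries, steady_state_tr,
)

seq = reference_sequence(n_tr=200)
tissue = reference_tissue(D=1.0e-3)

# motion-free signal reaches steady state in well under 50 TRs (2 s)
clean = simulate_timeseries(seq, tissue)
print("steady state by TR", steady_state_tr(clean, rel_tol=0.01))

# pulsatile corruption: 0.4 mm/s peak velocity, 50 bpm, along the gradient
model = PulsatilityModel(v_card=0.4, heart_rate=50.0)
trace = pulsatility_trace(model, 1.0, seq.TR, seq.n_tr)
epg = simulate_timeseries(seq, tissue, trace)

# independent isochromat oracle, 1e5 spins, 100 timesteps per TR
mc = simulate_mc_signal(McConfig(seq=seq, tissue=tissue, motion=model, seed=42))
rel = np.linalg.norm(epg.values - mc.values) / np.linalg.norm(epg.values)
print(f"EPG vs Monte-Carlo relative L2: {100 * rel:.1f}%")

# recover D and V(t) from the noisy series (last 100 TRs: 25 dummy + 75 fit)
noisy = add_noise(mc, snr=20.0, seed=7, sigma_ref=abs(clean.values[-1]))
fit = fit_voxel(noisy, seq, tissue, FitConfig())
off = fit_voxel(noisy, seq, tissue, FitConfig(estimate_motion=False))
print(f"D with motion estimation:    {fit.D_hat * 1e3:.2f}e-3 mm^2/s")
print(f"D without motion estimation: {off.D_hat * 1e3:.2f}e-3 mm^2/s")
```

Output:

```
steady state by TR 26
EPG vs Monte-Carlo relative L2: 1.6%
D with motion estimation:    1.01e-3 mm^2/s
D without motion estimation: 1.60e-3 mm^2/s
```

The signal settles within 2 s; the EPG model agrees with the isochromat
oracle to within sampling tolerance; and ignoring motion during fitting
inflates the diffusion coefficient by ~60% at this velocity, while the
motion-aware fit recovers the true value to ~1%.  A command-line interface
mirrors the library (`ssfp-motion simulate | mc | fit | bias-grid |
synthesize-image | tensor | generate`).

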