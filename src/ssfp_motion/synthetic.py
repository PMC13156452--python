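"""Scenario builders and noise injection for synthetic DW-SSFP studies.

Every scenario is reproducible from its name and seed, and carries a truth
record (ground-truth parameters, noise sigma, seeds) sufficient to
regenerate its data bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .epg import SignalTimeseries, simulate_timeseries
from .montecarlo import McConfig, simulate_mc_signal
from .motion import (
    PulsatilityModel,
    RigidBodyMotion,
    impulse_trace,
    pulsatility_trace,
    rigid_body_trace,
)
from .params import (
    InvalidParameterError,
    SequenceParams,
    TissueParams,
    _require,
    reference_sequence,
    reference_tissue,
)

__all__ = ["Scenario", "add_noise", "build_scenario", "SCENARIO_NAMES", "fig3_gradient_direction"]

SCENARIO_NAMES = ("fig2_impulse", "fig3_rigid", "fig3_pulsatile", "fig5_fit", "fig6_grid")


@dataclass
class Scenario:
    """A named simulation setup with generated data and its truth record."""

    name: str
    seq: SequenceParams
    tissue: TissueParams
    motion: Any
    snr: float | None
    seed: int
    data: SignalTimeseries | list[SignalTimeseries] | None
    truth: dict = field(default_factory=dict)


def add_noise(
    series: SignalTimeseries,
    snr: float | None,
    seed: int | np.random.Generator = 0,
    sigma_ref: float | None = None,
) -> SignalTimeseries:
    """Add independent Gaussian noise to the real and imaginary channels.

    The per-channel standard deviation is ``sigma_ref / snr`` where
    ``sigma_ref`` defaults to the steady-state magnitude of the series
    (mean magnitude of its last 10 samples).  ``snr=None`` or ``inf``
    returns the series unchanged.
    """
    if snr is None or np.isinf(snr):
        return series
    _require(snr > 0, "snr must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sigma_ref is None:
        sigma_ref = float(np.mean(np.abs(series.values[-10:])))
    sd = sigma_ref / snr
    n = len(series)
    noise = sd * (rng.standard_normal(n) + 1j * rng.standard_normal(n))
    return SignalTimeseries(
        values=series.values + noise, times=series.times, b_label=series.b_label
    )


def fig3_gradient_direction() -> np.ndarray:
    """Gradient orientation of the rigid-body reference scenario.

    The printed components decode to (3/10, 2/5, 1/(2*sqrt(2))); the vector
    is normalised to unit length.
    """
    g = np.array([3.0 / 10.0, 2.0 / 5.0, 1.0 / (2.0 * np.sqrt(2.0))])
    return g / np.linalg.norm(g)


def _rigid_reference() -> RigidBodyMotion:
    return RigidBodyMotion(
        v=np.array([3.0 / 20.0, -1.0 / 10.0, 1.0 / 20.0]),
        omega=np.array([1.0, -2.0 / 3.0, 1.0 / 3.0]),
        X0=np.array([-100.0, -100.0, -100.0]),
    )


def build_scenario(name: str, seed: int = 0, **overrides) -> Scenario:
    """Construct one of the named simulation scenarios.

    Supported names (defaults in parentheses):

    * ``fig2_impulse`` -- 200-TR motion-free series with a 1.5 mm/s impulse
      during one TR (TR index 100), i.e. a 0.06 mm displacement event.
    * ``fig3_rigid`` -- constant rigid-body translation + rotation.
    * ``fig3_pulsatile`` -- cardiac pulsatility, 0.4 mm/s peak, 50 bpm.
    * ``fig5_fit`` -- the pulsatile series with Gaussian noise at SNR 20;
      fit window = last 100 TRs (25 dummy + 75 measured).  ``source`` may
      be ``"mc"`` (Monte-Carlo data, the default) or ``"epg"``.
    * ``fig6_grid`` -- the velocity x SNR bias-grid configuration (no data).

    ``overrides`` replace scenario attributes (e.g. ``n_tr``, ``snr``,
    ``v_card``, ``n_spins``, ``at_tr``).
    """
    if name not in SCENARIO_NAMES:
        raise InvalidParameterError(f"unknown scenario {name!r}; one of {SCENARIO_NAMES}")
    n_tr = int(overrides.pop("n_tr", 200))
    seq = reference_sequence(n_tr=n_tr)
    tissue = reference_tissue(D=overrides.pop("D", 1.0e-3))

    if name == "fig2_impulse":
        at_tr = int(overrides.pop("at_tr", 100))
        v_peak = float(overrides.pop("v_peak", 1.5))
        trace = impulse_trace(v_peak, at_tr, n_tr)
        data = simulate_timeseries(seq, tissue, trace, b_label="impulse")
        truth = dict(
            D=tissue.D,
            V_trace=trace,
            at_tr=at_tr,
            v_peak=v_peak,
            displacement_mm=v_peak * seq.TR,
            seed=seed,
        )
        return Scenario(name, seq, tissue, trace, None, seed, data, truth)

    if name == "fig3_rigid":
        motion = overrides.pop("motion", _rigid_reference())
        seq = seq.with_(g_hat=fig3_gradient_direction())
        trace = rigid_body_trace(motion, seq.g_hat, seq.TR, n_tr)
        data = simulate_timeseries(seq, tissue, trace, b_label="rigid")
        truth = dict(D=tissue.D, V_trace=trace, seed=seed)
        return Scenario(name, seq, tissue, motion, None, seed, data, truth)

    if name == "fig3_pulsatile":
        model = PulsatilityModel(
            v_card=float(overrides.pop("v_card", 0.4)),
            heart_rate=float(overrides.pop("heart_rate", 50.0)),
        )
        trace = pulsatility_trace(model, 1.0, seq.TR, n_tr)
        data = simulate_timeseries(seq, tissue, trace, b_label="pulsatile")
        truth = dict(D=tissue.D, V_trace=trace, seed=seed)
        return Scenario(name, seq, tissue, model, None, seed, data, truth)

    if name == "fig5_fit":
        model = PulsatilityModel(
            v_card=float(overrides.pop("v_card", 0.4)),
            heart_rate=float(overrides.pop("heart_rate", 50.0)),
        )
        snr = overrides.pop("snr", 20.0)
        source = overrides.pop("source", "mc")
        trace = pulsatility_trace(model, 1.0, seq.TR, n_tr)
        if source == "mc":
            n_spins = int(overrides.pop("n_spins", 100_000))
            clean = simulate_mc_signal(
                McConfig(seq=seq, tissue=tissue, motion=model, n_spins=n_spins, seed=seed)
            )
        elif source == "epg":
            clean = simulate_timeseries(seq, tissue, trace, b_label="pulsatile")
        else:
            raise InvalidParameterError(f"unknown source {source!r}")
        sigma_ref = abs(simulate_timeseries(seq, tissue).values[-1])
        data = add_noise(clean, snr, seed=seed + 1, sigma_ref=sigma_ref)
        truth = dict(
            D=tissue.D,
            V_trace=trace,
            snr=snr,
            sigma=None if snr is None else sigma_ref / snr,
            source=source,
            seed=seed,
            noise_seed=seed + 1,
            clean=clean.values,
        )
        return Scenario(name, seq, tissue, model, snr, seed, data, truth)

    # fig6_grid: configuration only
    truth = dict(
        velocities=overrides.pop("velocities", [0.0, 0.3, 0.6, 0.9, 1.2, 1.5]),
        snrs=overrides.pop("snrs", [10.0, 20.0, 50.0, None]),
        n_repeats=int(overrides.pop("n_repeats", 10)),
        D=tissue.D,
        seed=seed,
    )
    return Scenario(name, seq, tissue, None, None, seed, None, truth)
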