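"""Extended-phase-graph (EPG) forward model of the DW-SSFP signal.

The magnetisation of a voxel is represented as a ladder of configuration
states of integer dephasing order k: transverse states F~_k (stored as
``F_plus[k]`` for k >= 0 and ``F_minus[k]`` holding conj(F~_{-k})) and
longitudinal states Z~_k.  Each TR applies, in order:

1. an RF mixing operator at the effective flip angle B1*alpha with phase phi,
2. per-state relaxation, diffusion-attenuation and motion-phase factors,
   with the diffusion gradient occupying the first ``delta`` of the TR
   (transverse orders shift k -> k+1 during the gradient),
3. the ladder shift of transverse states by one order,
4. longitudinal recovery of Z~_0 towards M0.

The motion factors depend on a single scalar velocity component per TR,
V_n, measured along the gradient orientation (mm/s).  The reported signal
is F~_0 at the end of each TR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import InvalidParameterError, SequenceParams, TissueParams, _require

__all__ = [
    "PhaseGraph",
    "SignalTimeseries",
    "rf_operator",
    "diffusion_operator",
    "motion_operator",
    "apply_tr",
    "simulate_timeseries",
    "steady_state_tr",
]


@dataclass
class SignalTimeseries:
    """Complex signal sampled once per TR."""

    values: np.ndarray
    times: np.ndarray
    b_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != self.times.shape:
            raise InvalidParameterError("values and times must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("signal values must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class PhaseGraph:
    """Configuration-state ladder of one voxel.

    ``F_plus[k]`` holds F~_k, ``F_minus[k]`` holds conj(F~_{-k}) (so
    ``F_minus[0] == conj(F_plus[0])`` always), ``Z[k]`` holds Z~_k.
    """

    F_plus: np.ndarray
    F_minus: np.ndarray
    Z: np.ndarray
    unit_q: float

    @classmethod
    def equilibrium(cls, k_max: int, unit_q: float, M0: float = 1.0) -> "PhaseGraph":
        n = k_max + 1
        Z = np.zeros(n, dtype=complex)
        Z[0] = M0
        return cls(
            F_plus=np.zeros(n, dtype=complex),
            F_minus=np.zeros(n, dtype=complex),
            Z=Z,
            unit_q=unit_q,
        )

    @property
    def k_max(self) -> int:
        return len(self.F_plus) - 1

    def as_stack(self) -> np.ndarray:
        return np.stack([self.F_plus, self.F_minus, self.Z])


def rf_operator(alpha_eff: float, phi_rf: float) -> np.ndarray:
    """3x3 complex RF mixing matrix acting on (F~_k, conj(F~_{-k}), Z~_k).

    Applied identically at every dephasing order k.
    """
    if not (np.isfinite(alpha_eff) and np.isfinite(phi_rf)):
        raise InvalidParameterError("RF angles must be finite")
    a, p = float(alpha_eff), float(phi_rf)
    c2, s2 = np.cos(a / 2.0) ** 2, np.sin(a / 2.0) ** 2
    sa, ca = np.sin(a), np.cos(a)
    ep = np.exp(1j * p)
    return np.array(
        [
            [c2, ep**2 * s2, -1j * ep * sa],
            [np.conj(ep) ** 2 * s2, c2, 1j * np.conj(ep) * sa],
            [-0.5j * np.conj(ep) * sa, 0.5j * ep * sa, ca],
        ]
    )


def diffusion_operator(
    k1: float, k2: float, D: float, seq: SequenceParams
) -> tuple[float, float, float]:
    """Diffusion attenuation factors (F+, F-, Z) for one TR.

    ``k1``/``k2`` are the transverse dephasing orders (integer units of q)
    before and after the gradient.  The transverse factor covers the gradient
    interval (with the order ramping linearly k1 -> k2) and the remaining
    TR - delta at constant order k2; the longitudinal factor covers a full TR
    at constant order k1.
    """
    if D < 0 or not np.isfinite(D):
        raise InvalidParameterError("D must be finite and >= 0")
    q2D = seq.q**2 * D
    dk = k2 - k1
    f = np.exp(-((k1 + dk / 2.0) ** 2 + dk**2 / 12.0) * q2D * seq.delta) * np.exp(
        -(k2**2) * q2D * (seq.TR - seq.delta)
    )
    z = np.exp(-(k1**2) * q2D * seq.TR)
    return float(f), float(f), float(z)


def motion_operator(
    k1: float, k2: float, V: float, seq: SequenceParams
) -> tuple[complex, complex, complex]:
    """Unit-magnitude motion phase factors (F+, F-, Z) for one TR.

    A configuration of instantaneous physical order K(t) accrues phase
    ``-K(t) * V`` per unit time as the spins displace; integrating over the
    gradient (order ramping k1 -> k2) and the remainder of the TR gives the
    transverse factor.  The F- factor is its conjugate; the longitudinal
    factor covers a full TR at constant order k1.  ``V`` is the velocity
    component along the gradient (mm/s); flipping its sign conjugates every
    factor, preserving motion polarity in the phase.
    """
    if not np.isfinite(V):
        raise InvalidParameterError("V must be finite")
    qV = seq.q * V
    f = np.exp(
        -1j * (k1 + k2) / 2.0 * qV * seq.delta - 1j * k2 * qV * (seq.TR - seq.delta)
    )
    z = np.exp(-1j * k1 * qV * seq.TR)
    return complex(f), complex(np.conj(f)), complex(z)


def _factors(
    seq: SequenceParams, tissue: TissueParams, k_max: int
) -> tuple[np.ndarray, np.ndarray]:
    """V-independent part: relaxation * diffusion factors, shape (3, k_max+1)."""
    k = np.arange(k_max + 1, dtype=float)
    q2D = seq.q**2 * tissue.D
    E1 = np.exp(-seq.TR / tissue.T1)
    E2 = np.exp(-seq.TR / tissue.T2)
    d_fp = np.exp(-((k + 0.5) ** 2 + 1.0 / 12.0) * q2D * seq.delta) * np.exp(
        -((k + 1.0) ** 2) * q2D * (seq.TR - seq.delta)
    )
    d_fm = np.exp(-((k - 0.5) ** 2 + 1.0 / 12.0) * q2D * seq.delta) * np.exp(
        -((k - 1.0) ** 2) * q2D * (seq.TR - seq.delta)
    )
    d_z = np.exp(-(k**2) * q2D * seq.TR)
    fac = np.stack([E2 * d_fp, E2 * d_fm, E1 * d_z])
    # Phase slope per unit V (rad s / mm): motion factor = exp(-1j * slope * V).
    s_fp = seq.q * ((k + 0.5) * seq.delta + (k + 1.0) * (seq.TR - seq.delta))
    s_fm = seq.q * ((k - 0.5) * seq.delta + (k - 1.0) * (seq.TR - seq.delta))
    s_z = seq.q * k * seq.TR
    slopes = np.stack([s_fp, s_fm, s_z])
    return fac, slopes


def _shift(stack: np.ndarray) -> None:
    """In-place ladder shift of transverse states by one order (k -> k+1).

    Works on a single (3, K) stack or a batch (..., 3, K).
    """
    stack[..., 0, 1:] = stack[..., 0, :-1]
    stack[..., 0, 0] = np.conj(stack[..., 1, 1])
    stack[..., 1, :-1] = stack[..., 1, 1:]
    stack[..., 1, -1] = 0.0
    stack[..., 1, 0] = np.conj(stack[..., 0, 0])


def apply_tr(
    state: PhaseGraph,
    seq: SequenceParams,
    tissue: TissueParams,
    V_n: float,
    M0: float = 1.0,
) -> PhaseGraph:
    """Evolve a phase graph through one full TR with velocity ``V_n``."""
    if not np.isfinite(V_n):
        raise InvalidParameterError("V_n must be finite")
    T = rf_operator(tissue.B1 * seq.alpha, seq.phi_rf)
    fac, slopes = _factors(seq, tissue, state.k_max)
    stack = T @ state.as_stack()
    stack *= fac * np.exp(-1j * slopes * V_n)
    _shift(stack)
    E1 = np.exp(-seq.TR / tissue.T1)
    stack[2, 0] += M0 * (1.0 - E1)
    return PhaseGraph(
        F_plus=stack[0], F_minus=stack[1], Z=stack[2], unit_q=state.unit_q
    )


def simulate_timeseries(
    seq: SequenceParams,
    tissue: TissueParams,
    V_trace: np.ndarray | None = None,
    global_phase: float = 0.0,
    amplitude: float = 1.0,
    k_max: int | None = None,
    b_label: str = "",
) -> SignalTimeseries:
    """Forward-simulate the complex DW-SSFP signal over ``seq.n_tr`` TRs.

    ``values[n] = amplitude * exp(1j*global_phase) * F~_0`` at the end of
    TR n (the sampling point matched by the Monte-Carlo oracle).
    """
    if V_trace is None:
        V_trace = np.zeros(seq.n_tr)
    V_trace = np.asarray(V_trace, dtype=float)
    if V_trace.shape != (seq.n_tr,):
        raise InvalidParameterError(
            f"V_trace must have length n_tr={seq.n_tr}, got {V_trace.shape}"
        )
    signal, _ = _run_epg(seq, tissue, V_trace, k_max=k_max)
    values = amplitude * np.exp(1j * global_phase) * signal
    times = seq.TR * np.arange(1, seq.n_tr + 1)
    return SignalTimeseries(values=values, times=times, b_label=b_label)


def _run_epg(
    seq: SequenceParams,
    tissue: TissueParams,
    V_trace: np.ndarray,
    k_max: int | None = None,
    deriv_trs: np.ndarray | None = None,
    signal_trs: slice | None = None,
):
    """EPG recursion returning the end-of-TR F~_0 series.

    If ``deriv_trs`` (sorted TR indices) is given, forward-mode derivative
    states are propagated and the Jacobian ``dF0[m]/dV_n`` is returned as a
    (len(deriv_trs), n_tr) complex array.  The evolution is linear in the
    state, so every derivative state is evolved by the same operators; the
    derivative of the motion factor seeds the state of its own TR.
    """
    n_tr = seq.n_tr
    if k_max is None:
        k_max = n_tr + 2
    K = k_max + 1
    T = rf_operator(tissue.B1 * seq.alpha, seq.phi_rf)
    fac, slopes = _factors(seq, tissue, k_max)
    E1 = np.exp(-seq.TR / tissue.T1)

    stack = np.zeros((3, K), dtype=complex)
    stack[2, 0] = 1.0
    signal = np.empty(n_tr, dtype=complex)

    want_jac = deriv_trs is not None
    if want_jac:
        deriv_trs = np.asarray(deriv_trs, dtype=int)
        P = len(deriv_trs)
        dstack = np.zeros((P, 3, K), dtype=complex)
        jac = np.zeros((P, n_tr), dtype=complex)
        tr_to_p = {int(t): i for i, t in enumerate(deriv_trs)}
        n_active = 0

    for n in range(n_tr):
        mfac = fac * np.exp(-1j * slopes * V_trace[n])
        stack = T @ stack
        stack *= mfac
        if want_jac:
            if n_active:
                d = dstack[:n_active]
                np.matmul(T, d, out=d)
                d *= mfac
            p = tr_to_p.get(n)
            if p is not None:
                # Seed: d(mfac)/dV = -1j * slopes * mfac acting on this TR's state.
                dstack[p] = -1j * slopes * stack
                n_active = max(n_active, p + 1)
            if n_active:
                _shift(dstack[:n_active])
        _shift(stack)
        stack[2, 0] += 1.0 - E1
        signal[n] = stack[0, 0]
        if want_jac and n_active:
            jac[:n_active, n] = dstack[:n_active, 0, 0]

    if want_jac:
        return signal, jac
    return signal, None


def steady_state_tr(series: SignalTimeseries, rel_tol: float = 0.01) -> int:
    """Smallest TR index n such that all later per-TR signal changes are
    below ``rel_tol`` relative to the final value.  Returns -1 if the
    series never settles under this criterion.
    """
    if rel_tol <= 0:
        raise InvalidParameterError("rel_tol must be > 0")
    v = series.values
    if len(v) < 2:
        return 0
    ref = abs(v[-1])
    if ref == 0:
        return -1
    rel = np.abs(np.diff(v)) / ref
    ok = rel < rel_tol
    if not ok[-1]:
        return -1
    # last index where the criterion fails, +1
    bad = np.nonzero(~ok)[0]
    return int(bad[-1] + 1) if len(bad) else 0
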