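"""Estimation of (D, S0, phi, V(t)) from complex DW-SSFP time-series.

The EPG forward model is embedded in a bounded trust-region-reflective
least-squares fit on the concatenated real and imaginary residuals.  The
simulated window is split into three regions:

* ``n_burnin`` TRs with no motion parameters, letting the simulated signal
  reach its motion-free steady state;
* ``n_dummy`` TRs whose velocity parameters are estimated but excluded from
  the cost ("dummy measurements": motion effects persist over many TRs, so
  these let the modelled signal carry a realistic motion history into the
  first measured TR);
* ``n_measured`` TRs compared against the data.

One velocity parameter is estimated per dummy/measured TR (and per shell
when fitting two b-shells simultaneously, which share a single D).  The
Jacobian is analytic in S0, phi and every V_n (forward-mode propagation of
derivative states through the linear EPG recursion) and finite-difference
in D.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .epg import SignalTimeseries, _run_epg, simulate_timeseries
from .motion import PulsatilityModel, pulsatility_trace
from .params import InvalidParameterError, SequenceParams, TissueParams, _require

__all__ = ["FitConfig", "FitResult", "fit_voxel", "bias_grid"]


@dataclass
class FitConfig:
    """Fit-window layout, bounds and initial values."""

    n_burnin: int = 100
    n_dummy: int = 25
    n_measured: int = 75
    estimate_motion: bool = True
    estimate_s0: bool = False
    jacobian_mode: str = "analytic-hybrid"  # or "numeric"
    D_init: float = 1.0e-3
    D_bounds: tuple[float, float] = (0.05e-3, 4.0e-3)
    V_init: float = 0.0
    V_bounds: tuple[float, float] = (-5.0, 5.0)
    phi_bounds: tuple[float, float] = (-np.pi, np.pi)
    s0_max_scale: float = 10.0
    k_max: int = 80
    max_nfev: int | None = None

    def __post_init__(self) -> None:
        _require(self.n_dummy >= 0, "n_dummy must be >= 0")
        _require(self.n_measured >= 1, "n_measured must be >= 1")
        _require(self.n_burnin >= 0, "n_burnin must be >= 0")
        _require(
            self.D_bounds[0] <= self.D_init <= self.D_bounds[1],
            "D_init outside D_bounds",
        )
        _require(
            self.jacobian_mode in ("analytic-hybrid", "numeric"),
            "jacobian_mode must be 'analytic-hybrid' or 'numeric'",
        )

    @property
    def n_motion(self) -> int:
        return self.n_dummy + self.n_measured

    @property
    def n_total(self) -> int:
        return self.n_burnin + self.n_dummy + self.n_measured


@dataclass
class FitResult:
    """Estimated parameters with uncertainties and diagnostics."""

    D_hat: float
    S0_hat: float
    phi_hat: np.ndarray  # one per shell
    V_hat: np.ndarray  # (n_shells, n_dummy + n_measured)
    D_var: float
    residual_norm: float
    converged: bool
    message: str = ""
    n_iter: int = 0
    #: True when the optimizer returned a finite best point, even if it
    #: stopped on the iteration budget rather than a tolerance
    usable: bool = True

    @property
    def V_measured(self) -> np.ndarray:
        """Velocity trace restricted to the measured window (per shell)."""
        return self._v_measured

    _v_measured: np.ndarray = field(default=None, repr=False)


class _VoxelModel:
    """Packs/unpacks the parameter vector and evaluates model + Jacobian."""

    def __init__(
        self,
        series: list[SignalTimeseries],
        seqs: list[SequenceParams],
        tissue: TissueParams,
        cfg: FitConfig,
    ):
        self.cfg = cfg
        self.tissue = tissue
        self.series = series
        self.n_shells = len(series)
        self.seqs = [s.with_(n_tr=cfg.n_total) for s in seqs]
        self.data = np.concatenate([np.asarray(s.values)[-cfg.n_measured :] for s in series])
        nm = cfg.n_motion
        self.motion_trs = np.arange(cfg.n_burnin, cfg.n_total)
        # layout: D | [S0] | phi (per shell) | V blocks (per shell)
        self.i_d = 0
        self.i_s0 = 1 if cfg.estimate_s0 else None
        base = 2 if cfg.estimate_s0 else 1
        self.i_phi = [base + j for j in range(self.n_shells)]
        base += self.n_shells
        self.i_v = [
            slice(base + j * nm, base + (j + 1) * nm) if cfg.estimate_motion else None
            for j in range(self.n_shells)
        ]
        self.n_params = base + (self.n_shells * nm if cfg.estimate_motion else 0)

    def initial_and_bounds(self, s0_fixed: float):
        cfg = self.cfg
        p0 = np.zeros(self.n_params)
        lo = np.full(self.n_params, -np.inf)
        hi = np.full(self.n_params, np.inf)
        p0[self.i_d] = cfg.D_init
        lo[self.i_d], hi[self.i_d] = cfg.D_bounds
        refs = [self._shell_signal(p0, j, want_jac=False)[0] for j in range(self.n_shells)]
        if cfg.estimate_s0:
            # amplitude of the data relative to the motion-free model prediction
            pred_mag = float(np.mean([np.mean(np.abs(r)) for r in refs]))
            s0_init = float(np.mean(np.abs(self.data))) / max(pred_mag, 1e-300)
            p0[self.i_s0] = s0_init if s0_init > 0 else 1.0
            lo[self.i_s0], hi[self.i_s0] = 1e-12, cfg.s0_max_scale * p0[self.i_s0]
        for j in range(self.n_shells):
            # phase offset of the data relative to the motion-free model
            # prediction at the first measured TR (the forward model carries
            # its own intrinsic steady-state phase)
            first = self.series[j].values[-cfg.n_measured]
            pred = refs[j][0]
            phi0 = np.angle(first / pred) if abs(first) > 0 and abs(pred) > 0 else 0.0
            p0[self.i_phi[j]] = np.clip(phi0, *cfg.phi_bounds)
            lo[self.i_phi[j]], hi[self.i_phi[j]] = cfg.phi_bounds
            if cfg.estimate_motion:
                p0[self.i_v[j]] = cfg.V_init
                lo[self.i_v[j]], hi[self.i_v[j]] = cfg.V_bounds
        return p0, lo, hi

    def _shell_signal(self, p, j, want_jac):
        cfg = self.cfg
        V = np.zeros(cfg.n_total)
        if cfg.estimate_motion:
            V[self.motion_trs] = p[self.i_v[j]]
        sig, jac = _run_epg(
            self.seqs[j],
            self.tissue.with_(D=p[self.i_d]),
            V,
            k_max=cfg.k_max,
            deriv_trs=self.motion_trs if want_jac and cfg.estimate_motion else None,
        )
        return sig[-cfg.n_measured :], (
            jac[:, -cfg.n_measured :] if jac is not None else None
        )

    def model(self, p, want_jac=False, s0_fixed=1.0):
        cfg = self.cfg
        s0 = p[self.i_s0] if cfg.estimate_s0 else s0_fixed
        models, jacs = [], []
        for j in range(self.n_shells):
            sig, vjac = self._shell_signal(p, j, want_jac)
            scale = s0 * np.exp(1j * p[self.i_phi[j]])
            models.append(scale * sig)
            jacs.append(None if vjac is None else scale * vjac)
        return np.concatenate(models), models, jacs

    def residual(self, p, s0_fixed=1.0):
        m, _, _ = self.model(p, s0_fixed=s0_fixed)
        r = self.data - m
        return np.concatenate([r.real, r.imag])

    def jacobian(self, p, s0_fixed=1.0):
        """Residual Jacobian: analytic in S0/phi/V, central FD in D."""
        cfg = self.cfg
        nm_pts = cfg.n_measured
        J = np.zeros((2 * self.n_shells * nm_pts, self.n_params))
        _, models, vjacs = self.model(p, want_jac=cfg.estimate_motion)

        def put(col, dmodel_by_shell):
            dm = np.concatenate(dmodel_by_shell)
            J[:, col] = -np.concatenate([dm.real, dm.imag])

        # D by central finite difference
        h = max(1e-6, 1e-3 * abs(p[self.i_d]))
        pp, pm = p.copy(), p.copy()
        pp[self.i_d] += h
        pm[self.i_d] -= h
        m_plus, _, _ = self.model(pp, s0_fixed=s0_fixed)
        m_minus, _, _ = self.model(pm, s0_fixed=s0_fixed)
        dm = (m_plus - m_minus) / (2 * h)
        J[:, self.i_d] = -np.concatenate([dm.real, dm.imag])

        if cfg.estimate_s0:
            s0 = p[self.i_s0]
            put(self.i_s0, [m / s0 for m in models])
        for j in range(self.n_shells):
            put(self.i_phi[j], [1j * m if i == j else np.zeros_like(m) for i, m in enumerate(models)])
            if cfg.estimate_motion:
                vj = vjacs[j]  # (n_motion, n_measured) complex, d model_j / d V_n
                rows_re = slice(j * nm_pts, (j + 1) * nm_pts)
                off = self.n_shells * nm_pts
                rows_im = slice(off + j * nm_pts, off + (j + 1) * nm_pts)
                J[rows_re, self.i_v[j]] = -vj.real.T
                J[rows_im, self.i_v[j]] = -vj.imag.T
        return J


def _wrap_repair(model, res, lo, hi, s0_fixed, ls_kwargs, max_rounds: int = 2):
    """Map wrapped velocity estimates back to the principal branch.

    The motion phase of the dominant (order 0 -> 1) pathway is periodic in
    V_n with spacing 2*pi / (q * (delta/2 + TR - delta)), so the optimizer
    can land on a near-degenerate wrapped branch, typically during the
    systolic TRs.  Each estimate is mapped to its nearest-to-zero branch
    representative and the solve is repeated from there; the repair is
    kept only when the cost decreases, so the procedure never degrades
    the original solution.  Velocities whose
    magnitude genuinely exceeds half a spacing are intrinsically ambiguous
    and are left where the data put them.
    """
    for _ in range(max_rounds):
        x = res.x.copy()
        moved = False
        for j in range(model.n_shells):
            seq = model.seqs[j]
            spacing = 2 * np.pi / (seq.q * (seq.delta / 2 + seq.TR - seq.delta))
            sl = model.i_v[j]
            v = x[sl]
            principal = v - spacing * np.round(v / spacing)
            if np.any(np.abs(principal - v) > 1e-9):
                x[sl] = np.clip(principal, lo[sl], hi[sl])
                moved = True
        if not moved:
            break
        res2 = least_squares(
            lambda p: model.residual(p, s0_fixed=s0_fixed), x, **ls_kwargs
        )
        if res2.cost < res.cost * (1.0 - 1e-9):
            res = res2
        else:
            break
    return res


def _phase_init_start(model, p0, lo, hi, s0_fixed, ls_kwargs, base_res):
    """Second optimizer start seeded from unwrapped per-TR phase increments.

    When the fitted trace contains velocities beyond half a wrap spacing,
    the zero-velocity start is prone to systolic branch errors: the per-TR
    phase increment exceeds pi and the local basin is ambiguous.  The
    per-TR phase increments of the *data*, temporally unwrapped, give a
    first-order velocity estimate on the physically continuous branch (the
    observed signal phase advances by q(delta/2+TR-delta) per unit
    velocity per TR through the dominant refocusing pathway).  Returns
    None when the extra start is not needed or the data do not cover the
    motion window.
    """
    cfg = model.cfg
    spacings = [
        2 * np.pi / (s.q * (s.delta / 2 + s.TR - s.delta)) for s in model.seqs
    ]
    vmax = max(
        float(np.max(np.abs(base_res.x[model.i_v[j]])))
        for j in range(model.n_shells)
    )
    if vmax <= 0.5 * min(spacings):
        return None
    p1 = p0.copy()
    for j in range(model.n_shells):
        y = np.asarray(model.series[j].values)
        if len(y) < cfg.n_motion + 1:
            return None
        seg = y[-(cfg.n_motion + 1) :]
        if np.any(np.abs(seg) == 0):
            return None
        dphi = np.unwrap(np.angle(seg[1:] / seg[:-1]))
        seq = model.seqs[j]
        slope = seq.q * (seq.delta / 2 + seq.TR - seq.delta)
        p1[model.i_v[j]] = np.clip(
            dphi / slope, lo[model.i_v[j]], hi[model.i_v[j]]
        )
    return least_squares(
        lambda p: model.residual(p, s0_fixed=s0_fixed), p1, **ls_kwargs
    )


def fit_voxel(
    series: SignalTimeseries | list[SignalTimeseries],
    seq: SequenceParams | list[SequenceParams],
    tissue: TissueParams,
    cfg: FitConfig | None = None,
    s0_fixed: float = 1.0,
) -> FitResult:
    """Fit the EPG-motion forward model to one voxel's complex time-series.

    ``series``/``seq`` may be single objects or equal-length lists of
    b-shells fitted simultaneously with a shared diffusion coefficient
    (and shared S0; phase offset and velocity trace are per shell).  Only
    the last ``cfg.n_measured`` samples of each series enter the cost.
    The tissue relaxation times and B1 are taken as known; ``tissue.D`` is
    ignored in favour of the estimate.
    """
    if cfg is None:
        cfg = FitConfig()
    series_l = series if isinstance(series, list) else [series]
    seq_l = seq if isinstance(seq, list) else [seq]
    if len(series_l) != len(seq_l):
        raise InvalidParameterError("series and seq lists must have equal length")
    for s in series_l:
        if len(s) < cfg.n_measured:
            raise InvalidParameterError(
                f"series has {len(s)} samples < n_measured={cfg.n_measured}"
            )

    model = _VoxelModel(series_l, seq_l, tissue, cfg)
    p0, lo, hi = model.initial_and_bounds(s0_fixed)
    kwargs = dict(bounds=(lo, hi), method="trf", x_scale="jac")
    kwargs["max_nfev"] = cfg.max_nfev if cfg.max_nfev is not None else 100
    if cfg.jacobian_mode == "analytic-hybrid":
        kwargs["jac"] = lambda p: model.jacobian(p, s0_fixed=s0_fixed)
    try:
        res = least_squares(lambda p: model.residual(p, s0_fixed=s0_fixed), p0, **kwargs)
        if cfg.estimate_motion:
            repair_kwargs = dict(kwargs, max_nfev=min(kwargs["max_nfev"], 60))
            res = _wrap_repair(model, res, lo, hi, s0_fixed, repair_kwargs)
            alt = _phase_init_start(model, p0, lo, hi, s0_fixed, kwargs, res)
            if alt is not None and alt.cost < res.cost:
                res = _wrap_repair(model, alt, lo, hi, s0_fixed, repair_kwargs)
        else:
            # the low-dimensional conventional-EPG cost can be multimodal in
            # D on motion-corrupted data; restart from spread-out D values
            for d0 in (0.3e-3, 3.0e-3):
                if not (lo[model.i_d] <= d0 <= hi[model.i_d]):
                    continue
                p_alt = p0.copy()
                p_alt[model.i_d] = d0
                alt = least_squares(
                    lambda p: model.residual(p, s0_fixed=s0_fixed), p_alt, **kwargs
                )
                if alt.cost < res.cost:
                    res = alt
        converged = bool(res.status > 0)
        usable = bool(res.status >= 0) and np.all(np.isfinite(res.x))
        message = res.message
    except Exception as exc:  # fit must never crash the caller
        class res:  # noqa: N801
            x = p0
            fun = model.residual(p0, s0_fixed=s0_fixed)
            jac = None
            nfev = 0
        converged = False
        usable = False
        message = f"optimizer raised: {exc}"

    p = res.x
    nm = cfg.n_motion
    if cfg.estimate_motion and p[model.i_d] <= cfg.D_bounds[0] * 1.02:
        # D pinned at its lower physical bound with free velocities is the
        # signature of the degenerate overfit mode (velocity jitter
        # mimicking diffusion); the estimate carries no information
        converged = False
        usable = False
        message = "D pinned at lower bound (degenerate motion/diffusion fit); " + message
    V_hat = (
        np.stack([p[model.i_v[j]] for j in range(model.n_shells)])
        if cfg.estimate_motion
        else np.zeros((model.n_shells, nm))
    )
    # variance of D from the Gauss-Newton approximation of the covariance
    D_var = np.nan
    if converged and getattr(res, "jac", None) is not None:
        try:
            JTJ = res.jac.T @ res.jac
            dof = max(len(res.fun) - len(p), 1)
            s2 = float(res.fun @ res.fun) / dof
            D_var = s2 * float(np.linalg.pinv(JTJ)[model.i_d, model.i_d])
        except np.linalg.LinAlgError:
            pass
    out = FitResult(
        D_hat=float(p[model.i_d]),
        S0_hat=float(p[model.i_s0]) if cfg.estimate_s0 else s0_fixed,
        phi_hat=np.array([p[i] for i in model.i_phi]),
        V_hat=V_hat,
        D_var=D_var,
        residual_norm=float(np.linalg.norm(res.fun)),
        converged=converged,
        message=message,
        n_iter=int(getattr(res, "nfev", 0)),
        usable=usable,
    )
    out._v_measured = V_hat[:, cfg.n_dummy :]
    return out


def hybrid_jacobian(
    p: np.ndarray,
    series: SignalTimeseries | list[SignalTimeseries],
    seq: SequenceParams | list[SequenceParams],
    tissue: TissueParams,
    cfg: FitConfig,
    s0_fixed: float = 1.0,
) -> np.ndarray:
    """Residual Jacobian at parameter vector ``p`` (exposed for testing)."""
    series_l = series if isinstance(series, list) else [series]
    seq_l = seq if isinstance(seq, list) else [seq]
    return _VoxelModel(series_l, seq_l, tissue, cfg).jacobian(p, s0_fixed=s0_fixed)


def bias_grid(
    velocities,
    snrs,
    n_repeats: int = 3,
    cfg: FitConfig | None = None,
    seq: SequenceParams | None = None,
    tissue: TissueParams | None = None,
    heart_rate: float = 50.0,
    seed: int = 0,
    progress: bool = False,
) -> pd.DataFrame:
    """Mean estimated D over a (max pulsatile velocity) x SNR grid.

    For every cell, pulsatile time-series are generated with the EPG forward
    model, complex Gaussian noise is added at the stated SNR (``None`` or
    ``inf`` = noise-free), and both fit variants (with and without motion
    estimation) are run ``n_repeats`` times with fresh noise.  Noise-free
    cells are evaluated once.  Returns a tidy frame with columns
    ``velocity``, ``snr``, ``variant``, ``D_mean``, ``D_sd``, ``bias_pct``,
    ``n_ok``.
    """
    from .synthetic import add_noise  # local import to avoid a cycle

    if seq is None:
        from .params import reference_sequence

        seq = reference_sequence(n_tr=200)
    if tissue is None:
        from .params import reference_tissue

        tissue = reference_tissue()
    if cfg is None:
        cfg = FitConfig()
    ss_ref = abs(
        simulate_timeseries(seq, tissue).values[-1]
    )  # motion-free steady-state magnitude, sets the noise scale
    rows = []
    for v in velocities:
        model = PulsatilityModel(v_card=v, heart_rate=heart_rate)
        trace = pulsatility_trace(model, 1.0, seq.TR, seq.n_tr)
        clean = simulate_timeseries(seq, tissue, trace)
        for snr in snrs:
            noise_free = snr is None or np.isinf(snr)
            reps = 1 if noise_free else n_repeats
            fits = {"motion": [], "no_motion": []}
            for r in range(reps):
                data = (
                    clean
                    if noise_free
                    else add_noise(clean, snr, seed=seed + 1000 * r, sigma_ref=ss_ref)
                )
                for variant, est in (("motion", True), ("no_motion", False)):
                    c = replace(cfg, estimate_motion=est)
                    fit = fit_voxel(data, seq, tissue, c)
                    if fit.usable:
                        fits[variant].append(fit.D_hat)
            for variant in ("motion", "no_motion"):
                d = np.array(fits[variant])
                d_mean = float(d.mean()) if len(d) else np.nan
                rows.append(
                    dict(
                        velocity=v,
                        snr=np.inf if noise_free else snr,
                        variant=variant,
                        D_mean=d_mean,
                        D_sd=float(d.std(ddof=1)) if len(d) > 1 else 0.0,
                        bias_pct=100.0 * (d_mean - tissue.D) / tissue.D,
                        n_ok=len(d),
                    )
                )
            if progress:
                print(f"bias_grid: v={v} snr={snr} done")
    return pd.DataFrame(rows)
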