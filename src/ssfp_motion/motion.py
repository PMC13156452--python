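"""Generative motion models producing per-TR velocity traces.

A *motion trace* is a 1D float array of length ``n_tr`` holding V_n, the
component of the instantaneous tissue velocity along the diffusion gradient
orientation during TR n (mm/s).  Rigid-body motion (translation + rotation
about a centre) and a cardiac-pulsatility waveform are provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .params import InvalidParameterError, _require

__all__ = [
    "MotionTrace",
    "RigidBodyMotion",
    "PulsatilityModel",
    "rotation_matrix",
    "rigid_body_trace",
    "pulsatility_waveform",
    "pulsatility_trace",
    "spatial_velocity_map",
    "impulse_trace",
]

#: A per-TR velocity trace is a plain 1D ndarray (mm/s).
MotionTrace = np.ndarray


@dataclass(frozen=True)
class RigidBodyMotion:
    """Constant or per-TR rigid-body motion.

    Parameters
    ----------
    v : array, shape (3,) or (n_tr, 3)
        Translational velocity (mm/s).
    omega : array, shape (3,) or (n_tr, 3)
        Rotational velocity in deg/s at the interface (converted to rad/s
        internally).
    X0 : array, shape (3,)
        Initial position relative to the rotation centre (mm).
    """

    v: np.ndarray = field(default_factory=lambda: np.zeros(3))
    omega: np.ndarray = field(default_factory=lambda: np.zeros(3))
    X0: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        for name in ("v", "omega", "X0"):
            a = np.asarray(getattr(self, name), dtype=float)
            _require(np.all(np.isfinite(a)), f"{name} must be finite")
            object.__setattr__(self, name, a)
        _require(self.X0.shape == (3,), "X0 must be a 3-vector")
        for name in ("v", "omega"):
            a = getattr(self, name)
            _require(
                a.shape == (3,) or (a.ndim == 2 and a.shape[1] == 3),
                f"{name} must be shape (3,) or (n_tr, 3)",
            )

    def per_tr(self, name: str, n_tr: int) -> np.ndarray:
        """Broadcast ``v`` or ``omega`` to shape (n_tr, 3)."""
        a = getattr(self, name)
        if a.shape == (3,):
            return np.broadcast_to(a, (n_tr, 3))
        if a.shape[0] != n_tr:
            raise InvalidParameterError(
                f"{name} has {a.shape[0]} rows but n_tr={n_tr}"
            )
        return a


@dataclass(frozen=True)
class PulsatilityModel:
    """Cardiac-pulsatility velocity waveform of brain tissue.

    Systole is a single ``A * sin^4`` lobe spanning the first quarter of
    each cardiac cycle; diastole is a constant return velocity over the
    remaining three quarters, fixed so the displacement per cycle is
    exactly zero (plateau value -A/8, since the sin^4 lobe averages 3/8
    over its support).
    """

    v_card: float = 0.4
    heart_rate: float = 50.0
    spatial_scale_c: float = 175.0
    duration: float = 8.0

    def __post_init__(self) -> None:
        _require(np.isfinite(self.v_card) and self.v_card >= 0, "v_card must be >= 0")
        _require(self.heart_rate > 0, "heart_rate must be > 0")
        _require(self.spatial_scale_c > 0, "spatial_scale_c must be > 0")

    @property
    def cycle(self) -> float:
        """Cardiac period (s)."""
        return 60.0 / self.heart_rate


def rotation_matrix(theta: np.ndarray) -> np.ndarray:
    """3D rotation R = Rz(tz) @ Ry(ty) @ Rx(tx) for angles in rad."""
    tx, ty, tz = np.asarray(theta, dtype=float)
    cx, sx = np.cos(tx), np.sin(tx)
    cy, sy = np.cos(ty), np.sin(ty)
    cz, sz = np.cos(tz), np.sin(tz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def rigid_body_trace(
    motion: RigidBodyMotion, g_hat: np.ndarray, TR: float, n_tr: int
) -> MotionTrace:
    """Per-TR velocity component of rigid-body motion along ``g_hat``.

    V_n = v_n . g + (g x omega_n) . X, with the position updated once per
    TR as X_{n+1} = R(omega_n * TR) X_n + v_n * TR.  The rotational term is
    evaluated at the TR-midpoint position (half a rotation/translation step
    from X_n), the best single-sample representative of the instantaneous
    velocity during that TR.
    """
    g = np.asarray(g_hat, dtype=float)
    _require(abs(np.linalg.norm(g) - 1.0) < 1e-9, "g_hat must be a unit vector")
    v = motion.per_tr("v", n_tr)
    omega = np.deg2rad(motion.per_tr("omega", n_tr))
    X = motion.X0.copy()
    V = np.empty(n_tr)
    for n in range(n_tr):
        X_mid = rotation_matrix(omega[n] * TR / 2.0) @ X + v[n] * TR / 2.0
        V[n] = v[n] @ g + np.cross(g, omega[n]) @ X_mid
        X = rotation_matrix(omega[n] * TR) @ X + v[n] * TR
    return V


def pulsatility_waveform(model: PulsatilityModel, t: np.ndarray) -> np.ndarray:
    """Continuous pulsatile velocity at times ``t`` (s), in mm/s."""
    t = np.asarray(t, dtype=float)
    tc = model.cycle
    tau = np.mod(t, tc)
    systole = tau < tc / 4.0
    out = np.full(t.shape, -model.v_card / 8.0)
    out[systole] = model.v_card * np.sin(np.pi * tau[systole] / (tc / 4.0)) ** 4
    return out


def pulsatility_trace(
    model: PulsatilityModel,
    relative_spatial_velocity: float,
    TR: float,
    n_tr: int,
    samples_per_tr: int = 100,
) -> MotionTrace:
    """Box-average the continuous waveform over each TR window.

    ``relative_spatial_velocity`` in [0, 1] scales the trace (the value of
    the spatial velocity map at the voxel).
    """
    _require(
        0.0 <= relative_spatial_velocity <= 1.0,
        "relative_spatial_velocity must lie in [0, 1]",
    )
    if TR > model.cycle / 4.0:
        warnings.warn(
            "TR exceeds a quarter cardiac cycle: systolic lobe is under-resolved",
            stacklevel=2,
        )
    # midpoint sampling of samples_per_tr sub-intervals per TR
    dt = TR / samples_per_tr
    t = (np.arange(n_tr * samples_per_tr) + 0.5) * dt
    w = pulsatility_waveform(model, t).reshape(n_tr, samples_per_tr)
    return relative_spatial_velocity * w.mean(axis=1)


def spatial_velocity_map(
    shape: tuple[int, int],
    voxel_size: float,
    centre: tuple[float, float] | None = None,
    c: float = 175.0,
) -> np.ndarray:
    """Relative pulsatile-velocity amplitude map, ((c - r)/c)^3 clipped to [0, 1].

    ``r`` is the distance (mm) of each voxel from ``centre`` (grid
    coordinates; defaults to the grid midpoint).  The cubic fall-off with a
    fixed length constant ``c`` keeps the profile independent of voxel size
    and field of view.
    """
    ny, nx = shape
    if centre is None:
        centre = ((ny - 1) / 2.0, (nx - 1) / 2.0)
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = voxel_size * np.hypot(yy - centre[0], xx - centre[1])
    return np.clip((c - r) ** 3 / c**3, 0.0, 1.0)


def impulse_trace(V_peak: float, at_tr: int, n_tr: int) -> MotionTrace:
    """Velocity trace that is ``V_peak`` during exactly one TR, zero elsewhere."""
    if not 0 <= at_tr < n_tr:
        raise InvalidParameterError(f"at_tr={at_tr} outside [0, {n_tr})")
    V = np.zeros(n_tr)
    V[at_tr] = V_peak
    return V
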