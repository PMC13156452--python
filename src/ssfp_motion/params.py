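"""Acquisition and tissue parameter containers.

Internal unit conventions used throughout the package:

* lengths in mm, times in s, angles in rad,
* gradient amplitude at the interface in mT/m (the unit scanners quote),
* diffusion coefficients in mm^2/s,
* the per-TR dephasing increment ``q = gamma * G * delta`` in rad/mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Proton gyromagnetic ratio (rad s^-1 T^-1).
GAMMA = 2.6752218744e8


class InvalidParameterError(ValueError):
    """Raised when a physical parameter fails validation."""


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise InvalidParameterError(message)


@dataclass(frozen=True)
class SequenceParams:
    """DW-SSFP sequence settings: one RF pulse and one diffusion gradient per TR.

    Parameters
    ----------
    G : float
        Diffusion gradient amplitude (mT/m).
    delta : float
        Gradient duration (s); the gradient occupies the first ``delta`` of
        each TR.
    TR : float
        Repetition time (s).
    alpha : float
        Nominal flip angle (rad); the effective flip is ``B1 * alpha``.
    phi_rf : float
        RF phase (rad), constant across TRs (no RF spoiling schedule).
    g_hat : ndarray
        Unit 3-vector giving the diffusion gradient orientation.
    n_tr : int
        Number of TRs to simulate.
    """

    G: float
    delta: float
    TR: float
    alpha: float
    phi_rf: float = 0.0
    g_hat: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    n_tr: int = 200

    def __post_init__(self) -> None:
        g = np.asarray(self.g_hat, dtype=float).reshape(3)
        object.__setattr__(self, "g_hat", g)
        _require(np.isfinite(self.G) and self.G >= 0, "G must be finite and >= 0")
        _require(
            np.isfinite(self.delta) and np.isfinite(self.TR) and 0 < self.delta < self.TR,
            "require 0 < delta < TR",
        )
        _require(
            np.isfinite(self.alpha) and 0 < self.alpha < np.pi,
            "alpha must lie in (0, pi)",
        )
        _require(np.isfinite(self.phi_rf), "phi_rf must be finite")
        _require(np.all(np.isfinite(g)), "g_hat must be finite")
        _require(abs(np.linalg.norm(g) - 1.0) < 1e-9, "g_hat must be a unit vector")
        _require(int(self.n_tr) >= 1, "n_tr must be >= 1")
        object.__setattr__(self, "n_tr", int(self.n_tr))

    @property
    def q(self) -> float:
        """Per-TR dephasing increment q = gamma * G * delta (rad/mm)."""
        return GAMMA * self.G * 1e-6 * self.delta

    def with_(self, **kwargs) -> "SequenceParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TissueParams:
    """Relaxation, diffusion and transmit-scale properties of one voxel."""

    T1: float
    T2: float
    D: float
    B1: float = 1.0

    def __post_init__(self) -> None:
        _require(
            np.isfinite(self.T1) and np.isfinite(self.T2) and self.T1 > self.T2 > 0,
            "require T1 > T2 > 0",
        )
        _require(np.isfinite(self.D) and self.D >= 0, "D must be finite and >= 0")
        _require(np.isfinite(self.B1) and self.B1 > 0, "B1 must be > 0")

    def with_(self, **kwargs) -> "TissueParams":
        return replace(self, **kwargs)


#: Sequence settings of the reference simulation scenario:
#: G = 40 mT/m, delta = 6.5 ms, alpha = 30 deg, TR = 40 ms, phi = 0.
def reference_sequence(n_tr: int = 200, g_hat=(0.0, 0.0, 1.0)) -> SequenceParams:
    return SequenceParams(
        G=40.0,
        delta=6.5e-3,
        TR=40e-3,
        alpha=np.deg2rad(30.0),
        phi_rf=0.0,
        g_hat=np.asarray(g_hat, dtype=float),
        n_tr=n_tr,
    )


#: Approximate brain tissue at 3 T: T1 = 832 ms, T2 = 110 ms, D = 1e-3 mm^2/s.
def reference_tissue(D: float = 1.0e-3, B1: float = 1.0) -> TissueParams:
    return TissueParams(T1=0.832, T2=0.110, D=D, B1=B1)
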