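"""Image-level synthesis and diffusion-tensor reconstruction.

Voxels are simulated independently with the EPG forward model (voxel
locations are taken as stationary over the simulated time-course; motion
enters only through each voxel's velocity trace).  A segmented Cartesian
readout can then be emulated by assembling k-space lines from successive
instantaneous images.  Per-direction diffusion-coefficient maps are
combined into a rank-2 tensor by (weighted) linear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epg import SignalTimeseries, rf_operator, _factors, _shift
from .params import GAMMA, InvalidParameterError, SequenceParams, TissueParams, _require

__all__ = [
    "PhantomMap",
    "TensorResult",
    "brain_phantom",
    "synthesize_image_series",
    "segmented_readout",
    "dwse_signal",
    "tensor_from_adc",
    "icosahedral_directions",
]


@dataclass
class PhantomMap:
    """Per-voxel tissue parameters on a 2D grid."""

    D_map: np.ndarray
    T1: np.ndarray | float
    T2: np.ndarray | float
    B1: np.ndarray | float
    mask: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.D_map = np.asarray(self.D_map, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.D_map.shape:
            raise InvalidParameterError("mask and D_map shapes differ")
        if np.any(self.D_map[self.mask] < 0):
            raise InvalidParameterError("D must be >= 0 inside the mask")

    def _field(self, name: str) -> np.ndarray:
        v = getattr(self, name)
        return np.broadcast_to(np.asarray(v, dtype=float), self.D_map.shape)


@dataclass
class TensorResult:
    """Diffusion tensor and derived scalars, per voxel."""

    tensor: np.ndarray  # (..., 3, 3)
    L1: np.ndarray
    L2: np.ndarray
    L3: np.ndarray
    MD: np.ndarray
    FA: np.ndarray
    V1: np.ndarray  # (..., 3) principal eigenvector


# representative diffusivities (mm^2/s) of the three tissue classes
_D_WM, _D_GM, _D_CSF = 0.7e-3, 0.9e-3, 3.0e-3


def brain_phantom(shape: tuple[int, int] = (32, 32), voxel_size: float = 6.0) -> PhantomMap:
    """Procedural brain-like phantom: elliptical support with a grey-matter
    rim, white-matter interior and CSF-filled central "ventricles"."""
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    ry, rx = 0.44 * ny, 0.40 * nx
    r2 = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    mask = r2 <= 1.0
    D = np.zeros(shape)
    D[mask] = _D_GM
    D[r2 <= 0.72] = _D_WM
    vent = (np.abs(xx - cx) < 0.12 * nx) & (((yy - cy) / (0.28 * ny)) ** 2 < 1.0)
    D[vent & mask] = _D_CSF
    return PhantomMap(D_map=D, T1=0.832, T2=0.110, B1=1.0, mask=mask, voxel_size=voxel_size)


def synthesize_image_series(
    phantom: PhantomMap,
    seq: SequenceParams,
    v_traces: np.ndarray | None = None,
    k_max: int | None = None,
) -> np.ndarray:
    """Complex image per TR, shape (n_tr, ny, nx).

    ``v_traces`` holds one velocity trace per voxel, shape (ny, nx, n_tr)
    (zeros if omitted).  All masked voxels are evolved together through a
    batched EPG recursion; voxels outside the mask are zero.
    """
    ny, nx = phantom.D_map.shape
    n_tr = seq.n_tr
    if v_traces is None:
        v_traces = np.zeros((ny, nx, n_tr))
    v_traces = np.asarray(v_traces, dtype=float)
    if v_traces.shape != (ny, nx, n_tr):
        raise InvalidParameterError(
            f"v_traces must have shape {(ny, nx, n_tr)}, got {v_traces.shape}"
        )
    if k_max is None:
        k_max = n_tr + 2
    K = k_max + 1
    idx = np.nonzero(phantom.mask)
    nv = len(idx[0])
    out = np.zeros((n_tr, ny, nx), dtype=complex)
    if nv == 0:
        return out

    T1 = phantom._field("T1")[idx]
    T2 = phantom._field("T2")[idx]
    B1 = phantom._field("B1")[idx]
    D = phantom.D_map[idx]
    V = v_traces[idx]  # (nv, n_tr)

    # per-voxel factors: build by evaluating the scalar helper per voxel class
    fac = np.empty((nv, 3, K))
    slopes = None
    Ts = np.empty((nv, 3, 3), dtype=complex)
    E1 = np.exp(-seq.TR / T1)
    cache: dict[tuple, tuple] = {}
    for i in range(nv):
        key = (T1[i], T2[i], B1[i], D[i])
        if key not in cache:
            tis = TissueParams(T1=T1[i], T2=T2[i], D=D[i], B1=B1[i])
            f, s = _factors(seq, tis, k_max)
            cache[key] = (f, s, rf_operator(B1[i] * seq.alpha, seq.phi_rf))
        f, s, T = cache[key]
        fac[i] = f
        slopes = s  # identical across voxels (geometry only)
        Ts[i] = T

    stack = np.zeros((nv, 3, K), dtype=complex)
    stack[:, 2, 0] = 1.0
    uniform_rf = np.isscalar(phantom.B1) or np.all(B1 == B1[0])
    T0 = Ts[0]
    for n in range(n_tr):
        if uniform_rf:
            stack = np.einsum("ij,vjk->vik", T0, stack)
        else:
            stack = np.einsum("vij,vjk->vik", Ts, stack)
        stack *= fac * np.exp(-1j * slopes[None, :, :] * V[:, n, None, None])
        _shift(stack)
        stack[:, 2, 0] += 1.0 - E1
        frame = np.zeros((ny, nx), dtype=complex)
        frame[idx] = stack[:, 0, 0]
        out[n] = frame
    return out


def segmented_readout(
    image_stack: np.ndarray,
    lines_per_tr: int,
    start_tr: int = 0,
    noise_snr: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Reconstruct one image from a segmented Cartesian readout.

    Per TR (starting at ``start_tr``) the instantaneous image is Fourier
    transformed and the next ``lines_per_tr`` phase-encode rows (sequential
    order) are kept; the assembled k-space is inverse transformed.  Optional
    complex Gaussian noise is added to k-space at an image-domain SNR of
    ``noise_snr`` relative to the mean magnitude of the contributing frames.
    """
    stack = np.asarray(image_stack)
    n_tr, ny, nx = stack.shape
    _require(lines_per_tr >= 1, "lines_per_tr must be >= 1")
    n_needed = int(np.ceil(ny / lines_per_tr))
    if start_tr + n_needed > n_tr:
        raise InvalidParameterError(
            f"need {n_needed} TRs from {start_tr} but stack has {n_tr}"
        )
    kspace = np.empty((ny, nx), dtype=complex)
    for i in range(n_needed):
        frame_k = np.fft.fftshift(np.fft.fft2(stack[start_tr + i]))
        rows = slice(i * lines_per_tr, min((i + 1) * lines_per_tr, ny))
        kspace[rows] = frame_k[rows]
    if noise_snr is not None:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        used = stack[start_tr : start_tr + n_needed]
        sig = float(np.mean(np.abs(used[np.abs(used) > 0]))) if np.any(used) else 1.0
        # image-domain noise sd sig/snr maps to k-space sd via sqrt(N_pixels)
        sd = sig / noise_snr * np.sqrt(ny * nx)
        kspace = kspace + sd * (
            rng.standard_normal(kspace.shape) + 1j * rng.standard_normal(kspace.shape)
        )
    return np.fft.ifft2(np.fft.ifftshift(kspace))


def dwse_signal(
    tissue: TissueParams,
    seq: SequenceParams,
    Delta: float,
    V_trace: np.ndarray | float = 0.0,
) -> complex:
    """Reference diffusion-weighted spin-echo signal with diffusion time ``Delta``.

    Magnitude attenuation is exp(-b D) with b = q^2 (Delta - delta/3);
    motion between the two gradient lobes adds the pure phase q * (net
    displacement along the gradient), leaving the magnitude untouched.
    ``V_trace`` may be a scalar velocity or an array of velocities uniformly
    sampling the interval ``Delta``.  Transverse relaxation is applied over
    the Delta + delta interval from excitation to echo.
    """
    _require(Delta >= seq.delta, "Delta must be >= delta")
    q = seq.q
    b = q**2 * (Delta - seq.delta / 3.0)
    V = np.atleast_1d(np.asarray(V_trace, dtype=float))
    displacement = float(np.sum(V) * (Delta / len(V)))
    relax = np.exp(-(Delta + seq.delta) / tissue.T2)
    return complex(relax * np.exp(-b * tissue.D) * np.exp(-1j * q * displacement))


def icosahedral_directions() -> np.ndarray:
    """12 unit vectors from icosahedron vertices (a standard well-spread
    diffusion-encoding scheme)."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = []
    for s1 in (1, -1):
        for s2 in (1, -1):
            verts.append([0.0, s1 * 1.0, s2 * phi])
            verts.append([s1 * 1.0, s2 * phi, 0.0])
            verts.append([s2 * phi, 0.0, s1 * 1.0])
    v = np.array(verts)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def tensor_from_adc(
    adc: np.ndarray,
    directions: np.ndarray,
    weights: np.ndarray | None = None,
) -> TensorResult:
    """Fit a symmetric diffusion tensor to per-direction ADCs.

    Solves ``adc_i = g_i^T T g_i`` for the six unique tensor elements by
    (optionally inverse-variance weighted) linear least squares, then
    eigen-decomposes.  ``adc`` has shape (n_dir,) or (n_dir, ...) for maps;
    ``weights`` matches ``adc``'s shape or is (n_dir,).
    """
    g = np.asarray(directions, dtype=float)
    adc = np.asarray(adc, dtype=float)
    n_dir = g.shape[0]
    _require(g.shape == (n_dir, 3), "directions must be (n_dir, 3)")
    _require(adc.shape[0] == n_dir, "adc first axis must match directions")
    if n_dir < 6:
        raise InvalidParameterError("at least 6 directions required")
    A = np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )
    if np.linalg.matrix_rank(A) < 6:
        raise InvalidParameterError("direction set is rank deficient")
    spatial = adc.shape[1:]
    y = adc.reshape(n_dir, -1)
    if weights is None:
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape == (n_dir,):
            w = np.broadcast_to(w[:, None], y.shape)
        else:
            w = w.reshape(n_dir, -1)
        coef = np.empty((6, y.shape[1]))
        for i in range(y.shape[1]):
            sw = np.sqrt(w[:, i])
            coef[:, i], *_ = np.linalg.lstsq(A * sw[:, None], y[:, i] * sw, rcond=None)
    xx, yy_, zz, xy, xz, yz = coef
    T = np.empty((y.shape[1], 3, 3))
    T[:, 0, 0], T[:, 1, 1], T[:, 2, 2] = xx, yy_, zz
    T[:, 0, 1] = T[:, 1, 0] = xy
    T[:, 0, 2] = T[:, 2, 0] = xz
    T[:, 1, 2] = T[:, 2, 1] = yz
    evals, evecs = np.linalg.eigh(T)  # ascending
    L1, L2, L3 = evals[:, 2], evals[:, 1], evals[:, 0]
    V1 = evecs[:, :, 2]
    MD = (L1 + L2 + L3) / 3.0
    num = (L1 - MD) ** 2 + (L2 - MD) ** 2 + (L3 - MD) ** 2
    den = L1**2 + L2**2 + L3**2
    with np.errstate(invalid="ignore", divide="ignore"):
        FA = np.sqrt(1.5 * num / den)
    FA = np.where(den > 0, FA, 0.0)

    def rs(a, extra=()):
        return a.reshape(spatial + tuple(extra)) if spatial else (a[0] if not extra else a.reshape(extra))

    return TensorResult(
        tensor=T.reshape(spatial + (3, 3)) if spatial else T[0],
        L1=rs(L1),
        L2=rs(L2),
        L3=rs(L3),
        MD=rs(MD),
        FA=rs(FA),
        V1=V1.reshape(spatial + (3,)) if spatial else V1[0],
    )
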