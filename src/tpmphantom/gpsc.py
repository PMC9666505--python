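"""Weak-scattering baseline: Direct Inversion and Gerchberg-Papoulis.

Direct Inversion (the Wolf transform) maps each measured complex field,
linearised with the Rytov approximation, onto an Ewald-sphere cap in the
object's 3D frequency space via the Fourier Diffraction Theorem, then
inverse-transforms the partially filled spectrum.  Under the 47°
circular scan the coverage has the classic missing cone around the
axial frequency axis, which elongates features axially and
underestimates RI.

The Gerchberg-Papoulis loop with support constraint (GPSC) iteratively
repairs the missing cone: alternate between the signal domain (clamp
Δn ≥ 0, zero outside a binary object support) and the frequency domain
(replenish the measured Ewald caps with the original data).  The
support mask comes from binarising a strongly TV-regularised initial
reconstruction (Chambolle-Pock primal-dual solver on the same
linearised data).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.restoration import unwrap_phase

from .forward import ProjectionSet
from .geometry import RIVolume
from .regularize import ReconHistory, dynamics, should_stop, _grad, _div

logger = logging.getLogger(__name__)

__all__ = [
    "FrequencyCoverage",
    "SupportMask",
    "direct_inversion",
    "tv_initial_reconstruction",
    "make_support",
    "gpsc_reconstruct",
]


@dataclass
class FrequencyCoverage:
    """Ewald-cap coverage of the reconstruction frequency grid.

    ``accumulated_spectrum`` holds the *sum* of all cap samples per
    frequency voxel and ``weights`` the hit counts; the averaged
    measured spectrum is ``accumulated_spectrum / weights`` on the
    filled set.
    """

    filled_mask: np.ndarray
    accumulated_spectrum: np.ndarray
    weights: np.ndarray

    @property
    def averaged(self) -> np.ndarray:
        out = np.zeros_like(self.accumulated_spectrum)
        m = self.filled_mask
        out[m] = self.accumulated_spectrum[m] / self.weights[m]
        return out

    @property
    def filled_fraction(self) -> float:
        return float(self.filled_mask.mean())


@dataclass
class SupportMask:
    """Binary object support on the reconstruction grid."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not np.any(self.mask):
            raise ValueError("support mask is empty")


def _centered_origin(shape, pitch) -> np.ndarray:
    return np.array([-(n // 2 + 0.5) * p for n, p in zip(shape, pitch)])


def _rytov_field(values: np.ndarray, floor_rel: float = 1e-6) -> np.ndarray:
    """Complex Rytov log of a normalised total field, phase-unwrapped."""
    amp = np.abs(values)
    floor = floor_rel * amp.max()
    n_floored = int(np.count_nonzero(amp < floor))
    if n_floored:
        logger.warning("Rytov amplitude floor applied to %d pixels", n_floored)
    amp = np.maximum(amp, floor)
    phase = np.asarray(unwrap_phase(np.angle(values)))
    # remove a possible global 2π offset using the (object-free) border
    border = np.concatenate([phase[0], phase[-1], phase[:, 0], phase[:, -1]])
    phase -= 2.0 * np.pi * np.round(np.median(border) / (2.0 * np.pi))
    return np.log(amp) + 1j * phase


def direct_inversion(
    pset: ProjectionSet,
    nz: int | None = None,
    symmetrize: bool = True,
) -> tuple[RIVolume, FrequencyCoverage]:
    """Single-pass Fourier-Diffraction-Theorem reconstruction.

    Per projection the Rytov-linearised scattered spectrum is placed on
    the Ewald cap shifted by the illumination vector; multiply-hit
    frequency voxels are averaged (nearest-voxel gridding).  The inverse
    FFT of the filled spectrum gives the scattering potential, converted
    to Δn; output RI is ``n_immersion + Δn``.

    With ``symmetrize=True`` (default) every cap sample is also
    deposited, conjugated, at the mirrored frequency −K: the scattering
    potential of a lossless object is real, so its spectrum is
    Hermitian, and enforcing that symmetry keeps the accumulated
    spectrum exactly consistent with the real-valued volume the
    Gerchberg-Papoulis loop iterates on.

    The reconstruction grid is ``(nx, ny, nz)`` at the (isotropic) field
    pixel pitch, ``nz`` defaulting to ``nx``.
    """
    cfg = pset.config
    nx, ny = pset.fields.shape[1:]
    if nz is None:
        nz = nx
    pitch = float(pset.pixel_pitch[0])
    if abs(pset.pixel_pitch[1] - pitch) > 1e-12:
        raise ValueError("direct inversion expects isotropic pixel pitch")

    lam = cfg.wavelength_um
    k0 = 2.0 * np.pi / lam
    k_m = cfg.k_medium

    kx = 2.0 * np.pi * np.fft.fftfreq(nx, d=pitch)
    ky = 2.0 * np.pi * np.fft.fftfreq(ny, d=pitch)
    kzg = 2.0 * np.pi * np.fft.fftfreq(nz, d=pitch)
    dkz = 2.0 * np.pi / (nz * pitch)
    kz_nyq = np.abs(kzg).max()

    P_x = kx[:, None]
    P_y = ky[None, :]

    F_sum = np.zeros((nx, ny, nz), dtype=np.complex128)
    counts = np.zeros((nx, ny, nz), dtype=np.int64)
    ix_grid, iy_grid = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")

    for i in range(pset.n_projections):
        s = pset.directions[i]
        psi = _rytov_field(pset.fields[i])
        # continuous-FT normalisation of the 2D spectrum
        Psi = np.fft.fft2(np.fft.ifftshift(psi)) * pitch * pitch
        qx = P_x + k_m * s[0]
        qy = P_y + k_m * s[1]
        qt2 = qx * qx + qy * qy
        valid = qt2 < k_m * k_m
        if cfg.pupil:
            valid &= qt2 <= cfg.k_na**2
        qz = np.sqrt(np.maximum(k_m * k_m - qt2, 0.0))
        Kz = qz - k_m * s[2]
        valid &= np.abs(Kz) <= kz_nyq + 0.5 * dkz
        # Fourier Diffraction Theorem (first-order / Rytov):
        # F(K) = -2 i qz * FT2[u0 * psi_R] evaluated on the Ewald cap
        vals = (-2j * qz * Psi)[valid]
        iz = np.round(Kz[valid] / dkz).astype(np.int64) % nz
        flat = (ix_grid[valid] * ny + iy_grid[valid]) * nz + iz
        np.add.at(F_sum.reshape(-1), flat, vals)
        np.add.at(counts.reshape(-1), flat, 1)

    if symmetrize:
        axes = (0, 1, 2)
        F_sum = F_sum + np.conj(np.roll(np.flip(F_sum, axis=axes), 1, axis=axes))
        counts = counts + np.roll(np.flip(counts, axis=axes), 1, axis=axes)
    mask = counts > 0
    coverage = FrequencyCoverage(mask, F_sum, counts)
    F_avg = coverage.averaged
    f = np.fft.fftshift(np.fft.ifftn(F_avg)) / pitch**3
    dn = np.real(f) / (2.0 * cfg.n_immersion * k0 * k0)
    vol = RIVolume(
        cfg.n_immersion + dn,
        np.full(3, pitch),
        _centered_origin((nx, ny, nz), np.full(3, pitch)),
    )
    return vol, coverage


# ---------------------------------------------------------------------------
# TV-regularised initial reconstruction (Chambolle-Pock)
# ---------------------------------------------------------------------------

def tv_initial_reconstruction(
    pset: ProjectionSet,
    tv_weight: float = 1e-2,
    n_iter: int = 100,
    coverage: FrequencyCoverage | None = None,
    di_volume: RIVolume | None = None,
) -> RIVolume:
    """TV-regularised solve of the linearised tomographic problem.

    Minimises ``0.5 ||A x - b||² + tv_weight TV(x)`` with Chambolle-Pock
    primal-dual iterations, where A samples the (orthonormal) 3D FFT of
    the Δn volume on the measured Ewald-cap frequencies and b is the
    measured spectrum there.  With ``tv_weight = 0`` this converges to
    the minimum-norm (zero-filled) solution, i.e. Direct Inversion.

    A strong weight (default 1e-2) produces the deliberately smooth
    volume used for support generation.
    """
    if di_volume is None or coverage is None:
        di_volume, coverage = direct_inversion(pset)
    n_m = pset.config.n_immersion
    x_di = di_volume.values - n_m
    mask = coverage.filled_mask

    def A(x):
        return np.fft.fftn(np.fft.ifftshift(x), norm="ortho")[mask]

    def AH(y):
        Y = np.zeros(mask.shape, dtype=np.complex128)
        Y[mask] = y
        return np.fft.fftshift(np.fft.ifftn(Y, norm="ortho")).real

    b = A(x_di)

    # ||A|| = 1 (orthonormal FFT restriction), ||grad||^2 <= 12
    L = np.sqrt(13.0)
    tau = sigma = 1.0 / L
    x = np.zeros_like(x_di)
    x_bar = x.copy()
    y1 = np.zeros_like(b)
    y2 = np.zeros((3,) + x.shape)

    prev_change = np.inf
    n_increase = 0
    for it in range(n_iter):
        y1 = (y1 + sigma * (A(x_bar) - b)) / (1.0 + sigma)
        g = y2 + sigma * _grad(x_bar)
        mag = np.sqrt((g**2).sum(axis=0))
        y2 = g / np.maximum(1.0, mag / tv_weight) if tv_weight > 0 else np.zeros_like(g)
        x_new = x - tau * (AH(y1) - _div(y2))
        change = float(np.linalg.norm(x_new - x))
        x_bar = 2.0 * x_new - x
        x = x_new
        if change > prev_change:
            n_increase += 1
            if n_increase >= 50:
                warnings.warn(
                    "TV initial reconstruction not converging; returning "
                    "current iterate",
                    RuntimeWarning,
                )
                break
        else:
            n_increase = 0
        prev_change = change
    return RIVolume(n_m + x, di_volume.voxel_pitch.copy(), di_volume.origin.copy())


def make_support(
    init: RIVolume,
    method: str = "otsu",
    dilation: int = 2,
    closing: int = 0,
) -> SupportMask:
    """Binarise an initial reconstruction into an object support.

    Otsu threshold on the RI histogram, keep the largest connected
    component, optionally close by ``closing`` voxels (to bridge the
    pores of sparse microstructure such as the rod lattice, so the
    support outlines the object envelope), fill enclosed cavities, and
    morphologically dilate by ``dilation`` voxels.
    """
    vals = init.values
    if not np.all(np.isfinite(vals)):
        raise ValueError("initial volume must be finite")
    if method != "otsu":
        raise ValueError(f"unknown binarization method {method!r}")
    if np.ptp(vals) == 0:
        raise ValueError("no object detected: constant volume")
    thr = threshold_otsu(vals)
    mask = vals > thr
    if not np.any(mask):
        raise ValueError("no object detected: empty mask after threshold")
    if closing > 0:
        padded = np.pad(mask, closing)
        padded = ndimage.binary_closing(padded, iterations=closing)
        mask = padded[tuple(slice(closing, -closing) for _ in range(3))]
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    if dilation > 0:
        mask = ndimage.binary_dilation(mask, iterations=dilation)
    return SupportMask(mask)


# ---------------------------------------------------------------------------
# Gerchberg-Papoulis iterations
# ---------------------------------------------------------------------------

def gpsc_reconstruct(
    pset: ProjectionSet,
    support: SupportMask,
    eps: float = 0.02,
    init: RIVolume | None = None,
    coverage: FrequencyCoverage | None = None,
    max_iter: int = 200,
) -> tuple[RIVolume, ReconHistory]:
    """Gerchberg-Papoulis missing-cone recovery with object support.

    Each iteration replenishes the measured Ewald-cap frequencies with
    the original data, then applies the signal-domain constraints
    (Δn ≥ 0, zero outside support).  Terminates when the median of the
    last 10 relative dynamics drops below ``eps`` (default 0.02).
    """
    if init is None or coverage is None:
        di, cov = direct_inversion(pset)
        init = init if init is not None else di
        coverage = coverage if coverage is not None else cov
    if init.values.shape != coverage.filled_mask.shape:
        raise ValueError("init volume and coverage grids differ")
    if support.mask.shape != init.values.shape:
        raise ValueError("support and volume grids differ")

    cfg = pset.config
    k0 = 2.0 * np.pi / cfg.wavelength_um
    pitch = float(init.voxel_pitch[0])
    scale = 2.0 * cfg.n_immersion * k0 * k0 * pitch**3
    # measured Δn-spectrum in plain-FFT convention
    D_meas = coverage.averaged / scale
    mask = coverage.filled_mask

    x = init.values - cfg.n_immersion
    X = np.fft.fftn(np.fft.ifftshift(x))
    history = ReconHistory(eps=eps)
    first_step_norm: float | None = None
    for it in range(max_iter):
        X[mask] = D_meas[mask]  # frequency-domain replenishment
        x_new = np.real(np.fft.fftshift(np.fft.ifftn(X)))
        np.maximum(x_new, 0.0, out=x_new)  # nonnegativity
        x_new[~support.mask] = 0.0  # finite object support
        X = np.fft.fftn(np.fft.ifftshift(x_new))
        # data misfit of the constrained iterate: non-increasing because
        # both constraint steps are projections onto convex sets
        misfit = float(np.linalg.norm(X[mask] - D_meas[mask]))
        step = float(np.linalg.norm(x_new - x))
        if first_step_norm is None:
            # a numerically-zero first step means the input was already a
            # fixed point of both constraint sets
            tiny = 1e-12 * max(1.0, float(np.linalg.norm(x_new)))
            first_step_norm = step if step > tiny else 0.0
        history.record(dynamics(x_new, x, first_step_norm), misfit)
        x = x_new
        if should_stop(history, eps):
            history.stopped_at = it + 1
            break
    vol = RIVolume(cfg.n_immersion + x, init.voxel_pitch.copy(), init.origin.copy())
    return vol, history
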