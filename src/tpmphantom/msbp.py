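"""Multiple-scattering reconstruction by multi-slice beam propagation.

MSBP-E (the Learning-Tomography loop) fits the 3D refractive index to
the measured complex fields by gradient descent: simulate every
projection through the current RI estimate with the multi-slice forward
model, backpropagate the field misfit through the slice stack (the
exact adjoint of the forward model) to get the gradient, take a
sequential per-projection step, and regularise each full cycle with a
weak TV proximal step.  The electric-field variant starts from the
Direct Inversion volume; the intensity-only variant (MSBP-I) consumes
measurement amplitudes alone and starts from zeros.

Both variants share the median-dynamics stopping rule (ε = 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import ProjectionSet, _propagation_kernel, _pupil_mask, msbp_forward
from .geometry import RIVolume
from .gpsc import direct_inversion, _centered_origin
from .regularize import ReconHistory, dynamics, should_stop, tv_prox

__all__ = ["MsbpSettings", "msbp_residual", "msbp_gradient", "msbp_reconstruct"]


@dataclass
class MsbpSettings:
    """Solver configuration for the MSBP reconstructions.

    ``step_size`` is a dimensionless relaxation factor: the actual
    gradient step is ``step_size / (gamma^2 * nz)`` with
    ``gamma = 2π dz/λ``, which makes the update scale-free in grid size
    and wavelength.  ``mode="field"`` defaults to a Direct Inversion
    initial guess, ``mode="intensity"`` to zeros.
    """

    mode: str = "field"  # "field" | "intensity"
    step_size: float = 0.5
    tv_weight: float = 1e-4
    eps: float = 0.01
    max_iter: int = 60
    init: str | None = None  # "direct_inversion" | "zeros"; None = per-mode default
    nonneg: bool = True

    def validate(self) -> None:
        if self.mode not in ("field", "intensity"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.tv_weight < 0:
            raise ValueError("tv_weight must be >= 0")

    @property
    def init_effective(self) -> str:
        if self.init is not None:
            return self.init
        return "direct_inversion" if self.mode == "field" else "zeros"


def _residual_field(sim: np.ndarray, meas: np.ndarray, mode: str) -> tuple[float, np.ndarray]:
    """Misfit and Wirtinger residual dM/dd* for one projection."""
    if mode == "field":
        r = sim - meas
        return float(np.sum(np.abs(r) ** 2)), r
    if mode == "intensity":
        amp = np.abs(meas)
        mag = np.abs(sim)
        safe = np.maximum(mag, 1e-12)
        r = (mag - amp) * sim / safe
        return float(np.sum((mag - amp) ** 2)), r
    raise ValueError(f"unknown mode {mode!r}")


def msbp_residual(
    volume: RIVolume,
    pset: ProjectionSet,
    mode: str = "field",
) -> tuple[float, list[np.ndarray]]:
    """Total data misfit and per-projection residual fields.

    Field mode: ``Σ ||simulated − measured||²``; intensity mode:
    ``Σ (|simulated| − |measured|)²`` (amplitude misfit — only the
    measurement amplitudes are consumed).  The returned residuals are
    the Wirtinger derivatives of the misfit w.r.t. the simulated field,
    as needed by :func:`msbp_gradient`.
    """
    total = 0.0
    residuals: list[np.ndarray] = []
    for i in range(pset.n_projections):
        sim = msbp_forward(volume, pset.directions[i], pset.config)
        m, r = _residual_field(sim.values, pset.fields[i], mode)
        total += m
        residuals.append(r)
    return total, residuals


def _backpropagate_one(
    volume: RIVolume,
    residual: np.ndarray,
    direction: np.ndarray,
    config,
    slices: list[np.ndarray] | None = None,
    s_eff: np.ndarray | None = None,
) -> np.ndarray:
    """Adjoint of the multi-slice model for one projection's residual."""
    nx, ny, nz = volume.shape
    pitch = volume.voxel_pitch
    dz = pitch[2]
    k_m = config.k_medium
    gamma = 2.0 * np.pi * dz / config.wavelength_um

    if slices is None or s_eff is None:
        _, slices, s_eff = msbp_forward(volume, direction, config, return_slices=True)
    gamma = gamma / s_eff[2]  # slant-path screen, matching the forward model
    dn = volume.values - config.n_immersion

    # chain rule through the normalisation d = v / u0_mid with |u0| = 1
    kz_ill = k_m * s_eff[2]
    x = (np.arange(nx) - nx // 2)[:, None] * pitch[0]
    y = (np.arange(ny) - ny // 2)[None, :] * pitch[1]
    u0_mid = np.exp(1j * (k_m * (s_eff[0] * x + s_eff[1] * y) + kz_ill * 0.5 * nz * dz))
    lam_v = residual / np.conj(u0_mid)

    spec = np.fft.fft2(lam_v)
    if config.pupil:
        spec = spec * _pupil_mask((nx, ny), pitch[:2], config.k_na)
    # adjoint of propagation by distance d is propagation by -d
    spec = spec * _propagation_kernel((nx, ny), pitch[:2], 0.5 * nz * dz, k_m)
    lam = np.fft.ifft2(spec)

    back_kernel = _propagation_kernel((nx, ny), pitch[:2], -dz, k_m)
    grad = np.zeros((nx, ny, nz))
    for k in range(nz - 1, -1, -1):
        lam = np.fft.ifft2(np.fft.fft2(lam) * back_kernel)
        t = np.exp(1j * gamma * dn[:, :, k])
        w = slices[k] * t
        grad[:, :, k] = 2.0 * np.real(np.conj(lam) * 1j * gamma * w)
        lam = lam * np.conj(t)
    return grad


def msbp_gradient(
    volume: RIVolume,
    residuals: list[np.ndarray],
    pset: ProjectionSet,
    mode: str = "field",
) -> np.ndarray:
    """Gradient of the data misfit w.r.t. the voxel RI values.

    The residual of each projection is backpropagated slice-by-slice
    through the current sample estimate (exact adjoint of the forward
    chain) and the contributions summed over projections.
    """
    del mode  # the mode already shaped the residuals
    grad = np.zeros(volume.shape)
    for i, r in enumerate(residuals):
        grad += _backpropagate_one(volume, r, pset.directions[i], pset.config)
    return grad


def msbp_reconstruct(
    pset: ProjectionSet,
    settings: MsbpSettings | None = None,
    init_volume: RIVolume | None = None,
) -> tuple[RIVolume, ReconHistory]:
    """Iterative MSBP reconstruction (Learning-Tomography style).

    One outer iteration sweeps all projections in fixed cyclic order,
    taking a gradient step after each (stochastic-gradient style), then
    applies the TV proximal map and an optional nonnegativity projection
    on Δn.  The step is halved whenever the cycle misfit increases;
    twenty consecutive increases raise ``RuntimeError``.  Stops via the
    shared median-dynamics criterion (ε = 0.01 by default).
    """
    if settings is None:
        settings = MsbpSettings()
    settings.validate()
    cfg = pset.config
    nx, ny = pset.fields.shape[1:]
    nz = nx
    pitch = float(pset.pixel_pitch[0])

    if init_volume is not None:
        x = init_volume.values - cfg.n_immersion
        origin = init_volume.origin.copy()
        nz = init_volume.shape[2]
    elif settings.init_effective == "direct_inversion":
        init_vol, _ = direct_inversion(pset)
        x = init_vol.values - cfg.n_immersion
        origin = init_vol.origin.copy()
    elif settings.init_effective == "zeros":
        x = np.zeros((nx, ny, nz))
        origin = _centered_origin((nx, ny, nz), np.full(3, pitch))
    else:
        raise ValueError(f"unknown init {settings.init_effective!r}")

    gamma = 2.0 * np.pi * pitch / cfg.wavelength_um
    alpha = settings.step_size / (gamma * gamma * nz)

    history = ReconHistory(eps=settings.eps)
    first_step_norm: float | None = None
    prev_misfit = np.inf
    n_increase = 0
    pitch3 = np.full(3, pitch)

    for it in range(settings.max_iter):
        x_prev = x.copy()
        cycle_misfit = 0.0
        for i in range(pset.n_projections):
            vol = RIVolume(cfg.n_immersion + x, pitch3, origin)
            sim, slices, s_eff = msbp_forward(
                vol, pset.directions[i], cfg, return_slices=True
            )
            m, r = _residual_field(sim.values, pset.fields[i], settings.mode)
            cycle_misfit += m
            if m == 0.0:
                continue
            grad = _backpropagate_one(
                vol, r, pset.directions[i], cfg, slices=slices, s_eff=s_eff
            )
            x = x - alpha * grad
        if settings.tv_weight > 0:
            x = tv_prox(x, settings.tv_weight, n_inner=20)
        if settings.nonneg:
            np.maximum(x, 0.0, out=x)

        step = float(np.linalg.norm(x - x_prev))
        if first_step_norm is None:
            tiny = 1e-12 * max(1.0, float(np.linalg.norm(x)))
            first_step_norm = step if step > tiny else 0.0
        history.record(dynamics(x, x_prev, first_step_norm), cycle_misfit)

        if cycle_misfit > prev_misfit:
            n_increase += 1
            alpha *= 0.5
            if n_increase >= 20:
                raise RuntimeError("step size too large: misfit diverging")
        else:
            n_increase = 0
        prev_misfit = cycle_misfit

        if should_stop(history, settings.eps):
            history.stopped_at = it + 1
            break

    vol = RIVolume(cfg.n_immersion + x, pitch3, origin)
    return vol, history
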