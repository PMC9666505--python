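"""Shared total-variation machinery and the median-dynamics stopping rule.

Every reconstruction loop in this package terminates the same way: the
per-iteration "dynamics" — the norm of the change between consecutive
volume estimates, normalised by the norm of the first step — is
recorded, and iteration stops once the median of the last 10 dynamics
values drops below a saturation level ``eps``.  Normalising by the first
step makes ``eps`` scale-free, so the same thresholds work across
algorithms and RI scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ReconHistory", "tv_prox", "total_variation", "dynamics", "should_stop"]

STOP_WINDOW = 10


@dataclass
class ReconHistory:
    """Per-iteration record driving the stopping criterion."""

    dynamics: list[float] = field(default_factory=list)
    misfit: list[float] = field(default_factory=list)
    eps: float = 0.0
    stopped_at: int | None = None

    @property
    def n_iter(self) -> int:
        return len(self.dynamics)

    def record(self, dyn: float, misfit: float) -> None:
        if dyn < 0:
            raise ValueError("dynamics must be non-negative")
        self.dynamics.append(float(dyn))
        self.misfit.append(float(misfit))

    def to_dict(self) -> dict:
        return {
            "dynamics": list(self.dynamics),
            "misfit": list(self.misfit),
            "eps": self.eps,
            "stopped_at": self.stopped_at,
        }


def _grad(u: np.ndarray) -> np.ndarray:
    """Forward-difference gradient with Neumann boundary, shape (3, ...)."""
    g = np.zeros((3,) + u.shape, dtype=u.dtype)
    g[0, :-1] = u[1:] - u[:-1]
    g[1, :, :-1] = u[:, 1:] - u[:, :-1]
    g[2, :, :, :-1] = u[:, :, 1:] - u[:, :, :-1]
    return g


def _div(p: np.ndarray) -> np.ndarray:
    """Divergence, negative adjoint of :func:`_grad`."""
    d = np.zeros(p.shape[1:], dtype=p.dtype)
    d[:-1] += p[0, :-1]
    d[1:] -= p[0, :-1]
    d[:, :-1] += p[1, :, :-1]
    d[:, 1:] -= p[1, :, :-1]
    d[:, :, :-1] += p[2, :, :, :-1]
    d[:, :, 1:] -= p[2, :, :, :-1]
    return d


def total_variation(u: np.ndarray) -> float:
    """Isotropic total variation (sum of voxel gradient magnitudes)."""
    g = _grad(np.asarray(u, dtype=np.float64))
    return float(np.sqrt((g**2).sum(axis=0)).sum())


def tv_prox(volume: np.ndarray, weight: float, n_inner: int = 20) -> np.ndarray:
    """Approximate proximal map of isotropic TV (Rudin-Osher-Fatemi).

    Solves ``argmin_u 0.5 ||u - v||^2 + weight * TV(u)`` with the dual
    projection algorithm of Chambolle (fixed number of inner iterations,
    dual step 1/12 for the 3D stencil).  ``weight`` is in the same units
    as the volume values.
    """
    if weight < 0:
        raise ValueError("weight must be >= 0")
    v = np.asarray(volume, dtype=np.float64)
    if weight == 0 or n_inner <= 0:
        return v.copy()
    tau = 1.0 / 12.0
    p = np.zeros((3,) + v.shape)
    for _ in range(n_inner):
        u = _div(p) - v / weight
        g = _grad(u)
        mag = np.sqrt((g**2).sum(axis=0))
        p = (p + tau * g) / (1.0 + tau * mag)
    return v - weight * _div(p)


def dynamics(current, previous, first_step_norm: float) -> float:
    """Relative change between consecutive volume estimates.

    ``||current - previous||_2 / first_step_norm`` where
    ``first_step_norm`` is the norm of the very first update; a zero
    first step means the iteration converged immediately and the
    dynamics is defined as 0.
    """
    cur = np.asarray(getattr(current, "values", current), dtype=np.float64)
    prev = np.asarray(getattr(previous, "values", previous), dtype=np.float64)
    if cur.shape != prev.shape:
        raise ValueError("volumes must share a grid")
    if first_step_norm == 0:
        return 0.0
    if first_step_norm < 0:
        raise ValueError("first_step_norm must be positive")
    return float(np.linalg.norm(cur - prev) / first_step_norm)


def should_stop(history: ReconHistory, eps: float) -> bool:
    """Stop once the median of the last 10 dynamics falls below ``eps``.

    Never stops before 10 iterations have been recorded (the median
    needs a full window); even-length medians use the standard midpoint
    of the two central order statistics.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if history.n_iter < STOP_WINDOW:
        return False
    return float(np.median(history.dynamics[-STOP_WINDOW:])) < eps
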