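"""Shared level-set machinery.

A region is represented implicitly as the positive set of a scalar field
``phi`` kept close to a signed distance function (SDF): ``phi > 0`` inside
the region, ``phi < 0`` outside, ``|phi|`` approximately the Euclidean
distance (in pixels) to the region boundary.  The smooth Heaviside
``H_eps`` and its derivative ``delta_eps`` regularize the region indicator
so segmentation energies are differentiable; gradient descent on those
energies moves the zero level set.

This module provides the regularized step functions, SDF construction and
maintenance, and a baseline two-phase Chan-Vese evolution that the spatial
(shape-prior) and temporal (region-information) stages both build on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class DegenerateInputError(ValueError):
    """A mask or field without the structure the operation needs."""


class InstabilityError(RuntimeError):
    """Energy descent diverged; usually the time step is too large."""

    def __init__(self, message: str, dt: float):
        super().__init__(message)
        self.dt = dt


def heaviside(z: np.ndarray | float, eps: float = 1.5) -> np.ndarray:
    """Smooth Heaviside ``H_eps(z) = 1/2 (1 + (2/pi) arctan(z/eps))``.

    Monotone increasing, ``H(0) = 0.5`` and ``H(z) + H(-z) = 1``.
    ``eps`` (pixels) sets the width of the transition band.
    """
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    return 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(np.asarray(z, dtype=float) / eps))


def dirac(z: np.ndarray | float, eps: float = 1.5) -> np.ndarray:
    """Smooth Dirac delta: the analytic derivative of :func:`heaviside`.

    ``delta_eps(z) = eps / (pi (eps^2 + z^2))``; even, non-negative, and
    integrates to 1 along any line crossing ``z = 0``.
    """
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    z = np.asarray(z, dtype=float)
    return (eps / np.pi) / (eps * eps + z * z)


def signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed distance field of a binary mask, positive inside.

    Distances are measured to the region boundary (taken to run halfway
    between the last inside and first outside pixel, hence the 0.5 pixel
    offset), so a pixel adjacent to the boundary has ``|phi| = 0.5``.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise DegenerateInputError("mask is empty")
    if mask.all():
        raise DegenerateInputError("mask covers the whole frame")
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return np.where(mask, inside - 0.5, -(outside - 0.5))


def reinitialize(phi: np.ndarray) -> np.ndarray:
    """Restore the SDF property while keeping the current region.

    The far field is rebuilt from the sign mask of ``phi``; in the band of
    pixels touching the interface the sub-pixel front position is kept via
    the local linear estimate ``phi / |grad phi|`` (a grid-snapped rebuild
    there would erase the progress of a slowly moving front between
    reinitializations).  The zero level set moves by less than one pixel
    and ``|grad phi| ~ 1`` is restored.
    """
    phi = np.asarray(phi, dtype=float)
    pos = phi > 0
    if not pos.any() or pos.all():
        raise DegenerateInputError("phi has no zero crossing")
    out = signed_distance(pos)
    band = np.zeros_like(pos)
    band[:-1, :] |= pos[:-1, :] != pos[1:, :]
    band[1:, :] |= pos[1:, :] != pos[:-1, :]
    band[:, :-1] |= pos[:, :-1] != pos[:, 1:]
    band[:, 1:] |= pos[:, 1:] != pos[:, :-1]
    gy, gx = np.gradient(phi)
    grad = np.maximum(np.sqrt(gx * gx + gy * gy), 0.2)
    delta = np.clip(phi / grad, -1.5, 1.5)
    # keep the sign so the region itself never changes
    same_sign = (delta > 0) == pos
    keep = band & same_sign & (np.abs(delta) <= np.abs(out))
    out[keep] = delta[keep]
    return out


def curvature(phi: np.ndarray) -> np.ndarray:
    """Mean curvature ``div(grad phi / |grad phi|)``, clipped to [-1, 1]."""
    gy, gx = np.gradient(phi)
    norm = np.sqrt(gx * gx + gy * gy) + 1e-8
    ny_y, _ = np.gradient(gy / norm)
    _, nx_x = np.gradient(gx / norm)
    return np.clip(nx_x + ny_y, -1.0, 1.0)


@dataclass
class ChanVeseParams:
    """Weights and numerics for the two-phase Chan-Vese evolution.

    The underlying energy is

        E = mu * Length(C) + lambda_in  * sum_in  (I - c1)^2
                           + lambda_out * sum_out (I - c2)^2

    with the two region means c1/c2 recomputed every iteration.  The weights are conventional
    Chan-Vese defaults for images normalized to [0, 1].  The explicit
    scheme is stable for ``dt <= 0.45 / mu``.
    """

    lambda_in: float = 1.0
    lambda_out: float = 1.0
    mu: float = 0.2
    eps: float = 1.5
    dt: float = 0.5
    max_iter: int = 200
    tol: float = 1e-3
    reinit_every: int = 10
    stall_window: int = 25

    def __post_init__(self):
        for name in ("lambda_in", "lambda_out", "mu", "eps", "dt", "tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_iter < 1 or self.reinit_every < 1 or self.stall_window < 1:
            raise ValueError("max_iter, reinit_every and stall_window must be >= 1")
        if self.dt > 0.45 / self.mu + 1e-12:
            raise ValueError(
                f"dt={self.dt} violates the stability bound 0.45/mu={0.45 / self.mu:.3g}"
            )


def region_means(
    image: np.ndarray, phi: np.ndarray, eps: float, valid: np.ndarray | None
) -> tuple[float, float]:
    """Inside/outside means of ``image`` weighted by the smooth indicator."""
    h = heaviside(phi, eps)
    w = np.ones_like(h) if valid is None else valid.astype(float)
    win = h * w
    wout = (1.0 - h) * w
    sin_, sout = win.sum(), wout.sum()
    c1 = float((win * image).sum() / sin_) if sin_ > 0 else 0.0
    c2 = float((wout * image).sum() / sout) if sout > 0 else 0.0
    return c1, c2


def _cv_energy(
    image: np.ndarray,
    phi: np.ndarray,
    params: ChanVeseParams,
    valid: np.ndarray | None,
    c1: float,
    c2: float,
) -> float:
    h = heaviside(phi, params.eps)
    gy, gx = np.gradient(phi)
    length = (dirac(phi, params.eps) * np.sqrt(gx * gx + gy * gy)).sum()
    w = 1.0 if valid is None else valid.astype(float)
    data = (
        params.lambda_in * (h * w * (image - c1) ** 2).sum()
        + params.lambda_out * ((1.0 - h) * w * (image - c2) ** 2).sum()
    )
    return float(params.mu * length + data)


@dataclass
class IterationRecord:
    iteration: int
    energy: float
    dt: float
    changed_fraction: float


def evolve_chan_vese(
    image: np.ndarray,
    phi: np.ndarray,
    params: ChanVeseParams | None = None,
    valid: np.ndarray | None = None,
    extra=None,
) -> tuple[np.ndarray, list[IterationRecord]]:
    """Gradient descent on the Chan-Vese energy, optionally plus an extra term.

    ``extra`` is any object exposing ``prepare(phi)`` (per-iteration state
    update, e.g. pose recomputation), ``force(phi)`` (an additive force
    field, already carrying its sign so it is *added* to ``d phi/dt``) and
    ``energy(phi)`` (the extra term's value, for the monotonicity check).

    A backtracking step halves the local time step when a trial update
    raises the total energy, so the energy trace is non-increasing up to
    round-off; ten consecutive uphill steps raise :class:`InstabilityError`.
    Invalid pixels (``valid == 0``) carry no data force and are excluded
    from the region means.

    Returns the evolved field and a per-iteration log.
    """
    if params is None:
        params = ChanVeseParams()
    image = np.asarray(image, dtype=float)
    phi = np.asarray(phi, dtype=float).copy()
    if image.shape != phi.shape:
        raise ValueError(f"image shape {image.shape} != phi shape {phi.shape}")
    if valid is not None:
        valid = np.asarray(valid).astype(bool)
    vmask = None if valid is None else valid.astype(float)

    def total_energy(p: np.ndarray) -> float:
        c1, c2 = region_means(image, p, params.eps, valid)
        e = _cv_energy(image, p, params, valid, c1, c2)
        if extra is not None:
            e += extra.energy(p)
        return e

    log: list[IterationRecord] = []
    rises = 0
    snapshot = phi.copy()
    for it in range(params.max_iter):
        if extra is not None:
            extra.prepare(phi)
        c1, c2 = region_means(image, phi, params.eps, valid)
        e_here = _cv_energy(image, phi, params, valid, c1, c2)
        if extra is not None:
            e_here += extra.energy(phi)

        data = -params.lambda_in * (image - c1) ** 2 + params.lambda_out * (image - c2) ** 2
        if vmask is not None:
            data = data * vmask
        force = dirac(phi, params.eps) * (params.mu * curvature(phi) + data)
        if extra is not None:
            force = force + extra.force(phi)

        dt_local = params.dt
        phi_new = phi + dt_local * force
        e_new = total_energy(phi_new)
        n_back = 0
        while e_new > e_here + 1e-9 * (1.0 + abs(e_here)) and n_back < 5:
            dt_local *= 0.5
            phi_new = phi + dt_local * force
            e_new = total_energy(phi_new)
            n_back += 1
        if e_new > e_here + 1e-9 * (1.0 + abs(e_here)):
            rises += 1
            if rises >= 10:
                raise InstabilityError(
                    f"energy increased for {rises} consecutive steps; "
                    f"time step dt={params.dt} is likely too large",
                    dt=params.dt,
                )
        else:
            rises = 0

        changed = float(np.mean((phi_new > 0) != (phi > 0)))
        phi = phi_new
        log.append(IterationRecord(it, e_new, dt_local, changed))

        if (it + 1) % params.reinit_every == 0 and (phi > 0).any() and not (phi > 0).all():
            phi = reinitialize(phi)
        # converged once the interface stays put over a whole window of
        # iterations AND the field has stopped moving in the interface
        # band: a slowly advancing front (well under a pixel per step)
        # flips pixels in bursts, so quiet steps alone are not evidence
        # of convergence
        w = params.stall_window
        if (it + 1) % w == 0:
            quiet = sum(r.changed_fraction for r in log[-w:]) < params.tol
            if quiet:
                band = np.abs(phi) < 3 * params.eps
                moved = float(np.abs(phi[band] - snapshot[band]).max()) if band.any() else 0.0
                if moved < 0.15:
                    break
            snapshot = phi.copy()
        # at a sharp-contrast optimum the band values keep oscillating
        # under the opposing forces, so also accept a long flip-free run
        if it >= 2 * w - 1 and sum(r.changed_fraction for r in log[-2 * w:]) < params.tol:
            break
    return phi, log
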